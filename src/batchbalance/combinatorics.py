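"""Counting distinct batch layouts.

How many ways are there to allocate n distinguishable samples into the
minimum number m = ceil(n/k) of indistinguishable batches, each holding
at most k samples?  For every integer partition of n into exactly m
parts of size <= k, the number of set partitions with those part sizes
is the multinomial coefficient n! / prod(s_i!) divided by the factorial
of the multiplicity of each repeated part size (batches are unlabelled).
The total is the sum over partitions, accumulated in log-space
(log-factorials and log-sum-exp) so the result stays finite for
hundreds of samples; an exact big-integer count is carried alongside.

Because m is minimal, the total slack m*k - n is below k, so the valid
partitions correspond to the partitions of the slack — enumeration is
cheap at any n.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional

from scipy.special import logsumexp

from .errors import ValidationError


@dataclass(frozen=True)
class LayoutCount:
    """Number of distinct layouts of n samples into m batches of size <= k."""

    n: int
    k: int
    m: int
    log_count: float  #: natural log of the number of layouts
    count: int  #: exact integer count

    @property
    def log10_count(self) -> float:
        return self.log_count / math.log(10)


def _bounded_partitions(total: int, max_parts: int, max_part: int) -> Iterator[list[int]]:
    """Partitions of ``total`` into at most ``max_parts`` parts, each in
    [1, max_part], yielded as descending lists."""

    def rec(remaining: int, parts_left: int, cap: int):
        if remaining == 0:
            yield []
            return
        if parts_left == 0:
            return
        for p in range(min(cap, remaining), 0, -1):
            if p * parts_left < remaining:
                break
            for rest in rec(remaining - p, parts_left - 1, p):
                yield [p] + rest

    yield from rec(total, max_parts, max_part)


def _partitions_exact_parts(n: int, m: int, k: int) -> Iterator[Counter]:
    """Partitions of n into exactly m parts, each <= k, as size->multiplicity
    Counters.  Enumerated through the per-batch deficits d_i = k - s_i,
    which sum to the slack m*k - n (< k since m is minimal)."""
    slack = m * k - n
    if slack == 0:
        yield Counter({k: m})
        return
    for deficits in _bounded_partitions(slack, m, min(k - 1, slack)):
        parts = Counter({k: m - len(deficits)})
        for d in deficits:
            parts[k - d] += 1
        parts.pop(0, None)  # a full deficit (d == k) cannot occur: d <= k-1
        yield parts


def count_layouts(n: int, k: int) -> LayoutCount:
    """Count distinct allocations of n samples into ceil(n/k) batches.

    Returns both the log-space count (the primary, numerically stable
    result) and the exact integer count.
    """
    if n < 1 or k < 1:
        raise ValidationError("n and k must be positive integers")
    m = -(-n // k)
    log_terms = []
    exact = 0
    log_n_fact = math.lgamma(n + 1)
    for parts in _partitions_exact_parts(n, m, k):
        log_term = log_n_fact
        denom = 1
        for size, mult in parts.items():
            log_term -= mult * math.lgamma(size + 1) + math.lgamma(mult + 1)
            denom *= math.factorial(size) ** mult * math.factorial(mult)
        log_terms.append(log_term)
        exact += math.factorial(n) // denom
    return LayoutCount(n=n, k=k, m=m, log_count=float(logsumexp(log_terms)), count=exact)
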