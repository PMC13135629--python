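"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive: exhaustive enumeration and
direct formulas, sharing no code with the package's implementation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# -- exact Fisher p by exhaustive enumeration -------------------------------


def _tables_with_margins(rows, cols):
    """All non-negative integer tables with the given margins."""

    def fill_row(remaining_cols, row_total):
        def rec(j, left, acc):
            if j == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield acc + [left]
                return
            for x in range(min(left, remaining_cols[j]) + 1):
                yield from rec(j + 1, left - x, acc + [x])

        yield from rec(0, row_total, [])

    def rec_rows(i, remaining_cols, acc):
        if i == len(rows) - 1:
            if sum(remaining_cols) == rows[i]:
                yield acc + [list(remaining_cols)]
            return
        for row in fill_row(remaining_cols, rows[i]):
            rem = [c - x for c, x in zip(remaining_cols, row)]
            yield from rec_rows(i + 1, rem, acc + [row])

    yield from rec_rows(0, list(cols), [])


def _log_table_prob(table, rows, cols, n):
    lp = sum(math.lgamma(r + 1) for r in rows) + sum(math.lgamma(c + 1) for c in cols)
    lp -= math.lgamma(n + 1)
    lp -= sum(math.lgamma(x + 1) for row in table for x in row)
    return lp


def fisher_exact_enum_p(table) -> float:
    """Two-sided Fisher p: total probability of all fixed-margin tables at
    most as probable as the observed one."""
    table = [list(map(int, row)) for row in np.asarray(table)]
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    lp_obs = _log_table_prob(table, rows, cols, n)
    p = 0.0
    for t in _tables_with_margins(rows, cols):
        lp = _log_table_prob(t, rows, cols, n)
        if lp <= lp_obs + 1e-7:
            p += math.exp(lp)
    return min(p, 1.0)


def labels_batches_from_table(table):
    """Per-sample (category label, batch label) arrays realizing a table."""
    labels, batches = [], []
    for i, row in enumerate(np.asarray(table)):
        for j, count in enumerate(row):
            labels.extend([f"cat{i}"] * int(count))
            batches.extend([f"batch{j}"] * int(count))
    return np.array(labels, dtype=object), np.array(batches, dtype=object)


# -- set-partition layout counting ------------------------------------------


def count_layouts_enum(n: int, k: int) -> int:
    """Count set partitions of n items into exactly ceil(n/k) unordered
    non-empty parts of size <= k, by sympy enumeration."""
    from sympy.utilities.iterables import multiset_partitions

    m = -(-n // k)
    if m == 1:
        return 1
    total = 0
    for parts in multiset_partitions(list(range(n)), m):
        if max(len(p) for p in parts) <= k:
            total += 1
    return total


# -- brute-force global optimum for two-batch instances ---------------------


def best_two_batch_score(table, batch_size, seed=0, method="harmonic"):
    """Global-optimum balance score over all 2-batch layouts (unordered),
    scored with the package's engine so values are directly comparable."""
    from batchbalance.metrics import BalanceEngine

    n = table.n
    engine = BalanceEngine(table, n_batches=2, method=method, seed=seed)
    best = -np.inf
    lo = max(n - batch_size, 1)
    hi = min(batch_size, n - 1)
    for size0 in range(lo, hi + 1):
        # sample 0 fixed in batch 0: each unordered split enumerated once
        for rest in combinations(range(1, n), size0 - 1):
            batch = np.ones(n, dtype=np.intp)
            batch[0] = 0
            batch[list(rest)] = 0
            best = max(best, engine.score(batch))
    return float(best)
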