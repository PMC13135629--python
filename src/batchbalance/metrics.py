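"""Per-covariate balance tests and the composite balance score.

Balance of a layout is measured per covariate by treating the batch as
the independent variable: a Kruskal-Wallis rank test for continuous
covariates and Fisher's exact test for categorical ones.  The single
objective ("balance score") is by default the harmonic mean of the
per-covariate p-values — in (0, 1], dominated by the worst-balanced
covariate, so one well-balanced covariate cannot compensate for another.
Alternatives: the plain product of p-values (appropriate for independent
covariates), or an effect-size mode using 1 - eta (ANOVA) for continuous
and 1 - Cramer's V for categorical covariates, combined the same way.

Missing metadata is handled by per-covariate complete-case analysis: a
sample missing covariate X is dropped from X's test only, never from the
allocation itself.

Fisher's exact test is exact for 2x2 tables.  For larger r x c tables an
exact network algorithm is impractical at 10-20 batches, so a Monte-Carlo
p-value is computed over tables drawn at fixed margins:
``p = (1 + #{simulated tables at most as probable as observed}) / (B + 1)``.
The null tables are generated by permuting the sorted category-code
vector, so the simulated null depends only on the table margins and the
covariate's sub-seed; sorted null statistics are cached per margin
multiset, which makes repeated scoring during optimization cheap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._seeds import derive_seed
from .errors import ValidationError
from .metadata import CATEGORICAL, CONTINUOUS, Allocation, CovariateSpec, SampleTable

logger = logging.getLogger(__name__)

#: floor applied to per-covariate values before combination, guarding the
#: harmonic mean against degenerate zero p-values
P_FLOOR = 1e-12

#: default number of Monte-Carlo replicates for r x c Fisher tests
DEFAULT_MC_REPLICATES = 10_000

SCORE_METHODS = ("harmonic", "product", "effect_size")


@dataclass
class CovariateResult:
    """Balance of a single covariate under one allocation."""

    name: str
    kind: str
    p_value: Optional[float]
    effect_size: Optional[float]
    n_used: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "n_used": self.n_used,
        }


@dataclass
class BalanceReport:
    """Per-covariate results plus the combined balance score."""

    per_covariate: list[CovariateResult]
    score: float
    method: str

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "method": self.method,
            "per_covariate": [c.to_dict() for c in self.per_covariate],
        }


def combine_scores(values: Sequence[float], method: str = "harmonic") -> float:
    """Combine per-covariate values in (0, 1] into one score.

    ``harmonic``: L / sum(1/v); ``product``: prod(v).  Values <= 0 are
    clamped to ``P_FLOOR`` (with a logged warning) before combining.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot combine an empty list of values")
    if np.any(v > 1.0):
        raise ValidationError(f"values outside (0, 1]: {v[v > 1.0].tolist()}")
    if np.any(v <= 0.0):
        logger.warning("clamping %d non-positive value(s) to %g", int((v <= 0).sum()), P_FLOOR)
        v = np.clip(v, P_FLOOR, None)
    if method == "harmonic":
        return float(len(v) / np.sum(1.0 / v))
    if method == "product":
        return float(np.prod(v))
    raise ValidationError(f"unknown combiner {method!r} (use 'harmonic' or 'product')")


# ---------------------------------------------------------------------------
# continuous covariates: Kruskal-Wallis p-value and eta effect size
# ---------------------------------------------------------------------------


class _ContinuousCovariate:
    """Pre-ranked continuous covariate, re-scored in O(n) per layout.

    Ranks and the tie correction depend only on the values, not on the
    allocation, so they are computed once.
    """

    def __init__(self, name: str, values: np.ndarray, n_batches: int):
        self.name = name
        self.m = n_batches
        values = np.asarray(values, dtype=float)
        self.idx = np.flatnonzero(np.isfinite(values))
        v = values[self.idx]
        self.v = v
        self.N = len(v)
        if self.N >= 2:
            self.ranks = stats.rankdata(v)
            _, tie_counts = np.unique(v, return_counts=True)
            denom = self.N**3 - self.N
            self.tie_correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / denom
            self.ss_total = float(((v - v.mean()) ** 2).sum())
        else:
            self.ranks = np.zeros(self.N)
            self.tie_correction = 0.0
            self.ss_total = 0.0

    def p_value(self, batch: np.ndarray) -> float:
        """Tie-corrected Kruskal-Wallis p (chi-square approximation).

        Batches with no non-missing value are dropped; with fewer than
        two non-empty groups, or all values tied, returns 1 (no
        detectable imbalance).
        """
        if self.N < 2:
            return 1.0
        b = batch[self.idx]
        counts = np.bincount(b, minlength=self.m)
        nz = counts > 0
        g = int(nz.sum())
        if g < 2 or self.tie_correction <= 0.0:
            return 1.0
        rank_sums = np.bincount(b, weights=self.ranks, minlength=self.m)
        h = (
            12.0 / (self.N * (self.N + 1)) * float((rank_sums[nz] ** 2 / counts[nz]).sum())
            - 3.0 * (self.N + 1)
        )
        h = max(h / self.tie_correction, 0.0)
        return float(stats.chi2.sf(h, g - 1))

    def effect(self, batch: np.ndarray) -> float:
        """Eta: sqrt(SS_between / SS_total); 0 for degenerate input."""
        if self.N < 2 or self.ss_total <= 0.0:
            return 0.0
        b = batch[self.idx]
        counts = np.bincount(b, minlength=self.m)
        nz = counts > 0
        if int(nz.sum()) < 2:
            return 0.0
        sums = np.bincount(b, weights=self.v, minlength=self.m)
        ss_between = float((sums[nz] ** 2 / counts[nz]).sum()) - self.v.sum() ** 2 / self.N
        ss_between = min(max(ss_between, 0.0), self.ss_total)
        return math.sqrt(ss_between / self.ss_total)


# ---------------------------------------------------------------------------
# categorical covariates: Fisher's exact test and Cramer's V
# ---------------------------------------------------------------------------


class _FisherNull:
    """Cached Monte-Carlo null for fixed-margin r x c Fisher tests.

    ``B`` permutations of the sorted category codes are drawn once; for
    any column-margin multiset, null tables are obtained by segmenting
    each permutation at the margin boundaries (cumulative counts are
    precomputed per category, so each new margin key costs O(B * m * r)).
    The statistic is sum(log c_ij!): larger means a less probable table
    at fixed margins.
    """

    def __init__(self, codes: np.ndarray, n_categories: int, mc_replicates: int, seed: int):
        n = len(codes)
        self.B = int(mc_replicates)
        rng = np.random.default_rng(seed)
        # canonical base vector: the null depends only on the row-margin
        # multiset, never on category code order or sample order
        counts = np.sort(np.bincount(codes, minlength=n_categories))[::-1]
        base = np.repeat(np.arange(n_categories), counts).astype(np.int16)
        perm = rng.permuted(np.tile(base, (self.B, 1)), axis=1)
        zeros = np.zeros((self.B, 1), dtype=np.int32)
        self._cums = [
            np.concatenate([zeros, np.cumsum(perm == c, axis=1, dtype=np.int32)], axis=1)
            for c in range(n_categories)
        ]
        self._lg = gammaln(np.arange(n + 2, dtype=float))  # _lg[c + 1] = log(c!)
        self._cache: dict[tuple[int, ...], np.ndarray] = {}

    def _null_stats(self, sizes: tuple[int, ...]) -> np.ndarray:
        cached = self._cache.get(sizes)
        if cached is not None:
            return cached
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        stat = np.zeros(self.B)
        for cum in self._cums:
            seg = cum[:, bounds[1:]] - cum[:, bounds[:-1]]
            stat += self._lg[seg + 1].sum(axis=1)
        stat.sort()
        self._cache[sizes] = stat
        return stat

    def p_value(self, table: np.ndarray) -> float:
        sizes = tuple(sorted(int(s) for s in table.sum(axis=0)))
        null = self._null_stats(sizes)
        observed = float(self._lg[table + 1].sum())
        n_ge = self.B - int(np.searchsorted(null, observed - 1e-7, side="left"))
        return (1 + n_ge) / (self.B + 1)


class _CategoricalCovariate:
    """Pre-coded categorical covariate with exact/Monte-Carlo Fisher test."""

    def __init__(
        self,
        name: str,
        values: np.ndarray,
        n_batches: int,
        mc_replicates: int = DEFAULT_MC_REPLICATES,
        sub_seed: int = 0,
    ):
        self.name = name
        self.m = n_batches
        values = np.asarray(values, dtype=object)
        missing = pd.isna(values)
        self.idx = np.flatnonzero(~missing)
        codes, categories = pd.factorize(values[self.idx])
        self.codes = codes.astype(np.intp)
        self.categories = tuple(categories)
        self.r = len(categories)
        self.N = len(self.idx)
        self.mc_replicates = int(mc_replicates)
        self.sub_seed = int(sub_seed)
        self._null: Optional[_FisherNull] = None

    def _table(self, batch: np.ndarray) -> np.ndarray:
        b = batch[self.idx]
        table = np.bincount(self.codes * self.m + b, minlength=self.r * self.m)
        table = table.reshape(self.r, self.m)
        table = table[:, table.sum(axis=0) > 0]
        table = table[table.sum(axis=1) > 0]
        return table

    def p_value(self, batch: np.ndarray) -> float:
        """Exact two-sided Fisher p for 2x2; Monte-Carlo for larger tables.

        Degenerate tables (a single observed category or a single
        non-empty batch) return 1: such a covariate cannot be unbalanced.
        """
        if self.N == 0 or self.r < 2:
            return 1.0
        table = self._table(batch)
        if table.shape[0] < 2 or table.shape[1] < 2:
            return 1.0
        if table.shape == (2, 2):
            return float(stats.fisher_exact(table)[1])
        if self._null is None:
            self._null = _FisherNull(self.codes, self.r, self.mc_replicates, self.sub_seed)
        return self._null.p_value(table)

    def effect(self, batch: np.ndarray) -> float:
        """Cramer's V (no continuity correction); 0 for degenerate tables."""
        if self.N == 0 or self.r < 2:
            return 0.0
        table = self._table(batch)
        return _cramers_v_from_table(table)


def _cramers_v_from_table(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return 0.0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    v = math.sqrt(chi2 / (n * (min(r, c) - 1)))
    return min(v, 1.0)


# ---------------------------------------------------------------------------
# standalone per-covariate operations
# ---------------------------------------------------------------------------


def _batch_codes(batch_of) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(batch_of))
    if (codes < 0).any():
        raise ValidationError("batch labels must not be missing")
    return codes.astype(np.intp), len(uniques)


def kruskal_wallis_p(values, batch_of) -> float:
    """Tie-corrected Kruskal-Wallis p-value of ``values`` across batches.

    ``values`` may contain NaN (missing, dropped case-wise); ``batch_of``
    holds per-sample batch labels of any hashable type.
    """
    codes, m = _batch_codes(batch_of)
    return _ContinuousCovariate("", np.asarray(values, dtype=float), m).p_value(codes)


def eta_effect(values, batch_of) -> float:
    """Eta (from ANOVA): sqrt(SS_between / SS_total), in [0, 1]."""
    codes, m = _batch_codes(batch_of)
    return _ContinuousCovariate("", np.asarray(values, dtype=float), m).effect(codes)


def fisher_exact_p(
    labels,
    batch_of,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    sub_seed: int = 0,
) -> float:
    """Fisher's exact p of category labels across batches.

    Exact for 2x2 tables; Monte-Carlo at fixed margins (deterministic
    given ``sub_seed``) for larger tables.  Missing labels (None/NaN) are
    dropped case-wise.
    """
    codes, m = _batch_codes(batch_of)
    cov = _CategoricalCovariate(
        "", np.asarray(labels, dtype=object), m, mc_replicates=mc_replicates, sub_seed=sub_seed
    )
    return cov.p_value(codes)


def cramers_v(labels, batch_of) -> float:
    """Cramer's V of the label-by-batch contingency table, in [0, 1]."""
    codes, m = _batch_codes(batch_of)
    return _CategoricalCovariate("", np.asarray(labels, dtype=object), m).effect(codes)


# ---------------------------------------------------------------------------
# the composite score
# ---------------------------------------------------------------------------


class BalanceEngine:
    """Scores batch-label vectors for a fixed table and covariate spec.

    Precomputes ranks, category codes and complete-case masks once, so
    that the optimizer can evaluate many thousand candidate layouts
    cheaply.  ``balance_score`` is a one-shot convenience wrapper.
    """

    def __init__(
        self,
        table: SampleTable,
        n_batches: int,
        spec: Optional[CovariateSpec] = None,
        method: str = "harmonic",
        mc_replicates: int = DEFAULT_MC_REPLICATES,
        seed: int = 0,
    ):
        if method not in SCORE_METHODS:
            raise ValidationError(f"unknown score method {method!r}; choose from {SCORE_METHODS}")
        self.spec = spec if spec is not None else table.spec
        self.method = method
        self.n_batches = int(n_batches)
        self._covariates = []
        for name, kind in self.spec.entries:
            if kind == CONTINUOUS:
                self._covariates.append(
                    _ContinuousCovariate(name, table.covariate(name), self.n_batches)
                )
            else:
                self._covariates.append(
                    _CategoricalCovariate(
                        name,
                        table.covariate(name),
                        self.n_batches,
                        mc_replicates=mc_replicates,
                        sub_seed=derive_seed(seed, f"fisher:{name}"),
                    )
                )

    def _values(self, batch: np.ndarray) -> list[float]:
        if self.method == "effect_size":
            return [1.0 - cov.effect(batch) for cov in self._covariates]
        return [cov.p_value(batch) for cov in self._covariates]

    def score(self, batch: np.ndarray) -> float:
        """Combined balance score of one batch-label vector."""
        combiner = "product" if self.method == "product" else "harmonic"
        return combine_scores(self._values(batch), combiner)

    def report(self, batch: np.ndarray) -> BalanceReport:
        """Full per-covariate report plus the combined score."""
        values = self._values(batch)
        results = []
        for cov, spec_entry, value in zip(self._covariates, self.spec.entries, values):
            name, kind = spec_entry
            if self.method == "effect_size":
                results.append(CovariateResult(name, kind, None, 1.0 - value, cov.N))
            else:
                results.append(CovariateResult(name, kind, value, None, cov.N))
        combiner = "product" if self.method == "product" else "harmonic"
        return BalanceReport(results, combine_scores(values, combiner), self.method)


def balance_score(
    table: SampleTable,
    alloc: Allocation,
    spec: Optional[CovariateSpec] = None,
    method: str = "harmonic",
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> BalanceReport:
    """Balance report of one allocation of ``table`` into batches.

    Covariates are always evaluated at the sample level, including under
    blocking.  ``seed`` drives the Monte-Carlo Fisher sub-seeds (derived
    per covariate name), so a score computed here reproduces exactly the
    score an optimizer run with the same master seed reports.
    """
    engine = BalanceEngine(
        table,
        n_batches=alloc.n_batches,
        spec=spec,
        method=method,
        mc_replicates=mc_replicates,
        seed=seed,
    )
    return engine.report(alloc.batch_vector(table))
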