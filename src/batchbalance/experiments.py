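"""Reproduction experiments: score-distribution study and SA vs random search.

Two numerical experiments accompany the allocator.  The first samples
many random layouts and summarizes the balance-score distribution as a
function of how many covariates are balanced simultaneously (with one
continuous covariate the scores are test p-values under the null and
hence approximately uniform; each added covariate makes highly balanced
layouts rarer).  The second pits simulated annealing against a
random-search baseline at a matched number of objective evaluations over
replicate cohorts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .anneal import AnnealingConfig, _BlockArrays, _n_batches, _random_packing, optimize, random_search
from .cohort import CohortRecipe, simulate_cohort
from .metadata import CovariateSpec, SampleTable, build_blocks
from .metrics import DEFAULT_MC_REPLICATES, BalanceEngine


def random_layout_scores(
    table: SampleTable,
    batch_size: int,
    spec: Optional[CovariateSpec] = None,
    n_sims: int = 10_000,
    seed: int = 0,
    method: str = "harmonic",
    mc_replicates: int = DEFAULT_MC_REPLICATES,
) -> np.ndarray:
    """Balance scores of ``n_sims`` independent random layouts."""
    blocks = build_blocks(table, batch_size)
    arrays = _BlockArrays(blocks, table)
    m = _n_batches(arrays.n, batch_size)
    rng = np.random.default_rng(derive_seed(seed, "layouts"))
    engine = BalanceEngine(
        table, n_batches=m, spec=spec, method=method, mc_replicates=mc_replicates, seed=seed
    )
    scores = np.empty(n_sims)
    for i in range(n_sims):
        block_batch, _ = _random_packing(arrays.sizes, batch_size, m, rng)
        scores[i] = engine.score(arrays.expand(block_batch))
    return scores


def _demo_cohort(n_samples: int, n_covariates: int, seed: int) -> SampleTable:
    """Demo cohort: age, bmi, sex, then standard-normal extras as needed."""
    continuous = [("age", 55.0, 10.0), ("bmi", 30.0, 5.0)]
    categorical = [("sex", ("male", "female"), (0.5, 0.5))]
    for i in range(3, n_covariates):
        continuous.append((f"cov{i + 1}", 0.0, 1.0))
    recipe = CohortRecipe(
        n_samples=n_samples,
        continuous=tuple(continuous),
        categorical=tuple(categorical),
        seed=seed,
    )
    return simulate_cohort(recipe)


def _demo_spec_subset(table: SampleTable, n_covariates: int) -> CovariateSpec:
    ordered = ["age", "bmi", "sex"] + [n for n in table.spec.names if n.startswith("cov")]
    chosen = ordered[:n_covariates]
    return CovariateSpec(tuple((n, table.spec.kind(n)) for n in chosen))


def experiment_score_distribution(
    n_sims: int = 10_000,
    n_samples: int = 98,
    batch_size: int = 13,
    n_covariates_list: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
) -> pd.DataFrame:
    """Median and 95th percentile of random-layout balance scores per
    covariate count.  The same simulated layouts are scored for every
    covariate count, isolating the effect of the combiner."""
    table = _demo_cohort(n_samples, max(n_covariates_list), seed)
    rows = []
    for c in n_covariates_list:
        spec = _demo_spec_subset(table, c)
        scores = random_layout_scores(
            table, batch_size, spec=spec, n_sims=n_sims, seed=seed, mc_replicates=mc_replicates
        )
        rows.append(
            {
                "n_covariates": c,
                "median": float(np.median(scores)),
                "p95": float(np.percentile(scores, 95)),
                "n_sims": n_sims,
            }
        )
    return pd.DataFrame(rows)


def experiment_sa_vs_random(
    n_samples: int = 98,
    batch_size: int = 13,
    budget: int = 1000,
    n_seeds: int = 20,
    seed: int = 0,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
) -> dict:
    """Paired SA vs random-search comparison at a matched evaluation budget.

    For each replicate a fresh demo cohort (age, bmi, sex) is simulated;
    SA runs ``budget`` iterations and random search scores ``budget``
    layouts.  Returns the per-replicate table, the two medians, and the
    fraction of replicates where SA found at least as good a layout.
    """
    rows = []
    for i in range(n_seeds):
        table = _demo_cohort(n_samples, 3, derive_seed(seed, f"cohort-{i}"))
        sa = optimize(
            table,
            batch_size,
            config=AnnealingConfig(
                iterations=budget, seed=derive_seed(seed, f"sa-{i}"), mc_replicates=mc_replicates
            ),
        )
        rs = random_search(
            table,
            batch_size,
            n_layouts=budget,
            seed=derive_seed(seed, f"rs-{i}"),
            mc_replicates=mc_replicates,
        )
        rows.append(
            {
                "replicate": i,
                "sa_best": sa.best_score,
                "random_best": rs.best_score,
                "sa_wins": sa.best_score >= rs.best_score,
            }
        )
    frame = pd.DataFrame(rows)
    return {
        "per_replicate": frame,
        "sa_median": float(frame["sa_best"].median()),
        "random_median": float(frame["random_best"].median()),
        "win_fraction": float(frame["sa_wins"].mean()),
        "budget": budget,
        "n_seeds": n_seeds,
    }
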