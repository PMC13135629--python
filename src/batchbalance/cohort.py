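"""Synthetic cohort generation.

Generators for the metadata tables used throughout the package's tests
and experiments: a basic clinical-style cohort (age ~ Normal(55, 10),
BMI ~ Normal(30, 5), sex as a fair coin), and structural analogs of two
proteomics case studies:

* case study A — 200 biopsies from 40 subjects at 5 timepoints, blocked
  by subject (every biopsy from a subject shares a batch), with a
  5-level timepoint covariate and two subject-level binary covariates
  (diabetes status, chronic allograft dysfunction);
* case study B — 200 kidney-perfusate samples from 100 donor pairs,
  blocked by donor, with three binary covariates (trial arm constant
  within a pair; delayed graft function and acute rejection per
  recipient) and two continuous covariates (12-month eGFR, perfusion
  duration).

The case-study prevalences and continuous distributions are plausible
clinical values chosen for the synthetic analogs (the design structure
— sample counts, block layout, covariate kinds — is what the analogs
reproduce); all are configurable.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metadata import CovariateSpec, SampleTable


@dataclass(frozen=True)
class CohortRecipe:
    """Declarative description of a synthetic cohort.

    ``continuous`` entries are (name, mean, sd); ``categorical`` entries
    are (name, levels, probabilities).  With ``blocks = (n_blocks,
    block_size)``, samples are grouped into equal blocks and the
    covariates named in ``block_level`` are drawn once per block.
    """

    n_samples: int
    continuous: tuple[tuple[str, float, float], ...] = ()
    categorical: tuple[tuple[str, tuple, tuple], ...] = ()
    blocks: Optional[tuple[int, int]] = None
    block_level: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        for name, levels, probs in self.categorical:
            if len(levels) != len(probs):
                raise ValidationError(f"covariate {name!r}: levels and probabilities differ in length")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"covariate {name!r}: probabilities must sum to 1")
        if self.blocks is not None:
            n_blocks, block_size = self.blocks
            if n_blocks * block_size != self.n_samples:
                raise ValidationError(
                    f"block design {n_blocks} x {block_size} does not match n_samples = {self.n_samples}"
                )
        names = [n for n, *_ in self.continuous] + [n for n, *_ in self.categorical]
        unknown = set(self.block_level) - set(names)
        if unknown:
            raise ValidationError(f"block_level names not among covariates: {sorted(unknown)}")


def simulate_cohort(recipe: CohortRecipe) -> SampleTable:
    """Draw a :class:`SampleTable` from a :class:`CohortRecipe`."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_samples
    width = len(str(n))
    frame = pd.DataFrame({"sample_id": [f"S{i + 1:0{width}d}" for i in range(n)]})

    block_column = None
    block_index = None
    if recipe.blocks is not None:
        n_blocks, block_size = recipe.blocks
        block_index = np.repeat(np.arange(n_blocks), block_size)
        bw = len(str(n_blocks))
        frame["block"] = [f"B{b + 1:0{bw}d}" for b in block_index]
        block_column = "block"

    def per_unit(draw):
        """Draw per block (repeated) or per sample."""
        if block_index is not None:
            return np.asarray(draw(recipe.blocks[0]))[block_index]
        return np.asarray(draw(n))

    for name, mean, sd in recipe.continuous:
        if name in recipe.block_level:
            frame[name] = per_unit(lambda size: rng.normal(mean, sd, size))
        else:
            frame[name] = rng.normal(mean, sd, n)
    for name, levels, probs in recipe.categorical:
        levels = np.asarray(levels, dtype=object)
        if name in recipe.block_level:
            frame[name] = per_unit(lambda size: rng.choice(levels, size=size, p=list(probs)))
        else:
            frame[name] = rng.choice(levels, size=n, p=list(probs))

    spec = CovariateSpec.of(
        categorical=[name for name, *_ in recipe.categorical],
        continuous=[name for name, *_ in recipe.continuous],
    )
    return SampleTable(frame, spec, id_column="sample_id", block_column=block_column)


def simulate_basic_cohort(n: int, seed: int = 0) -> SampleTable:
    """Cohort with age ~ N(55, 10), bmi ~ N(30, 5) and fair-coin sex."""
    recipe = CohortRecipe(
        n_samples=n,
        continuous=(("age", 55.0, 10.0), ("bmi", 30.0, 5.0)),
        categorical=(("sex", ("male", "female"), (0.5, 0.5)),),
        seed=seed,
    )
    return simulate_cohort(recipe)


def simulate_case_study_A(
    seed: int = 0,
    p_diabetes: float = 0.3,
    p_dysfunction: float = 0.25,
) -> SampleTable:
    """Serial-biopsy analog: 40 subjects x 5 timepoints, blocked by subject.

    Timepoint is categorical with each level appearing exactly once per
    subject; diabetes and chronic allograft dysfunction are binary and
    constant within subject.
    """
    rng = np.random.default_rng(seed)
    n_subjects, n_timepoints = 40, 5
    diabetes = np.where(rng.random(n_subjects) < p_diabetes, "yes", "no")
    dysfunction = np.where(rng.random(n_subjects) < p_dysfunction, "yes", "no")
    rows = []
    for s in range(n_subjects):
        subject = f"P{s + 1:02d}"
        for t in range(n_timepoints):
            rows.append(
                {
                    "sample_id": f"{subject}-T{t + 1}",
                    "subject": subject,
                    "timepoint": f"T{t + 1}",
                    "diabetes": diabetes[s],
                    "dysfunction": dysfunction[s],
                }
            )
    frame = pd.DataFrame(rows)
    spec = CovariateSpec.of(categorical=("timepoint", "diabetes", "dysfunction"))
    return SampleTable(frame, spec, id_column="sample_id", block_column="subject")


def simulate_case_study_B(
    seed: int = 0,
    p_treated: float = 0.5,
    p_dgf: float = 0.3,
    p_rejection: float = 0.2,
    egfr_mean: float = 50.0,
    egfr_sd: float = 15.0,
    perfusion_mean: float = 300.0,
    perfusion_sd: float = 60.0,
) -> SampleTable:
    """Donor-pair analog: 100 donors x 2 kidneys, blocked by donor.

    Trial arm is constant within a pair; delayed graft function and
    acute rejection vary per recipient; eGFR (mL/min/1.73 m^2) and
    perfusion duration (minutes) are per-sample continuous covariates.
    """
    rng = np.random.default_rng(seed)
    n_donors = 100
    arm = np.where(rng.random(n_donors) < p_treated, "oxygenated", "control")
    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1:03d}"
        for side in ("L", "R"):
            rows.append(
                {
                    "sample_id": f"{donor}-{side}",
                    "donor": donor,
                    "arm": arm[d],
                    "dgf": "yes" if rng.random() < p_dgf else "no",
                    "rejection": "yes" if rng.random() < p_rejection else "no",
                    "egfr": rng.normal(egfr_mean, egfr_sd),
                    "perfusion_minutes": rng.normal(perfusion_mean, perfusion_sd),
                }
            )
    frame = pd.DataFrame(rows)
    spec = CovariateSpec.of(
        categorical=("arm", "dgf", "rejection"),
        continuous=("egfr", "perfusion_minutes"),
    )
    return SampleTable(frame, spec, id_column="sample_id", block_column="donor")


def inject_missingness(table: SampleTable, fraction: float, seed: int = 0) -> SampleTable:
    """Blank a fixed fraction of covariate cells, uniformly at random.

    Exactly ``round(fraction * n_samples * n_covariates)`` cells become
    missing; sample ids and block labels are never touched.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must be in [0, 1]")
    columns = list(table.spec.names)
    total = table.n * len(columns)
    n_missing = int(round(fraction * total))
    rng = np.random.default_rng(seed)
    cells = rng.choice(total, size=n_missing, replace=False)
    frame = table.frame.copy()
    for col in columns:
        if frame[col].dtype != object:
            frame[col] = frame[col].astype(object)
    for cell in cells:
        row, col = divmod(int(cell), len(columns))
        frame.iat[row, frame.columns.get_loc(columns[col])] = None
    return SampleTable(frame, table.spec, table.id_column, table.block_column)
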