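"""Sample metadata containers, validation, and CSV/TSV input-output.

The central objects are :class:`SampleTable` (one row per sample, with
categorical and/or continuous covariates that may contain missing
values, plus an optional blocking label), :class:`CovariateSpec` (which
columns to balance and their kinds), :class:`BlockStructure` (groups of
samples that must share a batch) and :class:`Allocation` (the
sample -> batch assignment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    InfeasibleError,
    ParseError,
    SchemaError,
    ValidationError,
)

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: cell contents treated as missing on read (case-insensitive)
MISSING_MARKERS = frozenset({"", "na", "nan"})


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float):
        return math.isnan(value)
    if isinstance(value, str):
        return value.strip().lower() in MISSING_MARKERS
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered declaration of the covariates to balance.

    ``entries`` is a tuple of ``(name, kind)`` pairs with kind one of
    ``"categorical"`` or ``"continuous"``.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.entries:
            raise ValidationError("covariate spec must declare at least one covariate")
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError(f"covariate names are not distinct: {names}")
        for name, kind in self.entries:
            if kind not in (CATEGORICAL, CONTINUOUS):
                raise ValidationError(
                    f"covariate {name!r}: kind must be 'categorical' or 'continuous', got {kind!r}"
                )

    @classmethod
    def of(
        cls,
        categorical: Sequence[str] = (),
        continuous: Sequence[str] = (),
    ) -> "CovariateSpec":
        entries = tuple((n, CATEGORICAL) for n in categorical) + tuple(
            (n, CONTINUOUS) for n in continuous
        )
        return cls(entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    def kind(self, name: str) -> str:
        for n, k in self.entries:
            if n == name:
                return k
        raise KeyError(name)


class SampleTable:
    """Validated cohort metadata: one row per sample.

    Wraps the original :class:`pandas.DataFrame` (preserved verbatim for
    round-trip output) together with parsed covariate arrays: continuous
    covariates as float arrays with NaN for missing, categorical
    covariates as object arrays with None for missing.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        spec: CovariateSpec,
        id_column: str = "sample_id",
        block_column: Optional[str] = None,
    ):
        if id_column not in frame.columns:
            raise SchemaError(f"id column {id_column!r} not found in table")
        for name in spec.names:
            if name not in frame.columns:
                raise SchemaError(f"covariate column {name!r} not found in table")
        if block_column is not None and block_column not in frame.columns:
            raise SchemaError(f"block column {block_column!r} not found in table")

        self.frame = frame.reset_index(drop=True)
        self.spec = spec
        self.id_column = id_column
        self.block_column = block_column

        self._ids = self._parse_ids()
        self._covariates = {
            name: self._parse_column(name, kind) for name, kind in spec.entries
        }

    # -- parsing -------------------------------------------------------

    def _parse_ids(self) -> tuple[str, ...]:
        raw = self.frame[self.id_column].tolist()
        ids = []
        bad_rows = [i for i, v in enumerate(raw) if _is_missing(v)]
        if bad_rows:
            raise ValidationError(f"missing sample id in rows {bad_rows}")
        for v in raw:
            ids.append(str(v))
        seen: dict[str, int] = {}
        dupes = []
        for i, sid in enumerate(ids):
            if sid in seen:
                dupes.append((sid, seen[sid], i))
            seen.setdefault(sid, i)
        if dupes:
            msg = "; ".join(f"id {sid!r} in rows {a} and {b}" for sid, a, b in dupes)
            raise ValidationError(f"duplicate sample ids: {msg}")
        return tuple(ids)

    def _parse_column(self, name: str, kind: str) -> np.ndarray:
        values = self.frame[name].tolist()
        if kind == CONTINUOUS:
            out = np.full(len(values), np.nan)
            for i, v in enumerate(values):
                if _is_missing(v):
                    continue
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"column {name!r}, row {i}: cannot parse {v!r} as a number"
                    ) from None
                if not math.isfinite(x):
                    raise ParseError(
                        f"column {name!r}, row {i}: non-finite value {v!r}"
                    )
                out[i] = x
            return out
        out = np.empty(len(values), dtype=object)
        for i, v in enumerate(values):
            out[i] = None if _is_missing(v) else v
        return out

    # -- accessors -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self._ids

    def covariate(self, name: str) -> np.ndarray:
        """Parsed values for one covariate (NaN/None marks missing)."""
        return self._covariates[name]

    @property
    def block_labels(self) -> Optional[np.ndarray]:
        """Object array of block labels (None = unblocked), or None."""
        if self.block_column is None:
            return None
        values = self.frame[self.block_column].tolist()
        out = np.empty(len(values), dtype=object)
        for i, v in enumerate(values):
            out[i] = None if _is_missing(v) else str(v)
        return out

    def with_block(self, block_column: Optional[str]) -> "SampleTable":
        """Return a copy of this table using a different blocking column."""
        return SampleTable(self.frame, self.spec, self.id_column, block_column)


@dataclass(frozen=True)
class BlockStructure:
    """Partition of the sample ids into co-batched groups.

    Samples without a block label get singleton blocks; labelled samples
    with equal labels share a block.
    """

    blocks: dict[str, tuple[str, ...]]

    @property
    def block_ids(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.blocks.values())

    @property
    def n_samples(self) -> int:
        return sum(self.sizes)

    def block_of(self) -> dict[str, str]:
        return {sid: bid for bid, members in self.blocks.items() for sid in members}


def build_blocks(table: SampleTable, batch_size: int) -> BlockStructure:
    """Group samples into blocks; unblocked samples become singletons.

    Raises :class:`InfeasibleError` if any block exceeds ``batch_size``
    (such a block could never fit in a single batch).
    """
    if batch_size < 1:
        raise ValidationError(f"batch_size must be >= 1, got {batch_size}")
    labels = table.block_labels
    blocks: dict[str, list[str]] = {}
    for i, sid in enumerate(table.sample_ids):
        label = labels[i] if labels is not None else None
        key = f"__singleton__{sid}" if label is None else str(label)
        blocks.setdefault(key, []).append(sid)
    for bid, members in blocks.items():
        if len(members) > batch_size:
            raise InfeasibleError(
                f"block {bid!r} has {len(members)} samples but the batch size "
                f"is {batch_size}; blocked samples cannot be split across batches"
            )
    return BlockStructure({bid: tuple(m) for bid, m in blocks.items()})


@dataclass
class Allocation:
    """Assignment of every sample to exactly one batch (0-based indices).

    ``n_batches`` is always ``ceil(n / batch_size)`` — the minimum number
    of batches; the last batches may be smaller than ``batch_size``.
    """

    assignment: dict[str, int]
    n_batches: int
    batch_size: int

    def batch_vector(self, table: SampleTable) -> np.ndarray:
        """Batch index per sample, aligned with the table's row order."""
        try:
            return np.array(
                [self.assignment[sid] for sid in table.sample_ids], dtype=np.intp
            )
        except KeyError as exc:
            raise ConsistencyError(
                f"allocation is missing sample {exc.args[0]!r}"
            ) from None

    def batch_sizes(self) -> np.ndarray:
        out = np.zeros(self.n_batches, dtype=int)
        for b in self.assignment.values():
            out[b] += 1
        return out

    def validate(self, table: SampleTable, blocks: Optional[BlockStructure] = None):
        """Check coverage, capacity, batch count and (optionally) blocking."""
        ids = set(table.sample_ids)
        got = set(self.assignment)
        if ids != got:
            missing = sorted(ids - got)[:5]
            extra = sorted(got - ids)[:5]
            raise ConsistencyError(
                f"allocation does not cover the table (missing {missing}, extra {extra})"
            )
        sizes = self.batch_sizes()
        if sizes.max(initial=0) > self.batch_size:
            raise ValidationError(
                f"batch sizes {sizes.tolist()} exceed capacity {self.batch_size}"
            )
        expected = -(-table.n // self.batch_size)
        if self.n_batches != expected:
            raise ValidationError(
                f"n_batches is {self.n_batches}, expected ceil({table.n}/{self.batch_size}) = {expected}"
            )
        if blocks is not None:
            for bid, members in blocks.blocks.items():
                batches = {self.assignment[s] for s in members}
                if len(batches) > 1:
                    raise ValidationError(
                        f"block {bid!r} is split across batches {sorted(batches)}"
                    )


def read_sample_table(
    path,
    spec: CovariateSpec,
    id_column: str = "sample_id",
    block_column: Optional[str] = None,
) -> SampleTable:
    """Read a CSV/TSV metadata file into a validated :class:`SampleTable`.

    The delimiter is chosen from the extension (``.tsv``/``.tab`` means
    tab, anything else comma).  Empty cells and the markers ``NA`` /
    ``NaN`` (case-insensitive) are treated as missing; original cell
    text is preserved for round-trip output.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return SampleTable(frame, spec, id_column=id_column, block_column=block_column)


def write_allocation(table: SampleTable, alloc: Allocation, path) -> None:
    """Write the input table plus a 1-based ``batch`` column as CSV.

    Row order is preserved; original cell text (including missing-value
    markers) is written back verbatim.
    """
    batch = []
    for sid in table.sample_ids:
        if sid not in alloc.assignment:
            raise ConsistencyError(f"allocation is missing sample {sid!r}")
        batch.append(alloc.assignment[sid] + 1)
    out = table.frame.copy()
    out["batch"] = batch
    out.to_csv(path, index=False)
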