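"""Simulated-annealing search over block allocations, plus random search.

The search space is the set of assignments of whole blocks to
``ceil(n / batch_size)`` batches of capacity ``batch_size``.  Starting
from a random feasible packing, each step proposes a neighbouring layout
(swap one block between two batches, or relocate one block), scores it
with the balance engine, and accepts it by the Metropolis criterion for
maximization: always if it improves (or ties), otherwise with
probability exp(delta / T).  The temperature follows a geometric cooling
schedule T_t = T0 * cooling_rate**t.  The best layout ever evaluated is
returned, not the final state.

``random_search`` is the baseline: score many independent random layouts
and keep the best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .errors import InfeasibleError, ValidationError
from .metadata import Allocation, BlockStructure, CovariateSpec, SampleTable, build_blocks
from .metrics import DEFAULT_MC_REPLICATES, BalanceEngine, BalanceReport


@dataclass
class AnnealingConfig:
    """Optimizer settings.

    Defaults are temperature = 1, cooling_rate = 0.975, 1000 iterations;
    one neighbour evaluation per iteration.
    """

    temperature: float = 1.0
    cooling_rate: float = 0.975
    iterations: int = 1000
    seed: int = 0
    score_method: str = "harmonic"
    mc_replicates: int = DEFAULT_MC_REPLICATES

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if not (0.0 < self.cooling_rate < 1.0):
            raise ValidationError("cooling_rate must be in (0, 1)")
        if self.iterations < 0:
            raise ValidationError("iterations must be non-negative")

    def to_dict(self) -> dict:
        return {
            "temperature": self.temperature,
            "cooling_rate": self.cooling_rate,
            "iterations": self.iterations,
            "seed": self.seed,
            "score_method": self.score_method,
            "mc_replicates": self.mc_replicates,
        }


@dataclass
class TraceRecord:
    iteration: int
    temperature: Optional[float]
    current_score: float
    best_score: float
    accepted: bool


class AnnealingTrace:
    """Per-iteration history; ``best_score`` is non-decreasing."""

    def __init__(self):
        self.records: list[TraceRecord] = []

    def append(self, record: TraceRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def best_scores(self) -> np.ndarray:
        return np.array([r.best_score for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "temperature": [r.temperature for r in self.records],
                "current_score": [r.current_score for r in self.records],
                "best_score": [r.best_score for r in self.records],
                "accepted": [r.accepted for r in self.records],
            }
        )


@dataclass
class AllocationResult:
    """Best allocation found, its balance report, and the search trace."""

    allocation: Allocation
    report: BalanceReport
    trace: AnnealingTrace
    config: Union[AnnealingConfig, dict]
    initial_score: float

    @property
    def best_score(self) -> float:
        return self.report.score


# ---------------------------------------------------------------------------
# internal array representation of a block-level layout
# ---------------------------------------------------------------------------


class _BlockArrays:
    """Blocks as arrays: sizes, member row-indices, expansion helpers."""

    def __init__(self, blocks: BlockStructure, table: SampleTable):
        row_of = {sid: i for i, sid in enumerate(table.sample_ids)}
        self.block_ids = list(blocks.block_ids)
        self.members = [
            np.array([row_of[sid] for sid in blocks.blocks[bid]], dtype=np.intp)
            for bid in self.block_ids
        ]
        self.sizes = np.array([len(m) for m in self.members], dtype=np.intp)
        self.n = int(self.sizes.sum())
        self._member_concat = np.concatenate(self.members) if self.members else np.empty(0, np.intp)
        self._block_of_member = np.repeat(np.arange(len(self.members)), self.sizes)
        self.table = table

    def expand(self, block_batch: np.ndarray) -> np.ndarray:
        """Sample-level batch vector (table row order) from a block layout."""
        out = np.empty(self.n, dtype=np.intp)
        out[self._member_concat] = block_batch[self._block_of_member]
        return out

    def to_allocation(self, block_batch: np.ndarray, n_batches: int, batch_size: int) -> Allocation:
        assignment = {}
        for bi, bid in enumerate(self.block_ids):
            batch = int(block_batch[bi])
            for sid in (self.table.sample_ids[r] for r in self.members[bi]):
                assignment[sid] = batch
        return Allocation(assignment, n_batches, batch_size)


def _n_batches(n: int, batch_size: int) -> int:
    return -(-n // batch_size)


def _random_packing(
    sizes: np.ndarray, batch_size: int, n_batches: int, rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomized first-fit-decreasing packing of blocks into batches.

    Blocks are shuffled, sorted descending by size (random tie order),
    and each is placed into a uniformly chosen batch with remaining
    capacity.  Retries a bounded number of times before declaring the
    instance infeasible.
    """
    n_blocks = len(sizes)
    for _ in range(max_tries):
        order = rng.permutation(n_blocks)
        order = order[np.argsort(-sizes[order], kind="stable")]
        loads = np.zeros(n_batches, dtype=np.intp)
        assign = np.empty(n_blocks, dtype=np.intp)
        feasible = True
        for i in order:
            candidates = np.flatnonzero(loads + sizes[i] <= batch_size)
            if candidates.size == 0:
                feasible = False
                break
            b = candidates[rng.integers(candidates.size)]
            assign[i] = b
            loads[b] += sizes[i]
        if feasible:
            return assign, loads
    raise InfeasibleError(
        f"could not pack {n_blocks} blocks into {n_batches} batches of size "
        f"{batch_size}; consider a larger batch size"
    )


def _propose(
    block_batch: np.ndarray,
    sizes: np.ndarray,
    loads: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """One neighbouring layout, or None if no feasible move was found.

    Each attempt flips a fair coin between (a) swapping one uniformly
    chosen block between two distinct uniformly chosen batches and
    (b) relocating one uniformly chosen block to a different batch;
    capacity-violating draws are rejected and redrawn.
    """
    m = len(loads)
    if m < 2 or len(sizes) == 0:
        return None
    for _ in range(max_attempts):
        if rng.random() < 0.5:
            a, b = rng.choice(m, size=2, replace=False)
            in_a = np.flatnonzero(block_batch == a)
            in_b = np.flatnonzero(block_batch == b)
            if in_a.size == 0 or in_b.size == 0:
                continue
            i = in_a[rng.integers(in_a.size)]
            j = in_b[rng.integers(in_b.size)]
            if (
                loads[a] - sizes[i] + sizes[j] <= batch_size
                and loads[b] - sizes[j] + sizes[i] <= batch_size
            ):
                new_batch = block_batch.copy()
                new_batch[i], new_batch[j] = b, a
                new_loads = loads.copy()
                new_loads[a] += sizes[j] - sizes[i]
                new_loads[b] += sizes[i] - sizes[j]
                return new_batch, new_loads
        else:
            i = rng.integers(len(sizes))
            a = block_batch[i]
            t = int(rng.integers(m - 1))
            if t >= a:
                t += 1
            if loads[t] + sizes[i] <= batch_size:
                new_batch = block_batch.copy()
                new_batch[i] = t
                new_loads = loads.copy()
                new_loads[a] -= sizes[i]
                new_loads[t] += sizes[i]
                return new_batch, new_loads
    return None


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def initial_allocation(
    blocks: BlockStructure,
    batch_size: int,
    rng: Union[int, np.random.Generator],
    table: Optional[SampleTable] = None,
) -> Allocation:
    """Random feasible allocation of whole blocks into batches.

    ``rng`` may be a seed or a numpy Generator.  Block ids are mapped
    back to sample ids; ``table`` is only needed when callers want the
    allocation expressed against a specific table (defaults to the block
    structure's own sample ids).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sizes = np.array(blocks.sizes, dtype=np.intp)
    n = int(sizes.sum())
    m = _n_batches(n, batch_size)
    assign, _ = _random_packing(sizes, batch_size, m, rng)
    assignment = {}
    for bi, bid in enumerate(blocks.block_ids):
        for sid in blocks.blocks[bid]:
            assignment[sid] = int(assign[bi])
    return Allocation(assignment, m, batch_size)


def propose_neighbor(
    alloc: Allocation,
    blocks: BlockStructure,
    rng: Union[int, np.random.Generator],
) -> Allocation:
    """A neighbouring allocation differing by one block swap or relocation.

    With a single batch (or when no feasible move is found within the
    attempt budget) the input allocation is returned unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    block_ids = list(blocks.block_ids)
    sizes = np.array(blocks.sizes, dtype=np.intp)
    block_batch = np.empty(len(block_ids), dtype=np.intp)
    for bi, bid in enumerate(block_ids):
        members = blocks.blocks[bid]
        batches = {alloc.assignment[s] for s in members}
        if len(batches) != 1:
            raise ValidationError(f"block {bid!r} is split across batches")
        block_batch[bi] = batches.pop()
    loads = np.bincount(block_batch, weights=sizes, minlength=alloc.n_batches).astype(np.intp)
    move = _propose(block_batch, sizes, loads, alloc.batch_size, rng)
    if move is None:
        return Allocation(dict(alloc.assignment), alloc.n_batches, alloc.batch_size)
    new_batch, _ = move
    assignment = {}
    for bi, bid in enumerate(block_ids):
        for sid in blocks.blocks[bid]:
            assignment[sid] = int(new_batch[bi])
    return Allocation(assignment, alloc.n_batches, alloc.batch_size)


def accept_move(
    current_score: float,
    proposed_score: float,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis acceptance for maximization.

    Improving (or equal) moves are always accepted; worsening moves with
    probability exp((proposed - current) / temperature).
    """
    if proposed_score >= current_score:
        return True
    if temperature <= 0:
        return False
    return rng.random() < math.exp((proposed_score - current_score) / temperature)


def optimize(
    table: SampleTable,
    batch_size: int,
    spec: Optional[CovariateSpec] = None,
    config: Optional[AnnealingConfig] = None,
    block_column: Optional[str] = None,
) -> AllocationResult:
    """Simulated-annealing search for a covariate-balanced allocation.

    Runs ``config.iterations`` steps from a random initial packing; each
    step proposes one neighbour, evaluates the balance score, applies
    the Metropolis rule, then cools the temperature geometrically.
    Returns the best layout ever evaluated.  Fully deterministic given
    ``config.seed``.  Blocking comes from the table's block column (or
    ``block_column`` override); unblocked samples are singleton blocks.
    """
    config = config if config is not None else AnnealingConfig()
    if block_column is not None:
        table = table.with_block(block_column)
    blocks = build_blocks(table, batch_size)
    arrays = _BlockArrays(blocks, table)
    m = _n_batches(arrays.n, batch_size)
    rng = np.random.default_rng(derive_seed(config.seed, "annealer"))
    engine = BalanceEngine(
        table,
        n_batches=m,
        spec=spec,
        method=config.score_method,
        mc_replicates=config.mc_replicates,
        seed=config.seed,
    )

    block_batch, loads = _random_packing(arrays.sizes, batch_size, m, rng)
    current_score = engine.score(arrays.expand(block_batch))
    initial_score = current_score
    best_batch = block_batch.copy()
    best_score = current_score

    trace = AnnealingTrace()
    temperature = config.temperature
    for t in range(config.iterations):
        move = _propose(block_batch, arrays.sizes, loads, batch_size, rng)
        if move is None:
            proposed_score = current_score
            accepted = True
        else:
            new_batch, new_loads = move
            proposed_score = engine.score(arrays.expand(new_batch))
            accepted = accept_move(current_score, proposed_score, temperature, rng)
            if proposed_score > best_score:
                best_score = proposed_score
                best_batch = new_batch.copy()
            if accepted:
                block_batch, loads = new_batch, new_loads
                current_score = proposed_score
        trace.append(TraceRecord(t, temperature, current_score, best_score, accepted))
        temperature *= config.cooling_rate

    allocation = arrays.to_allocation(best_batch, m, batch_size)
    report = engine.report(arrays.expand(best_batch))
    return AllocationResult(allocation, report, trace, config, initial_score)


def random_search(
    table: SampleTable,
    batch_size: int,
    spec: Optional[CovariateSpec] = None,
    n_layouts: int = 1000,
    seed: int = 0,
    score_method: str = "harmonic",
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    block_column: Optional[str] = None,
) -> AllocationResult:
    """Baseline: score ``n_layouts`` independent random layouts, keep the best."""
    if n_layouts < 1:
        raise ValidationError("n_layouts must be >= 1")
    if block_column is not None:
        table = table.with_block(block_column)
    blocks = build_blocks(table, batch_size)
    arrays = _BlockArrays(blocks, table)
    m = _n_batches(arrays.n, batch_size)
    rng = np.random.default_rng(derive_seed(seed, "random-search"))
    engine = BalanceEngine(
        table,
        n_batches=m,
        spec=spec,
        method=score_method,
        mc_replicates=mc_replicates,
        seed=seed,
    )

    trace = AnnealingTrace()
    best_batch = None
    best_score = -np.inf
    initial_score = None
    for t in range(n_layouts):
        block_batch, _ = _random_packing(arrays.sizes, batch_size, m, rng)
        score = engine.score(arrays.expand(block_batch))
        if initial_score is None:
            initial_score = score
        improved = score > best_score
        if improved:
            best_score = score
            best_batch = block_batch.copy()
        trace.append(TraceRecord(t, None, score, best_score, improved))

    allocation = arrays.to_allocation(best_batch, m, batch_size)
    report = engine.report(arrays.expand(best_batch))
    return AllocationResult(
        allocation,
        report,
        trace,
        {"method": "random_search", "n_layouts": n_layouts, "seed": seed,
         "score_method": score_method, "mc_replicates": mc_replicates},
        float(initial_score),
    )
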