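"""A minimal weighted-ensemble (WE) rare-event sampling engine.

WE runs many weighted trajectory "walkers" in parallel and periodically
resamples them on a progress-coordinate grid: bins holding fewer than the
target number of walkers have their walkers split (weight divided exactly
among copies), over-occupied bins have walkers merged (one of two candidates
survives with probability proportional to its weight and absorbs both
weights).  Both moves preserve the expected contribution of every walker, so
any weighted ensemble average is an unbiased estimate of the corresponding
brute-force ensemble average, while sampling effort is spread evenly across
progress-coordinate space — the point of the method for rare events.

The progress coordinate here is two-dimensional: a bounded reaction
likelihood score in [0, 1] and a discrete Trp identity label (1/2/3), so a
bin is (score interval, identity).  The engine is propagator-agnostic: any
callable advancing an opaque walker state by tau under a NumPy RNG stream
plugs in, as does any scorer mapping a state to (score, identity).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .reaction_score import ReactionScoreParams, best_trp

__all__ = [
    "Walker",
    "WalkerRecord",
    "BinGrid",
    "WERun",
    "pose_scorer",
    "assign_bins",
    "resample",
    "run_we",
    "extract_iteration",
]

#: Advances a walker state by tau_ns, drawing randomness from the given RNG.
Propagator = Callable[[object, float, np.random.Generator], object]

#: Maps a walker state to its progress coordinate (score in [0,1], identity).
Scorer = Callable[[object], tuple[float, int]]


@dataclass
class Walker:
    """One weighted trajectory segment."""

    id: int
    weight: float
    state: object
    parent_id: int | None = None
    history: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"walker weight must lie in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class WalkerRecord:
    """Immutable snapshot of a walker at the end of an iteration."""

    id: int
    parent_id: int | None
    weight: float
    score: float
    identity: int
    state: object
    history: tuple[tuple[float, int], ...]


@dataclass(frozen=True)
class BinGrid:
    """Progress-coordinate bins: score intervals x discrete identities."""

    score_edges: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    identities: tuple[int, ...] = (1, 2, 3)
    target_per_bin: int = 4

    def __post_init__(self) -> None:
        edges = np.asarray(self.score_edges, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("score_edges must be strictly ascending")
        if edges[0] != 0.0 or edges[-1] != 1.0:
            raise ValueError("score_edges must span [0, 1]")
        if self.target_per_bin < 1:
            raise ValueError("target_per_bin must be >= 1")

    def score_bin(self, score: float) -> int:
        """Index of the half-open interval [e_i, e_{i+1}); top edge inclusive."""
        if not 0.0 <= score <= 1.0:
            raise RuntimeError(
                f"progress score {score} outside [0, 1]; scores are bounded "
                "by construction, this indicates an internal error"
            )
        idx = int(np.searchsorted(self.score_edges, score, side="right")) - 1
        return min(idx, len(self.score_edges) - 2)


@dataclass
class WERun:
    """Bookkeeping of one seeded WE run: post-resampling ensembles per iteration."""

    iterations: list[list[WalkerRecord]]
    tau_ns: float
    seed: int
    grid: BinGrid

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def total_weight(self, k: int) -> float:
        return sum(rec.weight for rec in extract_iteration(self, k))

    def summary(self) -> dict:
        """JSON-serializable summary (ids, weights, progress coordinates)."""
        return {
            "tau_ns": self.tau_ns,
            "seed": self.seed,
            "score_edges": list(self.grid.score_edges),
            "target_per_bin": self.grid.target_per_bin,
            "iterations": [
                [
                    {
                        "id": rec.id,
                        "parent_id": rec.parent_id,
                        "weight": rec.weight,
                        "score": rec.score,
                        "identity": rec.identity,
                    }
                    for rec in ensemble
                ]
                for ensemble in self.iterations
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), sort_keys=True)


def pose_scorer(params: ReactionScoreParams | None = None) -> Scorer:
    """Scorer for states exposing per-Trp geometry via a ``channels`` mapping."""
    params = params or ReactionScoreParams()

    def score(state: object) -> tuple[float, int]:
        identity, s = best_trp(state.channels, params)  # type: ignore[attr-defined]
        return s, identity

    return score


def assign_bins(
    walkers: Sequence[Walker], grid: BinGrid, scorer: Scorer
) -> dict[int, tuple[int, int]]:
    """Map walker id -> (score-bin index, identity)."""
    out = {}
    for walker in walkers:
        score, identity = scorer(walker.state)
        out[walker.id] = (grid.score_bin(score), identity)
    return out


def _split(
    bin_walkers: list[Walker], target: int, counter: itertools.count
) -> list[Walker]:
    """Split heaviest-first by repeated halving until the bin holds target."""
    while len(bin_walkers) < target:
        bin_walkers.sort(key=lambda w: (-w.weight, w.id))
        parent = bin_walkers.pop(0)
        half = parent.weight / 2.0
        for _ in range(2):
            bin_walkers.append(
                Walker(
                    id=next(counter),
                    weight=half,
                    state=parent.state,
                    parent_id=parent.id,
                    history=list(parent.history),
                )
            )
    return bin_walkers


def _merge(
    bin_walkers: list[Walker], target: int, rng: np.random.Generator
) -> list[Walker]:
    """Merge the two lightest walkers repeatedly; survivor chosen by weight."""
    while len(bin_walkers) > target:
        bin_walkers.sort(key=lambda w: (w.weight, w.id))
        a, b = bin_walkers[0], bin_walkers[1]
        total = a.weight + b.weight
        survivor = a if rng.random() < a.weight / total else b
        survivor.weight = total
        bin_walkers = [survivor] + bin_walkers[2:]
    return bin_walkers


def resample(
    walkers: Sequence[Walker],
    grid: BinGrid,
    rng: np.random.Generator,
    scorer: Scorer,
    id_counter: itertools.count | None = None,
) -> list[Walker]:
    """Split/merge so every occupied bin holds exactly ``target_per_bin``.

    Total weight is conserved exactly up to floating-point addition
    (halving is exact in binary; merge sums two weights), so Σw stays at 1
    to well under 1e-12 over many iterations.  Empty bins are skipped.
    """
    if id_counter is None:
        id_counter = itertools.count(max((w.id for w in walkers), default=-1) + 1)
    bins = assign_bins(walkers, grid, scorer)
    grouped: dict[tuple[int, int], list[Walker]] = {}
    for walker in walkers:
        grouped.setdefault(bins[walker.id], []).append(walker)

    out: list[Walker] = []
    for key in sorted(grouped):
        members = grouped[key]
        if len(members) > grid.target_per_bin:
            members = _merge(members, grid.target_per_bin, rng)
        elif len(members) < grid.target_per_bin:
            members = _split(members, grid.target_per_bin, id_counter)
        out.extend(members)
    out.sort(key=lambda w: w.id)
    return out


def run_we(
    propagator: Propagator,
    initial_walkers: Sequence[Walker],
    grid: BinGrid,
    n_iterations: int,
    tau_ns: float,
    seed: int,
    scorer: Scorer,
) -> WERun:
    """Alternate propagate -> score -> bin -> resample for n iterations.

    Fully deterministic given the seed: one named RNG drives propagation and
    merge decisions.  Iterations are 1-based, so "iteration 12" is the 12th
    post-resampling ensemble.  With ``n_iterations = 0`` the initial
    ensemble is recorded unchanged.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    total = sum(w.weight for w in initial_walkers)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"initial weights sum to {total}, expected 1")

    rng = np.random.default_rng(seed)
    counter = itertools.count(max((w.id for w in initial_walkers), default=-1) + 1)
    walkers = [
        Walker(w.id, w.weight, w.state, w.parent_id, list(w.history))
        for w in initial_walkers
    ]

    def snapshot(current: Sequence[Walker]) -> list[WalkerRecord]:
        records = []
        for w in current:
            score, identity = scorer(w.state)
            records.append(
                WalkerRecord(
                    id=w.id,
                    parent_id=w.parent_id,
                    weight=w.weight,
                    score=score,
                    identity=identity,
                    state=w.state,
                    history=tuple(w.history),
                )
            )
        return records

    iterations: list[list[WalkerRecord]] = []
    if n_iterations == 0:
        return WERun(
            iterations=[snapshot(walkers)], tau_ns=tau_ns, seed=seed, grid=grid
        )

    for iteration in range(1, n_iterations + 1):
        for walker in walkers:
            try:
                walker.state = propagator(walker.state, tau_ns, rng)
            except Exception as exc:
                raise RuntimeError(
                    f"propagator failed at iteration {iteration}, "
                    f"walker {walker.id}: {exc}"
                ) from exc
            score, identity = scorer(walker.state)
            walker.history.append((score, identity))
        walkers = resample(walkers, grid, rng, scorer, counter)
        iterations.append(snapshot(walkers))
    return WERun(iterations=iterations, tau_ns=tau_ns, seed=seed, grid=grid)


def extract_iteration(run: WERun, k: int) -> list[WalkerRecord]:
    """Post-resampling ensemble of (1-based) iteration k, with history."""
    if not 1 <= k <= run.n_iterations:
        raise IndexError(
            f"iteration {k} out of range 1..{run.n_iterations}"
        )
    return run.iterations[k - 1]
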