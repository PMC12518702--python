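"""End-to-end orchestration: design enumeration, simulation, WE, landscapes.

A run configuration mirrors the study design of the simulation campaign:
a list of starting configurations (each placing one Trp channel in the
catalytic pose) times a replicate count, expanded into independent seeded
runs (4 configurations x 3 replicates = 12 runs by default).  Each run
drives the synthetic propagator through the weighted-ensemble engine (or
plain trajectory simulation when WE is disabled); pooled weighted samples
are projected into per-channel free-energy surfaces with a shared zero,
basins are located, and dissociation times tabulated.  Every output is
reproducible from the master seed and the serialized config alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import free_energy as fe
from .geometry import dissociation_time
from .reaction_score import ReactionScoreParams
from .synthetic import (
    ChannelKinetics,
    PoseState,
    default_kinetics,
    simulate_series,
    we_propagator,
)
from .weighted_ensemble import BinGrid, Walker, WERun, pose_scorer, run_we

__all__ = ["DesignEntry", "RunDescriptor", "RunConfig", "enumerate_design", "run_pipeline"]

#: d (Å) the non-focused channels start from, well outside the catalytic site.
_DISPLACED_D = 15.0
_DISPLACED_THETA = 90.0


@dataclass(frozen=True)
class DesignEntry:
    """One starting configuration and its replicate count."""

    name: str
    replicates: int
    focus_channel: int

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"configuration {self.name!r}: replicates must be >= 1")


@dataclass(frozen=True)
class RunDescriptor:
    name: str
    replicate: int
    seed: int
    focus_channel: int


@dataclass
class RunConfig:
    """Serializable pipeline configuration with explicit seeds."""

    design: list[DesignEntry] = field(
        default_factory=lambda: [
            DesignEntry("af2m_original", 3, 1),
            DesignEntry("trp8_optimized", 3, 1),
            DesignEntry("trp12_shifted", 3, 2),
            DesignEntry("trp14_shifted", 3, 3),
        ]
    )
    score: ReactionScoreParams = field(default_factory=ReactionScoreParams)
    grid: BinGrid = field(default_factory=BinGrid)
    fe_params: fe.FEParams = field(default_factory=fe.FEParams)
    kinetics: dict[int, ChannelKinetics] = field(default_factory=default_kinetics)
    seed: int = 1
    we_enabled: bool = True
    n_iterations: int = 12
    tau_ns: float = 0.5
    n_walkers: int = 20
    warmup_iterations: int = 2
    plain_duration_ns: float = 100.0
    plain_dt_ns: float = 0.1
    d_edges: tuple[float, float, float] = (2.0, 20.0, 0.5)
    theta_edges: tuple[float, float, float] = (0.0, 180.0, 5.0)
    dissociation_threshold_a: float = 12.0
    dissociation_persistence_ns: float = 5.0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "design" in kwargs:
            kwargs["design"] = [DesignEntry(**entry) for entry in kwargs["design"]]
        if "score" in kwargs:
            kwargs["score"] = ReactionScoreParams(**kwargs["score"])
        if "grid" in kwargs:
            grid = dict(kwargs["grid"])
            if "score_edges" in grid:
                grid["score_edges"] = tuple(grid["score_edges"])
            if "identities" in grid:
                grid["identities"] = tuple(grid["identities"])
            kwargs["grid"] = BinGrid(**grid)
        if "fe_params" in kwargs:
            kwargs["fe_params"] = fe.FEParams(**kwargs["fe_params"])
        if "kinetics" in kwargs:
            kwargs["kinetics"] = {
                int(i): ChannelKinetics(**params)
                for i, params in kwargs["kinetics"].items()
            }
        for key in ("d_edges", "theta_edges"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        out = asdict(self)
        out["kinetics"] = {str(i): asdict(k) for i, k in self.kinetics.items()}
        return out

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi, step = self.d_edges
        d = np.arange(lo, hi + step / 2, step)
        lo, hi, step = self.theta_edges
        theta = np.arange(lo, hi + step / 2, step)
        return d, theta


def enumerate_design(config: RunConfig) -> list[RunDescriptor]:
    """Expand configurations x replicates into seeded run descriptors.

    Per-run seeds are derived from the master seed through a NumPy seed
    sequence, so they are reproducible, distinct, and independent of the
    order in which runs later execute.
    """
    if not config.design:
        raise ValueError("design block is empty")
    total = sum(entry.replicates for entry in config.design)
    children = np.random.SeedSequence(config.seed).spawn(total)
    descriptors = []
    i = 0
    for entry in config.design:
        for replicate in range(1, entry.replicates + 1):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            descriptors.append(
                RunDescriptor(entry.name, replicate, seed, entry.focus_channel)
            )
            i += 1
    return descriptors


def _initial_walkers(config: RunConfig, focus: int) -> list[Walker]:
    """Focused channel starts bound at its basin; the rest start displaced."""
    channels = {}
    bound = {}
    for identity, kin in config.kinetics.items():
        if identity == focus:
            channels[identity] = (kin.basin_d, kin.basin_theta)
            bound[identity] = True
        else:
            channels[identity] = (_DISPLACED_D, _DISPLACED_THETA)
            bound[identity] = False
    state = PoseState(channels=channels, bound=bound)
    n = config.n_walkers
    return [Walker(id=i, weight=1.0 / n, state=state) for i in range(n)]


def _pool_we_samples(
    run: WERun, config: RunConfig
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Weighted (d, theta) samples per channel, pooled over iterations.

    Each post-warmup iteration contributes its full ensemble; weights are
    divided by the number of pooled iterations so the grand total is 1.
    """
    start = min(config.warmup_iterations, run.n_iterations - 1)
    pooled = run.iterations[start:]
    samples: dict[int, list] = {i: [] for i in config.kinetics}
    weights: dict[int, list] = {i: [] for i in config.kinetics}
    for ensemble in pooled:
        for rec in ensemble:
            for identity, (d, theta) in rec.state.channels.items():
                samples[identity].append((d, theta))
                weights[identity].append(rec.weight / len(pooled))
    return (
        {i: np.array(v) for i, v in samples.items() if v},
        {i: np.array(v) for i, v in weights.items() if v},
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages and write the report bundle.

    Outputs under ``out_dir``: per-run WE summaries (JSON), a long-form
    landscape CSV (channel, d, theta, p, F), a basin table, a
    dissociation-time table, and ``summary.json`` holding the config, the
    derived seeds, and headline numbers.  Deterministic per master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    descriptors = enumerate_design(config)
    d_edges, theta_edges = config.edge_arrays()
    scorer = pose_scorer(config.score)

    all_samples: dict[int, list[np.ndarray]] = {i: [] for i in config.kinetics}
    all_weights: dict[int, list[np.ndarray]] = {i: [] for i in config.kinetics}
    we_summaries = []

    for desc in descriptors:
        if config.we_enabled:
            run = run_we(
                propagator=we_propagator(config.kinetics),
                initial_walkers=_initial_walkers(config, desc.focus_channel),
                grid=config.grid,
                n_iterations=config.n_iterations,
                tau_ns=config.tau_ns,
                seed=desc.seed,
                scorer=scorer,
            )
            samples, weights = _pool_we_samples(run, config)
            we_summaries.append(
                {
                    "run": f"{desc.name}_r{desc.replicate}",
                    "seed": desc.seed,
                    "final_total_weight": run.total_weight(run.n_iterations),
                    "n_walkers_final": len(run.iterations[-1]),
                }
            )
        else:
            series = simulate_series(
                config.kinetics, config.plain_duration_ns, config.plain_dt_ns,
                desc.seed,
            )
            samples = {
                i: np.column_stack([series.d(i), series.theta(i)])
                for i in series.identities
            }
            n = len(series)
            weights = {i: np.full(n, 1.0 / n) for i in series.identities}
        for identity in samples:
            all_samples[identity].append(samples[identity])
            all_weights[identity].append(weights[identity])

    n_runs = len(descriptors)
    samples_by_channel = {
        i: np.vstack(chunks) for i, chunks in all_samples.items() if chunks
    }
    weights_by_channel = {
        i: np.concatenate(all_weights[i]) / n_runs for i in samples_by_channel
    }
    surfaces = fe.channel_surfaces(
        samples_by_channel, weights_by_channel, d_edges, theta_edges,
        config.fe_params,
    )

    landscape_rows = []
    basin_rows = []
    for identity, surface in sorted(surfaces.items()):
        for i, d_c in enumerate(surface.d_centers):
            for j, t_c in enumerate(surface.theta_centers):
                if surface.occupied[i, j]:
                    landscape_rows.append(
                        {
                            "channel": identity,
                            "d": d_c,
                            "theta": t_c,
                            "p": surface.p[i, j],
                            "F": surface.F[i, j],
                        }
                    )
        for rank, (d_c, t_c, f_val) in enumerate(
            fe.find_basins(surface), start=1
        ):
            basin_rows.append(
                {"channel": identity, "rank": rank, "d": d_c, "theta": t_c,
                 "F": f_val}
            )
    pd.DataFrame(landscape_rows).to_csv(
        out / "landscape.csv", index=False, float_format="%.9g"
    )
    pd.DataFrame(basin_rows).to_csv(
        out / "basins.csv", index=False, float_format="%.9g"
    )

    dissociation_rows = []
    for desc in descriptors:
        series = simulate_series(
            config.kinetics, config.plain_duration_ns, config.plain_dt_ns,
            desc.seed,
        )
        for identity in series.identities:
            t_diss = dissociation_time(
                series, identity,
                config.dissociation_threshold_a,
                config.dissociation_persistence_ns,
            )
            dissociation_rows.append(
                {
                    "run": f"{desc.name}_r{desc.replicate}",
                    "channel": identity,
                    "dissociation_ns": t_diss if t_diss is not None else np.nan,
                }
            )
    pd.DataFrame(dissociation_rows).to_csv(
        out / "dissociation.csv", index=False, float_format="%.9g"
    )

    summary = {
        "config": config.to_dict(),
        "n_runs": n_runs,
        "runs": [asdict(d) for d in descriptors],
        "we": we_summaries,
        "basins": basin_rows,
        "outputs": ["landscape.csv", "basins.csv", "dissociation.csv"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
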