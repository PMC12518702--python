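"""Synthetic ensembles with the statistical structure the analysis assumes.

Real halogenase–substrate trajectories are not available offline, so this
module generates surrogate data exhibiting the phenomenology the analysis
stages are built to detect:

* two-state (bound/unbound) kinetics per Trp channel — mean-reverting
  (Ornstein–Uhlenbeck) fluctuation of (d, theta) about a catalytic basin
  while bound, an exponentially distributed escape to an unbound state, and
  linear drift away from the site with broadened angular noise afterwards;
* a "Leu displacement" channel: an extra escape rate standing in for the
  transient Leu–indole contacts that evict the C-terminal Trp from the
  catalytic site;
* an inverse-geometry constructor that places the named atoms (Lys CE/NZ,
  Trp CZ3/C5, Arg CZ, Asp CG, peptide atoms) so the geometry stage recovers
  requested (d, theta) and anchor targets exactly, under a random rigid
  transform;
* a WE-ready propagator over the same kinetics, plus a 1D double-well
  diffusion toy used to validate the weighted-ensemble engine against
  brute force.

This is an emulation of the described phenomenology, not force-field
physics: defaults put the stable channels' basin at (8 Å, 140°) and give
the dissociating channel a 40 ns mean escape time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geometry import DEFAULT_IDENTITY_MAP, GeometrySeries, default_atom_map
from .trajectory_io import AtomKey, TrajectoryFrame, write_geometry_table, write_pdb_frames

__all__ = [
    "ChannelKinetics",
    "AnchorKinetics",
    "PoseState",
    "default_kinetics",
    "simulate_series",
    "frames_from_targets",
    "initial_pose_state",
    "we_propagator",
    "double_well_propagator",
    "double_well_scorer",
    "write_fixture_bundle",
    "SCENARIOS",
]

#: Angle (degrees) unbound Trp orientations scatter about, and their spread.
_UNBOUND_THETA_CENTER = 90.0
_UNBOUND_THETA_SD = 35.0
#: Residual positional noise (Å) superposed on the unbound drift.
_UNBOUND_D_SD = 0.3


@dataclass(frozen=True)
class ChannelKinetics:
    """Two-state kinetics of one Trp channel.

    Bound state: OU fluctuation about (``basin_d``, ``basin_theta``) with
    stationary spreads ``sd_d``/``sd_theta`` and relaxation time
    ``relaxation_ns``.  Escape to the unbound state is exponential with
    total rate ``k_off + leu_contact_rate`` (the latter emulating
    displacement of the indole by an adjacent Leu side chain); once unbound,
    d drifts away at ``unbound_drift`` Å/ns and theta decorrelates.
    """

    basin_d: float = 8.0
    basin_theta: float = 140.0
    sd_d: float = 0.8
    sd_theta: float = 8.0
    relaxation_ns: float = 1.0
    k_off: float = 0.0
    unbound_drift: float = 2.0
    leu_contact_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.basin_d, self.sd_d, self.sd_theta, self.relaxation_ns) <= 0:
            raise ValueError("basin_d, sd_d, sd_theta, relaxation_ns must be positive")
        if not 0.0 <= self.basin_theta <= 180.0:
            raise ValueError("basin_theta must lie in [0, 180]")
        if self.k_off < 0 or self.leu_contact_rate < 0 or self.unbound_drift <= 0:
            raise ValueError("rates must be >= 0 and unbound_drift > 0")

    @property
    def total_escape_rate(self) -> float:
        return self.k_off + self.leu_contact_rate


@dataclass(frozen=True)
class AnchorKinetics:
    """OU fluctuation of the two anchoring distances."""

    d15_center: float = 8.5
    d15_sd: float = 0.7
    com_center: float = 11.0
    com_sd: float = 1.5
    relaxation_ns: float = 1.0

    def __post_init__(self) -> None:
        if min(self.d15_center, self.d15_sd, self.com_center, self.com_sd,
               self.relaxation_ns) <= 0:
            raise ValueError("anchor parameters must be positive")


def default_kinetics() -> dict[int, ChannelKinetics]:
    """Study-condition kinetics for the three Trp channels.

    Channels 1 and 2 (Trp8/Trp12) are stably bound in the (8 Å, 140°) basin
    with a slow residual escape; channel 3 (Trp14) has a broader basin and a
    40 ns mean escape time dominated by the Leu-contact displacement rate.
    """
    stable = ChannelKinetics(k_off=1e-3)
    return {
        1: stable,
        2: stable,
        3: ChannelKinetics(
            sd_d=1.2, sd_theta=14.0, k_off=0.005, leu_contact_rate=0.020
        ),
    }


def _ou_path(
    n: int,
    dt: float,
    center: float,
    sd: float,
    relaxation: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact-discretization stationary OU path of length n."""
    a = np.exp(-dt / relaxation)
    step_sd = sd * np.sqrt(1.0 - a * a)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, sd)  # stationary start
    noise[1:] = rng.normal(0.0, step_sd, n - 1)
    return center + lfilter([1.0], [1.0, -a], noise)


def simulate_series(
    kinetics: dict[int, ChannelKinetics],
    duration_ns: float,
    dt_ns: float,
    seed: int,
    anchors: AnchorKinetics | None = None,
    identity_map: dict[int, str] | None = None,
) -> GeometrySeries:
    """Simulate per-channel (d, theta) traces plus anchor distances.

    The escape time of each channel is drawn in continuous time (so halving
    the sampling interval does not change the escape-time distribution);
    bound-state OU segments use the exact discrete update.  Deterministic
    per seed.
    """
    if duration_ns <= 0 or dt_ns <= 0:
        raise ValueError("duration_ns and dt_ns must be positive")
    anchors = anchors or AnchorKinetics()
    identity_map = identity_map or dict(DEFAULT_IDENTITY_MAP)
    rng = np.random.default_rng(seed)

    n = int(round(duration_ns / dt_ns)) + 1
    t = np.arange(n) * dt_ns
    data: dict[str, np.ndarray] = {"frame": np.arange(n), "time_ns": t}

    for identity in sorted(kinetics):
        kin = kinetics[identity]
        label = identity_map[identity]
        rate = kin.total_escape_rate
        t_esc = rng.exponential(1.0 / rate) if rate > 0 else np.inf

        d = _ou_path(n, dt_ns, kin.basin_d, kin.sd_d, kin.relaxation_ns, rng)
        theta = _ou_path(
            n, dt_ns, kin.basin_theta, kin.sd_theta, kin.relaxation_ns, rng
        )
        unbound = t >= t_esc
        if unbound.any():
            k = int(np.argmax(unbound))
            d_at_escape = d[k - 1] if k > 0 else kin.basin_d
            d[k:] = (
                d_at_escape
                + kin.unbound_drift * (t[k:] - t_esc)
                + rng.normal(0.0, _UNBOUND_D_SD, n - k)
            )
            theta[k:] = rng.normal(
                _UNBOUND_THETA_CENTER, _UNBOUND_THETA_SD, n - k
            )
        data[f"d_{label}"] = np.maximum(d, 1e-6)
        data[f"theta_{label}"] = np.clip(theta, 0.0, 180.0)

    data["d_r430_d15"] = np.maximum(
        _ou_path(n, dt_ns, anchors.d15_center, anchors.d15_sd,
                 anchors.relaxation_ns, rng),
        1e-6,
    )
    data["d_r430_com"] = np.maximum(
        _ou_path(n, dt_ns, anchors.com_center, anchors.com_sd,
                 anchors.relaxation_ns, rng),
        1e-6,
    )
    return GeometrySeries(pd.DataFrame(data), dict(identity_map))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def frames_from_targets(
    targets: dict[int, tuple[float, float]],
    anchor_targets: tuple[float, float] = (8.5, 11.0),
    seed: int = 0,
    frame_index: int = 0,
    time_ns: float = 0.0,
) -> TrajectoryFrame:
    """Build a frame whose computed observables equal the targets exactly.

    ``targets`` maps Trp identity to the desired (d, theta);
    ``anchor_targets`` fixes the Arg CZ–Asp CG and Arg CZ–COM distances.
    A random rigid rotation + translation (from ``seed``) is applied, so
    different seeds give different coordinates with identical observables.
    """
    for identity, (d, theta) in targets.items():
        if d <= 0:
            raise ValueError(f"channel {identity}: target distance must be positive")
        if not 0.0 <= theta <= 180.0:
            raise ValueError(f"channel {identity}: target angle outside [0, 180]")
    d15_target, com_target = anchor_targets
    if d15_target <= 0 or com_target <= 0:
        raise ValueError("anchor targets must be positive")

    atom_map = default_atom_map()
    coords: dict[AtomKey, np.ndarray] = {}

    lys_ce, lys_nz = atom_map.lys_keys
    u = np.array([0.0, 0.0, 1.0])  # CE -> NZ direction
    coords[lys_ce] = np.zeros(3)
    coords[lys_nz] = 1.5 * u

    for identity in sorted(targets):
        d, theta = targets[identity]
        azimuth = 2.0 * np.pi * (identity - 1) / 3.0
        w = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])  # perp to u
        radial = _unit(0.5 * u + w)
        c5 = coords[lys_nz] + d * radial
        v = np.cos(np.radians(theta)) * u + np.sin(np.radians(theta)) * w
        cz3 = c5 - 1.4 * v  # so (C5 - CZ3) is parallel to v, angle(v, u) = theta
        cz3_key, c5_key = atom_map.trp_keys(identity)
        coords[c5_key] = c5
        coords[cz3_key] = cz3

    asp_cg = np.array([6.0, -4.0, 0.0])
    coords[atom_map.asp_cg] = asp_cg
    arg_cz = asp_cg + d15_target * np.array([1.0, 0.0, 0.0])
    coords[atom_map.arg_cz] = arg_cz

    # Two dummy peptide carbons tune the (equal-mass) chain-P center of mass
    # onto a point at exactly com_target from the Arg CZ.
    com_point = arg_cz + com_target * np.array([0.0, 1.0, 0.0])
    peptide_atoms = [k for k in coords if k.chain_id == "P"]
    n_peptide = len(peptide_atoms) + 2
    known_sum = np.sum([coords[k] for k in peptide_atoms], axis=0)
    pair_sum = n_peptide * com_point - known_sum
    delta = np.array([0.7, 0.0, 0.3])
    coords[AtomKey("P", 1, "GLY", "CA")] = pair_sum / 2.0 + delta
    coords[AtomKey("P", 2, "GLY", "CA")] = pair_sum / 2.0 - delta

    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))  # well-defined orthogonal matrix
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]  # proper rotation
    shift = rng.uniform(-20.0, 20.0, 3)
    transformed = {key: q @ xyz + shift for key, xyz in coords.items()}
    return TrajectoryFrame(frame_index, time_ns, transformed)


@dataclass(frozen=True)
class PoseState:
    """Walker state of the synthetic propagator: per-channel (d, theta)."""

    channels: dict[int, tuple[float, float]] = field(default_factory=dict)
    bound: dict[int, bool] = field(default_factory=dict)
    time_ns: float = 0.0


def initial_pose_state(kinetics: dict[int, ChannelKinetics]) -> PoseState:
    """All channels bound at their basin centers."""
    return PoseState(
        channels={i: (k.basin_d, k.basin_theta) for i, k in kinetics.items()},
        bound={i: True for i in kinetics},
    )


def we_propagator(kinetics: dict[int, ChannelKinetics]):
    """Propagator advancing a :class:`PoseState` by tau under the kinetics.

    Bound channels follow the exact OU update over tau unless their
    exponential escape clock fires inside the interval, in which case they
    finish the interval drifting away unbound.  Unbound channels keep
    drifting; there is no rebinding.  All randomness comes from the RNG
    stream handed in by the WE engine, so runs are seed-deterministic.
    """

    def _ou_step(x: float, center: float, sd: float, relaxation: float,
                 dt: float, rng: np.random.Generator) -> float:
        if dt <= 0:
            return x
        a = np.exp(-dt / relaxation)
        return center + (x - center) * a + rng.normal(0.0, sd * np.sqrt(1 - a * a))

    def propagate(state: PoseState, tau_ns: float, rng: np.random.Generator) -> PoseState:
        channels: dict[int, tuple[float, float]] = {}
        bound: dict[int, bool] = {}
        for identity in sorted(state.channels):
            kin = kinetics[identity]
            d, theta = state.channels[identity]
            is_bound = state.bound.get(identity, True)
            if is_bound:
                rate = kin.total_escape_rate
                wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if wait >= tau_ns:
                    d = _ou_step(d, kin.basin_d, kin.sd_d, kin.relaxation_ns,
                                 tau_ns, rng)
                    theta = _ou_step(theta, kin.basin_theta, kin.sd_theta,
                                     kin.relaxation_ns, tau_ns, rng)
                else:
                    d = _ou_step(d, kin.basin_d, kin.sd_d, kin.relaxation_ns,
                                 wait, rng)
                    d += kin.unbound_drift * (tau_ns - wait) + rng.normal(
                        0.0, _UNBOUND_D_SD
                    )
                    theta = rng.normal(_UNBOUND_THETA_CENTER, _UNBOUND_THETA_SD)
                    is_bound = False
            else:
                d += kin.unbound_drift * tau_ns + rng.normal(0.0, _UNBOUND_D_SD)
                theta = rng.normal(_UNBOUND_THETA_CENTER, _UNBOUND_THETA_SD)
            channels[identity] = (max(d, 1e-6), float(np.clip(theta, 0.0, 180.0)))
            bound[identity] = is_bound
        return PoseState(
            channels=channels, bound=bound, time_ns=state.time_ns + tau_ns
        )

    return propagate


def double_well_propagator(dt: float = 0.005, barrier: float = 2.0,
                           diffusion: float = 0.5):
    """Overdamped diffusion in U(x) = barrier * (x^2 - 1)^2.

    The classic two-state toy: wells at x = ±1 separated by a barrier of
    ``barrier`` energy units; with unit mobility the Euler–Maruyama step is
    x += -U'(x) dt + sqrt(2 D dt) xi.  Used to check WE estimates against
    brute-force ensembles.
    """

    def propagate(x: float, tau: float, rng: np.random.Generator) -> float:
        steps = max(1, int(round(tau / dt)))
        noise = rng.standard_normal(steps) * np.sqrt(2.0 * diffusion * dt)
        for k in range(steps):
            x += -4.0 * barrier * x * (x * x - 1.0) * dt + noise[k]
        return x

    return propagate


def double_well_scorer(x: float) -> tuple[float, int]:
    """Monotone map of position onto the bounded WE score axis."""
    return float(np.clip((x + 2.0) / 4.0, 0.0, 1.0)), 1


#: Named fixture scenarios: kinetics overrides + sampling schedule.
SCENARIOS: dict[str, dict] = {
    "trp8_stable": {"duration_ns": 50.0, "dt_ns": 0.5, "focus": 1},
    "trp12_stable": {"duration_ns": 50.0, "dt_ns": 0.5, "focus": 2},
    "trp14_dissociating": {"duration_ns": 200.0, "dt_ns": 0.1, "focus": 3},
    "leu_displacement": {"duration_ns": 200.0, "dt_ns": 0.1, "focus": 3,
                         "leu_only": True},
    "anchor_profile": {"duration_ns": 100.0, "dt_ns": 0.1, "focus": 1},
}


def write_fixture_bundle(
    out_dir: str | Path, scenario: str, seed: int, max_pdb_frames: int = 40
) -> dict[str, Path]:
    """Write one scenario as PDB frames + geometry CSV + JSON manifest.

    The PDB holds a subsample of frames rebuilt by the inverse-geometry
    constructor from the simulated series, so re-reading it and running the
    geometry stage reproduces the series values at those time points.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    spec = SCENARIOS[scenario]
    kinetics = default_kinetics()
    if spec.get("leu_only"):
        kin3 = kinetics[3]
        kinetics[3] = replace(
            kin3, k_off=0.0, leu_contact_rate=kin3.total_escape_rate
        )
    series = simulate_series(
        kinetics, spec["duration_ns"], spec["dt_ns"], seed
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{scenario}_geometry.csv"
    write_geometry_table(series, csv_path)

    stride = max(1, len(series) // max_pdb_frames)
    rows = series.data.iloc[::stride]
    frames = []
    for new_index, (_, row) in enumerate(rows.iterrows()):
        targets = {
            i: (row[f"d_{series.identity_map[i]}"],
                row[f"theta_{series.identity_map[i]}"])
            for i in series.identities
        }
        frames.append(
            frames_from_targets(
                targets,
                anchor_targets=(row["d_r430_d15"], row["d_r430_com"]),
                seed=seed * 100003 + new_index,
                frame_index=new_index,
                time_ns=float(row["time_ns"]),
            )
        )
    pdb_path = out / f"{scenario}_frames.pdb"
    write_pdb_frames(frames, pdb_path)

    manifest = {
        "scenario": scenario,
        "seed": seed,
        "duration_ns": spec["duration_ns"],
        "dt_ns": spec["dt_ns"],
        "pdb_stride": stride,
        "kinetics": {str(i): asdict(k) for i, k in kinetics.items()},
        "anchors": asdict(AnchorKinetics()),
    }
    manifest_path = out / f"{scenario}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"csv": csv_path, "pdb": pdb_path, "manifest": manifest_path}
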