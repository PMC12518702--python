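"""Per-frame geometric observables of the catalytic pose.

The observables quantify how a substrate Trp presents its indole to the
catalytic lysine of a flavin-dependent halogenase:

* ``d`` — distance between the Trp indole C5 atom and the Lys NZ atom (Å);
* ``theta`` — angle between the indole plane vector (CZ3 -> C5) and the Lys
  side-chain vector (CE -> NZ), in degrees in [0, 180];
* anchor distances — Arg guanidinium carbon (CZ) to the substrate Asp
  carboxylate carbon (CG), and Arg CZ to the peptide center of mass —
  probing a secondary electrostatic anchoring site;
* dissociation time — when a Trp leaves the catalytic site for good.

Trp channels are tracked by a discrete identity (default 1 -> Trp8,
2 -> Trp12, 3 -> Trp14 in substrate-core numbering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import AbsentAtomError, AtomKey, TrajectoryFrame

__all__ = [
    "GeometrySeries",
    "AtomMap",
    "AbsentObservableError",
    "DegenerateGeometryError",
    "default_atom_map",
    "atom_distance",
    "trp_lys_distance",
    "alignment_angle",
    "peptide_com",
    "compute_series",
    "dissociation_time",
    "DEFAULT_IDENTITY_MAP",
]

#: Default Trp identity labels (substrate-core numbering).
DEFAULT_IDENTITY_MAP: dict[int, str] = {1: "trp8", 2: "trp12", 3: "trp14"}


class AbsentObservableError(KeyError):
    """Query for an observable column the series does not carry."""


class DegenerateGeometryError(ValueError):
    """An angle was requested between vectors of zero length."""


@dataclass
class GeometrySeries:
    """Tidy per-frame table of observables.

    Columns: ``frame``, ``time_ns``, ``d_<label>`` / ``theta_<label>`` per
    Trp channel, and anchor columns ``d_r430_d15`` / ``d_r430_com``.
    Missing observables are simply absent columns; querying them raises
    :class:`AbsentObservableError`.
    """

    data: pd.DataFrame
    identity_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_MAP)
    )

    def __post_init__(self) -> None:
        for col in ("frame", "time_ns"):
            if col not in self.data.columns:
                raise ValueError(f"geometry table lacks required column {col!r}")
        t = self.data["time_ns"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("time_ns must be non-decreasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time_ns(self) -> np.ndarray:
        return self.data["time_ns"].to_numpy(dtype=float)

    def _column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise AbsentObservableError(f"observable {name!r} absent from series")
        return self.data[name].to_numpy(dtype=float)

    def _label(self, identity: int) -> str:
        try:
            return self.identity_map[identity]
        except KeyError:
            raise AbsentObservableError(
                f"unknown Trp identity {identity}; known: {sorted(self.identity_map)}"
            ) from None

    def d(self, identity: int) -> np.ndarray:
        """Trp C5 – Lys NZ distance trace (Å) for one Trp channel."""
        return self._column(f"d_{self._label(identity)}")

    def theta(self, identity: int) -> np.ndarray:
        """Alignment angle trace (degrees) for one Trp channel."""
        return self._column(f"theta_{self._label(identity)}")

    def anchor(self, name: str) -> np.ndarray:
        """Anchor distance trace; ``name`` is ``"r430_d15"`` or ``"r430_com"``."""
        return self._column(f"d_{name}")

    @property
    def identities(self) -> tuple[int, ...]:
        return tuple(
            i
            for i, label in sorted(self.identity_map.items())
            if f"d_{label}" in self.data.columns
        )


@dataclass
class AtomMap:
    """Names the atoms the observables are computed from.

    Residues are (chain_id, residue_number, residue_name) triples using the
    author numbering of the source structure.  ``peptide_chain`` selects the
    substrate-peptide atoms entering the center of mass (all atoms of that
    chain, mass-weighted).
    """

    trp_residues: dict[int, tuple[str, int, str]]
    lys: tuple[str, int, str]
    arg: tuple[str, int, str]
    asp: tuple[str, int, str]
    peptide_chain: str
    identity_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_MAP)
    )

    def trp_keys(self, identity: int) -> tuple[AtomKey, AtomKey]:
        """(CZ3, C5) keys for a Trp channel."""
        chain, num, name = self.trp_residues[identity]
        return (
            AtomKey(chain, num, name, "CZ3"),
            AtomKey(chain, num, name, "C5"),
        )

    @property
    def lys_keys(self) -> tuple[AtomKey, AtomKey]:
        """(CE, NZ) keys of the catalytic lysine."""
        chain, num, name = self.lys
        return AtomKey(chain, num, name, "CE"), AtomKey(chain, num, name, "NZ")

    @property
    def arg_cz(self) -> AtomKey:
        chain, num, name = self.arg
        return AtomKey(chain, num, name, "CZ")

    @property
    def asp_cg(self) -> AtomKey:
        chain, num, name = self.asp
        return AtomKey(chain, num, name, "CG")

    def peptide_selection(self, frame: TrajectoryFrame) -> list[AtomKey]:
        return [k for k in frame.coords if k.chain_id == self.peptide_chain]


def default_atom_map() -> AtomMap:
    """Atom map for the synthetic complex: enzyme chain E, substrate chain P."""
    return AtomMap(
        trp_residues={1: ("P", 8, "TRP"), 2: ("P", 12, "TRP"), 3: ("P", 14, "TRP")},
        lys=("E", 139, "LYS"),
        arg=("E", 430, "ARG"),
        asp=("P", 15, "ASP"),
        peptide_chain="P",
    )


def atom_distance(frame: TrajectoryFrame, a: AtomKey, b: AtomKey) -> float:
    """Euclidean distance (Å) between two named atoms of a frame."""
    return float(np.linalg.norm(frame.position(a) - frame.position(b)))


def trp_lys_distance(
    frame: TrajectoryFrame, trp_c5: AtomKey, lys_nz: AtomKey
) -> float:
    """Catalytic approach distance: Trp indole C5 to Lys NZ (Å)."""
    return atom_distance(frame, trp_c5, lys_nz)


def alignment_angle(
    frame: TrajectoryFrame,
    trp_cz3: AtomKey,
    trp_c5: AtomKey,
    lys_ce: AtomKey,
    lys_nz: AtomKey,
) -> float:
    """Angle theta (degrees) between CZ3->C5 and CE->NZ vectors.

    The normalized dot product is clamped to [-1, 1] before the arccos so
    rounding can never produce a NaN; the result lies in [0, 180].
    """
    u = frame.position(trp_c5) - frame.position(trp_cz3)
    v = frame.position(lys_nz) - frame.position(lys_ce)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError(
            "alignment angle undefined for zero-length vector"
        )
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def peptide_com(
    frame: TrajectoryFrame, selection: Sequence[AtomKey]
) -> np.ndarray:
    """Mass-weighted mean position (Å) of the selected atoms."""
    if len(selection) == 0:
        raise ValueError("peptide COM selection is empty")
    masses = np.array([frame.mass(k) for k in selection])
    coords = np.array([frame.position(k) for k in selection])
    return masses @ coords / masses.sum()


def compute_series(
    frames: Iterable[TrajectoryFrame], atom_map: AtomMap | None = None
) -> GeometrySeries:
    """Evaluate all observables on every frame.

    Per-Trp distance/angle channels use the identities declared in the atom
    map; anchor distances are computed when the Arg/Asp atoms are present.
    Absent-atom errors are re-raised with the frame index attached.
    """
    atom_map = atom_map or default_atom_map()
    rows: list[dict[str, float]] = []
    for frame in frames:
        row: dict[str, float] = {
            "frame": frame.frame_index,
            "time_ns": frame.time_ns,
        }
        lys_ce, lys_nz = atom_map.lys_keys
        try:
            for identity in sorted(atom_map.trp_residues):
                label = atom_map.identity_map[identity]
                cz3, c5 = atom_map.trp_keys(identity)
                row[f"d_{label}"] = trp_lys_distance(frame, c5, lys_nz)
                row[f"theta_{label}"] = alignment_angle(
                    frame, cz3, c5, lys_ce, lys_nz
                )
            row["d_r430_d15"] = atom_distance(
                frame, atom_map.arg_cz, atom_map.asp_cg
            )
            com = peptide_com(frame, atom_map.peptide_selection(frame))
            row["d_r430_com"] = float(
                np.linalg.norm(frame.position(atom_map.arg_cz) - com)
            )
        except AbsentAtomError as exc:
            raise AbsentAtomError(
                f"frame {frame.frame_index}: {exc.args[0]}"
            ) from None
        rows.append(row)

    if not rows:
        columns = ["frame", "time_ns"]
        for identity in sorted(atom_map.trp_residues):
            label = atom_map.identity_map[identity]
            columns += [f"d_{label}", f"theta_{label}"]
        columns += ["d_r430_d15", "d_r430_com"]
        return GeometrySeries(
            pd.DataFrame(columns=columns), dict(atom_map.identity_map)
        )
    return GeometrySeries(pd.DataFrame(rows), dict(atom_map.identity_map))


def dissociation_time(
    series: GeometrySeries,
    identity: int,
    threshold_a: float = 12.0,
    persistence_ns: float = 5.0,
) -> float | None:
    """Earliest time after which a Trp stays beyond the catalytic site.

    Returns the earliest time t such that d > ``threshold_a`` for every
    frame in [t, t + ``persistence_ns``]; the window must be fully covered
    by the series, so brief excursions and end-of-series truncation do not
    count as dissociation.  Returns None if the Trp never dissociates.
    """
    if threshold_a <= 0:
        raise ValueError("threshold_a must be positive")
    if persistence_ns < 0:
        raise ValueError("persistence_ns must be non-negative")
    d = series.d(identity)
    t = series.time_ns
    above = d > threshold_a
    n = len(d)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if t[j] - t[i] >= persistence_ns - 1e-12:
                return float(t[i])
            i = j + 1
        else:
            i += 1
    return None
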