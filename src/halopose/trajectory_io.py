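"""Minimal trajectory frame I/O: a strict PDB subset and geometry CSV tables.

The frames handled here carry a handful of labeled atoms (catalytic Lys
side chain, Trp indole atoms, anchoring Arg/Asp atoms, peptide atoms), not
full topologies, so only ATOM/HETATM, MODEL/ENDMDL, TER and END records are
interpreted; coordinates come from the fixed PDB columns. Residue numbering
is taken verbatim from the file — positions refer to author numbering
(enzyme Lys139/Arg430, substrate core positions 1-15). Insertion codes are
rejected and only blank/'A' altlocs are kept, so atom identity is
deterministic.

PDB files carry no time axis; frames are stamped ``time_ns = frame_index *
dt_ns`` with a caller-supplied saving interval (default 0.1 ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .masses import element_mass_amu

__all__ = [
    "AtomKey",
    "TrajectoryFrame",
    "PdbParseError",
    "UnsupportedFormatError",
    "AbsentAtomError",
    "read_pdb_frames",
    "write_pdb_frames",
    "read_geometry_table",
    "write_geometry_table",
]


class PdbParseError(ValueError):
    """A malformed record; the message names the offending line number."""


class UnsupportedFormatError(ValueError):
    """A legal PDB feature outside the supported dialect (insertion codes)."""


class AbsentAtomError(KeyError):
    """Lookup of an atom not present in a frame."""


@dataclass(frozen=True, order=True)
class AtomKey:
    """Identity of one atom: chain, author residue number, residue, atom name."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if len(self.chain_id) != 1:
            raise ValueError(f"chain_id must be one character, got {self.chain_id!r}")


@dataclass
class TrajectoryFrame:
    """Named atom coordinates (Å) for one time point."""

    frame_index: int
    time_ns: float
    coords: dict[AtomKey, np.ndarray]
    masses: dict[AtomKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0 or self.time_ns < 0:
            raise ValueError("frame_index and time_ns must be non-negative")
        for key, xyz in self.coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"bad coordinates for {key}: {xyz}")
            self.coords[key] = arr

    def position(self, key: AtomKey) -> np.ndarray:
        try:
            return self.coords[key]
        except KeyError:
            raise AbsentAtomError(f"atom {key} absent from frame {self.frame_index}") from None

    def mass(self, key: AtomKey) -> float:
        """Atom mass in amu; inferred from the atom name when not stored."""
        if key in self.masses:
            return self.masses[key]
        return element_mass_amu(key.atom_name)

    def __contains__(self, key: AtomKey) -> bool:
        return key in self.coords


def read_pdb_frames(path: str | Path, dt_ns: float = 0.1) -> list[TrajectoryFrame]:
    """Read MODEL/ENDMDL-delimited frames from a PDB file.

    A file without MODEL records is a single implicit frame. Altloc 'A' or
    blank is kept, other altlocs dropped; insertion codes raise
    :class:`UnsupportedFormatError`.
    """
    frames: list[TrajectoryFrame] = []
    current: dict[AtomKey, np.ndarray] | None = None
    saw_model = False

    def close(coords: dict[AtomKey, np.ndarray]) -> None:
        idx = len(frames)
        frames.append(TrajectoryFrame(idx, idx * dt_ns, coords))

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                if current:
                    close(current)
                current = {}
            elif record == "ENDMDL":
                close(current or {})
                current = None
            elif record in ("ATOM", "HETATM"):
                if current is None:
                    current = {}
                key, xyz = _parse_atom_line(line, lineno)
                if key is not None:
                    if key in current:
                        raise PdbParseError(
                            f"line {lineno}: duplicate atom {key} within a frame"
                        )
                    current[key] = xyz
            # TER, END and all other records are ignored

    if current:
        close(current)
    if not frames and not saw_model:
        raise PdbParseError(f"{path}: no ATOM/HETATM records found")
    return frames


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomKey | None, np.ndarray]:
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None, np.empty(0)
    icode = line[26]
    if icode != " ":
        raise UnsupportedFormatError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    try:
        key = AtomKey(
            chain_id=line[21],
            residue_number=int(line[22:26]),
            residue_name=line[17:20].strip(),
            atom_name=line[12:16].strip(),
        )
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    if not np.all(np.isfinite(xyz)):
        raise PdbParseError(f"line {lineno}: non-finite coordinates")
    return key, xyz


def write_pdb_frames(frames: Iterable[TrajectoryFrame], path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks with fixed-column ATOM records."""
    with open(path, "w") as handle:
        for frame in frames:
            handle.write(f"MODEL     {frame.frame_index + 1:4d}\n")
            for serial, (key, xyz) in enumerate(sorted(frame.coords.items()), start=1):
                name = key.atom_name
                # column-13 convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                handle.write(
                    f"ATOM  {serial:5d} {name_field:4s} {key.residue_name:<3s} "
                    f"{key.chain_id}{key.residue_number:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}\n"
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")


def read_geometry_table(path: str | Path):
    """Read a geometry CSV (frame, time_ns, one column per observable).

    Column order is irrelevant; absent observable columns are permitted and
    later queries for them raise an absent-observable error.  Returns a
    :class:`halopose.geometry.GeometrySeries`.
    """
    from .geometry import GeometrySeries  # io <-> geometry layering

    df = pd.read_csv(path)
    required = {"frame", "time_ns"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and not df[col].isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, "
                f"column {col!r}"
            )
        df[col] = numeric
    return GeometrySeries(df)


def write_geometry_table(series, path: str | Path) -> None:
    """Write a GeometrySeries as CSV with 9 significant digits."""
    series.data.to_csv(path, index=False, float_format="%.9g")
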