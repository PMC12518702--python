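"""Peptide halogenation mass spectrometry: masses, m/z ladders, b/y ions.

Implements the arithmetic behind MALDI-TOF readouts of enzymatic Trp
halogenation: molecular-formula masses (monoisotopic and average,
electron-corrected for ions), halogenation m/z ladders for 0..n Cl/Br,
ppm errors against observed high-resolution masses, stoichiometry
assignment of observed peak lists, and b/y fragment ladders for
MALDI-LIFT-style site localization.

Halogenation is modeled as a net H -> Cl (or H -> Br) substitution on the
Trp indole (monoisotopic shifts +33.96103 and +77.91051 Da); the ring
position of the substitution is mass-invisible and not tracked.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from .masses import AVERAGE, ELECTRON, MONOISOTOPIC, PROTON, RESIDUE_FORMULAS

__all__ = [
    "MolecularFormula",
    "PeptideSpecies",
    "PeakAssignment",
    "LocalizationResult",
    "formula_mass",
    "residue_mass",
    "peptide_formula",
    "mz",
    "ppm_error",
    "halogen_shift",
    "assign_stoichiometry",
    "fragment_ladder",
    "localize_halogen",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_WATER = {"H": 2, "O": 1}

#: Net formula change per halogenation event (H -> X on the indole ring).
_HALOGEN_SUBSTITUTION = {"Cl": {"Cl": 1, "H": -1}, "Br": {"Br": 1, "H": -1}}


class UnknownElementError(KeyError):
    """Raised when a formula references an element with no tabulated mass."""


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition plus net charge, parseable to/from Hill notation."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        cleaned = {el: int(n) for el, n in self.counts.items() if n != 0}
        if any(n < 0 for n in cleaned.values()):
            raise ValueError(f"negative element count in {cleaned}")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse Hill notation, e.g. ``C49H59N10O9Cl2``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(0):
                break
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        return cls(counts, charge=charge)

    def to_string(self) -> str:
        """Hill notation: C, then H, then the rest alphabetically."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order
        )

    def _combine(self, other: "MolecularFormula", sign: int) -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + sign * n
        return MolecularFormula(counts, charge=self.charge + sign * other.charge)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return self._combine(other, +1)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return self._combine(other, -1)

    def with_substitution(self, delta: dict[str, int], times: int = 1) -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in delta.items():
            counts[el] = counts.get(el, 0) + times * n
        return MolecularFormula(counts, charge=self.charge)


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with a halogenation state and terminal chemistry.

    ``n_term`` is ``"free"`` (H-) or ``"formyl"`` (CHO-, e.g. an initiating
    formyl-Met installed for cell-free translation — the Met itself is part
    of ``sequence``).  ``c_term`` is ``"acid"`` (-OH) or ``"amide"`` (-NH2);
    amide hydrolysis to the free acid shifts the mass by +0.984 Da.
    Halogenation sites are Trp, so ``n_cl + n_br`` may not exceed the Trp
    count of the sequence.
    """

    sequence: str
    n_cl: int = 0
    n_br: int = 0
    n_term: str = "free"
    c_term: str = "acid"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(RESIDUE_FORMULAS)
        if bad:
            raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.n_cl < 0 or self.n_br < 0:
            raise ValueError("halogen counts must be non-negative")
        if self.n_cl + self.n_br > self.trp_count:
            raise ValueError(
                f"{self.n_cl + self.n_br} halogenations exceed "
                f"{self.trp_count} Trp sites in {self.sequence!r}"
            )
        if self.n_term not in ("free", "formyl"):
            raise ValueError(f"unknown N-terminal state {self.n_term!r}")
        if self.c_term not in ("acid", "amide"):
            raise ValueError(f"unknown C-terminal state {self.c_term!r}")

    @property
    def trp_count(self) -> int:
        return self.sequence.count("W")

    @property
    def trp_positions(self) -> tuple[int, ...]:
        """1-based positions of Trp residues."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "W")

    def with_halogens(self, n_cl: int | None = None, n_br: int | None = None) -> "PeptideSpecies":
        return replace(
            self,
            n_cl=self.n_cl if n_cl is None else n_cl,
            n_br=self.n_br if n_br is None else n_br,
        )


@dataclass(frozen=True)
class PeakAssignment:
    observed_mz: float
    species: "PeptideSpecies | MolecularFormula"
    n_halogen: int
    theoretical_mz: float
    ppm_error: float
    mode: str


@dataclass(frozen=True)
class LocalizationResult:
    """Outcome of b/y-based halogen-site localization.

    ``placements`` holds every placement (mapping 1-based residue position ->
    halogen symbol) that explains the maximal number of observed peaks; more
    than one entry means the data are ambiguous.
    """

    placements: tuple[dict[int, str], ...]
    n_matched: int
    n_observed: int

    @property
    def unique(self) -> bool:
        return len(self.placements) == 1


def _mass_table(mode: str) -> dict[str, float]:
    if mode in ("monoisotopic", "mono"):
        return MONOISOTOPIC
    if mode == "average":
        return AVERAGE
    raise ValueError(f"unknown mass mode {mode!r}")


def formula_mass(formula: MolecularFormula, mode: str = "monoisotopic") -> float:
    """Mass of a formula in Da; ion masses are electron-corrected.

    For a formula carrying net charge q, q electron masses are subtracted
    (q > 0) or added (q < 0), matching high-resolution MS practice.
    """
    table = _mass_table(mode)
    total = 0.0
    for element, count in formula.counts.items():
        try:
            total += table[element] * count
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} has no tabulated {mode} mass"
            ) from None
    return total - formula.charge * ELECTRON


def residue_mass(residue: str, mode: str = "monoisotopic") -> float:
    """Monoisotopic or average residue mass of a one-letter amino acid."""
    try:
        composition = RESIDUE_FORMULAS[residue.upper()]
    except KeyError:
        raise KeyError(f"unknown residue {residue!r}") from None
    table = _mass_table(mode)
    return sum(table[el] * n for el, n in composition.items())


def halogen_shift(halogen: str, mode: str = "monoisotopic") -> float:
    """Mass shift of one H -> halogen substitution (+33.96103 Da for Cl)."""
    table = _mass_table(mode)
    if halogen not in _HALOGEN_SUBSTITUTION:
        raise ValueError(f"unsupported halogen {halogen!r}")
    return table[halogen] - table["H"]


def peptide_formula(species: PeptideSpecies) -> MolecularFormula:
    """Neutral molecular formula of a peptide species.

    Residue compositions are summed, one water is added for the termini,
    terminal modifications are applied, and each halogenation substitutes
    one H by Cl or Br.
    """
    counts: dict[str, int] = {}

    def add(delta: dict[str, int], times: int = 1) -> None:
        for el, n in delta.items():
            counts[el] = counts.get(el, 0) + times * n

    for residue in species.sequence:
        add(RESIDUE_FORMULAS[residue])
    add(_WATER)
    if species.n_term == "formyl":
        add({"C": 1, "O": 1})
    if species.c_term == "amide":
        add({"O": -1, "N": 1, "H": 1})
    formula = MolecularFormula(counts)
    if species.n_cl:
        formula = formula.with_substitution(_HALOGEN_SUBSTITUTION["Cl"], species.n_cl)
    if species.n_br:
        formula = formula.with_substitution(_HALOGEN_SUBSTITUTION["Br"], species.n_br)
    return formula


def _neutral_mass(
    species: PeptideSpecies | MolecularFormula, mode: str
) -> float:
    if isinstance(species, PeptideSpecies):
        return formula_mass(peptide_formula(species), mode)
    if species.charge != 0:
        raise ValueError("mz() expects a neutral formula; got a charged ion")
    return formula_mass(species, mode)


def mz(
    species: PeptideSpecies | MolecularFormula,
    z: int = 1,
    mode: str = "monoisotopic",
) -> float:
    """m/z of the z-fold protonated ion [M + zH]^z+ of a neutral species.

    The proton mass used (1.007276 Da) is already electron-corrected, so the
    result matches the electron-corrected mass of the ion formula.
    """
    if z < 1:
        raise ValueError("charge z must be >= 1")
    return (_neutral_mass(species, mode) + z * PROTON) / z


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """|observed - theoretical| / theoretical x 1e6."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6


def assign_stoichiometry(
    peaks: list[float],
    base: PeptideSpecies | MolecularFormula,
    halogen: str = "Cl",
    max_n: int | None = None,
    tol_da: float = 1.0,
    mode: str = "both",
    z: int = 1,
) -> list[PeakAssignment | None]:
    """Assign each observed m/z to a halogenation count n in [0, max_n].

    For each peak the candidate with minimal |observed - theoretical| is
    taken; peaks farther than ``tol_da`` from every candidate are reported as
    ``None``.  MALDI figure captions mix rounding conventions between
    monoisotopic and average masses, so ``mode="both"`` evaluates both tables
    and reports which one matched.

    Returns one entry per input peak, in input order.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if isinstance(base, PeptideSpecies):
        if max_n is None:
            max_n = base.trp_count
        if max_n > base.trp_count:
            raise ValueError("max_n exceeds the number of Trp sites")
    elif max_n is None:
        raise ValueError("max_n is required when base is a bare formula")

    modes = ("monoisotopic", "average") if mode == "both" else (mode,)
    shift_delta = _HALOGEN_SUBSTITUTION[halogen]

    candidates: list[tuple[int, float, str]] = []
    for n in range(max_n + 1):
        for m in modes:
            if isinstance(base, PeptideSpecies):
                if halogen == "Cl":
                    theo = mz(base.with_halogens(n_cl=n), z=z, mode=m)
                else:
                    theo = mz(base.with_halogens(n_br=n), z=z, mode=m)
            else:
                theo = mz(base.with_substitution(shift_delta, n), z=z, mode=m)
            candidates.append((n, theo, m))

    out: list[PeakAssignment | None] = []
    for peak in peaks:
        n, theo, m = min(candidates, key=lambda c: abs(peak - c[1]))
        if abs(peak - theo) > tol_da:
            out.append(None)
        else:
            out.append(
                PeakAssignment(
                    observed_mz=peak,
                    species=base,
                    n_halogen=n,
                    theoretical_mz=theo,
                    ppm_error=ppm_error(peak, theo),
                    mode=m,
                )
            )
    return out


def _validate_placement(
    species: PeptideSpecies, placement: dict[int, str], strict: bool = True
) -> None:
    n_cl = sum(1 for h in placement.values() if h == "Cl")
    n_br = sum(1 for h in placement.values() if h == "Br")
    if (n_cl, n_br) != (species.n_cl, species.n_br):
        raise ValueError(
            f"placement totals ({n_cl} Cl, {n_br} Br) disagree with species "
            f"({species.n_cl} Cl, {species.n_br} Br)"
        )
    for pos, hal in placement.items():
        if not 1 <= pos <= len(species.sequence):
            raise ValueError(f"placement position {pos} outside sequence")
        if hal not in _HALOGEN_SUBSTITUTION:
            raise ValueError(f"unsupported halogen {hal!r}")
        if strict and species.sequence[pos - 1] != "W":
            raise ValueError(
                f"halogen placed on non-Trp residue "
                f"{species.sequence[pos - 1]}{pos}"
            )


def fragment_ladder(
    species: PeptideSpecies,
    placement: dict[int, str] | None = None,
    mode: str = "monoisotopic",
    strict: bool = True,
) -> dict[str, list[float]]:
    """Singly protonated b- and y-ion m/z ladders with site-resolved halogens.

    ``placement`` maps 1-based residue positions to ``"Cl"``/``"Br"``; the
    halogen mass shift travels with its residue into every fragment that
    contains it.  By construction b_i(+1) + y_{n-i}(+1) = [M+H]+ + proton for
    every cut site i (the complementarity identity used to sanity-check
    assigned MALDI-LIFT spectra).

    Returns ``{"b": [b1..b_{n-1}], "y": [y1..y_{n-1}]}``.
    """
    placement = placement or {}
    _validate_placement(species, placement, strict=strict)
    table = _mass_table(mode)

    res = [residue_mass(aa, mode) for aa in species.sequence]
    for pos, hal in placement.items():
        res[pos - 1] += halogen_shift(hal, mode)

    n_term_extra = table["C"] + table["O"] if species.n_term == "formyl" else 0.0
    if species.c_term == "amide":
        c_term_extra = table["N"] + 3 * table["H"]  # NH3
    else:
        c_term_extra = 2 * table["H"] + table["O"]  # H2O

    n = len(res)
    b = []
    acc = n_term_extra
    for i in range(n - 1):
        acc += res[i]
        b.append(acc + PROTON)
    y = []
    acc = c_term_extra
    for j in range(n - 1):
        acc += res[n - 1 - j]
        y.append(acc + PROTON)
    return {"b": b, "y": y}


def enumerate_placements(species: PeptideSpecies) -> list[dict[int, str]]:
    """All ways to place the species' halogen totals on its Trp residues.

    Each Trp carries at most one halogen (no evidence exists for double
    halogenation of a single indole by this enzyme family).
    """
    sites = species.trp_positions
    placements = []
    for cl_sites in itertools.combinations(sites, species.n_cl):
        remaining = [s for s in sites if s not in cl_sites]
        for br_sites in itertools.combinations(remaining, species.n_br):
            placement = {pos: "Cl" for pos in cl_sites}
            placement.update({pos: "Br" for pos in br_sites})
            placements.append(placement)
    return placements


def localize_halogen(
    species: PeptideSpecies,
    observed_mz: list[float],
    tol_da: float = 0.3,
    mode: str = "monoisotopic",
) -> LocalizationResult:
    """Find halogen placements whose b/y ladders best explain observed peaks.

    Every placement of the species' halogen totals over its Trp residues is
    enumerated; each is scored by how many observed peaks fall within
    ``tol_da`` of some predicted b or y ion.  All placements achieving the
    maximal count are returned — multiple survivors mean the fragmentation
    data cannot distinguish the sites (a real outcome for closely spaced
    Trp), and callers must treat the localization as inconclusive.
    """
    if not observed_mz:
        raise ValueError("observed peak list is empty")
    best: list[dict[int, str]] = []
    best_count = -1
    for placement in enumerate_placements(species):
        ladder = fragment_ladder(species, placement, mode=mode)
        predicted = ladder["b"] + ladder["y"]
        count = sum(
            1
            for peak in observed_mz
            if any(abs(peak - p) <= tol_da for p in predicted)
        )
        if count > best_count:
            best, best_count = [placement], count
        elif count == best_count:
            best.append(placement)
    return LocalizationResult(
        placements=tuple(best), n_matched=best_count, n_observed=len(observed_mz)
    )
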