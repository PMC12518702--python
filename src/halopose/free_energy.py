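"""Weighted free-energy surfaces and 1D profiles with basin identification.

Weighted samples of the catalytic-pose observables (d, theta) or of 1D
anchor distances are turned into a potential of mean force

    F = -kT * ln(p / p_max)

where p is the weighted occupation probability of a grid cell, so the most
populated cell sits at F = 0 and less populated regions cost free energy.
Both raw weighted histograms and Gaussian-kernel-density-smoothed profiles
are provided; basins are local minima of F over the occupied grid.

kT defaults to 0.593 kcal/mol (298.15 K); units of F follow kT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FEParams",
    "FreeEnergySurface",
    "Profile1D",
    "weighted_histogram",
    "weighted_histogram_1d",
    "surface_from_histogram",
    "kde_profile_1d",
    "profile_1d_free_energy",
    "find_basins",
    "channel_surfaces",
]

#: Minimum bandwidth (in data units) the auto rule may fall back to.
_MIN_BANDWIDTH = 1e-3


@dataclass(frozen=True)
class FEParams:
    """Temperature factor and KDE bandwidth settings.

    ``bandwidth`` is an absolute, per-dimension kernel width in data units,
    or ``"auto"`` for Silverman's rule evaluated at the Kish effective
    sample size of the weights.
    """

    kT: float = 0.593
    bandwidth: float | str = "auto"

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not (self.bandwidth == "auto" or (
            isinstance(self.bandwidth, (int, float)) and self.bandwidth > 0
        )):
            raise ValueError("bandwidth must be positive or 'auto'")


@dataclass
class FreeEnergySurface:
    """Binned weighted probability and F = -kT ln(p/p_max) on a 2D grid."""

    d_edges: np.ndarray
    theta_edges: np.ndarray
    p: np.ndarray
    F: np.ndarray
    occupied: np.ndarray
    kT: float

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


@dataclass
class Profile1D:
    """Raw-histogram and KDE-smoothed 1D free-energy profile."""

    centers: np.ndarray
    p_raw: np.ndarray
    F_raw: np.ndarray
    density: np.ndarray
    F_kde: np.ndarray
    kT: float

    @property
    def argmin_raw(self) -> float:
        occ = self.p_raw > 0
        idx = np.flatnonzero(occ)[np.argmin(self.F_raw[occ])]
        return float(self.centers[idx])

    @property
    def argmin_kde(self) -> float:
        return float(self.centers[int(np.argmin(self.F_kde))])


def _check_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0 or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return weights


def weighted_histogram(
    samples: np.ndarray,
    weights: np.ndarray,
    d_edges: np.ndarray,
    theta_edges: np.ndarray,
    clamp: bool = False,
) -> tuple[np.ndarray, int]:
    """Normalized 2D weighted histogram of (d, theta) samples.

    Cells are half-open with the top edge inclusive.  Samples outside the
    grid are clamped into the nearest edge cell when ``clamp`` is true;
    otherwise dropped, with the dropped count returned for logging.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    weights = _check_weights(weights)
    d_edges = np.asarray(d_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)
    if np.any(np.diff(d_edges) <= 0) or np.any(np.diff(theta_edges) <= 0):
        raise ValueError("histogram edges must be strictly ascending")

    d, theta = samples[:, 0], samples[:, 1]
    inside = (
        (d >= d_edges[0]) & (d <= d_edges[-1])
        & (theta >= theta_edges[0]) & (theta <= theta_edges[-1])
    )
    n_dropped = 0
    if clamp:
        d = np.clip(d, d_edges[0], d_edges[-1])
        theta = np.clip(theta, theta_edges[0], theta_edges[-1])
    else:
        n_dropped = int(np.sum(~inside))
        d, theta, weights = d[inside], theta[inside], weights[inside]
        if weights.size == 0 or weights.sum() <= 0:
            raise ValueError("no samples fall inside the histogram grid")

    grid, _, _ = np.histogram2d(d, theta, bins=(d_edges, theta_edges), weights=weights)
    return grid / weights.sum(), n_dropped


def weighted_histogram_1d(
    samples: np.ndarray,
    weights: np.ndarray,
    edges: np.ndarray,
    clamp: bool = False,
) -> tuple[np.ndarray, int]:
    """1D analogue of :func:`weighted_histogram`."""
    samples = np.asarray(samples, dtype=float)
    weights = _check_weights(weights)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("histogram edges must be strictly ascending")
    inside = (samples >= edges[0]) & (samples <= edges[-1])
    n_dropped = 0
    if clamp:
        samples = np.clip(samples, edges[0], edges[-1])
    else:
        n_dropped = int(np.sum(~inside))
        samples, weights = samples[inside], weights[inside]
        if weights.size == 0 or weights.sum() <= 0:
            raise ValueError("no samples fall inside the histogram grid")
    hist, _ = np.histogram(samples, bins=edges, weights=weights)
    return hist / weights.sum(), n_dropped


def surface_from_histogram(
    p: np.ndarray,
    d_edges: np.ndarray,
    theta_edges: np.ndarray,
    params: FEParams | None = None,
    p_ref: float | None = None,
) -> FreeEnergySurface:
    """F = -kT ln(p/p_max) over occupied cells; unoccupied cells masked.

    ``p_ref`` overrides the reference probability (by default the grid's own
    maximum) so surfaces for several Trp channels can share a global zero —
    required when comparing basin depths *between* channels.
    """
    params = params or FEParams()
    p = np.asarray(p, dtype=float)
    if p.sum() <= 0:
        raise ValueError("probability grid is all zero")
    occupied = p > 0
    ref = float(p.max()) if p_ref is None else float(p_ref)
    F = np.full(p.shape, np.nan)
    F[occupied] = -params.kT * np.log(p[occupied] / ref)
    return FreeEnergySurface(
        d_edges=np.asarray(d_edges, dtype=float),
        theta_edges=np.asarray(theta_edges, dtype=float),
        p=p,
        F=F,
        occupied=occupied,
        kT=params.kT,
    )


def _auto_bandwidth(samples: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule at the Kish effective sample size of the weights."""
    w = weights / weights.sum()
    n_eff = 1.0 / np.sum(w**2)
    mean = np.sum(w * samples)
    sd = float(np.sqrt(np.sum(w * (samples - mean) ** 2)))
    order = np.argsort(samples)
    cum = np.cumsum(w[order])
    q25 = samples[order][np.searchsorted(cum, 0.25)]
    q75 = samples[order][min(np.searchsorted(cum, 0.75), len(samples) - 1)]
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        warnings.warn(
            "degenerate sample spread; falling back to minimum KDE bandwidth",
            stacklevel=3,
        )
        return _MIN_BANDWIDTH
    return max(0.9 * spread * n_eff ** (-0.2), _MIN_BANDWIDTH)


def kde_profile_1d(
    samples: np.ndarray,
    weights: np.ndarray,
    grid: np.ndarray,
    params: FEParams | None = None,
) -> np.ndarray:
    """Weighted Gaussian-kernel density evaluated on a 1D grid.

    density(x) = sum_i w_i * phi((x - x_i)/h) / h with normalized weights,
    so the density integrates to ~1 over a grid spanning the data ±5h.
    """
    params = params or FEParams()
    samples = np.asarray(samples, dtype=float)
    weights = _check_weights(weights)
    if samples.shape != weights.shape:
        raise ValueError("samples and weights must have matching shapes")
    w = weights / weights.sum()
    if params.bandwidth == "auto":
        h = _auto_bandwidth(samples, w)
    else:
        h = float(params.bandwidth)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - samples[None, :]) / h
    kernel = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
    return kernel @ w / h


def profile_1d_free_energy(
    samples: np.ndarray,
    weights: np.ndarray,
    edges: np.ndarray,
    params: FEParams | None = None,
    clamp: bool = True,
) -> Profile1D:
    """Raw-histogram and KDE free-energy profiles along one distance.

    The KDE is evaluated at the histogram cell centers; each profile is
    referenced to its own maximum-probability point (min F = 0).
    """
    params = params or FEParams()
    edges = np.asarray(edges, dtype=float)
    p_raw, _ = weighted_histogram_1d(samples, weights, edges, clamp=clamp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = p_raw > 0
    F_raw = np.full(p_raw.shape, np.nan)
    F_raw[occ] = -params.kT * np.log(p_raw[occ] / p_raw.max())
    density = kde_profile_1d(samples, weights, centers, params)
    if density.max() <= 0:
        raise ValueError("KDE density vanished on the requested grid")
    F_kde = -params.kT * np.log(np.maximum(density, 1e-300) / density.max())
    return Profile1D(
        centers=centers, p_raw=p_raw, F_raw=F_raw,
        density=density, F_kde=F_kde, kT=params.kT,
    )


def find_basins(
    surface: FreeEnergySurface, min_separation: int = 1
) -> list[tuple[float, float, float]]:
    """Local F minima (8-neighborhood) over the occupied mask.

    Candidates are cells whose F does not exceed any occupied neighbor and
    that lie strictly below at least one neighbor (so flat plateaus are not
    reported; an isolated occupied cell still counts).  After sorting
    ascending by F, candidates within ``min_separation`` cells (Chebyshev
    distance) of an accepted basin are suppressed.
    Returns (d_center, theta_center, F) tuples, deepest first.
    """
    F = surface.F
    occ = surface.occupied
    if not occ.any():
        return []
    ni, nj = F.shape
    candidates: list[tuple[float, int, int]] = []
    for i in range(ni):
        for j in range(nj):
            if not occ[i, j]:
                continue
            value = F[i, j]
            is_min = True
            has_higher = False
            n_neighbors = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < ni and 0 <= b < nj and occ[a, b]:
                        n_neighbors += 1
                        if F[a, b] < value:
                            is_min = False
                            break
                        if F[a, b] > value:
                            has_higher = True
                if not is_min:
                    break
            if is_min and (has_higher or n_neighbors == 0):
                candidates.append((float(value), i, j))

    candidates.sort()
    accepted: list[tuple[float, int, int]] = []
    for value, i, j in candidates:
        if all(
            max(abs(i - ai), abs(j - aj)) > min_separation
            for _, ai, aj in accepted
        ):
            accepted.append((value, i, j))
    return [
        (float(surface.d_centers[i]), float(surface.theta_centers[j]), value)
        for value, i, j in accepted
    ]


def channel_surfaces(
    samples_by_channel: dict[int, np.ndarray],
    weights_by_channel: dict[int, np.ndarray],
    d_edges: np.ndarray,
    theta_edges: np.ndarray,
    params: FEParams | None = None,
) -> dict[int, FreeEnergySurface]:
    """Per-Trp-channel surfaces sharing one global free-energy zero.

    Cell probabilities are normalized over *all* channels jointly — with
    mass that left the projected (d, theta) window still counted in the
    normalization, so a channel that dissociates out of the window shows a
    correspondingly depleted surface — and every surface is referenced to
    the global maximum.  Basin depths are therefore comparable between
    channels: the well of a rarely bound Trp sits above the well of a
    stably bound one.
    """
    params = params or FEParams()
    d_edges = np.asarray(d_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)
    totals = {}
    grand = 0.0
    for ch, samples in samples_by_channel.items():
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        weights = _check_weights(weights_by_channel[ch])
        grand += weights.sum()
        d, theta = samples[:, 0], samples[:, 1]
        inside = (
            (d >= d_edges[0]) & (d <= d_edges[-1])
            & (theta >= theta_edges[0]) & (theta <= theta_edges[-1])
        )
        if not inside.any():
            continue
        grid, _, _ = np.histogram2d(
            d[inside], theta[inside], bins=(d_edges, theta_edges),
            weights=weights[inside],
        )
        totals[ch] = grid
    if not totals:
        raise ValueError("no channel has samples inside the grid window")
    joint = {ch: grid / grand for ch, grid in totals.items()}
    p_ref = max(grid.max() for grid in joint.values())
    return {
        ch: surface_from_histogram(grid, d_edges, theta_edges, params, p_ref=p_ref)
        for ch, grid in joint.items()
    }
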