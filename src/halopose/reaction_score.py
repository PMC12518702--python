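"""Reaction-likelihood progress coordinate and discrete Trp-identity bin.

The score collapses the two catalytic-pose observables — Trp C5 to Lys NZ
distance d and alignment angle theta — into a single number in [0, 1] that
is maximal at the catalytically optimal geometry and decays smoothly away
from it:

    S(d, theta) = exp(-(d - d0)^2 / (2 sigma_d^2))
                * exp(-(theta - theta0)^2 / (2 sigma_theta^2))

The separable-Gaussian form is this package's choice of a smooth, bounded,
unimodal score; the defaults (d0 = 8 Å, sigma_d = 1.5 Å, theta0 = 140°,
sigma_theta = 25°) center the peak on the low-free-energy basin geometry
(~7–9 Å, ~140°) where halogenation-competent poses concentrate.  All four
parameters are configuration.

``best_trp`` reduces a multi-Trp frame to (identity, score): the Trp channel
with the maximal score wins, ties broken toward the lowest identity so the
reduction is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ReactionScoreParams", "reaction_likelihood", "best_trp"]


@dataclass(frozen=True)
class ReactionScoreParams:
    """Peak position and widths of the reaction-likelihood score."""

    d0: float = 8.0
    sigma_d: float = 1.5
    theta0: float = 140.0
    sigma_theta: float = 25.0

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_theta <= 0:
            raise ValueError("sigma_d and sigma_theta must be positive")
        if not 0.0 <= self.theta0 <= 180.0:
            raise ValueError("theta0 must lie in [0, 180] degrees")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


def reaction_likelihood(
    d: float, theta: float, params: ReactionScoreParams | None = None
) -> float:
    """Score in [0, 1]; equals 1 iff (d, theta) == (d0, theta0)."""
    params = params or ReactionScoreParams()
    zd = (d - params.d0) / params.sigma_d
    zt = (theta - params.theta0) / params.sigma_theta
    return math.exp(-0.5 * (zd * zd + zt * zt))


def best_trp(
    channels: dict[int, tuple[float, float]],
    params: ReactionScoreParams | None = None,
) -> tuple[int, float]:
    """Identity and score of the best-posed Trp channel.

    ``channels`` maps Trp identity (1/2/3) to its (d, theta).  Exact score
    ties resolve to the lowest identity; the result is independent of dict
    ordering.
    """
    if not channels:
        raise ValueError("no Trp channels present")
    params = params or ReactionScoreParams()
    best_id: int | None = None
    best_score = -1.0
    for identity in sorted(channels):
        d, theta = channels[identity]
        score = reaction_likelihood(d, theta, params)
        if score > best_score:
            best_id, best_score = identity, score
    assert best_id is not None
    return best_id, best_score
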