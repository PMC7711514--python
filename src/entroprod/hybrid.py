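"""Mixed discrete-continuous processes on a ring.

Run-and-tumble particles and their M-mode generalisation, the switching
diffusion process: a particle diffuses with constant D on a ring of
circumference L while its drift switches between modes ``v_i`` according
to an M-state Markov process with rate matrix ``alpha``.

At steady state the spatial density is uniform in every mode, with mode
weights ``z`` given by the stationary distribution of ``alpha``, and the
entropy production separates exactly into a drift-diffusion part
``sum_i z_i v_i^2 / D`` and the discrete switching part — the stationary
production of the mode chain.  Only stationary rates are available in
closed form; transients are accessible through simulation
(:mod:`entroprod.simulate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import (
    RateMatrix,
    entropy_rates,
    stationary_distribution,
    validate_rate_matrix,
)

__all__ = [
    "SwitchingSpec",
    "rtp_stationary_entropy",
    "switching_stationary_weights",
    "switching_stationary_entropy",
]


@dataclass(frozen=True)
class SwitchingSpec:
    """Switching diffusion on a ring: drifts ``v`` (one per mode),
    diffusion constant ``D``, circumference ``L`` and mode-switching
    rate matrix ``alpha`` (M x M, same convention as :class:`RateMatrix`)."""

    v: tuple[float, ...]
    D: float
    L: float
    alpha: RateMatrix

    def __post_init__(self):
        v = tuple(float(x) for x in self.v)
        object.__setattr__(self, "v", v)
        if len(v) < 2:
            raise ValueError("need at least 2 drift modes")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not isinstance(self.alpha, RateMatrix):
            object.__setattr__(
                self, "alpha", validate_rate_matrix(self.alpha)
            )
        if self.alpha.d != len(v):
            raise ValueError("alpha size must match the number of modes")

    @property
    def M(self) -> int:
        return len(self.v)


def rtp_stationary_entropy(
    v1: float, v2: float, D: float, alpha: float = 1.0, L: float = 1.0
) -> float:
    """Stationary entropy production of a run-and-tumble particle.

    ``si = (v1^2 + v2^2) / (2 D)``, independent of the tumble rate and of
    the ring size: two-mode symmetric switching against a uniform density
    produces no entropy of its own, so only the two drift modes
    (each occupied half the time) dissipate.  ``se = -si``.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if alpha <= 0:
        raise ValueError("tumble rate must be positive")
    if L <= 0:
        raise ValueError("L must be positive")
    return (v1**2 + v2**2) / (2.0 * D)


def switching_stationary_weights(alpha) -> np.ndarray:
    """Stationary mode weights ``z`` of the switching chain:
    ``sum_j z_j alpha_ji = 0`` with ``sum z = 1``."""
    if not isinstance(alpha, RateMatrix):
        alpha = validate_rate_matrix(alpha)
    return stationary_distribution(alpha)


def switching_stationary_entropy(spec: SwitchingSpec) -> float:
    """Stationary entropy production of the switching diffusion process.

    ``si = sum_i z_i v_i^2 / D + (1/2) sum_ij (z_i a_ij - z_j a_ji)
    ln(a_ij / a_ji)``: a drift-diffusion term weighted by the stationary
    mode occupations plus the production of the mode chain itself.  The
    drift part is invariant under a uniform rescaling of the switching
    rates.  Returns ``+inf`` when a populated switch has zero reverse
    rate (irreversible transmutation).
    """
    z = switching_stationary_weights(spec.alpha)
    drift = float(np.sum(z * np.square(spec.v)) / spec.D)
    switch = entropy_rates(z, spec.alpha, pi=z).si
    return drift + switch if math.isfinite(switch) else math.inf
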