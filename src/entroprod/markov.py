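"""Generic engine for continuous-time Markov chains.

Master-equation solution, stationary states, probability currents and the
decomposition of the entropy rate into internal production, external flow,
and adiabatic/non-adiabatic parts.  Entropy is measured in nats with
k_B = 1; the arbitrary rate and density scales that make the logarithms
dimensionless are fixed to 1 throughout (they cancel in every decomposition).

Conventions
-----------
* ``w[n, m]`` is the transition rate from state ``n`` to state ``m`` for
  ``n != m``; the diagonal is ``w[n, n] = -sum_{m != n} w[n, m]`` so every
  row sums to zero.
* Probability vectors are rows: the master equation reads ``dP/dt = P w``
  and its solution is ``P(t) = P(0) expm(w t)``.
* ``0 * ln 0 = 0``: a pair contributes nothing when both the forward and
  the reverse probability flux vanish.  A forward flux with an exactly zero
  *reverse rate* makes the internal production infinite; this is surfaced
  as ``si = +inf`` with ``irreversible_transition=True`` rather than
  clamped, since absolute irreversibility is outside the model class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eig, expm

__all__ = [
    "RateMatrix",
    "EntropyRates",
    "MultipleStationaryStatesError",
    "validate_rate_matrix",
    "solve_master",
    "stationary_distribution",
    "shannon_entropy",
    "entropy_rates",
    "probability_currents",
    "detailed_balance_residual",
    "random_rate_matrix",
    "validate_probability",
]

#: Tolerance on row sums of a valid rate matrix.
ROW_SUM_TOL = 1e-12
#: Tolerance on normalisation of a probability vector.
PROB_TOL = 1e-12
#: A zero eigenvalue of the generator is "simple" when every other
#: eigenvalue has modulus above this spectral-gap tolerance.
SPECTRAL_GAP_TOL = 1e-10


class MultipleStationaryStatesError(ValueError):
    """The zero eigenvalue of the generator is degenerate.

    Chains with several ergodic components have no unique stationary
    distribution; we refuse rather than silently pick one.
    """


@dataclass(frozen=True)
class RateMatrix:
    """A validated generator of a continuous-time Markov chain.

    Attributes
    ----------
    w : (d, d) ndarray
        Off-diagonal entries are non-negative transition rates per unit
        time; rows sum to zero.
    labels : tuple of str
        External state labels; internally states are indexed ``0..d-1``.
    """

    w: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"rate matrix must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValueError("a Markov chain needs at least 2 states")
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(w.sum(axis=1))) > ROW_SUM_TOL:
            raise ValueError("rate-matrix rows must sum to zero")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(str(i) for i in range(w.shape[0]))
            )
        elif len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def d(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class EntropyRates:
    """Entropy and entropy rates at one instant, in nats and nats/time.

    ``sdot = si + se`` and ``si = sia + sina`` whenever all parts are
    finite.  ``sia``/``sina`` are ``nan`` when the chain has no unique
    stationary distribution.  ``irreversible_transition`` marks the case
    of a populated transition whose reverse rate is exactly zero, which
    makes ``si`` (and ``-se``) infinite.
    """

    shannon: float
    sdot: float
    si: float
    se: float
    sia: float = math.nan
    sina: float = math.nan
    irreversible_transition: bool = False


def validate_rate_matrix(raw, labels: Sequence[str] = ()) -> RateMatrix:
    """Build a :class:`RateMatrix` from off-diagonal rates.

    The diagonal of ``raw`` is ignored and overwritten with minus the
    off-diagonal row sums, enforcing the Markov (zero row-sum) condition.
    """
    w = np.array(raw, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"rate matrix must be square, got shape {w.shape}")
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    np.fill_diagonal(w, -w.sum(axis=1))
    return RateMatrix(w, tuple(labels))


def validate_probability(p) -> np.ndarray:
    """Check non-negativity and normalisation of a probability vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -PROB_TOL):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    return np.clip(p, 0.0, None)


def solve_master(W: RateMatrix, P0, times) -> np.ndarray:
    """Evolve ``P(t) = P0 expm(w t)`` on a grid of non-negative times.

    Returns an array of shape ``(len(times), d)``; each row is a
    normalised probability vector.
    """
    P0 = validate_probability(P0)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    out = np.empty((times.size, W.d))
    for i, t in enumerate(times):
        out[i] = np.clip(P0 @ expm(W.w * t), 0.0, None)
        out[i] /= out[i].sum()
    return out


def stationary_distribution(W: RateMatrix) -> np.ndarray:
    """Unique left null vector of the generator, normalised to 1.

    Raises
    ------
    MultipleStationaryStatesError
        If the zero eigenvalue is not simple (spectral gap below
        ``SPECTRAL_GAP_TOL`` relative to the largest rate).
    """
    vals, vecs = eig(W.w.T)
    scale = max(np.max(np.abs(W.w)), 1.0)
    order = np.argsort(np.abs(vals))
    if len(vals) > 1 and np.abs(vals[order[1]]) < SPECTRAL_GAP_TOL * scale:
        raise MultipleStationaryStatesError(
            "zero eigenvalue of the generator is degenerate: "
            "no unique stationary distribution"
        )
    pi = np.real(vecs[:, order[0]])
    pi = np.abs(pi)
    return pi / pi.sum()


def shannon_entropy(P) -> float:
    """Shannon entropy ``-sum P ln P`` in nats, with 0 ln 0 = 0."""
    P = np.asarray(P, dtype=float)
    nz = P > 0
    return float(-np.sum(P[nz] * np.log(P[nz])))


def _pair_fluxes(P: np.ndarray, w: np.ndarray):
    """Forward/backward probability fluxes ``a = P_n w_nm``, ``b = P_m w_mn``."""
    a = P[:, None] * w
    b = a.T
    np.fill_diagonal(a, 0.0)
    return a, b


def entropy_rates(P, W: RateMatrix, pi=None) -> EntropyRates:
    """All entropy-rate decompositions at distribution ``P``.

    ``si`` uses the symmetric half-sum over ordered pairs
    ``(1/2) sum (P_n w_nm - P_m w_mn) ln(P_n w_nm / P_m w_mn)`` which is
    manifestly non-negative; ``se`` carries the reservoir log-ratio
    ``ln(w_nm / w_mn)``; ``sdot = si + se`` equals ``dS/dt`` along the
    master equation.  The adiabatic/non-adiabatic split needs the
    stationary distribution ``pi``; if ``pi`` is omitted it is computed,
    and set to ``nan`` when no unique one exists.
    """
    P = validate_probability(P)
    w = W.w
    a, b = _pair_fluxes(P, w)

    irreversible = False
    si = 0.0
    se = 0.0
    d = W.d
    for n in range(d):
        for m in range(n + 1, d):
            fwd, rev = w[n, m], w[m, n]
            if fwd == 0.0 and rev == 0.0:
                continue
            an, bn = a[n, m], b[n, m]
            if fwd == 0.0 or rev == 0.0:
                if an > 0.0 or bn > 0.0:
                    # populated transition with zero reverse *rate*
                    irreversible = True
                    si = math.inf
                    se = -math.inf
                continue
            if an == 0.0 and bn == 0.0:
                continue
            if an == 0.0 or bn == 0.0:
                # zero from a vanishing occupation, not a zero rate:
                # instantaneous divergence (e.g. a delta initial condition)
                si = math.inf
            elif math.isfinite(si):
                si += (an - bn) * math.log(an / bn)
            if math.isfinite(se):
                se += -(an - bn) * math.log(fwd / rev)

    if pi is None:
        try:
            pi = stationary_distribution(W)
        except MultipleStationaryStatesError:
            pi = None
    sia = sina = math.nan
    if pi is not None and math.isfinite(si):
        pi = validate_probability(pi)
        sia = 0.0
        for n in range(d):
            for m in range(d):
                if n == m or a[n, m] == 0.0:
                    continue
                if pi[n] <= 0.0 or pi[m] <= 0.0:
                    sia = math.inf
                    break
                sia += a[n, m] * math.log(
                    (pi[n] * w[n, m]) / (pi[m] * w[m, n])
                )
            if not math.isfinite(sia):
                break
        Pdot = P @ w
        sina = 0.0
        for n in range(d):
            if P[n] > 0.0 and pi[n] > 0.0:
                sina += -Pdot[n] * math.log(P[n] / pi[n])
            elif Pdot[n] != 0.0:
                sina = math.nan
                break

    sdot = si + se if math.isfinite(si) else math.nan
    return EntropyRates(
        shannon=shannon_entropy(P),
        sdot=sdot,
        si=si,
        se=se,
        sia=sia,
        sina=sina,
        irreversible_transition=irreversible,
    )


def probability_currents(P, W: RateMatrix) -> np.ndarray:
    """Antisymmetric current matrix ``J[n, m] = P_n w_nm - P_m w_mn``."""
    P = validate_probability(P)
    a, b = _pair_fluxes(P, W.w)
    return a - b


def detailed_balance_residual(W: RateMatrix) -> float:
    """Max over pairs of ``|pi_n w_nm - pi_m w_mn|`` at stationarity.

    Zero iff the steady state is an equilibrium one.
    """
    pi = stationary_distribution(W)
    return float(np.max(np.abs(probability_currents(pi, W))))


def random_rate_matrix(d: int, seed, mode: str = "generic") -> RateMatrix:
    """Reproducible random generators for testing and fixtures.

    Modes
    -----
    generic
        Independent uniform off-diagonal rates on (0.1, 1.1).
    detailed_balance
        ``w_nm = r_nm exp((E_n - E_m)/2)`` with symmetric ``r`` and random
        state energies ``E``: detailed balance holds by construction.
    cyclic
        Nearest-neighbour ring with a single clockwise rate ``alpha`` and
        counter-clockwise rate ``beta`` drawn at random.
    """
    if d < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    if mode == "generic":
        w = rng.uniform(0.1, 1.1, size=(d, d))
    elif mode == "detailed_balance":
        r = rng.uniform(0.1, 1.1, size=(d, d))
        r = 0.5 * (r + r.T)
        E = rng.normal(size=d)
        w = r * np.exp((E[:, None] - E[None, :]) / 2.0)
    elif mode == "cyclic":
        alpha, beta = rng.uniform(0.5, 2.5, size=2)
        w = np.zeros((d, d))
        for i in range(d):
            w[i, (i + 1) % d] = alpha
            w[i, (i - 1) % d] = beta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return validate_rate_matrix(w)
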