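"""Closed-form probabilities and entropy rates for the discrete catalogue.

Each system here has an exact time-dependent solution of its master
equation and closed-form internal production ``si`` and external flow
``se``; all of them are cross-checkable against the generic engine in
:mod:`entroprod.markov` on the corresponding finite chain.

Systems: the two-state process, the cyclic three-state process, the random
walk on a complete graph, N independent particles (distinguishable and
indistinguishable, two-state and d-state), and asymmetric random walks on
the infinite lattice and on a ring lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb, factorial
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import ive

from .markov import EntropyRates, RateMatrix, entropy_rates, validate_rate_matrix

__all__ = [
    "TwoStateSpec",
    "LatticeRWSpec",
    "UnsupportedTopologyError",
    "two_state_rate_matrix",
    "two_state_solution",
    "three_state_rate_matrix",
    "three_state_solution",
    "complete_graph_rate_matrix",
    "complete_graph_solution",
    "complete_graph_asymptote",
    "distinguishable_sum",
    "occupation_rate_matrix",
    "indistinguishable_two_state",
    "indistinguishable_dstate",
    "lattice_rw_density",
    "lattice_rw_entropy",
    "lattice_rw_entropy_asymptote",
    "ring_rw_solution",
    "cyclic_rate_matrix",
]


class UnsupportedTopologyError(ValueError):
    """Ring lattices need at least 3 sites.

    A two-site ring has a different phase-space topology (each bond
    carries both directions at once); use the two-state system with
    ``alpha = beta = r + l`` instead.
    """


@dataclass(frozen=True)
class TwoStateSpec:
    """Two-state chain: rate ``alpha`` (1 -> 2), ``beta`` (2 -> 1), initial
    probability ``p`` of state 1.  ``r = alpha p - beta (1 - p)`` is the
    initial probability current."""

    alpha: float
    beta: float
    p: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def r(self) -> float:
        return self.alpha * self.p - self.beta * (1.0 - self.p)


@dataclass(frozen=True)
class LatticeRWSpec:
    """Nearest-neighbour random walk: right rate ``right``, left rate
    ``left``, lattice spacing ``spacing``, initial site ``x0`` (physical
    position).  For ring lattices, ``circumference`` is a multiple of the
    spacing with at least 3 sites."""

    right: float
    left: float
    spacing: float = 1.0
    x0: float = 0.0
    circumference: float | None = None

    def __post_init__(self):
        if self.right <= 0 or self.left <= 0:
            raise ValueError("hopping rates must be positive")
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if self.circumference is not None:
            n = self.circumference / self.spacing
            if abs(n - round(n)) > 1e-9:
                raise ValueError("circumference must be a multiple of the spacing")
            if round(n) < 3:
                raise UnsupportedTopologyError(
                    "ring lattices need >= 3 sites; a 2-site ring is the "
                    "two-state system with alpha = beta = right + left"
                )

    @property
    def n_sites(self) -> int:
        if self.circumference is None:
            raise ValueError("not a ring lattice")
        return round(self.circumference / self.spacing)


class TwoStateSolution(NamedTuple):
    P1: float
    P2: float
    si: float
    se: float


class ThreeStateSolution(NamedTuple):
    P1: float
    P2: float
    P3: float
    si: float
    se: float


# ---------------------------------------------------------------------------
# Two-state process
# ---------------------------------------------------------------------------

def two_state_rate_matrix(spec: TwoStateSpec) -> RateMatrix:
    return validate_rate_matrix(
        [[0.0, spec.alpha], [spec.beta, 0.0]], labels=("1", "2")
    )


def two_state_solution(spec: TwoStateSpec, t: float) -> TwoStateSolution:
    """Exact occupation probabilities and entropy rates at time ``t``.

    ``P(t) = (beta + r e^{-(a+b)t}, alpha - r e^{-(a+b)t}) / (a + b)``;
    ``si = [P1 a - P2 b] ln(P1 a / P2 b)`` and
    ``se = -r e^{-(a+b)t} ln(a/b)``, both decaying to zero: the two-state
    chain always equilibrates.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    a, b, r = spec.alpha, spec.beta, spec.r
    decay = math.exp(-(a + b) * t)
    P1 = (b + r * decay) / (a + b)
    P2 = (a - r * decay) / (a + b)
    flux = P1 * a - P2 * b  # equals r * decay
    if flux == 0.0:
        si = 0.0
    elif P1 <= 0.0 or P2 <= 0.0:
        si = math.inf
    else:
        si = flux * math.log((P1 * a) / (P2 * b))
    se = -r * decay * math.log(a / b)
    return TwoStateSolution(P1, P2, si, se)


# ---------------------------------------------------------------------------
# Cyclic three-state process (and M-state generalisation)
# ---------------------------------------------------------------------------

def cyclic_rate_matrix(M: int, alpha: float, beta: float) -> RateMatrix:
    """Ring of ``M`` states, clockwise rate ``alpha``, counter-clockwise
    ``beta``; the M = 3 case is the classic three-state cycle."""
    if M < 3:
        raise ValueError("cyclic chains need at least 3 states")
    w = np.zeros((M, M))
    for i in range(M):
        w[i, (i + 1) % M] = alpha
        w[i, (i - 1) % M] = beta
    return validate_rate_matrix(w, labels=tuple(str(i + 1) for i in range(M)))


def three_state_rate_matrix(alpha: float, beta: float) -> RateMatrix:
    return cyclic_rate_matrix(3, alpha, beta)


def three_state_solution(alpha: float, beta: float, t: float) -> ThreeStateSolution:
    """Exact solution of the three-state cycle started at state 1.

    Relaxation combines the decay ``e^{-3 phi t}`` with an oscillation
    of frequency ``sqrt(3) psi``, where ``phi = (alpha+beta)/2`` and
    ``psi = (alpha-beta)/2`` — the complex eigenvalue pair of the cyclic
    generator.  The flow ``se = -(alpha-beta) ln(alpha/beta)`` is constant:
    the cycle sustains a current ``(alpha-beta)/3`` at stationarity.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if alpha <= 0 or beta <= 0:
        raise ValueError("rates must be positive")
    phi = (alpha + beta) / 2.0
    psi = (alpha - beta) / 2.0
    decay = math.exp(-3.0 * phi * t)
    th = math.sqrt(3.0) * psi * t
    P1 = (1.0 + 2.0 * decay * math.cos(th)) / 3.0
    P2 = (1.0 - 2.0 * decay * math.cos(th + math.pi / 3.0)) / 3.0
    P3 = (1.0 - 2.0 * decay * math.cos(th - math.pi / 3.0)) / 3.0
    se = -(alpha - beta) * math.log(alpha / beta)
    if min(P1, P2, P3) <= 0.0:
        si = math.inf
    else:
        si = (
            (alpha - beta) * math.log(alpha / beta)
            + (P1 * alpha - P2 * beta) * math.log(P1 / P2)
            + (P2 * alpha - P3 * beta) * math.log(P2 / P3)
            + (P3 * alpha - P1 * beta) * math.log(P3 / P1)
        )
    return ThreeStateSolution(P1, P2, P3, si, se)


# ---------------------------------------------------------------------------
# Random walk on a complete graph
# ---------------------------------------------------------------------------

def complete_graph_rate_matrix(d: int, alpha: float) -> RateMatrix:
    if d < 2:
        raise ValueError("need at least 2 nodes")
    w = np.full((d, d), float(alpha))
    return validate_rate_matrix(w)


def complete_graph_solution(d: int, alpha: float, P0, t: float):
    """Relaxation on the complete graph with uniform rate ``alpha``.

    ``P_j(t) = 1/d + e^{-d alpha t} (P_j(0) - 1/d)``; all rates being
    equal, the reservoir log-ratio vanishes and ``se = 0`` throughout:
    the walk relaxes to the uniform equilibrium state.

    Returns ``(P, si, se)`` with ``P`` the distribution at ``t``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    P0 = np.asarray(P0, dtype=float)
    if P0.size != d:
        raise ValueError("initial distribution size must equal d")
    E = math.exp(-d * alpha * t)
    P = 1.0 / d + E * (P0 - 1.0 / d)
    si = 0.0
    for j in range(d):
        for k in range(d):
            if j == k:
                continue
            num = 1.0 + E * (P0[j] * d - 1.0)
            den = 1.0 + E * (P0[k] * d - 1.0)
            if num <= 0.0 or den <= 0.0:
                return P, math.inf, 0.0
            si += 0.5 * alpha * E * (P0[j] - P0[k]) * math.log(num / den)
    return P, si, 0.0


def complete_graph_point_start(d: int, alpha: float, t: float) -> float:
    """``si`` for a walker started on a single node:
    ``(d-1) alpha e^{-d alpha t} ln(1 + d e^{-d a t}/(1 - e^{-d a t}))``."""
    if t <= 0:
        return math.inf
    E = math.exp(-d * alpha * t)
    return (d - 1) * alpha * E * math.log(1.0 + d * E / (1.0 - E))


def complete_graph_asymptote(d: int, alpha: float, t: float) -> float:
    """Leading large-time behaviour ``d (d-1) alpha e^{-2 d alpha t}``."""
    return d * (d - 1) * alpha * math.exp(-2.0 * d * alpha * t)


# ---------------------------------------------------------------------------
# N-particle systems
# ---------------------------------------------------------------------------

def distinguishable_sum(particles: Sequence[tuple]) -> EntropyRates:
    """Entropy rates of N independent distinguishable particles.

    ``particles`` is a list of ``(P, W)`` pairs (one per particle); the
    production and flow of the joint process are simply the sums of the
    single-particle values — distinguishability factorises the joint
    distribution and the joint rates.
    """
    if not particles:
        raise ValueError("need at least one particle")
    parts = [entropy_rates(P, W) for P, W in particles]
    return EntropyRates(
        shannon=sum(p.shannon for p in parts),
        sdot=sum(p.sdot for p in parts),
        si=sum(p.si for p in parts),
        se=sum(p.se for p in parts),
        sia=sum(p.sia for p in parts),
        sina=sum(p.sina for p in parts),
        irreversible_transition=any(p.irreversible_transition for p in parts),
    )


def occupation_rate_matrix(N: int, alpha: float, beta: float) -> RateMatrix:
    """Occupation-number chain for N indistinguishable two-state particles.

    State ``n`` = number of particles in state 1; hop ``n -> n-1`` at rate
    ``alpha n`` and ``n -> n+1`` at rate ``beta (N - n)``.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    w = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        if n - 1 >= 0:
            w[n, n - 1] = alpha * n
        if n + 1 <= N:
            w[n, n + 1] = beta * (N - n)
    return validate_rate_matrix(w, labels=tuple(str(n) for n in range(N + 1)))


def indistinguishable_two_state(N: int, spec: TwoStateSpec, t: float):
    """N indistinguishable two-state particles, binomially initialised.

    The occupation distribution stays binomial with parameter ``P1(t)``;
    ``si`` is exactly N times the single-particle production, while ``se``
    picks up a combinatorial correction — a difference of microcanonical
    entropies of the occupation states — that vanishes at ``N = 1``, at
    ``P1 = 1/2`` and at stationarity.

    Returns ``(P_occupation, si, se)``.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    sol = two_state_solution(spec, t)
    P1 = sol.P1
    occ = np.array(
        [comb(N, n) * P1**n * (1.0 - P1) ** (N - n) for n in range(N + 1)]
    )
    si = N * sol.si
    flux = spec.alpha * P1 - spec.beta * (1.0 - P1)
    corr = sum(
        P1**n * (1.0 - P1) ** (N - 1 - n) * comb(N - 1, n)
        * math.log((n + 1) / (N - n))
        for n in range(N)
    )
    se = -N * flux * (math.log(spec.alpha / spec.beta) + corr)
    return occ, si, se


def _compositions(N: int, d: int):
    """All occupation vectors of N particles over d states."""
    for slots in combinations_with_replacement(range(d), N):
        n = [0] * d
        for s in slots:
            n[s] += 1
        yield tuple(n)


def _log_multinomial(n: tuple[int, ...]) -> float:
    N = sum(n)
    return math.lgamma(N + 1) - sum(math.lgamma(k + 1) for k in n)


def indistinguishable_dstate(N: int, W_single: RateMatrix, P_single) -> tuple:
    """N indistinguishable particles on a d-state graph, multinomial regime.

    All particles share the single-particle distribution ``P_single`` (they
    were initialised identically), so the occupation distribution is
    multinomial.  Then ``si = N si^(1)`` exactly, while
    ``se = N se^(1) - sum_n Pdot_n ln(N! / prod n_i!)``: the correction is
    the expected rate of change of the microcanonical (Boltzmann) entropy
    of the occupation states, and vanishes at stationarity.

    Returns ``(si, se)``.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    P = np.asarray(P_single, dtype=float)
    d = W_single.d
    if P.size != d:
        raise ValueError("P_single size must match the rate matrix")
    single = entropy_rates(P, W_single)
    si = N * single.si
    se = N * single.se

    # correction: -sum_n Pdot_n ln(multinomial degeneracy of n)
    w = W_single.w
    logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -math.inf)
    corr = 0.0
    for n in _compositions(N, d):
        if any(k > 0 and P[j] == 0.0 for j, k in enumerate(n)):
            continue
        # multinomial probability of configuration n
        lp = _log_multinomial(n) + sum(
            k * logP[j] for j, k in enumerate(n) if k > 0
        )
        Pn = math.exp(lp)
        # dPn/dt from the occupation master equation: in-flux minus out-flux;
        # the source configuration m = n + e_j - e_k has probability
        # P_m = Pn (P_j/P_k) n_k/(n_j+1) and exits to n at rate (n_j+1) w_jk
        Pdot = 0.0
        for j in range(d):
            for k in range(d):
                if j == k or w[j, k] == 0.0:
                    continue
                if n[j] >= 1:
                    Pdot -= Pn * n[j] * w[j, k]
                if n[k] >= 1:
                    Pdot += Pn * (P[j] / P[k]) * n[k] * w[j, k]
        corr += -Pdot * _log_multinomial(n)
    return si, se + corr


# ---------------------------------------------------------------------------
# Random walk on the infinite lattice
# ---------------------------------------------------------------------------

def lattice_rw_density(spec: LatticeRWSpec, x: float, t: float) -> float:
    """Site-occupation probability of the asymmetric walk at time ``t``.

    ``P(x,t) = e^{-(l+r)t} (r/l)^{(x-x0)/2a} I_{|x-x0|/a}(2t sqrt(rl))``
    with the modified Bessel function of the first kind; evaluated with
    exponential scaling for numerical stability at large ``t``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    r, l, a = spec.right, spec.left, spec.spacing
    m = (x - spec.x0) / a
    if abs(m - round(m)) > 1e-9:
        raise ValueError("x is not on the lattice")
    m = round(m)
    if t == 0:
        return 1.0 if m == 0 else 0.0
    z = 2.0 * t * math.sqrt(r * l)
    # ive(m, z) = I_m(z) e^{-z}; restore the exact prefactor
    return float(
        math.exp(-(l + r) * t + z) * (r / l) ** (m / 2.0) * ive(abs(m), z)
    )


def lattice_rw_entropy(
    spec: LatticeRWSpec, t: float, truncation: int | None = None
) -> tuple[float, float]:
    """Internal production and external flow of the infinite-lattice walk.

    ``se = -(r-l) ln(r/l)`` exactly (position-independent rates).  ``si``
    is the Bessel-function sum over sites; the sum is truncated
    adaptively, extending symmetrically in the site index until the next
    term falls below 1e-15 of the partial sum — terms compete at large
    times, so no fixed truncation is safe.  Returns ``(si, se)``;
    ``si = +inf`` at ``t = 0`` (delta initial condition).
    """
    r, l = spec.right, spec.left
    se = -(r - l) * math.log(r / l)
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0.0:
        return math.inf, se
    z = 2.0 * t * math.sqrt(r * l)
    pref = math.exp(-(l + r) * t + z)  # scaled-Bessel compensation

    def term(m: int) -> float:
        Im = float(ive(abs(m), z))
        Ip = float(ive(abs(m + 1), z))
        Imn = float(ive(abs(m - 1), z))
        if Im <= 0.0 or Ip <= 0.0 or Imn <= 0.0:
            return 0.0
        return (
            (r / l) ** (m / 2.0)
            * Im
            * (r * math.log(Im / Ip) + l * math.log(Im / Imn))
        )

    total = term(0)
    M = truncation if truncation is not None else 10_000_000
    m = 1
    while m <= M:
        step = term(m) + term(-m)
        total += step
        if truncation is None and abs(step) < 1e-15 * max(abs(total), 1e-300):
            break
        m += 1
    si = 0.5 * (r - l) * math.log(r / l) + pref * total
    return si, se


def lattice_rw_entropy_asymptote(spec: LatticeRWSpec, t: float) -> float:
    """Large-time behaviour: ``(r-l) ln(r/l) + 1/(2t)`` for asymmetric
    hopping, ``1/(2t)`` for the symmetric walk."""
    if t <= 0:
        raise ValueError("t must be positive")
    r, l = spec.right, spec.left
    if r == l:
        return 1.0 / (2.0 * t)
    return (r - l) * math.log(r / l) + 1.0 / (2.0 * t)


# ---------------------------------------------------------------------------
# Random walk on a ring lattice
# ---------------------------------------------------------------------------

def ring_rw_solution(spec: LatticeRWSpec, t: float):
    """Wrapped density and entropy rates of the walk on a ring lattice.

    The ring density is the infinite-lattice density summed over winding
    numbers; the winding sum is truncated where the Poissonian jump-count
    tail makes further images smaller than 1e-14 of the total.  At
    stationarity the density is uniform and ``si = (r-l) ln(r/l) = -se``.

    Returns ``(P_ring, si, se)`` with ``P_ring[k]`` the probability of
    site ``k`` (physical position ``k * spacing``), for ``k = 0..L/a-1``.
    """
    if spec.circumference is None:
        raise ValueError("spec does not describe a ring")
    if t < 0:
        raise ValueError("t must be non-negative")
    r, l, a = spec.right, spec.left, spec.spacing
    n_sites = spec.n_sites
    # images beyond the bulk of the jump-count distribution are negligible:
    # the walker makes ~ (r+l)t jumps, with Poisson tails
    n_jumps = (r + l) * t
    reach = n_jumps + 10.0 * math.sqrt(n_jumps + 1.0) + 20.0
    J = int(reach // n_sites) + 2
    x0_site = round(spec.x0 / a) % n_sites
    P = np.zeros(n_sites)
    for k in range(n_sites):
        s = 0.0
        for j in range(-J, J + 1):
            s += lattice_rw_density(
                spec, spec.x0 + ((k - x0_site) + j * n_sites) * a, t
            )
        P[k] = s
    P /= P.sum()

    se = -(r - l) * math.log(r / l)
    if np.any(P <= 0.0):
        return P, math.inf, se
    si = (r - l) * math.log(r / l)
    for k in range(n_sites):
        kp, km = (k + 1) % n_sites, (k - 1) % n_sites
        si += P[k] * (
            r * math.log(P[k] / P[kp]) + l * math.log(P[k] / P[km])
        )
    return P, si, se
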