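"""Stochastic sampling and trajectory-level entropy estimators.

Exact (Gillespie) sampling of jump processes and Euler-Maruyama
integration of the Langevin systems, together with estimators that
recover the analytic entropy rates from single trajectories:

* the medium-entropy (jump log-ratio) estimator for chains, where each
  jump ``n -> m`` contributes ``ln(w_nm / w_mn)``;
* the path-KL plug-in estimator, the discretised Kullback-Leibler rate
  between forward and time-reversed path ensembles;
* the Stratonovich medium-entropy estimator for Langevin paths,
  ``S_m = int F(x) o dx / T`` with midpoint evaluation and ``T = D/mu``;
* the mode-switch estimator for hybrid processes.

All estimators return ``(estimate, standard_error)``; standard errors
come from batch means over independent paths.  Seeding uses one root
seed with per-path child streams, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .markov import RateMatrix, validate_probability

__all__ = [
    "JumpPath",
    "LangevinPath",
    "sample_jump_paths",
    "medium_entropy_rate",
    "path_kl_rate",
    "euler_maruyama",
    "stratonovich_medium_entropy",
    "mode_switch_entropy",
    "suggest_burn_in",
]


@dataclass(frozen=True)
class JumpPath:
    """A single realisation of a jump process.

    ``times[i]`` is the instant of the i-th jump, after which the system
    occupies ``states[i]``; before the first jump it occupies
    ``initial_state``.  ``absorbed`` marks a path that reached a state
    with no exit rate before the horizon.
    """

    initial_state: int
    times: np.ndarray
    states: np.ndarray
    horizon: float
    absorbed: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        if t.size != s.size:
            raise ValueError("times and states must have equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0 or t[-1] > self.horizon):
            raise ValueError("jump times must be strictly increasing in (0, horizon]")

    def state_at(self, t: float) -> int:
        """State occupied at time ``t``."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.initial_state if i == 0 else int(self.states[i - 1])


@dataclass(frozen=True)
class LangevinPath:
    """A discretised Langevin trajectory.

    ``x`` holds unwrapped positions on the time grid ``k dt``; for ring
    processes the physical position is ``x mod L`` and the winding number
    ``floor(x / L)``.  ``modes`` (optional) is the drift-mode index per
    grid point for hybrid processes.
    """

    dt: float
    x: np.ndarray
    modes: np.ndarray | None = None
    mode_path: "JumpPath | None" = None
    L: float | None = None
    seed: object = None

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.modes is not None:
            m = np.asarray(self.modes, dtype=np.int64)
            if m.size != self.x.size:
                raise ValueError("modes must align with positions")
            object.__setattr__(self, "modes", m)

    @property
    def horizon(self) -> float:
        return (self.x.size - 1) * self.dt

    def wrapped(self) -> np.ndarray:
        if self.L is None:
            return self.x
        return np.mod(self.x, self.L)

    def winding(self) -> np.ndarray:
        if self.L is None:
            raise ValueError("not a ring path")
        return np.floor_divide(self.x, self.L).astype(np.int64)


# ---------------------------------------------------------------------------
# Jump processes
# ---------------------------------------------------------------------------

def sample_jump_paths(
    W: RateMatrix, P0, T: float, n_paths: int, seed
) -> list[JumpPath]:
    """Exact continuous-time sampling of the chain (Gillespie algorithm).

    Waiting times are exponential with the state's total exit rate; the
    destination is drawn proportionally to the outgoing rates.  Each path
    gets its own child RNG stream spawned from the root seed.
    """
    if T <= 0:
        raise ValueError("horizon must be positive")
    P0 = validate_probability(P0)
    w = W.w
    d = W.d
    exit_rates = -np.diag(w)
    jump_probs = []
    for n in range(d):
        if exit_rates[n] > 0:
            jump_probs.append(w[n] .clip(0) / exit_rates[n])
        else:
            jump_probs.append(np.zeros(d))
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    paths = []
    for child in root.spawn(n_paths):
        rng = np.random.default_rng(child)
        state = int(rng.choice(d, p=P0))
        init = state
        t = 0.0
        times, states = [], []
        absorbed = False
        while True:
            lam = exit_rates[state]
            if lam <= 0.0:
                absorbed = True
                break
            t += rng.exponential(1.0 / lam)
            if t > T:
                break
            state = int(rng.choice(d, p=jump_probs[state]))
            times.append(t)
            states.append(state)
        paths.append(
            JumpPath(
                initial_state=init,
                times=np.array(times),
                states=np.array(states, dtype=np.int64),
                horizon=T,
                absorbed=absorbed,
            )
        )
    return paths


def _batch_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error over independent per-path values."""
    values = np.asarray(values, dtype=float)
    n = values.size
    est = float(np.mean(values))
    se = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else math.inf
    return est, se


def medium_entropy_rate(paths: list[JumpPath], W: RateMatrix):
    """Time-averaged jump-entropy estimator.

    Each jump ``n -> m`` contributes ``ln(w_nm / w_mn)`` — the entropy
    exported to the reservoir — and the per-path sum divided by the
    horizon estimates ``-se``, which at stationarity equals ``si``.
    Returns ``(estimate, standard_error)``; ``(inf, inf)`` if any jump
    has a zero reverse rate.
    """
    w = W.w
    rates = np.empty(len(paths))
    for i, p in enumerate(paths):
        s = p.initial_state
        total = 0.0
        for t, nxt in zip(p.times, p.states):
            if w[int(nxt), s] <= 0.0:
                warnings.warn("observed jump with zero reverse rate")
                return math.inf, math.inf
            total += math.log(w[s, int(nxt)] / w[int(nxt), s])
            s = int(nxt)
        rates[i] = total / p.horizon
    return _batch_stats(rates)


def path_kl_rate(
    paths: list[JumpPath],
    W: RateMatrix,
    tau_sample: float,
    n_batches: int = 20,
):
    """Plug-in estimate of the forward/reverse path-KL divergence rate.

    Paths are discretised at interval ``tau_sample``; empirical state
    frequencies combine with the exact propagator ``T = expm(w tau)`` in
    ``(1/tau) sum_nm p_n T_nm ln(p_n T_nm / (p_m T_mn))``, which
    converges to the internal entropy production as ``tau -> 0``.
    State pairs never visited are excluded with a warning.
    """
    if tau_sample <= 0:
        raise ValueError("tau_sample must be positive")
    T = expm(W.w * tau_sample)
    T = np.clip(T, 0.0, None)
    d = W.d
    n_batches = min(n_batches, len(paths))
    batches = np.array_split(np.arange(len(paths)), n_batches)

    def estimate(idx) -> float:
        counts = np.zeros(d)
        for i in idx:
            p = paths[i]
            grid = np.arange(0.0, p.horizon + 1e-12, tau_sample)
            if p.states.size == 0:
                states = np.full(grid.size, p.initial_state, dtype=np.int64)
            else:
                # vectorised state lookup on the sampling grid
                pos = np.searchsorted(p.times, grid, side="right")
                states = np.where(
                    pos == 0, p.initial_state, p.states[np.maximum(pos - 1, 0)]
                )
            counts += np.bincount(states, minlength=d)
        freq = counts / counts.sum()
        kl = 0.0
        excluded = False
        for n in range(d):
            for m in range(d):
                if n == m:
                    continue
                a = freq[n] * T[n, m]
                b = freq[m] * T[m, n]
                if a > 0.0 and b > 0.0:
                    kl += a * math.log(a / b)
                elif a > 0.0 or b > 0.0:
                    excluded = True
        if excluded:
            warnings.warn("unvisited transitions excluded from path-KL estimate")
        return kl / tau_sample

    vals = np.array([estimate(idx) for idx in batches if idx.size])
    return _batch_stats(vals)


# ---------------------------------------------------------------------------
# Langevin processes
# ---------------------------------------------------------------------------

def euler_maruyama(
    spec,
    dt: float,
    T: float,
    n_paths: int,
    seed,
    x0: float = 0.0,
) -> list[LangevinPath]:
    """Euler-Maruyama integration of the catalogued Langevin systems.

    ``spec`` is a :class:`~entroprod.continuum.DiffusionSpec` (drift,
    optional stiffness, optional periodic potential, line or ring) or a
    :class:`~entroprod.hybrid.SwitchingSpec` (mode-switching drift on a
    ring).  Increments have variance ``2 D dt``; mode switching uses
    exact exponential clocks read on the step grid.  Stability demands
    ``dt k < 0.1`` and ``dt max|alpha| < 0.1``; violations raise with a
    suggested step.
    """
    from .continuum import DiffusionSpec  # local import avoids a cycle
    from .hybrid import SwitchingSpec

    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    n_steps = int(round(T / dt))
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_paths)

    if isinstance(spec, SwitchingSpec):
        amax = float(np.max(-np.diag(spec.alpha.w)))
        if dt * amax >= 0.1:
            raise ValueError(
                f"dt too large for switching rates; use dt <= {0.09 / amax:.3g}"
            )
        return _em_switching(spec, dt, n_steps, children, x0)

    if not isinstance(spec, DiffusionSpec):
        raise TypeError("spec must be a DiffusionSpec or SwitchingSpec")
    if spec.k > 0 and dt * spec.k >= 0.1:
        raise ValueError(
            f"dt too large for stiffness k; use dt <= {0.09 / spec.k:.3g}"
        )

    Vp = None
    if spec.potential is not None:
        # spectral derivative of the sampled potential on the ring
        if spec.domain != "ring":
            raise ValueError("potential currently supported on the ring only")
        ngrid = 2048
        xg = np.linspace(0.0, spec.L, ngrid, endpoint=False)
        Vg = np.asarray(spec.potential(xg), dtype=float)
        kfreq = 2.0 * math.pi * np.fft.rfftfreq(ngrid, d=spec.L / ngrid)
        dVg = np.append(np.fft.irfft(1j * kfreq * np.fft.rfft(Vg), n=ngrid),
                        0.0)
        dVg[-1] = dVg[0]

        def Vp(x):
            return np.interp(np.mod(x, spec.L) / spec.L * ngrid,
                             np.arange(ngrid + 1), dVg)

    sig = math.sqrt(2.0 * spec.D * dt)
    # per-path child streams keep runs bit-reproducible; the time stepping
    # itself is vectorised across paths
    noise = np.stack(
        [np.random.default_rng(c).normal(0.0, sig, size=n_steps)
         for c in children]
    )
    x = np.empty((n_paths, n_steps + 1))
    x[:, 0] = x0
    if spec.k == 0.0 and Vp is None:
        x[:, 1:] = x0 + np.cumsum(spec.v * dt + noise, axis=1)
    else:
        for i in range(n_steps):
            drift = spec.v - spec.k * x[:, i]
            if Vp is not None:
                drift = drift - Vp(x[:, i])
            x[:, i + 1] = x[:, i] + drift * dt + noise[:, i]
    ring_L = spec.L if spec.domain == "ring" else None
    return [
        LangevinPath(dt=dt, x=x[i], L=ring_L, seed=children[i].entropy)
        for i in range(n_paths)
    ]


def _em_switching(spec, dt, n_steps, children, x0):
    """Mode-switching Euler-Maruyama.

    The mode process is sampled exactly (exponential clocks / Gillespie);
    positions then integrate the mode's drift on the step grid with the
    mode read at the left endpoint of each step, vectorised across paths.
    """
    M = spec.M
    v = np.asarray(spec.v)
    T = n_steps * dt
    mode_paths = sample_jump_paths(
        spec.alpha, np.full(M, 1.0 / M), T, len(children), _spawn_key(children)
    )
    sig = math.sqrt(2.0 * spec.D * dt)
    grid = np.arange(n_steps + 1) * dt
    paths = []
    for child, mp in zip(children, mode_paths):
        rng = np.random.default_rng(child)
        if mp.states.size:
            pos = np.searchsorted(mp.times, grid, side="right")
            modes = np.where(pos == 0, mp.initial_state,
                             mp.states[np.maximum(pos - 1, 0)]).astype(np.int64)
        else:
            modes = np.full(n_steps + 1, mp.initial_state, dtype=np.int64)
        noise = rng.normal(0.0, sig, size=n_steps)
        x = np.empty(n_steps + 1)
        x[0] = x0
        x[1:] = x0 + np.cumsum(v[modes[:-1]] * dt + noise)
        paths.append(
            LangevinPath(dt=dt, x=x, modes=modes, mode_path=mp, L=spec.L,
                         seed=child.entropy)
        )
    return paths


def _spawn_key(children) -> np.random.SeedSequence:
    """A deterministic sibling seed for the auxiliary mode process."""
    return np.random.SeedSequence(entropy=children[0].entropy, spawn_key=(10_007,))


def stratonovich_medium_entropy(
    paths: list[LangevinPath],
    F,
    D: float,
    mu: float = 1.0,
    ito: bool = False,
    burn_in: float = 0.0,
):
    """Medium-entropy rate from Langevin paths.

    ``S_m = sum_k F((x_k + x_{k+1})/2) (x_{k+1} - x_k) / T`` with the
    bath temperature ``T = D / mu``; the midpoint (Stratonovich) rule is
    essential — the Ito variant (``ito=True``, left-point evaluation) is
    provided only to demonstrate the discrepancy.  For ergodic stationary
    systems ``S_m / t`` converges to the stationary entropy production.

    ``F`` is a callable ``F(x)`` or, for mode-carrying paths, ``F(x, mode)``.
    The initial ``burn_in`` time units are discarded so the relaxation
    transient (heat released while the density equilibrates) does not
    contaminate the stationary estimate.
    """
    T_bath = D / mu
    rates = np.empty(len(paths))
    for i, p in enumerate(paths):
        k0 = min(int(round(burn_in / p.dt)), p.x.size - 2)
        x = p.x[k0:]
        dx = np.diff(x)
        xeval = x[:-1] if ito else 0.5 * (x[:-1] + x[1:])
        if p.modes is not None:
            f = F(xeval, p.modes[k0:-1])
        else:
            f = F(xeval)
        rates[i] = float(np.sum(np.asarray(f) * dx)) / T_bath / (p.horizon - k0 * p.dt)
    return _batch_stats(rates)


def mode_switch_entropy(paths: list[LangevinPath], alpha):
    """Jump-contribution estimator over mode transitions.

    Each observed switch ``i -> j`` contributes ``ln(alpha_ij/alpha_ji)``;
    the per-path total over the horizon estimates the switching part of
    the stationary entropy production.  Returns ``(inf, inf)`` if an
    irreversible switch (zero reverse rate) is observed.
    """
    if not isinstance(alpha, RateMatrix):
        from .markov import validate_rate_matrix

        alpha = validate_rate_matrix(alpha)
    a = alpha.w
    rates = np.empty(len(paths))
    for i, p in enumerate(paths):
        if p.mode_path is not None:
            # exact switch sequence: no O(dt) blind spot for double switches
            seq = np.concatenate(([p.mode_path.initial_state],
                                  p.mode_path.states))
            pairs = zip(seq[:-1], seq[1:])
        elif p.modes is not None:
            m = p.modes
            chg = np.nonzero(m[1:] != m[:-1])[0]
            pairs = ((int(m[c]), int(m[c + 1])) for c in chg)
        else:
            raise ValueError("paths carry no mode labels")
        total = 0.0
        for src, dst in pairs:
            if a[dst, src] <= 0.0:
                warnings.warn("observed irreversible mode switch")
                return math.inf, math.inf
            total += math.log(a[src, dst] / a[dst, src])
        rates[i] = total / p.horizon
    return _batch_stats(rates)


def suggest_burn_in(W: RateMatrix | None = None, k: float = 0.0,
                    alpha_max: float = 0.0) -> float:
    """Burn-in horizon: five relaxation times of the slowest given scale."""
    gaps = []
    if W is not None:
        vals = np.linalg.eigvals(W.w)
        nonzero = sorted(abs(v.real) for v in vals if abs(v) > 1e-12)
        if nonzero:
            gaps.append(nonzero[0])
    if k > 0:
        gaps.append(k)
    if alpha_max > 0:
        gaps.append(alpha_max)
    if not gaps:
        raise ValueError("no relaxation scale available")
    return 5.0 / min(gaps)
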