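# Methods

This note documents the models implemented in `entroprod`, the numerical
choices behind them, and what the test suite does and does not establish.

## Model class and conventions

All processes are time-homogeneous Markov processes: finite
continuous-time chains (generator `w` with non-negative off-diagonal
rates and zero row sums), one-dimensional overdamped diffusions
(Fokker–Planck dynamics with constant diffusion coefficient `D` and
time-independent force), and hybrid processes whose drift switches
between a finite set of modes. Time-dependent driving protocols,
absorbing-state chains, correlated noise and dimensions above one are
out of scope. Entropy is in nats with `k_B = 1`; the arbitrary rate and
density scales that make logarithms dimensionless are fixed to 1, since
they cancel in every internal/external decomposition. The mobility is 1
unless supplied, so the bath temperature is `T = D`.

States are 0-indexed internally; external labels are carried alongside.
Probability vectors are rows, so the master equation reads `dP/dt = P w`
and is solved by the matrix exponential (`scipy.linalg.expm`), which for
the system sizes at hand (d ≲ 100) is both faster and more accurate than
ODE stepping; an ODE integration at `rtol = 1e-12` serves as an
independent oracle in the tests only.

## Entropy-rate decompositions

The internal production `si` uses the symmetric half-sum over ordered
pairs, which is manifestly non-negative term by term. Zero handling
follows `0 ln 0 = 0`: a pair contributes nothing when both the forward
and reverse probability fluxes vanish. Two qualitatively different
divergences are distinguished rather than clamped:

- a populated transition whose **reverse rate** is exactly zero makes
  `si = +inf` and sets `irreversible_transition=True` — absolute
  irreversibility lies outside the model class and is surfaced loudly;
- a populated transition into a state of zero **occupation** (e.g. a
  delta initial condition at `t = 0`) also gives `si = +inf`, but is not
  flagged as irreversible, matching the `1/(2t)`-type transients of the
  continuum systems.

The adiabatic/non-adiabatic split needs the stationary distribution; it
is computed from the eigendecomposition of `w^T`, and the zero
eigenvalue is accepted as simple only when every other eigenvalue has
modulus above `1e-10` relative to the largest rate. Chains with several
ergodic components raise `MultipleStationaryStatesError` — the package
refuses to pick a component silently, and `entropy_rates` reports the
split as `NaN` in that case while still returning `si`, `se` and `sdot`.

## Discrete catalogue

Each closed form is cross-checked against the generic engine on the
corresponding finite chain at `1e-8` or better. Numerical specifics:

- **Lattice walk.** The site occupation uses exponentially scaled Bessel
  functions (`scipy.special.ive`) so that densities and the entropy sum
  remain finite at large `t`, where `I_m(2t√(rl))` alone overflows. The
  entropy sum is truncated adaptively — terms are added symmetrically in
  the site index until the next pair falls below `1e-15` of the running
  total — because the terms compete at large times and no fixed
  truncation is safe. Positions are held as integer site indices;
  physical positions are reconstructed as `x0 + index * spacing`,
  avoiding float-parity bugs in the even/odd jump-count bookkeeping.
- **Ring lattice.** The wrapped density sums lattice images over winding
  numbers; the number of images retained covers the Poissonian
  jump-count distribution out to ten standard deviations plus a fixed
  margin, beyond which images are below `1e-14` of the total. Rings with
  fewer than three sites are rejected (`UnsupportedTopologyError`): a
  two-site ring has both directions on one bond and is exactly the
  two-state chain with `alpha = beta = r + l`.
- **N-particle systems.** Indistinguishable particles are handled in the
  occupation-number representation under the binomial/multinomial
  initialisation for which the closed forms hold; other initialisations
  route through the generic engine on the occupation chain. The
  combinatorial correction to the flow (a difference of microcanonical
  entropies of the occupation states) is evaluated by exact enumeration
  of occupation vectors, practical for the `N ≤ 4`, `d ≤ 4` regime the
  tests exercise.
- The stationary production of the infinite lattice walk is reported via
  the numerical asymptote `(r−l) ln(r/l) + 1/(2t)` only; no claim is
  made about `lim S(t)` on the infinite lattice, where the Shannon
  entropy itself does not converge.

## Continuum systems

Two independent routes are implemented and must agree:

1. **Current route** — quadrature of `∫ j²/(D P) dx` and
   `−∫ (μ/D) F j dx` on the supplied grid (trapezoid; spectrally
   accurate for smooth periodic integrands on the ring). Points with
   `P = 0` but `j ≠ 0` raise with the offending locations; they signal
   an inconsistent field pair, not a numerical issue to be smoothed over.
2. **Propagator-limit route** — the short-lag Kullback–Leibler rate,
   evaluated as a double integral over position and displacement at lags
   `τ_k = τ0 · 2^{-k}`, `k = 0..6` (default `τ0 = 1e-2`), followed by
   first-order Richardson extrapolation in τ. The finite-lag rate is
   `si + c τ + O(τ²)`, so the extrapolation removes the leading bias;
   the residual between the last two extrapolants must fall below a
   tolerance (default `1e-4`) or the routine raises. The displacement
   grid is sized from the propagator's own first two moments (ten
   standard deviations), which assumes a roughly Gaussian kernel — true
   for every catalogued process.

The stationary ring density is built from the standard
double-exponential representation with the inner integral unwrapped
over one extra period (the second period contributes the factor
`e^{-vL/D}`); cumulative Simpson integration runs on a grid oversampled
16× relative to the 512-point output grid, which puts the two printed
routes (`si = ∫ j²/(D Ps)` versus `−se = j v L / D`) within `1e-8` of
each other. The uniform stationary current is evaluated in closed form
from the normalisation prefactor, `j = D A (1 − e^{-vL/D})` with
`A > 0`, which reduces to `j = v/L` for a flat potential. Potential
derivatives for the simulator are obtained by spectral differentiation
of the sampled potential.

## Hybrid processes

Only stationary rates have closed forms: the spatial density is uniform
in every mode, the mode weights are the stationary vector of the
switching chain, and the production separates exactly into a weighted
drift part `Σ z_i v_i²/D` and the switching chain's own production. The
time-dependent density of these processes is not available analytically;
transients are accessible only through simulation. The short-lag
propagators of the hybrid processes appear as small-τ expansion checks
in the tests, not as user-facing solvers.

## Simulation and estimators

- **Jump processes** are sampled exactly (exponential waiting times,
  categorical destinations). One root seed spawns per-path child
  streams (`numpy` `SeedSequence`), so every run is bit-reproducible
  and paths are statistically independent.
- **Langevin paths** use Euler–Maruyama with increment variance
  `2 D dt`. Steps are refused unless `dt·k < 0.1` and
  `dt·max|alpha| < 0.1`. For switching processes the mode trajectory is
  sampled exactly first (exponential clocks) and read at the left
  endpoint of each step; the exact switch sequence is retained on the
  path so the mode-switch estimator has no blind spot for double
  switches within one step.
- **Estimators.** The jump estimator adds `ln(w_nm/w_mn)` per jump; the
  Stratonovich medium-entropy estimator evaluates the force strictly at
  midpoints `(x_k + x_{k+1})/2` (an Itô variant exists behind a flag
  solely to demonstrate that the discretisation matters — the two
  differ by `O(1)` for state-dependent forces). Standard errors are
  batch means over independent paths. An optional burn-in discards the
  initial relaxation window, whose heat release otherwise contaminates
  stationary estimates at finite horizon as `ΔV/(D T)`.
- The path-KL plug-in estimator combines empirical state frequencies
  with the exact propagator matrix at the sampling interval τ. Its
  finite-τ value is a deterministic underestimate of `si` (the
  discretised KL rate), converging as τ → 0 with no closed-form bias
  correction; the tests therefore assert the monotone τ-trend and
  closeness at small τ, not agreement within sampling error.

Euler–Maruyama carries `O(dt)` weak bias; the equilibrium-ring test runs
at `dt = 1e-3`, where the measured bias (linear in `dt`, about
`-7e-3` at `dt = 5e-3` for the test's parameters) is below sampling
noise. Stochastic assertions use 3–4 standard errors at fixed seeds.

## Problem sizes

The default test run uses chains with up to ~120 states (truncated
lattice oracles), 200 random ensembles for the non-negativity property,
1 500–5 000 paths for stochastic checks and horizons of 10–50 time
units — sizes at which every analytic comparison is already at its
asymptotic tolerance while the whole suite completes in well under a
minute of simulation time.

## What the tests do and do not show

All verification targets *exactly solvable* systems: the generators are
small and well-conditioned, densities are Gaussian or nearly so, and
potentials are smooth. Passing tests demonstrate correctness of the
formulas and estimators in this regime. They do not probe stiff rate
matrices spanning many orders of magnitude, rough or discontinuous
potentials, heavy-tailed propagators (where the moment-based
displacement grid would be inadequate), or estimation from experimental
trajectories, which is explicitly out of scope.
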