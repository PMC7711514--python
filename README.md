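# entroprod

Entropy production rates for exactly solvable stochastic processes.

The rate of entropy production quantifies how far a stochastic process is
from thermodynamic equilibrium: it vanishes exactly when global detailed
balance — and with it time-reversal symmetry — holds. `entroprod` is a
toolkit for biophysicists and statistical physicists who need trustworthy
reference values for this quantity: exact rates for a catalogue of
solvable models (molecular-motor-like driven cycles and lattice walks,
driven colloidal particles, run-and-tumble bacteria), a generic engine
for arbitrary finite Markov chains, and stochastic simulators whose
trajectory-level estimators converge to the analytic rates.

## The quantities

For a continuous-time Markov chain with rates $w_{nm}$ and occupation
probabilities $P_n(t)$, the entropy rate $\dot S = \dot S_i + \dot S_e$
splits into the non-negative **internal production**

$$\dot S_i(t) = \tfrac12 \sum_{n,m} \left(P_n w_{nm} - P_m w_{mn}\right)
\ln \frac{P_n w_{nm}}{P_m w_{mn}} \;\ge\; 0$$

and the **entropy flow** to the environment
$\dot S_e = -\tfrac12 \sum_{n,m} (P_n w_{nm} - P_m w_{mn}) \ln(w_{nm}/w_{mn})$.
$\dot S_i$ further decomposes into adiabatic (housekeeping) and
non-adiabatic (excess) parts, and equals the Kullback–Leibler divergence
rate between forward and time-reversed path ensembles. For overdamped
diffusions with density $P(x,t)$ and current $j(x,t)$,

$$\dot S_i(t) = \int \mathrm{d}x\, \frac{j^2(x,t)}{D\,P(x,t)}, \qquad
\dot S_e(t) = -\int \mathrm{d}x\, \frac{\mu F(x)\, j(x,t)}{D}.$$

Entropy is in nats with $k_B = 1$.

## Worked example

A particle on a driven three-state cycle (clockwise rate α = 2,
counter-clockwise β = 1) never equilibrates — the cycle sustains a
current (α − β)/3 — and produces entropy at the stationary rate
(α − β) ln(α/β) = ln 2:

```python
from entroprod import (stationary_distribution, entropy_rates,
                       sample_jump_paths, medium_entropy_rate)
from entroprod.catalogue import cyclic_rate_matrix

W = cyclic_rate_matrix(3, alpha=2.0, beta=1.0)
pi = stationary_distribution(W)          # [1/3, 1/3, 1/3]
r = entropy_rates(pi, W)
print(f"si = {r.si:.6f}, se = {r.se:.6f}")

paths = sample_jump_paths(W, pi, T=50.0, n_paths=1500, seed=5)
est, se_err = medium_entropy_rate(paths, W)
print(f"trajectory estimate = {est:.4f} +- {se_err:.4f}")
```

```
si = 0.693147, se = -0.693147
trajectory estimate = 0.6918 +- 0.0044
```

The first line is the exact stationary production/flow pair
(ln 2 ≈ 0.6931, equal and opposite: the state distribution is steady while
the medium keeps absorbing entropy). The second is the same rate
recovered from 1500 simulated trajectories via the jump log-ratio
estimator, agreeing within its standard error.

The same three-route cross-check — closed form vs generic engine vs
simulation — is available for every catalogued system from the shell:

```sh
entroprod compare two_state --params '{"alpha": 2, "beta": 1, "p": 1}'
entroprod continuum ou --v 1 --k 1 --d 1 --t 20
entroprod hybrid rtp --v 1,-2 --d 1
entroprod simulate ctmc --rates w.json --paths 2000 --t 50 --seed 1
```

## Layout

- `entroprod.markov` — generic chain engine: master equation, stationary
  states, all entropy-rate decompositions, currents, detailed balance.
- `entroprod.catalogue` — closed forms for the discrete systems.
- `entroprod.continuum` — drift–diffusion, harmonic trap, ring with
  periodic potential; current-based and propagator-limit routes.
- `entroprod.hybrid` — run-and-tumble and switching diffusion.
- `entroprod.simulate` — Gillespie and Euler–Maruyama samplers and the
  trajectory-level estimators.
- `entroprod.io` / `entroprod.cli` — formats, configs and the
  `entroprod` command.

See `docs/methods.md` for the numerical choices and their rationale.
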