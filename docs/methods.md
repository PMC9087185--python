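# Methods

## Model

`hospflow` models monthly outpatient visit volumes at China's three
hospital tiers as a three-compartment logistic system with one-way
transfer. Let `x`, `y`, `z` be the visit volumes (units of 10,000
visits per month) at first-, second- and third-level hospitals:

```
dx/dt = -(r_f/m_f) x² + r_f x - (α + η + c_f) x
dy/dt = -(r_s/m_s) y² + r_s y + αx - (β + c_s) y
dz/dt = -(r_t/m_t) z² + r_t z + ηx + βy - c_t z
```

Each tier grows logistically — the growth rate declines linearly from
the inherent rate `r` at zero load to zero at the capacity `m` — and
loses a fraction `c` per month to churn (death, abandoned treatment).
The transfer terms encode patients' preference for higher tiers:
fractions `α` and `η` of the FLH volume move per month to SLHs and
TLHs respectively, and a fraction `β` of the SLH volume moves to
TLHs. Transfers are strictly upward, so the coupling matrix is lower
triangular: `x` is autonomous, `y` depends on `x`, and `z` on both.

Assumptions worth keeping in mind: visit volume is treated as a
continuous, differentiable state; the twelve parameters are constant
in time (no policy change, demography or epidemic shocks); transfers
are proportional to the donor tier's volume; and there is no seasonal
forcing in the dynamics — the pronounced seasonality of real monthly
visit data is deliberately left to the observation layer (see the
generator below).

### Parameters, units and defaults

Time is in months, volumes in units of 10,000 visits/month.

| parameter | meaning | reference value |
|---|---|---|
| `r_f, r_s, r_t` | inherent growth rate per tier (1/month) | 0.0982, 0.1096, 0.0020 |
| `m_f, m_s, m_t` | visit capacity per tier (10,000/month) | 9000.1, 29899.2, 42999.8 |
| `c_f, c_s, c_t` | churn rate per tier (1/month) | 0.0010, 0.0406, 0.0271 |
| `alpha` | leapfrog FLH→SLH (1/month) | 0.044 |
| `beta` | leapfrog SLH→TLH (1/month) | 0.037 |
| `eta` | leapfrog FLH→TLH (1/month) | 0.030 |

The reference values (`hospflow.REFERENCE_PARAMS`) come from a
least-squares fit of this model to China's national monthly visit
series, January–November 2011–2018. Growth, capacity and churn
parameters must be strictly positive; the transfer rates are admitted
at exactly zero so that decoupled single-tier limits are expressible
(in the motivating application they are positive).

## Equilibria and stability

Setting the right side to zero and solving tier by tier gives four
non-negative equilibria: the origin `E1*`; `E2* = (0, 0,
m_t(r_t−c_t)/r_t)` existing iff `H1: r_t > c_t`; `E3* = (0, y₃, z₃)`
with `y₃ = m_s(r_s−β−c_s)/r_s`, existing iff `H2: r_s > β + c_s`; and
the fully occupied `E4*` with `x₄ = m_f(r_f−α−η−c_f)/r_f`, existing
iff `H3: r_f > α + η + c_f`. Whenever a tier receives a constant
transfer inflow `I` at equilibrium, its coordinate is the unique
non-negative root of the scalar quadratic
`-(r/m) v² + (r − loss) v + I = 0`, evaluated by the explicit
quadratic formula (`positive_root_z`); this is numerically exact
(residuals at machine precision) and avoids fragile nested radical
transcriptions. Existence conditions are strict inequalities; an
exact equality is reported as non-existence with a `marginal` flag,
because at the boundary the candidate coordinate merges with a lower
equilibrium.

The Jacobian is lower triangular (diagonal `-2rv/m + r − loss` per
tier, sub-diagonal `α`, `η`, `β`), so all eigenvalues are real and
equal to the diagonal entries. Classification is by eigenvalue sign:
all negative → locally asymptotically stable, any positive →
unstable, any `|λ| ≤ 10⁻¹⁰·max(r)` → marginal (no claim; the
stability theory is silent on boundary cases). The conditions
`H4`–`H7` — which of the four sign patterns obtains — partition
parameter space off the boundary hypersurfaces, so exactly one
equilibrium is stable for generic parameters. The analytic
eigenvalues are cross-checked in the tests against a general numeric
eigensolver and against finite-difference Jacobians, and the
classifications against simulated attraction/escape of perturbed
trajectories.

## Numerics

- **Integration**: `scipy.integrate.solve_ivp` with RK45, `rtol
  1e-8`, `atol 1e-10`. The right side is a smooth quadratic at
  monthly-scale rates; stiffness does not arise. States are clipped
  at zero only to absorb solver-tolerance undershoot (the exact flow
  preserves the non-negative octant: on each zero face the outflow
  terms vanish).
- **Analytic oracle**: the autonomous FLH equation is scalar logistic
  with effective rate `ρ = r_f−α−η−c_f` and carrying value
  `K = m_f ρ/r_f`; its closed form (`closed_form_x`, including the
  separable `ρ = 0` degenerate case) is used as an independent
  correctness oracle for the integrator, agreeing to better than
  `1e-6` relative.
- **Steady-state detection**: integrate in 200-month chunks until
  `max|dv/dt| / max(m) < tol` (default `1e-8`) or `t_max` is reached;
  non-convergence is a returned flag, not an error. The achievable
  floor of this criterion is set by the solver tolerance; tests that
  need a tighter floor pass tighter `rtol`/`atol` through.
- **Sweeps**: one re-integration per parameter value, everything else
  held fixed, identical time grid and initial state. Because the
  error controller acts on the full state vector, trajectories of a
  component that is mathematically independent of the swept parameter
  (e.g. `x` under a `β` sweep) agree across values to solver
  tolerance rather than bit-exactly; the structural statements are
  asserted at `1e-6` relative.
- **Serialisation**: floats are written with 17 significant digits
  and read back with round-trip parsing, so write-then-read of every
  artifact is bit-exact.

## Fitting

`fit` minimises the pooled sum of squared residuals over all tiers
and observation months with `scipy.optimize.least_squares`
(trust-region reflective, positivity bounds, variables scaled by the
initial guess). The trajectory's initial state is fixed to the first
observation triple rather than estimated, which removes three
parameters the data constrain only weakly. The reported R² is pooled
— `1 − SSE/SST` with SST about the grand mean of all tier-month
observations — matching the single pooled objective; per-tier R²
values are reported for diagnostics. Residuals are unweighted by
default (an optional inverse-variance per-tier weighting exists),
reflecting that the reference analysis pooled raw residuals despite
the roughly ten-fold scale differences between tiers. A seeded
multi-start (default 8 starts, log-normal jitter of the guess,
sd 0.15) mitigates local minima; the best final objective wins, and
the fit is deterministic given data, guess and seed. Progress is
monitored as "final SSE ≤ SSE at the guess" for every start; scipy
exposes no per-iteration trace, so monotonicity inside an iteration
is not asserted.

### Identifiability

The solution of the system depends on the twelve parameters only
through nine combinations: per tier the crowding coefficient `r/m`
and the net linear rate (`r_f−α−η−c_f`, `r_s−β−c_s`, `r_t−c_t`), plus
the transfer rates `α`, `β`, `η`, which enter through the cross-tier
coupling. The within-tier family `r → r+s`, `c → c+s`,
`m → m(1+s/r)` leaves the trajectory *exactly* unchanged, so the
individual growth/churn/capacity values are structurally
non-identifiable from visit series — any fit that reproduces the data
perfectly can still disagree arbitrarily with the generating `r`, `c`
and `m`. `identifiable_combinations` exposes what the data determine,
and the tests assert recovery at that level: on noiseless synthetic
data a fit started 20% off recovers all nine combinations essentially
to machine precision while driving SSE to ~1e-22.

With observation noise the picture degrades further in a practical
sense: at 2% relative noise over an 8-year window, alternative
transfer structures (e.g. suppressing `α` and `β` while inflating
`η`) can attain an SSE as low as the truth-region optimum while the
fitted trajectory stays within a fraction of a percent of the
noiseless truth. Fitted parameter values from windows of this length
should therefore be read as a description of the trajectory, not as
sharp estimates of the individual rates — which is also why a
published parameter vector for this model class is not an exact
reproduction target.

## Synthetic data generator

The generator emulates the structure of China's national monthly
reporting: the system is integrated continuously over `years × 12`
months and sampled at months 1–11 of each year (December is simulated
but never reported, matching the source statistics). Observations are
multiplied by an optional seasonal factor
`1 + A·sin(2π·month/12)` (phase fixed at zero — it exists to test
estimator robustness, not to model actual seasonality) and by
multiplicative Gaussian noise `1 + N(0, σ²)`, then truncated at zero.
Noise is relative because the tiers differ in scale by an order of
magnitude. Defaults: the reference parameter vector as generating
truth; initial state `(1500, 8000, 12000)` — monthly volumes at the
rough scale of the early-2010s system, below the attractor so the
series exhibits growth; 8 years; `σ = 0.02`; no seasonality.

What passing tests on generated data do and do not show: the
generator shares the estimator's trajectory model, so recovery
results certify the estimation machinery (objective, bounds,
determinism, identifiable structure), not robustness to real-data
features — genuine seasonality with drifting phase, reporting
revisions, policy breaks and demographic trends are all absent. The
seasonal option probes only the simplest such misspecification.

## Problem sizes

Test-suite and acceptance-script experiments use sizes at which every
check runs in seconds to a few minutes on one CPU: 20–100 random
parameter sets for oracle/equilibrium/classification checks,
600-month sweeps on a 121-point grid, single-start fits from a
1.2× guess for recovery experiments (the multi-start default stays 8
for general use), 20 noise seeds in the test suite and 5 in the
acceptance script's Monte-Carlo summary.

## Known limitations

- No global stability or basin-of-attraction analysis; all stability
  claims are local (linearisation), verified by small-perturbation
  simulation only.
- No stochastic (SDE) variant and no seasonal forcing inside the
  dynamics; seasonality exists only as an observation-layer option.
- The fitting surface is non-convex; multi-start mitigates but does
  not guarantee a global optimum.
- Individual `r`, `c`, `m` per tier are not identifiable from visit
  series (see above); downstream quantities that depend only on the
  identifiable combinations (trajectories, equilibria of the fitted
  system) are unaffected, but capacity estimates `m` in particular
  inherit the degeneracy.
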