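# Methods

## Model family

Eight variants along three axes: two vs three components, Malthusian
(`a = 0`) vs logistic (`a > 0`) host growth, constant vs virus-dependent
immunity. The canonical three-component equations are

    dx/dt = x (1 − l − a(x+y)) − b x z (1−p) + e s y z
    dy/dt = y + l x − a y (x+y) − b y z (1−s) − e s y z
    dz/dt = z (−d + b M (x(1−p) + y(1−s)) − b (x p + y s))

with `p = p_const` or `p(z) = (1−s)e^(−kz) + s`. Host growth rates are
fixed at 1 and are not exposed as parameters. With `p_const = s` the host
equations sum to the two-component system in `(u, z) = (x+y, z)` exactly;
this reduction is a standing consistency test. Parameters (all per unit
time except the dimensionless `M`, `s`, `p_const`):

| name | meaning | constraint | typical |
|---|---|---|---|
| `l` | immunity decay (immune → sensitive) | ≥ 0 | 0.1–0.9 |
| `e` | immunity acquisition on survived encounter | ≥ 0 | 0.1–0.5 |
| `d` | virus death rate | > 0 | 1 (default where a scenario's source leaves it unprinted) |
| `M` | burst factor | > 0 | 10–1000 |
| `b` | encounter rate coefficient | > 0 | 0.01–0.1 |
| `a` | host density dependence | ≥ 0 | 0 or 1 (logistic analyses use `a = 1`) |
| `k` | immunity steepness in `z` | > 0 | 0.1–1 |
| `s` | innate immunity of sensitive hosts | 0 < s < 1 | 0.1–0.2 |

## Equilibria

Interior equilibria come from a scalar reduction derived from the
equilibrium conditions rather than from any printed closed form (several
of the source's displayed reductions are typographically corrupted, and
deriving from the system itself is safer): summing the host equations and
substituting the virus balance gives, at fixed `z`, the host-total
quadratic `a u² − u(1+M−bz)/(M+1) + dz/(M+1) = 0`; the virus balance then
fixes `p x + s y`, which with `x + y = u` determines the split linearly
(a dedicated branch handles `p = s`, where the split comes from the
sensitive-host balance instead). The one remaining condition is a scalar
function of `z`, scanned for sign changes and refined by Brent's method.

Numerical care: the radicand of the `u` quadratic is itself quadratic in
`z`, so the exact `z`-intervals on which each branch exists are computed
up front and each interval is gridded to its endpoints (2000 linear plus
1000 log-spaced points by default; the log grid protects small-`z` roots
when the search box `0 < z < (1+M)/b` is large). Without this, roots
squeezed against a branch fold get stepped over. Every candidate is
re-polished by multivariate root finding on the full system (residual
tolerance 1e-10), positivity-filtered, and de-duplicated at 1e-6 in `z`.
An independent multistart search (200 random starts per draw) serves as
the completeness oracle in the tests.

## Stability

Classification is by eigenvalues of the analytic Jacobian, with a
hyperbolicity tolerance of 1e-8 on real parts; sorted output (descending
real, then imaginary part) keeps reports deterministic. Closed forms at
the trivial equilibria (`{1, −d, 1−l}` at the origin; `{−l, −1,
(b(M(1−s)−s) − da)/a}` at the virus-free state) are retained as checks.

Near-degenerate equilibria need more than double precision: in the
Malthusian three-component model the equilibrium virus load satisfies
`b z_e (1−s) ≈ 1`, so `k z_e` is large and the destabilizing real part of
the complex pair — of order `(1−s)e^(−k z_e)` — is ~1e-23 at reference
parameters, far below what LAPACK can resolve. `eigenvalues_highprec`
re-polishes the fixed point and solves the eigenproblem in 50-digit
mpmath arithmetic; `malthusian_interior_instability` escalates to it
automatically whenever the double-precision label is center/nonhyperbolic.
The same scale appears in the two-component Malthusian trace, which is
asserted through its closed form `b(1+M) x z k (1−s) e^(−kz)`.

## Bifurcations

* **Transcritical**: closed form `M^tc = (ad+bs)/(b(1−s))`, cross-checked
  by bisection on the numeric leading eigenvalue of the virus-free state.
* **Hopf**: bisection (60 iterations, early exit at |Re| < 1e-12) on the
  real part of the leading complex pair along the continued equilibrium
  branch; continuation is naive re-solving with the previous solution as
  the start, which suffices for these one-branch problems. Transversality
  is estimated by centered differences. Two-parameter curves repeat the
  bracket-and-bisect per grid point.
* **Saddle-node** (two-component logistic, `p(z)`): the 0 → 2 jump in the
  interior-equilibrium count is bracketed in `M`, then the extended system
  {equilibrium, det J = 0} is Newton-polished; at the reference parameter
  set (`a=1, b=0.1, d=1, k=1, s=0.15`) the fold sits at M* ≈ 16.17.
* **Bogdanov–Takens**: damped-Newton solve of {equilibrium, det J = 0,
  trace J = 0} in `(x, z, M, k)` from a coarse grid of starts; at the same
  reference set the double-zero point is (M̄, k̄) ≈ (31.81, 0.1234) with
  condition residuals ~1e-16.
* **Unstable limit cycle**: backward-time integration from just outside
  the stable spiral B2; a bounded reversed orbit that settles to steady
  oscillation with amplitude well above the perturbation witnesses the
  cycle.
* **Hopf criticality** is assessed numerically (amplitude-scaling test)
  instead of via symbolic normal-form coefficients: integrate at a ladder
  of offsets above threshold and fit log(amplitude) against log(offset).
  A supercritical Hopf gives slope ≈ 1/2. At the reference logistic family
  the measured slope is ≈ 0 with amplitude ~22 even at offsets of 0.02 in
  `M`, and the same large cycle persists as a coexisting attractor well
  below threshold: the transition there is subcritical/fold-mediated, and
  the package reports it as such. The figure scenarios just above the
  printed family's threshold therefore start in the coexisting cycle's
  basin rather than at the (still locally stable) equilibrium.

## Integration

`solve_ivp`/LSODA with rtol 1e-9, atol 1e-12 and uniform output sampling
(default 0.1 time units). The vector field is evaluated without domain
checks inside the integrator (it extends smoothly past the orthant
faces); the public `rhs` validates. Extinction (coordinate < 1e-12) is
recorded as an event; exceeding 1e12 truncates the trajectory with an
`unbounded` event. The conservation monitor `hamiltonian_drift` uses
DOP853 instead: the conservative flow is smooth and non-stiff, and at
equal tolerances the 8th-order scheme holds the invariant below 7e-7 over
t = 1e4 where LSODA drifts ~4e-6. Quasi-chaotic trajectories are
shadowing-level accurate only: statistics are reproducible, pointwise
values far along an orbit are not, and regime labels are checked to be
robust to 10× tighter tolerances rather than pointwise agreement.

## Regime classification

After discarding a transient (default first half of the run):
unbounded → extinction → stable equilibrium (terminal window within 1e-4
of a computed equilibrium) → limit cycle → quasi-chaotic → undetermined.

Periodicity uses two statistics on the virus coordinate. Peak-height CV
(threshold 0.01) is the coarse test, but parabolically refined peak
heights carry O(dt²) interpolation error near the sharp virus maxima —
measured to dominate the genuine modulation of a thin torus at dt = 0.1.
The decisive statistic is therefore the spread of a Poincaré-like
section (immune-host coordinate at upward crossings of the mid-range
virus level): crossings are transversal, so the interpolation error is
negligible, and a closed orbit collapses the section to relative std
~1e-4 while a surface-filling attractor keeps it above 1e-2. The
threshold between them is 1e-3. These defaults were calibrated on the
reference scenarios (an order of magnitude of margin on each side) and
are exposed in `RegimeOptions`.

"Quasi-chaotic" covers bounded, aperiodic, non-contracting attractors:
both weak chaos (positive largest Lyapunov exponent) and quasi-periodic
torus flow (exponent ≈ 0). The model family realizes the whole range —
at the reference logistic family the `M = 500` attractor is a thin torus
(section spread 1.2e-2, stationary over 1e5 time units, exponent
+2e-4 ± 0.5e-4), with clearly positive exponents at larger `M`. A
clearly negative exponent on an aperiodic window signals an unfinished
transient and yields `undetermined`.

The Lyapunov exponent is the tangent-linear Benettin estimate: the
perturbation evolves under the Jacobian along the orbit and is
renormalized every τ (default 1 time unit; heavy runs use 10 — the
tangent flow is linear in the perturbation, so rescaling is exact and
the interval only guards against overflow). Finite-offset two-trajectory
estimates are unreliable for this family: population densities crash far
below any practical offset, pushing the perturbed pair into the
nonlinear regime and inflating the estimate.

## Scenarios

The registry bundles the reference parameter sets (figures 1–6,
supplementary panels, a conservative demo). Where the source leaves `d`
unprinted it defaults to 1, the value that reproduces the printed
coexistence equilibrium to all printed digits. The two scenarios just
above the reference family's oscillatory transition start at
(0.4, 0.05, 35), inside the basin of the coexisting large limit cycle
(see Bifurcations above); all other three-component scenarios start at
the printed initial condition or at the interior equilibrium with a 1%
relative offset. Scenario configs serialize to flat JSON and round-trip
losslessly; CLI outputs print numbers at 12 significant digits so reruns
are byte-identical on one platform.

## Problem sizes

Default horizons were chosen as the shortest that make the reference
classifications unambiguous: t = 2e4 for equilibrium/cycle scenarios
(the near-threshold pair contracts at only ~1e-3 per unit time), t = 3e4
to 4e4 for the torus scenario (its amplitude modulation develops over
~2e4 time units), Lyapunov windows of 1e4–2e4 with the second half
averaged. The multistart completeness oracle uses 200 starts per draw
and 50 draws per model variant.

## Known limitations

* The scalar reduction's completeness is guaranteed only on the scan box
  `0 < z < (1+M)/b` and at the default grid resolution; pathological
  parameter corners (e.g. near-tangent crossings) could in principle
  still slip through, which is why the multistart oracle runs in CI.
* Regime labels near classifier thresholds (e.g. a torus with modulation
  near the section threshold) are sensitive to the calibrated constants;
  the evidence dictionary always carries the raw statistics.
* No global bifurcation analysis (homoclinics near the Bogdanov–Takens
  point) and no rigorous chaos proofs — "quasi-chaotic" is an
  operational, not a mathematical, label.
* Two-parameter Hopf curves use naive continuation; folds of the Hopf
  curve itself would need pseudo-arclength continuation.
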