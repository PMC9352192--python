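# Methods

## Model

`stemflux` implements a minimal population model of non-genetic drug
resistance. A tumor is a mixture of drug-sensitive cells `x1` and
drug-resistant (stem-like) cells `x2` that divide, die, and interconvert at
constant per-capita rates:

```
dx/dt = A x,    A = [ b_S - d_S - k_SR      k_RS            ]
                    [ k_SR                  b_R - d_R - k_RS ]
```

`b` are division rates, `d` total death rates under treatment, `k_SR` the
rate at which treatment stress pushes sensitive cells into the resistant
state, and `k_RS` the backflow (resensitization) rate. All six rates are
strictly positive, in units of 1/time with the time unit left arbitrary:
none of the qualitative results depend on it, and the default rates
(0.01–0.35 per unit) are in the range where one unit is loosely a day.

Because the off-diagonal entries `k_RS`, `k_SR` are positive, the
discriminant `(a11 - a22)^2 + 4 k_SR k_RS` is strictly positive: both
eigenvalues are always real and distinct, the dominant eigenvector can be
taken strictly positive, and the flow preserves the non-negative quadrant.
The solution is the explicit two-mode expansion

```
x(t) = c1 e^{lambda1 t} v1 + c2 e^{lambda2 t} v2 ,
```

which the package evaluates directly rather than integrating numerically.

### Stability of the extinction state

The only fixed point is `x = 0`. Its character decides the clinical
storyline:

| trace/determinant of A       | eigenvalues          | label         | meaning                    |
|------------------------------|----------------------|---------------|----------------------------|
| det > 0, tr > 0              | 0 < λ2 < λ1          | UNSTABLE_NODE | unchecked growth           |
| det > 0, tr < 0              | λ2 < λ1 < 0          | STABLE_NODE   | extinction                 |
| det < 0                      | λ2 < 0 < λ1          | SADDLE        | regression, then regrowth  |
| det = 0 (numerically)        | one λ ≈ 0            | DEGENERATE    | boundary case, flagged     |

(det > 0 forces tr ≠ 0 away from the degenerate boundary, so the table is
exhaustive; it is derived from the trace/determinant sign rules rather than
copied from any external enumeration.) The saddle is the interesting
regime: the tumor shrinks along the stable manifold before the growing
mode takes over — relapse as an intrinsic property of the dynamics.

An equivalent "fitness-ratio" form of the saddle criterion,
`g_S/g_R > (g_S - k_SR)/k_RS` with `g_S = b_S - d_S`, `g_R = b_R - d_R`,
follows from expanding `det A = g_S g_R - g_S k_RS - g_R k_SR` and dividing
by `g_R k_RS`. The division is sign-safe only for `g_R > 0`, so
`saddle_ratio_condition` returns `None` outside that domain rather than a
misleading boolean.

**Degeneracy tolerance.** An eigenvalue within
`1e-12 x max(|λ1|, |λ2|, 1)` of zero is labelled DEGENERATE and excluded
from further analysis; the boundary case is flagged, not studied.

**Eigenvector convention.** Unit Euclidean norm, first nonzero component
positive. Every physically meaningful quantity downstream (the mode
amplitudes `alpha_i = c_i (v_i_1 + v_i_2)` of the total population) is
invariant to this choice, which the tests assert explicitly. For any
non-negative initial state the dominant amplitude `alpha1` is positive
automatically (Perron-type argument: `v1` lies strictly inside the positive
quadrant, `v2` does not).

## Time to progression

TTP is `t_P = inf{ t > 0 : N(t) > N(0) }` with `N = x1 + x2`. Writing
`N(t) = alpha1 e^{lambda1 t} + alpha2 e^{lambda2 t}`:

* if `N'(0) > 0` the infimum is 0 (the tumor never dips below its
  pretreatment size) — reported as `t_P = 0` so dose curves are total;
* if `lambda1 <= 0` the population can never re-attain `N(0)`; the result
  is censored at the horizon and flagged (no infinity sentinels in output
  files);
* otherwise the crossing exists and, in the saddle regime, is unique: `N`
  is strictly decreasing before the turning point and strictly increasing
  after it.

The turning point `t_min` (argmin of `N`) is available in closed form from
`N'(t) = 0`:
`t_min = ln(-alpha2 lambda2 / (alpha1 lambda1)) / (lambda1 - lambda2)`,
clamped to `[0, horizon]` with the boundary cases handled explicitly.

**Root refinement.** The crossing is bracketed by doubling steps from
`t_min` and refined with Brent's method to relative tolerance 1e-9. All
evaluations use the log-population excess
`h(t) = ln alpha1 + lambda1 t + log1p(rho(t)) - ln N(0)` with
`rho = (alpha2/alpha1) e^{(lambda2-lambda1) t}`, which cannot overflow even
when the horizon lies far beyond the crossing.

**Batch kernel.** `ttp_exact_batch` computes the identical quantity for
whole arrays at once (closed-form eigenvalues, vectorized doubling bracket,
90 bisection iterations, i.e. < 1e-12 relative): this is what makes a
100 x 1000-patient cohort at 11 doses run in seconds. The tests pin the
kernel against the scalar path to 1e-8 on random draws spanning all three
stability regimes.

**Asymptotic approximation.** When regrowth is driven by the dominant
mode, `t_P* = (1/lambda1) ln[N(0)/alpha1]`. It is reported only for saddle
dynamics with an initial remission phase; requesting it with
`lambda1 <= 0` or `alpha1 <= 0` raises. Its error is governed by the
decaying-mode contribution `|alpha2| e^{lambda2 t_P}` — below `1e-3 N(0)`
the relative error is under 1 % on the default fixtures, and the tests
assert the error tracks that contribution. Note that scaling the initial
state with its direction fixed changes neither `t_P` nor `t_P*` (the
dynamics are linear, so `N(t)` and the threshold `N(0)` rescale together);
the approximation improves with longer regrowth phases, i.e. across doses,
not across tumor sizes.

## Pharmacodynamics

Treatment enters through three logistic dose-response curves
(`rate(m) = delta + E / (1 + e^{-r (m - P)})`, dose `m` in % of the
maximum tolerated dose): the kill curves `d_S(m)`, `d_R(m)` and the
stemness-induction curve `k_SR(m)`. Division rates and the backflow rate
do not respond to dose. `E` is efficacy (maximal increment), `P` the EC50
(inverse potency), `r` the saturation rate. Structural assumptions
enforced at construction: `b_S > b_R` (fitness cost of resistance),
`delta_S = delta_R` (equal basal death), `E_R < E_S` (the resistant state
is protected against killing) with a warning — not an error — when
`E_R >= 0.5 E_S`, since "much less than" has no canonical threshold.

### Default parameter set

The shared baseline (in `stemflux.fixtures.BASELINE`, version-stamped,
config-overridable) was chosen once, before any downstream analysis, to
satisfy the model's structural constraints and land the four canonical
regimes; it is a documented default, not a reproduction of any published
table:

| parameter | value | rationale |
|-----------|-------|-----------|
| `b_S` / `b_R` | 0.2 / 0.1 | ~2x division-rate cost of the stem-like state |
| `delta_S = delta_R` | 0.05 | basal death well below division: untreated tumor grows |
| `kappa` | 0.01 | rare spontaneous stemness induction |
| `k_RS` | 0.01 | slow resensitization backflow |
| `E_S` / `E_R` | 0.3 / 0.03 | full dose overwhelms sensitive growth (`g_S(100) = -0.15`) but leaves resistant cells viable (`g_R(100) = +0.02`) |
| `P_S = P_R` | 20 | kill EC50 well below the low-potency induction EC50 (50) |
| `r_S = r_R = r_SR` | 0.3 | transition width ~13 dose points: distinctly sigmoid on [0, 100] |
| `N0` | 1e9 | a clinically detectable ~1 cm^3 tumor |
| resistant fraction | 0.01 | small pre-existing resistant pool at detection |

The four canonical cases vary only the induction curve: efficacy
`E_SR ∈ {0.2, 0.02}` (high/low) and EC50 `P_SR ∈ {50, 10}` (low/high
potency). With the baseline above they produce the four regimes that the
acceptance suite gates on: interior TTP optima for A and C (argmax at
34 % and 38 % of MTD, max TTP 224 and 241 time units), monotone
dose-response for B and D (optimum at MTD), and MTD outcomes ordered by
induction efficacy (152 vs 36 units).

**Horizon.** The default TTP search horizon is 2500 time units, ~10x the
longest canonical-case TTP; beyond it results are censored and flagged.

## Virtual cohorts

Patients vary in the basal rates (`b_S`, `b_R`, `delta`, `kappa`, `k_RS`)
and in the resistant fraction at detection; each is an independent uniform
draw. Defaults: ±20 % around the baseline rates and resistant fraction
uniform on [0.001, 0.05] — wide enough that cohorts are heterogeneous,
narrow enough that most patients keep the saddle regime at intermediate
doses (otherwise KM curves collapse to steps at 0). Tumor size at
detection and all drug constants are fixed across patients. Draws
violating `b_S > b_R` are rejected and redrawn, capped at 100 attempts.

Per patient and dose the exact TTP is computed with the batch kernel; a
cohort's Kaplan-Meier curve is the plain counting estimator
`fraction(t) = #{t_P > t}/n_p` (there is no within-cohort censoring other
than the horizon, and horizon-censored patients count as progression-free
through it, so the Greenwood variance adds nothing); variability is
reported as the across-cohort standard deviation instead. The reference
ensemble is 100 cohorts x 1000 patients at 11 doses (~7 s on one core).

RNG streams: patient `p` of cohort `c` draws from
`SeedSequence(seed, spawn_key=(c, p))`, so growing `n_p` or `n_c` never
reshuffles existing patients, and the entire pipeline is a pure function
of (config, seed).

## What the defaults do and do not show

Passing tests demonstrate that the implementation reproduces the model's
qualitative taxonomy — regimes, optima, orderings — under the documented
default parameter set, and that all numerics (closed form vs. integration,
root finding, batch vs. scalar) agree to stated tolerances. They do not
calibrate the model to any real tumor: absolute TTP values are in
arbitrary time units, the uniform patient distributions are a convenience
prior, and dose is constant over time (no scheduling, no pharmacokinetics,
no selection/competition nonlinearity, no more than two states).

## Numerical choices, in one place

* eigenvalues by the closed 2x2 formula; eigenvector from whichever of the
  two analytic forms `(a12, λ - a11)`, `(λ - a22, a21)` has the larger
  norm (conditioning);
* degenerate-eigenvalue tolerance `1e-12` relative (above);
* crossing refinement: doubling bracket + Brent, rel. tol. 1e-9; batch
  path: 90 bisections;
* argmax over a discrete dose grid breaks ties toward the lowest dose
  (clinically conservative) and treats horizon-censored TTP as equal to
  the horizon;
* CSV output uses 12 significant digits so byte-identical reruns are a
  testable contract;
* strict positivity of rates is enforced at the public API;
  `RateConstants.unchecked` exists for analytic limiting cases (decoupled
  populations) used in tests.
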