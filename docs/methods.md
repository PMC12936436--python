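# Methods

## Model

Mortality follows the Gompertz–Makeham hazard

    mu(x) = G e^{R x} + M

with ages in years. `G` (per year) is the potential mortality risk from
internal damage at age 0, `R` (per year) the senescence rate — the
exponential rate at which that internal risk grows as damage
accumulates — and `M` (per year) the age-independent external risk.
`R = 0` is negligible senescence: a constant hazard `G + M`. The three
parameters are treated as independently evolvable. Survival from birth
is the closed form

    l(x) = exp(-(G/R)(e^{Rx} - 1) - M x),

with the analytic limit `exp(-(G+M)x)` used whenever `R < 1e-10` to
avoid cancellation in `(G/R)(e^{Rx}-1)`.

Reproduction starts at the maturity age `xs` and by default proceeds at
a constant rate `zeta` (offspring per individual per year); an arbitrary
integrable rate function of age is also accepted. Juvenile mortality is
assumed independent of senescence and finished before `xs`; it never
enters the hazard, only the effective reproduction rate (below).

Two fitness estimators:

* **LRS** `= int_{xs} l(x) m(x) dx`, for populations held at a stable
  size by density dependence of reproduction;
* **Euler–Lotka r**, the unique real root of
  `1 = int_{xs} e^{-rx} l(x) m(x) dx`, for growing/declining
  populations and external-mortality regulation.

Density-dependence regimes: `dd_reproduction` rescales the reproduction
schedule by 1/LRS (regulated LRS = 1); `dd_external` adds the
unregulated growth rate to `M` (regulated r = 0; defined only for
r > 0); `growing`/`declining` multiply the `dd_reproduction`-normalized
schedule by theta (defaults 10 and 0.1).

## Numerical conventions

* **Truncation.** Every improper age integral runs to the age `x_d` at
  which survivorship reaches 1e-4 (also the "certain-mortality age" and
  the viability threshold for parameter-scan masks). `x_d` is found by
  Brent root search on the cumulative hazard inside the guaranteed
  bracket `[0, -ln(1e-4)/(G+M)]`.
* **Quadrature.** `scipy.integrate.quad` with absolute and relative
  tolerance 1e-10.
* **Euler–Lotka root.** The discounted-LRS deficit is strictly
  decreasing in r; the bracket starts at [-1, 1] per year and doubles
  (up to 60 times) until it straddles the root, then Brent refinement to
  ~1e-13. Overflowing evaluations (possible far below the root for very
  long-lived parameterizations) are clamped to a large positive value,
  which preserves the bracketing sign.
* **dd_external refinement.** `M -> M + r` compensates exactly only on
  an unbounded age domain; because the truncation window moves with `M`,
  a residual growth rate of order 1e-7 remains. Since dr/dM = -1, a few
  fixed-point corrections (`M += r_residual`) drive the regulated r
  below 1e-12.

## Selection gradients

Differentiating `l(x)` in `R` gives `dl/dR = l(x) G k(x)` with the
kernel

    k(x) = (e^{Rx}(1 - Rx) - 1) / R^2  <=  0,

so `dLRS/dR = G int_{xs} k l m dx` and, via implicit differentiation of
the Euler–Lotka equation, `dr/dR = G int k e^{-rx} l m dx / T` with `T`
the generation-time integral `int x e^{-rx} l m dx`. The kernel is
evaluated by a Taylor branch (`-x^2/2 - Rx^3/3 - R^2x^4/8`) for
`|Rx| < 1e-4`; its `R -> 0` limit `-x^2/2` gives the
negligible-senescence gradients, which for constant `zeta` under LRS
have the closed form `-(G zeta/2) e^{-c xs}(xs^2/c + 2xs/c^2 + 2/c^3)`,
`c = G + M`. The generation-time denominator is written from `xs`; this
is identical to integrating from 0 because the reproduction schedule
vanishes below `xs`.

Gradients in `G`, `M`, `xs`, `zeta` use central finite differences with
step `h = max(1e-6, 1e-4 |p|)` and one Richardson level. Two onset-age
(classic) gradients are provided: the permanent-increment form with
numerator weight `(x - a)` and the instantaneous form with weight 1;
only the latter is exactly constant for onset ages below maturity.

**Moving-boundary caveat.** Differentiating the *truncated* estimators
numerically picks up a boundary term of relative size ~1e-4 (the
truncation survivorship times d`x_d`/d-parameter). All finite-difference
cross-checks against the closed forms therefore pin the integration
window at the base point (`x_trunc=...`/`fix_truncation=True`); the
closed forms themselves are derivatives of the underlying model, not of
the truncation artifact.

**The G -> 0 limit.** On a fixed age window the senescence gradient is
`G` times a bounded integral, hence linear in `G` and vanishing as
`G -> 0`. On the adaptive window this is true only when `M > R`: for
`M < R` the truncation age grows like `ln(1/G)/R` and the gradient
magnitude *grows* logarithmically instead. The package therefore states
and tests the limit on a fixed window (the base parameterization's
`x_d`), where two-point linear extrapolation in `G` recovers zero to
~1e-13.

## Evolutionary feedback

Under reproduction-limited density dependence every point of parameter
space represents a population regulated to LRS = 1, so the selection
gradient field over a parameter map is that of the normalized schedule —
for constant fecundity `S'(R)/S(R)` with `S = int_{xs} l dx`,
equivalently `d ln LRS / dR`. Feedback is the derivative of this field:

* `second_derivative_R` = d/dR of the equilibrated gradient (the
  curvature of log fitness), central step 1e-4, one-sided at `R = 0`;
* `mixed_derivative` = d/d{G,M,xs,zeta} of the same field (symmetric in
  the differentiation order by continuity).

All stencil points are evaluated on the base point's integration window
(see the moving-boundary caveat). The raw fixed-`zeta` curvature is
available via `equilibrate=False`; it differs qualitatively — raw LRS(R)
is convex near the viability boundary, whereas the equilibrated feedback
is negative there, which is the behavior the sign analysis describes.
Positive feedback means that slowing senescence strengthens selection
for further slowing (the route to negligible senescence); a negative
R–G mixed derivative in the `M > G` regime is the model's mechanism for
a Strehler–Mildvan-like negative association between `G` and `R`.

Parameter-scan maps mask cells where survivorship at `xs` is below 1e-4
(fitness treated as zero; NaN in exported matrices). Plotted values use
the log-modulus transform `sign(v) log10(1 + |v|)`.

Two advisory rules of thumb accompany the computed derivatives: positive
feedback near `R = 0` roughly when `G > (M/2) e^{-0.12 xs}` (an
alternative grouping `M^2 e^{-0.12 xs}` is selectable), and positive
feedback at substantial `R` while `xs < 0.5 x_d` ("maturity far from
certain death"; `xs > 0.9 x_d` is flagged as the always-negative
regime). Against the computed curvature at `R = 0.001` over a log-uniform
sample of (G, M, xs) the first rule agrees in ~90% of draws; they are
heuristics, never substitutes for the derivatives.

## Trade-off and ESS

A single allocation `z in [0, 1]` couples senescence and reproduction:

    R(z)    = (Rmax - Rmin) z^alpha + Rmin,
    zeta(z) = (zeta_max - zeta_min)(1 - (1 - z)^beta) + zeta_min,

`alpha, beta >= 1`. `Rmax` is pinned by requiring maturity to precede
certain death: the `R` at which survivorship at `xs` equals 1e-4.
Defaults mirror the species calibrations: `beta = 1`, `Rmin = 1e-4`,
`zeta_min = 0`.

The ESS allocation satisfies `dLRS/dz = 0` with negative curvature. The
gradient is assembled by the chain rule from the closed-form senescence
gradient and the linearity of LRS in `zeta`
(`dLRS/dz = zeta(z) S'(R) R'(z) + S(R) zeta'(z)`); it is sign-scanned on
an even z grid (201 points by default), refined by Brent to 1e-8, and
curvature read from a central difference with step 1e-4. With
`zeta_min = 0` the whole gradient scales linearly in `zeta_max`, so the
ESS is invariant to the reproduction ceiling; `fit_alpha` exploits this
by fitting with a placeholder `zeta_max = 1` and `infer_zeta_max`
rescaling afterwards. Fitting is brute force per the original procedure:
alpha grid [1, 3] at step 0.01, refined to step 0.001 around the best
coarse point, minimizing |ESS R - observed R| (the z scan inside the fit
uses 41 points; the refinement is by Brent, so scan density only affects
bracket detection). `infer_zeta_max` inverts `R(z)` at the observed
senescence rate and scales the reproduction branch through the observed
rate.

A useful identity (used as an independent test oracle, not as the
implementation): with `beta = 1`, `zeta_min = 0`, an interior stationary
point at the observed `R` forces
`alpha = -S(R) / ((R - Rmin) S'(R))`, independent of `Rmax` and
`zeta_max`.

**Truncation sensitivity of fitted alpha.** For long-lived, slowly
senescing parameterizations the fitted alpha is sensitive to the upper
integration age because `S` and `S'` keep accumulating mass far beyond
age 100. For the killer-whale parameterization (`x_d = 128` y at the
observed `R`), the survivorship-1e-4 rule gives alpha = 1.166, whereas
capping the age window near ~107 y would give ~1.25; the other three
bundled species have `x_d` at or below ~104 y and are insensitive to any
such cap. This package applies the survivorship rule uniformly. The
corresponding whale quantities downstream (ESS rate under alpha = 1.25,
implied zeta_max) inherit the sensitivity; the human, baboon and lion
calibrations do not.

## Calibration from life tables

`GompertzMakehamModel` fits (G, R, M) to survivorship at ages >= `xs`,
renormalized to 1 at the first tabulated age at or above `xs`, against
the conditional model curve `exp(-(H(x) - H(x0)))` — a least-squares fit
on the survival scale. Bounded (`>= 0`) `scipy.optimize.least_squares`
runs from the 27-point multi-start grid G in {1e-4, 1e-3, 1e-2}, R in
{0.01, 0.1, 0.5}, M in {1e-5, 1e-2, 0.1}; the lowest-SSE solution wins.
A constant-survivorship table is non-identifiable in (G, R); it warns
and returns an external-mortality-only fit. Fitting mortality rates
(log-hazard loss) instead of survivorship would weight old ages more
heavily; the survival-scale loss is the one used here.

The effective reproduction rate folds juvenile mortality into fecundity:

    zeta = (1 - l(xs) + l*(xs)) * mean(mx at ages >= xs),

where `l` excludes and `l*` includes juvenile deaths; with no separate
juvenile schedule this is just the mean observed fecundity. The
formula's grouping is ambiguous in its source; the adopted additive
reading equals the plain mean when `l* = l` and shrinks `zeta` by the
extra juvenile-death fraction, while the multiplicative alternative
`(l*/l) mean(mx)` is available via `reading="ratio"`.

## Synthetic life tables

`simulate_life_table` emulates an annual (configurable step) life table
from known truth, on an age grid reaching `x_d`:

* deterministic mode — survivorship is the closed form, fecundity the
  constant rate above `xs`; round-tripping through the fit recovers
  (G, R, M) to relative error below 1e-4 for all four bundled species;
* stochastic mode — a birth cohort of `n` individuals with binomial
  interval deaths at the exact conditional probability
  `1 - l(x+d)/l(x)` and Poisson-observed fecundity among survivors;
* an optional constant juvenile hazard on `[0, xs)` produces the
  `lx_star` column (an independent cohort draw in stochastic mode);
* a fixed seed gives identical output (`numpy.random.default_rng`).

What the generator emulates: sampling noise in death counts and
fecundity for a homogeneous cohort under exactly Gompertz–Makeham
mortality with constant adult fecundity. What it does not: age-varying
fecundity schedules, heterogeneity/frailty, age-misreporting, censoring,
or model misspecification — so passing recovery tests demonstrates
correctness of the estimator under the model, not robustness of the
model on real data.

## Bundled parameterizations

Four wild-mammal parameterizations ship as named fixtures
(annual rates): human (G=0.00041, R=0.071, M=0.00001, xs=13,
zeta=0.036), killer whale (G=0.00094, R=0.048, M=0.00001, xs=11,
zeta=0.051), yellow baboon (G=0.003, R=0.208, M=0.05, xs=5,
zeta=0.182), lion (G=0.0025, R=0.325, M=0.0522, xs=2, zeta=0.2).
They span slow/late to fast/early life histories and anchor all tests
and the acceptance script. Problem sizes used by the shipped checks —
fit-alpha grids of 222 alpha values with 41-point z scans, 50-replicate
recovery ensembles at cohort sizes 10^3..10^5, 50 random parameter sets
for the gradient cross-checks — were chosen so each check completes in
seconds to a couple of minutes on one core while leaving the measured
quantities' precision comfortably inside the asserted tolerances.

## Known limitations

* Only Gompertz–Makeham hazards; no Siler/bathtub early-life term, no
  age-varying `G` or `M` (juvenile mortality enters only through the
  effective reproduction rate).
* Density dependence acts equally on all ages; no age-structured
  regulation, no stochastic demography.
* The ESS machinery covers the senescence–reproduction trade-off only;
  other parameter pairs are out of scope.
* The feedback heuristics (Table-style threshold rules) are advisory
  approximations with ~90% empirical agreement in the sampled regime.
* Time units are fixed to years; mixing differently scaled rate sets is
  the caller's responsibility.
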