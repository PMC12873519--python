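# Methods

## Hydraulic model

A conduit column is a stack of cylindrical elements whose lumen
diameter follows `D(x) = d_ref (x / x_ref)^b`, `x` the distance from
the organ tip in mm. Each element of length ℓ contributes
Hagen–Poiseuille resistance `128 μ ℓ / (π D⁴)`; cumulative resistance
is the running sum from `x_min` outward. Units are arbitrary but
consistent (default viscosity 1); diameters are in µm, distances in mm.

Numerical choices:

* **Element geometry.** Default `element_length = 1 mm` and
  `x_min = 1 mm`. A positive `x_min` is required because the resistance
  density `x^(-4b)` is non-integrable at the tip once `4b ≥ 1`.
* **Where the diameter is sampled.** Each element's diameter is the
  power law at the *geometric mean* of the element's endpoints. For a
  power-law integrand this is markedly more accurate than the
  arithmetic midpoint near the quasi-singular tip: at 1000 elements
  over 1–1000 mm the arithmetic midpoint misses the analytic integral
  by 3.3% at `b = 0.4`, the geometric mean by 0.54% (and it is exact at
  `b = 0` and `b = 0.5`). The closed form
  `∫ 128 μ x_ref^{4b} / (π d_ref⁴) · x^{-4b} dx` (logarithmic at
  `4b = 1`) is kept as an independent cross-check, not used by the
  discrete model.
* **Single column.** The model treats one tip-to-base conduit file; no
  furcation or parallel-conduit counts. Scale covariance is exact:
  scaling `d_ref` by k scales every resistance by `k⁻⁴`.

**Resistance-balancing tip law.** To ask what terminal diameter keeps
whole-plant resistance constant during height growth we use the family
`R(H, D) ∝ H^c / D⁴`, where `c ≥ 0` is the height-exponent of the
resistance left unbuffered by tip-to-base widening and the whole
widening profile scales multiplicatively with the tip diameter `D`.
Balancing against an anchor `(h_ref, d_ref)` gives
`D = d_ref (H/h_ref)^{c/4}`, which the implementation solves by
deterministic bracketed root search on `log10 D` (Brent, tolerance
1e-12, bracket `d_ref × 10^±2`) so the closed form doubles as an
independent check. `c = 1.04` (tip exponent `g = c/4 = 0.26`)
reproduces the classic 18.2 µm @ 10 m / 21.8 µm @ 20 m worked examples
anchored at 10 µm @ 1 m. We deliberately expose `c` as a parameter
rather than deriving it from a stem-widening exponent: the literal
single-column integral with `b = 0.2` leaves a residual growth of only
`H^{1-4b} = H^{0.2}`, i.e. a balanced tip exponent of 0.05, so the 0.26
figure must encode additional unbuffered resistance (leaf turnover,
root path, per-leaf-area normalisation) that the stacked-column model
alone does not determine.

The published illustration's absolute "resistance units" (≈0.07→0.18
for leaves, ≈0.16→1.0 for stems over 100→1000 mm) depend on an
unstated normalisation and are not reproduced; the package reproduces
the structural contrast — the 100→1000 mm resistance ratio is ≈1.05
under `b = 0.4` versus ≈1.98 under `b = 0.2` — which is the
scientifically meaningful claim (leaf resistance nearly independent of
leaf length).

## Allometric suite

All continuous traits are log10-transformed; every scaling fit is OLS
of `log10 y` on `log10 x` (OLS, not SMA, because the predictor is
treated as causally upstream). `ScalingResults` reports slope and
intercept with t-based 95% CIs, adjusted R², F and residual df.
Missing values are deleted pairwise per fit with a logged count; zero
or negative trait values are an error naming the offending species, not
a silent drop, because they indicate data corruption rather than
missingness.

**Slope comparison.** Two independently fitted slopes are compared with
`t = (b₁−b₂)/√(SE₁²+SE₂²)` and Welch–Satterthwaite degrees of freedom
`(SE₁²+SE₂²)² / (SE₁⁴/df₁ + SE₂⁴/df₂)`. Reconstructing the slope SEs
from the published petiole (0.396, CI 0.344–0.448) and twig (0.263, CI
0.201–0.324) leaf-length fits at 86 df gives t ≈ 3.28, df ≈ 167,
matching the published t = 3.298, df = 166.24 — which is why this
construction was adopted; the test's type-I error is verified at 5% by
simulation. The exact p is reported (no flooring).

**Group models.** `log10 y ~ log10 x * group` tests slope heterogeneity
(interaction) and intercept shifts (main effect). For two-level groups
the coefficient Wald t-tests are reported (what `summary(lm)` prints in
R); for ≥3 levels, joint type-II F-tests. Note the main-effect
coefficient is the offset at `log10 x = 0`; with an interaction in the
model the interpretable offset is at the predictor mean.

No multiple-testing correction is applied across the nine standard
regressions; they are reported as a descriptive suite.

## Phylogenetic comparative machinery

Trees are rooted, with branch lengths; ultrametricity is checked to a
relative tolerance of 1e-6. Polytomies are resolved randomly (seeded):
new internal edges get length `1e-8 × tree depth`, then pendant edges
are adjusted so every root-to-tip depth is restored exactly, keeping
the tree ultrametric while the covariance stays non-singular.

Residual structures for PGLS (`covariance_matrix`):

* **WN** — identity (phylogenetic independence; PGLS ≡ OLS, exactly:
  the coefficients agree to machine precision, which is the bridge that
  makes the ordinary and phylogenetic slope estimates coincide when the
  best structure is WN);
* **BM** — `C_ij` = depth of the most recent common ancestor of i and j
  (diagonal = tip depth);
* **OU(α)** — correlation `exp(−α d_ij)` with `d_ij` the patristic
  distance; α is fixed (default 1), not estimated;
* **Pagel λ** — BM with off-diagonals multiplied by λ ∈ [0, 1].

GLS estimation profiles the residual variance by ML, so the reported
log-likelihood is the Gaussian profile likelihood (verified against a
direct multivariate-normal density evaluation and against R's
`nlme::gls(method="ML")` with `ape` correlation structures, which
agrees to ≥6 significant digits). Structures are ranked by
`AICc = −2logL + 2k + 2k(k+1)/(n−k−1)` with k = coefficients + 1
(variance); all three candidate structures here have equal k, so the
ranking is likelihood-driven and both AIC and AICc are reported.
Covariances failing a Cholesky check get diagonal jitter
`1e-10 · tr(C)/n` (logged); this only arises for degenerate inputs.
Species are matched between table and tree by name; the intersection
count is logged and extra tips are pruned, since trait tables and
grafted supertrees routinely disagree by a species.

**Phylogenetic signal.**

* *Pagel's λ*: ML over [0, 1] for an intercept-only model, LR test
  against λ = 0. Because λ = 0 is a boundary, the null LR is a mixture
  of a point mass at zero and (conditionally, to a good approximation)
  χ²₁. The textbook 1/2 : 1/2 mixture is asymptotic and badly
  conservative at realistic sizes — on an 88-tip unit-depth pure-birth
  tree the ML estimate hits the boundary for ~80% of independent
  traits, giving an empirical size of ~1.7% at nominal 5%. The
  implementation therefore estimates the boundary mass for the tree at
  hand by fitting λ to `n_null = 500` simulated independent traits
  (seeded, cached per tree) and uses `p = (1−ŵ) · P(χ²₁ > LR)`, `p = 1`
  at LR = 0. Measured size: 5.4% at nominal 5% over 2000 null
  simulations; power is unaffected (Brownian traits give p ≈ 1e-26).
  On constant-depth trees the Pagel family shares eigenvectors across
  λ, so after one eigendecomposition each likelihood evaluation is
  O(n), making the weight simulation cheap.
* *Blomberg's K*: observed (variance / phylogenetically corrected
  variance) over its Brownian expectation; p by seeded tip-shuffling
  permutation (add-one corrected).

## Synthetic data generator

The generator emulates a cross-species study of 88 vessel-bearing
angiosperms. Heights are log-uniform over 0.25–52.5 m (log-uniform
because wide, even coverage of the size range is precisely what such
field campaigns aim for); downstream traits follow the generative chain

| relation | slope | intercept (log10) | target adj. R² |
|---|---|---|---|
| leaf length ~ height | 0.482 | 0.839 | 0.22 |
| petiole diameter ~ leaf length | 0.396 | 0.898 | 0.72 |
| twig diameter ~ petiole diameter | 0.679 | 0.592 | 0.65 |
| wood density ~ leaf length | −0.271 | −0.284 | 0.24 |

with Gaussian log10-scale residuals whose SD inverts the R²:
`sd(ε) = |slope| · sd(log10 x) · √(1/R² − 1)` (published tables report
R², not residual SDs, so this is the natural calibration). The implied
twig ~ leaf-length composite slope is 0.679 × 0.396 ≈ 0.27, consistent
with the directly fitted 0.263. Wood densities are clipped to
0.03–1.4 g/cm³; values outside are physically implausible wood.
Leaf type and site are uniform draws with no trait effect, mirroring
the finding that neither moderates the petiole–twig relationship.
Under `residual_mode="brownian"`/`"ou"` the residuals are drawn from
the tree's correlation matrix scaled to the same marginal SD, giving
data with genuine phylogenetic structure for testing PGLS and the
signal statistics.

Trees are pure-birth (Yule, unit rate), observed an Exp(n·rate) waiting
time after the n-th speciation (so no tip edge is ever zero), rescaled
to unit depth. Everything is deterministic given the seed.

What the generator does *not* emulate: intraspecific replication
(thousands of twigs per study), measurement error, site/climate effects
on traits, unbalanced group sizes, or the single implausible published
wood-density maximum of 6.42 g/cm³. Passing tests on synthetic data
therefore demonstrate the statistical machinery is correct under the
stated generative model, not that any particular biological data set
satisfies that model.

## Problem sizes and determinism

Monte-Carlo checks run at the study scale of n = 88 species: CI
coverage over 200 seeds, correlation-structure recovery over 200
simulations, and test-size calibration over 2000 simulations per test —
sizes at which binomial noise on the checked proportions is well inside
the asserted bands. All random draws (tree simulation, trait noise,
polytomy resolution, permutations, calibration loops) flow from
explicit integer seeds; reruns are byte-identical, and the pipeline
stamps its seed into the report bundle.

## Known limitations

* OU α and Pagel λ are fixed in PGLS, never jointly estimated with the
  regression; λ estimation exists only in the signal module's
  intercept-only model.
* The hydraulic model is a single unbranched conduit column; no
  furcation networks, embolism, or non-Newtonian effects.
* The resistance-balancing exponent `c` is an input, not derived.
* Blomberg's K uses the standard permutation null, which tests
  exchangeability of tips, not a specific evolutionary model.
* PGLS matching is by exact species-name string equality.
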