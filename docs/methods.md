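# Methods

## Model

`fsvmcip` implements a fuzzy soft-margin SVM for two-class imbalanced
data. Training data are held in canonical order: the m₁ majority/normal
samples (label +1) first, then the m₂ minority/abnormal samples
(label −1). The linear primal minimizes

    ½wᵀw − νρ + 1/(v₁m₁) Σᵢ μᵢξᵢ + 1/(v₂m₂) Σⱼ μⱼξⱼ + (η/2) wᵀSw

subject to `wᵀxᵢ + b ≥ 1 − ξᵢ` for positives, `−(wᵀxⱼ + b) ≥ 1 + ρ − ξⱼ`
for negatives, ξ ≥ 0 and ρ ≥ 0. Its dual is the box-equality QP

    min ½αᵀHα,   Σ_{pos} α = Σ_{neg} α = ν,   0 ≤ αᵢ ≤ μᵢ/(v_c m_c)

with `Hᵢⱼ = yᵢyⱼ xᵢᵀ(I + ηS)⁻¹xⱼ`. The kernel version substitutes
`M = YKᵀQ⁻¹KY`, `Q = K + η(T₁ + T₂)`, recovers the representer
coefficients `β* = Q⁻¹KYα*`, and predicts with
`sgn(Σ βᵢ*K(x, xᵢ) + b*)`.

Two structural consequences of this dual are worth keeping in mind when
choosing parameters; both were verified against a direct solve of the
primal (SLSQP on (w, b, ρ, ξ) with ρ ≥ 0 enforced):

1. **The ν regime.** The dual has no linear term, so it computes the
   distance between the two membership-capped *reduced convex hulls*,
   with per-sample weights capped at `μᵢ/(ν v_c m_c)`. When ν is small
   relative to the caps the reduced hulls of overlapping classes
   intersect, the optimal w collapses toward 0 and the recovered offset
   ρ* falls to ≈ −2: the model degenerates to majority-only predictions.
   This is a property of the published constraint set, which pins *both*
   class sums at ν and drops the multiplier that would enforce ρ ≥ 0 in
   the dual; whenever the optimum has ρ > 0 the dual solution coincides
   with the ρ-constrained primal exactly (checked to ~1e−5 against the
   primal oracle). Practically, ν·v_c·m_c is the margin-error mass
   budget of class c, and useful fits keep it between roughly one sample
   and a modest fraction of the class.

2. **How v₂ steers specificity.** v₂ enters the dual only through the
   minority caps `μⱼ/(v₂m₂)`. Raising v₂ tightens the caps, forces the
   minority dual mass to spread across more samples, shrinks that
   class's reduced hull and *enlarges* the recovered ρ*, which moves the
   zero-level boundary toward the majority class — so training
   specificity is monotonically **non-decreasing in v₂** at fixed ν, v₁.
   The complementary lever is v₁: raising it (cheapening majority
   errors, i.e. v₂ < v₁) shrinks the majority hull and likewise raises
   specificity. The package's imbalance experiment contrasts
   (v₁, v₂) = (0.05, 0.01) with the symmetric (0.01, 0.01).

## Fuzzy memberships

Per-sample weights are computed on the training set only, from the
distance dᵢ to the own-class mean:

- linear family: `μᵢ = 1 − dᵢ/(max_class d + δ)`, δ = 1e−6 by default;
  the max ranges over the sample's own class, so the farthest sample of
  each class gets `δ/(d_max + δ)` — strictly positive but tiny.
- exponential family: `μᵢ = 2/(1 + exp(λdᵢ))`, λ ∈ [0, 1]; λ = 0 gives
  uniform weights, λ = 1 the steepest decay. λ has no default and is
  grid-searched.

Feature-space variants replace dᵢ by the kernel-expansion distance
`√(Kᵢᵢ − (2/|C|)ΣⱼKᵢⱼ + (1/|C|²)Σₛₜ Kₛₜ)`; with the linear kernel they
reduce exactly to the input-space versions. The kernel estimator uses
feature-space memberships by default. Both families are positive,
bounded by 1, and non-increasing in distance.

## Locality graph and scatter

Within each class, every sample is joined to its k nearest same-class
neighbors (Euclidean in input space, kernel-induced
`√(Kᵢᵢ + Kⱼⱼ − 2Kᵢⱼ)` in feature space), OR-symmetrized, self-edges
excluded, ties broken by smaller index. Edge weights are heat-kernel
values `exp(−d²/t)` row-normalized by the raw row sum (the definition's
self-referential normalizer is read this way); the row-minimum distance
is subtracted before exponentiation, which leaves the normalized weights
unchanged but avoids underflow for distant neighbor pairs. The scatter
is `S = Σᵢ rᵢrᵢᵀ` with residual `rᵢ = xᵢ − Σⱼ Wᵢⱼxⱼ`, equivalently
`Σ_c X_cᵀ(I − W_c)ᵀ(I − W_c)X_c`. Isolated samples (singleton class, k
truncation leaving no neighbor) contribute zero: with no neighborhood
there is nothing to preserve, and the literal residual would inject a
spurious xᵢxᵢᵀ term. S is symmetric PSD by construction; the kernel-side
terms T_c = K_cA_cᵀA_cK_cᵀ likewise, and with the linear kernel
T₁ + T₂ = XSXᵀ.

## Numerical choices

- **QP backend.** scipy's trust-constr (exact gradient and Hessian,
  deterministic start at the cap-proportional feasible point) followed
  by a primal active-set refinement: variables within 1e−9·max(u) of a
  bound are pinned, the reduced equality-constrained KKT system is
  solved by least squares with two rounds of iterative refinement, steps
  are ratio-tested against the box, and bound variables with
  wrong-signed multipliers are released. The refined solutions satisfy
  stationarity and complementarity to ~1e−12 on the package's test
  instances.
- **Thresholds.** b* = 1 − mean(wᵀx over threshold SVs of the positive
  class); ρ* = −1 − b* − mean(wᵀx over threshold SVs of the negative
  class), i.e. the values that make the averaged active margin
  constraints exact. By default the averages run over *strictly
  interior* SVs (0 < α < u), whose slacks are exactly zero at the
  optimum; bound SVs carry positive slack and would bias the averages
  and break KKT complementarity. `sv_mode="all"` restores the
  closed-interval alternative. In the kernel case the threshold
  expansions use `Σⱼ βⱼK(xᵢ, xⱼ)` without an extra label factor — the
  variant with a `yⱼ` factor inside the sum double-counts Y (β* already
  absorbs it once) and demonstrably breaks the linear-kernel reduction;
  it remains available behind `threshold_label_factor=True` and the
  choice is recorded in model metadata.
- **Regularized solves.** `(I + ηS)` is always nonsingular and solved by
  Cholesky; Q is only guaranteed PSD, so factorization retries with an
  escalating trace-scaled ridge (1e−10 → 1e−6 of trace(Q)/N). M's PSD
  property (min eigenvalue ≥ −1e−8·‖M‖) is asserted at runtime.
- **Tolerances.** SV/ME membership threshold 1e−8·max(u) (scale-aware);
  sign(0) predicts +1 (deterministic, favors the majority class on exact
  ties); equality sums are accepted within 1e−6·ν.
- **Margin-mass report.** For each class the package reports
  `mean_μ(ME)·#ME ≤ ν·v_c·m_c ≤ mean_μ(SV)·#SV` together with all six
  raw quantities. The chain restates Σ_ME u ≤ Σα = ν ≤ Σ_SV u under
  u = μ/(v_c m_c); the left bound is vacuous when a class has no margin
  errors.

## Hyperparameters

| parameter | meaning | default / grid |
|---|---|---|
| ν | per-class dual mass; ν·v_c·m_c is class c's margin-error budget | grid {1, 5, 10, …, 80} |
| v₁, v₂ | per-class cost scalers (smaller = costlier errors) | grid {0.001, 0.005, 0.01, 0.05} |
| η | scatter–margin tradeoff | grid log₂η ∈ {−5, −4.5, …, 6} |
| k | within-class neighbors | grid {3, 5, …, 15}, truncated to class size − 1 |
| t | heat-kernel width | grid {0.5, 1.0, …, 4.0} |
| δ | linear-membership floor | 1e−6 |
| λ | exponential-membership steepness | grid {0.1, …, 1.0}, no default |
| σ | RBF spread | grid {τ²/16, …, 16τ²}, τ² = mean squared row norm |

τ² is implemented as the mean *squared* norm (the quantity σ divides is
a squared distance); a config switch in `tau_squared`'s caller can
substitute any other value. Model selection uses stratified 5-fold CV
with mean validation accuracy, ties broken by two-way G-mean and then by
grid enumeration order; the full grid product is combinatorially large,
so `cv_select` accepts a `budget` that subsamples candidates with the
run's seed.

## Synthetic data

The generator emulates the intended regime rather than any particular
clinical table: two Gaussian classes (unit within-class std, means
separated by `separation` units along the first axis; default 2.5, a
moderately overlapping problem), a positive:negative ratio set by the
class counts (the five bundled protocol shapes use 240/120/9-D,
80/20/13-D, 100/10/19-D, 150/10/6-D and 180/10/8-D with 5% outliers and
2% label noise), outliers resampled onto a uniform shell at 5–8× the
separation (they keep their labels and stress the membership
down-weighting), and exact `round(rate·N)` label flips with the pre-flip
truth retained. A `two_arcs` shape (interleaved half-circles) exists
solely to exercise the kernel path's nonlinearity. What passing tests on
these data do *not* show: behavior under real clinical feature
distributions (mixed scales, discreteness, correlated features, missing
values — the loader rejects missing cells rather than imputing).

The imbalance experiment bundled in the acceptance script uses the
conditions 150/10 (15:1), 2-D, separation 2.0, 5% label noise, training
splits of 75/5, ν = 15, η = 1, k = 3, t = 1, λ = 0.5, σ = τ², and
10 seeds per configuration; problem sizes throughout the test suite and
script (N ≤ 20 for oracle comparisons, N ≈ 160 for the experiment) keep
every check exact or well-resolved at interactive runtimes.

## Known limitations

- The published dual (class sums pinned at ν) departs from the
  ρ-constrained primal in the small-ν regime (see above); the package
  implements the published form and surfaces the regime through ρ* and
  the margin report rather than silently switching formulations.
- Dense O(N²)–O(N³) linear algebra throughout; intended for the
  hundreds-of-samples scale of clinical feature tables, not for large-N
  problems.
- Binary classification only; no probability calibration; no
  missing-data handling; features are consumed as-is by default (an
  opt-in train-statistics standardizer is provided but off, since the
  method definition does not prescribe scaling).
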