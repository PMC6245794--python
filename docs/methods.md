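# Methods

## Model and assumptions

Single-grain dry weight within one cultivar is modelled as a mixture of
two gamma densities, `f(x) = p Γ(x; a1, b1) + (1−p) Γ(x; a2, b2)`,
with the left component collecting unfilled/partially filled grains and
the right component filled grains. The gamma family was chosen over an
exponential-plus-Gaussian construction because its support excludes
zero (no special handling of empty husks inside the likelihood) and it
covers both the right-skewed unfilled cluster and the nearly symmetric,
sharp filled cluster. The model assumes grains are exchangeable within
a cultivar once panicle replicates are pooled; positional effects
(superior vs inferior grains) are treated descriptively via the
posterior classification, not modelled.

Weights at or below a floor (default 0.1 mg, configurable) are removed
before fitting and counted separately (`n_excluded_zero`): the gamma
likelihood is unbounded at 0 for shapes below 1 and such readings are
measurement zeros, not weights. A configurable minimum sample size
(default 50 grains) guards the five-parameter fit.

## Estimation

EM with responsibilities of the left component; the M-step updates `p`
to the mean responsibility and refits each component by the weighted
gamma MLE, solving `ln â − ψ(â) = ln x̄_w − ⟨ln x⟩_w` with Minka's
generalized-Newton fixed point (convergence `|Δ ln â| < 1e−10`, ≤ 200
iterations; `b̂ = x̄_w/â`). The per-iteration log-likelihood is
asserted non-decreasing (1e−9 float slack) in the tests.

Initialisation: `p₀ = 0.5`; two distinct grains are drawn without
replacement (ties redrawn), and each seeds one component via
`a₀ = x′²/Var(x)`, `b₀ = Var(x)/x′` with the sample variance taken over
the whole cultivar — so each initial component mean equals the sampled
weight. EM stops when the log-likelihood gain falls below 1e−8 or after
1000 iterations (a standard criterion; cheap at 10³ grains per
cultivar). Restarts: default 100 in the CLI; simulation and test
configurations use 20, which in pilot runs already lands ≥ 95 % of
restarts on the winning likelihood for well-separated samples. A
restart whose component responsibility mass vanishes or whose weighted
log-moment gap degenerates is discarded; the winner is the converged
restart with the highest log-likelihood. Because EM is label-symmetric
the result is canonically relabelled so the left component has the
smaller mean.

## Derived statistics

Feature values are computed literally from the fitted parameters:
`mode1 = (a1−1)b1` clamped at 0 for `a1 < 1`, `skewness1 = 2/√b1`,
`mu2 = a2 b2`, `var2 = a2 b2²`. The `skewness1` form uses the scale
parameter where the standard gamma skewness uses the shape; both
conventions are implemented (`skewness_convention="scale"|"shape"`)
and the scale form is the default for continuity with how the trait is
conventionally reported.

The boundary analysis scans the mixture density on a 10⁴-point grid
between the left-component mode (or a small epsilon when that mode is
0) and the right-component mode `(a2−1)b2`, refines the grid minimum by
bounded scalar minimisation (xatol 1e−10), and reports the mass within
±0.1 mg of the boundary and of the right mode, plus their ratio. When
the right component has no interior mode (`a2 ≤ 1`), the interval is
empty, or the density is monotone on it, the mixture is reported as not
bimodal and the fields are absent. The grid resolution bounds the
bracketing error at ~(interval length)/10⁴ mg before refinement; the
tests hold the refined point to within 0.01 mg of a 10⁶-point scan.

A grain of weight *x* is classified as filled when the posterior
`(1−p) f2(x)/f(x)` exceeds 0.5.

Conventional traits use the type-7 percentile rule (linear
interpolation between order statistics — the default of mainstream
numeric stacks) and strict "lighter than" inequalities; both are
configurable, as is the 23 mg threshold, since the appropriate
filled-grain threshold is cultivar-dependent. q95 is computed on the
pooled cultivar sample, consistent with the replicate pooling used for
fitting.

## Shape distance

`∫(f − f̂)²` expands termwise into the `g`/`h` kernels. The expansion is
re-derived from `(A + B − C − D)²` rather than transcribed: the two
self-energies contribute their own cross terms with a **plus** sign
(`+p(1−p)h(a1,a2,b1,b2)` and `+p̂(1−p̂)h(â1,â2,b̂1,b̂2)`) and only the
four observed×predicted cross terms enter negatively. Every term is
validated against adaptive quadrature in the tests (≤ 1e−6 relative
over random parameter sweeps), and a dedicated test shows that flipping
the predicted-mixture cross term's sign breaks that agreement. All
kernels are evaluated in log-space (`betaln`, log powers): filled-grain
shapes near 100 overflow naive powers. Shapes ≤ 0.5 make the
self-energy diverge; the package raises a clear error because a fitted
shape that small indicates a degenerate fit upstream, rather than
silently returning infinity. Q² normalises PRESS by the same sum
against the mixture built from the per-parameter observed means; it is
1 for perfect prediction, 0 for the mean-parameter predictor, and may
be negative (no clamping).

## Genomic prediction

Markers are coded −1/0/1 (reference hom / het / alternate hom).
Filtering drops MAF < 0.025 (heterozygotes counted as half an alternate
allele), heterozygote fraction ≥ 5 %, monomorphic columns, and columns
in complete linkage — implemented as exact duplicates up to sign, first
occurrence kept, since no r² threshold is defined for "incomplete
linkage". The kinship is VanRaden method 1,
`K = ZZᵀ / (2Σ p_k(1−p_k))` on column-centred codes; any positive
rescaling of K is prediction-equivalent because the variance ratio
re-estimates compensate (tested to 1e−6).

GBLUP fits `y = 1μ + g + e`, `g ~ N(0, σ²g K)`, by REML on the spectral
decomposition of K: the restricted likelihood is profiled over μ and
σ²e and maximised over the log variance ratio on a grid over [−20, 20]
followed by bounded refinement. The wide range matters: traits with no
genetic signal push the optimum to the boundary, and a narrow range
leaves a rescaling-dependent residue in the predictions. The
implementation reproduces statsmodels MixedLM on a block-kinship
(random-intercept) problem to ~7 significant digits and the closed-form
ridge solution exactly at a fixed ratio. Narrow-sense heritability is
reported as σ²g/(σ²g+σ²e); note that with inbred lines the VanRaden
diagonal is ≈ 2, so this is a model-scale quantity tied to K's scaling.

PLS is multi-response NIPALS (centred, unscaled — per-trait scaling is
exposed as the parameters span orders of magnitude), deterministic for
fixed input order, with per-component-count coefficient extraction so
one fit serves every smaller count. It matches scikit-learn's
PLSRegression (tight tolerance) to ≤ 1e−6 and ordinary least squares at
full rank. The three grouping schemes are: all five parameters in one
model; {p}, {a1, b1}, {a2, b2}; one model per parameter.

Component counts (≤ 30) are chosen by the shape Q² of leave-one-out
predictions. When a grouped model predicts only a subset of the
parameters, the remaining parameters are held at their observed values
while scoring, isolating that model's own contribution — the
combination rule is otherwise underdetermined. Selection is performed
inside each LOO fold by default (the held-out cultivar's phenotype
never enters centring, variance components or component choice); the
simpler protocol that selects once on the full data is available via
`select_per_fold=False` / `--select-global` and is what
`scripts/acceptance.py` uses for its scheme comparison. Predicted
parameter vectors from linear models can leave the valid domain; before
shape-distance evaluation `p` is clipped to [0, 1] and shapes floored
just above 0.5, with the clip count reported.

Accuracy is Pearson correlation between observed and fitted (training)
or LOO-predicted values, for the five parameters and — via plugging the
predicted parameters into their formulas — the feature values, boundary
traits and conventional traits (model-based analogues: mixture CDF at
23 mg, CDF at 0.9 × the mixture 95th percentile, mixture mean over that
percentile; measured conventional traits are substituted when a traits
table is supplied). For GBLUP a direct route is also reported in which
each derived trait is predicted as a trait in its own right.

## Synthetic data

The generator emulates (i) an inbred biallelic panel — codes ±1, allele
frequencies uniform on a MAF spectrum of (0.05, 0.5), optional
heterozygote contamination and duplicated columns to exercise the
filters; (ii) additive architecture — for each parameter, a genetic
value from `n_qtl` random marker effects scaled so the link-scale
variance ratio equals the target h², plus independent Gaussian noise;
(iii) grain weights drawn from each cultivar's mixture with membership
labels retained. Links are logistic for `p` and log for the shapes and
scales, around baselines chosen at the field-realistic regime: unfilled
mean ≈ 6 mg and right-skewed (a1 = 1.5, b1 = 4), filled mean ≈ 25 mg
and sharp (a2 = 100, b2 = 0.25), `p` centred at 0.175; link-scale SDs
(0.45 logit for `p`; 0.25, 0.25, 0.20, 0.10 log for a1, b1, a2, b2)
give parameter ranges comparable to a diverse cultivar panel. Rows
whose component means would cross have their left-side deviations
shrunk until ordering holds.

What the generator does **not** emulate: linkage disequilibrium and
pedigree structure (markers are independent, so cultivars are
essentially unrelated and LOO accuracies are conservative relative to a
structured breeding panel), genotype-by-environment interaction,
positional within-panicle structure, and measurement error in single
grain weights. Passing tests therefore demonstrate correctness of the
estimation and prediction machinery under the stated architecture, not
field-level accuracy values.

## Problem sizes and numerical choices

Default simulation conditions are 150 cultivars, 2000 markers, 1500
grains per cultivar. The test and acceptance runs use: 20 cultivars ×
4000 grains (EM recovery), n = 300 × m = 2000 × 20 replicates (h²
recovery), 150 cultivars × 400 markers × 20 replicates per h² level
(signal chain), and 150 cultivars × 800 markers × 1200 grains with 12
restarts for the full-pipeline experiment in `scripts/acceptance.py` —
sizes at which every stage's sampling error is small relative to the
assertions while the whole suite runs in minutes on one CPU. Quadrature
oracles use `scipy.integrate.quad` with breakpoints at component means,
`epsrel = 1e−12`, over the joint 1−1e−13 quantile range.

## Known limitations

- Unimodal-vs-bimodal model selection is out of scope; samples that are
  genuinely unimodal still receive a two-component fit (the boundary
  analysis flags them as not bimodal).
- Mixtures with more than two components, kernel density estimates and
  other divergences (KL, Wasserstein, Hellinger) are not provided.
- The GBLUP heritability is tied to the VanRaden scaling of K (inbred
  diagonal ≈ 2); compare h² values only under a fixed kinship
  convention.
- LOO accuracy of a near-constant trait is dominated by the fold-mean
  artifact (each fold's mean anti-correlates with its held-out value),
  which is why zero-heritability traits show systematically negative,
  not zero, LOO correlations.
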