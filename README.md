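# grainfill

Rice grain yield depends not only on how many grains a panicle sets but
on how completely they fill. Within one cultivar, single-grain dry
weights are typically **bimodal**: a light, right-skewed cluster of
unfilled and partially filled grains and a heavy, sharp cluster of
filled grains. `grainfill` treats that whole distribution as the
phenotype. It models the per-cultivar weight density as a two-component
gamma mixture, turns the fitted parameters into interpretable
grain-filling statistics, measures distances between whole
distributions in closed form, and predicts the parameters from
genome-wide markers — so grain-filling ability can be handled as a
quantitative trait in genomic selection.

## The model

The density of a single grain weight *x* (mg) in a cultivar is

```
f(x) = p Γ(x; a1, b1) + (1 − p) Γ(x; a2, b2)
```

with mixing proportion `p` (the unfilled-grain fraction), shape/scale
`(a1, b1)` for the unfilled (left) component and `(a2, b2)` for the
filled (right) component. The five genotype-specific parameters are
estimated per cultivar by maximum likelihood: EM whose M-step solves the
weighted gamma MLE with Minka's generalized-Newton fixed point, run from
many random initialisations (`p₀ = 0.5`; each component seeded from a
randomly drawn grain weight *x′* via `a₀ = x′²/Var(x)`,
`b₀ = Var(x)/x′`), keeping the best converged log-likelihood.

Derived statistics per cultivar:

- feature values `mode1 = (a1−1)b1`, `skewness1 = 2/√b1`
  (the standard gamma skewness `2/√a1` is available as an option),
  `mu2 = a2 b2`, `var2 = a2 b2²`;
- the boundary analysis — the density minimum between the two peaks and
  the probability mass within ±0.1 mg of it, a measure of how cleanly
  filled and unfilled grains separate;
- conventional traits: `p.23mg` (fraction below 23 mg), `p.90%`
  (fraction below 90 % of the 95th-percentile weight), and the
  sink-filling rate (total weight over q95 × grain count).

Between two mixtures the squared L2 distance `∫(f − f̂)² dx` has a
closed form in the kernels

```
g(α, β) = 2^(1−2α) / ((2α − 1) β B(α, α))          (self-energy)
h(α1, α2, β1, β2) = 2 β1^(α2−1) β2^(α1−1)
        / ((α1+α2−1)(β1+β2)^(α1+α2−1) B(α1, α2))   (2 × cross-energy)
```

Summed over cultivars this gives PRESS, and normalising by the same sum
against the population mean-parameter mixture gives the shape skill
score **Q²** (1 = perfect, 0 = no better than the mean mixture).

The genomic layer codes biallelic markers −1/0/1, filters them
(MAF ≥ 0.025, heterozygosity < 5 %, monomorphic and completely linked
columns dropped), and predicts the five parameters with **GBLUP**
(VanRaden kinship, REML variance components, narrow-sense h² =
σ²g/(σ²g+σ²e)) and **multi-response PLS** in three grouping schemes —
all five parameters together, the groups {p}, {a1,b1}, {a2,b2}, or one
model per parameter — with component counts (≤ 30) chosen by
leave-one-out shape Q². Skill is reported as per-trait Pearson
correlations under leave-one-out cross-validation plus PRESS/Q².

A synthetic-data generator produces inbred marker panels, additively
heritable parameters (tunable link-scale heritability) and grain
weights drawn from each cultivar's mixture, so the full pipeline runs
and is tested without any external data.

## Worked example

`examples/fit_grain_weight_mixture.py` simulates 1500 grains from a
known mixture and refits it:

```
cultivar 'demo': 1500 grains, log-likelihood -4255.4, converged=True
                  p       a1       b1       a2       b2
true          0.175    1.500    4.000  100.000    0.250
estimated     0.187    1.490    4.179  108.368    0.231

feature values: mode1=2.05 mg (unfilled-grain mode), skewness1=0.98,
  mu2=25.07 mg (filled-grain mean), var2=5.80 mg^2

boundary point 17.11 mg separates the components;
  mass within +-0.1 mg of it: 3.73e-04 vs 0.027 at the filled-grain mode
  (ratio 0.0138 -> clearly bimodal)
```

The mixing proportion and the filled-grain mean/variance are recovered
closely (`a2` and `b2` individually trade off against each other; their
products `mu2`/`var2` are the stable, interpretable quantities). The
tiny boundary-to-mode mass ratio says this cultivar's filled and
unfilled grains are almost perfectly separable.

`examples/genomic_prediction.py` predicts heritable parameters
(link-scale h² = 0.8) on a 120-cultivar synthetic panel:

```
 trait    gblup     pls3   (LOO prediction accuracy)
     p     0.428    0.441
   ...
   mu2     0.617    0.567
  var2     0.655    0.513
gblup: PRESS=7.939  shape Q^2=0.226
```

The other examples cover the conventional traits / positional grain
classification and the closed-form shape distance.

## Command line

```sh
grainfill simulate --out-dir run/ --n-cultivars 150 --seed 1
grainfill fit run/weights.csv --out run/fitted.tsv --restarts 100 --seed 1
grainfill traits run/weights.csv --out run/traits.tsv
grainfill predict run/fitted.tsv --geno run/genotypes.csv --out run/report.json
grainfill report run/report.json --fitted-tsv run/fitted.tsv \
    --weights-csv run/weights.csv --out-dir run/plots
```

Genotypes may be a −1/0/1 matrix CSV or a biallelic-SNP VCF. Every
command writes a manifest (config, seed, version); identical config and
seed reproduce byte-identical tables.

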