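# Methods

## Problem and model

`mimeta` pools per-gene differential-expression evidence across several
independent case/control studies and asks two questions per gene: what is
the common log2 fold-change (LFC), and is the between-study spread larger
than sampling noise alone would produce?  A third stage asks whether
study-level attributes (sample size, country, study age) explain the
spread, and a final stage folds the statistical results into a
literature-derived classification of disease regulators.

### Effect sizes

For gene *g* in study *i* with case values x and control values y (both on
the log2 scale),

    T_i = mean(x) − mean(y)
    v_i = s_x²/n_x + s_y²/n_y        (unbiased sample variances)
    W_i = 1/v_i

The variance is the Welch (unpooled) form.  The mean-difference model does
not require equal group variances, and with arm sizes as unbalanced as 3
vs 84 the pooled form could be badly biased; the unpooled form is the safe
default.  Array data occasionally contains constant probes, which would
give v = 0 and an infinite weight; v is floored at 1e−8 with a logged
warning rather than erroring, keeping the gene in the analysis.

### Heterogeneity and pooling

With k studies of one gene:

    Q   = Σ W_i T_i² − (Σ W_i T_i)² / Σ W_i
    df  = k − 1
    I²  = (Q − df)/Q   if Q > df, else 0

Q is the inverse-variance-weighted dispersion of the study effects around
their weighted mean; under homogeneity it is approximately χ²(df), so df is
its expected value.  When Q ≤ df the observed dispersion is no more than
chance predicts, I² is clamped to zero, and the **fixed-effect** model is
selected (the boundary Q = df counts as fixed).  Otherwise the
**random-effects** model is used with the DerSimonian–Laird moment
estimator

    τ² = max(0, (Q − df)/C),   C = Σ W_i − Σ W_i² / Σ W_i

and re-weighting W*_i = 1/(v_i + τ²).  In both models the pooled estimate
is the weighted mean with standard error (Σ weights)^(−1/2), and
significance is a two-sided z-test on pooled/se.  Model selection is per
gene, so one report can mix fixed- and random-effects rows.

Numerical guards: Q is clamped at zero against floating-point
cancellation; τ² = 0 reproduces fixed-effect pooling exactly, which the
tests assert.  DL was chosen over REML/Paule–Mandel because it is the
standard closed-form companion of the Q/I² machinery and is exactly
reproducible by hand, which the worked three-study example
((T, v) = (0.5, 0.1), (1.0, 0.2), (1.5, 0.1) → Q = 5, I² = 0.6,
τ² = 0.1875, pooled = 1.0) exploits.

### Moderator regression

Per gene, the study effects T_i are regressed by ordinary least squares on
an intercept plus three study-level covariates: total sample size
(n_case + n_control), country (a single integer label, alphabetical order
of the distinct names from 0), and study age in years.  Each covariate gets
a two-sided t-test p-value.

Design choices and their costs:

* **Single-label country encoding, not one-hot.**  With at most nine
  studies and six countries, dummy coding exhausts the residual degrees of
  freedom, and the report format carries exactly one p-value per factor.
  The cost is that the label order is arbitrary — the country p-value tests
  a linear trend along an alphabetical ordering, not a general country
  effect.  This is a documented limitation, not a recommendation.
* **Unweighted OLS, not inverse-variance-weighted meta-regression.**
  Plain OLS treats study effects as exchangeable with a common error
  variance.  That assumption holds when between-study heterogeneity
  dominates the per-study sampling variances (τ² ≫ v_i) and fails when
  τ² = 0 and arm sizes are very unequal, in which case the t-tests are
  conservative (measured rejection ≈ 0.01–0.02 at nominal 0.05 under the
  nine-study design).  The null-calibration check is therefore run in the
  heterogeneity-dominated regime (τ² = 0.25, per-sample sd = 1), where
  unweighted OLS is the right model and its p-values are uniform.
* **Minimum of five studies** for a full fit (intercept + 3 covariates + 1
  residual df).  Genes below the threshold are reported with NaN
  statistics rather than dropped, so thinly measured genes remain visible.
  Constant (zero-variance) covariates are dropped the same way.  A perfect
  fit (zero residuals) reports the limiting p = 0 for nonzero coefficients
  with a warning.

### Regulator-role classification

Each regulator carries a biological level (gene, small molecule, gene
family, complex), a disease role (promoter or inhibitor of myocardial
infarction), and the direction in which schizophrenia drives it (activates
or deactivates).  The classification is the pure two-bit function:
activating a promoter or deactivating an inhibitor is **harmful**; the two
complementary pairings are **protective**.  The packaged 19-row roles
table (nine genes, six small molecules, two gene families, two complexes)
yields 9/9 harmful at the gene level and 18/19 harmful overall, the single
protective entry being a deactivated small-molecule promoter (arachidonic
acid).  Relationships with fewer than three supporting references were
filtered out upstream; the loader enforces that floor.  One nuance is
deliberately flattened: thioredoxin (TXN) is protective in early-stage
disease but the table encodes the chronic-stage direction (deactivated
inhibitor → harmful).

## Synthetic data generator

The generator emulates the kind of collection the pipeline targets: k
studies with unequal arm sizes (the packaged default is the nine-study
design with arms from 3/3 to 14/84), per-gene true pooled effect μ_g on
the log2 scale, between-study heterogeneity τ²_g, optional moderator
coefficients β_g on (total n, country code, study age), and i.i.d.
Gaussian per-sample noise:

    θ_gi ~ N(μ_g + X_i·β_g, τ²_g)
    control ~ N(baseline, sd²),  case ~ N(baseline + θ_gi, sd²)

Defaults: baseline 8.0 log2 units (typical bulk-array intensity), sd 1.0
log2 units (typical per-sample spread).  Every θ_gi is recorded in a truth
table.  Randomness is keyed by one integer seed with an independent
substream per (gene, study) pair, so regeneration is bit-identical and
adding a gene does not perturb another gene's draws.  A per-study dropout
list removes genes from chosen studies, emulating platforms that do not
measure a gene and exercising the varying per-gene study counts.

What the generator does **not** emulate: heavy-tailed or outlier noise,
probe-level structure (it emits gene-keyed matrices), correlated genes,
batch effects, or platform-specific intensity distributions.  Passing
tests therefore show the estimators are correct under the stated Gaussian
model, not that real microarray collections satisfy that model.

## Dataset ingestion conventions

* Raw-scale detection: a matrix with maximum > 50 is assumed to be raw
  intensity and log2(x+1)-transformed; log2 microarray data rarely exceeds
  ~20.  Negative values in a matrix flagged for transform are an error.
* Probe collapsing: element-wise median over a probe's gene group, robust
  to a single aberrant probe; unmapped probes are dropped with a log line.
* Samples without a phenotype label are dropped with a warning (public
  series routinely carry extra samples); a study must retain at least one
  case and one control.
* Manifest filtering applies the four inclusion criteria in order (array
  data, downloadable, human, case-vs-healthy design) with per-stage
  surviving counts logged, so the selection funnel on any catalog is
  inspectable.

## Problem sizes used in checks

The statistical checks run at the replicate counts they state: 200 random
effect sets for the engine-vs-brute-force oracle, 200 simulation
replicates for parameter recovery (μ = 0.7, τ² = 0.01, sd = 1, the
nine-study arm sizes), 1000 replicates for the pooled-test type-I error,
and 500 for the moderator-null calibration.  All are single-CPU and
complete in well under a minute each.

## Known limitations

* The z-test on pooled/se ignores uncertainty in τ² (no Hartung–Knapp
  adjustment); with very few studies its type-I error can drift above
  nominal, though it measures 0.04–0.06 under the nine-study design.
* DL τ² is a moment estimator; REML would be more efficient under strong
  heterogeneity but has no closed form.
* The country encoding tests a linear trend over an arbitrary alphabetical
  ordering (see above).
* Real-data reproduction of published per-gene effect sizes requires the
  original public expression series and their platform annotations;
  probe-to-gene annotation choices are not standardized and the packaged
  pipeline does not attempt to fix them.
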