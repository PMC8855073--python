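# Methods

## Design and model

The package targets a four-group factorial knockout design measured by bulk
RNA-seq. Two knockout-vs-control contrasts come from different mouse lines:
contrast A deletes a receptor pair with a downstream transcription factor
family intact; contrast B deletes the same receptors on a background where
the factors are already gone. Because the two contrasts involve disjoint
animals and separate fits, their estimators are treated as statistically
independent throughout; that independence is what the dependence and
intersection tests below rely on.

### Per-contrast differential expression

Counts are normalized to log2 scale by one of two exactly specified schemes:

* `cpm_log2` (default): `log2((count + c) * 1e6 / library)` with prior count
  `c = 0.5` and `library` the sample's raw total.
* `median_of_ratios_log2`: DESeq-style size factors — the per-sample median
  across all-positive genes of count / geometric-mean-count — then
  `log2((count + c) / size_factor)`.

Each gene then receives an ordinary pooled two-group fit (β = difference of
group means of log2 expression, pooled variance s², df = n − 2,
u = √(1/n₁ + 1/n₂)), followed by empirical-Bayes variance moderation. The
prior (d₀, s₀²) is fit by method of moments on log variances: the mean and
excess variance of log s²_g are matched to the log-chi-square model via
digamma/trigamma functions, with the trigamma inverted by Newton iteration.
When the observed spread of log variances is at or below pure chi-square
sampling noise, d₀ is capped at 10⁶ (an effectively infinite prior) and s₀²
is the plain mean of the variances — the infinite-shrinkage limit, which also
matches the reference R implementation of this moderation scheme. Moderated
p-values are two-sided t tail probabilities at d₀ + df degrees of freedom,
BH-adjusted within the contrast's gene family. DE calls use FDR < 0.05
(boundary exclusive) and |FC| ≥ 1.5 (boundary inclusive) on the raw β.

Genes with fewer than 10 total counts across the contrast's samples are
dropped before fitting so that all-zero genes cannot distort the variance
prior; the filter is configurable, including off.

### Dependence test

"Dependent" genes are those whose contrast-A effect is statistically greater
than `factor` (default 2) times their contrast-B effect. Direction matters:
for a downregulated gene the test must demand a *more negative* logFC in
contrast A. This is operationalized as a one-sided test on the sign-aligned
contrast with h = sign(β_A):

    z = h (β_A − factor·β_B) / sqrt(se_A² + factor²·se_B²)

referred to a t distribution with Satterthwaite-combined degrees of freedom
(the two fits are independent, so the variance of the contrast is the sum
with the factor applied). The construction is symmetric under a joint sign
flip of both effects. β_A = 0 has no direction to align and returns p = 1.

### Independence test (min-t intersection)

"Independent" genes moved in the same direction in both contrasts with
evidence in each. The statistic is m = min(|t_A|, |t_B|), set to 0 when the
signs disagree or either t is 0 — an intersection-union score: m is large
only if *both* contrasts changed. Its null distribution under two
independent central t variates is simulated (seeded; default 10⁶ draws), and
the p-value uses the (r+1)/(n+1) tail-fraction estimator so Monte-Carlo
p-values are never exactly 0. When df_A = df_B the closed form

    P(M ≥ m) = 2·S(m)²   (S = upper-tail t probability)

is exact — both statistics must exceed m with a shared sign, and the two sign
configurations are disjoint — and is used directly; in the end-to-end
pipeline the two contrasts carry different moderated df, so the Monte-Carlo
route runs there (one shared simulation per unique df pair) and the closed
form serves as the calibration oracle in the test suite. Zero minima occur
with probability 1/2 under the null, so opposite-sign genes can never be
called independent.

### Categorization

Both tests run on a restriction family — by default the genes called DE in
contrast A, since the question "is this response mediated?" only makes sense
for genes that responded; running on all genes is a flag. Each family of
p-values is BH-adjusted separately. A gene is *dependent* if q_dep < 0.05,
else *independent* if q_indep < 0.05, else *neither*: dependent takes
precedence so the categories are disjoint (both q-values are always
reported). The restriction is applied before adjustment.

### Enrichment

Over-representation only: p = hypergeometric upper tail P(X ≥ k) for overlap
k between the query and each GMT set intersected with the universe, BH over
all tested sets, with up/down splits of the overlap when call labels are
available. The universe defaults to the genes passing the expression filter,
not the whole genome. Name filters run first: RIKEN genes (suffix `Rik`,
case-sensitive full match) and the knockout-target genes themselves, which
are artifacts of the genetic manipulation rather than biology in these
comparisons.

## Synthetic data

The generator plants a known architecture: `frac_dependent` genes with
contrast-A log2FC drawn uniform in ±[1, 3] and contrast-B effect multiplied
by `attenuation_B` (default 0 — fully mediated); `frac_independent` genes
with the same effect in both contrasts (optional multiplicative jitter,
sign-preserving); the rest null. Counts are negative binomial with mean
`relative_abundance × library_size × size_factor × 2^log2FC` and variance
mu + φ·mu² (φ = 0 is Poisson; the size/probability mapping is
NB(n = 1/φ, p = 1/(1 + φ·mu))).

Defaults are fixed as the package's study conditions: 10,000 genes, 6
replicates per group (a typical mouse cohort), constant dispersion φ = 0.1
(typical for biological replicates of bulk tissue), expected library size
5×10⁶ (a desk-scale bulk depth giving a median gene roughly 200 counts per
sample), baseline log2 relative abundance ~ Normal(5, 2), and per-sample
size factors log-normal with σ = 0.1 so normalization is non-trivial.

What the generator does *not* emulate: batch effects, GC/length bias,
gene–gene correlation, outlier samples, and mean-dependent dispersion. A
passing recovery test therefore shows the chain is correct and calibrated
under clean NB sampling, not that it is robust to those artifacts.

One artifact it *does* reproduce is composition bias: planted fold changes
shift the knockout groups' library totals (the expected linear fold change
2^U[1,3] exceeds 1 even with symmetric signs), so per-total CPM
normalization leaks a shared offset into every gene's logFC — in both
contrasts, which also inflates same-sign minima. With 25% of genes affected
the offset reaches ≈ −0.4 log2 units and visibly inflates DE and independent
calls; the median-of-ratios option is robust to it (the median tracks the
null majority) and is the right choice when many strong effects are
expected. The default remains CPM for its simplicity and transparency.

## Numerical choices

* BH step-up is computed exactly as q_(i) = min_{j≥i}(m·p_(j)/j), clipped at
  1, mergesort for stable ties.
* Trigamma inversion: Newton iteration with asymptotic endpoints
  (x ≈ 1/√y for small x, x ≈ 1/y for large), relative tolerance 1e-10.
* Zero posterior variance with nonzero β yields t = ±∞ and p = 0 (sentinel);
  β = 0 always yields t = 0, p = 1.
* Volcano tables floor p at the smallest positive double before −log10.
* PCA: top 500 genes by variance of log-normalized values, gene-wise
  centering, no scaling, full SVD.
* All result tables are written with shortest-round-trip float formatting
  and read back with round-trip parsing, so a resumed run reproduces
  in-memory results bit-for-bit; the run manifest stores outdir-relative
  paths and SHA-256 hashes, making two runs with the same config and seed
  byte-identical.
* Monte-Carlo seeds derive from the run seed through `SeedSequence` spawning,
  one stream per unique df pair, and are kept below 2³¹.

## Open design points, resolved

* Whether the dependence test compares signed or absolute logFCs is not
  determined by the definition alone; the sign-aligned contrast was chosen
  because it treats up- and downregulated genes symmetrically and reduces to
  the natural one-sided test in each direction.
* The simulated min-t null uses the per-contrast moderated df (per unique df
  pair), not a single pooled df.
* The DE-in-contrast-A restriction is applied before BH adjustment of the
  dependence families, keeping each family's FDR interpretable over the
  genes actually under consideration.
* Enrichment q-values from the pipeline are computed over the supplied
  collection only; no attempt is made to emulate proprietary pathway scores
  (activation z-scores, upstream regulators).

## Limitations

* Two-group contrasts only: no covariates, batch terms, or multi-factor
  designs, and no count-model (NB GLM) inference — moderation operates on
  log-normalized values.
* The dependence test treats the two contrasts as independent; if both
  contrasts shared control animals the combined SE would be wrong.
* The min-t null assumes central t marginals, i.e. correct per-contrast
  calibration; miscalibrated DE statistics propagate into the independence
  calls.
* With `attenuation_B` near 1/factor the dependent and boundary hypotheses
  coincide and power for the dependent call drops toward the nominal level,
  as it should.
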