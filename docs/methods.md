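# Methods

## Problem and model

`splicemod` tests whether the inclusion level of a cassette exon in a
candidate modulator protein M changes the regulatory relationship between a
transcription factor F and a target gene T. The observable signature is a
change in the F–T expression association between cohort samples with low
and high inclusion of M's exon.

Samples are ranked by M's PSI (Ψ, percent spliced in) and the bottom and
top `strat_frac` fraction form the low and high strata (`⌊frac·n⌋` samples
each; ties broken by stable input order; samples with missing Ψ excluded).
The tested statistic is the change in within-stratum Spearman correlation

    γ = ρ_high − ρ_low ∈ [−2, 2].

Spearman correlation is used because cohort expression values are heavily
skewed and the association of interest is monotone, not linear. γ is
antisymmetric under exchanging the strata.

For interpretation, an ordinary least-squares fit over the included
(low ∪ high) samples provides coefficients on a pinned scale:

    T = α₀ + α_f·F + β_f·m + β_m·(F·m) + ε,

with m the 0/1 high-stratum indicator and F, T log₂(x+1)-transformed and
z-scored over the included samples of that triplet. Under this
parameterization α_f is the F→T association at low inclusion (the
*unmodulated activity*: activation if significantly positive, inhibition
if significantly negative, inactive otherwise), α_f + β_m the association
at high inclusion (the *modulated activity*), and β_m the interaction —
the amount of modulation on the regression scale. Because ranks are
invariant to monotone transforms, the log transform affects only the
regression coefficients, not γ.

Assumptions worth stating: the modulator acts through a threshold-like
contrast between low- and high-inclusion states (a stratified model, not a
continuous dose–response); expression and PSI are measured on the same
samples; and candidate (F, T) pairs come from an external relation list
that is treated as given, not inferred.

## Significance and calling

γ's null distribution is generated by permutation: stratum labels are
shuffled among the included samples B times (`n_perm`, default 999) and

    p = (1 + #{b : |γ*_b| ≥ |γ_obs|}) / (B + 1),

the standard add-one two-sided permutation p-value, which is never zero
and is exact under exchangeability of labels given no modulation.
Benjamini–Hochberg adjustment is applied across the full candidate batch
(all events × pairs in one run, not per TF), and triplets with
q ≤ `fdr` (default 0.05) are called. Note the resolution limit: with C
candidates the smallest attainable q is C/(B+1), so B must grow with the
candidate count for the FDR threshold to be reachable at all.

Sign significance for classification uses, at nominal level `alpha_sign`
(default 0.05): the permutation p-value for γ; the within-stratum Spearman
test p-values for α_f (low stratum) and α_f + β_m (high stratum), since on
monotone data sign(α_f) = sign(ρ_low) and the stratum correlation is the
direct evidence about the activity's sign; and the asymptotic OLS t-tests
for β_f and β_m.

## Classification

Each called triplet's pattern of significant signs over
(γ, α_f, β_f, β_m, α_f+β_m) is matched against the six-category constraint
table (see README). Blank cells are unconstrained. When several categories
match — the inversion rows strictly contain the attenuation rows — the
category satisfying the most constraints wins, with remaining ties
resolved by specificity: inversion > enhancement > attenuation. A pattern
matching no row is `unclassified`; called-but-unclassified triplets are
reported as such rather than forced into a category. The
`strict_all_columns` flag (default on) enforces every non-blank column
including β_f; switching it off treats β_f as unconstrained for users who
regard that column as incidental.

"Inactive if zero" for α_f cannot hold exactly in floating point; it is
interpreted throughout as "not significantly nonzero".

## QC cascade

Event-side, in order: credible-interval filter → read-support filter →
median imputation → IQR filter. Gene-side: presence → CV. Comparison
strictness follows the wording each rule is usually stated with: CI width
passes strictly below `max_ci_width` (0.25) and the passing fraction must
strictly exceed `min_ci_frac` (0.95), with missing intervals counting as
failures; read support is inclusive (≥ `min_reads`, 10); the
post-imputation PSI IQR must strictly exceed `min_iqr` (0.1); gene
presence must strictly exceed `min_present_frac` (0.95); the expression CV
keeps genes inclusively at ≥ `min_cv` (0.5). "CI" is taken to mean the
full interval width, not the half-width; the threshold is exposed in the
configuration should the other reading be wanted.

Medians, quartiles and the IQR use linear interpolation between order
statistics (recorded in the filter report metadata); the CV uses the
sample standard deviation (ddof = 1) over observed values on the raw
scale, and a gene with mean zero is dropped. Imputation precedes the IQR
filter deliberately — filling missing entries with the event median
shrinks the spread, so the order is observable and is asserted by a test.

## Synthetic cohorts

The generator emulates the statistical structure the inference stage
consumes, so every pipeline stage is testable without cohort access:

* **PSI measurements.** True inclusion ψ ~ Beta(a, b) per sample (default
  Beta(2, 2): mean 0.5, ample variability so the IQR filter is passed);
  read depth ~ Poisson(`read_depth_mean`, default 1000); inclusion reads ~
  Binomial(depth, ψ). The reported Ψ is the Beta(inc+1, depth−inc+1)
  posterior mean and the credible interval its central 95% region —
  interval width therefore shrinks with depth, reproducing the
  depth-dependence the CI filter keys on (depth 1000 passes it, depth ~5
  fails it). A `missing_frac` (default 0.02) of entries is masked
  uniformly at random; the default is deliberately below the 5% level at
  which missingness alone would sit on the strict >95% CI-pass boundary.
* **Expression.** TFs and null targets are log-normal with coefficient of
  variation `expr_cv` (default 1.0, comfortably above the 0.5 gene
  filter). Planted targets follow the model equation on the log₂ scale,
  with m the *true*-ψ top-tertile indicator and F_z the z-scored log₂ TF
  expression, plus N(0, `noise_sd`) noise (default 0.05); values are
  mapped back through 2^y − 1 with baseline α₀ = 8 so they are positive
  and the log₂(x+1) fitting transform recovers y exactly. Planting on the
  fitting scale makes coefficient recovery a sharp test.
* **Generation order.** One generator stream, ordered events → genes →
  per-planted noise, with planted targets overwriting their null draws:
  adding planted triplets never changes the events or TF draws for the
  same seed.

Inference stratifies by *estimated* Ψ while generation uses true-ψ
tertiles; the residual mismatch at depth 1000 (posterior error ≈ 0.016)
is deliberate realism and slightly attenuates recovered effects.

Default planted effect sizes per category were chosen from the sign
algebra, fixed once: attenuation fully cancels the unmodulated activity
(α_f = ∓1, β_m = ±1, so the modulated activity is null rather than merely
smaller — the cleanest attenuation pattern); enhancement starts from a
weak same-sign activity (α_f = ±0.05, β_f = ±0.4, β_m = ±1.4), so ρ_low
has a stable, genuinely significant sign instead of a coin-flip one;
inversion flips a strong activity (α_f = ∓0.8, β_f = ±0.3, β_m = ±1.6).
All satisfy |β_m| ≥ 0.8, and all keep the planted target's expression CV
above the 0.5 gene filter. `PlantedTriplet` validates at construction that
user-supplied effects realise their category's sign pattern.

What the generator does **not** emulate: correlated expression beyond the
planted relations, batch effects, PSI–expression coupling of the modulator
gene itself, cohort-specific distributions, or read-level artifacts.
Passing the synthetic benchmarks therefore demonstrates correctness of the
statistical machinery under its own assumptions, not performance on any
particular cohort.

## Benchmarks and problem sizes

Two standing benchmarks, both at n = 300 samples, depth 1000,
noise_sd = 0.05, B = 999, over 20 seeded repeats:

* **Category recovery** — one planted triplet per category among 240
  candidates (234 null): all six must be called at q ≤ 0.05 with the
  correct category in ≥ 90% of repeats.
* **False-discovery control** — 20 planted (cycling the categories) among
  200 candidates (10% planted): the false-discovery proportion among
  called triplets must stay at or below the 5% calling threshold plus a
  binomial 95% Monte-Carlo margin. With ~90% null candidates the expected
  proportion under Benjamini–Hochberg is ≈ π₀ · q ≈ 4.5%, so individual
  repeat sets fluctuate on both sides of 5% within the margin.

These sizes keep a full benchmark run to roughly a minute per 20-repeat
sweep on one CPU while leaving the permutation resolution (min q =
240/1000 · 1/rank) adequate for the planted effects.

## Numerical choices

* The permutation path ranks with ordinal (stable double-argsort) ranks
  vectorised over all permutations, while the observed statistic uses the
  standard Spearman implementation with average ranks; the two agree
  exactly on tie-free data, which continuous expression values are almost
  surely. A 10⁻¹² tolerance in the ≥ comparison guards against one-ulp
  differences between the two code paths.
* Included samples are taken in sorted-sample-name order before the
  permutation stream is drawn, so p-values are invariant to the column
  order of the input matrices. Per-event permutation streams are spawned
  from the run seed, so results do not depend on which pairs are tested.
* TSV writers emit shortest round-trip decimal representations and readers
  parse with round-trip precision: write-then-read reproduces every float
  bit-for-bit, which the determinism guarantee (byte-identical triplet
  tables for identical config and seed) relies on.
* Degenerate cases: a stratum in which F or T is constant yields a flagged
  fit and the triplet is skipped with a reason; an event whose PSI is
  missing everywhere is an error naming the event; an empty PSI profile
  flows through QC with zero counts and no error.

## Known limitations

* The stratified two-group contrast discards the middle tertile and any
  dose–response shape within strata.
* FDR is controlled over the tested batch; selecting candidates by prior
  screens outside the package changes the multiplicity interpretation.
* The regression p-values for β_f and β_m are asymptotic and assume
  homoscedastic residuals; on noiseless constructed data they degenerate
  (zero residual variance), which the tests treat as exact-fit cases.
* Modulator events are identified by coordinates only; mapping events to
  host genes (for gene-level modulator counts) requires a user-supplied
  event→gene table.
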