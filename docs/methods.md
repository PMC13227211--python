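# Methods

## The experiment being modeled

A genetically targeted proximity-labeling experiment biotinylates
proteins within a few tens of nanometers of a single promoter (a
catalytically dead Cas9 fused to an engineered peroxidase, steered by
guide RNAs tiling the promoter). After streptavidin capture and
on-bead digestion, peptides from all conditions are barcoded with
isobaric TMT reagents and quantified in a single MS run. The design
analyzed here multiplexes sixteen used channels of an 18-plex:

- three guide RNAs (g1/g2/g3) x three biological replicates — the
  on-target conditions, treated as pseudo-technical replicates of the
  same promoter;
- NoG+ x3 — labeling with no guide: the untargeted-labeling
  background, the reference for the enrichment contrast;
- NoG- x3 — no labeling at all: endogenous-biotin and bead background,
  the reference for the contaminant filter;
- one pooled-sample channel (detection reference only, never used in a
  contrast) and two empty channels.

## Quantification model

Grouped protein abundances (reporter-ion rollups) are overdispersed
counts; their log2 transform is approximately normal. The pipeline:

1. **Median normalization.** Each channel is scaled multiplicatively so
   its median equals the mean of the original per-channel medians.
   Using the mean of medians (rather than 1.0) as the reference keeps
   the data on their native scale, so linear-space standard errors
   remain interpretable. The operation is idempotent and
   rank-preserving within channels.
2. **Detection filters.** Proteins never quantified in any channel are
   removed, then proteins lacking at least one value in each of the
   four reference groups (NoG-, NoG+, pooled gRNAs, sample pool) —
   those would produce undefined ratios. Missing values are never
   imputed; they are informative (low-abundance proteins near the
   detection limit) and the generator models them as
   missing-not-at-random.
3. **Condition summaries.** Per protein: mean and SEM (sample SD /
   sqrt(n)) over the contributing channels of each condition. For the
   pooled on-target condition the default pools all contributing
   channel values (up to nine; `sem_pooling_rule =
   per_channel_values`), maximizing degrees of freedom; the
   alternative `per_gRNA_means` first averages biological replicates
   within each gRNA and then summarizes the three gRNA means. Both
   give identical means on balanced data and are switchable because
   the pooling order is a genuine free choice of the design.
4. **Delta method.** The log2 transform carries its uncertainty
   through the first-order propagation `sem_log2 = sem_y / (y ln 2)`.
   This is accurate to well under 10% relative error while
   `sem_y / y <= 0.1` (verified against Monte Carlo in the tests); it
   degrades for noisier proteins, a known limitation of first-order
   propagation.

## Enrichment calling

For a contrast of two summarized conditions, `x` is the difference of
log2 means, `sigma_x = sqrt(sem_a^2 + sem_b^2)`, `Z = x / sigma_x`,
and p is the two-tailed standard-normal tail of |Z|. The linear fold
change is `2^x`.

- **Contaminant list** — NoG- versus the pooled labeling conditions
  (all gRNA channels plus NoG+). Proteins enriched in NoG- at
  FC > 1.2 with Bonferroni-adjusted p < 0.05 are background
  (bead-binding or endogenously biotinylated) and are removed.
  Family-wise control is deliberately strict here: a false positive
  on this list throws away a real signal.
- **Enrichment call** — pooled on-target versus NoG+, over the
  post-contaminant universe. Storey's q-value is computed with
  pi0 = #(p > lambda) / (n (1 - lambda)) at lambda = 0.4, clamped
  into (1/n, 1]; q-values follow the step-up recursion
  `q_i = min(pi0 n p_i / rank_i, q_{i+1})` with tied p sharing the
  larger rank. A protein is enriched when FC > 1.2 and q < 0.05; the
  FC-only set (ignoring q) is reported alongside, since
  near-threshold proteins can still be biologically real. Depletion
  is reported but never called enriched. Exact-zero p-values are kept
  for inference and replaced by the smallest nonzero p only in the
  volcano-plot reporting column.

### Degenerate contrasts

A protein whose combined SEM is exactly zero with a nonzero difference
has an infinite Z. It is assigned p = 0, flagged `excluded`, and a
warning is logged; calling logic treats it as deterministically
significant (with zero noise, any nonzero fold change is infinitely
many standard errors from zero). This keeps the noise-free limit
consistent: on zero-noise synthetic data the enriched set equals the
true on-target class exactly. Proteins with a single contributing
value on either side have an undefined SEM and are excluded from
inference with NaN statistics.

### Known statistical limitation

The p-value uses the standard normal although `sigma_x` is estimated —
for the NoG+ reference from only three channels. The statistic is
therefore t-like with a Welch-Satterthwaite effective df near 3.5, and
its normal-tail p-values are anti-conservative: on a pure-null
simulation about 12% of proteins reach p < 0.05 and the q-value filter
admits dozens of false calls per 5000 proteins. This is a property of
the method itself, faithfully implemented (no small-sample t
correction is applied); the FC > 1.2 filter removes some but not all
of the inflation. The acceptance suite contains a calibration test
that documents the failure rather than hiding it; users wanting
calibrated error control at three replicates should prefer moderated
or permutation statistics, which are out of scope here.

## Class enrichment

The fraction of a curated class (TFs, spliceosome components) among
the enriched proteins is compared against the full inferred-protein
universe via a 2x2 contingency table and the plain Pearson chi-square
(no Yates correction; the tables are large). The enriched set is a
subset of the universe, so the margins are not independent samples;
the table is built exactly as described and this caveat is inherited
from the procedure itself.

## Binding-matrix concordance

Binary TF x locus occupancy (reproducible ChIP-Seq peak or not) is
analyzed with Cochran's Q,

    Q = k (k-1) * sum_j (G_j - N/k)^2 / sum_i x_i (k - x_i),

with loci in columns (totals `G_j`), TFs in rows (totals `x_i`), `N`
the grand total, referred to chi-square with k-1 df. Fully concordant
rows drop out of both numerator deviation and denominator; a matrix
with no discordant rows is reported as Q = 0, p = 1. Follow-up
pairwise McNemar tests use (b-c)^2/(b+c) on the discordant counts
without continuity correction, Bonferroni-adjusted over the pairs in
the analyzed panel (15 pairs for six loci; 10 when a no-binder locus
is dropped). An all-zero locus column is kept in the proportions but
excluded from Q/McNemar when requested, and the pipeline reports both
panels.

Detection-versus-binding 2x2 tables use the margin-product expected
overlap and a two-sided Fisher exact test (verified against exhaustive
hypergeometric enumeration for small tables). "Detected by MS"
defaults to quantified-or-identified (detected-not-quantified TFs
count as detected) with a switch, since the three-state detection
classification leaves that boundary open. Expression (log2(TPM+1))
stratified by detection and binding status is compared with two-sided
t-tests, Welch by default (a `pooled` variance option exists; which
variant the original analysis used is not stated), Bonferroni-adjusted
over the family of comparisons in the run.

## qPCR quantification

ChIP enrichment over an off-target reference locus is 2^-ddCt with
ddCt = chip(Ct_target - Ct_ref) - adjusted input(Ct_target - Ct_ref).
The diluted input aliquot is normalized to 100% by subtracting
log2(dilution / input_fraction) cycles (9.966 for a 10x dilution of a
1% input). Quadruplicate wells are averaged on the Ct scale first,
then multiple target primer pairs within a replicate; replicate fold
changes are averaged on the linear FC scale (not the ddCt scale) and
reported as mean +/- SEM over the flat replicate list (biological x
technical treated as n values, matching how such assays report n = 6).

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
study conditions for all calibration and recovery tests and were fixed
once:

| parameter | default | why |
| --- | --- | --- |
| n_proteins | 5000 | order of the quantified proteome in a deep TMT run |
| frac on-target / background / contaminant | 0.05 / 0.10 / 0.10 | minor signal class against a dominant null background |
| effect sizes (on-target, background, contaminant) | 2.0 / 2.0 / 4.0 | modest promoter enrichment; strong bead background |
| nb_mean, nb_dispersion | 2e5, 2.0 | heavy-tailed grouped abundances (variance mu + mu^2/k) |
| channel_bias_sd | 0.2 (ln scale) | labeling/loading bias removed by median normalization |
| replicate_noise_sd | 0.25 (ln scale) | ~25% CV per channel value |
| missing_midpoint, missing_slope | 5000, 1.0 | a few percent missingness, concentrated at low abundance |

Mechanics: baseline ~ NB(mean, k); on-target effect applies in gRNA
channels only, background effect in all labeling channels, contaminant
effect in NoG- channels (for the contrast, excess without labeling is
indistinguishable from depletion under labeling, so only the ratio
matters); per-channel lognormal bias; per-cell lognormal noise; the
pool channel is the mean of all sample channels before missingness;
each cell goes missing with probability logistic in -log2(abundance).
Proteins with every cell missing may still carry an identified flag —
the detection limit sits four-fold below the quantification midpoint —
so the detected-but-not-quantified state exists. A single global seed
is split into named substreams per operation (abundance / binding /
expression / ct), so any stage can be re-run reproducibly on its own.

Binding matrices use a Gaussian copula: a per-TF latent propensity
shared across loci with latent correlation `tf_concordance` induces
within-row association while column means converge to the requested
locus probabilities. Expression-coupled detection draws lognormal TPM
values and assigns quantified / detected-not-quantified / undetected
through two logistic thresholds sharing the slope (margin 1.5 between
identification and quantification), so the saturation limit quantifies
everything and a zero slope decouples detection from expression. Ct
tables are constructed so the noise-free ddCt equals -log2(true fold
change) for any dilution/input-fraction combination, with two target
primer pairs at opposite fixed offsets and quadruplicate wells to
exercise the averaging steps.

What the generator does **not** model: peptide/PSM-level structure,
reporter-ion ratio compression and isotopic impurity, protein-inference
ambiguity, batch effects beyond a per-channel scalar, and correlation
between proteins. Passing tests therefore validate the statistical
machinery under the stated model, not robustness to those real-data
phenomena.

## Numerical and design choices

- pi0 clamped into (1/n, 1]: the estimator can exceed 1 or reach 0 on
  finite data; clamping keeps q-values defined. Clamps are logged.
- Storey tie handling: tied p share the maximal rank (the standard
  step-up convention); at pi0 = 1 the q-values coincide with
  Benjamini-Hochberg (cross-checked against statsmodels).
- The Storey universe is the post-contaminant protein set, matching
  the narrative order of the analysis (filter, then test).
- Contaminant-contrast reference = mean over all twelve labeling
  channel values with SEM over contributing values, parallel to the
  on-target pooling rule.
- File dialect: TSV, UTF-8, "." decimal, empty cell = missing. The
  original analysis lived in spreadsheets whose exact export formats
  are unknown; this dialect is this package's convention.
- Identifiers are opaque strings matched exactly; locus names are
  labels (no coordinate arithmetic).
- Outputs are a pure function of (inputs, config, seed): no
  timestamps; one seeded RNG stream per generator operation.

## Problem sizes used in the test suite

Regular tests run seconds-scale reductions (hundreds of proteins, tens
of replicate reruns). The acceptance tests use the full stated sizes:
the pure-null experiment at 5000 proteins x 100 repetitions, Cochran's
Q size calibration on 1000 null 218 x 6 panels, 200,000-draw Monte
Carlo for the delta-method check. The whole suite completes in well
under a minute on one CPU.

## Known limitations

- Normal-tail p-values at three replicates are anti-conservative (see
  above); the published-style q < 0.05 hit lists should be read as
  ranked candidates, not calibrated discoveries.
- The chi-square class test treats the enriched set and the universe
  as independent margins, which they are not.
- The delta method is first-order; for proteins with sem/y > ~0.3 the
  propagated log-scale SEM is biased.
- The qPCR model assumes perfect primer efficiency (no standard-curve
  correction) and treats biological x technical replicates as a flat
  sample when forming the SEM.
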