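# Methods

This note documents the models, conventions and design choices behind
`phycotad`: what each stage computes, what the synthetic generator does and
does not emulate, and where genuinely open choices were resolved.

## Abundance normalization

RPKM is `reads / ((length_bp/1000) · (total_mapped/1e6))`; relative
abundance divides each sample's RPKM column by its sum over the MAGs
present in the input table.  Whether the denominator should span the whole
MAG catalogue or only the taxa under study is a per-figure choice in
practice; the default here is *all MAGs in the input table*, and callers
can subset the table first to get any other convention.

**Zero handling before log transforms.**  The CLR transform is undefined at
zero.  Default: multiplicative replacement (via scikit-bio) with
δ = 0.5 × the smallest nonzero relative abundance in the matrix; a plain
pseudocount strategy is selectable.  The same replacement feeds the log10
profiles used for pattern clustering.  The choice is recorded in the
output header of `abundance_clr.tsv`.

**Pattern clustering.**  Profiles are log10 relative abundances; pairwise
distances are Canberra; linkage is Ward on distances, which reproduces the
R `hclust` method `ward.D2` (Ward's criterion on squared distances).  The
tree is cut at k = 2 and the cluster with the higher mean relative
abundance is labelled *persistent*; an exact tie is broken toward the
cluster containing the single highest relative-abundance value, which
makes the labelling deterministic.

## RDA and the permutation test

RDA is multivariate least squares of the column-centred response matrix
(samples × CLR abundances) on the column-centred predictors (samples ×
Hellinger diatom proportions): R² = SS_fit/SS_total pooled over response
columns, adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), pseudo-F =
(SS_fit/p)/(SS_res/(n−p−1)), canonical axis variances are eigenvalues of
the fitted-value covariance.  Collinear predictor columns are dropped by
pivoted QR with a warning; adjusted R² is reported missing when
n ≤ p + 1.  The unit test suite holds this implementation against an
independent normal-equations + eigendecomposition oracle at 1e-8.

The significance test permutes rows of Y (the unrestricted, "ANOVA-like"
scheme), recomputes the pseudo-F, and applies the add-one rule
`p = (1 + #{F* ≥ F}) / (n_perm + 1)`; SS_total is permutation-invariant,
so only SS_fit is recomputed (through a QR factor of X, once).  The test
requires a seed and records it in the output.  RDA runs **per year** by
default, since bloom–community coupling is a within-season phenomenon and
pooling years would confound inter-annual turnover with diatom response;
a pooled call is available by passing the full matrices directly.

## Correlation screen and classification

Spearman rho uses average ranks; p-values are exact (full permutation
enumeration) for n ≤ 9 without ties and the t-approximation otherwise.
Correlations are computed across **all samples pooled over years** by
default: per-year series (12–13 points) are short, and the biological
claim — a MAG tracks a host species — should hold across blooms.  A
per-year mode is available by subsetting columns.  The exact pairing of
samples used by any particular real-data analysis can differ; both modes
exist precisely because this is ambiguous in practice.

No multiplicity correction is applied to the correlation screen: the
classification rule uses raw p < 0.05, deliberately, because the screen
feeds a conservative conjunction (a MAG must *also* be in the fluctuating
cluster).  Users screening many MAGs for standalone inference should
correct.  The observation that recovered colonizer correlations tend to be
strong (rho > 0.5) is treated as a property of the data, not a filter; a
`min_rho` argument reproduces it as a filter if wanted.

Classification: colonizer ⇔ (∃ species with significant positive rho) ∧
(cluster = fluctuating).  Generalists carry the first matching rationale in
the fixed order `PERSISTENT` → `NEG_ONLY` → `NO_SIG`, so rationale codes
partition the generalists deterministically.

## Enrichment

Fisher's exact test is two-sided by the minimum-likelihood convention
(sum of hypergeometric table probabilities ≤ the observed table's) —
stated explicitly because two-sided conventions differ between packages.
Mann–Whitney uses the exact U distribution when the pooled size is ≤ 12
without ties, else the normal approximation with tie correction.  The
correction method is Benjamini–Hochberg by default (Bonferroni and none
selectable); a *passing* feature needs corrected p < 0.05 **and** strict
> 50 % prevalence in the enriched group — applied to the enriched group
only, the less restrictive reading of a within-group prevalence filter.

The occurrence criterion (> 70 % of colonizers, < 20 % of generalists,
both strict) bypasses p-values entirely: with 14 vs 19 genomes no single
feature may survive correction, yet a coherent block of colonization genes
can still satisfy the criterion — that is the regime it is designed for.

## Metaproteome quantification

Hit filtering is strict at both thresholds (identity > 99, e-value
< 1e-10) and excludes any protein whose passing hits touch ≥ 2 distinct
MAGs; hits to multiple contigs of the *same* MAG are kept (subject ids of
the form `mag|contig` are resolved at the MAG level).  %NSAF is the
standard length-normalized spectral count share × 100; the formula is the
convention of the metaproteomics literature rather than something this
package innovates.  Category cells are **sum-then-log**: %NSAF summed over
the proteins of a category/year/phase/order cell, then log10 — recorded in
the output metadata since the opposite order (log-then-sum) is not
equivalent.  Cobalamin biosynthesis counts only terminal-pathway enzymes
(adenosyltransferase MMAB/pduO, CobW); the KO→flag map ships as an
editable TSV resource and unmapped KOs get no flags.

## Tad locus scoring

The canonical reference is the 14-gene cluster
`flp1 flp2 tadV rcpC rcpA rcpB tadZ tadA tadB tadC tadD tadE tadF tadG`,
with 12 essential genes (all but *flp2*, *rcpB*) and the synonym map
cpaA→tadV, cpaB→rcpC, cpaC→rcpA, cpaE→tadZ, cpaF→tadA.  *rcpB* is counted
like any other gene for completeness, despite its uncertain essentiality
in the reference organism — discounting it would silently change the
14-gene denominator.

Detection is **annotation-based** (symbol and product-string matching,
case-insensitive, against a shipped and user-extensible regex resource),
not sequence search; an `external_hits` hook accepts a table from users
who run their own HMM/BLAST searches.  Completeness: `complete` = 14/14,
`near_complete` = ≤ 2 genes missing (configurable `near_gap`), `partial`
otherwise, `absent` = 0.  The near-complete threshold is configurable
because published gene-map figures have labelled loci missing anywhere
from 1 to 5 genes as "near-complete"; with `near_gap=5` that more
permissive reading is reproduced.  Contiguity reports the largest run of
canonical genes on a single contig with inter-gene gaps ≤ 10 kb (default).
Feature tallies are normalized per coding sequence; group contrasts use
pooled-variance Student's t by default (Welch optional) on the per-CDS
rates.

## The synthetic generator

The generator's defaults are the study conditions of the analysis: 38
samples split 13 + 13 + 12 over three spring blooms, 8 diatom species,
19 generalist and 14 colonizer MAGs, 2 × 10⁶ mapped reads per sample,
log-scale noise sd 0.3, tad prevalence 0.857/0.105
(colonizers/generalists), *luxI* prevalence 0.714/0.316, and an expected
85 % generalist share of transport protein expression.

* **Diatoms** follow Gaussian bloom curves in time on the count scale
  (the simplest unimodal bloom shape), with one or two dominant species
  per year whose amplitudes (~5·10⁵ cells/L at peak vs ~10⁴ background)
  guarantee dominance at the realized bloom peak; dominance rotates
  across years.  Count magnitudes are free parameters chosen at
  coastal-spring-bloom scale; no real dataset fixes them.
* **Recruitment**: generalist latent abundance is a persistent lognormal
  baseline × lognormal noise; colonizer latent abundance is affine in the
  (normalized) host diatom counts × noise — linear coupling keeps the
  planted correlation analytically controllable.  Reads are multinomial
  over MAGs (probability ∝ latent × genome length) at exactly the
  configured depth, so per-sample column sums are fixed.  At
  `noise_sd = 0` the generator returns exact expected read counts rather
  than integerized draws: the zero-noise limit is the analytic limit, and
  planted colonizer–host correlations are exactly 1 there.
* **Gene content**: tad blocks are planted as contiguous 14-gene runs
  (single contig, gaps < 2 kb) in exactly `round(prevalence × n)` members
  of each group (the configured prevalences are rational counts, so
  rounding realizes them exactly); about half the planted blocks use
  *cpa* synonyms to exercise the synonym map.  *luxI* carriers are chosen
  the same way; chemotaxis (0.85/0.55), motility (0.95/0.95) and *luxR*
  (0.8, with Poisson multiplicity) are Bernoulli; 235 features are planted
  in every MAG as a core-genome stand-in and 200 background features get a
  shared per-feature rate in U(0.15, 0.85) for both groups.
* **Proteome**: spectral counts are Poisson with rates proportional to
  source-MAG relative abundance; colonizer transport emission is rescaled
  so the *expected* generalist transport share equals the configured
  value; each protein gets one true hit (identity 99.2–100, e-value
  ≤ 1e-31) plus, at configured rates, a low-identity decoy (filtered by
  the identity rule) or a second passing hit to another MAG (planted
  ambiguity, excluded by the multi-MAG rule).  Cobalamin-biosynthesis
  markers are emitted by exactly four MAGs; all simulated MAGs are
  Rhodobacterales, and cobalamin *transport* proteins are absent from
  them by construction.
* **Determinism**: every operation draws from its own child RNG stream
  keyed on (config seed, operation name), so each simulator is
  independently reproducible and a given seed yields byte-identical
  output files regardless of call order.  Each written file records the
  seed in a header comment.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level sequence error and mapping bias,
assembly/binning artefacts and genome incompleteness correlated with
abundance, compositional interactions with the unmodelled remainder of the
community (the simulated MAGs are the whole denominator), diatom count
measurement error structure, spectral-search FDR, and taxonomically
structured annotation error.  Recovery results on synthetic data are a
correctness check of the pipeline's logic under its own assumptions, not a
field-performance estimate.

## Problem sizes and numerical conventions

Validation uses desk-scale problems: oracle equivalence on 50 random
20 × (3, 10) RDA problems at 1e-8; permutation-test calibration over 200
null datasets (n = 12, p = 2, n_perm = 199); exact-test oracles by full
enumeration (group sizes ≤ 8 for Fisher, ≤ 6 + 6 for Mann–Whitney);
classifier recovery over 20 seeded default datasets; null enrichment
calibration over 20 × 200 Bernoulli features.  Normalization invariants
(relative-abundance columns sum to 1, CLR samples to 0, %NSAF samples to
100, Hellinger rows to unit sum of squares) are enforced at 1e-9.

Known limitations: the per-year RDA runs 8 predictors against 12–13
samples, so single-year permutation tests are honestly low-powered
(roughly one marginal year in three datasets is expected at default
noise); hierarchical cluster labels are only meaningful when both
abundance regimes are present; and annotation-based tad detection inherits
the vocabulary of the upstream annotator — loci annotated with
nonstandard product strings need either the regex resource extended or an
external hit table.
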