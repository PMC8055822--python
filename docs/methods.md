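# Methods

## Ratio model

All quantities are log2 ratios of SILAC channel intensities. The
source tables never state a log base, but the knockout-over-wild-type
column equals the difference of the two per-strain columns, which
fixes a log scale; log2 is the SILAC field convention and is set in
exactly one function (`design.log2_ratio`).

A **shift ratio** for strain *s* is the arithmetic mean over
biological replicates of log2(I_malate / I_glucose), where both
channels must come from the same SILAC mix (the same MS run), so the
ratio is free of run effects. Replicates where either channel is
missing contribute nothing; a site quantified in a single replicate is
kept and carries `n_replicates = 1`, since the reference tables do not
annotate replicate counts. The **delta** statistic is the knockout
shift minus the wild-type shift, always computed at full precision;
two-decimal half-away-from-zero rounding is applied only when writing
reports.

Missing intensities are represented explicitly (absent slot / NaN),
never as zero; any operation needing a missing channel yields missing,
never an exception. Phosphosite positions are 1-based on the protein
sequence.

**Common-reference integration.** The wild-type/glucose Lys0 channel
appears in every mix. Within one experiment the identity
log2(H/L) − log2(M/L) = log2(H/M) holds exactly on noiseless data
(tested to 1e-9), which is what makes ratios composed through the
reference interchangeable with direct ones. `integrate_experiments`
joins per-experiment tables on (protein, position, residue) and treats
a duplicated (analyte, experiment, replicate, channel) slot as a hard
error.

## Thresholds and calls

* **Differential proteome.** Per strain axis, mean and *population*
  SD (ddof = 0) over finite shifts; a protein is called at or beyond
  mean ± 2 SD. Population SD and the inclusive boundary follow the
  convention that the cutoff describes the observed distribution
  rather than estimating a larger one. Adding a constant to an axis
  moves the cutoff with it, so calls are translation-invariant. A
  protein beyond the cutoff on both axes is assigned the axis with the
  larger standardized excursion.
* **Phosphosite scenarios.** Default `sd_based` mode reuses the same
  2-SD convention on the delta distribution about its mean — the only
  cutoff convention the source analysis states. `fixed` mode
  (threshold in log2 units, default 1.0) exists for small worked
  examples where a 36-row SD is dominated by one extreme site. Ties at
  exactly |delta − mean| = t are `independent` (strict inequality), so
  the t → 0 limit is well defined. Classification is equivariant under
  swapping the strain labels (direct ↔ indirect).
* **Localization filter.** Sites need localization probability ≥ 0.75
  (the class-I convention; the source states only that sites were
  localized) before classification; configurable.
* **Wild-type-only sites.** "No longer phosphorylated at all" is
  operationalized as *zero detections* across all knockout channels
  and replicates — not low intensity — together with detection of the
  wild type in both conditions and a computable WT shift (at least one
  replicate with both WT channels). Sites detected in both WT
  conditions only in disjoint replicates have no within-run ratio and
  are skipped with a warning.

## QC

* **Incorporation**: labeled / (labeled + unlabeled) per analyte,
  summarized per (experiment, channel) by the median; a channel passes
  at ≥ 0.94 (inclusive) and a failing channel is meant to be excluded
  wholesale. The spectral estimation of incorporation is upstream;
  this module consumes intensity pairs.
* **Mixing check**: median per-analyte log2 ratio between two
  channels; |median| ≤ 0.5 log2 (≈1.4-fold) passes. The source states
  only that a mixing check was done; the tolerance is this package's
  choice and is configurable. Fewer than 10 shared analytes →
  flagged insufficient, verdict undefined.
* **Replicate correlation**: Pearson r on complete pairs (≥ 3), zero
  variance flagged rather than raised.

## Enrichment

Per GO category (the three ontologies are separate families), every
term with at least one annotated background gene is tested with the
two-sided Fisher exact test: the sum of hypergeometric probabilities
of all same-margin tables no more probable than the observed one. The
implementation sums `scipy.stats.hypergeom` mass with a 1e-9 relative
tie tolerance (so mathematically equal-probability tables are included
despite float noise); the test suite checks it against an exact
rational-arithmetic enumeration (to 1e-12) and against
`scipy.stats.fisher_exact`. Bonferroni (p×m per category) is the
default correction — the named procedure in the source, which
conflates "Bonferroni" and "FDR" — with Benjamini–Hochberg available
as an option. Direction is `over` iff fold > 1. The background is the
detected proteome, not the genome. Annotations are used as given (no
GO-graph ancestor propagation); a propagated annotation can be
supplied externally if wanted.

GAF 2.x parsing is a straightforward 17-column TSV read (aspects
P/F/C mapped to the three ontologies, keyed by object symbol,
deduplicated); no annotation-toolkit dependency is needed for this.

## Synthetic data generator

The generator emulates the study design so the pipeline is fully
testable offline. What it models:

* two mixes with the shared WT/glucose Lys0 reference, biological
  duplicates (`replicates = 2`);
* log-normal base abundances (log2 mean 20, SD 2 — typical orbitrap
  intensity scales; no distribution is given in the source, so these
  are scenario choices);
* true WT shifts ~ N(0, `base_shift_sd` = 1.0); knockout protein
  shifts add N(0, 0.3) strain dispersion;
* planted site scenarios with fractions direct 0.05 / indirect 0.10 /
  wt_only 0.12 (roughly the published class sizes relative to 127
  sites); direct subtracts `effect_log2` (2.0) from the knockout
  shift, indirect adds it, wt_only deletes every knockout channel;
* per-cell log-normal channel noise 2^N(0, `noise_sd` = 0.25) and
  missing-completely-at-random dropout at `missing_rate` = 0.1;
* residue classes S/T/Y at 0.677/0.2831/0.0394 — the published
  proportions, which sum to 0.9995 as printed and are renormalized
  preserving ratios;
* a QC table whose incorporation fractions scatter (SD 0.005) around
  `incorporation` = 0.98;
* default scale `n_proteins = 1772`, mean sites per protein
  127/1772; `n_sites` can override with an exact site count.

One `numpy.random.default_rng(seed)` stream with a documented draw
order (protein abundances → protein shifts → site placement →
residues → positions → scenarios → site shifts → noise → missingness
→ QC) makes output byte-identical for identical parameters.

What it does **not** model: peptide-level effects (digestion, missed
cleavages, charge states, co-isolation), intensity-dependent
missingness (an MCAR mechanism only), ratio compression, or
correlated noise across sites of one protein. Passing recovery tests
therefore demonstrates correctness of the ratio algebra and the
classifier's discrimination under the stated noise model — not
robustness to every artifact of real MS data.

**Printed-table inversion.** `invert_printed_table` turns published
shift columns into noiseless intensities: reference channels pinned at
1000, shifted channels scaled by 2^shift, single replicate, knockout
channels omitted for wild-type-only rows. This makes the published
tables usable as exact end-to-end fixtures; the transcribed tables
ship as package data. Recomputing delta from the two printed shift
columns matches the printed delta column exactly (at two decimals) for
the 26 self-consistent rows and within ±0.015 for the remaining 10,
which disagree in the source's own second decimal (printed-rounding
artifacts).

## Problem sizes in checks

The statistical test-suite checks run at sizes chosen for tight
binomial error at reasonable cost: residue proportions at 20,000
(unit) and 100,000 sites (acceptance script; binomial SE ≈ 0.15
percentage points on the serine fraction), classifier
sensitivity/false-call rates on ~1,500 sites with `missing_rate = 0`
so that discrimination is measured among quantifiable sites, Fisher
agreement on 500 random margins with N ≤ 60, and estimator bias at
replicates ∈ {2, 8, 32}.

## Known limitations

* Calls are *candidates*: nothing in a knockout comparison proves a
  direct enzymatic relationship (an activated intermediate kinase
  produces the same signature); validation is orthogonal work.
* The sd_based threshold is descriptive, not inferential — no p-value
  is attached to a site call, and a single extreme site inflates the
  SD it is judged against (visible on the 36-row reference fixture).
* Cross-experiment ratios through the common reference are exact only
  without noise; with noise they add the reference channel's variance.
* The wild-type-only rule is sensitive to missingness: a single
  stochastic dropout of all knockout channels fakes the class, and a
  single spurious knockout detection hides a true member. At the
  default 10% MCAR rate the chance that a site loses all four
  knockout observations (two channels × two replicates) by chance is
  1e-4, so the class is reliable at realistic missingness but not
  immune to it.
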