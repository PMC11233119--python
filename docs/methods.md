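# Methods

## Probe identity and mapping

An Infinium probe ID is a class code (`cg`, `ch`, `rs`; control probes are out
of scope) followed by decimal digits, optionally extended by `_` and a
4-character design suffix `[TB][CO][12][0-9]`: strand Top/Bottom, a
conversion designator (parsed and preserved, never interpreted — its exact
semantics are not fixed by the public naming convention), Infinium chemistry
(1 = type I, 2 = type II), and a single-digit replicate index.  The grammar is
isolated in one table (`probe_identity.SUFFIX_GRAMMAR`) so other dialects can
be registered.  All probe classes are treated uniformly by the parser.

Two probes are *replicates* when they share a prefix but differ in full ID.
Cross-platform mapping uses prefix equality as the sole criterion: a prefix
carried by *j* source and *k* target designs contributes all *j*·*k* pairs,
each initially flagged high confidence.  Source probes with no prefix match
on the target are absent from the mapping and become imputation candidates.
This makes mapping construction symmetric up to pair reversal, a property the
tests check against a quadratic double-loop oracle.

## Replicate aggregation

Aggregation is per sample, never pooled across samples, and missing readings
are skipped, never zero-filled.  Two strategies:

- **mean** — arithmetic mean of non-missing replicate betas; missing iff all
  replicates are missing.  Masked designs are included unless the caller opts
  out (`respect_mask`), since the mean is robust to a single poor design.
- **best_detection** — the beta whose detection *p*-value is smallest among
  unmasked replicates with a non-missing value.  Ties break to the
  lexicographically lowest probe ID (deterministic and platform-independent).
  If no replicate is eligible — all masked, or no *p*-values supplied for the
  group — the strategy falls back to the mean of non-missing values rather
  than dropping the CpG.

Output probes are the distinct mapped target IDs in lexicographic order; fan
out to replicate targets copies the source reading verbatim to each.

## Platform-bias filtering

Given paired experiments (identical samples on both platforms), a mapping
pair is high confidence iff |β_source − β_target| ≤ δ in at least *m*
experiments where both readings are present.  Defaults δ = 0.05 (inclusive
comparison) and *m* = 4.  Experiments missing either reading do not count
toward *m*; a pair observed fewer than *m* times is therefore flagged low
confidence — stricter than ignoring missingness, and logged.  The
high-confidence set is monotone in δ and anti-monotone in *m*, properties the
suite verifies over random thresholds.

## Tissue-reference imputation

The reference panel stores per-tissue, per-probe medians and SDs (plus sample
counts), not raw samples: this matches how an empirical repository is
summarized and keeps fixtures small.  Tissue inference minimizes the mean
absolute deviation between the sample and each tissue's median profile over
shared probes — MAD is robust and natural on the bounded beta scale; the
metric choice is a package decision since "nearest neighbor" alone does not
fix one, and matching is to tissue-level aggregates rather than individual
repository samples.  At least 100 shared probes (`min_overlap`) are required;
below that the distance estimate is unstable and an explicit tissue label is
demanded.  Ties break to the first-listed tissue.

Imputation fills each reference probe absent from the input with the matched
tissue's median.  When an SD threshold is set, probes whose within-tissue SD
exceeds it stay missing (rows of NA with provenance `missing`): high
within-tissue variance means the probe's level is driven by unmodelled
covariates (age, sex, malignancy), so a median would be a guess, not an
estimate.  No threshold is applied by default; 0.08 is the validated choice
exposed as `VALIDATED_SD_THRESHOLD`.  Measured cells are never altered, so
imputation is idempotent, and each column is processed independently —
single-sample operation is a contract, tested by column permutation.
Sporadically missing cells of probes the platform does measure are filled
only on request (`fill_sporadic`), since within-platform missingness is
usually better handled by detection-aware methods upstream.

## Signal conversion

Signal records (M, U, detection *p*, mask) transfer verbatim along the
mapping.  Replicate resolution uses best-detection only: averaging raw
intensities across differently designed probes would conflate chemistries, so
no averaging option exists on the signal side.  If every candidate is masked,
the least-*p* masked record transfers with its mask intact so downstream can
exclude it.  Chemistry-mismatched transfers (type I record onto a type II
design ID) are counted and logged but not altered.  Target probes with no
feed are absent — signal imputation is out of scope by design.

## Synthetic data

The generators define the study conditions for all tests:

- **Platform pair** — 300 prefixes by default, 80% shared between a
  legacy-style platform (one probe per prefix) and a suffixed platform whose
  replicate count per prefix is drawn from {1: 0.7, 2: 0.2, 3: 0.1}; 2% of
  probes are masked by design.
- **Cohort** — five tissue median profiles drawn from a bimodal distribution
  over [0.05, 0.95] (methylation is empirically bimodal; staying off the
  boundaries keeps clipped noise symmetric), enforced pairwise MAD ≥ 0.1;
  samples are profile + Gaussian noise (SD 0.02 by default) clipped to
  [0, 1].  "Truncation" is implemented as clipping: with profiles ≥ 2.5 SD
  from the boundaries the point mass this creates is negligible.
- **Reference** — medians/SDs from an independent draw of 500 samples per
  tissue, so the reference is an estimate of the generating profile exactly
  as an empirical compendium would be; with zero noise the summaries are set
  exactly (median = profile, SD = 0) rather than computed from tiled draws,
  avoiding float-summation residue.
- **Paired experiments** — 10% of mapped target probes receive a fixed 0.2
  offset on the target side in every experiment, directed toward the interior
  of [0, 1] so it never saturates; bias is modelled operationally as a beta
  offset, not mechanistically.
- All generators are bit-reproducible given (seed, config); per-generator
  seed streams are derived from the base seed.

What the fixtures do **not** emulate: real probe sequences or genomic
positions, batch effects, covariate structure (age, sex), platform-specific
chemistry artefacts, or realistic missingness patterns.  Passing tests
therefore demonstrate the correctness of the harmonization contracts — not
that real cross-platform conversions reach any particular accuracy on
biological data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 40–300-prefix platforms,
cohorts of up to 100 samples, 20-fixture sweeps and 10-replicate bias
simulations — sizes at which brute-force oracles (quadratic pair enumeration,
per-cell nested-loop recomputation) remain exact and fast, which is the point
of the synthetic regime.  Beta validity is checked strictly (values in
[0, 1], unique probe IDs); threshold comparisons are inclusive with no
epsilon, so exact-boundary behavior is well defined and tested with
binary-representable constants.  Missing values are NaN throughout; TSV I/O
renders them as `NA`.

## Known limitations

Imputation accuracy is bounded by how well tissue identity explains a probe's
level; covariate-aware or genomic-neighbor imputation is not implemented.
Only platforms with reference data can be imputation targets.  Real Illumina
manifest ingestion is not included — manifests use the package's minimal TSV
dialect.  Batch effects are explicitly not addressed.
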