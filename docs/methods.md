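# Methods

## Scope and data model

The package operates strictly downstream of DIA search and quantification:
its input is a proteins × samples matrix of non-negative intensities with
explicit missing entries, plus sample metadata (patient, tissue out of a
closed 16-label vocabulary, disease state tumor / NAT / normal). NAT
(tumor-adjacent normal) and true normal tissues are pooled into a single
"normal" group for every comparison. Zero and negative intensities are
treated as "not quantified": label-free zero is absence of a quantification
event, and the imputation rules presuppose positive observed values; the
coercion count is logged. Wide TSV is the canonical interchange format;
long (protein_id, sample_id, intensity) reports are supported read-only.

## Statistical conventions

All tests and fold changes run on log2-transformed intensities, so
"fold change > 2" means |log2FC| > 1 and "> 4-fold" means |log2FC| > 2.
The two-sample test is Welch's unequal-variance t by default (robust to the
unequal arm sizes and variances typical of these cohorts); the
equal-variance variant is a config switch. P-values are two-sided (both
directions of regulation are of interest). Benjamini–Hochberg adjustment is
applied within one comparison family at a time — across proteins within a
tissue pair for enrichment, across proteins within a cancer type for
differential analysis — matching how each family's results are consumed;
the family choice is config-exposed. Replicate CV is computed on the raw
intensity scale (100·SD/mean, sample SD), the convention for
injection-replicate QC; correlations use pairwise-complete observations.

## Sample qualification (3-of-5 rule)

The five qualification criteria are named but not formalized in the
workflow this package implements; the operationalizations here are the
package's own reading, all thresholds configurable and logged:

1. *Detection*: ≥50% of the proteins detected anywhere in the sample's own
   cancer cohort are quantified in the sample (the cohort-detected set
   supplies the denominator the rule needs).
2. *Similar median*: the sample's median log2 intensity lies within
   k·MAD (k = 3) of the cohort's median-of-medians; the MAD is floored at
   0.2 log2 units so a near-degenerate cohort cannot fail every sample.
3. *Correlation*: mean pairwise Pearson correlation (log2,
   pairwise-complete) with same-tissue samples > 0.6 (the stated cutoff).
4. *Similar distribution*: two-sample Kolmogorov–Smirnov statistic of the
   sample's observed log2 values against the pooled same-tissue values
   ≤ 0.3 — a single interpretable shape knob.
5. *PCA grouping*: on the median-normalized log2 matrix restricted to
   proteins observed in ≥80% of samples (remaining gaps filled with the
   protein mean for the projection only), the sample's nearest tissue
   centroid on the first two principal components — leaving the sample out
   of its own centroid — must be its own tissue.

A sample qualifies with ≥3 passing criteria. A tissue with a single sample
cannot support criteria 2–5; those flags are then tied to criterion 1 (the
sample qualifies iff its detection fraction passes), with a logged warning —
this keeps the flag-count/qualification invariant intact while matching the
intended behaviour.

## Quantifiability and imputation

A protein is retained if quantified in ≥40% (inclusive) of the qualified
samples of at least one cancer type, tumor and normal pooled. Missing cells
are then filled per tissue: if the protein is observed in <50% of that
tissue's samples, the fill is 0.05 × the smallest observed intensity
exceeding 100 *in the target sample* — "5% of the lowest intensity (>100)"
is read as a fraction of the minimum supra-100 intensity, not as a 5th
percentile, because the >100 qualifier attaches to a single intensity;
otherwise the fill is the tissue's observed mean − 2·SD (sample SD), floored
at 1.0 intensity unit since mean − 2SD can go negative and downstream log2
requires positivity. A sample with no observed intensity above 100 receives
the floor with a warning; a branch-B protein with fewer than two observed
values (possible only in 2-sample tissues at exactly 50% observation) falls
back to the branch-A fill, logged. Imputation is idempotent and never
touches observed cells.

## Housekeeping, enrichment, differential, annotation rules

*Housekeeping*: presence fractions are computed pre-imputation over the
pooled tumor-sample set and pooled normal-sample set (the counts behave as
sample fractions, not per-tissue-type fractions; a per-tissue mode is a
switch). "More than 90%" is strict. The across-tissue stability score is
the CV of the 16 tissue-mean log2 intensities, separating constant from
fluctuating universal proteins.

*Tissue enrichment*: each tissue (tumor+normal pooled) is compared with
each other tissue per protein; enrichment in a tissue requires beating
≥ ceil(0.7 × (T−1)) comparators — 11 of 15 at T = 16 (the ceiling is the
conservative integerization of "70% of other tissue types") — each win
requiring log2FC > log2(4) and adjusted p < 0.05. Group enrichment pools a
tissue group (digestive: colon/stomach/esophagus/pancreas/liver; urinary:
bladder/prostate/kidney; gynecologic: breast/uterus/ovary) into one entity
and applies the identical rule against each non-member tissue — the minimal
consistent extension of the per-tissue rule.

*Differential*: per-cancer Welch t tumor vs normal, BH across proteins
within the cancer, calls at fold change > 2 and adjusted p < 0.05. Cancers
lacking two samples in either arm are skipped with a notice (the brain
cohort is tumor-only by design). Cross-cancer "common-up" proteins must be
up in strictly more than 40% of the *analysed* cancers (7 of 16; the
denominator excludes skipped cohorts so they are not penalized). Protein
groups: per-protein Z scores (population SD) across samples, agglomerative
clustering with Ward linkage on Euclidean distances, tree cut at k = 4;
proteins enter in id order and PG labels are assigned by decreasing mean
tumor-minus-normal Z difference, making the output deterministic.

*Annotation*: the module consumes pre-built boolean flag tables rather than
parsing live drug/antigen databases, whose version-dependent contents are
not reproducible. Druggable candidates are the conjunction FDA-approved
target ∧ up-called in ≥1 cancer, sorted by maximum log2FC. CT antigens are
"detected" when inside the quantifiable set and "elevated" when up-called
anywhere. Candidate lists are pure functions of their inputs.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes. Per
protein, a baseline log2 mean is drawn N(20, 2²) (arbitrary MS intensity
units, spanning the typical 4–5 orders of magnitude); per cell, Gaussian
noise with SD 0.3 is added, and intensities are 2^latent, giving log-normal
abundances on which planted log2 effects are exact in expectation. Cohort
arm sizes default to a realistic 16-tissue pan-cancer design (4–12 tumors
per tissue with matched normals; the brain cohort tumor-only; 246 samples
total). Planted structure, all counts/effects configurable:

- housekeeping proteins (default 200): exempt from dropout, hence observed
  in every non-outlier sample;
- tissue-enriched proteins at multiplicities 1/2/3/4+ (defaults
  50/20/10/5) with a +3 log2 shift in all samples of their tissues;
- per-cancer up/down proteins (default 10+10 per cancer) with a ±2 log2
  shift in that cancer's tumor samples only;
- optional expression archetypes (normal-high, pan-tumor-high, digestive-
  restricted, urinary-restricted tumor-high) giving coherent cross-cancer
  patterns for clustering and aggregation benchmarks;
- outlier samples (default 4): ≥60% forced missingness, a ±2 log2 global
  shift, and half the proteome replaced by noise independent of the shared
  protein baselines — constructed to violate qualification criteria 1–3;
- dropout: logistic in the latent log2 intensity with configurable slope,
  the intercept centred by bisection so the marginal missing rate hits the
  target (default 10%); slope 0 gives missing-completely-at-random.

Everything flows from one integer seed; equal seeds give byte-identical
cohorts.

What the generator does *not* emulate: peptide-level structure, retention-
time drift, spectral interference, batch/injection-order effects beyond the
outlier mechanism, correlated protein modules, or heavy-tailed noise.
Passing recovery tests therefore demonstrates that the implementation's
thresholded rules recover the signals they are defined to detect under the
assumed log-normal/MNAR model — not that those thresholds are optimal for
real cohorts.

## Problem sizes and numerical choices in the validation suite

Recovery experiments are sized for clear planted-signal recovery at
desk-scale: QC recovery uses 600-protein cohorts of the full 246-sample
design over multiple seeds; enrichment recovery uses 2000-protein,
16-tissue cohorts with a +3 log2 effect and within-tissue SD 0.5;
differential recovery uses uniform 8 tumor / 8 normal arms with ±2 log2
effects and SD 0.3; clustering uses 30 proteins per archetype. Each planted
class is measured on cohorts planting only that class, so cross-talk
between planted signal types (e.g. a tumor-only cohort whose per-cancer
up-shift doubles as a tissue shift) does not contaminate the measured
error rates. Type-I calibration uses 10,000 simulated null Welch tests at
n = 10 per group.

Numerical details: BH is delegated to statsmodels and cross-checked against
a brute-force sort/scale/cummin oracle; Welch statistics are vectorized
from per-group summary moments and degenerate zero-variance comparisons
return t = 0, p = 1; ties in clustering are broken by protein-id order;
the dropout intercept bisection runs 200 iterations over a generous
bracket. Known limitations: the imputation rule itself injects variance
into sparsely observed proteins (noise-floor fills sit far below signal),
which genuinely suppresses differential power for low-abundance proteins —
visible in default-cohort runs and documented rather than patched, since it
is a property of the published rule, not of this implementation.
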