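# Methods

## The learning problem

The package trains a per-variant pathogenicity score s ∈ [0, 1] from a
labeled set of single-nucleotide variants in which pathogenic positives are
outnumbered by proxy-benign negatives by three to five orders of magnitude,
using a fixed panel of 26 numeric annotations grouped into five categories
(sequence composition, epigenetics, conservation, population variance,
regulatory regions). Two failure modes dominate this regime and drive the
design: a single learner on the raw data collapses toward the majority
class and produces coarse, poorly ranked probabilities; and naive
cross-validation is optimistically biased because genomically proximal
variants share annotation values and pathogenic variants cluster around
well-studied loci.

## Imbalance-aware ensemble

Per ensemble member i of `n_partitions`:

* **SMOTE oversampling.** Each original positive x contributes
  `oversample_factor` synthetic points x + u·(x_nn − x), where x_nn is one
  of x's `smote_k` nearest minority neighbours under Euclidean distance on
  the imputed, unscaled features (no scaling step is part of the method)
  and u ~ Uniform(0, 1). Synthetics are drawn freshly per member; the
  original minority is shared by all members.
* **Partition + subsample.** The majority indices are shuffled once and cut
  into `n_partitions` non-overlapping partitions whose sizes differ by at
  most one (the first N mod n partitions take the extra element). Member i
  subsamples its partition, without replacement, down to
  `ratio` × |original minority| points; if the partition is smaller than the
  target (degenerate small-data case) it is used whole, with a warning.
* **Forest.** A random forest with `trees_per_forest` trees is fitted on the
  member's minority ∪ synthetics ∪ subsampled majority.

The ensemble score is the arithmetic mean of the member class-1
probabilities — exactly, not a vote share. Averaging many coarse member
estimates is what produces a fine-grained, well-ranked score under extreme
imbalance.

**Semantics choices.** "Oversampled by factor f" is implemented as f
synthetics per original (final minority = (1+f) × original; factor 2 turns
406 positives into 1,218), the parameter meaning of the published
hyperSMURF implementation; the alternative reading (final minority =
f × original) is reachable by adjusting the factor. "Undersampled by ratio
r" means r × |original minority| negatives per member (3 × 406 = 1,218),
which together with the factor reproduces the documented ~2,400-point
member training sets at the real scale. Defaults `smote_k = 5` and
`trees_per_forest = 10` follow SMOTE-literature and hyperSMURF conventions
respectively; forest depth and feature subsampling default to scikit-learn's
`max_depth=None`, `max_features="sqrt"`. All are configurable.

**Reproducibility.** One master seed; the majority shuffle and each member
derive independent child streams keyed by partition index
(`SeedSequence(seed, spawn_key=...)`), so raising `n_partitions` leaves
earlier members' training sets untouched. (seed, data, config) fully
determines the model and every score.

## Imputation

Missing feature values are filled per feature by one of three constant
policies: **zero** (epigenetic/regulatory signal tracks, where missing means
"too low to measure"), **genome-mean** (sequence composition and
conservation, where missingness carries no signal — implemented as the mean
of the defined values in the training matrix, the available stand-in for a
genome-wide average), and **one** (P-value-like features, where "no test"
is the null P value). Means are training-time statistics and are reused
unchanged at scoring time; a genome-mean feature with no defined values is
an error rather than a silent fallback. Imputation is idempotent and never
touches a defined cell. The per-feature policy table ships as an editable
YAML file next to the feature matrix.

## Cytoband-aware cross-validation

Bands are assigned to `n_folds` (default 10) folds with greedy
longest-processing-time packing: bands carrying positives in descending
count order, each to the currently lightest fold (ties to the lowest fold
index); bands without positives uniformly at random from a dedicated child
seed. The greedy bound max − min fold count ≤ max single-band count is
asserted in the tests. Every variant inherits its band's fold; fold f's
model is trained on the other folds (imputer re-fitted on that training
portion only) and scores fold f. Each training variant thus receives
exactly one held-out score from a model that never saw its band — the
leakage-control contract the tests verify directly. A fold whose training
portion lacks a class raises an error naming the fold (the prescribed
remedy is fewer folds). A repeat-runs driver (`repeat_cv`) re-runs the CV
over a seed list and reports mean ± sd of pooled AUPRC, with an index
selecting one run as the released model.

## Thresholds and metrics

Curves are evaluated at every unique score plus sentinels 0 and 1 under the
inclusive rule score ≥ cutoff → positive. AUPRC uses the step-function
(non-interpolated) convention, standard for imbalanced-data reporting;
AUROC uses the trapezoid rule anchored at (0, 0), which equals the
Mann-Whitney pairwise statistic with half-credit ties. F_β =
(1+β²)PR/(β²P+R) with F = 0 at P = R = 0; the optimal threshold maximises
F_β over all evaluated thresholds, ties broken toward the larger (stricter)
threshold. Precision at zero predicted positives is reported as 0 with an
explicit flag. Classification bands: score ≥ F1-optimal threshold →
"pathogenic", between the F2- and F1-optimal thresholds →
"likely pathogenic", else below evidence; band construction rejects
F2 > F1. Reported percentages round half-up.

## Score tracks and scoring workflow

The release track scores every requested position with the general model
(trained on all data) and then substitutes the held-out CV score at every
training-set position, so benchmarks driven from the track never see an
optimistically biased value. Tracks are sorted (chrom, pos, score) TSVs,
one record per position, serialized at 3 decimals (the granularity of
published whole-genome score files; configurable) and optionally
bgzip-compressed with a tabix index for htslib interoperability; point and
range lookups go through a binary-search index and are tested against a
linear-scan oracle. VCF scoring writes the looked-up value into the INFO
field (key `REMM`). Chromosome names are opaque strings throughout — no
"chr"-prefix harmonisation, to avoid silent mismatches.

## Synthetic data

The generator emulates the structure the method is designed for, at desk
scale: `n_pos` positives confined to a `pos_band_fraction` subset of
`n_bands` bands; `imbalance` negatives per positive spread uniformly;
feature values baseline(category) + band effect + δ·label + ε with unit
Gaussian ε, per-band-per-feature effects ~ N(0, band_sd²); regulatory
features folded to zero-inflated positive values (sparse signal tracks);
per-feature Bernoulli missingness from ~0 (GC content) to 0.97
(enhancer annotation). Defaults — 200 positives, 1:1,000 (200,000
negatives), 50 bands of 100 kb on 5 chromosomes, 20% positive-carrying
bands, δ = 0.3, band_sd = 0.5 — were fixed once as a realistic desk-scale
analogue: 1:1,000 is the largest imbalance that keeps a full 10-fold CV in
tens of seconds per run, and δ = 0.3 per feature gives moderate aggregate
separation (≈1.5 sd over 26 features) so ranking is hard but learnable.
Training on these defaults uses 20 partitions, scaling the 100-partition
full-data configuration to the reduced majority size.

The generator does **not** emulate real coordinates, sequence context, the
marginal distributions of real annotations, or inter-feature correlation
beyond the shared band effect. Green tests therefore validate the
machinery — sampling arithmetic, fold hygiene, calibration, importance
readout — not real-data performance; headline metrics published for the
real 14M-variant training sets are out of reach by construction at desk
scale and are not reproduced here.

**Baseline for the imbalance-awareness check.** The control arm is a single
random forest with the ensemble's per-member capacity (`trees_per_forest`
trees) trained on the raw imbalanced data and evaluated on the same folds —
i.e. one ensemble member stripped of the sampling machinery, which isolates
the contribution of SMOTE + partitioning + averaging rather than comparing
against a differently sized model.

## Numerical and degenerate-input choices

* SMOTE requires ≥2 minority points and k < |minority| (error instructs to
  lower k); identical minority points interpolate to themselves.
* Duplicate positions in a score track are an error on write; lookups on
  absent chromosomes return empty results, not errors.
* Constant score vectors produce a degenerate curve with a warning, not an
  error.
* Zero-variance input to correlation is an error (undefined), not 0.
* Model archives are written to a temporary path and atomically renamed, so
  a crashed run never leaves a partial archive.

## Known limitations

Feature extraction from real genomic databases, liftover between genome
builds, transcript-consequence annotation and comparisons against other
published scores are out of scope. The genome-mean imputation statistic is
a training-matrix mean, not a true genome-wide mean. Fold assignment
balances pathogenic counts only (not band sizes), matching the method it
implements; with very few positive-carrying bands the prescribed behaviour
is an error prompting a lower fold count rather than silent rebalancing.
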