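# Methods

This note documents the models and procedures implemented in `tmtquant`,
the synthetic data they are validated against, the numerical conventions
chosen where the field leaves them open, and the limitations of both.

## Quantification model

Reporter-ion quantification treats each PSM's ten reporter intensities as
multiplicative signals on a common log2 scale. All inference is performed
on **ratios to the pooled reference channel** (the "master mix", channel
131 of each plex, pooled from every cohort sample), which cancels per-PSM
ionization efficiency and puts all plexes on one scale.

**Filtering.** A PSM is kept only if all criteria pass: reference reporter
present and positive; peptide probability ≥ 0.9; precursor purity ≥ 0.5;
MS1 precursor intensity ≥ 0.05% of the largest MS1 intensity in its plex;
summed reporter (MS2) intensity ≥ 5% of the per-plex median of that sum;
protein not carrying the `contam_` prefix. Two of these thresholds are
stated in the literature as bare percentages; the denominators (per-plex
maximum for MS1, per-plex median for MS2) are this package's documented
choices, isolated behind `FilterCriteria` so they can be reconfigured.
The rejection report attributes each lost PSM to the *first* failing
criterion in the order reference → probability → purity → MS1 → MS2 →
contaminant. The MS2 criterion evaluates the stored
`ms2_summed_intensity` column (the acquisition-time total) rather than a
re-sum of surviving reporter cells, so reporter-level missingness cannot
change a PSM's filter verdict.

**Roll-up.** Among PSMs sharing a spectrum identifier only the one with
the highest summed TMT intensity survives (ties: first occurrence). Log2
ratios are grouped by gene (or protein), trimmed once per protein × sample
group by the 1.5·IQR rule — applied only to groups of ≥ 4 values, since
quartiles of fewer points over-trim; quartiles use linear interpolation —
and summarized by the median. Single-plex cohorts without a master mix may
instead use the per-PSM mean of all log2 channels as reference
(`pooled_reference=True`).

**Normalization.** Per sample over non-missing entries:
median centering (M_j), MAD scaling with MAD_j of the centered values and
the global MAD₀ = median of sample MADs, giving
Rᴺ_ij = (Rᶜ_ij / MAD_j)·MAD₀. The operation is idempotent and invariant to
per-sample shifts; after it, every sample has median 0 and MAD equal to
MAD₀ (asserted to 1e-9 on every run). A sample whose values are all equal
has MAD 0 and is returned centered, unscaled, with a warning.

**Back-conversion.** Each protein's reference intensity REF_i is the mean
over plexes of the top-3 summed MS1 precursor intensities (the "weighted"
sum uses unit weights, configurable, since no weights are prescribed);
plexes where the protein is absent contribute the global minimum REF. The
final log2 abundance is A_ij = Rᴺ_ij + log2(REF_i): a per-protein constant
shift, so all between-sample contrasts live entirely in the normalized
ratios.

Rows are proteins and columns samples everywhere (the ratio and abundance
conventions in the literature disagree on index order; one convention is
fixed here and documented).

## Imputation and pooling

Missing abundances are imputed by chained equations with **predictive mean
matching**: each sample column with missingness is regressed by least
squares on all other columns' current completions (proteins are the
observations); each missing cell receives the observed value of a donor
drawn uniformly from the 5 observed cells with nearest predicted means.
Columns are visited in order of descending missingness, 50 sweeps, with
m = 5 independent chains started from random draws of the observed column
values. Every imputed value is therefore an observed value of its own
column, and observed cells are never altered. Rows with fewer than 3
observed values are dropped with a warning; a rank-deficient regression
falls back to column-median prediction. The regression coefficients are
the OLS point estimates (no posterior draw); the between-chain variability
from the random initialization and donor draws is what Rubin's rules see.

Per-imputation group contrasts are pooled by **Rubin's rules**: point
estimate = mean, within-variance W = mean of squared standard errors,
between-variance B = sample variance of estimates,
total T = W + (1 + 1/m)·B, with the Barnard–Rubin small-sample degrees of
freedom when the complete-data df is known (the pipeline supplies
n_a + n_b − 2). Pooling of linear-model contrasts is used for continuous
abundances; a median-p pooling helper is also provided. Batch correction
is per-protein batch-mean centering (subtract the batch mean, add back the
grand mean), which preserves within-batch contrasts exactly; an
empirical-Bayes variant is out of scope.

The pipeline imputes the combined matrix after plex integration and before
batch correction, and runs the differential tests on each completed matrix
with Rubin pooling (running them on a single completed matrix is also
possible through the library).

## Differential statistics, clustering, GSEA, signatures

Fold change is the difference of group means on log2 data; "FC > 1" is
read as |log2FC| > 1 (the volcano cut lines are symmetric at ±1).
Student's pooled-variance t is the default (Welch optional); q-values are
Benjamini–Hochberg. One-way ANOVA uses the classical F-test. Clustering
follows Cluster 3.0: median centering of protein rows, uncentered
correlation distance d = 1 − Σxy/(‖x‖‖y‖) over pairwise-complete
positions, complete linkage with a deterministic smallest-index tie-break
(hand-rolled because library linkage implementations do not guarantee this
tie-break). Item pairs sharing fewer than 3 positions receive the maximum
observed distance, with a warning. PCA is a feature-centered SVD of the
complete (post-imputation) matrix with a deterministic sign convention.

Preranked GSEA uses the weighted running-sum statistic (weight exponent 1,
classic exponent 0 by flag), a **gene-permutation null** (random same-size
sets from the ranked universe — the only null available for preranked
input), NES = ES / mean(|null ES| of matching sign), and an add-one
corrected same-sign exceedance p, BH-adjusted across sets. Ranking ties
break lexicographically by symbol for reproducibility. Signature calling
uses strict inequalities (p < 0.05, q < 0.1, |log2FC| > 1); homolog
mapping is case-insensitive with one-to-many expansion (the later
intersection removes spurious targets), and cross-species signatures are
per-direction intersections with full Venn accounting.

## Synthetic cohorts

The generator emulates the target study design: 3 TMT 10-plexes, 27
tissue samples in five groups (normal 6, TNBC 6, spindle 6, squamous 4,
sarcomatoid 5), one pooled reference per plex, and per-plex missingness
defaulting to 18% / 14% / 12%. Reporter cells are generated as
2^(true abundance + batch shift + per-PSM effect + noise); the reference
channel carries the linear mean of all cohort samples' true signal times
the same per-PSM effect. Batch shifts (default sd 0.3 log2) apply to
sample channels but not the reference, so they survive into ratio space
where the batch-correction stage must remove them. Defaults: baseline
abundance N(25, 1) log2, biological between-sample sd 0.2, PSM noise sd
0.3, per-PSM effect sd 0.4, 10% of proteins carrying a ±1.5 log2 group
effect (in all tumor groups by default; a per-subtype mode exists),
per-protein PSM counts 1 + Poisson, 2% contaminant PSMs (`contam_`
prefix), 5% deliberately corrupted PSMs labeled with the criterion they
violate. Missingness is cell-level and by default intensity-dependent
(logistic in log2 intensity, low-abundance cells preferred — MNAR); an
MCAR switch exists because the real mechanism is not identifiable from
the published description. Blanked-cell counts are exact
(round(rate × cells)), so realized rates match requests to rounding.

Two generator details exist purely so that expected answers are exact:
clean PSMs are floored above the MS1/MS2 filter thresholds (raising values
strictly below the plex maximum/median leaves those statistics unchanged,
and row-scaling preserves ratios), making the filter's kept set provably
equal to the hidden clean labels; and the DE gene list can be planted
explicitly so two cohorts (e.g. human and mouse) share effects.

What the simulation does **not** model: peptide-level interference and
co-isolation structure, isotope-impurity crosstalk between reporter
channels, retention-time or spectral features, shared/razor peptide
ambiguity (the input's assignments are trusted), and correlated biological
modules. Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated noise model, not
robustness to every pathology of real LC-MS/MS data.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) run: normalization exactness on 20 random
missing-valued matrices plus the worked example ([1,2,3] and [2,4,6] both
normalize to [−1.5, 0, 1.5]); brute-force oracle agreement on 100 random
≤ 20-PSM instances (the oracle is a straight-line pure-Python
reimplementation with longhand quantiles and medians); end-to-end
differential-expression recovery on five 3-plex cohorts of 200 proteins
(10% DE at 1.5 log2, PSM noise 0.3, batch shifts 0.3, 15% missingness) —
sensitivity and empirical FDR at the signature cutoffs; PMM versus
column-median RMSE on five 120 × 18 matrices with 15% MCAR; GSEA type-I
error over 200 repetitions (universe 300, set size 20, 1000 permutations)
plus a top-15 positive control; eleven closed-form checks of t, F, BH,
Rubin and distance values; and a byte-level determinism check of two
identically seeded full runs on the shipped fixture. These sizes were
chosen as the smallest at which the binomial/sampling noise of each
estimate is well inside its acceptance band.

One exactness property deserves a note: after MAD normalization the map
from true to recovered abundances is per-sample *affine* (shift and
scale), not a pure shift, so noise-free recovery is asserted in two exact
forms — the pre-normalization ratio matrix equals truth minus log2(master
mix) to machine precision (hence all between-sample differences match
truth exactly), and the normalized/abundance matrices equal a longhand
reapplication of the four formula steps to the true ratios.

## Known limitations

- PMM uses OLS predictions without a posterior parameter draw
  ("type-0"-style matching); between-imputation variance is driven by
  initialization and donor randomness and can be mildly underestimated.
- The permutation-null p has a floor of 1/(1 + same-sign permutations);
  deeply significant sets are reported at the floor, as is standard.
- Batch correction assumes additive per-protein batch offsets; it will
  not remove batch-by-group interactions, and confounded designs (a group
  confined to one plex) are the user's responsibility.
- The MS1/MS2 filter denominators are per-plex; with very few PSMs per
  plex these reference statistics are themselves noisy.
- Protein inference, search-engine FDR and reporter isotope correction
  are out of scope; the pipeline starts from a PSM table that already
  carries identification probabilities.
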