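# Methods

This note documents the models, numerical choices, and limitations of the
`oliveauth` workflow in enough detail to reproduce or audit any stage.

## Synthetic study generator

The generator emulates a three-origin table-olive authenticity study:
65 samples (20 Greece, 24 Egypt, 21 Chile), 6 pooled-QC injections,
4 procedural blanks, and an 11-sample "suspect" set from the protected
origin but a later harvest year. The intensity of feature *j* in sample
*i* is multiplicative:

    x_ij = baseline_j · class_effect_ij · dilution_i · noise_ij

* **baseline_j** ~ LogNormal(μ=12, σ=1) in natural-log units (median
  ≈ 1.6·10⁵ counts) — the standard abundance model for LC-MS peak areas,
  which span several orders of magnitude with right skew.
* **class_effect** = `marker_fold_change` (default 5) when *j* is one of
  the 10 markers injected per origin, else 1. Markers are elevated in
  their characteristic origin, matching the one-class-high semantics of
  origin markers; the three marker sets are disjoint.
* **dilution_i** ~ LogNormal(0, 0.15) — per-extract dilution spread of the
  size PQN is designed to correct.
* **noise_ij** ~ LogNormal with coefficient of variation 0.10 — typical
  QTOF peak-area repeatability.

QC rows are the arithmetic mean of all sample rows re-measured with the
same multiplicative noise, so their grand mean converges to the sample
grand mean as noise vanishes. Blanks carry only a 5% "contaminant" subset
of features at 0.8x the sample baseline — high enough that the 3x
blank-filter rule removes every contaminant. Ten duplicate columns are
injected as 0.8x-intensity copies within 3 mDa / 0.05 min of their source;
feature (m/z, tR) positions are drawn uniformly over 80–1000 Da x
0.5–15 min with a minimum-separation rejection step so that *only* the
injected duplicates fall within the curation tolerances. The suspect set
multiplies the Greek generative model by a shared per-feature
LogNormal(0, 0.15) harvest-year effect.

What the generator does **not** emulate: retention-time drift and
alignment error, heteroscedastic detector saturation, missing values
(intensities are either present or exactly zero), isotopologue columns,
correlated metabolite modules, and class-dependent dilution. Passing
tests therefore demonstrate correctness of the algorithms under a clean
multiplicative model, not performance on real instrument data, where
effect sizes and within-class variance are unknown (the real study's are
not published).

## Curation

Blank filtering keeps feature *j* iff mean(sample rows) ≥ 3 x mean(blank
rows); features absent from blanks are always kept. Duplicate merging
links features with |Δm/z| ≤ 5 mDa **and** |ΔtR| ≤ 0.1 min by single
linkage (union-find over an m/z-sorted sweep, deterministic) and keeps the
member with the highest mean intensity, ties broken toward lower m/z.
Retained intensity values are never modified. Missing values are stored
as 0 and treated as true zeros.

## Scaling

All parameters (per-feature mean, sample standard deviation with n−1
denominator, min/max, PQN reference, glog λ) are estimated on **training
sample rows only** and applied unchanged to test and suspect rows — the
data source for these parameters is otherwise a leakage channel.
Degenerate 0/0 columns (constant features) map to 0: they carry no
information and this keeps every matrix finite. The PQN reference is the
per-feature median of the QC rows (median of training samples when no QCs
exist); each row is divided by the median of its positive quotients
against the reference. The variance-stabilizing method is a
generalized-log transform glog(x; λ) = log((x + √(x²+λ²))/2) with λ = the
median non-zero training intensity, then mean-centered; this approximates
arsinh-type variance stabilization without fitting a full error model and
is documented as such. log2 uses an offset of ε = 1 to admit zeros.

The composite score ranks methods with weights 0.15/0.15/0.20 on
R²X/R²Y/Q², 0.15/0.30 on (1−RMSEE)/(1−RMSEP), and 0.01/0.02/0.02 on
train/test/CV accuracy; prediction error on the held-out set deliberately
carries the largest single weight.

## Kennard–Stone splitting

Canonical max–min: seed with the two mutually farthest samples
(Euclidean), then repeatedly add the sample maximizing its minimum
distance to the current training set; ties break toward the lowest sample
index, making the split deterministic and order-invariant when distances
are distinct. Distances are computed on a Pareto-scaled matrix fitted on
all sample rows — this touches intensities only, never class labels, so
it leaks no response information; the classifier then refits its own
scaling on the selected training rows. An `alternating` variant assigning
successive farthest pairs alternately to train and test is provided for
completeness; it produces ≈50/50 splits and is not the default because
the study design is 51/14.

## PLS-DA

NIPALS PLS2 on the one-hot class dummy matrix: per component, the
weight/score/loading iteration runs to a relative score-change tolerance
of 1e−10 (max 500 iterations), then both blocks are deflated. Components
stop early if the dummy-response residual is numerically exhausted
(< 1e−12 of its initial sum of squares); requesting more components than
`min(n, p)` is an error. Predictions use B = W(PᵀW)⁻¹Cᵀ; class assignment
is the argmax dummy column (first class in model order on ties), and
class probabilities are the softmax of predicted dummy values — the
dummy predictions are not bounded in [0,1], and softmax is the simplest
monotone map to a proper probability vector. The latent-variable count is
the smallest one minimizing stratified k-fold (default k = 5; k = n gives
leave-one-out) CV misclassification error; folds are dealt round-robin
from per-class shuffles under a fixed seed.

VIP uses SSYₐ = ‖tₐ‖²‖cₐ‖², the exact reduction in dummy sum of squares
achieved by component *a* under NIPALS deflation; squared VIPs then
average to exactly 1. Pairwise contrasts are one-vs-one OPLS-DA: for each
class pair, one orthogonal component is removed
(w_orth ∝ p − (wᵀp)w) before a single predictive component is fitted, and
the pairwise VIP is √p·|w_j|/‖w‖. One-vs-one (rather than one-vs-rest)
matches the three pairwise contrasts reported for each marker; one
orthogonal component is the default because the within-pair orthogonal
structure of the data is a single dilution-like direction.

## Validation

Q² = 1 − PRESS/SS with PRESS from out-of-fold dummy predictions and SS
from the centered training dummies. RMSEE/RMSEP are root **mean squared**
dummy residuals on training/test (the conventional reading of the
acronyms). ROC curves sweep the unique probability values plus ±∞ as
thresholds, store (100−specificity, sensitivity), and integrate by the
trapezoid rule — with ties this equals the Mann–Whitney U statistic
normalized by n₊n₋, which the tests verify against SciPy. The permutation
test refits and cross-validates under 20 uniform label permutations and
reports the add-one p-value (1 + #{Q²perm ≥ Q²obs})/(n_perm + 1), which
cannot reach an artifactual zero with only 20 permutations. Hotelling's
T² normalizes squared scores by training-score variances with the 95%
limit A(n−1)/(n−A)·F₀.₉₅(A, n−A); Q residuals use the squared
off-plane reconstruction error with the Jackson–Mudholkar limit computed
from the eigenvalues of the training residual matrix. A sample is flagged
an outlier when it exceeds **both** limits. Suspect samples are scaled
with training parameters, predicted, and checked against the same limits.

## Annotation

Monoisotopic masses are summed from a pinned CODATA/IUPAC constants table
(C 12 exactly, H 1.00782503, O 15.99491462, …); the deprotonated ion
subtracts the **proton** mass 1.00727646 Da, not the hydrogen-atom mass —
the electron's mass matters at the 4th decimal. Mass error is
(theoretical − observed)·1000 mDa; that sign convention makes an observed
mass above theory a negative error. Isotope patterns come from exact
polynomial expansion (repeated-squaring convolution of single-atom
isotope distributions, aggregated on a 1 mDa grid, pruned below 1e−12
probability, reported above 0.01% of base peak). The isotope-fit score is
1000·(1 − cosine) over abundance vectors aligned within 5 mDa with
unmatched peaks as zeros; it is *mSigma-like* — the vendor's proprietary
score is not reproducible, so only the accept-below-100 semantics are
mapped and printed vendor values are treated as qualitative. MS/MS
similarity is a cosine over √intensity vectors with greedy
highest-intensity-product-first matching within 0.01 Da; symmetric and
bounded in [0,1]. Candidate search keeps |error| < 5 mDa on [M−H]⁻, drops
candidates whose predicted-vs-observed retention-time error reaches
1.8 min, and ranks by |mass error| then isotope fit. Identification
levels: 1 = reference standard; 2a = library MS/MS cosine ≥ 0.7 (or ≥ 3
matched fragments when the library spectrum has no intensities); 2b = the
same evidence but isomer-indistinguishable; 3 = literature/in-silico
MS/MS or retention-time prioritization only; 4 = unequivocal formula
(isotope fit < 100) only; 5 = exact mass only. In-source-fragment
relationships are a flag on the annotation, not automated detection.

## Targeted method validation

Calibration is unweighted OLS of the IS-normalized response
(spiked − neat)/IS on spiked concentration; a flat response returns a
zero slope with zero standard errors rather than NaNs. LOD = 3.3·Sa/b and
LOQ = 10·Sa/b from the intercept standard error, so LOQ/LOD = 10/3.3
identically; low-concentration-range curves should be used for limits.
The matrix effect is the signed slope ratio 100·(b_matrix/b_solvent − 1)
(suppression negative); an alternative post-extraction-spike definition
exists but the slope ratio is the one consistent with signed percentage
reporting. Precision is 100·sd/mean, with inter-day replicates pooled
across days.

## Problem sizes and determinism

The default synthetic design (65 + 6 + 4 rows, 2010 features) runs the
complete pipeline — including the 20-permutation test — in a couple of
seconds on one core, so tests and the acceptance script use the full
study-scale design rather than a reduced one. Every stochastic step
(generation, CV folds, permutations) draws from generators seeded by the
single configured seed; re-running a configuration reproduces every
artifact byte for byte.

## Known limitations

* The synthetic effect sizes are plausible defaults, not calibrated to
  the real olive data (within-class variances were never published);
  data-bound quantities from the real study (feature counts like
  4144→2108, specific marker identities, the real outlier sample) are
  out of reach by construction.
* Exact VSN model fitting, raw-spectra processing (peak picking,
  alignment, adduct annotation), in-silico fragmentation, and retention
  -time prediction model training are out of scope; predicted retention
  times are accepted as user input.
* PQN is not invertible row-wise from scaled values alone, and `vast`
  has no defined inverse here.
* One orthogonal component only in the pairwise contrasts; kernel/sparse
  PLS and multi-block methods are not implemented.
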