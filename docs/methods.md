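# Methods

This note records the models, conventions and numerical choices behind
`neurofuse`, and what the synthetic-data experiments do and do not show.

## Cohort model

The target design is a two-group case–control cohort of seniors: normal
aging (NA) versus neurocognitive disorders (NCD). Defaults emulate a
50-senior cohort (21 NA / 29 NCD) for the demographic statistics and a
41-subject subset (19 NA / 22 NCD) for the classifier; group ages are
N(72.62, 3.64²) and N(80.31, 8.11²) years. NA is the positive class
throughout, which makes confusion matrices at N = 41 consistent with
19 positives / 22 negatives.

The synthetic generator draws each modality's features as iid standard
normals and adds a standardized mean difference d to the first
`n_discriminative` features of the NCD group. Per-modality feature counts
(microbiome 500, metabolome 300, EEG 400) are package defaults chosen as
plausible post-screening panel sizes; the counts that entered the original
selection are not published. Microbiome features are made compositional by
exponentiating and closing rows to sum 1; the effect is injected **before**
closure (on the log scale), so the realized post-closure d is approximate —
recovery tests therefore assert rank recovery of the planted set, not the
exact effect size. One `SeedSequence` per generator spawns independent
sub-streams (ages, one per modality), so modalities are independent but
jointly reproducible from a single seed.

What the generator does *not* emulate: feature–feature correlation within a
modality, batch effects, heavy-tailed intensity noise, taxonomic structure
beyond a cyclic phylum assignment, and any coupling between EEG and omics
features. Passing tests therefore show the pipeline recovers the structure
it assumes; they say nothing about robustness to correlated or confounded
real data.

## EEG spectra

Preprocessing follows the standard resting-state contract: common average
reference, zero-phase (forward–backward) 4th-order Butterworth band-pass
1–30 Hz, non-overlapping 2-s epochs, trailing partial epoch dropped.
"Re-referenced to the whole brain" is read as the common average reference.

PSD is estimated per epoch and averaged. The default estimator is multitaper
with DPSS tapers at time-half-bandwidth NW = 4 per 2-s epoch (concentration
half-bandwidth 2 Hz); the alternative is Welch with a Hann window spanning
the epoch. Band power integrates the PSD over half-open intervals
[low, high) by rectangle rule on the uniform frequency grid — half-open so
the six touching bands partition 1–30 Hz with no double counting, rectangle
rule so relative powers sum to exactly 1.

Estimator choice matters for narrowband signals: the NW = 4 multitaper
smooths a pure 10 Hz tone over ±2 Hz, pushing part of its energy across the
11.5 Hz alpha1/alpha2 edge (alpha1 relative power ≈ 0.85 instead of ≈ 1).
Narrowband validation checks therefore use the Welch estimator, which
concentrates a stationary tone in one bin; for broadband spectra the two
estimators agree within a few percent and either is fine. Note also that the
1–30 Hz Butterworth has its −3 dB points *at* the band edges, so edge bands
(delta, beta2) of a filtered broadband signal are attenuated relative to an
ideal flat response; flat-spectrum sanity checks are computed on unfiltered
epochs for this reason.

The group comparison is an OLS linear model `value ~ group * hemisphere
(+ age)` with Type-II sums of squares — the most common reading of a
"two-way ANOVA controlling for age". It treats rows as independent; if both
hemispheres of the same subject enter one table, p-values are only
approximate (a subject-level random effect is out of scope).

## Microstates

GFP uses the population standard deviation (divisor = n channels). Peak maps
are local GFP maxima at least 10 ms apart (the larger peak wins a conflict);
if more than `n_peaks` (default 1000) survive, the highest are kept.

TAAHC operationalization (the published one-line description leaves these
open, so they are frozen here): clusters start as singletons; cluster
quality = Σ members |spatial correlation to the cluster prototype|; each
step dissolves the lowest-quality cluster (ties → lowest id) and reassigns
every orphan to the remaining cluster with highest |correlation|; prototypes
are the polarity-aligned member means, renormalized. All spatial similarity
is polarity-invariant. Agglomeration continues to a single cluster so the
dispersion curve W_K exists for K = 1…9.

K selection reports four criteria per K ∈ [2, 8]: global explained variance
GEV = Σ(GFP·corr)²/ΣGFP²; the Pascual-Marqui cross-validation criterion
σ̂²·((C−1)/(C−1−K))²; within-cluster dispersion W_K = Σ(1−corr²); and the
Krzanowski–Lai index KL(K) = |DIFF(K)|/|DIFF(K+1)| with
DIFF(K) = (K−1)^{2/m} W_{K−1} − K^{2/m} W_K and m = C−1 (average reference
removes one dimension). The default decision rule is max-KL; the other
criteria are reported for inspection.

Backfitting labels every sample (not only peaks) with the prototype of
minimal polarity-invariant GMD, equivalent to maximal |spatial correlation|;
samples with GFP below 1e-6 µV stay unassigned. Smoothing dissolves label
runs shorter than 30 ms: each sample of a short run joins the temporally
nearest run meeting the threshold, ties going to the preceding run, iterated
to a fixed point; if no run meets the threshold the longest run absorbs the
record (this is what makes a pathological single-sample alternation converge
rather than oscillate). Metrics are computed at run level: duration = mean
run length, occurrence = runs/s of record, coverage = sample fraction,
mean GFP over the state's samples, and transitions counted between
consecutive distinct runs (self-transitions impossible by construction),
normalized per source state.

Under the default simulation conditions (64 channels, 500 Hz, 5 min, 4
orthogonal states, SNR 4, 80 ms mean geometric dwell) the pipeline selects
K = 4, recovers prototypes at |r| > 0.99 and relabels ≈ 95% of samples after
Hungarian matching; transition probabilities on a 10-min record are within
±0.05 of the simulated kernel.

## Omics statistics

Chao1 uses S_obs + F1²/(2F2) with the bias-corrected form
S_obs + F1(F1−1)/2 when F2 = 0, and requires integer counts. Shannon uses
the natural log. Bray–Curtis, BH-FDR, Wilcoxon, Spearman and Fisher's exact
test delegate to scipy/statsmodels; the Wilcoxon switches from the exact
null distribution to the tie-corrected normal approximation above n = 10 per
group or in the presence of ties. The age-partialled Spearman rank-transforms
all three series, residualizes the x- and y-ranks on the covariate ranks by
OLS and correlates the residuals (t-approximation, df = n−3). Fisher's exact
two-sided p is the probability-mass rule (sum of tables no more likely than
the observed one).

PLS-DA is NIPALS PLS1 against ±1 class coding, centered internally;
VIP_j = √(p · Σ_a SSY_a w²_aj / Σ_a SSY_a) with unit-norm weight vectors, so
mean VIP² = 1 exactly. Differential calls use fold change on the raw scale
(direction group2/group1, recorded in the output header), two-sided Welch t
on log values by default (Wilcoxon available), and optional VIP > 1 and
BH q < 0.05 gates — both published thresholds are exposed as independent
switches because the publication applies both without stating which gates
the final lists.

## Fusion classifier

Fisher scores use the two-class weighted form with population (ddof = 0)
within-class variances and a 1e-12 variance floor (a separable feature gets
a large finite score instead of ∞); ranking ties break by ascending feature
id so selection is deterministic. The SVM is the soft-margin linear machine
(libsvm via scikit-learn); C defaults to 1 and is tuned on the 2⁻⁵…2⁵
power-of-2 grid by inner-loop CV accuracy, ties resolved to the smallest C
(strongest regularization). Fusion takes the union of per-modality top-10
sets, retrains on the candidates and re-ranks to a final top 10, keeping the
feature budget equal across single- and multi-omics models.

Two evaluation scopes are deliberately provided. `global` normalizes,
selects and tunes on the complete data set before cross-validation — the
protocol described for the original analysis. It leaks test information into
selection: on null (d = 0) cohorts it inflates LOOCV accuracy well above
chance, which is measurable here and flagged in every report.
`train_fold` refits everything inside each training fold; on null cohorts
its LOOCV accuracy stays inside the 95% binomial band around the
majority-class rate. Model comparisons (e.g. fused vs single modality) are
run under `train_fold`: at the default planted effect (d = 1.5, 10 features
per modality) the global protocol drives *every* modality to ≈100% accuracy
and the comparison degenerates into ties at the ceiling, whereas the honest
protocol shows the expected single < fused ordering in ~85–90% of
replicates. k-fold CV is stratified by round-robin over shuffled per-class
indices, so fold composition is reproducible from the scheme seed.

ROC-AUC is trapezoidal (equal to the Mann–Whitney U statistic divided by
n₊n₋); PR-AUC is the step-wise average-precision sum; the reported operating
point maximizes Youden's J = TPR − FPR (the original convention is
unstated; this choice is recorded in report metadata).
`confusion_from_rates` enumerates all integer confusion matrices at a given
N consistent with printed precision/recall to the printed number of
decimals; it is how the package audits published performance tables (one
published row — gut microbiota, precision 66.67% / recall 89.47% at 19
positives — admits no exact integer table and is reported via nearest
candidates instead).

## Problem sizes in tests and the acceptance script

Simulation suites run at the study's data sizes (N = 41 cohorts; 64-channel,
500 Hz, 5–10 min EEG) with replicate counts chosen to keep a full run to
tens of seconds per suite: 10–12 seeds for microstate recovery, 15–20 seeds
for the fused-vs-single comparison, 10 permutations for the null band.
Success-rate thresholds are proportions (≥90%, ≥80%) independent of the
replicate count. Deterministic oracles (closed forms, enumeration,
hand-computed examples, reference libraries) run exactly.

## Known limitations

- The OLS ANOVA ignores within-subject correlation across hemispheres.
- TAAHC details beyond the published one-liner are this package's frozen
  operationalization; other toolboxes' prototypes may differ in detail.
- Microstate labels are arbitrary indices; no cosmetic matching to the
  canonical A–D templates is attempted.
- The generator's independence assumptions (see above) make synthetic
  recovery an upper bound on real-data performance.
- EDF export is not provided; EEG interchange uses the float32-binary +
  JSON-sidecar pair.
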