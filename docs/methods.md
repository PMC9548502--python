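# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
establish about real data.

## Repertoire representation

A repertoire is a multiset of CDR3β amino-acid clonotypes with read counts.
Clonotype identity defaults to the amino-acid sequence alone, because
cross-subject sharing of TCRs is conventionally assessed at the aa level
(convergent recombination makes nucleotide-level sharing far rarer); a
`(cdr3_aa, v_gene, j_gene)` key is available for analyses where V/J context
matters. Sequences containing stop/frameshift markers are rejected by
default since all downstream statistics assume productive amino-acid
clonotypes. On ingestion, duplicate keys are aggregated by summing counts
and clonal fractions are renormalised; every repertoire satisfies
Σ fractions = 1 ± 1e-9.

## Diversity indices

All entropies use natural logarithms (the choice cancels in evenness and is
otherwise a units convention). For the fraction vector *p* over *S* clones:

* Shannon *H = −Σ pᵢ ln pᵢ*;
* Pielou evenness *J = H / ln S*, with the monoclonal limit (*S* = 1)
  defined as *J* = 0, clonality = 1 — the limiting value as a repertoire
  collapses onto one clone;
* clonality = 1 − *J* (the Pielou-complement definition; a Simpson-based
  clonality can be derived from the Simpson output if preferred);
* Gini–Simpson index 1 − Σ pᵢ².

Clonal-homeostasis bins use the standard right-closed thresholds
(0, 1e-5], (1e-5, 1e-4], (1e-4, 1e-3], (1e-3, 1e-2], (1e-2, 1] for
rare/small/medium/large/hyperexpanded. Both the read mass and the clone
count per bin are computed; group comparisons default to read mass because
the clinically meaningful quantity is how much of the circulating T-cell
pool sits in expanded clones, not how many distinct sequences do. Note the
rare bin requires clonal fractions below 1e-5 and is structurally empty at
sequencing depths under ~100 000 reads; the selection stage drops such
constant columns with a warning.

Group differences use the two-sided Wilcoxon rank-sum test (exact
enumeration for small tie-free samples via scipy, normal approximation with
tie correction otherwise). The test is reported in the output because
boxplot-with-p-value figures in this field rarely name the test; a
nonparametric choice is the safe default for skewed diversity indices.
Feature–clinical association uses Spearman correlation with tie-corrected
ranks and pairwise-complete missing handling; a constant input yields NaN
with a warning rather than an error, so one degenerate covariate cannot
abort a cohort-level scan.

## Sharing, enrichment and motifs

Sharing is exact clone-key identity across subjects. Group-exclusive clones
are those carried by at least one subject of the target group and no
subject outside it; the exclusive fraction is relative to all distinct
clones in the cohort (distinct-sequence counting, not read-weighted).

The enriched-sequence rule combines two selections: each subject's top 30
sequences by clonal fraction, and the top 3000 sequences by pooled fraction
across subjects; the union is then filtered to sequences present in at
least 2 subjects. The two sub-rules and the filter are individually
configurable because the composite rule admits several readings; the
implemented order (union first, support filter last) is the most inclusive
one. Ties in any "top N by fraction" ranking break by count, then
lexicographically, making the selection deterministic and independent of
subject order.

Motif search returns all maximal substrings of length ≥ `min_length`
contained in ≥ `min_support` distinct enriched sequences. Maximality means
no longer substring has the same support set; because support sets are
nested along substring containment, it suffices to compare support counts
of one-character extensions. The implementation is exhaustive hashing of
all substrings — for enriched sets of a few thousand CDR3-length sequences
this is ~10⁵–10⁶ dictionary operations and needs no suffix structure.

## Feature selection

Candidate features are the eleven repertoire features (richness, Shannon,
evenness, Simpson, clonality, total reads, five bin masses) plus four
clinical covariates (GGN flag, nodule size, age, sex; sex and GGN are 0/1
encoded, missing numeric covariates are cohort-median imputed with a log
entry). Two rankings are computed: mean-decrease-impurity importance from a
500-tree random forest (√p features per split, fixed seed), and information
gain of the label given the feature discretised into quartiles (features
with ≤ 4 distinct values are used as-is). Quartile binning is a
scale-invariant default that behaves identically for monotone transforms of
a feature. The two rankings are fused by mean rank position — a neutral
choice when neither method is privileged — with ties broken by higher
information gain, then name; the top-3 features enter the classifier.
`RankedFeatureSelector` exposes the same computation as a scikit-learn
transformer.

## TCRnodseek classifier

Training standardises the selected features (training means and scales are
stored and reused at prediction), then runs a genetic algorithm over the
SVM hyperparameters: kernel ∈ {rbf, linear}, log₁₀C ∈ [−2, 3],
log₁₀γ ∈ [−3, 1]. Fitness is mean AUC over stratified k-fold
cross-validation (default 5 folds, folds fixed once per training so every
genome is scored on identical splits). The GA uses tournament selection
(size 3), uniform crossover (rate 0.8), per-gene Gaussian mutation with sd
= 10 % of the bound range (rate 0.1), and elitism of 2 in a population of
30 for 40 generations — ordinary GA settings; elitism makes the recorded
best-fitness trajectory non-decreasing, which is asserted in the tests.
Fitness evaluations are cached by genome, so converged populations cost
little.

The final SVM is refit on all training rows with the selected
hyperparameters. Decision scores are mapped to a bounded predicted value by
an unpenalised logistic (Platt) fit on the training scores — bounded scores
are what the downstream waterfall and cutoff analyses assume — and raw
decision scores remain available. The operating point is the Youden cutoff
(max J = sensitivity + specificity − 1) computed on the training predicted
values, with the lowest maximising threshold taken on ties; computing it on
training data keeps the validation set untouched, and a supplied split can
be used instead. The whole train → predict path is deterministic under the
seed; models serialise to a single JSON document (scaler, support vectors,
dual coefficients, calibration, cutoff, GA trajectory) and the loader
evaluates the stored kernel expansion directly.

The TCR-ablation comparison retrains with the same seed (hence identical
folds) on the clinical columns only, quantifying what the repertoire adds
over CT-derived information.

## Evaluation

AUC is computed as the trapezoidal integral of the ROC curve swept over the
unique observed scores, which equals the Mann–Whitney rank statistic with
half credit for ties; the tests assert exact agreement with brute-force
concordant-pair counting. Confusion metrics at a cutoff report NaN for
empty denominators rather than failing. Stratified evaluation applies the
*global* model cutoff within each stratum (GGN vs non-GGN; nodule size
≤ 20 mm and ≤ 10 mm, inclusive thresholds; each malignant stage against all
benign subjects); strata containing a single class are flagged insufficient
and skipped. The expert-agreement table cross-tabulates pathology truth,
model calls and any number of expert raters.

## Synthetic cohorts

The generator's purpose is to emulate the statistical structure the
analysis assumes — heavy-tailed clone-size spectra, lower diversity and
excess hyperexpanded clones in malignant subjects, public clones, a
plantable CDR3β motif, correlated clinical covariates — with effect sizes
chosen so the planted effects are reliably detectable at cohorts of tens of
subjects. The defaults are design choices for testability, not estimates
from any patient cohort.

Each subject's clone-probability spectrum has two parts. An *expanded
head* carries mass *m* split across ~tens of clones by a low-concentration
Dirichlet draw; *m* is lognormal around a base expansion (0.05) plus, for
malignant subjects, the hyperexpansion boost (0.04). A *tail* of *K* clones
(lognormal around `clones_per_subject`) follows a roughened Zipf law:
log-weights −t·ln(rank) plus per-clone Gaussian roughness, with tilt and
roughness drawn per subject. The class diversity effect is planted directly
on the Shannon entropy: each subject draws a target entropy around the
entropy of its class's reference spectrum (a Zipf distribution over
`clones_per_subject` ranks with the class boost moved into the top clones,
exponents 1.05 benign / 1.25 malignant), and the tail log-weights are
tempered — raised to a solved exponent, found by bisection — until the full
spectrum matches the target. Because the reference entropy is strictly
decreasing in the boost, raising the boost lowers expected malignant
Shannon, and with equal exponents and zero boost the two classes are
distributionally identical.

This entropy-targeted construction is deliberate: in a pure one-parameter
Zipf model every diversity summary (Simpson, bin masses, richness) is a
deterministic function of the exponent, so all features would separate the
classes equally and feature selection would be a coin flip among
statistically equivalent proxies. Here the nuisance degrees of freedom —
realised clone count, expansion mass and its allocation, tail tilt and
roughness, sequencing depth (lognormal, sd 0.55 in log space) — vary
independently of the class label, so Shannon carries the class signal
directly while the other indices see it only through partially decoupled
channels. That is what makes the planted "Shannon + GGN" selection target
recoverable.

Reads are multinomial at the subject's depth; unobserved clones are
dropped. Sequences are uniform random strings over the 20 amino acids
(lengths 8–20), drawn from a cohort-wide public pool with probability 0.10,
and the planted motif (`SSGGSSYEQYF` by default) is embedded as a substring
of spiked clones (malignant spike rate 0.10 by default). Clinical
covariates: the GGN flag is Bernoulli with rates 0.02 benign / 0.92
malignant — planted as the dominant clinical discriminator, mirroring its
top importance in this diagnostic setting, and deliberately stronger than
realistic GGN prevalence so selection recovery is unambiguous at n = 50+50;
nodule sizes are lognormal (medians 12 mm benign, 16 mm malignant, keeping
the cohort mean near ~14 mm); ages are mildly informative; sex is not.
Malignant stages are drawn I/II/III with probabilities 0.7/0.2/0.1, typical
of screening-detected nodules. One global seed fans out to per-subject
substreams via spawned `SeedSequence` children, so cohorts are bit-for-bit
reproducible.

What passing tests on these cohorts does **not** show: performance on real
repertoires. The generator has no V(D)J recombination statistics or
generation-probability structure (public clones and motifs are planted, not
emergent), no batch or library-preparation effects, no HLA structure, and
class effects far cleaner than clinical reality — held-out AUCs near 1.0
here say the chain recovers a planted signal, not that the signal is this
strong in patients.

## Numerical and problem-size choices

Bisection for the tail temperature runs 40 iterations on [0.2, 5], with the
target clipped into the attainable entropy range. The Youden scan sweeps
unique observed scores exactly. Default test and acceptance problem sizes
(cohorts of 100–160 subjects, 150–1000 clones per subject, replicate counts
of 10–50) are chosen so each planted-effect check has clear statistical
margin while the full suite runs in minutes on one CPU; the GA used inside
replicate-based tests is smaller (population ~10, ~6 generations) than the
default configuration because the fitness landscape over three features is
smooth and converges quickly.

## Known limitations

* Exclusive-clone fractions are distinct-sequence based; a read-weighted
  variant is not implemented.
* No rarefaction or depth correction is applied to the diversity indices;
  sequencing depth is treated as a covariate-free nuisance (and is a known
  confounder of observed richness).
* The motif finder reports exact substrings only — no position-weight
  matrices, gaps or mismatches.
* Youden cutoffs estimated on small training sets are high-variance; the
  package reports them as computed and leaves smoothing to the user.
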