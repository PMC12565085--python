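# Methods

This note documents the modeling choices behind tkqsar: what each procedure
assumes, which knobs matter, and where the design was genuinely open.

## Curation model

Structures are standardized locally with RDKit: cleanup (valence and
hydrogen normalization), selection of the largest covalently connected
fragment (salts and counter-ions are dropped), canonical SMILES output. No
tautomer canonicalization is applied; standardization is idempotent and
deterministic, which the tests assert. Registry lookups against external
services are deliberately not part of the pipeline — canonical SMILES is the
identity key.

Replicate measurements of one standardized structure are merged by the
arithmetic mean of the equality-qualified (EQ) values. For F%, replicates are
treated as repeated measurements of one quantity, so the *sample* (n−1)
standard deviation is the discordance statistic; structures with sd > 20
percentage points are excluded (`STD_GT_20`), as are structures with any
replicate or merged value outside [0, 100] (`OUT_OF_RANGE`); the range rule
is applied before the sd rule. VDss replicates are mean-merged on the linear
scale before the ln transform and have no sd rule; non-positive VDss values
are physically impossible and are excluded under the same `OUT_OF_RANGE`
reason code. Inequality-qualified values never enter an average: an EQ value
wins, otherwise the structure is kept qualifier-only and can still feed
classification sets when the qualifier pins the class.

## Splits and discretization

The validation set takes every k-th chemical (k = 4, offset 0) of the
endpoint-sorted list, which preserves the endpoint distribution across the
split: within every window of k consecutive sorted chemicals exactly one is
validation. Ties are broken by record id so the split is seed-free and
deterministic. On 1618 EQ-valued chemicals this yields the 405/1213
validation/training partition. The split is made on EQ-valued chemicals
only; qualifier-only chemicals join classification training sets afterwards.

Class boundaries use a strict-greater "high" convention everywhere (a value
exactly at a cutpoint falls in the lower class), shared by the discretizer,
the regression-to-class converter, and the TK categorizer, so regression and
classification views of the same value can never disagree. A "<"/">" value is
labeled only when every value compatible with the qualifier lands in one
class; otherwise it is `UNKNOWN` and excluded from that classification set.

## Descriptors

Backends are pluggable behind one registry; the default computes RDKit's 2D
descriptor set (~210 columns). Per-molecule backend failures become missing
cells, never dropped rows. Filtering removes, in order: columns with any
missing cell, zero-variance columns, and — for every remaining pair with
|Pearson r| > 0.97 — the later column in lexicographic name order. The name
ordering makes the filter deterministic, idempotent and independent of row
order; the surviving matrix provably contains no pair above the cutoff. The
Topliss ratio (training chemicals per descriptor, rounded half-up, with a
compliance flag at > 5) audits parsimony after selection.

## Variable selection

The two-stage selector re-specifies the VSURF idea rather than porting the R
package; numerical parity with VSURF is a non-goal.

*Stage 1 (thresholding).* A 500-tree random forest is fit on the design
augmented with shadow descriptors (seeded shuffled copies of every real
column). Importance of a column is the mean decrease, over `n_repeats`
(default 3) permutations, of out-of-bag performance — R² for regression,
accuracy for classification — with per-tree OOB membership tracked exactly.
The noise floor is the mean + 1 sd of the shadow importances; real
descriptors must exceed it. Shadows preserve each column's marginal
distribution while destroying its relation to the response, which makes the
floor adaptive to the data instead of a fixed quantile.

*Stage 2 (stepwise forward).* Surviving descriptors are visited in rank
order; a candidate is kept when it lowers the mean 5-fold CV error (RMSE or
misclassification rate, from 100-tree forests) by more than one standard
deviation of the incumbent model's fold errors, starting from the trivial
model (fold-train mean / majority class). The walk stops after `patience`
(default 3) consecutive rejections. The one-sd rule is a deliberate
conservative bias: it trades a small risk of missing weak signal for strong
protection against noise descriptors entering the interpretation set, which
the all-noise property test quantifies.

## Learner harness

Learners are adapters satisfying fit/predict only; random forest
(scikit-learn) and two gradient-boosting flavors (XGBoost, LightGBM) ship by
default, and any factory — including an external graph network — can be
registered. Grid search evaluates every point on shared seeded 5-fold splits
and selects by the fixed per-task criterion: highest mean Q²F3 (F%
regression), lowest mean GMFE (VDss regression), highest BA (binary), highest
macro-BA (multiclass); ties go to the first-listed point, and a point whose
fit fails scores worst. Robustness uses repeated CV — a fresh seeded
5-partition per iteration, 50 iterations by default — reporting mean ± sd
per metric; each iteration's folds are asserted to partition the training
set exactly. VDss models are fit on ln(VDss) and predictions are
exponentiated before thresholding or GMFE.

## Metrics

All metrics are computed at full precision; rounding is a reporting-layer
concern. R² is the 1 − SS_res/SS_tot form about the validation mean. Q²F3
normalizes the validation mean-square error by the training variance, making
it comparable across validation subsets — the property the AD curves rely
on. GMFE uses the absolute log₁₀ fold error, 10^(Σ|log₁₀(ŷ/y)|/n); without
the absolute value over- and under-predictions would cancel and any model
could reach the perfect value 1. Multiclass metrics are one-vs-rest per
class; macro averages classes equally, micro pools the one-vs-rest counts.
With two classes the pooled counts are symmetric and micro-SE = micro-SP =
accuracy — an identity the tests assert. Every metric is cross-checked
against independently coded brute-force oracles on random fixtures.

## Applicability domains

*3-NN Tanimoto.* Morgan fingerprints (radius 2, 2048 bits; both config keys)
are deterministic per canonical SMILES. A query's AD score is the mean
Tanimoto similarity of its three most similar training chemicals (ties
broken by training id). The cutoff is Dc = ⟨y⟩ − Z·σ with Z = 0.5, where
⟨y⟩, σ are the mean and population sd of the per-chemical scores;
subtraction (not addition) is correct on the similarity scale, where 1 means
identical — the classical formula adds because it operates on distances.
The PLUS mode is exposed for comparison but MINUS is the documented default.
The population-σ choice differs from the sample form by less than reporting
precision for n ≥ 300. Coverage–performance curves recompute the chosen
metric on the retained subset per threshold; coverage is non-increasing by
construction.

*Structural-alert LR.* Alerts are connected substructures (heavy-atom window
[2, 18] by default; bond subgraphs up to one ring closure) enumerated from
the training library, deduplicated by canonical fragment SMILES and scored
one-vs-rest per class with the prevalence-normalized likelihood ratio
LR = (tp/n_target)/(fp/n_nontarget), so class imbalance cannot inflate
scores. Zero-false-positive alerts have infinite LR and are capped at the
rule set's maximum finite LR; if no finite LR exists the cap falls back to
(tp/n_target)·n_nontarget, the largest LR resolvable at one false positive.
Rules below min_support (3) or min_lr (2) are dropped; ordering is
(LR desc, support desc, pattern asc); a rule whose matched training set is a
subset of a higher-ranked *same-class* rule's is pruned — cross-class
pruning is not applied, so minority-class alerts survive coverage overlap
with the other class's rules. Prediction takes the first matching rule; its
capped LR is the AD score, with unmatched chemicals always out of domain.
Mining is seed-free and independent of training input order.

*Leverage.* As a descriptor-space alternative, hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ on the
intercept-augmented design (so the training centroid has the minimum 1/n),
with the conventional warning cutoff h* = 3(p+1)/n.

## TK mapping

Categorization thresholds: VDss 0.6 and 5 L·kg⁻¹, F% 30 and 60 %,
elimination half-life 4 and 24 h, all with the shared strict-greater "high"
convention. Half-life is an input column from an external predictor; when it
is missing the chemical is categorized on the available properties and the
concern flag — true iff at least one category is high — considers those
only. Out-of-AD predictions are categorized but marked, never dropped, and
family summaries report the flagged fraction both over all chemicals and
restricted to in-AD chemicals, since either denominator can be the relevant
one for screening.

## Synthetic data

The generator assembles molecules from eight drug-like cores and sixteen
acyclic substituents, appending at most one planted terminal fragment per
molecule; this guarantees validity and uniqueness without a generative
model. Planted fragments use elements (F, S) absent from the base grammar,
and carrier sets are exact counts (round(rate·n), chosen by seeded shuffle),
so recovery tests have crisp ground truth. F% follows
clip(base + Σ effects + N(0, σ), 0, 100) — clipping reproduces the boundary
peaks of real bioavailability data — with base 70, effects −40 (CF3) and
+25 (dimethylamino) at rate 0.3 each, and σ = 5 by default; VDss is
exp(Σ ln-scale effects + noise), strictly positive and right-skewed.
Curation hazards (duplicate structures with discordant replicates,
qualifier-only records, out-of-range F%) are planted on disjoint subsets at
rates 0.05/0.05/0.02. What this library does *not* emulate: realistic
medicinal-chemistry descriptor correlations, activity cliffs, assay-specific
error structure, or the true chemical space of either endpoint — passing
recovery tests demonstrates algorithmic correctness, not real-data
predictive performance.

## Problem sizes and numerical choices

Test and example configurations run at desk scale by choice: synthetic
libraries of 120–400 chemicals, repeated CV at 2–5 iterations, alert-mining
windows of [2, 5–6] heavy atoms (the planted fragments have 3–4 heavy
atoms), selection forests of 100–300 trees for the 20-seed recovery study.
The shipped defaults remain the full-scale ones (50×5 CV, 500-tree ranking
forests, [2, 18] mining window). Degenerate inputs fail loudly with stable
error codes (`UNPARSEABLE_SMILES`, `ZERO_TRAIN_VARIANCE`,
`SINGULAR_MATRIX`, …) rather than returning sentinel values; boundary
conventions (cutpoint ties, empty fingerprints, empty AD subsets) are fixed
and tested rather than left to library defaults.

## Known limitations

* No parity with R's VSURF or with the original SARpy fragmentation grammar;
  both procedures are re-specified with documented defaults.
* Alert mining enumerates bond subgraphs up to one ring closure per
  fragment; polycyclic fragments beyond that are not candidates.
* Fragment SMILES are matched as SMARTS, which ignores hydrogen-count
  context; two fragments differing only in implicit hydrogens can collapse.
* The leverage AD assumes a full-rank descriptor matrix after filtering.
* Binary model persistence is out of scope: a fitted model is reproduced
  from its manifest (learner, hyperparameters, descriptors, transform,
  seeds) rather than serialized.
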