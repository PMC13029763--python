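# Methods

## The analysis in brief

The pipeline treats bioactivity modeling as binary classification of
compound–target interaction from circular-fingerprint representations.
Assay records are reduced to one labelled structure each; models are
evaluated under scaffold-grouped splits so that performance reflects
generalization to unseen chemical series rather than memorization of
analogues; an external library is then ranked by a seed ensemble, with
every prediction qualified by its distance to the training distribution.

## Curation model

A record survives filtering only if it is a quantitative concentration
measurement (IC50/Ki/Kd/EC50) in nM or µM, from an assay with confidence
score ≥ 7, with a positive numeric value, an exact "=" relation, a present
SMILES, and a validated or unassigned standardization flag. Rejections are
logged with the *first* failing predicate in the fixed order type → unit →
confidence → value → relation → smiles → flag; the order is a reporting
convention, not a scientific claim, and retained ∪ rejected always equals
the input.

Only IC50 records feed labeling. Concentrations are converted exactly
(µM × 1000 → nM) and transformed as pActivity = 9 − log₁₀(C_nM), so 1000 nM
↔ 6.0. Per-compound aggregation keeps the *maximum* pActivity (most
favorable measurement) by default; mean and median are available but not
used for the primary tables. The label threshold is inclusive:
pActivity ≥ 6.0 is positive, i.e. submicromolar potency.

Structure-level deduplication operates on canonical isomeric SMILES after
optional largest-fragment reduction (heavy-atom count; ties broken by the
lexicographically smallest canonical fragment SMILES so the result is
independent of fragment order). Merging rules are fixed: max pIC₅₀, OR of
positive labels, median of auxiliary numeric fields, and all other fields
inherited from the first contributing record in input order.

## Scaffold splitting

Bemis–Murcko frameworks (rings plus linkers, side chains removed) define
leakage groups; acyclic molecules share one empty-scaffold group. Groups
are ordered by size, permuted under the split seed, and assigned greedily
to the subset whose compound count is furthest below its target
(0.8/0.1/0.1 of compounds), ties resolved train > val > test. This greedy
largest-deficit rule is deterministic per seed, never divides a group, and
converges to the target fractions when groups are small relative to the
dataset (1000 singleton groups land on 0.800 exactly). A sequential-fill
alternative (fill train, then val, then test) is available behind a config
switch for comparison. Deficits are measured in compounds, not groups,
since the target fractions refer to compounds.

## Modeling and evaluation

All families consume the same cached 2048-bit, radius-2 Morgan
fingerprints (chirality off). Hyperparameters are tuned by randomized
search — 25 sampled configurations by default, stratified 5-fold CV on the
combined train+val subset, mean ROC-AUC objective — with the search, the CV
shuffling and the estimator all seeded by the split seed. The winner is
refit on all train+val rows and evaluated once on the test subset.
Logistic-regression and neural-network inputs are standardized inside the
CV pipeline so scaling is refit per fold.

Out-of-fold predictions reuse the same seeded folds, so every tuning row is
predicted exactly once by a model that excluded it. Metrics: rank-based
ROC-AUC, step-wise average precision, MCC and balanced accuracy at a fixed
0.5 threshold (probability equal to the threshold predicts positive), and
full confusion matrices. With a single class present, AUC/AP are reported
as an explicit undefined marker rather than a number. Cross-seed summaries
report mean and sample SD (n−1; a single seed reports SD 0 with a flag) and
rank models by mean test AUC, ties broken by mean test AP.

Calibration uses ten equal-width bins on [0,1] (probability 1.0 falls in
the last bin; empty bins are omitted from the curve but counts are
conserved) plus the Brier score. Decision thresholds are selected on OOF
predictions only: candidates are the midpoints between consecutive sorted
unique OOF probabilities plus 0 and 1, the MCC (or balanced-accuracy)
maximizer wins, ties go to the smallest candidate, and the frozen threshold
is applied unchanged to the test set.

## Applicability domain and stratification

Domain membership is inclusive: max Tanimoto similarity to the train+val
reference ≥ 0.35 is in-domain. Tanimoto of two all-zero fingerprints is
defined as 0 to avoid a 0/0. Similarity strata use fixed half-open bins
[0, 0.20), [0.20, 0.35), [0.35, 0.50), [0.50, 0.70), [0.70, 1.00] — the
half-open convention makes the 0.35 bin edge coincide exactly with
in-domain onset and maps every value to exactly one bin. Descriptor and
probability strata are quartiles of the evaluated set's own distribution
(duplicate quantile edges merged, merged labels reported). Scaffold
frequency counts occurrences of each test scaffold in train+val, binned as
0 / 1 / 2–5 / 6–20 / ≥ 21; the empty scaffold counts as one shared group.
Under scaffold splitting every non-empty test scaffold is necessarily in
bin 0 — the test suite asserts this cross-module invariant exactly.

At the screening stage the domain reference is the seed-1 train+val set,
while training-stage analysis is per-seed; both behaviors are implemented.

## Attribution

Feature attribution is computed in-house and is exactly additive where the
route permits: per explained sample, base value plus the per-feature
contributions reconstructs the model output to machine precision.

- **Tree path (forests):** for each tree, walking a sample's decision path
  and crediting the change in node value (positive-class fraction) to each
  split feature telescopes exactly to leaf − root; averaging over trees
  gives probability-scale attributions with base = mean root value.
- **Tree path (gradient boosting):** same walk on the regression trees,
  scaled by the learning rate, on the log-odds scale; the constant initial
  raw score is recovered from a reference prediction.
- **Linear:** φⱼ = wⱼ(xⱼ − μⱼ) against the background mean μ on the
  log-odds scale.
- **xgboost:** the booster's native per-feature contribution output.
- **Fallback:** seeded permutation-sampling Shapley estimates on the
  probability scale, walking only the features where the sample differs
  from the drawn background row (cheap on sparse binary fingerprints);
  additivity then holds only in expectation and tests use a loose
  tolerance.

Explanation sets are sampled without replacement (≤ 2000 explain, ≤ 200
background) under the split seed. Global importance is the within-seed mean
|φ| per feature, aggregated across seeds as mean ± sample SD.

Bit environments are reconstructed from the fingerprint generator's bit-info
map: every (center atom, radius) pair hashing to a bit is reported with its
induced substructure SMILES. Hash collisions are expected and all colliding
environments are reported rather than guessing a single "true" motif.

R-group analysis selects the modal non-empty Murcko scaffold among scored
compounds, subject to a minimum series size (default 10; ties → higher mean
score, then lexicographically smaller SMILES), decomposes members against
that core, canonicalizes substituent fragments (dummy-atom attachment
convention) so identical fragments unify, reports per-position counts and
mean scores (substituents below a minimum count are flagged out of
comparisons), and emits the R1×R2 mean-score grid only for combinations
with support ≥ 3.

## Screening

Seed models (1–3) score the cleaned library; per-compound mean and sample
SD are retained, and ranking breaks probability ties by public id for full
determinism. Library preparation mirrors training featurization, asserting
an identical fingerprint parameter hash. The 2-D embedding is PCA (≤ 50
components, limited by sample size) followed by UMAP (n_neighbors = 25,
min_dist = 0.10, seeded); for large libraries a random subsample is
embedded with forced inclusion of all top-ranked candidates. The embedding
is reporting plumbing — tests cover shape, inclusion and determinism, not
coordinate values.

Diversity selection is sphere-exclusion clustering at Tanimoto distance
≤ 0.35: iteratively, the unassigned compound with the most unassigned
neighbors seeds a cluster (ties → higher ensemble score, then smaller id)
and claims its unassigned neighbors, so every member lies within the cutoff
of its centroid. Each cluster's highest-scoring member represents it; the
shortlist is the top representatives by score. Note this variant recounts
unassigned neighbors each iteration rather than freezing the initial
neighbor counts; an independent brute-force implementation of the same
rules serves as the test oracle.

## Synthetic study conditions

The generator emulates the two real data regimes at defect level, not at
chemical-space fidelity. Compounds are built by attaching acyclic
substituents (pool of 10 fragments) to ring-system cores enumerated from a
fixed alphabet so that families are Murcko-distinct; latent pActivity is
base (5.5) plus planted substituent effects (carboxylic acid +1.5, primary
amide +0.7, chloro −0.7 log units), and each record reports
10^(9 − (latent + ε)) nM with ε ~ N(0, 0.3²) per record. Defaults: 2000
compounds over 150 families, 30% of records re-expressed in µM, 0.3
expected replicates per compound, 5% inexact relations, 2% unparsable
SMILES (from a fixed list, for deterministic audit counts), 5% salt forms,
5% low-confidence and 5% non-IC50 records. The screening library (600
entries) mixes in-family compounds with remote acyclic decoy chemotypes
(perfluoroalkanes, polyols, fatty esters) so the domain split is
non-degenerate, plus duplicates and defective rows. One seeded generator
stream with documented draw order makes identical specs yield
byte-identical tables.

These conditions are deliberately easier than real assay data: substituent
effects are additive and noiseless at the compound level, families are
cleanly separable, and decoys are trivially out-of-domain. Passing tests
therefore demonstrate that the machinery is correct and leak-free — they do
not predict discrimination levels on real bioactivity collections.

## Problem sizes and numerical choices

Heavier end-to-end checks run at reduced search effort (5 sampled
configurations instead of 25, shared across tests via a session fixture)
and the determinism check uses a 300-compound configuration with one seed;
the data-generating conditions themselves are never reduced. Tolerances:
metric implementations must match brute-force oracles to 1e−9; additive
attribution to 1e−6; similarity oracles to 1e−12. Degenerate inputs have
defined behavior throughout: empty filter input passes through, single-class
strata report undefined AUC/AP but keep MCC, empty clusters cannot occur by
construction, and an absent qualifying scaffold series yields an explicit
"no series" result.

## Known limitations

- Tautomer and charge standardization beyond largest-fragment keeping is
  not performed.
- The synthetic generator does not property-match decoys to actives or
  simulate ADMET/3-D properties.
- Scaffold-split target fractions are approached greedily; with a few very
  large scaffold groups the realized fractions can deviate substantially
  (an inherent property of group-level assignment, reported per split).
- Sampling-based attribution for non-tree, non-linear models is an
  estimate; its additivity is approximate and its cost grows with the
  explain set.
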