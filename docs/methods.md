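# Methods

## Problem setting

A protein–protein interaction (PPI) is an unordered pair of proteins.
Given curated positive interactions (experimentally detected), a negative
reference set, and per-protein annotation resources, the package trains
(a) a binary classifier that assigns each candidate pair an interaction
probability and (b) a regressor that estimates binding strength as a
normalized Gibbs free energy, then screens a receptor set against a
proteome and ranks the predicted interactions. All pair-level quantities
are symmetric: pairs are canonicalized by sorting the two UniProt
accessions, and every feature is invariant under argument exchange.

## Dataset curation

The curation cascade over MITAB-style records is: keep pairs where both
identifiers match the UniProt accession pattern; deduplicate by the
redundancy-group key (the RIGID/interaction-checksum column when present,
otherwise the canonical pair key — the two encode the same "same set of
proteins" semantics); filter by detection method (training keeps records
with at least one allowed method, e.g. yeast two-hybrid or tandem affinity
purification; testing keeps records with none of them); keep the stated
host taxon. These predicates are independent, so the cascade is
order-insensitive (asserted by test). Negatives are drawn from the
negative pool without replacement, `round(ratio x n_positives)` of them,
under a NumPy generator seeded explicitly; records labelled both positive
and negative abort assembly with an error.

Test/train homology decontamination removes a test pair (a, b) iff some
training pair (c, d) satisfies E(a,c) < t and E(b,d) < t, or the cross
match E(a,d) < t and E(b,c) < t, with t = 0.05 by default. E-values come
from a precomputed symmetric table; a missing entry is treated as
not-similar (conservative retention) and counted in the log, since an
incomplete all-vs-all search should not silently discard test data.

Splits use `floor(fraction x n)` training records (519 records at 0.8
give 415/104, matching the affinity-split convention), while negative
sampling uses `round` (1,678 positives at ratio 2 give exactly 3,356).

## The 61-feature registry

Fixed order: 3 GO similarities, 4 orthology flags (M. musculus,
D. melanogaster, S. cerevisiae, E. coli), 4 database flags (MINT, APID,
BIOGRID plus a configurable fourth source labelled "DB4" by default —
only three sources are named in the selected-feature vocabulary), the
pairwise sequence-similarity E-value, the Pfam domain–domain interaction
flag, co-localization, 17 Spearman co-expression correlations (one per
expression dataset; a configuration hook can append further datasets,
e.g. two RNA-seq series, extending the registry beyond 61), and 30
absolute physicochemical differences.

Choices that were genuinely open:

* **GO similarity** is the Jaccard index over direct annotations per
  aspect (both sets empty → missing). It is the simplest measure
  satisfying the [0,1] similarity contract; an information-content
  measure can be plugged in through the `measure` callable. No ancestor
  propagation is performed.
* **Secondary-structure fractions** use the classical residue classes
  helix {V,I,Y,F,W,L}, turn {N,P,G,S}, sheet {E,M,A,L}, implemented
  in-package with configurable sets. (Current biopython releases use a
  different, newer convention, so this is deliberately not delegated.)
* **Charge at pH 7** is Henderson–Hasselbalch over the EMBOSS pKa table
  (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
  Y 10.1), with the table swappable.
* Molecular weight, aromaticity, instability index, GRAVY and the molar
  extinction coefficients delegate to Bio.SeqUtils.ProtParam; the
  instability index is undefined for single-residue sequences and
  reported missing.

Missingness is a first-class mask: a feature that cannot be resolved
(no expression profile, unaligned pair, unknown localization, undefined
correlation on a constant vector) is NaN + flagged, never zeroed.
Imputation happens only inside model-training folds.

## Affinity endpoint

ΔG = RT ln K with R = 8.314 J mol⁻¹ K⁻¹, the experimental temperature
when stated and 300 K otherwise, output in kJ/mol. Curation keeps human,
dimeric, exact-valued records in Kd/Ki (molar units) or ΔG (kJ/mol or
kcal/mol); ranges and inequalities are rejected as imprecise, other
units rejected, duplicate unordered pairs collapsed to first occurrence,
each rejection carrying a reason code. The regression endpoint is the
min-max normalization of the retained ΔG values; the scaler is fitted on
the training endpoint and reused for inversion (RMSE on the [0,1] scale
times the scaler span equals RMSE in kJ/mol — an exact affine identity,
asserted numerically). Ranked libraries print |ΔG|; the sign convention
(more negative = stronger) is kept internally.

## Evolutionary model optimization

**Genome.** A vector in [0,1]^(d+4): d feature genes (selected iff
≥ 0.5; an all-off mask is repaired by enabling the argmax gene), one
estimator-selector gene (binned over the estimator list), and three
hyperparameter genes — C and gamma decoded log-uniformly onto
[2⁻⁵, 2¹⁵] and [2⁻¹⁵, 2³], tree count affinely onto [10, 500]. The
classification estimators are RBF SVM and random forest; the regression
estimators are linear SVR, RBF SVR and a forest regressor, with a small
feed-forward net available behind a flag but disabled by default
(determinism preferred; its architecture is not part of the method
definition).

**Evaluation.** Stratified k-fold cross-validation (k = 10 by default)
with fold-internal preprocessing: mean imputation and [0,1] min-max
scaling fitted on the training part of each fold only. Objectives are CV
means, normalized to maximize-oriented [0,1]:

* classification — feature-count minimization (weight 1), accuracy (10),
  F1 (10), F2 (1), precision (1), recall (1), ROC-AUC (1), model-size
  minimization (support vectors or trees, normalized by the training
  fold size or the tree bound; weight 1), and the Manhattan objective
  (1), interpreted as the mean L1 distance between the positive-class
  probability and the binary label;
* regression — feature-count minimization (the "feature significance"
  goal, weight 1), negative MSE (10), MAE (1), explained variance (1),
  model-complexity minimization (1), RMSE (1) and Spearman correlation
  (1), mapped to [0,1] via (rho+1)/2. MSE/MAE/RMSE are bounded by the
  [0,1] endpoint, so 1 − value is the normalized objective.

SVM class probabilities are the logistic squashing of the decision
function (ROC-AUC uses the raw decision scores); Platt scaling would add
an internal CV and nondeterminism for no benefit to rank-based metrics.

**Search.** The scalarization used for selection pressure is the
weighted sum of the normalized objectives. Each generation: the current
archive Pareto front re-enters the population (elitism, capped at half
the population, best-fitness first), and the rest are bred by binary
tournament on weighted fitness, two-point crossover with probability
0.9 (arithmetic crossover probability 0 by default), and per-gene
uniform-resample mutation at 0.01. Defaults: population 50, 100
generations for classification, 1000 for regression; the run count for
averaging is configurable (default 3). Evaluations are cached by genome
bytes, and the returned front is computed over the archive of *all*
evaluated individuals, then refitted on the full training data. Runs are
bitwise reproducible under the seed.

**Best model and ensembles.** The best model is the argmax of weighted
fitness (ties: fewer selected features, then lexicographic genome). The
front ensemble filters members by CV quality — accuracy strictly above
0.80 for classifiers, Spearman correlation strictly above 0.2 for
regressors, applied once at front load since CV metrics are the only
ones available at prediction time — and per sample a member votes only
when less than 50 % of its selected features are missing. Classification
is by majority vote with the mean positive-class probability reported;
even-vote ties resolve by mean probability ≥ 0.5. Regression averages
eligible members. A sample with no eligible voter is flagged
unpredictable rather than given a default.

## Screening and ranking

Candidate pairs are all unordered pairs containing at least one receptor
accession (self-pairs excluded). The classifier runs in best-model mode
over every pair; the regression ensemble runs over the predicted
positives only. The binding-strength score used for ranking is the
min-max scaling of |ΔG| over the screened positive set; no universal
scaling constants exist for predicted affinities, so the scaling is
data-dependent by default and configurable to a fixed scaler. Pairs are
ranked by the mean of probability and scaled affinity, descending, with
deterministic tie-breaks (probability, then pair key). The network export
keeps edges with probability strictly greater than the threshold
(default 0.55) and tags nodes with taste classes from a supplied catalog
file; no biology is hard-coded.

## Synthetic worlds

The generator emulates the real inputs: random sequences of length
50–350 drawn with natural residue frequencies (so composition features
carry variance), GO/Pfam/localization/expression annotations, MITAB
interaction files, negative lists, E-value tables, affinity tables and a
ground-truth manifest sufficient to recompute every label. Default
conditions: 300 proteins, 200 positive and 400 negative pairs (the 2:1
imbalance of the training corpus), label noise 0.05, and exactly five
informative features — BP and MF GO similarity, the Pfam interaction
flag, co-localization, and one co-expression dataset — with effect
sizes 0.7–0.8 (the probability that a true-positive pair receives the
enrichment). Interacting pairs share GO terms, a domain pair inserted
into the DDI table, a compartment, and a common latent expression factor
(mixing weight 0.9, expected Spearman rho ≈ 0.8). Orthology and database
flags fire at a 5 % background rate independent of label, and E-values
are log-uniform and uninformative, so they act as noise features.

Planted affinity is a linear rule, ΔG = −20 − 25·MF − 8·Pfam − 5·coloc
plus Gaussian noise, giving values in a realistic −58…−20 kJ/mol range;
half the rows are emitted as Kd by inverting ΔG = RT ln K at a stated
temperature, and decoy rows (ranges, unsupported units, non-human,
non-dimeric, duplicates) exercise every curation reason code.

What passing on these worlds shows — and does not. The worlds have
independent noise features, exchangeable proteins and clean annotation
tables; real interactomes have correlated features, hub proteins, study
bias and annotation incompleteness that the generator does not emulate.
Recovery of planted signal therefore validates the machinery (feature
computation, CV hygiene, search, ensembling), not real-data performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run a scaled-down optimization
on the default world: population 30, 20 generations, 5-fold CV, forest
sizes bounded at [10, 100], three fixed seeds. Under these conditions
the Pareto set reaches CV ROC-AUC above 0.9 and selects informative
features at roughly twice the noise-feature rate (binomial p ≪ 0.01).
A run's attained AUC is read off its Pareto set (AUC is an explicit
objective, so the front's AUC-best member is the AUC-optimal solution
found). Tolerances elsewhere: normalization round-trips are exact to
1e-12; metric reconstructions from printed rates are checked to 0.02
percentage points (the resolution implied by rate rounding); dominance
uses strict Pareto semantics with ties kept.

## Known limitations

* GO similarity ignores the ontology graph; semantically close but
  disjoint term sets score 0.
* The fourth database flag has no canonical source name and defaults to
  a placeholder label.
* The regression "feature significance" goal is implemented as
  feature-count minimization; per-feature significance weighting is not
  defined by the method description.
* The neural regressor is a stub estimator kind, off by default.
* Screening scales linearly in candidate pairs; no out-of-core batching
  is implemented.
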