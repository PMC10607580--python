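# Methods

`genecomm` implements a supervised framework for finding *discriminative
gene communities* in bulk expression data: groups of co-expressed genes
whose joint expression pattern separates two sample classes (here called
tumor vs normal). The framework has three phases — community detection on
a signed co-expression network, per-community feature selection and
classification, and Shapley-value explanation — plus a synthetic-data
generator that provides ground truth for every phase.

## Signed co-expression network

Genes are nodes; the edge weight between two genes is the Pearson (or
Spearman) correlation of their expression profiles across samples, kept
with its sign. The network is complete: no hard threshold is applied,
because the community objective consumes signed weights directly and
thresholding would add an arbitrary parameter. Constant genes, whose
correlation is undefined, are dropped with a warning. During hierarchical
recursion, subnetworks inherit the parent's edge weights (the procedure is
applied "independently" to communities of the existing network); a flag
allows re-estimating correlations per subnetwork for sensitivity analysis.

## Community detection: stability-driven hierarchical Leiden

**Objective.** Standard Newman–Girvan modularity is undefined for negative
weights. The scoring function `signed_quality` uses the common two-layer
extension Q = Q⁺ − Q⁻, where Q⁺ (Q⁻) is the γ-resolution modularity of the
positive (absolute negative) layer. The *optimizer*, however, maximizes a
deliberately asymmetric variant: γ-resolution modularity on the positive
layer minus the raw within-community negative weight (a null-free penalty
layer). The reason is a pathology of the symmetric form on correlation
networks: when the negative layer carries only noise-level weight, its
total strength 2m⁻ is small and the configuration-null term
γ·K⁻c·K⁻d/(2m⁻) becomes large for any pair of groups with appreciable
negative degree, *rewarding* their merger at every resolution. We verified
numerically that the symmetric objective prefers merging two independent
planted modules. The asymmetric form implements the design goal literally
— positive weight belongs inside communities, negative weight between
them — and has no such term. Optimization uses the Leiden
move/refine/aggregate cycle (leidenalg, two igraph layers with weights
+1/−1), each run seeded and started from a random assignment of nodes to a
random number of groups. The randomness parameter β recorded in the
configuration labels the run ensemble and enters per-run seed derivation;
the backend's internal refinement temperature is fixed, so distinct β
values produce re-randomized but statistically identical ensembles, and
the default β grid is the single value 0.05.

**Stability selection.** For each resolution γ in the grid (default 0.5,
0.75, 1.0, 1.25, 1.5) the algorithm is run L times (default 100) from
different random initial configurations. The ensemble is summarized by the
majority partition (most frequent partition up to label permutation) and
by the mean pairwise normalized mutual information
⟨NMI⟩ = 2/(L(L−1)) Σ_{a<b} NMI(p_a, p_b), with NMI = 2I/(H_a+H_b) on
natural-log entropies. A configuration is accepted only if the majority
partition is simultaneously

* **stable** — ⟨NMI⟩ ≥ 0.80,
* **nontrivial** — more than one community,
* **not fragmented** — no community smaller than 5% of the current
  (sub)network, strict inequality.

Among accepted configurations the one with the highest ⟨NMI⟩ wins. Exact
ties (several configurations at ⟨NMI⟩ = 1.0 are routine on clean
structure) are broken by *resolution-plateau width*: the majority
partition that recurs across the largest number of accepted configurations
is preferred, then higher signed quality at the reference resolution γ=1,
then smaller γ and β. The plateau rule reflects an asymmetry in the
procedure's failure modes: over-splitting is caught by the fragmentation
rejection, but a coarse merge below the 100-gene recursion bound is
irreversible, so when stability cannot discriminate, the partition robust
across resolutions is the safer choice.

**Hierarchy.** Detection recurses depth-first: communities of an accepted
majority partition with ≥ 100 genes are treated as subnetworks and
re-analyzed; communities with 4–99 genes become final leaves; communities
with < 4 genes are discarded (recorded with the reserved leaf id 0, so
gene accounting is conserved). A node of ≥ 100 genes where no
configuration is accepted is recorded as *unresolvable* rather than
force-split. The 5% fragmentation bound is evaluated against the current
subnetwork, not the root network.

## Feature selection: Boruta and the 40/60 split

To avoid leakage, samples are split once into a 40% selection set and a
60% classification set (stratified by class, nearest-integer rounding).
Boruta runs on the selection set only. Each iteration appends one freshly
permuted "shadow" copy of every active feature, fits a random forest
(default 300 trees, √p candidate features per split), and credits a *hit*
to every feature whose importance exceeds the best shadow importance.
Cumulative hits are tested against Binomial(t, ½): features in the upper
tail at the Bonferroni-corrected level (α = 0.05 over the features still
undecided) are confirmed, features in the lower tail are rejected and
leave the pool. The run stops when nothing is tentative or after
`max_iterations` (default 100; the binomial test cannot reach significance
before ~11 iterations at these settings, which sets the effective minimum
run length). Importance is the forest's impurity importance by default —
it is what the widely used Python implementation of the algorithm employs
and costs one forest fit per iteration; permutation importance is
available behind a flag at substantially higher cost. Features still
tentative at the end are excluded from classification by default.

## Classification and metrics

Each community (restricted to its Boruta-confirmed genes) gets a random
forest of M = 300 CART trees grown on bootstrap samples with *all*
features eligible at every split (s = |S|; √|S| is available as an
option). Performance is estimated by stratified 5-fold cross-validation
repeated (default 100×; smaller repeat counts are used in the test and
acceptance runs to keep them at desk scale): each repeat draws fresh
folds, held-out probabilities of a repeat are pooled into one metric set,
and the report is mean ± sd over repeats. Four metrics are computed from
pooled held-out probabilities:

* accuracy at the strict rule "positive iff p > 0.5" (in %),
* AUC by positive/negative pair counting with half credit for ties
  (equivalently the Mann–Whitney rank form; in %),
* F1 of the positive (tumor) class (in %),
* log loss, −(1/n) Σ [y log p + (1−y) log(1−p)], natural logs,
  probabilities clipped to [1e−15, 1−1e−15]. Log loss is non-negative by
  definition.

Communities whose mean accuracy exceeds a cutoff (default 90%) are
retained, and can be validated on an independent expression matrix:
features are matched by gene identifier, genes absent from the external
data are imputed at their training means (logged), and a single point
estimate per metric is reported.

A note on attainable accuracy: because a community's class signal lives on
its latent factor, the Bayes accuracy of a single-factor community with a
2-SD class shift is ≈ 85% at a 150:90 class ratio (the forest reaches the
corresponding AUC limit Φ(√2) ≈ 0.92). Mean accuracies above 90% therefore
require either stronger shifts or multiple informative factors; the
demonstration pipeline plants a 3-SD shift for exactly this reason.

## Shapley-value explanation

The contribution of gene j to the classifier's output for sample x is its
Shapley value: the factorially weighted average over feature subsets F of
v(F ∪ {j}) − v(F). The coalition value v(F) is the interventional
expectation — features in F take x's values, the rest are drawn from a
fixed background sample of training rows, and the model's positive-class
probability is averaged over the background. (Literally retraining the
model on every feature subset is prohibitive and is not what any standard
explainer does; the interventional expectation is the accepted surrogate.)
Two estimators are provided:

* `exact_shap` — full 2^|S| subset enumeration, |S| ≤ 15;
* `approx_shap` — Monte-Carlo over feature orderings; each sampled
  ordering switches features on one at a time over the full background, so
  contributions telescope and local accuracy
  (base value + Σ SHAP = model output) holds exactly at any number of
  permutations; the estimate converges to the exact values.

Explanations are computed for selection-split samples (held out from the
classifier) using the model trained on the classification split,
preserving the pipeline's leakage discipline. The summary ranks features
by mean |SHAP| and assigns each a direction: the sign of the correlation
between feature value and SHAP value (positive = higher expression pushes
toward the tumor class).

## Normalization and the unsupervised class-merging check

Expression input is assumed log-scale; `log2_transform` (with an optional
offset) and `quantile_normalize` are provided. Quantile normalization maps
every sample onto the reference distribution formed by rank-wise means of
the sorted samples; ties receive the average of the reference values over
the tied rank span. On tie-free data (continuous expression) all samples
share a bit-identical sorted value multiset afterwards and the map is
idempotent; with ties, the tie-averaging convention trades exact multiset
identity for symmetry.

The unsupervised check asks whether two nominal sample classes are
actually distinguishable: within-sum-of-squares and silhouette curves over
k (samples clustered on all genes by default, top-variance genes
optionally), k-means at the silhouette-optimal k (Lloyd, k-means++
seeding, best of 25 starts), and a contingency table of clusters against
classes. The merged-class agreement is the percentage of the designated
class union falling in its single majority cluster (ties toward the lower
cluster id).

## Synthetic data: what it emulates and what it does not

Each module m has one latent factor per sample, z_s ~ N(μ_class(m), 1);
gene g in m is λ z_s + ε with λ = √ρ and ε ~ N(0, √(1−ρ)), so the
model-implied within-module correlation is exactly ρ (default 0.8) and
can be checked against sample correlations analytically. Discriminative
modules shift their factor mean by `effect_size` (in factor SD units,
default 2) between tumor and normal; when several modules are
discriminative the shift directions alternate (up- and down-regulated
programs), which yields negative between-module correlation and exercises
the signed objective. By default exactly one module is discriminative:
two same-direction shifted modules would be genuinely correlated through
the shared class structure (r ≈ ρ·v/(1+v), v = Δ²p(1−p) — about 0.39 at
Δ=2) and would rightly be detected as one block; coupled modules are
modeled explicitly by the nested design instead, where a super-module
factor (loading √ρ_super) is shared by child modules on top of their own
factors. A third class ("peritumoral") can be drawn from the normal model
plus a configurable shift, and noise genes are i.i.d. normal. Default
sample counts (152 tumor / 91 normal / optionally 14 peritumoral) mirror
a typical single-center microarray study.

Finite-sample caveat: with n ≈ 240 samples the sample correlation between
two *independent* module factors has sd ≈ 1/√n ≈ 0.065, and occasional
realizations carry pair correlations of ~0.15 — statistically significant
coupling that any correlation-based detector legitimately reports as one
community. Recovery tests therefore fix the data realization (default
generator seed) and vary the detection master seed, mirroring a study
with one dataset and algorithmic randomness.

The generator does not emulate probe-level noise, batch effects, platform
mapping, heavy-tailed expression distributions, or correlated noise genes
(an optional weak global factor exists to stress-test fragmentation).
Passing tests demonstrate that the machinery recovers planted structure
under the factor model; they do not certify performance on real
microarray data.

## Problem sizes and numerical choices

The test and acceptance runs use L = 25–50 stability runs, 10 CV repeats,
300-tree forests, networks of 200–500 genes and 240 samples — sizes at
which every stage is exercised end-to-end on a single CPU within minutes;
the defaults (L = 100, 100 repeats) match the emulated study protocol.
Determinism: every stage's seed is derived from a single master seed via
SHA-256 (pipeline) or SeedSequence (per-run Leiden seeds), so reruns are
bit-identical. Partition identity uses canonical first-appearance
relabeling; majority ties within an ensemble are broken by signed quality,
then by the lexicographically smallest canonical label sequence. NMI
returns 1 by convention when both partitions are trivial. Degenerate
inputs (constant genes, single-class labels, empty merge sets, k exceeding
the sample count) raise errors naming the offending entity rather than
proceeding.

## Known limitations

* The β randomness level of the underlying Leiden implementation is not
  externally tunable; the β grid therefore degenerates to seed
  re-randomization and is a single value by default.
* Boruta's impurity importance is biased toward high-cardinality features
  in general; with continuous expression features of comparable scale the
  bias is immaterial, but the permutation-importance flag exists for
  conservative runs.
* Exact Shapley enumeration is limited to 15 features; larger communities
  rely on the permutation estimator.
* The hierarchical procedure never revisits an accepted split; a wrong
  coarse merge below the recursion bound cannot be repaired downstream
  (hence the plateau tie-break).
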