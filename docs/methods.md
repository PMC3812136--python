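# Methods

## Data model and contracts

The pipeline operates on a *parallel* dataset: an mRNA expression matrix
(genes, including the transcription factors) and a miRNA expression matrix
over the identical, identically ordered samples. Values are used as-is;
log-transformation and normalization are the caller's responsibility.
Candidate interactions come from a typed prior catalog restricted to three
edge types — TF→gene, TF→miRNA, miRNA→gene — with miRNA→TF regulation
represented as a miRNA→gene edge whose target appears in a TF roster.
Selection never invents edges: the identified set is always a subset of the
prior catalog.

Sample alignment intersects the two matrices' sample ids (sorted order when
the sets differ, mRNA order when they coincide) so that re-alignment is
idempotent. Missing expression values are handled at load time by an explicit
policy: drop the feature (default) or impute the feature mean.

## Mutual information and mRMR filtering

Mutual information is estimated on discretized profiles. The default
discretization maps each profile to three states around its mean ± k·σ with
k = 0.5, the convention of the mRMR literature for continuous microarray
data; equal-frequency binning (stable-rank tie splitting) is available by
configuration. MI is computed in bits (log₂) from the observed joint
frequencies with the 0·log 0 := 0 convention and clipped at zero against
rounding. The base only rescales scores, so rankings are invariant to it.

mRMR uses the difference form (relevance − mean redundancy), matching the
presentation of the criterion as two separate objectives; the quotient form
is not implemented. Selection is greedy: the first pick maximizes relevance
with the target, later picks maximize relevance minus the mean MI with the
already-selected set, ties break on lexicographic regulator id, and at most
20 candidates (configurable) are retained per target.

## Wrapper: backward elimination over OLS

Target and regulator profiles are z-scored before fitting, so "smallest
regression coefficient" is read as smallest *absolute standardized*
coefficient. This matters: raw coefficients are scale-dependent, and signed
elimination would preferentially discard repressive (miRNA) regulators,
defeating the purpose of joint TF/miRNA modeling. TFs and miRNAs compete in
one joint regression per target.

Each step fits ordinary least squares and records the overall F-test p-value
of the model against intercept-only, df = (p, n − p − 1); exactly duplicated
regulator columns are dropped with a warning. The path runs until the
one-regulator model has been evaluated, so p initial candidates produce
exactly p nested models. The accepted model is the argmin of the F p-value
along the path (ties to the larger set), provided p < α = 0.01. When the
filtered candidate list approaches the sample count it is truncated to
n − 3 top-ranked candidates for OLS identifiability.

**Known property: selection-biased acceptance.** Because the accepted model
minimizes the p-value over the whole path, the acceptance decision is made on
a selected minimum of correlated p-values, not a single test. Two
consequences, both measured by the test suite and the acceptance script:

* on pure-noise targets the acceptance rate at α = 0.01 is on the order of
  5–15% (depending on the candidate count), not 1%;
* on strong planted signals the argmin occasionally (≈ 25–30% of runs at
  standardized effects ≈ 0.5–0.6 with 17 decoys) lands on a strict superset
  of the true regulators — the true model plus one chance-correlated decoy
  whose inclusion lowers the overall F p-value slightly further.

These are intrinsic to the argmin-of-F selection rule, not estimation error;
the fitted coefficients and p-values agree with statsmodels to machine
precision. Downstream, the permutation FDR quantifies exactly this inflation
and is the measure by which the method should be judged.

## FFL enumeration

The three motif classes are defined over distinct vertex triples (TF, miRNA,
target gene). A motif whose TF and miRNA regulate each other mutually is
reported *only* as composite, never additionally as TF-FFL or miRNA-FFL, so
class counts are additive. A gene that is itself a TF may serve as another
motif's target vertex; self-loops are excluded. Enumeration joins indexed
adjacency sets over (TF, miRNA) pairs sharing a target — output-identical to
a depth-first scan over targets, and checked in tests against a brute-force
all-triples oracle.

## Validation statistics

**Permutation FDR.** Each permutation shuffles every feature's values
independently across samples, destroying regulator–target covariation while
preserving each feature's marginal distribution (sample-label shuffling would
preserve covariation and test nothing). Per repeat, FDR = mean discovery
count over permutations divided by the real-data discovery count; the report
carries the mean and variance over repeats. Defaults: 100 permutations,
3 repeats (20 permutations in the test suite and acceptance script, which is
ample at the simulated scale).

**Random-interaction null for FFL counts.** Each draw samples, uniformly
without replacement and per interaction type, as many prior edges as were
identified, then re-enumerates FFLs. The observed count per class is scored
one-sided via its studentized excess t = (observed − null mean)/null SD with
a Student-t tail on n_draws − 1 df. The single-draw SD (not the SD of the
mean) is the right scale here: the claim under test is that the observed
count is extreme *as one draw* from the null, and this scoring is what makes
a null-drawn observation score p ≈ uniform. The test is meaningful only when
null counts are not essentially all zero; with a degenerate null (mean ≪ 1)
any count-based test is uncalibrated, and the test suite exercises
calibration on a catalog dense enough to avoid that regime. Zero-variance
draws decide degenerately (p = 0 if observed exceeds the constant, else 1).

**PCC shift.** Per-pair Pearson correlations are compared on absolute value
(miRNA regulation is repressive, so only magnitudes are comparable across
regulator types) with a one-sided Mann–Whitney U test, after > before.
Constant profiles score |PCC| = 0 with a warning.

**Enrichment and composition.** Known-interaction enrichment is the
one-sided upper-tail hypergeometric probability of the selected/known overlap
within the candidate universe. Count-composition contrasts use the Pearson
chi-square on the 2×2 table with df = 1 and *no* continuity correction — the
uncorrected statistic reproduces the published STAT3 enrichment p-values
(2.6×10⁻¹² and 3.8×10⁻³) to the printed precision, which fixes the
convention. The chi-square tail is an asymptotic approximation to the
margin-fixed permutation null; at a few hundred samples the two agree to
~10⁻⁴ in the small-p regime, but for small tables the conditional
(hypergeometric) tail can exceed the asymptotic one by several 10⁻³.

## Classification evaluation

FFL member genes and miRNAs form the feature set of a soft-margin SVM
(linear kernel, C = 1 by default — the natural default when no kernel or
parameters are specified; RBF available). Evaluation is leave-one-out:
each fold z-scores features with training-fold statistics, trains on n − 1
samples and predicts the held-out one. Confusion counts pool over folds;
Acc, Sn, Sp and Mcc follow their standard definitions with Mcc := 0 when a
denominator factor vanishes. The ROC is built from the pooled per-fold
decision values by a threshold sweep with trapezoid area, which equals the
pairwise concordance probability (ties counting one half). The positive
class is the lexicographically larger label. The chance baseline repeats the
whole LOOCV under label permutation (default 100) and averages the metrics.
No class weighting is applied; Mcc is reported precisely because it exposes
imbalance effects that accuracy hides.

## Co-regulatory networks

The network is the deduplicated union of all motif edges, nodes typed TF /
miRNA / gene (a TF keeps its TF type even when it is another motif's
target), edges typed by the regulating layer. Degree is computed on the
undirected simple graph — parallel edges of different regulation type between
the same pair collapse — and the hub is the maximum-degree node with
lexicographic tie-break. Occurrence rankings count, per dataset, the FFLs
containing each regulator and rank *within regulator kind* (TFs among TFs,
miRNAs among miRNAs), dense 1-based, ties in lexicographic order, zero-count
regulators unranked. Ego subnetworks keep the center, its direct neighbors
and only center-incident edges. The power-law exponent is minus the
least-squares slope of log count versus log degree over the observed degree
distribution (at least three distinct degrees required); maximum-likelihood
tail fitting is deliberately out of scope. Exports: Cytoscape SIF
(`source TAB regulation_type TAB target`) and GraphML with node/edge type
attributes.

## Synthetic data generator

The generator emulates a parallel expression study with planted ground
truth. Root regulator profiles are i.i.d. standard normal; every regulated
feature is Σ βᵢ·E_regulator + ε with ε ~ N(0, σ²), σ = 0.5 by default.
Effect magnitudes are drawn uniformly from [0.6, 1.2]; TF regulation is
positive, miRNA regulation negative (repression). Planted FFLs of the three
classes occupy disjoint TF/miRNA/gene triples so each regulated feature has
an unambiguous generative model; composite loops couple TF and miRNA through
a single negative coefficient (the repressive direction), with both mutual
edges recorded as true — a linear generative model cannot realize a genuine
two-way cycle, so the mutual edge pair shares one association. Decoy prior
edges (4 per true edge by default) carry zero effect and populate the
catalog with the false positives the selection step must remove.

Two presets scale the study designs the pipeline targets: `pan_cancer_like`
(60 unlabeled samples, the scale of a cell-line panel) and `prostate_like`
(139 samples labeled 111 cancer / 28 normal). With labels, every
planted-FFL member feature receives a 2 σ class shift (genes up, miRNAs
down in the cancer class), giving a strongly but not trivially separable
cohort for classifier evaluation.

What the generator does *not* emulate: probe/batch effects, heavy-tailed or
heteroscedastic noise, nonlinear or combinatorial (AND-gate) regulation,
shared regulators across planted loops, and the extreme candidate densities
of genome-scale prediction databases (hundreds of candidate regulators per
target). Passing tests therefore demonstrate correctness of the algorithms
and their behavior under the linear model's assumptions — not expected
performance on real microarray cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 60–139 samples,
~8 TFs, ~8 miRNAs, ~30 genes, ~110 prior edges, 20 expression permutations ×
3 repeats for FDR, 100–1,000 draws for the FFL null, 100 label permutations
for the classification baseline, and 100 seeds for the wrapper benchmark.
Determinism: every stochastic routine takes a seed; identical seeds give
byte-identical outputs. Ties break lexicographically everywhere (mRMR picks,
elimination order, hub choice, rank order). Degenerate inputs are decided,
not nan-propagated: constant profiles discretize to one state and score zero
MI and zero |PCC|; zero-variance null draws decide the FFL test by direct
comparison; a zero Mcc denominator yields Mcc = 0.

## Known limitations

* The argmin-of-F acceptance rule inflates both false-positive edge
  acceptance and occasional superset selection (see the wrapper section);
  consumers should weigh identified edges by the permutation FDR rather than
  the nominal α.
* The FFL count null test assumes the null count distribution is roughly
  unimodal with nonzero spread; it is uninformative when nearly all draws
  contain zero motifs.
* The power-law exponent is a descriptive log–log regression, adequate for
  the "exponent below 3" style of statement, not a rigorous tail estimate.
* MI estimation is plug-in on 3 states and biased upward for small samples;
  this cancels in ranking (all candidates share the bias) but the absolute
  bit values should not be over-interpreted.
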