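# Methods

## Scope and data model

`plasmaseek` analyses a gene × sample matrix of nonnegative normalized
expression values (the scale of TCGA level-3 RSEM gene-normalized
estimates) with per-sample annotations: group (tumor/normal) and, for
tumors, stage I–IV or unknown. All tests are rank-based, so no log
transform or further normalization is applied before screening, and the
networks are built on the values as provided. Gene symbols are matched
case-sensitively after whitespace trimming; sub-stage tokens (IIa, IIIB…)
collapse to their Roman-numeral prefix. Normal samples always carry stage
"unknown" — staging is a tumor attribute.

## Screening and pattern classification

Each gene is screened with a two-sided Mann–Whitney U test, all tumors vs
all normals: midrank tie handling, exact p-values for tie-free samples
with min group size ≤ 8, otherwise the normal approximation with tie and
continuity corrections (scipy's implementation; an exhaustive
rank-enumeration oracle pins it down in the tests). The significance
threshold is raw p < 0.05 per the screening convention of the biomarker
literature; Benjamini–Hochberg q-values are emitted as a column for the
reader but do not drive any label. Direction (up/down) comes from the
median comparison of significant genes. Per-stage p-values test each
stage's tumors against all normals.

Pattern labels are assigned with the precedence
**stage-specific → progressive → leading → not significant**:

* *Stage-specific*: the focal-stage tumors differ from all other
  known-stage tumors (Mann–Whitney, p < α, with the focal median on the
  corresponding side), the focal stage is the only stage significant in
  that direction, and the remaining stages are mutually homogeneous
  (Kruskal–Wallis p ≥ α). The homogeneity clause is what separates a
  single-stage spike from a stage-wise trend — a monotone trend also
  elevates the last stage against the rest, but leaves the remaining
  stages heterogeneous. The raw focal-vs-rest map (without the uniqueness
  and homogeneity refinements) is exposed separately as
  `stage_specific_genes`, since significance against normals is reported
  but not required.
* *Progressive*: overall significance with matching direction, stage
  medians monotone from I to IV over stages with ≥ 2 tumors, and a
  one-sided Jonckheere–Terpstra ordered-trend p < α. The JT statistic is
  the sum of pairwise Mann–Whitney counts over ordered stage pairs; its
  normal approximation uses the tie-free variance (adequate for continuous
  expression values) with a continuity correction.
* *Leading*: of the remaining significant genes, the k = 5 smallest
  p-values per direction.

Unknown-stage tumors participate in the overall screen but are excluded
from every stage-wise comparison.

There is no canonical operational definition of a "stage-specific" or
"progressive" expression pattern; the comparator choices above (focal vs
other stages; median monotonicity plus ordered trend) are this package's
formalization, chosen so that each planted pattern class in the synthetic
cohorts is recovered as itself and not as a neighbor class.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, not
RNA-seq reads. Per gene g and sample s, the log2 signal is

    mu_g + sigma_g * (lambda * f_{m(g),s} + sqrt(1 - lambda^2) * z_gs) + sigma_g * delta_gs

with mu_g ~ U(3, 12), sigma_g ~ U(0.5, 1.5), z standard normal, f a
standard-normal factor shared by all genes of module m within a sample
(within-module correlation is exactly lambda² on the log scale), and delta
the planted effect in units of the gene's own SD — which makes rank-test
power independent of the baseline scale. Values are emitted as
2^(log2 signal). Effects: global shifts move all tumors; stage-specific
shifts move only the target stage; progressive shifts move stage-k tumors
by effect·k/4 (I = 1 … IV = 4). Unknown-stage tumors receive a latent stage
for effect generation that is then masked, mirroring cohorts where stage is
unrecorded rather than absent.

The two presets mirror the study layouts the pipeline targets:
`stomach_like` (415 tumors / 35 normals; stage proportions 0.137, 0.296,
0.407, 0.099, 6.1% unknown) and `esophagus_like` (185 / 11; 0.097, 0.422,
0.303, 0.049, 12.9% unknown). Both plant 5 genes per effect class at
effect size 1.5 SD (the stage-specific genes cycle over stages I–IV) and 4
correlation modules of 20 genes at loading λ = 0.6 in a 500-gene
background. The 500-gene background and the per-class count of 5 are
calibration choices — large enough that false-positive leakage into the
leading lists is realistic, small enough for routine test runs; planted
magnitudes are not claims about real effect sizes.

The `rewire_tumor` flag re-draws which genes belong to the modules in the
tumor group (same module sizes, members drawn uniformly from all genes).
Most normal-group module genes thereby lose their co-expression in tumors
— the "network disruption" signal the RCC statistic is designed to detect.

What the generator does **not** emulate: library-size and batch effects,
count noise, heavy-tailed expression distributions, gene-length bias,
correlated effect classes, and realistic (weak, polygenic) effect-size
distributions. Passing tests therefore demonstrate that the pipeline's
statistics behave as designed under their own assumptions, not that the
biological findings of any particular cohort are correct.

## Dual networks

Pearson correlations are computed per sample group (≥ 3 samples required);
zero-variance genes get r = 0 off-diagonal and stay as isolated nodes so
the gene set is identical across all four networks, which the RCC ratio
requires. The transforms ((1±r)/2)^β map correlations into [0, 1]; at
β = 1 they are exact complements.

The soft power β is selected per group — the two groups' correlation
estimates have very different precision at 415 vs 35 samples, and a joint
choice would let the larger group dictate the smaller one's topology. The
scale-free fit index follows the WGCNA convention: connectivities
k_i = Σ_j w_ij are discretized into 10 equal-width bins and the log10 bin
frequency is regressed on the log10 mean bin connectivity; the index is
−sign(slope)·R². The smallest β ∈ 1..20 with index ≥ 0.85 wins; when none
passes, the argmax is used with a warning. Candidates whose
hard-thresholded similarity or dissimilarity layer would leave more than
half the nodes isolated are excluded from selection: past that point the
network no longer supports closeness centrality (its sole consumer here),
and an unconstrained argmax routinely lands there on matrices whose
correlations are tightly estimated. Self-loops are zeroed and weights
strictly below 0.01 are removed after soft powering.

Note that block-modular synthetic matrices (equal-size, equal-loading
modules over an iid background) have a bimodal, not scale-free,
connectivity distribution; on such inputs the fit index typically peaks
well below 0.85 and the selection falls back to the constrained argmax.

## Closeness and RCC

Edge traversal length is 1/weight in both layers (strong edges are short).
The dissimilarity layer is often described as a "distance", so the
alternative of using its weights directly as lengths is available via
`distance_mode='direct'`; the default keeps one uniform contract so the
RCC ratio compares like with like. Closeness uses Dijkstra shortest paths
(scipy.sparse.csgraph) with Wasserman–Faust component scaling,

    closeness(v) = [(m−1)/Σ_u d(v,u)] · [(m−1)/(n−1)],

m the size of v's reachable set: this preserves "inverse of the average
shortest-path distance" within components while penalizing small
components; isolated nodes score 0. On a complete graph with uniform
weight w every closeness equals w exactly, which the tests use as an
anchor alongside a Floyd–Warshall brute-force oracle.

RCC_N = CN_sim/CN_dis and RCC_P = CT_sim/CT_dis per gene; genes with any
zero closeness among the four are flagged undefined and excluded from
testing — never imputed. The paired Wilcoxon signed-rank test on
log2(RCC_N) − log2(RCC_P) over a biomarker panel is two-sided, drops zero
differences, reports W as the positive-rank sum, and needs ≥ 3 usable
pairs.

### Known limitation: the paired RCC test is not calibrated

The paired Wilcoxon treats genes as independent replicates, but every
per-gene difference is computed from the *same* pair of network
realizations. Network sampling noise is a global graph property, so the
differences share a common per-dataset offset; whenever that offset
exceeds the across-gene spread the test rejects regardless of any real
group difference. Simulations with tumor and normal groups generated
identically (the exchangeable null) show rejection rates near 50% at
α = 0.05 — independent of the soft power, of whether the tested genes sit
in modules, and of balanced group sizes; with strongly unbalanced groups
(415/35) the systematic precision difference between the two correlation
matrices pushes the rate to ~100%. A small p-value from this test
therefore certifies that the biomarkers' network position differs between
the two *fitted* networks, not that the difference exceeds sampling noise.
A calibrated alternative would resample samples within groups (e.g.
permutation of group labels with network re-estimation), which is outside
the present scope. The acceptance suite keeps an honest failing check of
the naive calibration rather than weakening it.

## Panel classification

Linear-kernel SVM, C = 1, no class weighting (stratification alone handles
the 415/35 imbalance), features z-scored with training-fold statistics
only. Repeat r of the cross-validation seeds its stratified 5-fold split
with master_seed + r; the held-out decision values of the 5 folds are
pooled into a single ROC per repeat. Reported: mean and SD (ddof = 1) of
the repeat AUCs and a mean ROC curve by vertical averaging on a fixed
101-point FPR grid with anchored endpoints. The AUC from ROC integration
is cross-checked against the rank-sum probability formulation to 1e-9.
The random baseline draws 5 genes uniformly without replacement from the
cohort (seed recorded); its AUC is reported, not bounded — on a cohort
with strong global effects a random draw can be informative.

A cross-validated SVM on label-independent *features* shows a small
pessimistic bias (mean AUC slightly below 0.5 per cohort draw), a known
property of CV with overfit-then-anti-generalize noise features; the exact
0.5 baseline belongs to label-independent *scores*, which is what
`random_predictor_auc` checks.

## Determinism and seeds

Every stochastic stage derives its stream from the config's master seed by
fixed offsets (simulation uses it directly; CV repeat r uses
master_seed + r; the random panel uses master_seed + 7919). Identical
config and inputs give byte-identical output tables; manifests differ only
in paths.

## Problem sizes used in the automated checks

The test and acceptance runs use 200–500-gene cohorts at the preset sample
sizes, 10–50 cross-validation repeats, and 10–50 simulation seeds per
property — sizes at which every statistical property checked (type-I
calibration envelopes, ≥ 90–95% planted-signal recovery) is already stable
while a full run of the suite remains a routine desk operation.
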