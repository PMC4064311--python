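# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pleiomod`, in the spirit of a package methods appendix.

## Interactome handling

The network is an undirected `networkx.Graph` whose edges carry a
`confidence` in [0, 1]. STRING-style integer scores (0–999) are divided by
1000 (`score_scale="string999"`); the default inclusion filter is
confidence ≥ 0.7, applied at load time. Confidence is used *only* as an
inclusion filter — all downstream statistics (degrees, cliques, shortest
paths) treat the filtered graph as unweighted, because the detection
algorithm is defined on clique structure, not edge weights. Self-loops are
dropped and duplicate pairs keep the maximum score. Largest-component ties
are broken toward the lexicographically smallest sorted node list so the
operation is deterministic.

The shortest-path clustering test compares the observed mean pairwise hop
count of a gene set against `n_random` uniform same-size draws from the
largest connected component. The p-value is the one-sided empirical rank
of the observed mean within the null means, `(r+1)/(n+1)` with
`r = #{null ≤ observed}` — the exact rank test for a single observation
against a reference sample. All empirical p-values in the package use the
`(r+1)/(n+1)` estimator, which cannot return zero and is exact under
exchangeability.

## Differential expression and the set statistic

Expression preprocessing offers quantile normalization (every column is
mapped onto the vector of row means of the column-sorted matrix; ties
receive the mean of the target values their ranks span, so a constant
column maps to the overall mean) and median probe→gene collapse.
Quantile normalization is idempotent on tie-free data to floating
precision.

Per-gene statistics are ordinary pooled-variance two-sample t-tests.
Moderated (empirical-Bayes) statistics are a deliberate non-feature: the
module-detection algorithm consumes *any* per-gene P table, so a user can
substitute limma/edgeR-style P-values without touching the rest of the
pipeline. Zero-variance genes get `t = 0, p = 1` rather than being dropped
so gene universes stay aligned across diseases.

The set statistic is `T(S) = mean_{g∈S} t_g²`. For m independent null
genes at large group sizes each `t²` is approximately χ²(1), so
`m·T ≈ χ²(m)`; the test suite verifies this by simulation at 50 vs 50
samples. The degrees-of-freedom parameter of this reference distribution
counts *genes*, which is the only reading under which the χ² limit holds;
the p-value is nonetheless always computed by permuting sample labels
(`(r+1)/(n+1)`, one-sided for large T), because genes are correlated in
real data and the χ² reference is descriptive, not inferential.

For p-values beyond the permutation resolution, `gpd_tail_pvalue` fits a
generalized Pareto distribution by maximum likelihood (location fixed at
0) to the null exceedances above the 90th percentile and returns
`tail_fraction × SF(observed − threshold)`. The GPD branch is used only
when fewer than 10 null values reach the observed statistic; otherwise the
empirical estimate is returned unchanged, and degenerate (constant) nulls
fall back to the empirical estimate with a warning.

## Module detection

Maximal cliques come from networkx's Bron–Kerbosch implementation with
pivoting, filtered to size ≥ 2 (an isolated maximal edge is a clique) and
sorted (size descending, then lexicographic) for deterministic output.
Clique weights are `Σ −log10 P`; genes present in the network but never
measured contribute `P = 1` (weight 0) rather than disqualifying their
cliques, since excluding them would delete most large cliques whenever the
measured universe is smaller than the network. Base-10 logs are a
reporting convention only — empirical significance is invariant to the log
base because a global positive rescaling preserves weight ranks (tested).

Each permutation shuffles the gene→P assignment *once globally* over the
union of network and measured genes, then recomputes every clique weight
on that same shuffle. Sharing one shuffle across cliques preserves the
null's inter-clique correlation structure (overlapping cliques have
correlated null weights, as they do for the real weights). Cliques with
empirical P < 0.01 are unioned into the module; the threshold is a fixed
per-clique cut with no FDR across cliques, by design — the calibration
suite confirms that about 1 % of cliques pass under signal-free P-values,
which is the intended behaviour of the assembly rule, and module-level
error control comes from the randomized-null pleiotropy analysis, not from
per-clique multiplicity correction.

## Pleiotropy

The pleiotropic module is the intersection of all per-disease modules.
Significance comes from `n_repeats` (default 100) full reruns of the
detection for every disease with each disease's gene→P map independently
shuffled. Clique enumeration is reused across reruns (the network never
changes), which is the dominant constant-factor saving. Inside each null
repeat the per-clique permutation count may be reduced (default 1,000)
to keep the nested resampling tractable; the CLI records this in its
output. Reported quantities: intersection p `(r+1)/(n_repeats+1)` on the
null intersection sizes; per-gene pleiotropy p (fraction of repeats
placing the gene in at least as many modules); and fold enrichment
`FE = observed size / mean null size`, left undefined (`None`) when the
null mean is 0 — at desk scale the null intersection is frequently empty,
so FE is only meaningful when some null repeats produce nonzero overlap.

The module-count correlation analysis bins genes by the number of modules
they appear in (level 0 = universe genes in no module), computes the
annotated fraction per level, and reports the Pearson correlation of
fraction against level (scipy), with the correlation flagged undefined for
constant fractions.

## Enrichment and degree-matched nulls

`FE = (k/n)/(K/N)`; Fisher tests are hypergeometric upper tails
(`scipy.stats.hypergeom.sf(k−1, N, K, n)`); BH FDR is statsmodels'
step-up. The background size N is an explicit parameter everywhere: FE is
only comparable across annotations when the universe is stated.

Degree-matched random sets control enrichment for connectivity bias: every
sampled gene must have degree ≥ the test set's minimum, and the sampled
median degree must match the target within a tolerance (default ±2 % of
the target). Sampling draws half the set from genes with degree ≤ target
and half from degree ≥ target — the two pools overlap at the target degree
itself, which is what lets the realized median land exactly on an integer
target — followed by rejection on the realized median, with diagnostics
when the constraint is infeasible. The drug-response correlation screen
scores each agent by the mean |Pearson r| between member-gene expression
and response across samples, against same-size random gene sets from the
measured universe, with BH flagging. Mean |r| is one reasonable aggregate
of "frequently correlated"; it is sensitive to both signs of association
and robust to a single driving gene.

## Responder classification

The L1-penalized logistic fits minimize
`(1/n) Σ logloss + λ‖w‖₁` (intercept unpenalized) along a descending
100-point log-spaced λ grid from `λ_max = max_j |x_jᵀ(y − ȳ)|/n` down to
`λ_max/100` (the glmnet convention for n < p, which always holds here; the
deeper grid tail is in the separable, ill-posed regime and never wins
cross-validation). The solver is a numba-compiled FISTA proximal-gradient
path with warm starts along the grid and gradient-restart momentum; its
solutions match scikit-learn's `LogisticRegression(penalty="l1")` at
`C = 1/(nλ)` to ~1e-4 (tested), and the compiled path is what makes
nested-LOO permutation tests affordable. Step size is `1/L` with
`L = σ_max([1 X])²/(4n)`.

λ is selected by minimum mean leave-one-out binomial deviance, ties broken
toward the larger (sparser) penalty. Reported probabilities are genuinely
held out: an outer LOO leaves each sample out, the training fold is
re-standardized (zero mean, unit variance) and λ re-selected by inner LOO
within it, and only then is the held-out sample scored. The inner folds
reuse the outer fold's standardization. Held-out probabilities in the
deviance are clipped to [1e-10, 1−1e-10] so single-class inner folds
cannot produce infinite deviance. Calls use the 0.5 border; the
permutation test reruns the entire nested pipeline on permuted labels and
counts correct calls by default, with held-out deviance as the alternative
statistic. The call count matches the reported quantity but is discrete,
and at n = 16 with balanced classes its null has an irreducible ~1 % upper
tail: label permutations that nearly align with — or nearly complement —
the true grouping (the partition is symmetric under label exchange)
re-find the group structure and score almost as well. The deviance
statistic is continuous and penalizes the confidently mispredicted
mismatched samples of such permutations, so it is the statistic to use
when p-values near or below 0.01 must be resolved; the benchmark tests use
it for exactly that reason.

Two leave-one-out artifacts are worth knowing about. First, under the
null (shuffled labels), LOO accuracy does not hover at 0.5: weak or
intercept-only models predict the training majority, which for balanced
classes is always the opposite of the held-out sample, so null accuracies
cluster near 0 (anti-prediction). Chance-level behaviour is the *absence
of above-chance accuracy*, and that is what the no-leakage tests assert.
Second, the same ties that make the call count discrete make its
permutation p super-uniform (conservative) under the null; only the
deviance statistic's permutation p is exactly uniform.

Gene filtering (paired t-test P < 0.05 for drug-responsive genes) is
applied before the outer loop, mirroring standard practice for this
design. Because the filter compares pre vs post and never uses the HR/LR
labels, it cannot leak the classification target; the test suite includes
an adversarial leaked-filter check confirming that held-out accuracy on
pure noise stays at chance. An inside-fold filtering variant is
unnecessary for label-blind filters but the restriction utilities accept
any gene list, so callers can implement it.

The group perturbation statistic is the mean over genes of the squared
paired t statistic (pre vs post) within one label's samples; a label whose
post equals its pre scores exactly 0.

## Synthetic data

Generators are bit-reproducible for a fixed seed and emit truth records
sufficient to score recovery. The default scenario — the benchmark used
throughout the tests — is a 300-gene Barabási–Albert graph (attachment 5,
giving a filtered-interactome-like mean degree ≈ 10 and a right-skewed
degree distribution) carrying a 20-gene core clique shared by 4 diseases
plus one 8-gene disease-specific clique each; planted edges have
confidence 0.9 so the default 0.7 filter never removes them, background
edges draw confidence from U(0.7, 1). Expression is unit-SD Gaussian on
the log scale with cases shifted by 2 SD on core + specific genes, 10
cases vs 10 controls per disease. Annotation sets of size K include target
genes with probability `FE·K/N`, giving the requested expected fold
enrichment.

Responder cohorts model paired in-vitro drug exposure:
`post = ρ·pre + √(1−ρ²)·ε` with ρ = 0.9, so both matrices keep unit
marginal SD and effect sizes are exactly in within-group SD units; the
drug then shifts the 10 effect genes by 0 SD in high responders and 1.5 SD
in low responders. The differential response is therefore the *only*
signal separating groups after treatment — matching a drug whose
clinical non-responders are the more strongly perturbed group — and the
same shift drives both classifier recovery and the LR > HR perturbation
statistic.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heavy-tailed or count-distributed noise, gene–gene expression
correlation beyond the planted shifts, and identifier-mapping noise.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its own assumptions, not performance on real
microarray data.

## Problem sizes and tolerances

Test and benchmark sizes are chosen for single-CPU desk scale: 1,000
clique permutations and 50 pleiotropy repeats in the recovery benchmark
(against published-scale defaults of 10,000 and 100), 200 label
permutations in the classifier benchmark, 10,000 degree-matched sets on a
2,000-node graph in the null-contract check. Calibration tests use reduced
permutation counts (19–99) across 100+ seeded repetitions and
Kolmogorov–Smirnov uniformity at α = 0.01. Numerical tolerances: solver
parameter-change tolerance 1e-5 (250 iterations max) in production fits,
1e-10 in the solver-vs-scikit-learn cross-check; quantile-normalization
idempotence at 1e-9; probability clipping at 1e-10.

## Known limitations

- Clique enumeration is exponential in the worst case; dense networks
  (confidence filters well below 0.7) can blow up.
- The pleiotropy FE is undefined when no null repeat produces a nonzero
  intersection; more repeats or larger modules are then needed.
- The LOO-selected λ is variable at n = 16; fold-level λ values are
  reported so users can inspect selection stability.
- Accuracy-based permutation p-values are discrete (17 achievable values
  at n = 16), which makes them conservative near their floor.
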