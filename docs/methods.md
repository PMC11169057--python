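# Methods

This note documents the models and procedures implemented in `modnet`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmarks do and do not demonstrate.

## Normalization and FPKM

Size factors use the median-of-ratios estimator: for sample *s*,
`factor_s = median_g (count_gs / geomean_g)` over the reference set of genes
with a nonzero count in **every** sample; factors are rescaled to geometric
mean 1, which makes them identifiable (only ratios of factors are meaningful).
FPKM is computed on normalized counts, with the per-million denominator taken
from the **normalized** library size `N_s = Σ_g count_gs / factor_s`. Dialects
of FPKM differ on this point; the choice here makes FPKM exactly invariant to
rescaling any single sample's counts (a property the tests assert). Genes with
zero counts everywhere get FPKM 0.

## Differential expression

The two-group test is a Welch *t* on `log2(normalized count + 1)`, with the
fold change computed separately as `log2((mean_B + c)/(mean_A + c))`,
pseudocount `c = 1` (configurable). This is a deliberately simple engine: it
does not pool dispersion information across genes the way negative-binomial
frameworks do, so at n = 3 vs 3 it is conservative (measured type-I rate
≈ 0.03 at nominal 0.05 in the null benchmark). The DEG *filter* is exact and
separate from the test: up ⇔ `log2FC ≥ 1` and `p < 0.05`; down ⇔
`log2FC ≤ −1` and `p < 0.05`; the |log2FC| bound is inclusive, the p bound
strict. A p-value column computed elsewhere can be substituted before
filtering. No multiple-testing adjustment is applied: the filter is defined on
the raw p-value.

## Sample QC

Pairwise Pearson correlation between samples, and principal coordinates
(classical Torgerson MDS: double-centre `−d²/2`, eigendecompose) on the
distance `d = 1 − r`. Zero-variance samples are excluded from the ordination
with a warning. Negative eigenvalues (possible since `1 − r` is not Euclidean)
are clipped to zero.

## Module discovery: K-means with BIC model selection

Input: condition-averaged `log2(FPKM+1)` rows of the DEGs, row-standardized by
default so that modules group genes by profile *shape*; zero-variance rows are
dropped with a logged count. K-means uses k-means++ initialization with
`n_init = 10` restarts per K (best inertia wins). The number of modules is the
argmin over the K grid (default 10…100 step 5; ties break to the smaller K) of
a spherical-Gaussian, X-means-style BIC:

```
σ̂²    = inertia / (n·d)
LL    = Σ_k n_k ln(n_k/n) − (n·d/2)·ln(2π σ̂²) − n·d/2
BIC(K) = −2·LL + (K·d + K)·ln(n)
```

(K centroids of dimension d plus K mixing weights; the shared variance is
folded into the constant). σ̂² is floored at 1e-12 for degenerate perfect
fits. Only differences of BIC across K matter; the tests assert the argmin
behaviour against this exact formula. The central gene of a module is the
member with the smallest Euclidean distance to the centroid; ties within
1e-12 break to the lexicographically smallest gene id. The heatmap matrix
z-scores each module profile (constant profiles become zero rows, with a
warning) and orders rows by average-linkage Euclidean hierarchical-clustering
leaf order.

**A caveat measured on synthetic data:** the spherical BIC is consistent when
within-cluster noise is homogeneous, but RNA-seq count noise is expression-
level dependent. When per-gene noise variances differ appreciably inside a
cluster, the criterion over-splits (clusters are scale mixtures, and splitting
by noise level improves the spherical likelihood). The low-noise benchmark
fixture (below) is constructed so that a homogeneous gene-level noise term
dominates; there the sweep recovers the planted K. On real data the selected
K should be read as an upper bound on the number of distinct profile shapes.

## Network inference

The inference matrix stacks the module-mean profiles over the differentially
expressed TF profiles; columns are the individual experimental lines (not
condition means), since with few conditions the per-line replicate variation
carries most of the usable signal. Four scorers, all emitted as bipartite
TF × module matrices oriented "higher = stronger":

* **Mutual information** (shared by ARACNE and CLR). Default estimator is
  Gaussian-copula: rank-normal scores `Φ⁻¹(rank/(n+1))`, Pearson correlation
  ρ of those scores, `MI = −½ ln(1−ρ²)` (ρ clipped at 1−1e−12). It is
  rank-based (invariant under monotone transforms) and well-defined at very
  small n, where histogram estimators are degenerate. An equal-frequency
  binned plug-in estimator is provided for cross-checks against hand-computed
  tables.
* **ARACNE.** All triangles of the full MI matrix (modules and TFs together)
  are scanned; edge (i,j) is removed iff some k gives
  `MI_ij < min(MI_ik, MI_jk) − tol` (default tolerance 0, the strict
  data-processing-inequality rule, evaluated on the original MI matrix).
  Survivors keep their MI as score.
* **CLR.** `z_i(j) = max(0, (MI_ij − μ_i)/σ_i)` against node i's off-diagonal
  MI background (population SD); score `= √(z_i(j)² + z_j(i)²)`. Constant
  backgrounds contribute 0 with a warning.
* **LARS stability selection.** For each module, least-angle regression of
  the module profile on all TF profiles (columns centred, TF rows
  standardized per subsample), run on 200 random column subsamples of
  fraction 0.8; a TF's score is the fraction of subsamples in which it is
  among the first 3 variables to enter the path.
* **Shrinkage partial correlation.** The sample correlation matrix is shrunk
  toward the identity with the analytic intensity
  `λ* = clip(Σ_{i<j} Var̂(r_ij) / Σ_{i<j} r_ij², 0, 1)`; partial correlations
  come from the standardized inverse of the shrunk matrix, and the score is
  |pcor|. With λ = 0 and p < n this reduces exactly to classical partial
  correlation (asserted against direct precision-matrix inversion).

An optional fifth scorer (absolute Spearman correlation) is available so that
five-method consensus configurations are expressible.

## Consensus voting, scoring, classification

Each method calls the top `⌈top_fraction × n_pairs⌉` pairs by within-method
average rank (default 2%, of the order of magnitude implied by consensus sets
of ~1% of the pair universe). Support = number of calling methods; the
network keeps support ≥ `min_support` (default 4). The signed consensus score
is `S = sign(Spearman(TF profile, module profile)) × Σ_methods
Φ⁻¹(rank_method/(N+1))` — rank-inverse-normal z's are scale-free across
heterogeneous methods, so |S| grows with cross-method agreement, and the
construction makes the ±5/±10 classification thresholds attainable exactly
when 4–5 methods agree near their top ranks. Classes: `S ≥ 10` highly
significant activator, `5 < S < 10` activator, mirrored for suppressors,
otherwise unclassified. Flipping the sign of a module profile flips the sign
of S and swaps the activator/suppressor classes (asserted). Ties everywhere
use average ranks, then lexicographic id order, so outputs are deterministic.

## Synthetic data: what it emulates and what it does not

The generator plants a bipartite TF→module network (edges drawn uniformly
without replacement; activator probability 0.6; weight magnitudes uniform in
[0.5, 1.5]×scale). Per condition, TF activities are iid `N(0, activity_sd²)`;
a module's log-signal is the weighted sum of its regulators' activities plus
`N(0, module_noise_sd²)`; member genes add iid `N(0, gene_noise_sd²)` and are
otherwise conditionally independent given the module signal. Counts are
negative binomial, `Var = μ + α·μ²`, with
`μ = exp(base + signal) × length_kb × libfactor`; gene lengths are log-uniform
in [500, 5000] bp, library factors log-normal with a given CV. Replicates
share the condition signal and differ only in count noise.

Defaults mirror the motivating study at desk scale: 40 TFs, 10 modules × 20
genes, 2 conditions × 3 replicates (6 samples), edge density 0.05,
`activity_sd = 1`, `module_noise_sd = 0.1`, `gene_noise_sd = 0.2`,
`α = 0.05` (typical bulk RNA-seq biological dispersion), library CV 0.1, base
mean 100 counts/kb. Two derived fixtures exist because inference on six
columns is statistically degenerate: a **wide** fixture (30 conditions × 1
replicate, otherwise default) for network-inference benchmarks, and a
**clustering** fixture (30 conditions, edge density 0.2 so modules have
strong distinct signals, `α = 0.005` and base mean 1000 emulating deep
sequencing, `module_noise_sd = 0.05`) on which BIC K-selection is reliable —
see the caveat above for why heterogeneous count noise is the binding
constraint.

What passing these benchmarks does **not** show about real data: the
generator has no batch effects, no gene–gene correlation beyond shared module
membership, no TF post-transcriptional regulation (TF mRNA equals TF
activity), linear-Gaussian regulation on the log scale, and a single global
dispersion. Real consensus networks will not enjoy the clean
precision/sign-accuracy numbers the planted benchmarks produce.

## Numerical and design choices

* Correlations of constant vectors are treated as 0 (with warnings), MI of a
  constant vector is 0.
* The DEG stage requires exactly two conditions; multi-condition designs are
  analysed pairwise upstream of this package.
* A single global seed fans out to per-stage seeds by fixed offsets
  (cluster +101, infer +211), so stages are independently reproducible and a
  full rerun is byte-identical.
* Module ids are 1-based; gene ids are opaque strings.
* All tables are UTF-8, tab-separated, '.' decimal; exports are TSV
  (round-trippable), SIF (`tf regulates module`) and GraphML (node `kind`,
  edge `support`/`S`/`class` attributes).

## Known limitations

* The Welch stand-in for the DEG p-value is conservative at n = 3; borrow-
  strength NB tests will call more genes at the same nominal level.
* The spherical BIC over-splits under heteroscedastic noise (see above).
* With six experimental lines the per-method scores are weakly informative;
  the consensus is then dominated by the voting rule, which is honest but low
  powered. Benchmarks quantifying recovery therefore use the 30-condition
  fixtures, and module-count/precision claims should not be extrapolated to
  six-column designs.
* The consensus significance score is a reconstruction of a score whose
  published definition is not available; its ±5/±10 thresholds are exposed as
  configuration.
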