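# Methods

## Problem and model

Case/control expression studies often show weak, inconsistent single-gene
signals while the underlying biology is modular: disease perturbs groups of
functionally coupled genes. `pathpin` treats curated pathways as the unit of
analysis and asks which *connected* set of pathways best discriminates disease
from control samples.

The method has three stages.

**1. Pathway activity.** Expression is standardized per gene,
`z_ij = (g_ij − mean(g_i)) / std(g_i)` with the sample (n−1) standard
deviation, so genes are comparable regardless of scale. Genes not in any
pathway are set aside. For pathway *k* with member-gene submatrix `Z_k`
(genes × samples), the activity of sample *j* is `P_kj = wᵀ Z_k[:, j]` where
`w` is the unit-norm leading eigenvector of the gene–gene covariance of
`Z_k` — the first principal component, a "meta-gene" summarizing the
pathway's coordinated expression. PCA is fitted once on all samples jointly
so disease and control scores share a scale.

The PC sign is intrinsically arbitrary; we flip `w` so its coordinate sum is
positive, and on an exact zero sum we require the loading of the
lexicographically smallest gene id to be positive. This makes loadings and
scores bit-reproducible across runs and linear-algebra backends. Genes inside
a pathway are processed in sorted order, so activity is invariant to the
order genes appear in the gene-set file.

**2. Pathway interaction network (PIN).** Two pathways are *candidate*
neighbors if they share at least one gene or a protein–protein interaction
joins a gene of one to a gene of the other (membership suffices: an
interaction between two genes each belonging to both pathways still supports
the pair). A candidate edge is retained only with dataset-specific support —
at least one shared gene differentially expressed between the classes
(Student's pooled-variance two-sample t-test, p < 0.05, strict) or at least
one candidate PPI pair strongly co-expressed across all samples
(|Pearson r| > 0.8, strict). Mixed evidence is an OR: either kind of support
retains the edge. DE p-values are used raw; a Benjamini–Hochberg option
exists for users who want multiplicity control, and a Welch option drops the
equal-variance assumption. Edges therefore nest monotonically in both
thresholds: tightening α or ρ can only remove edges.

**3. Marker selection.** Each pathway activity row is a classifier feature.
Feature sets are scored by stratified five-fold cross-validation of an
RBF-kernel support-vector machine; the held-out decision values of the five
folds are pooled into a single ROC per repeat, the split is re-drawn
`n_repeats` times, and the mean AUC over repeats is the score. The AUC itself
is the normalized Mann–Whitney statistic (ties count one half). The greedy
search first picks the single pathway with the best mean AUC over *all* PIN
nodes, then repeatedly scores every unselected PIN neighbor of the selected
set appended to it, accepting the best candidate only if it improves the mean
AUC by more than `improvement_tol`; it stops when no candidate improves or
the frontier is empty. Every marker after the first is thus connected to an
earlier marker, and the trace's AUC is strictly increasing.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `alpha` | 0.05 | DE filter for shared-gene edge support (raw p, strict <) |
| `rho_min` | 0.8 | co-expression filter for PPI edge support (strict >) |
| `min_genes` | 1 | smallest measured-gene count for a pathway to survive mapping; a 1-gene pathway's activity is the gene itself |
| `n_folds` | 5 | CV folds; stratified so small classes never vanish from a fold |
| `n_repeats` | 100 | repeats for definitive scores (final set, hold-out) |
| `search_repeats` | 10 | repeats inside the greedy loop; the accepted set is re-scored at `n_repeats`. Setting it to `n_repeats` (CLI `--faithful`) keeps full repeats throughout at ~10× cost |
| `svm_cost` | 1.0 | SVM C; activities are variance-comparable post-PCA, so no per-fold rescaling is applied |
| `rbf_gamma` | `"auto"` | 1 / n_features |
| `improvement_tol` | 1e-3 | guards acceptance against Monte-Carlo jitter of the mean AUC |
| `frontier` | `all-selected` | candidates are neighbors of any selected pathway; `first-only` restricts to neighbors of the first marker |

Seed policy: repeat *r* of any evaluation seeds its fold splitter with
`seed + r`, and all candidate evaluations within a greedy run share the same
seeds, so candidates are compared on identical partitions and reruns are
deterministic. Exact AUC ties between candidates resolve to the
lexicographically smallest pathway id.

## Synthetic data

`simulate_dataset` draws a latent factor per pathway and sample,
`f_p ~ N(δ·1[disease ∧ p planted], 1)`; a member gene is
`√ρ·f + √(1−ρ)·ε` with `ε ~ N(0,1)`, so every gene has unit marginal
variance and within-pathway pairs correlate at ρ — matching the
one-dominant-component structure the PCA activity assumes. Genes shared by
several pathways take the variance-normalized sum of their factors
(`Σf_p/√k`), which keeps unit variance and creates the gene-sharing edges
between consecutive pathways: pathway *k* reuses a fraction
`overlap_fraction` of pathway *k−1*'s genes, so the collection forms an
overlapping chain like curated databases do. PPI edges are Bernoulli,
denser within pathways (0.3) than between (0.01).

Defaults (30 pathways of 8–12 genes, 25% overlap, ρ = 0.6, 50 samples per
class, two adjacent planted pathways at δ = 1.5, 400 genes total) describe a
mid-sized two-class microarray study with a moderate module-level effect.
Note an inherent ceiling: a factor shifted by δ separates classes at true
AUC Φ(δ/√2) — about 0.86 at δ = 1.5 and 0.92 at δ = 2 — so simulated
single-pathway AUCs cluster slightly above 0.85/0.9 rather than near 1.

What the generator does **not** emulate: probe-level noise, batch effects,
platform intensity distributions, heavy-tailed expression, class-imbalanced
designs, or biologically structured (scale-free) PPI topology. Passing tests
show the algorithmic machinery is correct and well calibrated under the
factor model; they do not certify performance on any particular clinical
dataset.

## Numerical and design choices

- Standardization uses the n−1 divisor (conventional for expression work);
  zero-variance genes cannot be standardized and are removed with a log
  message. Missing values are rejected by default; per-gene mean imputation
  is opt-in. Standardization precedes restriction to pathway-mapped genes.
- Eigendecomposition uses `numpy.linalg.eigh` on the covariance matrix —
  deterministic, and exact for the symmetric case. Covariance (not
  correlation) PCA; on standardized rows the two coincide up to the n−1
  convention.
- Probe collapsing (optional probe→gene map) takes the arithmetic mean of
  raw values per gene before standardization; unmapped probes are dropped.
- Near-constant gene rows can standardize once and then collapse to a
  numerically constant row (catastrophic cancellation); re-standardization
  treats them as zero-variance and removes them.
- Genes absent from every pathway still participate in the DE and
  co-expression edge filters; only the activity computation is restricted.
- Hold-out evaluation recomputes activities on the test dataset with the
  training run's pathway membership but the test data's own PCA, because
  loadings do not transfer across platforms; no re-selection occurs.
- The stopping rule uses the AUC criterion throughout ("classification
  accuracy" is read as the AUC index); accuracy-style reporting is secondary.

## Known limitations

- Greedy search is myopic: when planted pathways share genes, the first
  marker's activity already carries part of its neighbor's signal, and adding
  the neighbor occasionally fails to clear the improvement tolerance. At the
  default simulation conditions both planted pathways are recovered in about
  80–90% of replicates with fewer than one false positive on average.
- Global PCA fitting (the reproduction default) lets fold-external samples
  influence the activity basis; a fully leakage-free analysis should refit
  PCA per training fold, at substantial cost. The evaluation machinery
  accepts any activity matrix, so strict users can construct per-fold
  activities themselves.
- CV repeats share data, so the standard deviation over repeats understates
  the sampling variance of the AUC.
- With a single CPU, the greedy loop's cost is roughly
  (candidates × search_repeats × n_folds) SVM fits per step; the
  `search_repeats` default of 10 keeps a 30-pathway study to a few seconds
  per dataset.
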