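# Methods

`ppigcf` reduces a two-class gene-expression matrix (genes × samples) to a
small subset of "informative" genes by composing four deterministic
elimination layers. The method is unsupervised: class labels are only used
by the downstream evaluation harness, never by the filter itself.

## The four layers

### 1. GO grouping

Genes are mapped onto their Gene Ontology annotations; genes with no
annotation are eliminated (`UNMAPPED`). The mapped genes are partitioned
into disjoint groups anchored at a configurable list of target terms
(default: nine GO IDs dominated by cellular components — `GO:0005737`,
`GO:0005764`, `GO:0005783`, `GO:0005794`, `GO:0005886`, `GO:0015630`,
`GO:0016021`, plus the namespace roots `GO:0003674` and `GO:0008150`). A
gene joins a group when it is annotated to the anchor itself or to any
descendant of it. When several anchors match, the deepest one wins; ties
break to the lexicographically smallest GO ID. Both tie-breaks are total
orders, so the partition is deterministic.

Each group carries a similarity matrix over its members,

    sim[i][j] = sqrt(a_i * a_j),    sim[i][i] = 1,

where `a_g` is the maximum normalised term information content over the
gene's annotated terms in the group's namespace. Term IC is the standard
annotation-frequency (corpus) IC with Laplace smoothing:

    freq(t) = (annotations to t or its descendants + 1)
              / (total annotations + number of terms)
    ic(t)   = -log2 freq(t) / max_t' (-log2 freq(t')),

so `ic` lies in (0, 1] and rare, specific terms score high. The geometric
mean makes `sim` symmetric, which the network layer requires.

### 2. Interaction network (RD1)

Within each group the interaction weight is

    W[a][b] = PCC(x_a, x_b) * sim[a][b],   W[a][a] = 0,

with PCC the population-moment Pearson correlation of the two genes'
expression vectors. An undirected edge exists when `W >= tau_ppi`
(default 0.5; negative weights never form edges). Genes with degree 0 —
isolated interaction genes — are eliminated (`ISOLATED`); the survivors
form RD1. Zero-variance genes have undefined correlation; their weight
rows are zeroed and logged, so they are always isolated.

### 3. Correlation filter (RD2)

Per group, on the RD1 survivors:

1. **Negative-correlation removal.** A gene is dropped (`NEGATIVE_PCC`)
   when the mean of its off-diagonal correlations is negative (policy
   `mean`, the default; `any` and `majority` are stricter/looser variants).
2. On the survivors the correlation matrix is recomputed and three scores
   are derived:
   - **NSCC** `R2[i][j] = r[i][j]^2 / sum_{k != i} r[i][k]^2` — each squared
     correlation as a share of its row (diagonal excluded, so rows sum
     to 1). A small share means the pair's correlation is unexceptional
     within a generally well-correlated row.
   - **Likelihood score** `ll` — min–max normalisation of the off-diagonal
     NSCC entries to [0, 1].
   - **Semantic similarity** `sem[i][j] = mean_s(x_i[s] x_j[s]) / mu_g^2`
     with `mu_g` the group's grand expression mean (an error when that mean
     is exactly 0, unless a configured offset shifts the data).
3. **Pair gates.** An ordered pair survives iff `r > 0`, `R2 <= theta_R`,
   `ll >= theta_L` and `sem >= theta_S`; defaults `theta_R = 1/(k-1)` (the
   uniform row share for a k-gene matrix, i.e. "below-average share"),
   `theta_L = theta_S = 0.5`. A gene is kept in RD2 iff it belongs to at
   least one surviving pair (in either orientation); the rest are
   `WEAK_CORRELATION`.

### 4. Information content (FRD)

The surviving pairs of each group form an undirected graph on the RD2
genes. For a gene `g` in a connected component of size `c` with degree `d`:

    x_b = d / (c - 1),   x_b* = 1 - x_b
    IC(g) = (1/lambda) * (x_b log2 x_b + x_b* log2 x_b*),  0 log 0 := 0.

With the default `lambda = -1`, IC is the binary entropy `H(x_b)` in
[0, 1]: it vanishes for genes linked to everything or almost nothing in
their component and peaks when a gene is linked to exactly half. Genes with
`IC > delta` are kept; the per-group survivors are merged into the final
reduced dataset (FRD). `delta` defaults to the equal-weight mean (0.64665)
of a packaged 6 × 4 table of IC thresholds from six GO-analysis methods
(ABP, AMF, ACC, MBP, MMF, MCC) under four CESSM metrics (ECC, RES, Seq,
Pfam); any numeric `delta` (for example 0.6637) can be configured instead.

Per-gene diagnostics are reported but never gate selection: specificity
`log(d_g+1)/log(D_max+1)` with `d_g` the depth of the gene's deepest
annotated term; coverage `1 - N_desc(term)/(N_terms - 1)`; their product
CET; the conflict derivative `1 - 2 x_b`; and an acute-similarity value
`1 + log2(p log2 p)` with `p = x_b x_b*`, which is undefined (null) for
every `p` in (0, 1] and is retained purely as a report field. Setting
`score_mode: cet_times_ic` multiplies IC by CET before thresholding for
users who want the ontology diagnostics to gate selection.

### Design choices where the procedure was open

- **Which graph the IC layer scores.** The correlation filter accumulates
  surviving *pairs*, so the IC layer scores the graph of those pairs rather
  than the tau-thresholded weight graph restricted to RD2 nodes. The
  alternative makes every strongly-correlated block a near-clique, forcing
  `x_b -> 1` and `IC -> 0` for precisely the genes the filter is meant to
  keep, and would leave the final set empty on any clean signal.
- **NSCC denominator.** The row sum excludes the diagonal `r_ii = 1`;
  including it would make a "small share" unreachable for strongly
  correlated pairs.
- **Coverage denominator.** The descendant fraction is taken over all
  ontology terms excluding the gene's own term, so a leaf scores exactly 1
  and a term whose descendants exhaust the rest scores exactly 0.
- **Term depth** is the shortest path to the namespace root (deterministic
  on DAGs); a gene's depth is the maximum over its annotated terms.
- **Selection is strict** (`IC > delta`): a gene exactly at the threshold
  is eliminated.

## Synthetic data

The generator (`ppigcf.simulate`) plants three gene roles in a two-class
matrix:

- **Informative** genes form one equicorrelated block per group:
  `x = baseline + noise_sd * (sqrt(rho) z_block + sqrt(1-rho) eps) + shift`,
  giving expected pairwise correlation `rho` within the block. The class
  shift is `effect_size * noise_sd`, applied with alternating sign by block
  index (up-regulated in even blocks, down in odd ones) — real disease
  signatures contain both directions, and a single global direction would
  leave class-conditional feature *proportions* identical, a degenerate
  input for the multinomial naive-Bayes backend.
- **Isolated** genes are constant at `baseline` plus jitter of SD
  `1e-3 * noise_sd`, so their correlations are ~0 and the network layer
  should drop them.
- **Noise** genes are independent Gaussians with no class effect, spread
  round-robin over the groups.

Defaults are the study conditions used throughout the tests: 3 groups of
60 genes (30 informative each), 300 noise genes, 100 samples (50 per
class), `rho = 0.9`, `effect_size = 2.0`, `noise_sd = 1`, seed 42. The
baseline of 8.0 mimics a log2-intensity scale and keeps the grand mean
positive so the semantic-similarity score is well defined. The toy ontology
has one CC root, one anchor per group at varied depth and a private leaf
term per informative gene (isolated/noise genes annotate to the anchor), so
annotation-frequency IC separates specific from generic placement.

The generator does **not** mimic heavy-tailed intensity distributions,
batch effects, missingness or annotation noise; passing tests demonstrate
that the implementation recovers the structure it defines, not performance
on real microarrays.

## Evaluation harness

Stratified k-fold cross-validation (default k = 10, optionally repeated)
with four backends built on scikit-learn: Mahalanobis 20-NN (pooled
within-class covariance with a 1e-6 ridge, since genes ≫ samples makes the
covariance singular; k capped at the training-fold size), random forest
(20 trees, depth 15, Gini, ≤ 100 features per split), RBF SVM (C = 0.01;
gamma follows the dimension-aware `scale` convention of e1071/scikit-learn
— a fixed numeric gamma is only meaningful for a known feature count and
scale, and can be configured), and multinomial naive Bayes with Lidstone
smoothing on per-fold min-shifted features.

Confusion counts follow the convention that class1 is positive, with FP =
"class1 classified as class2" and FN = "class2 classified as class1" (note
these are transposed relative to the common convention; accuracy is
unaffected). Accuracy is the standard (TP+TN)/total. The default F1 is the
sensitivity/specificity harmonic mean; `--f1 standard` selects the
precision/recall form.

Known limitation: the multinomial NB backend only sees class differences in
feature proportions. When the final gene set happens to contain blocks
shifted in a single direction only, NB performs near chance even on
strongly separable data; the other three backends are unaffected.

## Numerical notes and problem sizes

- The filter pipeline is fully deterministic; the configured seed only
  affects simulation and CV fold assignment.
- Degenerate inputs: groups of size < 2 cannot form edges and go straight
  to `ISOLATED`; an RD1 set of size 1 yields an empty RD2; a flat NSCC
  range sets the likelihood score to 0.5 everywhere (logged); all-zero NSCC
  rows stay zero and are flagged.
- Tests and the acceptance script run the study-condition matrix
  (480 genes × 100 samples) and compact variants (≈ 70–120 genes,
  50–60 samples) for the seed sweeps; these sizes were chosen so the whole
  suite completes in seconds while keeping every planted-recovery rate
  estimable.
- Under the study conditions the informative recall of the final stage is
  volatile (≈ 0.4–0.95 across seeds): within one equicorrelated block the
  NSCC entries concentrate around the uniform share 1/(k−1), so the joint
  gate `R2 <= 1/(k-1)` and `ll >= 0.5` retains only the band of pairs
  between the distribution's midrange and its mean. The surviving-pair
  graph density — and with it `H(x_b)` — therefore depends on the extreme
  NSCC values of the realisation. This is a property of the gate
  definitions themselves, documented here rather than patched: the gates
  and their defaults are the method's definition, not free parameters.
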