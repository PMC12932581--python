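# Methods

## Model

`pgsubtype` treats patient subtyping as unsupervised representation learning
on a population graph. Nodes are patients; node features are regional
gray-matter volumes (GMV); edges encode joint imaging/clinical similarity.
The working assumptions are:

- patients of the same subtype have more similar regional GMV profiles and
  more similar clinical scores than patients of different subtypes;
- a low-dimensional embedding that reconstructs both the node features and
  the graph topology concentrates that shared structure, so centroid-based
  clustering of the embedding recovers subtypes;
- controls and patients share a common baseline covariance structure of GMV,
  so a single patient's deviation from the control covariance network is
  informative about individual pathology (the IDSCN premise).

### Graph construction

Imaging similarity is S_I = r_ROI + r_skel, the element-wise sum of two
cross-subject Pearson correlation matrices: one over the regional GMV vectors
and one over a "skeleton" channel (any per-subject vector summarizing
core-cortical gray matter; the synthetic generator uses a fixed random linear
projection of the regional features plus noise). Entries of S_I lie in
[−2, 2].

Clinical similarity is binary and adaptive. For each scale d ∈ {PSQI, SAS,
SDS} the threshold t_d is the 25th (linear-interpolation) percentile of the
upper-triangle absolute score differences; pair (i, j) is similar on d iff
|d_i − d_j| ≤ t_d. The per-scale gates are combined with OR by default: a
pair counts as clinically comparable when it is comparable on at least one
scale. The stricter AND rule is available (`combine="and"`), but with
realistic score dispersions it passes only ~3 % of pairs — far below the
20 % sparsification target — leaving a fragmented graph with isolated
patients, which degrades attention-based message passing; OR restores the
regime in which the top-percentile cap actually performs the selection.

The weighted adjacency is A = S_I ⊙ C_d with zero diagonal. Sparsification
ranks the M = N(N−1)/2 upper-triangle entries by signed weight (negative
structural correlation is not similarity), keeps the ⌊0.2·M⌋ largest, drops
any non-positive survivor, breaks ties at the cutoff by lexicographic (i, j),
and symmetrizes. An alternative reading — ranking only gate-surviving
entries — is exposed as `ranking="nonzero"`.

### Graph attention autoencoder

The encoder stacks four multi-head graph attention layers with concatenated
output widths 256, 128, 64, 32 and heads 4, 4, 1, 1 (per-head width =
width / heads). For head k:

    e_ij = LeakyReLU(a_k ⋅ [W_k h_i ‖ W_k h_j]),   slope 0.2
    α_ij = softmax over j ∈ N*_i of e_ij            (N*_i includes i itself)
    out_i = ‖_k Σ_j α_ij W_k h_j

Self-loops are inserted inside the layer, so every node has a non-empty
inclusive neighborhood and attention rows always sum to 1. Inside the encoder
each layer is ordered aggregation → LayerNorm → ELU (the standalone
`gat_layer_forward` applies ELU directly, matching the layer's definition as
a unit; the encoder requests the raw aggregation). The same LayerNorm + ELU
is applied after the fourth layer before the latent projection
z_i = W_μ h_i + b_μ (latent width 16).

The decoder is an MLP with hidden widths 32, 64, 128, LayerNorm + LeakyReLU
(slope 0.01) between layers, and a linear output back to F features. The
structure decoder is Â = σ(ZZᵀ).

Loss: L = (1/N) Σ_i ‖x̂_i − x_i‖² + λ · BCE(A₀, Â), the BCE averaged over
all N² cells (diagonal included) with predictions clamped to
[1e−7, 1 − 1e−7]. λ defaults to 0.3, the value the silhouette grid selects
in practice. Training is full-batch Adam (lr 0.001), default 500 epochs, no
early stopping, Glorot-uniform initialization with zero biases, all seeded.

Node features are column-standardized (z-scored) before training: raw GMV is
O(10³) mm³ and the feature MSE would otherwise dwarf the BCE term at any
λ ∈ [0, 1], making the structural loss vacuous. Similarity matrices are
computed on the raw tables (Pearson r is invariant to the per-subject scale
of a common affine map, and ranking only uses relative order). The
standardization is toggleable (`TrainConfig.standardize_features`).

The whole model runs on an in-package reverse-mode autodiff engine
(`_autodiff.py`): dense float64 tensors, ~15 primitives, Adam. This keeps the
dependency surface to the scientific Python stack, makes training
bit-reproducible from a seed on any machine, and is fast at cohort scale
(a few hundred nodes; ~0.1 s/epoch at N = 140, F = 166). Gradients of every
primitive and of the composed model are verified against central finite
differences in the test suite. Masked softmax uses a detached row-max shift;
non-neighbors receive an additive −10⁴ before the shift, so their attention
is exactly zero after masking.

### Model selection, stability, characterization

- K-means (scikit-learn, 50 restarts) on Z; mean silhouette with Euclidean
  distance selects (λ, C) over λ ∈ {0.0, 0.1, …, 1.0} (grid step 0.1 is a
  package choice; only the range is prescribed) and C ∈ {2, 3, 4, 5}. One
  model is trained per λ and reused for every C (the embedding does not
  depend on C); ties break toward smaller C, then smaller λ.
- Attention test: statistic = mean(α inter-subtype) − mean(α intra), null by
  permuting node labels, one-sided p = (1 + #{perm ≥ obs})/(1 + n_perm) —
  one-sided because the claim under test is directional (inter > intra).
- Stability: runs of ⌊0.8·N⌋ patients drawn without replacement with rng
  seed + run; the induced subgraph restricts the full-cohort adjacency
  rather than rebuilding similarity (a rebuild mode is a possible sensitivity
  analysis but is not shipped); training and K-means reuse the derived seed.
  All run pairs are compared by ARI on their overlapping subjects; the
  ARI-versus-overlap relation is an OLS line.
- Group statistics: Welch t for continuous variables (the unequal-variance
  default is the safer choice when subtype variances differ), Pearson
  chi-square without Yates correction for 2×2 tables, Benjamini–Hochberg FDR
  within each declared variable family (clinical table and ROI table are
  separate families). Pearson correlations between subtype-differentiated
  regions' GMV and clinical scores, BH-FDR over the whole feature × scale
  family.

### IDSCN

The reference network PCC_n is the partial Pearson correlation of GMV across
all region pairs in controls, controlling age, sex (F=0, M=1) and TIV by
residualizing every region on the covariates plus intercept. For each
patient, PCC_{n+1} is recomputed on controls + that patient (leave-one-in),
and

    Z = ΔPCC / ((1 − PCC_n²)/(n − 1)),   n = number of controls,

exactly as the single-sample-network formulation prints it (no square root).
Two-sided p-values come from the standard normal. Per-subject multiple-
testing correction over the R(R−1)/2 edges defaults to Bonferroni for the
edge-counting step, with BH-FDR available (`method="fdr"`); outputs record
which was used. Edges with |PCC_n| = 1 are masked as undefined with a
warning. The common-alteration summary keeps edges significant in ≥ 33
subjects (an absolute count matching a 140-patient cohort; scale it as
⌈0.236·N⌉ for other cohort sizes), ranked by count, then mean |Z|, then
lexicographic region index, truncated to the top 20. K-means on the
subjects × retained-edge Z matrix gives the alternative, network-based
clustering, cross-tabulated against the embedding-based subtypes.

Null calibration: with controls and probe subjects drawn from the same
multivariate normal and no covariate effects, the empirical mean of Z across
edges and subjects is ~0 and the per-subject Bonferroni flagging rate stays
well below 0.05 (the test suite checks both at 166 regions with 200 null
subjects).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
images. Defaults mirror a 140-patient / 57-control study with two planted
subtypes (90/50):

- Regional baselines μ_r ~ U(2000, 12000) mm³; per-region residual noise
  5 % of μ_r; a global volume-scaling factor (SD 1 %, partially tied to TIV)
  and a mild age trend (−0.1 %/year from age 40) supply realistic nuisance
  covariance for the covariate-controlling stages.
- Each subtype reduces a random 20 % of regions by
  effect_size · (1 + 0.3·s_i) residual SDs, where s_i ~ N(0, 1) is a latent
  per-patient severity; default effect_size 1.5.
- Clinical scores are subtype-profiled (PSQI 13.8 ± 2.3 / 12.1 ± 3.1;
  SAS 53.2 ± 7.1 / 42.2 ± 12.1; SDS 53.7 ± 8.2 / 44.4 ± 13.6; controls
  3.6/38.1/33.7) with the same severity latent mixed in at coupling 0.7, so
  imaging and clinical channels share the subtype signal. PSQI is clipped to
  [0, 21] and rounded to integers; SAS/SDS clipped to [25, 100]. Control
  score dispersions are parameters, not fixed facts.
- Covariates: age from truncated normals (patients 36.7 ± 11.5 on [18, 60];
  controls 34.8 ± 8.3 on [21, 56]), sex Bernoulli at the group rates
  (optional subtype imbalance, off by default — the pipeline must not rely
  on it), TIV ~ N(1.45·10⁶, 1.2·10⁵) mm³ with a sex offset.
- Optional residual covariance structures ("pairs", "block") give the control
  reference network known edges; `plant_edge_perturbations` adds
  anti-correlated excursions to chosen region pairs in patients, the
  engineered condition for exercising the common-edge filter.
- The skeleton channel is a seeded random projection (N(0,1)/√F weights) of
  the regional features plus noise at 50 % of the projected SD; an identity
  projection mode exists for exact-correlation checks.

Nuisance magnitudes (global scaling 1 %, age slope 0.1 %/year) were fixed by
the generator's own contract — at effect size 1.5, K-means on standardized
raw features must recover the planted subtypes (ARI ≥ 0.9), the regime the
pipeline's recovery guarantees are stated in — before any downstream stage
was built.

What the generator does **not** emulate: scanner/site effects, spatial
autocorrelation between neighboring regions, non-Gaussian score
distributions, missing data, diagnosis errors, or any image-space process.
Passing tests therefore show the pipeline's internal correctness and its
behaviour under idealized planted structure, not performance on real MRI.

## Numerical choices and degenerate inputs

- Percentiles use numpy's linear interpolation; sparsification tie-breaks
  are lexicographic; weights of exactly 0 are never edges.
- Subjects with constant feature vectors make Pearson similarity undefined
  and raise an error naming the subject.
- An empty graph (e.g. all-zero clinical gate) is a warning at construction
  and a hard error at training.
- Non-finite losses abort training with the epoch index.
- BCE clamps predictions at 1e−7 from the boundaries; LayerNorm uses
  ε = 1e−5.
- Silhouette requires ≥ 2 clusters; C = 1 is rejected.
- In stability runs whose induced subgraph is empty are recorded as failed
  and excluded from pairing, with a warning.

## Problem sizes used in the shipped checks

The test suite exercises the full default scale where the quantity checked
is structural (140/57 subjects, 166 regions: graph shape, latent width,
reference-network shape, common-edge cap, null calibration) and reduced
scales for repeated-training properties (e.g. 60–80 patients, 24–60 regions,
20–200 epochs for stability bookkeeping and embedding-quality medians over
10 seeds). These sizes are the package's chosen verification conditions; the
defaults users run remain 500 epochs at full cohort scale.

## Known limitations

- Full-batch dense implementation: memory and time scale as O(N²) per
  attention layer; appropriate for cohorts of hundreds, not tens of
  thousands.
- The silhouette criterion prefers compact spherical clusters and C = 2
  solutions when separation is strong along one axis; it inherits K-means'
  biases.
- The IDSCN Z formula relies on the approximate normality of the
  leave-one-in perturbation; with very small control groups (n ≲ 20) the
  tails are heavier than normal and Bonferroni counting is conservative but
  p-values for single edges should be treated with care.
- Model selection retrains once per λ; with very small graphs the selected λ
  can vary across seeds even when the C = 2 structure is stable.
- The AND clinical gate is retained for completeness but is not recommended
  at the default 25th-percentile thresholds (see Graph construction).
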