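# pgsubtype

Population-graph subtyping of insomnia disorder from structural MRI.

Insomnia disorder (ID) is clinically and neurobiologically heterogeneous:
group-level comparisons of patients against controls wash out subgroups that
differ in both symptom burden and brain structure. `pgsubtype` implements a
graph-based unsupervised subtyping pipeline for cohorts described by regional
gray-matter volumes (GMV; e.g. 166 regions of an AAL3-style parcellation) and
three clinical scales — PSQI (sleep quality), SAS (anxiety), SDS (depression):

1. **Population graph.** Each patient is a node with feature vector
   x_i ∈ ℝ^F (regional GMV). Imaging similarity is
   S_I = r(ROI channel) + r(skeletonized channel), the sum of two
   cross-subject Pearson correlation matrices. Clinical similarity C_d gates
   pairs whose score difference on a scale falls below the adaptive 25th
   percentile threshold. The weighted adjacency is the Hadamard product
   A = S_I ⊙ C_d, and the binary adjacency A₀ keeps the top 20 % of
   upper-triangle weights (positive weights only).
2. **Graph attention autoencoder (GAT-AE).** A four-layer multi-head graph
   attention encoder (hidden widths 256/128/64/32, heads 4/4/1/1, LayerNorm +
   ELU, no dropout) maps X to 16-dimensional embeddings
   z_i = W_μ h_i^(L) + b_μ. An MLP decoder (32/64/128) reconstructs features
   and an inner-product decoder Â = σ(ZZᵀ) reconstructs the adjacency. The
   loss is L = (1/N) Σ_i ‖x̂_i − x_i‖² + λ·BCE(A₀, Â), trained full-batch
   with Adam (lr 0.001). The model runs on a small in-package float64
   autodiff engine, so results are bit-reproducible from a seed with no GPU
   or deep-learning dependency.
3. **Subtyping.** K-means on Z; (λ, C) selected by the highest silhouette
   over λ ∈ {0.0,…,1.0} and C ∈ {2,…,5}. A permutation test compares
   attention weights on inter- vs intra-subtype edges.
4. **Stability.** 30 subsampling runs (80 % of patients, induced subgraph,
   retrain, recluster); all 435 run pairs compared by the adjusted Rand
   index (ARI) on overlapping subjects, plus an ARI-versus-overlap trend.
5. **IDSCN.** Individualized differential structural covariance networks:
   the control-group reference network PCC_n is the partial correlation of
   GMV over all region pairs (controlling age, sex, TIV); adding one patient
   gives PCC_{n+1}, and each edge receives
   Z = ΔPCC / ((1 − PCC_n²)/(n − 1)) with two-sided normal p-values. Edges
   significantly altered (Bonferroni) in ≥ 33 patients are summarized (top
   20), and their per-subject Z values support an alternative clustering.

Because clinical imaging cohorts are rarely shareable, the package ships a
first-class synthetic cohort generator that plants ID subtypes with coupled
gray-matter reductions and clinical elevations over a matched control group,
so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from pgsubtype import (CohortSpec, generate_cohort, build_population_graph,
                       TrainConfig, train, cluster_latent, compute_silhouette,
                       subsample_stability, compute_idscns, top_altered_edges,
                       build_reference, adjusted_rand_index)

spec = CohortSpec(seed=0)                     # 140 ID + 57 HC, 166 regions
cohort = generate_cohort(spec)
graph = build_population_graph(cohort)        # patients only, top-20% edges
print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges")

model, z, report = train(graph, cfg=TrainConfig(epochs=200, lambda_struct=0.3, seed=0))
labels = cluster_latent(z, c=2, seed=0)
print(f"embeddings: {z.shape}, silhouette(C=2) = {compute_silhouette(z, labels):.3f}, "
      f"subtype sizes = {np.bincount(labels)[1:]}")

truth = cohort.pheno.loc[cohort.pheno.group == 'ID', 'true_subtype'].astype(int)
print(f"ARI vs planted subtypes = {adjusted_rand_index(truth, labels):.3f}")

rep = subsample_stability(graph, train_cfg=TrainConfig(epochs=100, lambda_struct=0.3),
                          fraction=0.8, runs=10, c=2, seed=0)
print(f"stability: {len(rep.pairs)} pairs, ARI {rep.ari_mean:.3f} ± {rep.ari_sd:.3f}")

ref = build_reference(cohort.subset('HC'))
nets = compute_idscns(cohort, ref)
summary = top_altered_edges(nets, min_subjects=33, top_k=20)
print(f"reference network: {ref.pcc.shape}, common altered edges: {len(summary.edges)}")
```

Output:

```
graph: 140 nodes, 1946 edges
embeddings: (140, 16), silhouette(C=2) = 0.792, subtype sizes = [89 51]
ARI vs planted subtypes = 0.971
stability: 45 pairs, ARI 0.988 ± 0.020
reference network: (166, 166), common altered edges: 5
```

The graph keeps ⌊0.20 · 140·139/2⌋ = 1946 edges. The embedding clustering
recovers the two planted subtypes almost perfectly (ARI 0.971 against the
generator's ground truth; 89/51 vs the planted 90/50 split), assignments are
stable across subsampling runs (mean pairwise ARI 0.988), and on this
unperturbed cohort only a handful of covariance edges pass the
33-subject common-alteration criterion.

## Command line

```bash
pgsubtype simulate   --out cohort/ --seed 0
pgsubtype build-graph --features cohort/features.tsv --skeleton cohort/skeleton.tsv \
                      --pheno cohort/pheno.tsv --out graph/
pgsubtype train      --graph graph/ --lambda 0.3 --epochs 500 --seed 0 --out run/
pgsubtype subtype    --graph graph/ --out run/
pgsubtype stability  --graph graph/ --runs 30 --fraction 0.8 --c 2 --out run/
pgsubtype idscn      --features cohort/features.tsv --pheno cohort/pheno.tsv --out run/
pgsubtype run-all    --config config.yaml
```

All stochastic stages derive from a single `--seed`; `run-all` writes a
manifest with content hashes so identical configurations yield identical
outputs.

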