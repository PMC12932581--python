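"""Population graph construction.

Nodes are subjects; edges encode inter-subject similarity. Imaging similarity
is the sum of two cross-subject Pearson correlation matrices — one over the
regional gray-matter features and one over the skeleton channel. Clinical
similarity is a binary gate: a pair is clinically similar on a measure when
the absolute score difference is at or below an adaptive threshold (the 25th
percentile of all pairwise differences for that measure), and the per-measure
gates are combined (OR by default). The weighted adjacency is the Hadamard
product of the two, and the binary adjacency keeps the top fraction of
upper-triangle weights (positive weights only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrices",
    "PopulationGraph",
    "imaging_similarity",
    "clinical_similarity",
    "build_adjacency",
    "build_population_graph",
    "EmptyGraphWarning",
]


class EmptyGraphWarning(UserWarning):
    """Raised (as a warning) when sparsification leaves no edges."""


@dataclass
class SimilarityMatrices:
    """Intermediate similarity matrices with construction provenance."""

    s_roi: np.ndarray | None = None   # N x N Pearson r over ROI features
    s_skel: np.ndarray | None = None  # N x N Pearson r over skeleton features
    s_i: np.ndarray | None = None     # imaging similarity, s_roi + s_skel
    c_d: np.ndarray | None = None     # binary clinical similarity (AND/OR gate)
    a_weighted: np.ndarray | None = None
    thresholds: dict = field(default_factory=dict)  # per-measure score thresholds

    def merged_with(self, other: "SimilarityMatrices") -> "SimilarityMatrices":
        out = SimilarityMatrices(**{k: getattr(self, k) for k in
                                    ("s_roi", "s_skel", "s_i", "c_d", "a_weighted")})
        out.thresholds = dict(self.thresholds)
        for k in ("s_roi", "s_skel", "s_i", "c_d", "a_weighted"):
            if getattr(other, k) is not None:
                setattr(out, k, getattr(other, k))
        out.thresholds.update(other.thresholds)
        return out


@dataclass
class PopulationGraph:
    """Binary population graph: node features X plus adjacency A0."""

    node_features: np.ndarray          # N x F
    adjacency: np.ndarray              # N x N binary symmetric, zero diagonal
    edge_list: np.ndarray              # E x 2 upper-triangle (i < j) indices
    subject_ids: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def induced_subgraph(self, node_idx: np.ndarray) -> "PopulationGraph":
        """Restrict to a node subset; edges are filtered from A0, not rebuilt."""
        node_idx = np.asarray(node_idx)
        adj = self.adjacency[np.ix_(node_idx, node_idx)]
        iu = np.triu_indices(len(node_idx), 1)
        edges = np.column_stack([iu[0][adj[iu] > 0], iu[1][adj[iu] > 0]])
        return PopulationGraph(
            node_features=self.node_features[node_idx],
            adjacency=adj,
            edge_list=edges,
            subject_ids=[self.subject_ids[i] for i in node_idx],
            provenance={**self.provenance, "induced_from_n": self.n_nodes},
        )


def _pearson_rows(x: np.ndarray, channel: str) -> np.ndarray:
    """Cross-subject Pearson correlation (rows = subjects)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a meaningful similarity graph")
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"constant {channel} vector for subject index(es) {bad.tolist()}; "
            "Pearson similarity is undefined"
        )
    r = np.corrcoef(x)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def imaging_similarity(roi_features, skeleton_features) -> SimilarityMatrices:
    """Imaging similarity S_I = r(ROI channel) + r(skeleton channel)."""
    s_roi = _pearson_rows(np.asarray(roi_features), "ROI")
    s_skel = _pearson_rows(np.asarray(skeleton_features), "skeleton")
    if s_roi.shape != s_skel.shape:
        raise ValueError("ROI and skeleton tables must cover the same subjects")
    return SimilarityMatrices(s_roi=s_roi, s_skel=s_skel, s_i=s_roi + s_skel)


def clinical_similarity(
    pheno: pd.DataFrame,
    measures: tuple[str, ...] = ("psqi", "sas", "sds"),
    percentile: float = 25.0,
    combine: str = "or",
) -> SimilarityMatrices:
    """Binary clinical similarity with adaptive per-measure thresholds.

    threshold_d = `percentile`-th (linear-interpolation) percentile of the
    upper-triangle absolute score differences for measure d; a pair is
    similar on d iff |score_i - score_j| <= threshold_d. Per-measure gates
    are OR-combined by default (a pair is clinically similar when comparable
    on any scale); the stricter AND rule is available via `combine`.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    missing = [m for m in measures if m not in pheno.columns]
    if missing:
        raise ValueError(f"missing clinical measures: {missing}")
    n = len(pheno)
    iu = np.triu_indices(n, 1)
    c = np.ones((n, n), dtype=float) if combine == "and" else np.zeros((n, n))
    thresholds = {}
    for m in measures:
        col = pheno[m].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            bad = pheno.index[~np.isfinite(col)].tolist()
            raise ValueError(f"non-finite {m} scores for subjects {bad}")
        diff = np.abs(col[:, None] - col[None, :])
        t = float(np.percentile(diff[iu], percentile))
        thresholds[m] = t
        sim = (diff <= t).astype(float)
        c = c * sim if combine == "and" else np.maximum(c, sim)
    np.fill_diagonal(c, 0.0)
    return SimilarityMatrices(c_d=c, thresholds=thresholds)


def build_adjacency(
    sim: SimilarityMatrices,
    sparsity: float = 0.20,
    node_features: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    ranking: str = "all",
) -> PopulationGraph:
    """Fuse and sparsify: A_w = S_I (Hadamard) C_d; keep the floor(sparsity*M)
    largest upper-triangle weights, drop non-positive ones, binarize.

    ranking="all" ranks every upper-triangle entry; "nonzero" ranks only the
    entries that survive the clinical gate (an alternative reading of the
    top-percentile rule).
    """
    if sim.s_i is None or sim.c_d is None:
        raise ValueError("similarity matrices incomplete: need s_i and c_d")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    if ranking not in ("all", "nonzero"):
        raise ValueError("ranking must be 'all' or 'nonzero'")
    n = sim.s_i.shape[0]
    a_w = sim.s_i * sim.c_d
    np.fill_diagonal(a_w, 0.0)
    sim.a_weighted = a_w

    iu, ju = np.triu_indices(n, 1)
    w = a_w[iu, ju]
    if ranking == "nonzero":
        live = sim.c_d[iu, ju] > 0
        iu, ju, w = iu[live], ju[live], w[live]
    m = w.size
    k = int(np.floor(sparsity * m))
    # sort by (-weight, i, j): deterministic lexicographic tie-break
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    keep = keep[w[keep] > 0]

    adjacency = np.zeros((n, n))
    adjacency[iu[keep], ju[keep]] = 1.0
    adjacency = adjacency + adjacency.T
    edge_list = np.column_stack([iu[keep], ju[keep]])
    edge_list = edge_list[np.lexsort((edge_list[:, 1], edge_list[:, 0]))]

    if edge_list.size == 0:
        warnings.warn("sparsification produced an empty graph", EmptyGraphWarning)

    if node_features is None:
        node_features = np.zeros((n, 0))
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n)]
    return PopulationGraph(
        node_features=np.asarray(node_features, dtype=float),
        adjacency=adjacency,
        edge_list=edge_list,
        subject_ids=list(subject_ids),
        provenance={
            "sparsity": sparsity,
            "ranking": ranking,
            "thresholds": dict(sim.thresholds),
            "n_edges": int(len(edge_list)),
            "empty": bool(edge_list.size == 0),
        },
    )


def build_population_graph(
    cohort,
    group: str = "ID",
    measures: tuple[str, ...] = ("psqi", "sas", "sds"),
    percentile: float = 25.0,
    sparsity: float = 0.20,
    combine: str = "or",
    ranking: str = "all",
) -> PopulationGraph:
    """End-to-end graph construction for one group of a SubjectCohort."""
    sub = cohort.subset(group) if group is not None else cohort
    if sub.skeleton is None:
        raise ValueError("cohort has no skeleton channel; derive or supply one")
    sim = imaging_similarity(sub.features.to_numpy(), sub.skeleton.to_numpy())
    sim = sim.merged_with(clinical_similarity(sub.pheno, measures, percentile, combine))
    graph = build_adjacency(
        sim, sparsity,
        node_features=sub.features.to_numpy(),
        subject_ids=list(sub.pheno.index),
        ranking=ranking,
    )
    graph.provenance.update({"group": group, "measures": list(measures),
                             "percentile": percentile, "combine": combine})
    return graph
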