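"""Individualized differential structural covariance networks (IDSCN).

A reference structural covariance network is the matrix of partial Pearson
correlations of regional gray-matter volume across all region pairs in the
healthy-control group, controlling for age, sex and total intracranial
volume. For each patient, a perturbed network is computed by adding that one
subject to the controls (leave-one-in); the edge-wise change

    delta = PCC_{n+1} - PCC_n,      z = delta / ((1 - PCC_n^2) / (n - 1))

(n = number of controls) is approximately standard normal under no
perturbation, giving each patient an edge-wise Z map with two-sided normal
p-values. Edges repeatedly significant across patients are summarized, and
the per-subject Z values of the top common edges can serve as an alternative
clustering feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .subtyping import cluster_latent

__all__ = [
    "ReferenceNetwork",
    "SubjectIdscn",
    "EdgeSummary",
    "partial_correlation_matrix",
    "build_reference",
    "idscn_for_subject",
    "compute_idscns",
    "edge_significance",
    "top_altered_edges",
    "idscn_based_clustering",
]


@dataclass
class ReferenceNetwork:
    pcc: np.ndarray                 # R x R partial correlations
    n_hc: int
    covariates: tuple               # names of the controlled covariates
    roi_labels: list = field(default_factory=list)


@dataclass
class SubjectIdscn:
    subject_id: str
    delta_pcc: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray | None = None


@dataclass
class EdgeSummary:
    edges: list                     # [(roi_a_idx, roi_b_idx), ...] retained
    counts: np.ndarray              # per retained edge: #subjects significant
    mean_abs_z: np.ndarray
    z_table: pd.DataFrame           # subjects x retained edges (Z values)
    min_subjects: int
    top_k: int
    roi_labels: list = field(default_factory=list)


def partial_correlation_matrix(features: np.ndarray,
                               covariates: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation of the features after residualizing each column on
    the covariates (plus intercept). With no covariates this is the plain
    correlation matrix."""
    x = np.asarray(features, dtype=float)
    s, r = x.shape
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        resid = x - x.mean(axis=0)
        p_cov = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        p_cov = c.shape[1]
        design = np.column_stack([np.ones(s), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        resid = x - design @ beta
    if s <= p_cov + 2:
        raise ValueError(f"need more than {p_cov + 2} subjects for {p_cov} covariates")
    sd = resid.std(axis=0)
    sd[sd == 0] = np.nan
    rs = resid / sd
    pcc = (rs.T @ rs) / s
    pcc = np.clip((pcc + pcc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcc, 1.0)
    return pcc


def build_reference(hc_cohort) -> ReferenceNetwork:
    """Reference network from the control group (partial correlations over
    GM volumes, controlling age, sex, TIV)."""
    groups = hc_cohort.pheno["group"].unique()
    if set(groups) != {"HC"}:
        raise ValueError(f"reference cohort must contain HC subjects only, got {groups}")
    n_hc = hc_cohort.n_subjects
    if n_hc <= 5:
        raise ValueError("need more than 5 controls for a reference network")
    pcc = partial_correlation_matrix(hc_cohort.features.to_numpy(),
                                     hc_cohort.covariate_matrix())
    return ReferenceNetwork(pcc=pcc, n_hc=n_hc, covariates=("age", "sex", "tiv"),
                            roi_labels=list(hc_cohort.features.columns))


def idscn_for_subject(ref: ReferenceNetwork, subject_features: np.ndarray,
                      hc_features: np.ndarray, hc_covariates: np.ndarray,
                      subject_covariates: np.ndarray,
                      subject_id: str = "") -> SubjectIdscn:
    """Leave-one-in perturbation: PCC over HC + this subject, delta against
    the reference, edge-wise Z and two-sided normal p."""
    feats = np.vstack([hc_features, np.asarray(subject_features, dtype=float)[None, :]])
    cov = np.vstack([hc_covariates, np.asarray(subject_covariates, dtype=float)[None, :]])
    pcc_aug = partial_correlation_matrix(feats, cov)
    delta = pcc_aug - ref.pcc
    denom = (1.0 - ref.pcc**2) / (ref.n_hc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = delta / denom
    perfect = np.abs(ref.pcc) >= 1.0 - 1e-12
    np.fill_diagonal(perfect, True)
    off_perfect = perfect.copy()
    np.fill_diagonal(off_perfect, False)
    if off_perfect.any():
        warnings.warn(f"{int(off_perfect.sum() // 2)} edges with |PCC| = 1 masked as undefined")
    z[perfect] = np.nan
    np.fill_diagonal(delta, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[perfect] = np.nan
    return SubjectIdscn(subject_id=subject_id, delta_pcc=delta, z=z, p=p)


def edge_significance(idscn: SubjectIdscn, alpha: float = 0.05,
                      method: str = "bonferroni") -> np.ndarray:
    """Per-subject multiple-testing correction over the upper-triangle edges;
    returns (and stores) a symmetric binary matrix."""
    if method not in ("bonferroni", "fdr"):
        raise ValueError("method must be 'bonferroni' or 'fdr'")
    r = idscn.p.shape[0]
    iu = np.triu_indices(r, 1)
    p = idscn.p[iu]
    sig_flat = np.zeros_like(p, dtype=bool)
    valid = np.isfinite(p)
    if valid.any():
        if method == "bonferroni":
            m = p.size  # all R(R-1)/2 tests counted, masked edges can't pass
            sig_flat[valid] = p[valid] < alpha / m
        else:
            sig_flat[valid] = multipletests(p[valid], alpha=alpha, method="fdr_bh")[0]
    sig = np.zeros((r, r), dtype=bool)
    sig[iu] = sig_flat
    sig = sig | sig.T
    idscn.significant = sig
    return sig


def compute_idscns(cohort, ref: ReferenceNetwork | None = None,
                   alpha: float = 0.05, method: str = "bonferroni") -> list[SubjectIdscn]:
    """Reference from the cohort's HC group (unless given), then one IDSCN per
    ID subject, with per-subject edge significance."""
    if ref is None:
        ref = build_reference(cohort.subset("HC"))
    hc = cohort.subset("HC")
    hc_x = hc.features.to_numpy()
    hc_c = hc.covariate_matrix()
    idc = cohort.subset("ID")
    id_x = idc.features.to_numpy()
    id_c = idc.covariate_matrix()
    out = []
    for i, sid in enumerate(idc.subject_ids):
        net = idscn_for_subject(ref, id_x[i], hc_x, hc_c, id_c[i], subject_id=sid)
        edge_significance(net, alpha=alpha, method=method)
        out.append(net)
    return out


def top_altered_edges(idscns: list[SubjectIdscn], min_subjects: int = 33,
                      top_k: int = 20, roi_labels: list | None = None) -> EdgeSummary:
    """Edges significantly altered in at least `min_subjects` subjects, ranked
    by that count (ties: mean |z| descending, then lexicographic region index),
    truncated to `top_k`."""
    if not idscns:
        raise ValueError("need at least one subject network")
    r = idscns[0].z.shape[0]
    iu = np.triu_indices(r, 1)
    counts = np.zeros(iu[0].size, dtype=int)
    abs_z_sum = np.zeros(iu[0].size)
    for net in idscns:
        if net.significant is None:
            raise ValueError("edge significance not computed; run edge_significance")
        counts += net.significant[iu]
        abs_z_sum += np.nan_to_num(np.abs(net.z[iu]))
    mean_abs_z = abs_z_sum / len(idscns)

    keep = np.where(counts >= min_subjects)[0]
    order = sorted(keep, key=lambda k: (-counts[k], -mean_abs_z[k],
                                        int(iu[0][k]), int(iu[1][k])))
    order = order[:top_k]
    edges = [(int(iu[0][k]), int(iu[1][k])) for k in order]

    z_rows = {net.subject_id: [net.z[a, b] for a, b in edges] for net in idscns}
    labels = roi_labels or [f"ROI{i + 1:03d}" for i in range(r)]
    cols = [f"{labels[a]}--{labels[b]}" for a, b in edges]
    z_table = pd.DataFrame.from_dict(z_rows, orient="index", columns=cols)
    return EdgeSummary(
        edges=edges,
        counts=np.array([counts[k] for k in order]),
        mean_abs_z=np.array([mean_abs_z[k] for k in order]),
        z_table=z_table, min_subjects=min_subjects, top_k=top_k, roi_labels=labels,
    )


def idscn_based_clustering(edge_summary: EdgeSummary, c: int = 2, seed: int = 0,
                           reference_labels: np.ndarray | None = None):
    """K-means on the subjects x retained-edge Z matrix; optional cross-tab
    and ARI against an existing subtype labeling (aligned by subject order)."""
    if not edge_summary.edges:
        raise ValueError("no retained edges; cannot cluster")
    z = edge_summary.z_table.to_numpy(dtype=float)
    labels = cluster_latent(z, c=c, seed=seed)
    crosstab = None
    ari = None
    if reference_labels is not None:
        reference_labels = np.asarray(reference_labels)
        crosstab = pd.crosstab(pd.Series(reference_labels, name="reference"),
                               pd.Series(labels, name="idscn"))
        ari = float(adjusted_rand_score(reference_labels, labels))
    return labels, crosstab, ari
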