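"""Subtype identification and characterization.

K-means on the latent embeddings, silhouette-driven selection of the
structural-loss weight lambda and the cluster count C, a permutation test on
the learned attention coefficients (inter- vs intra-subtype edges), and the
group statistics used to characterize subtypes: Welch t-tests / chi-square
with Benjamini-Hochberg FDR, and Pearson correlations between regional
volumes and clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from . import gaae

__all__ = [
    "SelectionGrid",
    "SubtypeSolution",
    "cluster_latent",
    "compute_silhouette",
    "select_model",
    "attention_subtype_test",
    "compare_groups",
    "group_stats_table",
    "correlate_features_clinical",
]


@dataclass
class SelectionGrid:
    lambda_values: tuple = tuple(round(0.1 * i, 1) for i in range(11))
    c_values: tuple = (2, 3, 4, 5)
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        if not self.lambda_values or not self.c_values:
            raise ValueError("selection grid must be non-empty")


@dataclass
class SubtypeSolution:
    labels: np.ndarray            # 1-based cluster assignment per graph node
    chosen_lambda: float
    chosen_c: int
    silhouette: float
    grid_table: pd.DataFrame      # columns: lambda, c, silhouette
    subject_ids: list = field(default_factory=list)
    embeddings: np.ndarray | None = None
    model: object | None = None


def cluster_latent(z: np.ndarray, c: int, restarts: int = 50, seed: int = 0) -> np.ndarray:
    """Best-inertia K-means over `restarts` initializations; 1-based labels."""
    z = np.asarray(z, dtype=float)
    if c < 2:
        raise ValueError("need at least 2 clusters (silhouette undefined for 1)")
    if len(z) <= c:
        raise ValueError("need more samples than clusters")
    km = KMeans(n_clusters=c, n_init=restarts, random_state=seed)
    return km.fit_predict(z) + 1


def compute_silhouette(z: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-sample silhouette with Euclidean distance."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(z, dtype=float), labels, metric="euclidean"))


def select_model(graph, grid: SelectionGrid | None = None,
                 enc: "gaae.EncoderConfig | None" = None,
                 dec: "gaae.DecoderConfig | None" = None,
                 train_cfg: "gaae.TrainConfig | None" = None) -> SubtypeSolution:
    """Silhouette grid search over (lambda, C).

    One model is trained per lambda (the embedding does not depend on C) and
    its embedding is clustered at every C. The cell with the highest
    silhouette wins; ties break toward smaller C, then smaller lambda.
    """
    grid = grid or SelectionGrid()
    train_cfg = train_cfg or gaae.TrainConfig()
    rows = []
    per_lambda: dict[float, tuple] = {}
    for lam in grid.lambda_values:
        cfg = gaae.TrainConfig(
            learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
            lambda_struct=float(lam), seed=train_cfg.seed,
            standardize_features=train_cfg.standardize_features,
        )
        try:
            model, z, _ = gaae.train(graph, enc=enc, dec=dec, cfg=cfg)
        except (ValueError, FloatingPointError):
            for c in grid.c_values:
                rows.append((float(lam), int(c), np.nan))
            continue
        per_lambda[float(lam)] = (model, z)
        for c in grid.c_values:
            labels = cluster_latent(z, int(c), grid.kmeans_restarts, grid.seed)
            rows.append((float(lam), int(c), compute_silhouette(z, labels)))
    table = pd.DataFrame(rows, columns=["lambda", "c", "silhouette"])
    if table["silhouette"].isna().all():
        raise RuntimeError("every grid cell failed to train")
    ok = table.dropna(subset=["silhouette"])
    # argmax silhouette; ties -> smaller C, then smaller lambda
    best = ok.sort_values(["silhouette", "c", "lambda"],
                          ascending=[False, True, True]).iloc[0]
    lam, c = float(best["lambda"]), int(best["c"])
    model, z = per_lambda[lam]
    labels = cluster_latent(z, c, grid.kmeans_restarts, grid.seed)
    return SubtypeSolution(
        labels=labels, chosen_lambda=lam, chosen_c=c,
        silhouette=float(best["silhouette"]), grid_table=table,
        subject_ids=list(graph.subject_ids), embeddings=z, model=model,
    )


def attention_subtype_test(attention_edges: pd.DataFrame, labels: np.ndarray,
                           n_perm: int = 10000, seed: int = 0) -> tuple[float, float]:
    """One-sided permutation test: are inter-subtype attention weights higher
    than intra-subtype ones?

    statistic = mean(alpha on inter-subtype edges) - mean(alpha on intra ones);
    the null permutes node labels; p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    i = attention_edges["i"].to_numpy()
    j = attention_edges["j"].to_numpy()
    alpha = attention_edges["alpha"].to_numpy(dtype=float)

    def stat(lab):
        inter = lab[i] != lab[j]
        if inter.all() or (~inter).all():
            raise ValueError("all edges fall in one class; statistic undefined")
        return alpha[inter].mean() - alpha[~inter].mean()

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += stat(rng.permutation(labels)) >= observed
    return float(observed), float((1 + count) / (1 + n_perm))


def compare_groups(values, group_flags, variable_kind: str = "continuous") -> dict:
    """Two-group comparison of one variable.

    continuous -> Welch (unequal-variance) two-sample t-test;
    categorical -> Pearson chi-square on the contingency table (no Yates
    correction). Returns a stats row with group means/SDs (or counts).
    """
    values = np.asarray(values)
    flags = np.asarray(group_flags)
    groups = np.unique(flags)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = values[flags == groups[0]]
    b = values[flags == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    if variable_kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        return {
            "test": "welch_t", "statistic": float(t), "p": float(p),
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
            "n_a": len(a), "n_b": len(b),
        }
    if variable_kind == "categorical":
        cats = np.unique(values)
        table = np.array([[(values[flags == g] == cat).sum() for cat in cats]
                          for g in groups])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {"test": "chi2", "statistic": float(chi2), "p": float(p),
                "table": table.tolist(), "n_a": len(a), "n_b": len(b)}
    raise ValueError("variable_kind must be 'continuous' or 'categorical'")


def group_stats_table(df: pd.DataFrame, variables: dict, group_col: str) -> pd.DataFrame:
    """Compare each variable between the two groups of `group_col`, then
    BH-FDR across the declared family (this table)."""
    rows = []
    for var, kind in variables.items():
        res = compare_groups(df[var].to_numpy(), df[group_col].to_numpy(), kind)
        rows.append({"variable": var, "kind": kind, **{k: v for k, v in res.items()
                                                       if k != "table"}})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def correlate_features_clinical(features: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every (feature, clinical measure) pair, two-sided p,
    BH-FDR across the whole family."""
    if len(features) != len(clinical):
        raise ValueError("feature and clinical tables must align")
    if len(features) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for f in features.columns:
        x = features[f].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValueError(f"zero variance in feature {f!r}")
        for m in clinical.columns:
            y = clinical[m].to_numpy(dtype=float)
            if y.std() == 0:
                raise ValueError(f"zero variance in measure {m!r}")
            r, p = stats.pearsonr(x, y)
            rows.append({"feature": f, "measure": m, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
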