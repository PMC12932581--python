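"""Subsampling-based clustering stability.

Repeatedly retrain on a random subject subsample (default 80%, without
replacement), using the induced subgraph of the full-cohort adjacency, cluster
the resulting embeddings, and compare every pair of runs by the adjusted Rand
index computed on their overlapping subjects. With 30 runs this gives
30*29/2 = 435 pairwise comparisons; the ARI distribution summarizes stability
and an OLS line of ARI on overlap size checks for overlap dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import gaae
from .subtyping import cluster_latent

__all__ = ["StabilityReport", "adjusted_rand_index", "subsample_stability",
           "ari_overlap_trend"]


@dataclass
class StabilityReport:
    runs: int
    fraction: float
    run_labels: dict                      # run index -> pd.Series(labels, index=ids)
    pairs: pd.DataFrame                   # run_a, run_b, overlap_size, ari
    ari_mean: float
    ari_sd: float
    failed_runs: list = field(default_factory=list)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same subjects."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must cover the same subject set")
    return float(adjusted_rand_score(a, b))


def subsample_stability(graph, enc=None, dec=None, train_cfg=None,
                        fraction: float = 0.8, runs: int = 30, c: int = 2,
                        seed: int = 0) -> StabilityReport:
    """Retrain on `runs` random subsamples and compare all run pairs.

    Per run r the subsample is drawn with a rng seeded seed+r, the model is
    retrained on the induced subgraph with the same derived seed (all other
    hyperparameters fixed), and embeddings are K-means clustered at `c`.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if runs < 2:
        raise ValueError("need at least 2 runs")
    train_cfg = train_cfg or gaae.TrainConfig()
    n = graph.n_nodes
    m = int(np.floor(fraction * n))
    run_labels: dict[int, pd.Series] = {}
    failed = []
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = graph.induced_subgraph(idx)
        if sub.n_edges == 0:
            warnings.warn(f"run {r}: induced subgraph empty, excluded")
            failed.append(r)
            continue
        cfg = gaae.TrainConfig(
            learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
            lambda_struct=train_cfg.lambda_struct, seed=seed + r,
            standardize_features=train_cfg.standardize_features,
        )
        _, z, _ = gaae.train(sub, enc=enc, dec=dec, cfg=cfg)
        labels = cluster_latent(z, c, seed=seed + r)
        run_labels[r] = pd.Series(labels, index=sub.subject_ids)

    rows = []
    keys = sorted(run_labels)
    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            a, b = keys[ai], keys[bi]
            common = run_labels[a].index.intersection(run_labels[b].index)
            ari = adjusted_rand_index(run_labels[a].loc[common].to_numpy(),
                                      run_labels[b].loc[common].to_numpy())
            rows.append((a, b, len(common), ari))
    pairs = pd.DataFrame(rows, columns=["run_a", "run_b", "overlap_size", "ari"])
    return StabilityReport(
        runs=runs, fraction=fraction, run_labels=run_labels, pairs=pairs,
        ari_mean=float(pairs["ari"].mean()), ari_sd=float(pairs["ari"].std(ddof=1)),
        failed_runs=failed,
    )


def ari_overlap_trend(report: StabilityReport) -> tuple[float, float, float]:
    """OLS line of pairwise ARI on overlap size: (slope, intercept, r)."""
    pairs = report.pairs
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairwise comparisons")
    x = pairs["overlap_size"].to_numpy(dtype=float)
    y = pairs["ari"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("overlap size is constant; trend slope undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
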