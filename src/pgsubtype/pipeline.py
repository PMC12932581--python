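"""Table I/O, configuration and end-to-end pipeline orchestration.

All tables are tab-delimited UTF-8 with a header row and a subject_id key.
A single seeded configuration drives every stochastic stage (simulation,
weight initialization, K-means restarts, subsampling, permutations), and a
manifest records parameters, per-stage outputs and content hashes so two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from . import gaae, idscn, stability, subtyping
from .cohort import CohortSpec, SubjectCohort, generate_cohort, spec_from_dict, write_cohort
from .graph import PopulationGraph, build_population_graph

log = logging.getLogger("pgsubtype")

__all__ = ["PipelineConfig", "load_cohort_tables", "run_pipeline",
           "write_graph", "load_config"]


def load_cohort_tables(feature_path, skeleton_path=None, pheno_path=None) -> SubjectCohort:
    """Read features/skeleton/pheno tables and inner-join on subject_id.

    Rows missing from any table are dropped with a logged count; ROI column
    order is preserved as given (atlas order).
    """
    if pheno_path is None:
        raise ValueError("pheno table is required")

    def _read(path, name):
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids in {name}: {dup}")
        return df

    features = _read(feature_path, "features")
    pheno = _read(pheno_path, "pheno")
    bad = features.columns[~features.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        for col in bad:
            row = features[pd.to_numeric(features[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric feature cell at subject {row!r}, column {col!r}")
    skeleton = _read(skeleton_path, "skeleton") if skeleton_path else None

    common = features.index.intersection(pheno.index)
    if skeleton is not None:
        common = common.intersection(skeleton.index)
    dropped = (set(features.index) | set(pheno.index)
               | (set(skeleton.index) if skeleton is not None else set())) - set(common)
    if dropped:
        log.warning("dropped %d subject(s) absent from some table: %s",
                    len(dropped), sorted(dropped))
    # keep the feature table's subject order
    order = [s for s in features.index if s in set(common)]
    if "true_subtype" in pheno.columns:
        pheno["true_subtype"] = pheno["true_subtype"].astype("Int64")
    return SubjectCohort(
        features=features.loc[order].astype(float),
        pheno=pheno.loc[order],
        skeleton=None if skeleton is None else skeleton.loc[order].astype(float),
    )


@dataclass
class PipelineConfig:
    """Validated parameters for every stage; round-trips through YAML."""

    out_dir: str = "pgsubtype_out"
    seed: int = 0
    # input: either a simulation spec or paths to the three tables
    simulate: dict | None = None
    features: str | None = None
    skeleton: str | None = None
    pheno: str | None = None
    graph: dict = field(default_factory=lambda: {
        "group": "ID", "measures": ["psqi", "sas", "sds"], "percentile": 25.0,
        "sparsity": 0.20, "combine": "or", "ranking": "all"})
    encoder: dict = field(default_factory=dict)
    decoder: dict = field(default_factory=dict)
    train: dict = field(default_factory=lambda: {"epochs": 500, "learning_rate": 1e-3})
    # model selection: grid search or a fixed (lambda, c)
    grid: dict | None = None
    fixed_lambda: float | None = 0.3
    fixed_c: int | None = 2
    stability: dict | None = field(default_factory=lambda: {
        "runs": 30, "fraction": 0.8})
    idscn: dict = field(default_factory=lambda: {
        "alpha": 0.05, "method": "bonferroni", "min_subjects": 33, "top_k": 20})

    def validate(self) -> None:
        if self.simulate is None and (self.features is None or self.pheno is None):
            raise ValueError("config needs either a simulation spec or "
                             "feature + pheno table paths")
        if self.simulate is not None:
            spec_from_dict({**self.simulate, "seed": self.seed})  # raises if invalid
        if not 0 < float(self.graph.get("sparsity", 0.2)) <= 1:
            raise ValueError("graph.sparsity must be in (0, 1]")
        gaae.EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in self.encoder.items()})
        gaae.DecoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in self.decoder.items()})
        gaae.TrainConfig(**self.train, seed=self.seed)
        if self.grid is None and (self.fixed_lambda is None or self.fixed_c is None):
            raise ValueError("either a selection grid or fixed (lambda, c) is required")
        if self.stability is not None and self.stability.get("runs", 30) < 2:
            raise ValueError("stability.runs must be >= 2")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_graph(graph: PopulationGraph, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    mtx = out / "adjacency.mtx"
    mmwrite(str(mtx), csr_matrix(graph.adjacency))
    paths.append(mtx)
    sim = graph.provenance  # weights are recoverable from edges.tsv
    edges = out / "edges.tsv"
    pd.DataFrame(graph.edge_list, columns=["i", "j"]).assign(
        subject_i=[graph.subject_ids[i] for i in graph.edge_list[:, 0]],
        subject_j=[graph.subject_ids[j] for j in graph.edge_list[:, 1]],
    ).to_csv(edges, sep="\t", index=False)
    paths.append(edges)
    prov = out / "graph_provenance.json"
    prov.write_text(json.dumps(sim, indent=2, default=str))
    paths.append(prov)
    return paths


def _enc_dec_cfg(config: PipelineConfig):
    enc = gaae.EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in config.encoder.items()})
    dec = gaae.DecoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in config.decoder.items()})
    return enc, dec


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load -> graph -> subtype -> stability ->
    characterization -> IDSCN; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    t_start = time.time()

    def stage_done(name, files, **info):
        manifest["stages"][name] = dict(info)
        for f in files:
            manifest["files"][str(Path(f).relative_to(out))] = _sha256(Path(f))
        log.info("stage %s done in %.1fs (%s)", name, time.time() - t_start, info)

    # ------------------------------------------------------------------ input
    stage = "cohort"
    try:
        if config.simulate is not None:
            spec = spec_from_dict({**config.simulate, "seed": config.seed})
            cohort = generate_cohort(spec)
        else:
            cohort = load_cohort_tables(config.features, config.skeleton, config.pheno)
        paths = write_cohort(cohort, out / "cohort")
        stage_done(stage, paths.values(), n_subjects=cohort.n_subjects)

        # ------------------------------------------------------------- graph
        stage = "graph"
        g_kw = dict(config.graph)
        g_kw["measures"] = tuple(g_kw.get("measures", ("psqi", "sas", "sds")))
        graph = build_population_graph(cohort, **g_kw)
        files = write_graph(graph, out / "graph")
        stage_done(stage, files, n_nodes=graph.n_nodes, n_edges=graph.n_edges)

        # ----------------------------------------------------- model/subtype
        stage = "subtype"
        enc, dec = _enc_dec_cfg(config)
        base_train = gaae.TrainConfig(**config.train, seed=config.seed)
        if config.grid is not None:
            grid = subtyping.SelectionGrid(
                lambda_values=tuple(config.grid.get("lambda_values",
                                                    subtyping.SelectionGrid().lambda_values)),
                c_values=tuple(config.grid.get("c_values", (2, 3, 4, 5))),
                kmeans_restarts=int(config.grid.get("kmeans_restarts", 50)),
                seed=config.seed,
            )
            sol = subtyping.select_model(graph, grid, enc, dec, base_train)
        else:
            cfg_l = gaae.TrainConfig(**{**config.train,
                                        "lambda_struct": config.fixed_lambda},
                                     seed=config.seed)
            model, z, _ = gaae.train(graph, enc=enc, dec=dec, cfg=cfg_l)
            labels = subtyping.cluster_latent(z, config.fixed_c, seed=config.seed)
            sol = subtyping.SubtypeSolution(
                labels=labels, chosen_lambda=config.fixed_lambda,
                chosen_c=config.fixed_c,
                silhouette=subtyping.compute_silhouette(z, labels),
                grid_table=pd.DataFrame(
                    [(config.fixed_lambda, config.fixed_c,
                      subtyping.compute_silhouette(z, labels))],
                    columns=["lambda", "c", "silhouette"]),
                subject_ids=list(graph.subject_ids), embeddings=z, model=model,
            )
        files = []
        emb = pd.DataFrame(sol.embeddings, index=sol.subject_ids,
                           columns=[f"z{i + 1}" for i in range(sol.embeddings.shape[1])])
        emb.index.name = "subject_id"
        files.append(out / "embeddings.tsv")
        emb.to_csv(files[-1], sep="\t")
        files.append(out / "subtypes.tsv")
        pd.DataFrame({"subject_id": sol.subject_ids, "label": sol.labels}).to_csv(
            files[-1], sep="\t", index=False)
        files.append(out / "grid.tsv")
        sol.grid_table.to_csv(files[-1], sep="\t", index=False)
        att = gaae.attention_edge_table(sol.model, graph)
        files.append(out / "attention_edges.tsv")
        att.to_csv(files[-1], sep="\t", index=False)
        stage_done(stage, files, chosen_lambda=sol.chosen_lambda,
                   chosen_c=sol.chosen_c, silhouette=round(sol.silhouette, 4))

        # --------------------------------------------------------- stability
        if config.stability is not None:
            stage = "stability"
            st_cfg = gaae.TrainConfig(**{**config.train,
                                         "lambda_struct": sol.chosen_lambda},
                                      seed=config.seed)
            rep = stability.subsample_stability(
                graph, enc, dec, st_cfg,
                fraction=float(config.stability.get("fraction", 0.8)),
                runs=int(config.stability.get("runs", 30)),
                c=sol.chosen_c, seed=config.seed)
            files = [out / "stability_pairs.tsv"]
            rep.pairs.to_csv(files[-1], sep="\t", index=False)
            slope, intercept, rval = stability.ari_overlap_trend(rep)
            summary = {"runs": rep.runs, "n_pairs": len(rep.pairs),
                       "ari_mean": rep.ari_mean, "ari_sd": rep.ari_sd,
                       "trend_slope": slope, "trend_intercept": intercept,
                       "trend_r": rval, "failed_runs": rep.failed_runs}
            files.append(out / "stability_summary.json")
            files[-1].write_text(json.dumps(summary, indent=2))
            stage_done(stage, files, n_pairs=len(rep.pairs),
                       ari_mean=round(rep.ari_mean, 4))

        # ------------------------------------------------- characterization
        stage = "report"
        idc = cohort.subset(config.graph.get("group", "ID"))
        pheno = idc.pheno.loc[sol.subject_ids].assign(subtype=sol.labels)
        gst = subtyping.group_stats_table(
            pheno, {"psqi": "continuous", "sas": "continuous", "sds": "continuous",
                    "age": "continuous", "sex": "categorical"}, "subtype")
        files = [out / "group_stats.tsv"]
        gst.to_csv(files[-1], sep="\t", index=False)
        roi = subtyping.group_stats_table(
            idc.features.loc[sol.subject_ids].assign(subtype=sol.labels),
            {c: "continuous" for c in idc.features.columns}, "subtype")
        files.append(out / "roi_stats.tsv")
        roi.to_csv(files[-1], sep="\t", index=False)
        sig_rois = roi.loc[roi["p_fdr"] < 0.05, "variable"].tolist()
        if sig_rois:
            corr = subtyping.correlate_features_clinical(
                idc.features.loc[sol.subject_ids, sig_rois],
                pheno[["psqi", "sas", "sds"]])
            files.append(out / "correlations.tsv")
            corr.to_csv(files[-1], sep="\t", index=False)
        stage_done(stage, files, n_significant_rois=len(sig_rois))

        # -------------------------------------------------------------- idscn
        if (cohort.pheno["group"] == "HC").sum() > 5:
            stage = "idscn"
            icfg = config.idscn
            nets = idscn.compute_idscns(cohort, alpha=float(icfg.get("alpha", 0.05)),
                                        method=icfg.get("method", "bonferroni"))
            summary = idscn.top_altered_edges(
                nets, min_subjects=int(icfg.get("min_subjects", 33)),
                top_k=int(icfg.get("top_k", 20)),
                roi_labels=list(cohort.features.columns))
            files = []
            r = nets[0].z.shape[0]
            iu = np.triu_indices(r, 1)
            counts_all = np.zeros(iu[0].size, dtype=int)
            for net in nets:
                counts_all += net.significant[iu]
            files.append(out / "edge_counts.tsv")
            pd.DataFrame({"roi_a": iu[0], "roi_b": iu[1], "count": counts_all}).to_csv(
                files[-1], sep="\t", index=False)
            files.append(out / "top_edges.tsv")
            pd.DataFrame({
                "roi_a": [summary.roi_labels[a] for a, _ in summary.edges],
                "roi_b": [summary.roi_labels[b] for _, b in summary.edges],
                "count": summary.counts,
                "mean_abs_z": summary.mean_abs_z,
            }).to_csv(files[-1], sep="\t", index=False)
            # bulk Z matrices: binary scratch output, not part of the hashed manifest
            np.savez_compressed(out / "idscn_z.npz",
                                z=np.stack([n.z for n in nets]),
                                subjects=np.array([n.subject_id for n in nets]))
            if summary.edges:
                ref_labels = pd.Series(sol.labels, index=sol.subject_ids)
                common = summary.z_table.index.intersection(ref_labels.index)
                labels2, crosstab, ari = idscn.idscn_based_clustering(
                    idscn.EdgeSummary(
                        edges=summary.edges, counts=summary.counts,
                        mean_abs_z=summary.mean_abs_z,
                        z_table=summary.z_table.loc[common],
                        min_subjects=summary.min_subjects, top_k=summary.top_k,
                        roi_labels=summary.roi_labels),
                    c=sol.chosen_c, seed=config.seed,
                    reference_labels=ref_labels.loc[common].to_numpy())
                files.append(out / "idscn_labels.tsv")
                pd.DataFrame({"subject_id": common, "label": labels2}).to_csv(
                    files[-1], sep="\t", index=False)
                files.append(out / "idscn_crosstab.json")
                files[-1].write_text(json.dumps(
                    {"crosstab": crosstab.to_dict(), "ari": ari}, indent=2, default=int))
            stage_done(stage, files, n_top_edges=len(summary.edges))
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
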