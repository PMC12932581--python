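"""Synthetic cohorts with planted patient subtypes.

Emulates the statistical structure the subtyping pipeline assumes: a patient
(ID, insomnia disorder) group containing latent subtypes with correlated
regional gray-matter reductions and elevated clinical scores (PSQI, SAS, SDS),
plus a matched healthy-control (HC) reference group drawn from the baseline
gray-matter distribution. A per-subject latent severity scalar drives both the
gray-matter shift and the clinical elevation, so imaging and clinical channels
carry a shared subtype signal — the coupling the population graph exploits.

No image-space simulation is attempted: features are region-level volumes
(one column per atlas region), and the "skeleton" channel is a fixed random
linear projection of the regional features plus independent noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SubjectCohort",
    "generate_cohort",
    "derive_skeleton_channel",
    "plant_edge_perturbations",
    "roi_labels",
    "write_cohort",
]

CLINICAL_MEASURES = ("psqi", "sas", "sds")
# (min, max) of each clinical scale; PSQI is an integer scale.
SCALE_RANGES = {"psqi": (0.0, 21.0), "sas": (25.0, 100.0), "sds": (25.0, 100.0)}


def roi_labels(n_roi: int = 166) -> list[str]:
    """Deterministic ordered region label list (any 166-label atlas ordering
    works; users with a real parcellation supply their own labels)."""
    return [f"ROI{i + 1:03d}" for i in range(n_roi)]


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults reproduce the study conditions of the reference cohort: 140
    patients split 90/50 between two planted subtypes, 57 controls, 166
    atlas regions, subtype clinical profiles with the more severe subtype
    elevated on all three scales, and a standardized gray-matter reduction of
    ``effect_size`` (in units of the residual regional SD) on a random
    ``affected_roi_fraction`` of regions per subtype.
    """

    n_id: int = 140
    n_hc: int = 57
    n_roi: int = 166
    n_skeleton: int = 500
    subtype_fractions: tuple = (90 / 140, 50 / 140)
    effect_size: float = 1.5
    affected_roi_fraction: float = 0.2
    # per-subtype (PSQI, SAS, SDS) means / SDs
    clinical_means: tuple = ((13.80, 53.18, 53.72), (12.10, 42.16, 44.37))
    clinical_sds: tuple = ((2.32, 7.07, 8.22), (3.07, 12.13, 13.57))
    hc_clinical_means: tuple = (3.56, 38.12, 33.72)
    hc_clinical_sds: tuple = (1.51, 10.10, 7.31)
    clinical_coupling: float = 0.7      # corr between severity latent and scores
    severity_gain: float = 0.3          # severity modulation of the GM shift
    noise_sd: float = 0.05              # residual GM noise, fraction of region mean
    tiv_scale_sd: float = 0.01          # SD of the global volume scaling factor
    age_slope: float = -0.001           # relative GM change per year from age 40
    noise_structure: dict | None = None  # {"kind": "pairs"|"block", ...}
    skeleton_projection: str = "random"  # "random" | "identity"
    skeleton_noise_sd: float = 0.5      # fraction of projected-channel SD
    sex_p_female: tuple = (75 / 140, 21 / 57)  # (ID, HC)
    subtype_sex_shift: float = 0.0      # optional subtype sex imbalance, off
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-12:
            raise ValueError("subtype_fractions must sum to 1")
        if min(self.subtype_fractions) <= 0:
            raise ValueError("subtype_fractions must be positive")
        if self.n_roi < 2:
            raise ValueError("n_roi must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name in ("n_id", "n_hc", "n_skeleton"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.clinical_means) != len(self.subtype_fractions):
            raise ValueError("clinical_means must list one triple per subtype")
        if self.skeleton_projection not in ("random", "identity"):
            raise ValueError("skeleton_projection must be 'random' or 'identity'")
        if self.skeleton_projection == "identity" and self.n_skeleton != self.n_roi:
            raise ValueError("identity projection requires n_skeleton == n_roi")


@dataclass
class SubjectCohort:
    """A cohort as three aligned tables indexed by subject_id.

    features: subjects x n_roi gray-matter volumes (strictly positive).
    skeleton: subjects x n_skeleton projected-channel values (may be None).
    pheno: group (ID/HC), psqi, sas, sds, age, sex (F/M), tiv, true_subtype
           (1-based, <NA> for HC and for real data).
    """

    features: pd.DataFrame
    pheno: pd.DataFrame
    skeleton: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.features.index.equals(self.pheno.index):
            raise ValueError("features and pheno must share the same subject index")
        if self.skeleton is not None and not self.skeleton.index.equals(self.features.index):
            raise ValueError("skeleton must share the subject index")
        vals = self.features.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("roi features must be finite and strictly positive")
        for m, (lo, hi) in SCALE_RANGES.items():
            col = self.pheno[m].to_numpy(dtype=float)
            if np.any(col < lo) or np.any(col > hi):
                raise ValueError(f"{m} scores outside scale range [{lo}, {hi}]")

    @property
    def n_subjects(self) -> int:
        return len(self.pheno)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.pheno.index)

    def subset(self, group: str) -> "SubjectCohort":
        mask = self.pheno["group"] == group
        return SubjectCohort(
            features=self.features.loc[mask].copy(),
            pheno=self.pheno.loc[mask].copy(),
            skeleton=None if self.skeleton is None else self.skeleton.loc[mask].copy(),
        )

    def covariate_matrix(self) -> np.ndarray:
        """Covariate columns (age, sex coded F=0/M=1, TIV) as a float array."""
        sex = (self.pheno["sex"] == "M").astype(float).to_numpy()
        return np.column_stack(
            [self.pheno["age"].to_numpy(dtype=float), sex,
             self.pheno["tiv"].to_numpy(dtype=float)]
        )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def _structured_noise(rng, n_subj: int, n_roi: int, structure: dict | None) -> np.ndarray:
    """Standard-normal residual field, optionally with pairwise or block
    correlation (used to give the HC reference network known covariance)."""
    e = rng.standard_normal((n_subj, n_roi))
    if structure is None:
        return e
    kind = structure.get("kind", "independent")
    if kind == "independent":
        return e
    if kind == "pairs":
        rho = float(structure["rho"])
        for a, b in structure["pairs"]:
            e[:, b] = rho * e[:, a] + np.sqrt(1 - rho**2) * e[:, b]
        return e
    if kind == "block":
        rho = float(structure["rho"])
        bs = int(structure["block_size"])
        nb = int(structure["n_blocks"])
        for k in range(nb):
            cols = range(k * bs, min((k + 1) * bs, n_roi))
            f = rng.standard_normal(n_subj)
            for c in cols:
                e[:, c] = np.sqrt(rho) * f + np.sqrt(1 - rho) * e[:, c]
        return e
    raise ValueError(f"unknown noise structure kind: {kind!r}")


def generate_cohort(spec: CohortSpec) -> SubjectCohort:
    """Draw one cohort. Deterministic given ``spec`` (including its seed)."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n = spec.n_id + spec.n_hc
    n_sub = len(spec.subtype_fractions)

    # region-level population means and the per-region residual SD
    mu = rng.uniform(2000.0, 12000.0, spec.n_roi)
    roi_sd = spec.noise_sd * mu

    # subtype sizes: largest-remainder rounding of the fractions
    sizes = np.floor(np.asarray(spec.subtype_fractions) * spec.n_id).astype(int)
    rem = spec.n_id - sizes.sum()
    order = np.argsort(-(np.asarray(spec.subtype_fractions) * spec.n_id - sizes))
    sizes[order[:rem]] += 1
    subtype = np.concatenate([np.full(s, k + 1) for k, s in enumerate(sizes)])

    # disjoint-by-draw affected region sets, one per subtype
    n_aff = max(1, int(round(spec.affected_roi_fraction * spec.n_roi)))
    perm = rng.permutation(spec.n_roi)
    affected = [perm[k * n_aff:(k + 1) * n_aff] % spec.n_roi for k in range(n_sub)]

    # covariates
    group = np.array(["ID"] * spec.n_id + ["HC"] * spec.n_hc)
    age = np.empty(n)
    age[: spec.n_id] = _truncated_normal(rng, 36.69, 11.51, 18, 60, spec.n_id)
    age[spec.n_id:] = _truncated_normal(rng, 34.75, 8.32, 21, 56, spec.n_hc)
    p_f = np.where(group == "ID", spec.sex_p_female[0], spec.sex_p_female[1])
    if spec.subtype_sex_shift:
        p_f = p_f.copy()
        p_f[: spec.n_id] += spec.subtype_sex_shift * (subtype - np.mean(subtype))
    sex_f = rng.random(n) < np.clip(p_f, 0, 1)
    sex = np.where(sex_f, "F", "M")
    tiv = rng.normal(1.45e6, 1.2e5, n) + np.where(sex_f, -5e4, 5e4)

    # latent severity (per ID subject) couples GM reduction and clinical scores
    severity = rng.standard_normal(spec.n_id)

    # gray matter: baseline * global scaling * age trend + structured noise + shift
    scale = 1.0 + rng.normal(0.0, spec.tiv_scale_sd, n) + 0.12 * (tiv / 1.45e6 - 1.0)
    age_fac = 1.0 + spec.age_slope * (age - 40.0)
    eps = _structured_noise(rng, n, spec.n_roi, spec.noise_structure)
    gm = mu[None, :] * (scale * age_fac)[:, None] + eps * roi_sd[None, :]
    for k in range(n_sub):
        rows = np.where(subtype == k + 1)[0]
        shift = spec.effect_size * (1.0 + spec.severity_gain * severity[rows])
        gm[np.ix_(rows, affected[k])] -= shift[:, None] * roi_sd[affected[k]][None, :]
    gm = np.maximum(gm, 0.02 * mu[None, :])  # enforce positivity

    # clinical scores: subtype profile + coupled severity component
    rho = spec.clinical_coupling
    scores = np.empty((n, 3))
    for j in range(3):
        e = rng.standard_normal(n)
        z = np.empty(n)
        z[: spec.n_id] = rho * severity + np.sqrt(1 - rho**2) * e[: spec.n_id]
        z[spec.n_id:] = e[spec.n_id:]
        m = np.empty(n)
        s = np.empty(n)
        for k in range(n_sub):
            rows = subtype == k + 1
            m[: spec.n_id][rows] = spec.clinical_means[k][j]
            s[: spec.n_id][rows] = spec.clinical_sds[k][j]
        m[spec.n_id:] = spec.hc_clinical_means[j]
        s[spec.n_id:] = spec.hc_clinical_sds[j]
        scores[:, j] = m + s * z
    lo, hi = SCALE_RANGES["psqi"]
    scores[:, 0] = np.round(np.clip(scores[:, 0], lo, hi))
    for j, meas in ((1, "sas"), (2, "sds")):
        lo, hi = SCALE_RANGES[meas]
        scores[:, j] = np.clip(scores[:, j], lo, hi)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    features = pd.DataFrame(gm, index=ids, columns=roi_labels(spec.n_roi))
    features.index.name = "subject_id"
    true_subtype = np.concatenate([subtype, np.full(spec.n_hc, -1)])
    pheno = pd.DataFrame(
        {
            "group": group,
            "psqi": scores[:, 0],
            "sas": scores[:, 1],
            "sds": scores[:, 2],
            "age": age,
            "sex": sex,
            "tiv": tiv,
            "true_subtype": pd.array(
                [int(t) if t > 0 else None for t in true_subtype], dtype="Int64"
            ),
        },
        index=ids,
    )
    pheno.index.name = "subject_id"

    cohort = SubjectCohort(features=features, pheno=pheno)
    return derive_skeleton_channel(cohort, spec)


def derive_skeleton_channel(cohort: SubjectCohort, spec: CohortSpec) -> SubjectCohort:
    """Attach the skeleton channel: a fixed random linear projection of the
    regional features plus independent noise, seeded by ``spec.seed`` so the
    projection matrix is shared across cohorts generated with the same spec."""
    ss = np.random.SeedSequence(spec.seed)
    _, skel_seq = ss.spawn(2)
    rng = np.random.default_rng(skel_seq)

    x = cohort.features.to_numpy()
    if spec.skeleton_projection == "identity":
        proj = x * 1.0  # affine image handled by scale/offset below
        sk = 0.85 * proj + 120.0
    else:
        p = rng.standard_normal((x.shape[1], spec.n_skeleton)) / np.sqrt(x.shape[1])
        sk = x @ p
    if spec.skeleton_noise_sd > 0 and spec.skeleton_projection == "random":
        col_sd = sk.std(axis=0, ddof=1)
        col_sd[col_sd == 0] = 1.0
        sk = sk + rng.standard_normal(sk.shape) * (spec.skeleton_noise_sd * col_sd)

    skeleton = pd.DataFrame(
        sk, index=cohort.features.index,
        columns=[f"SK{i + 1:04d}" for i in range(sk.shape[1])],
    )
    skeleton.index.name = "subject_id"
    return SubjectCohort(features=cohort.features, pheno=cohort.pheno, skeleton=skeleton)


def plant_edge_perturbations(
    cohort: SubjectCohort,
    pairs: list[tuple[int, int]],
    magnitude: float = 3.0,
    seed: int = 0,
    group: str = "ID",
) -> SubjectCohort:
    """Decouple specific region pairs in one group.

    For every subject of ``group`` and every (a, b) pair, anti-correlated
    excursions of ``magnitude`` control-group SDs are added to the two
    regions (random sign per subject/pair). Against a control group in which
    those pairs covary, each perturbed subject then produces a large
    individual deviation on exactly those reference-network edges — the
    engineered condition for testing the common-alteration edge filter.
    """
    rng = np.random.default_rng(seed)
    feats = cohort.features.copy()
    hc = cohort.features.loc[cohort.pheno["group"] == "HC"]
    sd = hc.std(axis=0, ddof=1).to_numpy()
    rows = np.where((cohort.pheno["group"] == group).to_numpy())[0]
    x = feats.to_numpy()
    for a, b in pairs:
        signs = rng.choice([-1.0, 1.0], size=rows.size)
        x[rows, a] += magnitude * sd[a] * signs
        x[rows, b] -= magnitude * sd[b] * signs
    x = np.maximum(x, 1e-3)
    feats.iloc[:, :] = x
    return SubjectCohort(features=feats, pheno=cohort.pheno.copy(),
                         skeleton=None if cohort.skeleton is None else cohort.skeleton.copy())


def write_cohort(cohort: SubjectCohort, out_dir) -> dict[str, Path]:
    """Write features.tsv / skeleton.tsv / pheno.tsv (tab-delimited, header row)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["features"] = out / "features.tsv"
    cohort.features.to_csv(paths["features"], sep="\t")
    paths["pheno"] = out / "pheno.tsv"
    cohort.pheno.to_csv(paths["pheno"], sep="\t")
    if cohort.skeleton is not None:
        paths["skeleton"] = out / "skeleton.tsv"
        cohort.skeleton.to_csv(paths["skeleton"], sep="\t")
    return paths


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (e.g. parsed YAML), tolerating lists."""
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("subtype_fractions", "hc_clinical_means", "hc_clinical_sds", "sex_p_female"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    for key in ("clinical_means", "clinical_sds"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(tuple(row) for row in d[key])
    return CohortSpec(**d)
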