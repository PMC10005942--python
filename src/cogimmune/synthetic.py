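"""Synthetic cohort generator with planted cognitive–immune covariation.

The generator emulates a transdiagnostic cohort (schizophrenia spectrum SZ,
bipolar spectrum BD, healthy controls HC) in which a cognitive block (9
z-scored domain scores) and a plasma inflammatory/immune marker block (24
analytes) share two latent modes of covariation, and participants form two
latent subgroups separated along the first mode's variate diagonal.

Latent model
------------
Each participant carries a planted subgroup label (cluster 1 or 2, exact
sizes).  The first-mode latent pair ``(u1, v1)`` is bivariate normal with
within-cluster correlation ``rho_w`` around a cluster mean shifted by
``±separation/2`` along the ``(1, 1)/sqrt(2)`` direction (cluster 1 low on
both).  ``rho_w`` is derived from the configured pooled correlation
``mode1_rho`` through the mixture identity

    pooled covariance = within covariance + between-means covariance,

so the pooled correlation of ``(u1, v1)`` equals ``mode1_rho`` exactly in
population.  A second, weaker pair ``(u2, v2)`` with correlation
``mode2_rho`` carries no cluster structure.  Observed blocks are noisy
linear expansions of the latent pairs along configured loading vectors.

Diagnosis labels are assigned within clusters at exact configured counts;
covariates and clinical scores are drawn conditionally on (group, cluster)
from a table of means/SDs.  MCAR missingness and guaranteed-outlier
displacement are applied to marker columns only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COGNITIVE_DOMAINS",
    "MARKERS",
    "COVARIATE_COLUMNS",
    "CLINICAL_COLUMNS",
    "GeneratorConfig",
    "CalibrationError",
    "default_config",
    "generate_cohort",
    "calibrate_separation",
    "within_cluster_rho",
    "between_component_variance",
    "write_cohort",
    "read_cohort",
]

COGNITIVE_DOMAINS = [
    "fine_motor_speed",
    "psychomotor_processing_speed",
    "mental_processing_speed",
    "attention",
    "verbal_learning",
    "verbal_memory",
    "semantic_fluency",
    "working_memory",
    "cognitive_control",
]

# 24 plasma analytes; HNP1-3 (human neutrophil peptides 1-3) is one analyte.
MARKERS = [
    "SA3", "A2M", "BAFF", "APRIL", "S100b", "furin", "GFAP", "NSE",
    "MAdCAM-1", "JAMA", "ICAM-1", "VCAM-1", "PSEL",
    "IL-18", "IL-18BP", "IL-18R1", "IL-18RAP",
    "HNP1-3", "BD-1", "BD-2",
    "GROa", "SDF1a", "eotaxin", "RANTES",
]

COVARIATE_COLUMNS = [
    "age", "sex", "bmi", "crp", "education", "iq",
    "ddd_antipsychotics", "ddd_antidepressants", "ddd_antiepileptics",
    "ddd_lithium", "freezer_time",
]

CLINICAL_COLUMNS = [
    "panss_negative", "panss_positive", "panss_disorganized",
    "panss_excited", "panss_depressed", "ymrs",
    "gaf_s", "gaf_f", "age_at_onset", "duration_of_illness",
]

GROUPS = ["SZ", "BD", "HC"]

# --- default loading patterns -------------------------------------------------
# Mode 1 is anchored on verbal learning / psychomotor processing speed in the
# cognitive block and on the IL-18 system plus BD-2 (positive) and VCAM-1
# (negative) in the marker block; the remaining variables carry small
# background weights so structure loadings are realistic rather than sparse.

_COG_MODE1_RAW = {
    "fine_motor_speed": 0.20,
    "psychomotor_processing_speed": 0.85,
    "mental_processing_speed": 0.30,
    "attention": 0.20,
    "verbal_learning": 0.90,
    "verbal_memory": 0.35,
    "semantic_fluency": 0.25,
    "working_memory": 0.25,
    "cognitive_control": 0.25,
}

_COG_MODE2_RAW = {
    "fine_motor_speed": 0.10,
    "psychomotor_processing_speed": 0.10,
    "mental_processing_speed": 0.25,
    "attention": 0.70,
    "verbal_learning": 0.05,
    "verbal_memory": 0.05,
    "semantic_fluency": 0.15,
    "working_memory": 0.80,
    "cognitive_control": 0.45,
}

# Signs follow the reported subgroup contrast: participants low on the
# (verbal-learning-aligned) variate pair carry HIGHER IL-18-system and BD-2
# levels and LOWER VCAM-1, so those markers load negatively and VCAM-1
# positively on the marker variate.
_MARKER_MODE1_RAW = {m: -0.05 for m in MARKERS}
_MARKER_MODE1_RAW.update({
    "IL-18": -0.85, "IL-18BP": -0.80, "BD-2": -0.70, "VCAM-1": 0.60,
    "IL-18R1": -0.20, "IL-18RAP": -0.20,
})

_MARKER_MODE2_RAW = {m: 0.05 for m in MARKERS}
_MARKER_MODE2_RAW.update({
    "eotaxin": 0.70, "RANTES": 0.65, "GROa": 0.50, "SDF1a": 0.45,
})


#: norm of the mode-2 loading vectors relative to mode 1.  The second mode is
#: expressed more weakly in the observed variables; together with the
#: residual noise this sets its finite-sample estimate near the configured
#: mode2_rho at the study size.
MODE2_SCALE = 0.7


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_pair(raw1: dict, raw2: dict, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    a1 = _unit(np.array([raw1[n] for n in names], dtype=float))
    a2 = np.array([raw2[n] for n in names], dtype=float)
    a2 = a2 - (a2 @ a1) * a1
    return a1, MODE2_SCALE * _unit(a2)


# --- covariate model ----------------------------------------------------------
# Group margins follow the demographic table of the source cohort; cluster
# offsets are additive so that cluster margins approximate the subgroup table.
# Entries: (group means {SZ, BD, HC}, group SDs, (cluster1 mean, cluster2 mean)
# printed margins, clip range).  Clinical rows exist for SZ/BD only.

_DEMOGRAPHIC_MODEL = {
    "age":       ({"SZ": 30.2, "BD": 32.8, "HC": 32.9}, {"SZ": 10.2, "BD": 11.5, "HC": 9.1}, (33.2, 31.4), (18.0, 65.0)),
    "education": ({"SZ": 12.3, "BD": 13.6, "HC": 14.5}, {"SZ": 2.3, "BD": 2.2, "HC": 2.2}, (12.9, 14.4), (7.0, 25.0)),
    "iq":        ({"SZ": 101.0, "BD": 109.0, "HC": 113.0}, {"SZ": 13.6, "BD": 11.8, "HC": 10.4}, (103.7, 114.1), (70.0, 160.0)),
    "bmi":       ({"SZ": 26.3, "BD": 25.9, "HC": 24.7}, {"SZ": 5.5, "BD": 4.6, "HC": 3.7}, (26.5, 24.4), (14.0, 60.0)),
    "crp":       ({"SZ": 3.3, "BD": 2.7, "HC": 2.2}, {"SZ": 3.5, "BD": 3.0, "HC": 2.7}, (3.1, 2.2), (0.1, 19.5)),
    # freezer storage averages ~6 years (range 1-14), shorter in HC
    "freezer_time": ({"SZ": 7.0, "BD": 7.0, "HC": 5.2}, {"SZ": 3.0, "BD": 3.0, "HC": 2.5}, (None, None), (1.0, 14.0)),
}

_CLINICAL_MODEL = {
    "panss_negative":      ({"SZ": 13.4, "BD": 8.4}, {"SZ": 5.8, "BD": 3.4}, (11.9, 9.7), (7.0, 49.0)),
    "panss_positive":      ({"SZ": 9.8, "BD": 5.8}, {"SZ": 4.2, "BD": 2.8}, (8.6, 6.8), (4.0, 28.0)),
    "panss_disorganized":  ({"SZ": 5.6, "BD": 4.3}, {"SZ": 2.6, "BD": 1.6}, (5.3, 4.3), (3.0, 21.0)),
    "panss_excited":       ({"SZ": 5.7, "BD": 5.2}, {"SZ": 2.1, "BD": 1.6}, (5.5, 5.3), (4.0, 28.0)),
    "panss_depressed":     ({"SZ": 8.3, "BD": 7.7}, {"SZ": 3.3, "BD": 2.8}, (8.1, 7.9), (4.0, 28.0)),
    "ymrs":                ({"SZ": 4.3, "BD": 3.4}, {"SZ": 4.8, "BD": 4.8}, (4.0, 3.6), (0.0, 60.0)),
    "gaf_s":               ({"SZ": 45.1, "BD": 57.9}, {"SZ": 13.1, "BD": 11.2}, (48.8, 55.6), (1.0, 100.0)),
    "gaf_f":               ({"SZ": 45.4, "BD": 55.8}, {"SZ": 13.0, "BD": 13.1}, (47.7, 55.2), (1.0, 100.0)),
    "age_at_onset":        ({"SZ": 23.8, "BD": 25.2}, {"SZ": 8.6, "BD": 9.5}, (24.9, 23.4), (10.0, 65.0)),
    "duration_of_illness": ({"SZ": 6.7, "BD": 7.4}, {"SZ": 8.0, "BD": 9.2}, (7.5, 6.0), (0.0, 50.0)),
}

_DDD_MODEL = {
    "ddd_antipsychotics":  ({"SZ": 1.0, "BD": 0.4}, {"SZ": 0.9, "BD": 0.7}, (0.8, 0.5)),
    "ddd_antidepressants": ({"SZ": 0.4, "BD": 0.4}, {"SZ": 0.8, "BD": 0.8}, (0.4, 0.4)),
    "ddd_antiepileptics":  ({"SZ": 0.1, "BD": 0.3}, {"SZ": 0.2, "BD": 0.5}, (0.2, 0.2)),
    "ddd_lithium":         ({"SZ": 0.0, "BD": 0.2}, {"SZ": 0.1, "BD": 0.5}, (0.1, 0.1)),
}

# male fraction per group and per cluster margin
_SEX_MODEL = {"SZ": 188 / 343, "BD": 114 / 289, "HC": 423 / 770}
_SEX_CLUSTER = (370 / 625, 355 / 777)


def _build_covariate_model() -> dict:
    """Assemble the default (group, cluster)-conditional covariate model."""
    return {
        "demographic": {k: v for k, v in _DEMOGRAPHIC_MODEL.items()},
        "clinical": {k: v for k, v in _CLINICAL_MODEL.items()},
        "ddd": {k: v for k, v in _DDD_MODEL.items()},
        "sex_group": dict(_SEX_MODEL),
        "sex_cluster": _SEX_CLUSTER,
    }


class CalibrationError(RuntimeError):
    """Raised when no (separation, rho_w) pair can satisfy the targets."""


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Defaults (via :func:`default_config`) reproduce the study conditions:
    n = 1402 split SZ/BD/HC = 343/289/770, pooled mode correlations 0.34 and
    0.22, planted subgroup sizes 625/777 with the reported per-cluster
    diagnosis composition.
    """

    n_per_group: tuple[int, int, int] = (343, 289, 770)  # SZ, BD, HC
    mode1_rho: float = 0.34
    mode2_rho: float = 0.22
    cluster_sizes: tuple[int, int] = (625, 777)
    # per-cluster diagnosis counts: {group: (cluster1, cluster2)}
    cluster_diag_counts: dict = field(
        default_factory=lambda: {"SZ": (264, 79), "BD": (160, 129), "HC": (201, 569)}
    )
    separation: float = 1.5
    cognitive_loadings: tuple = ()
    cognitive_loadings2: tuple = ()
    marker_loadings: tuple = ()
    marker_loadings2: tuple = ()
    noise_sd: tuple[float, float] = (0.40, 0.40)  # (cognitive, marker)
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    covariate_model: dict = field(default_factory=_build_covariate_model)
    seed: int = 0

    def __post_init__(self):
        if not self.cognitive_loadings:
            a1, a2 = _orthonormal_pair(_COG_MODE1_RAW, _COG_MODE2_RAW, COGNITIVE_DOMAINS)
            self.cognitive_loadings = tuple(a1)
            self.cognitive_loadings2 = tuple(a2)
        if not self.marker_loadings:
            b1, b2 = _orthonormal_pair(_MARKER_MODE1_RAW, _MARKER_MODE2_RAW, MARKERS)
            self.marker_loadings = tuple(b1)
            self.marker_loadings2 = tuple(b2)
        self.validate()

    # -- invariants --
    def validate(self) -> None:
        n_total = sum(self.n_per_group)
        if sum(self.cluster_sizes) != n_total:
            raise ValueError(
                f"cluster_sizes sum {sum(self.cluster_sizes)} != total n {n_total}"
            )
        for g, n_g in zip(GROUPS, self.n_per_group):
            counts = self.cluster_diag_counts[g]
            if sum(counts) != n_g:
                raise ValueError(f"diagnosis counts for {g} sum to {sum(counts)} != {n_g}")
        for c in (0, 1):
            tot = sum(self.cluster_diag_counts[g][c] for g in GROUPS)
            if tot != self.cluster_sizes[c]:
                raise ValueError(
                    f"cluster {c + 1} diagnosis counts sum to {tot} != {self.cluster_sizes[c]}"
                )
        if not (0 <= self.missing_rate <= 0.15):
            raise ValueError("missing_rate must lie in [0, 0.15]")
        for rho in (self.mode1_rho, self.mode2_rho):
            if not (0 <= rho < 1):
                raise ValueError("mode correlations must lie in [0, 1)")
        for vec in (self.cognitive_loadings, self.cognitive_loadings2,
                    self.marker_loadings, self.marker_loadings2):
            if not np.all(np.isfinite(vec)):
                raise ValueError("loading vectors must be finite")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        for key in ("n_per_group", "cluster_sizes", "noise_sd",
                    "cognitive_loadings", "cognitive_loadings2",
                    "marker_loadings", "marker_loadings2"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "cluster_diag_counts" in d:
            d["cluster_diag_counts"] = {
                g: tuple(v) for g, v in d["cluster_diag_counts"].items()
            }
        return cls(**d)


# Separation of the two planted components along the (1,1)/sqrt(2) latent
# diagonal.  The value ships precomputed by calibrate_separation() with the
# 2-cluster Ward silhouette target 0.37 at n = 1402 and pooled rho 0.34
# (full-pipeline simulation; the implied within-cluster rho is -0.19, i.e.
# the between-cluster shift carries the whole pooled correlation).
DEFAULT_SEPARATION = 2.55


def default_config(seed: int = 0) -> GeneratorConfig:
    """The study-calibrated configuration (n = 1402, rho 0.34/0.22, 625/777)."""
    return GeneratorConfig(separation=DEFAULT_SEPARATION, seed=seed)


# --- mixture identities -------------------------------------------------------

def between_component_variance(separation: float, pi1: float, pi2: float) -> float:
    """Per-coordinate between-means (co)variance of the latent shift.

    With component means at ``±(separation/2)·(1,1)/sqrt(2)`` and mixing
    weights ``pi1, pi2``, the between-means contribution to each latent
    coordinate's variance, and to their covariance, is
    ``pi1 * pi2 * separation**2 / 2``.
    """
    return pi1 * pi2 * separation**2 / 2.0


def within_cluster_rho(mode_rho: float, separation: float, pi1: float, pi2: float) -> float:
    """Within-cluster correlation yielding the target pooled correlation.

    Solves ``(rho_w + b) / (1 + b) = mode_rho`` where ``b`` is the
    between-component variance share.  The within-cluster correlation may
    legitimately be negative (the between-cluster shift along the diagonal
    then carries the whole pooled correlation); only values outside (−1, 1)
    are impossible.
    """
    b = between_component_variance(separation, pi1, pi2)
    rho_w = mode_rho * (1.0 + b) - b
    if rho_w <= -1.0:
        raise ValueError(
            f"separation {separation:.3f} too large for pooled rho {mode_rho}: "
            f"implied within-cluster rho {rho_w:.3f} <= -1"
        )
    return rho_w


# --- cohort generation --------------------------------------------------------

def _draw_bivariate(rng, n, rho):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table with planted structure; deterministic per seed.

    Returns a DataFrame with one row per participant: identifiers, diagnosis
    group, planted cluster label, 9 cognitive columns (fully observed), 24
    marker columns (with MCAR holes and injected outliers), covariates and
    clinical scores (clinical set to NaN for HC).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    pi1, pi2 = (s / n for s in config.cluster_sizes)

    # exact (group, cluster) cell counts -> label vectors, then shuffle rows
    groups, clusters = [], []
    for g in GROUPS:
        for c in (0, 1):
            cnt = config.cluster_diag_counts[g][c]
            groups.extend([g] * cnt)
            clusters.extend([c + 1] * cnt)
    order = rng.permutation(n)
    group = np.array(groups)[order]
    cluster = np.array(clusters)[order]

    # latent mode-1 pair: cluster-shifted along the (1,1)/sqrt(2) diagonal
    rho_w = within_cluster_rho(config.mode1_rho, config.separation, pi1, pi2)
    uv1 = _draw_bivariate(rng, n, rho_w)
    shift = (config.separation / 2.0) / np.sqrt(2.0)
    sign = np.where(cluster == 1, -1.0, 1.0)
    uv1 += sign[:, None] * shift
    u1, v1 = uv1[:, 0], uv1[:, 1]

    # latent mode-2 pair: no cluster structure
    uv2 = _draw_bivariate(rng, n, config.mode2_rho)
    u2, v2 = uv2[:, 0], uv2[:, 1]

    a1 = np.asarray(config.cognitive_loadings)
    a2 = np.asarray(config.cognitive_loadings2)
    b1 = np.asarray(config.marker_loadings)
    b2 = np.asarray(config.marker_loadings2)
    sd_x, sd_y = config.noise_sd

    X = np.outer(u1, a1) + np.outer(u2, a2) + sd_x * rng.standard_normal((n, len(a1)))
    Y = np.outer(v1, b1) + np.outer(v2, b2) + sd_y * rng.standard_normal((n, len(b1)))

    df = pd.DataFrame(X, columns=COGNITIVE_DOMAINS)
    dfm = pd.DataFrame(Y, columns=MARKERS)

    # marker MCAR missingness, then guaranteed-outlier displacement
    if config.missing_rate > 0:
        mask = rng.random(dfm.shape) < config.missing_rate
        dfm = dfm.mask(mask)
    if config.outlier_rate > 0:
        observed = dfm.notna().to_numpy()
        pick = (rng.random(dfm.shape) < config.outlier_rate) & observed
        vals = dfm.to_numpy()
        for j, col in enumerate(MARKERS):
            rows = np.where(pick[:, j])[0]
            if rows.size == 0:
                continue
            colvals = vals[:, j]
            q1, q3 = np.nanquantile(colvals, [0.25, 0.75])
            iqr = q3 - q1
            mag = (0.05 + np.abs(rng.standard_normal(rows.size))) * max(iqr, 1e-6)
            up = rng.random(rows.size) < 0.5
            vals[rows, j] = np.where(up, q3 + 1.5 * iqr + mag, q1 - 1.5 * iqr - mag)
        dfm = pd.DataFrame(vals, columns=MARKERS)

    cov = _draw_covariates(rng, group, cluster, config)

    out = pd.concat(
        [
            pd.DataFrame({
                "participant_id": [f"P{i + 1:04d}" for i in range(n)],
                "group": group,
                "cluster_truth": cluster,
            }),
            df, dfm, cov,
        ],
        axis=1,
    )
    # keep the latent pair available for generator-level diagnostics
    out.attrs["latents"] = pd.DataFrame({"u1": u1, "v1": v1, "u2": u2, "v2": v2})
    return out


def _additive_mean(group_means, cluster_margins, weights, g, c):
    """Group mean plus an additive cluster offset derived from printed margins."""
    m1, m2 = cluster_margins
    if m1 is None:
        return group_means[g]
    w1, w2 = weights
    overall = (w1 * m1 + w2 * m2) / (w1 + w2)
    return group_means[g] + (m1 - overall if c == 1 else m2 - overall)


def _draw_covariates(rng, group, cluster, config: GeneratorConfig) -> pd.DataFrame:
    n = len(group)
    model = config.covariate_model
    n1, n2 = config.cluster_sizes
    smi1 = sum(config.cluster_diag_counts[g][0] for g in ("SZ", "BD"))
    smi2 = sum(config.cluster_diag_counts[g][1] for g in ("SZ", "BD"))
    out = {}

    is_smi = np.isin(group, ["SZ", "BD"])

    for name, (gm, gs, cm, clip) in model["demographic"].items():
        mu = np.array([_additive_mean(gm, cm, (n1, n2), g, c) for g, c in zip(group, cluster)])
        sd = np.array([gs[g] for g in group])
        out[name] = np.clip(mu + sd * rng.standard_normal(n), *clip)

    # sex: additive on male probability
    p_c = model["sex_cluster"]
    p_bar = (n1 * p_c[0] + n2 * p_c[1]) / (n1 + n2)
    p = np.array([
        np.clip(model["sex_group"][g] + (p_c[c - 1] - p_bar), 0.02, 0.98)
        for g, c in zip(group, cluster)
    ])
    out["sex"] = np.where(rng.random(n) < p, "m", "f")

    for name, (gm, gs, cm) in model["ddd"].items():
        vals = np.full(n, np.nan)
        mu = np.array([
            _additive_mean(gm, cm, (smi1, smi2), g, c) if s else 0.0
            for g, c, s in zip(group, cluster, is_smi)
        ])
        sd = np.array([gs[g] if s else 0.0 for g, s in zip(group, is_smi)])
        vals = np.clip(mu + sd * rng.standard_normal(n), 0.0, None)
        vals[~is_smi] = 0.0  # HC receive no psychopharmacological treatment
        out[name] = vals

    for name, (gm, gs, cm, clip) in model["clinical"].items():
        vals = np.full(n, np.nan)
        idx = np.where(is_smi)[0]
        mu = np.array([
            _additive_mean(gm, cm, (smi1, smi2), group[i], cluster[i]) for i in idx
        ])
        sd = np.array([gs[group[i]] for i in idx])
        vals[idx] = np.clip(mu + sd * rng.standard_normal(idx.size), *clip)
        out[name] = vals

    cols = COVARIATE_COLUMNS + CLINICAL_COLUMNS
    return pd.DataFrame({c: out[c] for c in cols})


# --- silhouette calibration ---------------------------------------------------

def calibrate_separation(
    target_silhouette: float,
    target_rho: float,
    config: GeneratorConfig | None = None,
    n_rep: int = 3,
    seed: int = 0,
    grid: np.ndarray | None = None,
    tol: float = 0.05,
) -> tuple[float, float]:
    """Find (separation, rho_w) matching the pooled rho and a silhouette target.

    The pooled-correlation constraint is analytic (mixture identity); the
    silhouette constraint is evaluated by simulation of the full analysis
    path — cohort generation with the configured missingness and outliers,
    preprocessing (standardize, fence, impute), CCA, and the 2-cluster Ward
    silhouette on the estimated mode-1 scores — since that is the quantity
    the analysis reports.  The curve is noisy and fairly shallow, so the
    grid point whose mean silhouette is closest to the target is returned
    rather than an interpolated root.

    Raises :class:`CalibrationError` when the target silhouette is outside
    the achievable range (beyond ``tol``) given the pooled-correlation
    constraint.
    """
    if not (0 < target_silhouette < 1):
        raise ValueError("target_silhouette must lie in (0, 1)")
    if not (0 <= target_rho < 1):
        raise ValueError("target_rho must lie in [0, 1)")
    base = config if config is not None else default_config()
    n = base.n_total
    pi1, pi2 = (s / n for s in base.cluster_sizes)
    # largest separation keeping rho_w > -1
    s_max = np.sqrt(2.0 * (1.0 + target_rho) / max((1.0 - target_rho) * pi1 * pi2, 1e-12))
    if grid is None:
        grid = np.linspace(0.8, 0.95 * s_max, 10)

    sil = np.array([
        np.mean([
            _simulated_silhouette(s, target_rho, base, seed * 10_000 + 101 * i + int(s * 1000))
            for i in range(n_rep)
        ])
        for s in grid
    ])

    if target_silhouette > sil.max() + tol or target_silhouette < sil.min() - tol:
        raise CalibrationError(
            f"target silhouette {target_silhouette} outside achievable range "
            f"[{sil.min():.3f}, {sil.max():.3f}] for pooled rho {target_rho} "
            f"(grid {grid[0]:.2f}..{grid[-1]:.2f})"
        )
    s_star = float(grid[int(np.argmin(np.abs(sil - target_silhouette)))])
    return s_star, within_cluster_rho(target_rho, s_star, pi1, pi2)


def _simulated_silhouette(separation, rho, base: GeneratorConfig, seed: int) -> float:
    from sklearn.metrics import silhouette_score

    from .cca import fit_cca, sign_align
    from .cluster import cut_tree_labels, linkage_tree
    from .preprocess import preprocess_cohort

    seed = seed % (2**31)
    cfg = dataclasses.replace(base, separation=separation, mode1_rho=rho, seed=seed)
    table = generate_cohort(cfg)
    clean, _ = preprocess_cohort(table, COGNITIVE_DOMAINS, MARKERS, seed=seed + 1)
    res = sign_align(fit_cca(clean[COGNITIVE_DOMAINS], clean[MARKERS]))
    pts = np.column_stack([res.x_scores[:, 0], res.y_scores[:, 0]])
    Z = linkage_tree(pts, "ward")
    labels = cut_tree_labels(Z, 2)
    return float(silhouette_score(pts, labels))


# --- I/O ----------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path: str | Path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort as CSV (missing cells empty) plus a config sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config is not None:
        path.with_suffix(".config.json").write_text(config.to_json())


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})
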