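import dataclasses

import numpy as np
import pytest

from cogimmune.cca import fit_cca, sign_align
from cogimmune.cluster import linkage_tree, select_k
from cogimmune.preprocess import preprocess_cohort
from cogimmune.synthetic import (
    COGNITIVE_DOMAINS,
    MARKERS,
    GeneratorConfig,
    default_config,
    generate_cohort,
)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A 140-participant cohort with the same planted geometry as the default."""
    cfg = default_config(seed=seed)
    fields = dict(
        n_per_group=(34, 29, 77),
        cluster_sizes=(62, 78),
        cluster_diag_counts={"SZ": (26, 8), "BD": (16, 13), "HC": (20, 57)},
        seed=seed,
    )
    fields.update(overrides)
    return dataclasses.replace(cfg, **fields)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=7))


def run_pipeline_once(seed: int) -> dict:
    """Generate, preprocess, fit and cluster one study-scale cohort."""
    table = generate_cohort(default_config(seed=seed))
    clean, _ = preprocess_cohort(table, COGNITIVE_DOMAINS, MARKERS, seed=seed + 100)
    res = sign_align(fit_cca(clean[COGNITIVE_DOMAINS], clean[MARKERS]))
    pts = np.column_stack([res.x_scores[:, 0], res.y_scores[:, 0]])
    Z = linkage_tree(pts, "ward")
    k, sil_by_k, _ = select_k(Z, pts)
    return {
        "clean": clean,
        "result": res,
        "points": pts,
        "k": k,
        "sil2": sil_by_k[2],
        "r1": float(res.correlations[0]),
        "r2": float(res.correlations[1]),
    }


@pytest.fixture(scope="session")
def study_runs():
    """Ten study-scale pipeline runs (seeds 1..10), shared across tests."""
    return [run_pipeline_once(seed) for seed in range(1, 11)]
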