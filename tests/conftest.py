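"""Shared fixtures: small and full-size synthetic suites, tiny hand datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossmb import ExpressionDataset, SyntheticConfig, analyze_suite, generate_suite
from crossmb.synthetic import generate_gmt_with_planted_sets


def small_config(seed: int = 7) -> SyntheticConfig:
    """Reduced suite for fast unit tests (structure, not power)."""
    return SyntheticConfig(
        n_genes=300,
        shared_set_size=20,
        human_specific_set_size=20,
        mouse_specific_set_size=20,
        probes_per_gene_max=2,
        mouse_groups={"Shh": 4, "cerebellum": 4},
        human_groups={"SHH": 5, "Group3": 5, "Group4": 5},
        seed=seed,
    )


def target_groups_for(datasets) -> dict[str, str]:
    return {d.dataset_id: ("Shh" if d.species == "mouse" else "SHH") for d in datasets}


@pytest.fixture(scope="session")
def small_suite():
    cfg = small_config()
    datasets, hmap, truth, coex = generate_suite(cfg)
    return {"config": cfg, "datasets": datasets, "homolog_map": hmap,
            "truth": truth, "coex": coex}


@pytest.fixture(scope="session")
def default_suite():
    """Full default-condition suite plus the complete analysis results."""
    cfg = SyntheticConfig(seed=1)
    datasets, hmap, truth, coex = generate_suite(cfg)
    sets = generate_gmt_with_planted_sets(truth, n_random_sets=50, seed=1)
    results = analyze_suite(
        datasets,
        target_groups_for(datasets),
        homolog_map=hmap,
        gene_sets=sets,
        coexpression_ranks=coex,
        gsea_n_perm=1000,
        seed=1,
    )
    return {"config": cfg, "datasets": datasets, "homolog_map": hmap,
            "truth": truth, "coex": coex, "gene_sets": sets, "results": results}


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """3 probesets × 4 samples, two groups, hand-checkable."""
    matrix = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [3.0, 5.0, 4.0],
            "s3": [100.0, 5.0, 6.0],
            "s4": [2.0, 7.0, 8.0],
        },
        index=["p1", "p2", "p3"],
    )
    return ExpressionDataset(
        dataset_id="tiny",
        species="mouse",
        matrix=matrix,
        feature_level="probeset",
        sample_groups={"s1": "Shh", "s2": "Shh", "s3": "Shh", "s4": "cerebellum"},
        probe_annotation={"p1": "Gli1", "p2": "Gli1", "p3": "Ptch1"},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
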