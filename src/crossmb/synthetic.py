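"""Synthetic multi-dataset expression suites with planted ground truth.

Emulates the structure of the microarray panel the pipeline targets:
several mouse datasets (Shh-driven tumors vs healthy cerebellum) and
several human datasets (SHH tumors vs other medulloblastoma subgroups),
on a log2 scale with probe-level redundancy.  Three gene categories are
planted on top of a shared log-normal-ish baseline:

* ``shared_target`` — canonical Hedgehog-target analogues, upregulated in
  the SHH group of *both* species;
* ``human_specific`` — upregulated only in human SHH tumors (the OXPHOS
  analogue);
* ``mouse_specific`` — upregulated only in mouse Shh tumors (the
  cell-cycle analogue);
* everything else is ``background``.

A Gli1-coexpression rank file is also emitted, ranking the shared-target
genes near the top with configurable jitter, to exercise the rank
concordance check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionDataset,
    GeneSet,
    HomologMap,
)


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generation parameters (all expression quantities in log2 units).

    Group sample counts default to magnitudes typical of public
    medulloblastoma expression panels: human subgroup cohorts of ~20
    samples, mouse tumor/control groups of ~8 animals.
    """

    n_genes: int = 2000
    probes_per_gene_min: int = 1
    probes_per_gene_max: int = 3
    n_mouse_datasets: int = 3
    n_human_datasets: int = 3
    mouse_groups: dict[str, int] = field(
        default_factory=lambda: {"Shh": 8, "cerebellum": 8}
    )
    human_groups: dict[str, int] = field(
        default_factory=lambda: {"SHH": 20, "Group3": 20, "Group4": 20}
    )
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.8
    shared_set_size: int = 50
    human_specific_set_size: int = 50
    mouse_specific_set_size: int = 50
    effect_log2: float = 1.5
    batch_shift_sd: float = 0.3
    probe_offset_sd: float = 0.3
    coex_jitter: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.shared_set_size + self.human_specific_set_size + self.mouse_specific_set_size
        )
        if planted > self.n_genes:
            raise SyntheticError(
                f"planted set sizes sum to {planted} > n_genes {self.n_genes}"
            )
        for name, sd in [
            ("baseline_sd", self.baseline_sd),
            ("noise_sd", self.noise_sd),
        ]:
            if sd <= 0:
                raise SyntheticError(f"{name} must be > 0")
        if self.batch_shift_sd < 0 or self.probe_offset_sd < 0:
            raise SyntheticError("shift/offset sds must be ≥ 0")
        if not (1 <= self.probes_per_gene_min <= self.probes_per_gene_max):
            raise SyntheticError("invalid probes-per-gene range")
        if self.n_mouse_datasets < 1 or self.n_human_datasets < 1:
            raise SyntheticError("need ≥1 dataset per species")
        for groups, target in [(self.mouse_groups, "Shh"), (self.human_groups, "SHH")]:
            if target not in groups:
                raise SyntheticError(f"group table lacks the {target!r} target group")
            if any(n < 1 for n in groups.values()):
                raise SyntheticError("every group needs ≥1 sample")


@dataclass
class SyntheticTruth:
    """Planted memberships and effect sizes, keyed by canonical symbol."""

    membership: dict[str, str]  # canonical (human) symbol -> category
    effect_log2: float
    homolog_pairs: list[tuple[str, str]]

    def genes_in(self, category: str) -> list[str]:
        return sorted(g for g, c in self.membership.items() if c == category)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"gene": sorted(self.membership), }
        )
        frame["category"] = [self.membership[g] for g in frame["gene"]]
        frame["effect_log2"] = [
            0.0 if self.membership[g] == "background" else self.effect_log2
            for g in frame["gene"]
        ]
        return frame.set_index("gene")


def _gene_symbols(n: int) -> tuple[list[str], list[str]]:
    """Mouse (title-case) and human (uppercase) symbols sharing a root."""
    roots = [f"Gnx{i + 1:04d}" for i in range(n)]
    return roots, [r.upper() for r in roots]


def generate_suite(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], HomologMap, SyntheticTruth, pd.Series]:
    """Generate the full multi-dataset suite plus ground truth.

    Returns the datasets (probeset level, with probe annotations), the
    case-convention homolog map, the planted truth, and the synthetic
    Gli1-coexpression quantile ranks (mouse-symbol keyed).  Fully
    reproducible for a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    mouse_syms, human_syms = _gene_symbols(n)

    order = rng.permutation(n)
    s0 = config.shared_set_size
    s1 = s0 + config.human_specific_set_size
    s2 = s1 + config.mouse_specific_set_size
    category = np.full(n, "background", dtype=object)
    category[order[:s0]] = "shared_target"
    category[order[s0:s1]] = "human_specific"
    category[order[s1:s2]] = "mouse_specific"
    membership = {human_syms[i]: str(category[i]) for i in range(n)}

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    datasets: list[ExpressionDataset] = []
    for species, n_ds, groups, target in [
        ("mouse", config.n_mouse_datasets, config.mouse_groups, "Shh"),
        ("human", config.n_human_datasets, config.human_groups, "SHH"),
    ]:
        syms = mouse_syms if species == "mouse" else human_syms
        up = {"shared_target", "mouse_specific" if species == "mouse" else "human_specific"}
        effect = np.where(np.isin(category, sorted(up)), config.effect_log2, 0.0)
        for d in range(n_ds):
            dataset_id = f"syn_{species}_{d + 1}"
            n_probes = rng.integers(
                config.probes_per_gene_min, config.probes_per_gene_max + 1, size=n
            )
            probe_gene_idx = np.repeat(np.arange(n), n_probes)
            probe_offset = rng.normal(0.0, config.probe_offset_sd, size=len(probe_gene_idx))
            probe_ids = []
            counter: dict[int, int] = {}
            for gi in probe_gene_idx:
                counter[gi] = counter.get(gi, 0) + 1
                probe_ids.append(f"{syms[gi]}_p{counter[gi]}")

            columns: dict[str, np.ndarray] = {}
            sample_groups: dict[str, str] = {}
            for group, n_samples in groups.items():
                group_effect = effect if group == target else 0.0
                for s in range(n_samples):
                    sample_id = f"{dataset_id}_{group}_{s + 1}"
                    shift = rng.normal(0.0, config.batch_shift_sd)
                    gene_values = (
                        baseline
                        + group_effect
                        + shift
                        + rng.normal(0.0, config.noise_sd, size=n)
                    )
                    columns[sample_id] = gene_values[probe_gene_idx] + probe_offset
                    sample_groups[sample_id] = group
            matrix = pd.DataFrame(columns, index=pd.Index(probe_ids, name="feature_id"))
            annotation = {pid: syms[gi] for pid, gi in zip(probe_ids, probe_gene_idx)}
            datasets.append(
                ExpressionDataset(
                    dataset_id=dataset_id,
                    species=species,  # type: ignore[arg-type]
                    matrix=matrix,
                    feature_level="probeset",
                    sample_groups=sample_groups,
                    probe_annotation=annotation,
                )
            )

    homolog_map = HomologMap.from_case_convention(mouse_syms, human_syms)
    truth = SyntheticTruth(
        membership=membership,
        effect_log2=config.effect_log2,
        homolog_pairs=list(homolog_map.pairs),
    )

    # Gli1-coexpression surrogate: shared targets score ~1, background ~0,
    # jitter controls the overlap; quantile-ranked to [0, 1].
    coex_score = rng.normal(0.0, config.coex_jitter, size=n)
    coex_score[category == "shared_target"] += 1.0
    from scipy.stats import rankdata

    coex_rank = (rankdata(coex_score) - 1.0) / (n - 1.0)
    coex = pd.Series(coex_rank, index=pd.Index(mouse_syms, name="gene"), name="coex_rank")
    return datasets, homolog_map, truth, coex


def generate_gmt_with_planted_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 50,
    set_size_range: tuple[int, int] = (15, 50),
    seed: int = 0,
) -> list[GeneSet]:
    """One gene set per planted category plus random background sets.

    Gene symbols use the canonical (human, uppercase) convention so the
    collection can be fed directly to the preranked enrichment stage.
    """
    genes = sorted(truth.membership)
    lo, hi = set_size_range
    if hi > len(genes):
        raise SyntheticError(f"set size {hi} exceeds gene count {len(genes)}")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for category in ("shared_target", "human_specific", "mouse_specific"):
        members = truth.genes_in(category)
        if members:
            sets.append(
                GeneSet(
                    name=f"PLANTED_{category.upper()}",
                    description=f"planted {category} genes",
                    members=frozenset(members),
                )
            )
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"RANDOM_SET_{i + 1:03d}",
                description="random background set",
                members=frozenset(str(m) for m in members),
            )
        )
    return sets


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t")


def read_coexpression_ranks(path: str | Path) -> pd.Series:
    """Read a two-column (gene, rank) TSV of coexpression quantile ranks."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise SyntheticError(f"coexpression rank file {path} needs ≥2 columns")
    s = pd.Series(frame.iloc[:, 1].to_numpy(float), index=frame.iloc[:, 0].astype(str))
    s.index.name = "gene"
    return s
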