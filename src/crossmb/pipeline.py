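"""End-to-end orchestration: datasets → ranks → diffs → enrichment → disk.

`analyze_suite` is the in-memory core used by tests and scripts;
`run_pipeline` adds file I/O, a YAML-config entry point, a deterministic
result bundle on disk, and a JSON run manifest.  All randomness flows from
the single seed recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression_io import (
    ExpressionDataset,
    GeneSet,
    HomologMap,
    read_expression_matrix,
    read_gmt,
    read_homolog_map,
    write_expression_dataset,
    write_gmt,
)
from .gsea import GseaResult, RankedList, gsea_results_frame, run_gsea
from .preprocess import (
    collapse_to_genes_max_mean,
    group_medians,
    invariant_set_normalize,
)
from .ranking import (
    ConcordanceResult,
    OverexpressionTable,
    RankVector,
    average_ranks_by_species,
    center_rows,
    cerebellum_normalize,
    dataset_correlogram,
    quantile_rank,
    rank_concordance,
    rank_difference,
)
from .synthetic import (
    SyntheticConfig,
    generate_gmt_with_planted_sets,
    generate_suite,
    read_coexpression_ranks,
    write_truth,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; mirrors the YAML config layout."""

    datasets: list[dict] = field(default_factory=list)
    # each entry: {id, species, matrix, annotation, probe_annotation (opt),
    #              target_group, control_group (opt)}
    homolog_map: str | None = None  # path, or None for auto case-convention
    gmt: list[str] = field(default_factory=list)
    coexpression_ranks: str | None = None
    mode: str = "row_centered"  # or "cerebellum_normalized"
    normalize: bool = False  # invariant-set renormalization before analysis
    correlogram_on_ranks: bool = False
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    seed: int = 0
    high_cutoff: float = 0.8
    low_cutoff: float = 0.2
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class SuiteResults:
    """In-memory result bundle of the full analysis."""

    overexpression: list[OverexpressionTable]
    rank_vectors: list[RankVector]
    homolog_map: HomologMap
    human_means: pd.DataFrame
    mouse_means: pd.DataFrame
    diff_table: pd.DataFrame
    correlogram: pd.DataFrame
    correlogram_n: pd.DataFrame
    ranked_list: RankedList
    gsea_results: list[GseaResult] | None = None
    concordance: dict[str, ConcordanceResult] | None = None


def dataset_to_gene_ranks(
    dataset: ExpressionDataset,
    target_group: str,
    mode: str = "row_centered",
    control_group: str | None = None,
) -> tuple[OverexpressionTable, RankVector]:
    """Single-dataset path: medians → gene collapse → overexpression → ranks."""
    med = group_medians(dataset)
    if dataset.feature_level == "probeset":
        if dataset.probe_annotation is None:
            raise PipelineError(f"{dataset.dataset_id}: probeset data without annotation")
        med = collapse_to_genes_max_mean(med, dataset.probe_annotation)
    if mode == "row_centered":
        table = center_rows(med)
    elif mode == "cerebellum_normalized":
        if control_group is None:
            raise PipelineError(
                f"{dataset.dataset_id}: cerebellum mode needs a control group"
            )
        table = cerebellum_normalize(med, control_group)
    else:
        raise PipelineError(f"unknown ranking mode {mode!r}")
    return table, quantile_rank(table, target_group)


def analyze_suite(
    datasets: Sequence[ExpressionDataset],
    target_groups: Mapping[str, str],
    homolog_map: HomologMap | None = None,
    mode: str = "row_centered",
    control_groups: Mapping[str, str] | None = None,
    gene_sets: Sequence[GeneSet] | None = None,
    coexpression_ranks: pd.Series | None = None,
    normalize: bool = False,
    correlogram_on_ranks: bool = False,
    gsea_min_size: int = 15,
    gsea_max_size: int = 500,
    gsea_n_perm: int = 1000,
    gsea_weight: float = 1.0,
    seed: int = 0,
    high_cutoff: float = 0.8,
    low_cutoff: float = 0.2,
) -> SuiteResults:
    """Run the full cross-species comparison on in-memory datasets."""
    by_species = {"human": 0, "mouse": 0}
    for ds in datasets:
        by_species[ds.species] += 1
    if by_species["human"] < 1 or by_species["mouse"] < 1:
        raise PipelineError(
            "the rank-difference stage needs ≥1 dataset of each species "
            f"(got {by_species})"
        )

    if normalize:
        datasets = [invariant_set_normalize(ds) for ds in datasets]

    tables: list[OverexpressionTable] = []
    vectors: list[RankVector] = []
    for ds in datasets:
        ctrl = (control_groups or {}).get(ds.dataset_id)
        table, vec = dataset_to_gene_ranks(
            ds, target_groups[ds.dataset_id], mode=mode, control_group=ctrl
        )
        tables.append(table)
        vectors.append(vec)

    if homolog_map is None:
        mouse_syms: set[str] = set()
        human_syms: set[str] = set()
        for t in tables:
            (mouse_syms if t.species == "mouse" else human_syms).update(t.values.index)
        homolog_map = HomologMap.from_case_convention(sorted(mouse_syms), sorted(human_syms))

    human_means = average_ranks_by_species(vectors, "human", homolog_map)
    mouse_means = average_ranks_by_species(vectors, "mouse", homolog_map)
    diff = rank_difference(human_means, mouse_means, high_cutoff, low_cutoff)

    corr, corr_n = dataset_correlogram(
        tables, {t.dataset_id: target_groups[t.dataset_id] for t in tables},
        homolog_map, on_ranks=correlogram_on_ranks,
    )

    ranked = RankedList.from_scores(diff["diff"])

    gsea_results = None
    if gene_sets:
        gsea_results = run_gsea(
            ranked,
            gene_sets,
            min_size=gsea_min_size,
            max_size=gsea_max_size,
            n_perm=gsea_n_perm,
            weight=gsea_weight,
            seed=seed,
        )

    concordance = None
    if coexpression_ranks is not None:
        coex_map = homolog_map.canonicalize_index(coexpression_ranks.index, "mouse")
        coex = coexpression_ranks.loc[list(coex_map)].rename(index=coex_map)
        coex = coex[~coex.index.duplicated()]
        concordance = {
            "mouse": rank_concordance(mouse_means["mean_rank"], coex),
            "human": rank_concordance(human_means["mean_rank"], coex),
        }

    return SuiteResults(
        overexpression=tables,
        rank_vectors=vectors,
        homolog_map=homolog_map,
        human_means=human_means,
        mouse_means=mouse_means,
        diff_table=diff,
        correlogram=corr,
        correlogram_n=corr_n,
        ranked_list=ranked,
        gsea_results=gsea_results,
        concordance=concordance,
    )


def _write_bundle(results: SuiteResults, config: PipelineConfig, out: Path) -> list[str]:
    """Write every result table as TSV; returns relative paths written."""
    written: list[str] = []

    def _save(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", float_format="%.6g")
        written.append(name)

    for table in results.overexpression:
        _save(table.values, f"overexpression_{table.dataset_id}.tsv")
    for vec in results.rank_vectors:
        _save(vec.ranks.rename("rank").to_frame(), f"ranks_{vec.dataset_id}.tsv")
    _save(results.human_means, "human_mean_ranks.tsv")
    _save(results.mouse_means, "mouse_mean_ranks.tsv")
    _save(results.diff_table, "rank_diff.tsv")
    _save(results.correlogram, "correlogram.tsv")
    _save(results.correlogram_n, "correlogram_n.tsv")

    # Plot-ready per-gene ranks across datasets (rank-boxplot layout):
    # the ten largest |diff| genes, most human-specific first.
    top = results.diff_table.reindex(
        results.diff_table["diff"].abs().sort_values(ascending=False).index
    ).head(10)
    rows = []
    for gene in top.index:
        for vec in results.rank_vectors:
            mapping = results.homolog_map.canonicalize_index(vec.ranks.index, vec.species)
            inverse = {c: s for s, c in mapping.items()}
            if gene in inverse:
                rows.append(
                    {
                        "gene": gene,
                        "dataset_id": vec.dataset_id,
                        "species": vec.species,
                        "rank": vec.ranks[inverse[gene]],
                    }
                )
    if rows:
        _save(pd.DataFrame(rows).set_index("gene"), "boxplot_ranks.tsv")

    if results.gsea_results is not None:
        frame = gsea_results_frame(results.gsea_results)
        _save(frame[frame["direction"] == "positive"], "gsea_positive.tsv")
        _save(frame[frame["direction"] == "negative"], "gsea_negative.tsv")
        _write_geneset_summaries(results, frame, _save)

    if results.concordance is not None:
        frame = pd.DataFrame(
            {
                species: {
                    "r_squared": c.r_squared,
                    "slope": c.slope,
                    "p_value": c.p_value,
                    "n": c.n,
                }
                for species, c in results.concordance.items()
            }
        ).T
        frame.index.name = "species"
        _save(frame, "concordance.tsv")
    return written


def _write_geneset_summaries(results: SuiteResults, frame: pd.DataFrame, _save) -> None:
    """Per-gene species summaries for the top set of each direction.

    For each member gene of the top positive and top negative enrichment
    set: the mean SHH-group overexpression value per species (under the
    run's ranking mode), the layout behind per-set expression dot plots.
    """
    by_name = {r.set_name: r for r in results.gsea_results}
    rows = []
    for direction in ("positive", "negative"):
        sub = frame[frame["direction"] == direction]
        if sub.empty:
            continue
        top_set = by_name[sub.index[0]]
        per_species: dict[str, pd.Series] = {}
        for table in results.overexpression:
            mapping = results.homolog_map.canonicalize_index(
                table.values.index, table.species
            )
            target_col = [
                v.target_group for v in results.rank_vectors
                if v.dataset_id == table.dataset_id
            ][0]
            s = table.values[target_col].loc[list(mapping)].rename(index=mapping)
            per_species.setdefault(table.species, []).append(s)
        for gene in sorted(top_set.leading_edge):
            row = {"set_name": top_set.set_name, "direction": direction, "gene": gene}
            for species, series_list in per_species.items():
                vals = [s[gene] for s in series_list if gene in s.index]
                row[f"{species}_mean_overexpression"] = (
                    float(np.mean(vals)) if vals else float("nan")
                )
            rows.append(row)
    if rows:
        _save(pd.DataFrame(rows).set_index("set_name"), "geneset_summary.tsv")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the result bundle under output_dir.

    Any stage failure aborts with a stage-named error and removes the
    partial outputs.  Two runs with identical inputs and seed produce
    byte-identical bundles.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "load"
    t0 = time.time()
    try:
        datasets: list[ExpressionDataset] = []
        target_groups: dict[str, str] = {}
        control_groups: dict[str, str] = {}
        for entry in config.datasets:
            probe_ann = None
            if entry.get("probe_annotation"):
                probe_ann = read_probe_annotation(entry["probe_annotation"])
            ds = read_expression_matrix(
                entry["matrix"],
                entry["annotation"],
                dataset_id=entry["id"],
                species=entry["species"],
                feature_level="probeset" if probe_ann is not None else "gene",
                probe_annotation=probe_ann,
            )
            datasets.append(ds)
            target_groups[ds.dataset_id] = entry["target_group"]
            if entry.get("control_group"):
                control_groups[ds.dataset_id] = entry["control_group"]
        logger.info("stage load: %d datasets in %.1fs", len(datasets), time.time() - t0)

        stage = "homolog_map"
        homolog = read_homolog_map(config.homolog_map) if config.homolog_map else None

        stage = "gene_sets"
        gene_sets: list[GeneSet] = []
        for path in config.gmt:
            gene_sets.extend(read_gmt(path))

        stage = "coexpression"
        coex = (
            read_coexpression_ranks(config.coexpression_ranks)
            if config.coexpression_ranks
            else None
        )

        stage = "analysis"
        results = analyze_suite(
            datasets,
            target_groups,
            homolog_map=homolog,
            mode=config.mode,
            control_groups=control_groups,
            gene_sets=gene_sets or None,
            coexpression_ranks=coex,
            normalize=config.normalize,
            correlogram_on_ranks=config.correlogram_on_ranks,
            gsea_min_size=config.gsea_min_size,
            gsea_max_size=config.gsea_max_size,
            gsea_n_perm=config.gsea_n_perm,
            gsea_weight=config.gsea_weight,
            seed=config.seed,
            high_cutoff=config.high_cutoff,
            low_cutoff=config.low_cutoff,
        )

        stage = "write"
        written = _write_bundle(results, config, out)

        stage = "manifest"
        manifest = {
            "crossmb_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "mode": config.mode,
            "normalize": config.normalize,
            "gsea": {
                "min_size": config.gsea_min_size,
                "max_size": config.gsea_max_size,
                "n_perm": config.gsea_n_perm,
                "weight": config.gsea_weight,
            },
            "cutoffs": {"high": config.high_cutoff, "low": config.low_cutoff},
            "datasets": [
                {"id": ds.dataset_id, "species": ds.species,
                 "n_features": int(ds.matrix.shape[0]),
                 "n_samples": int(ds.matrix.shape[1])}
                for ds in datasets
            ],
            "stages": ["load", "homolog_map", "gene_sets", "coexpression",
                       "analysis", "write", "manifest"],
            "outputs": sorted(written),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append("manifest.json")
        logger.info("pipeline complete in %.1fs (%d outputs)", time.time() - t0, len(written))
        return out
    except Exception as exc:
        for name in written:
            try:
                (out / name).unlink()
            except OSError:
                pass
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """Two-column probe→gene-symbol TSV (header optional not supported)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1].fillna("")))


def simulate_to_disk(
    config: SyntheticConfig,
    out_dir: str | Path,
    n_random_sets: int = 50,
) -> Path:
    """Write a complete synthetic suite plus a ready-to-run pipeline config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, homolog_map, truth, coex = generate_suite(config)

    entries = []
    for ds in datasets:
        matrix_path = out / f"{ds.dataset_id}_matrix.tsv"
        ann_path = out / f"{ds.dataset_id}_annotation.tsv"
        probe_path = out / f"{ds.dataset_id}_probes.tsv"
        write_expression_dataset(ds, matrix_path, ann_path)
        pd.DataFrame(
            {"probe_id": list(ds.probe_annotation),
             "gene": [ds.probe_annotation[p] for p in ds.probe_annotation]}
        ).to_csv(probe_path, sep="\t", index=False)
        entries.append(
            {
                "id": ds.dataset_id,
                "species": ds.species,
                "matrix": str(matrix_path),
                "annotation": str(ann_path),
                "probe_annotation": str(probe_path),
                "target_group": "Shh" if ds.species == "mouse" else "SHH",
                "control_group": "cerebellum" if ds.species == "mouse" else None,
            }
        )

    pd.DataFrame(homolog_map.pairs, columns=["mouse", "human"]).to_csv(
        out / "homolog_map.tsv", sep="\t", index=False, header=False
    )
    write_gmt(
        generate_gmt_with_planted_sets(truth, n_random_sets=n_random_sets, seed=config.seed),
        out / "genesets.gmt",
    )
    write_truth(truth, out / "truth.tsv")
    coex.rename("coex_rank").to_frame().to_csv(out / "coexpression_ranks.tsv", sep="\t")

    pipeline_cfg = {
        "datasets": entries,
        "homolog_map": str(out / "homolog_map.tsv"),
        "gmt": [str(out / "genesets.gmt")],
        "coexpression_ranks": str(out / "coexpression_ranks.tsv"),
        "mode": "row_centered",
        "seed": config.seed,
        "output_dir": str(out / "results"),
    }
    with open(out / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return out
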