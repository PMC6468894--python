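"""Array normalization and probeset→gene reduction.

The reduction order mirrors the analysis it implements: per-group medians
are computed at probeset level first, and the max-mean collapse to genes is
applied to that group-median table — not to the sample-level matrix.  A
separate sample-level max-mean probe selector exists only for single-gene
plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import rankdata

from .expression_io import ExpressionDataset, Species

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class GroupMedianTable:
    """Median log2 expression per feature per group for one dataset."""

    dataset_id: str
    species: Species
    values: pd.DataFrame  # rows: feature ids; columns: group labels
    feature_level: Literal["probeset", "gene"] = "probeset"


def group_medians(dataset: ExpressionDataset) -> GroupMedianTable:
    """Median expression of every feature within each sample group.

    Single-sample groups yield that sample's value.  Group columns are
    sorted alphabetically for determinism.
    """
    groups = dataset.groups
    counts = groups.value_counts()
    empty = [g for g in set(dataset.sample_groups.values()) if g not in counts.index]
    if empty:
        raise PreprocessError(f"{dataset.dataset_id}: groups with zero samples: {empty}")
    med = dataset.matrix.T.groupby(groups).median().T
    med = med[sorted(med.columns)]
    return GroupMedianTable(
        dataset_id=dataset.dataset_id,
        species=dataset.species,
        values=med,
        feature_level=dataset.feature_level,
    )


def _clean_annotation(
    annotation: Mapping[str, str],
    multi_symbol_policy: Literal["drop", "first"] = "drop",
) -> dict[str, str]:
    """Normalize a probe→symbol map; handle multi-symbol entries ('A /// B').

    ``drop`` discards probesets annotated to several genes; ``first`` keeps
    the first listed symbol.  Empty symbols (unannotated) are discarded.
    """
    out: dict[str, str] = {}
    n_multi = 0
    for probe, symbol in annotation.items():
        if not symbol:
            continue
        parts = [p for chunk in symbol.split("///") for p in chunk.split(";")]
        parts = [p.strip() for p in parts if p.strip()]
        if not parts:
            continue
        if len(parts) > 1:
            n_multi += 1
            if multi_symbol_policy == "drop":
                continue
        out[probe] = parts[0]
    if n_multi:
        logger.info(
            "annotation: %d multi-symbol probesets handled with policy %r",
            n_multi,
            multi_symbol_policy,
        )
    return out


def collapse_to_genes_max_mean(
    table: GroupMedianTable,
    annotation: Mapping[str, str],
    multi_symbol_policy: Literal["drop", "first"] = "drop",
) -> GroupMedianTable:
    """Collapse a probeset-level group-median table to gene level (MaxMean).

    For each gene the retained row is the probeset with the maximal mean
    across the table's group columns; ties break toward the
    lexicographically smallest probeset id.  Unannotated probesets are
    dropped.
    """
    if table.feature_level != "probeset":
        raise PreprocessError("collapse requires a probeset-level table")
    ann = _clean_annotation(annotation, multi_symbol_policy)
    ann = {p: g for p, g in ann.items() if p in table.values.index}
    if not ann:
        raise PreprocessError(
            f"{table.dataset_id}: annotation covers no probeset in the table"
        )
    sub = table.values.loc[sorted(ann)]
    means = sub.mean(axis=1)
    genes = pd.Series({p: ann[p] for p in sub.index}, name="gene")
    # Stable ordering: probes sorted by id, so idxmax returns the
    # lexicographically smallest probe among mean ties.
    best = means.groupby(genes).idxmax()
    collapsed = sub.loc[best.values]
    collapsed.index = best.index
    collapsed = collapsed.sort_index()
    return GroupMedianTable(
        dataset_id=table.dataset_id,
        species=table.species,
        values=collapsed,
        feature_level="gene",
    )


def select_max_mean_probe(
    dataset: ExpressionDataset,
    gene: str,
    annotation: Mapping[str, str] | None = None,
) -> pd.Series:
    """Sample-level expression row of a gene's highest-mean probeset.

    Used for per-gene expression plots; the gene is matched
    case-insensitively against the annotation's symbols.
    """
    ann = annotation if annotation is not None else dataset.probe_annotation
    if ann is None:
        raise PreprocessError("no probe annotation available")
    ann = _clean_annotation(ann, "first")
    probes = sorted(
        p for p, g in ann.items() if g.lower() == gene.lower() and p in dataset.matrix.index
    )
    if not probes:
        raise PreprocessError(f"gene {gene!r} has no annotated probeset in the matrix")
    sub = dataset.matrix.loc[probes]
    best = sub.mean(axis=1).idxmax()
    return sub.loc[best]


def _strictly_increasing_map(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Turn smoothed knots into a strictly increasing piecewise-linear map."""
    order = np.argsort(xs, kind="mergesort")
    xs, ys = xs[order], ys[order]
    # Average y over duplicated x so knot x-values are strictly increasing.
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inverse, ys)
    np.add.at(counts, inverse, 1.0)
    uy = uy / counts
    # Monotone envelope, then an infinitesimal slope so the map is strict.
    uy = np.maximum.accumulate(uy)
    uy = uy + np.arange(len(uy)) * 1e-12
    return ux, uy


def _apply_monotone_map(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear extrapolation at both ends."""
    if len(xs) == 1:
        return x - xs[0] + ys[0]
    out = np.interp(x, xs, ys)
    lo = x < xs[0]
    hi = x > xs[-1]
    if lo.any():
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out[lo] = ys[0] + slope * (x[lo] - xs[0])
    if hi.any():
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out[hi] = ys[-1] + slope * (x[hi] - xs[-1])
    return out


def invariant_set_normalize(
    dataset: ExpressionDataset,
    reference: str = "pseudo-median",
    rank_diff_threshold: float = 0.05,
    max_iter: int = 30,
    window: int = 51,
    min_invariant: int = 20,
) -> ExpressionDataset:
    """Between-array normalization through a rank-invariant feature set.

    Each non-reference array is monotonically transformed so that features
    whose ranks are stable between the array and the reference line up with
    the reference.  The invariant set is found iteratively: features whose
    proportion rank difference (|rank_a − rank_ref| / n) is below
    ``rank_diff_threshold`` are kept and the ranks recomputed within the
    surviving set, until the set stabilizes (≤ ``max_iter`` rounds).  The
    mapping through the invariant points is a running-median smooth
    (``window`` points) applied to all features by strictly monotone
    piecewise-linear interpolation, so within-array rank order is preserved
    exactly.  The reference array (or pseudo-median profile) is unchanged.
    """
    if dataset.matrix.shape[1] < 2:
        raise PreprocessError("invariant-set normalization needs ≥2 samples")
    if reference == "pseudo-median":
        ref_values = dataset.matrix.median(axis=1).to_numpy()
        ref_sample = None
    else:
        if reference not in dataset.matrix.columns:
            raise PreprocessError(f"reference sample {reference!r} not in matrix")
        ref_values = dataset.matrix[reference].to_numpy()
        ref_sample = reference

    out = dataset.matrix.copy()
    for sample in dataset.matrix.columns:
        if sample == ref_sample:
            continue
        x = dataset.matrix[sample].to_numpy()
        idx = np.arange(len(x))
        for _ in range(max_iter):
            rx = rankdata(x[idx])
            rr = rankdata(ref_values[idx])
            prd = np.abs(rx - rr) / len(idx)
            keep = prd < rank_diff_threshold
            if keep.all():
                break
            idx = idx[keep]
            if len(idx) < min_invariant:
                raise PreprocessError(
                    f"{dataset.dataset_id}/{sample}: only {len(idx)} invariant "
                    f"features (<{min_invariant}); increase rank_diff_threshold"
                )
        xs = x[idx]
        ys = ref_values[idx]
        order = np.argsort(xs, kind="mergesort")
        xs, ys = xs[order], ys[order]
        w = min(window, len(ys))
        if w % 2 == 0:
            w -= 1
        if w >= 3:
            ys = median_filter(ys, size=w, mode="nearest")
        xs, ys = _strictly_increasing_map(xs, ys)
        out[sample] = _apply_monotone_map(x, xs, ys)

    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        species=dataset.species,
        matrix=out,
        feature_level=dataset.feature_level,
        sample_groups=dict(dataset.sample_groups),
        probe_annotation=dict(dataset.probe_annotation)
        if dataset.probe_annotation is not None
        else None,
    )
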