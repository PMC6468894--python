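"""Overexpression values, quantile ranks, cross-species rank differences.

The central quantity is the *overexpression value*: a gene's group-median
log2 expression minus the mean of its group medians within one dataset
(row-centered mode), or minus the healthy-cerebellum median (cerebellum
mode).  Genes are quantile-ranked by their overexpression in the SHH/Shh
group of each dataset, ranks are averaged per species over homolog pairs,
and the human − mouse rank difference orders genes from most human-specific
(+) to most mouse-specific (−).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .expression_io import HomologMap, Species
from .preprocess import GroupMedianTable

Mode = Literal["row_centered", "cerebellum_normalized"]


class RankingError(ValueError):
    pass


@dataclass
class OverexpressionTable:
    """Gene × group table of overexpression values for one dataset."""

    dataset_id: str
    species: Species
    values: pd.DataFrame
    mode: Mode


@dataclass
class RankVector:
    """Quantile ranks in [0, 1] of genes by SHH-group overexpression."""

    dataset_id: str
    species: Species
    target_group: str
    ranks: pd.Series  # index: gene symbol; values in [0, 1]


@dataclass
class ConcordanceResult:
    """OLS fit of one rank vector on another (rank-rank concordance)."""

    r_squared: float
    slope: float
    p_value: float
    n: int


def center_rows(table: GroupMedianTable) -> OverexpressionTable:
    """Subtract each row's mean over groups: the row-centered overexpression.

    Positive values mean the gene's median in that group is higher than in
    the other tumor/tissue groups of the same dataset.
    """
    if table.values.shape[1] < 2:
        raise RankingError("row centering needs ≥2 group columns")
    centered = table.values.sub(table.values.mean(axis=1), axis=0)
    return OverexpressionTable(
        dataset_id=table.dataset_id,
        species=table.species,
        values=centered,
        mode="row_centered",
    )


def cerebellum_normalize(table: GroupMedianTable, control_group: str) -> OverexpressionTable:
    """Subtract the cerebellum-control median from every group column.

    The control column becomes exactly zero for every gene.
    """
    if control_group not in table.values.columns:
        raise RankingError(
            f"{table.dataset_id}: control group {control_group!r} not a column"
        )
    normalized = table.values.sub(table.values[control_group], axis=0)
    return OverexpressionTable(
        dataset_id=table.dataset_id,
        species=table.species,
        values=normalized,
        mode="cerebellum_normalized",
    )


def quantile_ranks_of(values: pd.Series) -> pd.Series:
    """Quantile ranks in [0, 1]: (average rank − 1) / (n − 1), ascending."""
    if len(values) < 2:
        raise RankingError("quantile ranking needs ≥2 genes")
    r = rankdata(values.to_numpy(), method="average")
    return pd.Series((r - 1.0) / (len(values) - 1.0), index=values.index)


def quantile_rank(table: OverexpressionTable, target_group: str) -> RankVector:
    """Rank genes by their overexpression in the target (SHH/Shh) group.

    The gene with the highest overexpression gets rank 1, the lowest 0;
    ties share their average rank.
    """
    if target_group not in table.values.columns:
        raise RankingError(
            f"{table.dataset_id}: target group {target_group!r} not a column"
        )
    ranks = quantile_ranks_of(table.values[target_group])
    return RankVector(
        dataset_id=table.dataset_id,
        species=table.species,
        target_group=target_group,
        ranks=ranks,
    )


def average_ranks_by_species(
    rank_vectors: Sequence[RankVector],
    species: Species,
    homolog_map: HomologMap,
) -> pd.DataFrame:
    """Unweighted mean quantile rank per gene over one species' datasets.

    Gene keys are the homolog-pair canonical (human, uppercase) symbol;
    genes with no resolvable homolog are dropped.  A gene present in only
    some datasets is averaged over those, with the count reported in the
    ``n_datasets`` column.
    """
    vecs = [rv for rv in rank_vectors if rv.species == species]
    if not vecs:
        raise RankingError(f"no rank vectors of species {species!r}")
    columns = {}
    for rv in vecs:
        mapping = homolog_map.canonicalize_index(rv.ranks.index, species)
        s = rv.ranks.loc[list(mapping)].rename(index=mapping)
        s = s[~s.index.duplicated()]
        columns[rv.dataset_id] = s
    frame = pd.DataFrame(columns)
    frame = frame.dropna(how="all")
    out = pd.DataFrame(
        {"mean_rank": frame.mean(axis=1), "n_datasets": frame.notna().sum(axis=1)}
    )
    return out.sort_index()


def rank_difference(
    human_means: pd.DataFrame | pd.Series | Mapping[str, float],
    mouse_means: pd.DataFrame | pd.Series | Mapping[str, float],
    high_cutoff: float = 0.8,
    low_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Human − mouse mean-rank difference with specificity labels.

    Genes with human rank ≥ ``high_cutoff`` and mouse rank ≤ ``low_cutoff``
    are labeled ``human_specific`` (and vice versa for ``mouse_specific``);
    genes extreme in the same direction in both species are ``shared``;
    everything else ``neither``.  Sorted by descending difference.
    """

    def _split(x):
        if isinstance(x, pd.DataFrame):
            return x["mean_rank"], x.get("n_datasets")
        s = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
        return s, None

    h, h_n = _split(human_means)
    m, m_n = _split(mouse_means)
    genes = h.index.intersection(m.index).sort_values()
    if len(genes) == 0:
        raise RankingError("no genes shared between human and mouse rank maps")
    h, m = h.loc[genes], m.loc[genes]
    diff = h - m
    label = pd.Series("neither", index=genes, dtype=object)
    label[(h >= high_cutoff) & (m <= low_cutoff)] = "human_specific"
    label[(m >= high_cutoff) & (h <= low_cutoff)] = "mouse_specific"
    both_high = (h >= high_cutoff) & (m >= high_cutoff)
    both_low = (h <= low_cutoff) & (m <= low_cutoff)
    label[both_high | both_low] = "shared"
    out = pd.DataFrame(
        {
            "human_mean_rank": h,
            "mouse_mean_rank": m,
            "n_human_datasets": h_n.loc[genes] if h_n is not None else np.nan,
            "n_mouse_datasets": m_n.loc[genes] if m_n is not None else np.nan,
            "diff": diff,
            "label": label,
        }
    )
    out.index.name = "gene"
    return out.sort_values("diff", ascending=False, kind="mergesort")


def dataset_correlogram(
    tables: Sequence[OverexpressionTable],
    target_group: str | Mapping[str, str],
    homolog_map: HomologMap,
    on_ranks: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of SHH-group overexpression values.

    Each cell uses the pairwise-complete intersection of (homolog-mapped)
    genes of the two datasets; the per-cell gene counts are returned as a
    second matrix.  With ``on_ranks`` the quantile ranks are correlated
    instead of the raw overexpression values.
    """
    if len(tables) < 2:
        raise RankingError("correlogram needs ≥2 datasets")

    def _target(t: OverexpressionTable) -> str:
        return target_group if isinstance(target_group, str) else target_group[t.dataset_id]

    series = {}
    for t in tables:
        col = _target(t)
        if col not in t.values.columns:
            raise RankingError(f"{t.dataset_id}: target group {col!r} not a column")
        mapping = homolog_map.canonicalize_index(t.values.index, t.species)
        s = t.values[col].loc[list(mapping)].rename(index=mapping)
        s = s[~s.index.duplicated()]
        if on_ranks:
            s = quantile_ranks_of(s)
        series[t.dataset_id] = s

    ids = [t.dataset_id for t in tables]
    corr = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    n = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(ids):
        n.loc[a, a] = len(series[a])
        for b in ids[i + 1 :]:
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < 3:
                raise RankingError(f"datasets {a!r} and {b!r} share <3 genes")
            r = float(np.corrcoef(series[a].loc[shared], series[b].loc[shared])[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
            n.loc[a, b] = n.loc[b, a] = len(shared)
    return corr, n


def rank_concordance(
    rank_a: pd.Series | Mapping[str, float],
    rank_b: pd.Series | Mapping[str, float],
) -> ConcordanceResult:
    """OLS regression of rank_b on rank_a over their shared genes.

    Returns R², the slope, the two-sided p-value for zero slope, and the
    number of genes regressed.
    """
    a = pd.Series(dict(rank_a)) if not isinstance(rank_a, pd.Series) else rank_a
    b = pd.Series(dict(rank_b)) if not isinstance(rank_b, pd.Series) else rank_b
    shared = a.index.intersection(b.index).sort_values()
    if len(shared) < 3:
        raise RankingError("rank concordance needs ≥3 shared genes")
    fit = linregress(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())
    return ConcordanceResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        p_value=float(fit.pvalue),
        n=int(len(shared)),
    )
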