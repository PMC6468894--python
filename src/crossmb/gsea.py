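"""Preranked gene-set enrichment with a permutation family-wise error rate.

Implements the weighted Kolmogorov–Smirnov-style running-sum statistic:
walking a score-ordered gene list top to bottom, members of a set ("hits")
increment the running sum by |score|^weight normalized over the set's hits,
non-members decrement by 1/(N − N_hits); the enrichment score (ES) is the
signed extremum.  The null is built by gene-label permutation: each
permutation reassigns list positions uniformly at random, every set is
re-scored on it, and the family-wise error rate of an observed set is the
fraction of permutations whose most extreme same-sign normalized ES (NES)
over the whole family meets or exceeds the observed NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import GeneSet

logger = logging.getLogger(__name__)


class GseaError(ValueError):
    pass


@dataclass
class RankedList:
    """A descending score-ordered gene list (ties broken by gene symbol)."""

    genes: np.ndarray  # dtype object/str, descending score order
    scores: np.ndarray  # float, aligned with genes

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise GseaError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise GseaError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: pd.Series | Mapping[str, float]) -> "RankedList":
        s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
        if s.index.duplicated().any():
            raise GseaError("duplicate genes in score map")
        frame = pd.DataFrame(
            {"score": s.astype(float).to_numpy(), "gene": s.index.astype(str)}
        )
        frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        return cls(
            genes=frame["gene"].to_numpy(dtype=object),
            scores=frame["score"].to_numpy(dtype=float),
        )

    def reversed(self) -> "RankedList":
        """The same genes with negated scores (re-sorted)."""
        return RankedList.from_scores(pd.Series(-self.scores, index=self.genes))


@dataclass
class GseaResult:
    set_name: str
    set_size_used: int
    es: float
    nes: float
    nominal_p: float
    fwer_p: float
    leading_edge: list[str]
    direction: Literal["positive", "negative"]
    flagged: bool = False  # NES undefined (no same-sign nulls); excluded from FWER


def _es_from_positions(
    scores: np.ndarray, positions: np.ndarray, weight: float
) -> np.ndarray:
    """Signed enrichment scores for hit-position sets (vectorized).

    ``positions`` is an (m, k) array of sorted 0-based hit positions in the
    ranked list; returns m signed ES values.  The running sum attains its
    positive candidates just after each hit and its negative candidates just
    before each hit, so only those 2k values need inspection.
    """
    positions = np.atleast_2d(positions)
    m, k = positions.shape
    n = len(scores)
    if not (0 < k < n):
        raise GseaError(f"set size {k} invalid for list of {n}")
    absw = np.abs(scores) ** weight
    w = absw[positions]  # (m, k)
    cumw = np.cumsum(w, axis=1)
    total = cumw[:, -1:].copy()
    # All-zero hit weights degrade gracefully to unweighted increments.
    zero = total[:, 0] == 0
    if zero.any():
        cumw[zero] = np.arange(1, k + 1, dtype=float)
        total[zero] = float(k)
    miss = 1.0 / (n - k)
    j = np.arange(1, k + 1, dtype=float)
    after = cumw / total - (positions + 1 - j) * miss
    before = (cumw - w) / total - (positions - (j - 1)) * miss
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, the full running sum, and the leading edge for one gene set.

    The leading edge comprises the hit genes at or before the running-sum
    extremum (positive ES) or at or after it (negative ES).
    """
    if weight < 0:
        raise GseaError("weight must be ≥ 0")
    members = {g.upper() for g in gene_set.members}
    hit = np.array([g.upper() in members for g in ranked.genes])
    k = int(hit.sum())
    n = len(ranked)
    if k == 0:
        raise GseaError(f"gene set {gene_set.name!r} shares no genes with the list")
    if k == n:
        raise GseaError(f"gene set {gene_set.name!r} covers the entire list")

    absw = np.abs(ranked.scores) ** weight
    hit_w = np.where(hit, absw, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = hit.astype(float)
        total = float(k)
    increments = hit_w / total - np.where(hit, 0.0, 1.0 / (n - k))
    running = np.cumsum(increments)

    positions = np.flatnonzero(hit)
    es = float(_es_from_positions(ranked.scores, positions[None, :], weight)[0])
    if es >= 0:
        # Extremum is just after some hit; find the hit achieving it.
        peak = positions[np.argmax(running[positions])]
        leading = [str(g) for g in ranked.genes[: peak + 1][hit[: peak + 1]]]
    else:
        trough_candidates = running[positions] - increments[positions]
        first = positions[np.argmin(trough_candidates)]
        leading = [str(g) for g in ranked.genes[first:][hit[first:]]]
    return es, running, leading


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    seed: int,
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES sample from uniformly drawn gene sets of the given size."""
    n = len(ranked)
    if not (0 < set_size < n):
        raise GseaError(f"set size {set_size} invalid for list of {n}")
    if n_perm < 100:
        raise GseaError("n_perm must be ≥ 100")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(keys, set_size, axis=1)[:, :set_size], axis=1)
    return _es_from_positions(ranked.scores, positions, weight)


def _shared_permutation_nulls(
    ranked: RankedList,
    member_positions: Mapping[str, np.ndarray],
    n_perm: int,
    seed: int,
    weight: float,
) -> dict[str, np.ndarray]:
    """Per-set null ES under a single gene-label permutation per iteration.

    One random relabeling of list positions is drawn per permutation and
    every set is scored on it, so the per-permutation maxima used for the
    FWER are coherent across the family.
    """
    n = len(ranked)
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    perm_positions = np.argsort(keys, axis=1)  # gene slot -> random position
    nulls: dict[str, np.ndarray] = {}
    for name, idx in member_positions.items():
        pos = np.sort(perm_positions[:, idx], axis=1)
        nulls[name] = _es_from_positions(ranked.scores, pos, weight)
    return nulls


def normalize_and_fwer(
    observed: Sequence[tuple[GeneSet, float, list[str]]],
    nulls: Mapping[str, np.ndarray],
    n_perm: int,
) -> list[GseaResult]:
    """Normalize ES to NES and attach nominal and family-wise p-values.

    NES divides each ES by the mean magnitude of its set's same-sign null
    ES.  The nominal p is the same-sign null tail fraction.  The FWER p of
    a set is the fraction of permutations whose most extreme same-sign NES
    over the whole family meets or exceeds the set's observed NES.  Sets
    with no same-sign null values are flagged and excluded from the family.
    """
    stats = []
    for gs, es, leading in observed:
        null = np.asarray(nulls[gs.name], dtype=float)
        if len(null) != n_perm:
            raise GseaError(f"null sample for {gs.name!r} has wrong length")
        same = null[null > 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            stats.append((gs, es, leading, np.nan, np.nan, None))
            continue
        denom = float(np.abs(same).mean())
        nes = es / denom
        nominal = float((np.abs(same) >= abs(es)).sum()) / len(same)
        stats.append((gs, es, leading, nes, nominal, denom))

    # Null NES matrices per direction over the unflagged family.  A
    # permutation with no same-sign ES anywhere in the family cannot attain
    # the observed NES and is excluded from the denominator; for a family
    # of one this makes the FWER p equal the nominal p on the NES scale.
    pos_cols, neg_cols = [], []
    for gs, es, leading, nes, nominal, denom in stats:
        if denom is None:
            continue
        null = np.asarray(nulls[gs.name], dtype=float)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore"):
            pos_cols.append(np.where(null > 0, null / pos_mean, -np.inf))
            neg_cols.append(np.where(null < 0, null / neg_mean, np.inf))
    if pos_cols:
        max_pos = np.max(np.column_stack(pos_cols), axis=1)
        max_pos = max_pos[np.isfinite(max_pos)]
    else:
        max_pos = np.array([])
    if neg_cols:
        min_neg = np.min(np.column_stack(neg_cols), axis=1)
        min_neg = min_neg[np.isfinite(min_neg)]
    else:
        min_neg = np.array([])

    results = []
    for gs, es, leading, nes, nominal, denom in stats:
        if denom is None:
            results.append(
                GseaResult(
                    set_name=gs.name,
                    set_size_used=len(leading) if leading else 0,
                    es=es,
                    nes=float("nan"),
                    nominal_p=float("nan"),
                    fwer_p=float("nan"),
                    leading_edge=list(leading),
                    direction="positive" if es >= 0 else "negative",
                    flagged=True,
                )
            )
            logger.warning("gene set %s: no same-sign nulls; NES undefined", gs.name)
            continue
        if es >= 0:
            fwer = float((max_pos >= nes).mean()) if len(max_pos) else float("nan")
        else:
            fwer = float((min_neg <= nes).mean()) if len(min_neg) else float("nan")
        results.append(
            GseaResult(
                set_name=gs.name,
                set_size_used=0,  # filled by run_gsea; standalone callers may ignore
                es=float(es),
                nes=float(nes),
                nominal_p=nominal,
                fwer_p=fwer,
                leading_edge=list(leading),
                direction="positive" if es >= 0 else "negative",
            )
        )
    return results


def run_gsea(
    ranked: RankedList,
    sets: Sequence[GeneSet],
    min_size: int = 15,
    max_size: int = 500,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Score every size-eligible gene set against the ranked list.

    Sets are filtered to ``min_size ≤ |set ∩ list| ≤ max_size``, scored,
    normalized against a shared gene-label-permutation null, and returned
    sorted by FWER then descending |NES| (name as final tie-break).
    """
    gene_pos = {str(g).upper(): i for i, g in enumerate(ranked.genes)}
    surviving: list[tuple[GeneSet, np.ndarray]] = []
    for gs in sets:
        idx = np.array(
            sorted(gene_pos[m] for m in {x.upper() for x in gs.members} if m in gene_pos),
            dtype=int,
        )
        if min_size <= len(idx) <= max_size and len(idx) < len(ranked):
            surviving.append((gs, idx))
        else:
            logger.info("gene set %s: size %d outside [%d, %d], skipped",
                        gs.name, len(idx), min_size, max_size)
    if not surviving:
        raise GseaError("no gene sets survive the size filters")

    observed = []
    sizes = {}
    for gs, idx in surviving:
        es, _, leading = enrichment_score(ranked, gs, weight)
        observed.append((gs, es, leading))
        sizes[gs.name] = len(idx)

    nulls = _shared_permutation_nulls(
        ranked, {gs.name: idx for gs, idx in surviving}, n_perm, seed, weight
    )
    results = normalize_and_fwer(observed, nulls, n_perm)
    for r in results:
        r.set_size_used = sizes[r.set_name]
    results.sort(key=lambda r: (r.fwer_p if np.isfinite(r.fwer_p) else 2.0,
                                -abs(r.nes) if np.isfinite(r.nes) else 0.0,
                                r.set_name))
    return results


def gsea_results_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    """Tabular view sorted by FWER then |NES| (mirrors the report layout)."""
    rows = [
        {
            "set_name": r.set_name,
            "set_size_used": r.set_size_used,
            "es": r.es,
            "nes": r.nes,
            "nominal_p": r.nominal_p,
            "fwer_p": r.fwer_p,
            "direction": r.direction,
            "leading_edge_size": len(r.leading_edge),
            "leading_edge": ",".join(r.leading_edge[:25]),
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["fwer_p", "nes", "set_name"],
        ascending=[True, False, True],
        key=lambda col: col.abs() if col.name == "nes" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return frame.set_index("set_name")
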