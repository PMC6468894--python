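"""Readers, writers and validated containers for the pipeline's external formats.

The pipeline consumes plain tab-separated expression matrices (features in
rows, samples in columns, log2 scale), two-column sample→group annotation
tables, Broad-dialect GMT gene-set collections, and an optional two-column
mouse↔human homolog symbol map.  Everything is validated on ingestion so the
downstream ranking stages can assume clean, complete data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Species = Literal["human", "mouse"]
FeatureLevel = Literal["probeset", "gene"]

#: Matrices whose maximum exceeds this are assumed to be on a linear
#: intensity scale and are log2(x+1)-transformed.  Log2 microarray values
#: rarely exceed ~16; linear intensities always do.
DEFAULT_LOG_THRESHOLD = 50.0


class ExpressionIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class ExpressionDataset:
    """A single expression dataset: log2 matrix plus sample grouping.

    Parameters
    ----------
    dataset_id
        Short identifier (e.g. a GEO-style accession or a synthetic tag).
    species
        ``"human"`` or ``"mouse"``.
    matrix
        Log2 expression values; rows are feature ids (probesets or gene
        symbols), columns are sample ids.
    feature_level
        ``"probeset"`` or ``"gene"``.
    sample_groups
        Map sample id → group label (e.g. ``"SHH"``, ``"Group3"``,
        ``"cerebellum"``).  Every matrix column must be covered.
    probe_annotation
        Probeset id → gene symbol map; only for probeset-level data.  An
        empty-string symbol marks an unannotated probeset.
    """

    dataset_id: str
    species: Species
    matrix: pd.DataFrame
    feature_level: FeatureLevel = "probeset"
    sample_groups: dict[str, str] = field(default_factory=dict)
    probe_annotation: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ExpressionIOError(f"unknown species {self.species!r}")
        if self.feature_level not in ("probeset", "gene"):
            raise ExpressionIOError(f"unknown feature level {self.feature_level!r}")
        if self.matrix.shape[0] == 0 or self.matrix.shape[1] == 0:
            raise ExpressionIOError(f"{self.dataset_id}: empty expression matrix")
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"{self.dataset_id}: duplicate feature ids {dupes[:5]}")
        if self.matrix.columns.duplicated().any():
            dupes = self.matrix.columns[self.matrix.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"{self.dataset_id}: duplicate sample ids {dupes[:5]}")
        missing = [s for s in self.matrix.columns if s not in self.sample_groups]
        if missing:
            raise ExpressionIOError(
                f"{self.dataset_id}: samples without group annotation: {missing}"
            )
        if self.feature_level == "gene" and self.probe_annotation is not None:
            raise ExpressionIOError(
                f"{self.dataset_id}: gene-level data must not carry a probe annotation"
            )
        if self.matrix.isna().any().any():
            raise ExpressionIOError(f"{self.dataset_id}: matrix contains missing values")

    @property
    def groups(self) -> pd.Series:
        """Group label per matrix column, in column order."""
        return pd.Series(
            [self.sample_groups[s] for s in self.matrix.columns],
            index=self.matrix.columns,
            name="group",
        )

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels, sorted for determinism."""
        return sorted(set(self.groups))


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ExpressionIOError(f"gene set {self.name!r} has no members")


@dataclass
class HomologMap:
    """Resolved one-to-one mouse↔human gene symbol correspondence.

    The canonical key for a homolog pair is the human (uppercase) symbol.
    Mouse symbols are stored as given but matched case-insensitively, per
    the Gpr153/GPR153 naming convention.
    """

    pairs: list[tuple[str, str]]  # (mouse symbol, human symbol)
    resolution: Literal["one_to_one_only", "max_mean_tiebreak"] = "one_to_one_only"

    def __post_init__(self) -> None:
        self._mouse_to_human = {m.lower(): h for m, h in self.pairs}
        self._human_to_mouse = {h.upper(): m for m, h in self.pairs}
        if len(self._mouse_to_human) != len(self.pairs) or len(
            self._human_to_mouse
        ) != len(self.pairs):
            raise ExpressionIOError("homolog map is not one-to-one after resolution")

    def __len__(self) -> int:
        return len(self.pairs)

    def canonical(self, symbol: str, species: Species) -> str | None:
        """Canonical (human, uppercase) symbol for ``symbol``, or None if unmapped."""
        if species == "human":
            s = symbol.upper()
            return s if s in self._human_to_mouse else None
        h = self._mouse_to_human.get(symbol.lower())
        return h.upper() if h is not None else None

    def canonicalize_index(self, symbols: Iterable[str], species: Species) -> dict[str, str]:
        """Map each resolvable symbol to its canonical form (unmapped dropped)."""
        out: dict[str, str] = {}
        for s in symbols:
            c = self.canonical(s, species)
            if c is not None:
                out[s] = c
        return out

    @classmethod
    def from_case_convention(
        cls, mouse_symbols: Iterable[str], human_symbols: Iterable[str]
    ) -> "HomologMap":
        """Pair symbols whose case-insensitive spellings agree (Gli1 ↔ GLI1)."""
        human_by_upper = {h.upper(): h for h in human_symbols}
        pairs = []
        for m in sorted(set(mouse_symbols)):
            h = human_by_upper.get(m.upper())
            if h is not None:
                pairs.append((m, h.upper()))
        return cls(pairs=pairs)


def read_expression_matrix(
    path: str | Path,
    annotation_path: str | Path,
    dataset_id: str,
    species: Species,
    feature_level: FeatureLevel = "probeset",
    probe_annotation: Mapping[str, str] | None = None,
    log_threshold: float = DEFAULT_LOG_THRESHOLD,
) -> ExpressionDataset:
    """Read a features×samples TSV and its sample→group annotation.

    Values detected as linear-scale (matrix maximum above ``log_threshold``)
    are log2(x+1)-transformed.  Rows with any missing value are dropped and
    the count is logged.  Samples missing from the annotation are a hard
    error.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ExpressionIOError(f"{dataset_id}: empty expression matrix in {path}")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ExpressionIOError(f"{dataset_id}: duplicate feature ids {dupes[:5]}")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    n_before = matrix.shape[0]
    matrix = matrix.dropna(axis=0, how="any")
    n_dropped = n_before - matrix.shape[0]
    if n_dropped:
        logger.info("%s: dropped %d rows with missing values", dataset_id, n_dropped)
    if matrix.shape[0] == 0:
        raise ExpressionIOError(f"{dataset_id}: no complete rows after NA filtering")

    if float(matrix.to_numpy().max()) > log_threshold:
        logger.info("%s: values look linear-scale; applying log2(x+1)", dataset_id)
        matrix = np.log2(matrix + 1.0)

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise ExpressionIOError(f"annotation {annotation_path} needs ≥2 columns")
    sample_groups = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    missing = [s for s in matrix.columns if s not in sample_groups]
    if missing:
        raise ExpressionIOError(
            f"{dataset_id}: samples absent from annotation: {missing}"
        )
    sample_groups = {s: sample_groups[s] for s in matrix.columns}

    return ExpressionDataset(
        dataset_id=dataset_id,
        species=species,
        matrix=matrix,
        feature_level=feature_level,
        sample_groups=sample_groups,
        probe_annotation=dict(probe_annotation) if probe_annotation is not None else None,
    )


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write the matrix (6-decimal TSV) and annotation so a read round-trips."""
    dataset.matrix.to_csv(matrix_path, sep="\t", float_format="%.6f", index_label="feature_id")
    ann = pd.DataFrame(
        {"sample_id": list(dataset.matrix.columns),
         "group": [dataset.sample_groups[s] for s in dataset.matrix.columns]}
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a Broad-dialect GMT file: name TAB description TAB member...

    Member symbols are uppercased and deduplicated within each set.
    Duplicate set names or lines with fewer than three fields are errors.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionIOError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need ≥3"
                )
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ExpressionIOError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            members = frozenset(m.upper() for m in fields[2:] if m)
            sets.append(GeneSet(name=name, description=desc, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format, members sorted for determinism."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_homolog_map(
    path: str | Path | None,
    resolution: Literal["one_to_one_only", "max_mean_tiebreak"] = "one_to_one_only",
    mean_expression: Mapping[str, float] | None = None,
) -> HomologMap | None:
    """Read a two-column (mouse, human) symbol map and resolve ambiguities.

    With ``one_to_one_only`` (default) any symbol participating in more than
    one pair is dropped and the count logged.  ``max_mean_tiebreak`` keeps,
    per ambiguous symbol, the partner with the highest supplied mean
    expression (lexicographically smallest partner when no means are given).
    Returns None when ``path`` is None (caller builds a case-convention map
    downstream).
    """
    if path is None:
        return None
    raw_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ExpressionIOError(f"{path}:{lineno}: malformed homolog-map line")
            raw_pairs.append((fields[0], fields[1].upper()))
    return resolve_homolog_pairs(raw_pairs, resolution, mean_expression)


def resolve_homolog_pairs(
    raw_pairs: Sequence[tuple[str, str]],
    resolution: Literal["one_to_one_only", "max_mean_tiebreak"] = "one_to_one_only",
    mean_expression: Mapping[str, float] | None = None,
) -> HomologMap:
    raw_pairs = sorted(set((m, h.upper()) for m, h in raw_pairs))
    mouse_count: dict[str, int] = {}
    human_count: dict[str, int] = {}
    for m, h in raw_pairs:
        mouse_count[m.lower()] = mouse_count.get(m.lower(), 0) + 1
        human_count[h] = human_count.get(h, 0) + 1

    if resolution == "one_to_one_only":
        pairs = [
            (m, h)
            for m, h in raw_pairs
            if mouse_count[m.lower()] == 1 and human_count[h] == 1
        ]
        n_dropped = len(raw_pairs) - len(pairs)
        if n_dropped:
            logger.info("homolog map: dropped %d ambiguous pairs", n_dropped)
    elif resolution == "max_mean_tiebreak":
        means = mean_expression or {}

        def score(pair: tuple[str, str]) -> float:
            m, h = pair
            return max(means.get(m, -math.inf), means.get(h, -math.inf))

        pairs = []
        used_mouse: set[str] = set()
        used_human: set[str] = set()
        # Highest-mean pairs claim their symbols first; lexicographic fallback.
        for m, h in sorted(raw_pairs, key=lambda p: (-score(p), p[0], p[1])):
            if m.lower() in used_mouse or h in used_human:
                continue
            used_mouse.add(m.lower())
            used_human.add(h)
            pairs.append((m, h))
        pairs.sort()
    else:
        raise ExpressionIOError(f"unknown resolution policy {resolution!r}")
    return HomologMap(pairs=pairs, resolution=resolution)


def write_results(table, path: str | Path) -> None:
    """Write a result table as TSV with a deterministic row order.

    Dispatches on table kind: a list of GSEA results is sorted by FWER then
    descending |NES|; a rank-difference table by descending diff; any other
    DataFrame keeps its (already deterministic) order.  Empty tables are an
    error.
    """
    from .gsea import GseaResult, gsea_results_frame  # local import: avoid cycle

    if isinstance(table, (list, tuple)):
        if len(table) == 0:
            raise ExpressionIOError("refusing to write an empty result table")
        if all(isinstance(t, GseaResult) for t in table):
            frame = gsea_results_frame(list(table))
        else:
            frame = pd.DataFrame(table)
    elif isinstance(table, pd.Series):
        frame = table.to_frame()
    elif isinstance(table, pd.DataFrame):
        frame = table
        if "diff" in frame.columns:
            frame = frame.sort_values(
                "diff", ascending=False, kind="mergesort"
            )
    else:
        raise ExpressionIOError(f"cannot write table of type {type(table)!r}")
    if frame.shape[0] == 0:
        raise ExpressionIOError("refusing to write an empty result table")
    frame.to_csv(path, sep="\t", float_format="%.6g", index=True)
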