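"""Readers and writers for every file format the pipeline touches.

Formats: expression TSV (genes in rows, sample-id header), GEO Series Matrix
text, STRING-dialect interaction edge lists, GMT gene-set collections,
two-column sample-label TSV, and JSON lineage scorecards.

Readers reject silently-corrupt input (non-numeric cells, missing delimiters,
short lines) with located errors instead of coercing. Gene symbols are
matched case-insensitively and stored uppercased, because microarray
annotations mix cases.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortLabels, VALID_GROUPS
from .errors import DataFormatError
from .scoring import LineageScoreCard

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_series_matrix",
    "collapse_probes",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "GeneSet",
    "GeneSetCollection",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_scorecards_json",
    "read_scorecards_json",
]

_FLOAT_FMT = "%.12g"  # round-trips to 12 significant digits


# ---------------------------------------------------------------- expression


def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()  # covers both unparsable cells and literal NA
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric or missing value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not np.isfinite(out.to_numpy()).all():
        r, c = np.argwhere(~np.isfinite(out.to_numpy()))[0]
        raise DataFormatError(
            f"{path}: non-finite value at row {out.index[r]!r}, "
            f"column {out.columns[c]!r}"
        )
    return out.astype(float)


def read_expression_tsv(
    path: str | Path,
    collapse: Literal["max_mean", "error"] = "max_mean",
) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene symbols).

    Duplicate gene symbols are collapsed by keeping the row with the maximal
    mean across samples (``collapse="max_mean"``), or rejected
    (``collapse="error"``). Symbols are uppercased.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise DataFormatError(f"{path}: no expression columns/rows found")
    raw.index = raw.index.astype(str).str.upper()
    df = _validate_numeric(raw, str(path))
    if df.index.has_duplicates:
        if collapse == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataFormatError(f"{path}: duplicated gene symbols {dups}")
        df = _collapse_max_mean(df)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicated sample ids {dups}")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(Path(path), sep="\t", float_format=_FLOAT_FMT)


def _collapse_max_mean(df: pd.DataFrame) -> pd.DataFrame:
    """One row per symbol: the row with the largest mean across samples."""
    means = df.mean(axis=1).to_numpy()
    keep: dict[str, int] = {}
    for i, sym in enumerate(df.index):
        j = keep.get(sym)
        if j is None or means[i] > means[j]:
            keep[sym] = i
    return df.iloc[sorted(keep.values())]


# ------------------------------------------------------------- series matrix


def read_series_matrix(
    path: str | Path,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse the expression table of a GEO Series Matrix text file.

    Returns the probe x sample matrix (probe ids uppercased, quotes
    stripped) and a sample-id -> title mapping for downstream group-label
    assignment (group labels themselves are never guessed here).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    accessions: list[str] = []
    titles: list[str] = []
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!Sample_geo_accession"):
            accessions = [_unquote(x) for x in line.split("\t")[1:]]
        elif line.startswith("!Sample_title"):
            titles = [_unquote(x) for x in line.split("\t")[1:]]
        elif line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin + 1:
        raise DataFormatError(
            f"{path}: missing !series_matrix_table_begin/_end delimiters"
        )
    header = [_unquote(x) for x in lines[begin + 1].split("\t")]
    ncol = len(header)
    records = []
    index = []
    for ln, line in enumerate(lines[begin + 2 : end], start=begin + 3):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise DataFormatError(
                f"{path}:{ln}: expected {ncol} fields, found {len(fields)}"
            )
        index.append(_unquote(fields[0]).upper())
        records.append([_unquote(x) for x in fields[1:]])
    sample_ids = accessions if accessions else header[1:]
    if len(sample_ids) != ncol - 1:
        raise DataFormatError(
            f"{path}: {len(sample_ids)} sample accessions for "
            f"{ncol - 1} table columns"
        )
    raw = pd.DataFrame(records, index=index, columns=sample_ids)
    df = _validate_numeric(raw, str(path))
    title_map = dict(zip(sample_ids, titles)) if titles else {}
    return df, title_map


def _unquote(s: str) -> str:
    return s.strip().strip('"')


def collapse_probes(
    expr: pd.DataFrame,
    mapping: Mapping[str, str],
    unmapped: Literal["drop", "keep"] = "drop",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene symbols.

    ``mapping`` maps probe id -> gene symbol (case-insensitive on both
    sides). For each symbol the probe with the maximal mean across samples
    is retained. Probes absent from the mapping are dropped or kept under
    their probe id per ``unmapped``.
    """
    if not mapping and expr.index.has_duplicates:
        raise DataFormatError(
            "empty probe mapping but duplicate row ids present"
        )
    up = {str(k).upper(): str(v).upper() for k, v in mapping.items()}
    new_index = []
    keep_rows = []
    for i, probe in enumerate(expr.index.astype(str).str.upper()):
        if probe in up:
            new_index.append(up[probe])
            keep_rows.append(i)
        elif unmapped == "keep":
            new_index.append(probe)
            keep_rows.append(i)
    out = expr.iloc[keep_rows].copy()
    out.index = new_index
    return _collapse_max_mean(out)


# ---------------------------------------------------------------- edge lists


def read_edge_list(
    path: str | Path,
    score_dialect: Literal["string", "unit"] = "string",
    node_cols: tuple[int, int] = (0, 1),
    score_col: int = 2,
    header: bool | None = None,
) -> list[tuple[str, str, float]]:
    """Read a STRING-dialect interaction edge list.

    ``score_dialect="string"`` expects combined scores on the 0-1000 scale
    and divides by 1000; ``"unit"`` expects scores already in [0, 1].
    Duplicate undirected pairs keep the maximal confidence; self-pairs are
    dropped. Node symbols are uppercased. ``header`` forces or forbids a
    header line; by default a first line with a non-numeric score field is
    treated as a header.
    """
    path = Path(path)
    edges: dict[frozenset[str], tuple[str, str, float]] = {}
    lines = [
        line for line in path.read_text().splitlines() if line.strip()
    ]
    if not lines:
        raise DataFormatError(f"{path}: empty edge list")
    start = 0
    first = re.split(r"[\t ]+", lines[0].strip())
    if header is True:
        start = 1
    elif header is None:
        try:
            float(first[score_col])
        except (ValueError, IndexError):
            start = 1
    hi = 1000.0 if score_dialect == "string" else 1.0
    for ln, line in enumerate(lines[start:], start=start + 1):
        fields = re.split(r"[\t ]+", line.strip())
        needed = max(*node_cols, score_col)
        if len(fields) <= needed:
            raise DataFormatError(
                f"{path}:{ln}: expected >= {needed + 1} fields, "
                f"found {len(fields)}"
            )
        a = fields[node_cols[0]].upper()
        b = fields[node_cols[1]].upper()
        try:
            score = float(fields[score_col])
        except ValueError as exc:
            raise DataFormatError(
                f"{path}:{ln}: non-numeric score {fields[score_col]!r}"
            ) from exc
        if not 0 <= score <= hi:
            raise DataFormatError(
                f"{path}:{ln}: score {score} outside [0, {hi:g}] for "
                f"dialect {score_dialect!r}"
            )
        conf = score / hi
        if a == b:
            continue
        key = frozenset((a, b))
        prev = edges.get(key)
        if prev is None or conf > prev[2]:
            edges[key] = (min(a, b), max(a, b), conf)
    return sorted(edges.values())


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b, conf in edges:
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % conf}\n")


# ----------------------------------------------------------------- gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


class GeneSetCollection:
    """Named gene sets parsed from GMT; names unique, sets non-empty."""

    def __init__(self, sets: Sequence[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise DataFormatError(f"duplicate gene-set name {gs.name!r}")
            if not gs.genes:
                raise DataFormatError(f"gene set {gs.name!r} is empty")
            self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    sets = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataFormatError(
                f"{path}:{ln}: GMT line needs >= 3 tab-separated fields"
            )
        genes = frozenset(g.upper() for g in fields[2:] if g.strip())
        if not genes:
            raise DataFormatError(f"{path}:{ln}: gene set with no genes")
        sets.append(GeneSet(fields[0], fields[1], genes))
    if not sets:
        raise DataFormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


# -------------------------------------------------------------------- labels


def read_labels_tsv(path: str | Path) -> CohortLabels:
    """Two- or three-column TSV: sample_id, group[, subtype]."""
    path = Path(path)
    assignment: dict[str, str] = {}
    subtype: dict[str, str] = {}
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise DataFormatError(f"{path}: empty label file")
    start = 0
    first = lines[0].split("\t")
    if len(first) >= 2 and first[1].strip().lower() in ("group", "label"):
        start = 1  # header line
    if not lines[start:]:
        raise DataFormatError(f"{path}: no label rows")
    for ln, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataFormatError(
                f"{path}:{ln}: expected >= 2 tab-separated fields"
            )
        sid = fields[0].strip()
        group = fields[1].strip().upper()
        if sid in assignment:
            raise DataFormatError(f"{path}:{ln}: duplicate sample {sid!r}")
        if group not in VALID_GROUPS:
            raise DataFormatError(
                f"{path}:{ln}: group {group!r} not in {VALID_GROUPS}"
            )
        assignment[sid] = group
        if len(fields) >= 3 and fields[2].strip():
            subtype[sid] = fields[2].strip()
    return CohortLabels(assignment=assignment, subtype=subtype)


def write_labels_tsv(labels: CohortLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, group in labels.assignment.items():
            fh.write(f"{sid}\t{group}\n")


# ---------------------------------------------------------------- scorecards


def write_scorecards_json(
    cards: Sequence[LineageScoreCard], path: str | Path
) -> None:
    """Serialize scorecards as a JSON array (lossless round-trip)."""
    if not cards:
        raise DataFormatError("refusing to write an empty scorecard list")
    payload = [card.to_dict() for card in cards]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_scorecards_json(path: str | Path) -> list[LineageScoreCard]:
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list) or not payload:
        raise DataFormatError(f"{path}: expected a non-empty JSON array")
    cards = [LineageScoreCard.from_dict(d) for d in payload]
    for card in cards:
        for k, v in card.scores.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise DataFormatError(
                    f"{path}: non-finite score {v!r} for {card.sample_id}/{k}"
                )
    return cards
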