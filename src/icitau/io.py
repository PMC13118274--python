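"""Readers and writers for the plain-text formats the tool consumes.

Abundance matrices are TSV (canonical) or CSV (sniffed) tables with the
first column holding feature ids and the header row holding sample ids;
features are rows, samples are columns (a ``transpose`` flag covers the
other orientation).  Missingness encodings are configurable — empty
string, "NA", "NaN" by default — and exact zeros can optionally be treated
as missing, since deposited datasets use either convention.  Groups are
two-column TSVs (sample_id, group); annotations are GMT-style lines
(id, description, then tab-separated feature ids).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, CorrelationMatrixSet, correlation_long_format

__all__ = [
    "DEFAULT_MISSING",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_groups",
    "read_gmt",
    "write_long_format",
]

DEFAULT_MISSING = ("", "NA", "NaN")


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_abundance_matrix(
    path: str | Path,
    missing_encodings: Iterable[str] = DEFAULT_MISSING,
    zero_as_missing: bool = False,
    transpose: bool = False,
) -> AbundanceMatrix:
    """Read a feature x sample abundance table with explicit missingness.

    Cells matching one of ``missing_encodings`` become masked; any other
    non-numeric cell is a parse error naming its row and column.  With
    ``zero_as_missing`` exact zeros are masked too.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dup}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    encodings = set(missing_encodings)
    values = np.zeros(raw.shape)
    mask = np.zeros(raw.shape, dtype=bool)
    for i, (fid, row) in enumerate(raw.iterrows()):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell in encodings:
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {fid!r}, column {raw.columns[j]!r}"
                ) from None
    if zero_as_missing:
        mask |= (values == 0.0) & ~mask
        values[mask] = 0.0
    matrix = AbundanceMatrix(
        values=values,
        missing_mask=mask,
        feature_ids=tuple(str(i) for i in raw.index),
        sample_ids=tuple(str(c) for c in raw.columns),
    )
    if transpose:
        matrix = AbundanceMatrix(
            values=matrix.values.T,
            missing_mask=matrix.missing_mask.T,
            feature_ids=matrix.sample_ids,
            sample_ids=matrix.feature_ids,
        )
    return matrix


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a TSV with missing cells as empty strings (round-trip lossless)."""
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(Path(path), sep="\t", na_rep="", float_format=None)


def read_groups(path: str | Path, matrix: AbundanceMatrix | None = None) -> dict[str, str]:
    """Read a (sample_id, group) table; validate against a matrix if given."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("groups file needs two columns: sample_id, group")
    sample_col, group_col = df.columns[:2]
    groups: dict[str, str] = {}
    for _, row in df.iterrows():
        sid, label = str(row[sample_col]), str(row[group_col])
        if label == "":
            raise ValueError(f"empty group label for sample {sid!r}")
        if sid in groups:
            raise ValueError(f"duplicate sample id {sid!r} in groups file")
        groups[sid] = label
    if matrix is not None:
        unknown = [s for s in groups if s not in matrix.sample_ids]
        if unknown:
            raise ValueError(f"group samples absent from the matrix: {unknown}")
        unlabeled = [s for s in matrix.sample_ids if s not in groups]
        if unlabeled:
            raise ValueError(f"matrix samples without a group: {unlabeled}")
    return groups


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read GMT-style annotation sets: id <tab> description <tab> features..."""
    out: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: need id, description and >=1 feature")
        name = parts[0]
        if name in out:
            raise ValueError(f"GMT line {lineno}: duplicate annotation id {name!r}")
        features = frozenset(p for p in parts[2:] if p)
        if not features:
            raise ValueError(f"GMT line {lineno}: empty feature set")
        out[name] = features
    if not out:
        raise ValueError("GMT file contains no annotation sets")
    return out


def write_long_format(
    corr_set: CorrelationMatrixSet, path: str | Path, include_diagonal: bool = False
) -> None:
    """Write the long-format correlation table as TSV."""
    correlation_long_format(corr_set, include_diagonal=include_diagonal).to_csv(
        Path(path), sep="\t", index=False
    )
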