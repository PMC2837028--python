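"""File I/O: tab-delimited expression matrices and sample label files."""

from __future__ import annotations

import csv
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .permutation import PilotDataset

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "load_pilot",
]


def read_expression_matrix(path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read a genes x samples matrix from tab-delimited text.

    Expected layout: a header row of sample names; each subsequent row a
    gene identifier followed by one numeric value per sample.  Errors
    name the offending row/column: ragged rows, duplicate gene ids and
    non-numeric cells are all rejected.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise DataError(f"{path}: expected a header row with at least one sample column")
    sample_ids = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    gene_ids: List[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)))
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise DataError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {width}"
            )
        gene_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:], start=1):
            try:
                data[i - 1, j - 1] = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                ) from None
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"{path}: duplicate gene identifiers: {dupes[:5]}")
    return data, gene_ids, sample_ids


def write_expression_matrix(path, matrix: np.ndarray, gene_ids: Sequence[str],
                            sample_ids: Sequence[str]) -> None:
    """Write a genes x samples matrix as tab-delimited text (lossless)."""
    df = pd.DataFrame(np.asarray(matrix), index=list(gene_ids), columns=list(sample_ids))
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_labels(path, sample_ids: Sequence[str]) -> List[str]:
    """Read a two-column sample -> group file; return groups in matrix order.

    Exactly two distinct groups are required and every matrix sample
    must be labeled exactly once.
    """
    mapping = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise DataError(f"{path}: line {i} must have exactly two tab-separated fields")
            sample, group = row[0].strip(), row[1].strip()
            if sample in mapping:
                raise DataError(f"{path}: sample {sample!r} labeled more than once")
            mapping[sample] = group
    unknown = sorted(set(mapping) - set(sample_ids))
    if unknown:
        raise DataError(f"{path}: unknown sample(s) not in the matrix: {unknown[:5]}")
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise DataError(f"{path}: matrix sample(s) without a label: {missing[:5]}")
    groups = sorted(set(mapping.values()))
    if len(groups) != 2:
        raise DataError(f"{path}: exactly two groups required, found {groups}")
    return [mapping[s] for s in sample_ids]


def load_pilot(matrix_path, labels_path, drop_degenerate: bool = False) -> PilotDataset:
    """Load a pilot dataset from a matrix file and a label file."""
    values, gene_ids, sample_ids = read_expression_matrix(matrix_path)
    labels = read_labels(labels_path, sample_ids)
    return PilotDataset(values=values, gene_ids=gene_ids, group_labels=labels,
                        drop_degenerate=drop_degenerate)
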