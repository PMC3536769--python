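"""Readers and writers: connectivity matrices, subject tables, node-value tables.

All on-disk formats are delimited text.  A matrix file is a square numeric
table, optionally with a header row and an index column of node labels; the
loader validates symmetry to 1e-8 and zeroes any nonzero diagonal with a
logged notice.  A subject table is a CSV with columns ``subject_id``,
``group``, optional ``covariate`` and optional ``matrix_path``.  A node-value
table is a CSV with subjects as rows (index column) and nodes as columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityError,
    ConnectivityMatrix,
    StudyDataset,
    Subject,
)

logger = logging.getLogger("netperm")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def save_matrix(matrix: ConnectivityMatrix, path, delimiter: str | None = None) -> None:
    """Write a labeled square matrix as delimited text (header + index labels)."""
    path = Path(path)
    sep = delimiter or _delimiter_for(path)
    df = pd.DataFrame(matrix.weights, index=matrix.node_labels, columns=matrix.node_labels)
    df.to_csv(path, sep=sep)


def _coerce_numeric(df: pd.DataFrame, path: Path) -> np.ndarray:
    """Float conversion with row/column coordinates on failure."""
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ConnectivityError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, column {col!r}: "
                    f"{df[col].iloc[i]!r}"
                ) from None
        raise


def load_matrix(path, kind: str = "correlation", delimiter: str | None = None) -> ConnectivityMatrix:
    """Load a square symmetric matrix from delimited text.

    A header row / index column of node labels is detected automatically
    (first cell of the first line non-numeric); without labels, nodes are
    named ``n000, n001, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    sep = delimiter or _delimiter_for(path)
    with open(path) as fh:
        first = fh.readline()
    cells = first.rstrip("\n").split(sep)
    try:
        float(cells[-1])
        labeled = False
    except ValueError:
        labeled = True
    if labeled:
        df = pd.read_csv(path, sep=sep, index_col=0)
        labels = tuple(str(c) for c in df.columns)
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        labels = tuple(f"n{i:03d}" for i in range(df.shape[1]))
    w = _coerce_numeric(df, path)
    if w.shape[0] != w.shape[1]:
        raise ConnectivityError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, not square")
    if np.any(np.diagonal(w) != 0.0):
        logger.info("%s: nonzero diagonal zeroed (self-connections excluded)", path)
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    try:
        return ConnectivityMatrix(w, labels, kind=kind)
    except ConnectivityError as exc:
        raise ConnectivityError(f"{path}: {exc}") from None


def load_subject_table(path) -> pd.DataFrame:
    """Subject table CSV -> validated DataFrame (subject_id, group, ...)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ConnectivityError(f"{path}: missing required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ConnectivityError(f"{path}: duplicate subjects: {sorted(dup.tolist())}")
    return df


def load_node_values(path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Node-value CSV (rows=subjects, columns=nodes) -> (subject_ids, node_labels, array)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    x = _coerce_numeric(df, path)
    return (
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
        x,
    )


def load_study(
    subject_table,
    node_values: str | Path | None = None,
    matrix_root: str | Path | None = None,
) -> StudyDataset:
    """Assemble a validated :class:`StudyDataset` from files.

    Either ``node_values`` (node-value table path) or per-subject matrix
    files referenced by the subject table's ``matrix_path`` column (relative
    paths resolved against ``matrix_root``, default: the table's directory).
    """
    table_path = Path(subject_table)
    table = load_subject_table(table_path)
    subjects = tuple(
        Subject(
            subject_id=str(r.subject_id),
            group=str(r.group),
            covariate=float(r.covariate) if "covariate" in table.columns and pd.notna(r.covariate) else None,
        )
        for r in table.itertuples()
    )
    if node_values is not None:
        ids, labels, x = load_node_values(node_values)
        pos = {s: i for i, s in enumerate(ids)}
        missing = [s.subject_id for s in subjects if s.subject_id not in pos]
        if missing:
            raise ConnectivityError(
                f"subjects missing from node-value table {node_values}: {missing}"
            )
        rows = np.array([pos[s.subject_id] for s in subjects], dtype=int)
        return StudyDataset(subjects=subjects, mode="node_values",
                            node_labels=labels, node_values=x[rows])
    if "matrix_path" not in table.columns:
        raise ConnectivityError(
            "subject table needs a 'matrix_path' column when no node-value table is given"
        )
    root = Path(matrix_root) if matrix_root is not None else table_path.parent
    mats = []
    for sub, rel in zip(subjects, table["matrix_path"]):
        mpath = Path(rel)
        if not mpath.is_absolute():
            mpath = root / mpath
        if not mpath.exists():
            raise ConnectivityError(
                f"matrix file for subject {sub.subject_id!r} not found: {mpath}"
            )
        mats.append(load_matrix(mpath))
    labels = mats[0].node_labels
    return StudyDataset(subjects=subjects, mode="subject_matrices",
                        node_labels=labels, matrices=tuple(mats))
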