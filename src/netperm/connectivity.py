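"""Connectivity matrices, group averaging, thresholding and threshold grids.

The unit of analysis is a square symmetric association matrix between brain
regions (nodes): Pearson correlations in [-1, 1] or coherence values in
[0, 1].  Matrices are stored with a zero diagonal (self-connections are
excluded from every statistic).  Thresholding at a cutoff tau keeps edges with
signed weight >= tau, producing the nested families of sparser networks on
which the multiple-thresholds approach operates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: tolerance for symmetry validation and for weight-bound checks
SYMMETRY_TOL = 1e-8

MATRIX_KINDS = ("correlation", "coherence", "binary")
GRID_CONVENTIONS = ("closed_inclusive", "half_open", "closed_omit_top")


class ZeroVarianceWarning(UserWarning):
    """A node had zero variance across subjects; its correlations were set to 0."""


class ConnectivityError(ValueError):
    """Invalid connectivity input (shape, symmetry, labels, bounds)."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square symmetric weighted association matrix with node labels.

    Parameters
    ----------
    weights
        ``(n, n)`` real matrix; symmetrized on construction (must already be
        symmetric to within :data:`SYMMETRY_TOL`).  The diagonal is stored as
        exactly 0.
    node_labels
        Ordered node names, unique, length ``n``.
    kind
        ``"correlation"`` (weights in [-1, 1]), ``"coherence"`` (weights in
        [0, 1]) or ``"binary"`` (weights in {0, 1}).
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]
    kind: str = "correlation"

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectivityError(f"weights must be a square matrix, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ConnectivityError("a connectivity matrix needs at least 2 nodes")
        labels = tuple(str(lab) for lab in self.node_labels)
        if len(labels) != n:
            raise ConnectivityError(
                f"{len(labels)} node labels for a {n}-node matrix"
            )
        if len(set(labels)) != n:
            raise ConnectivityError("duplicate node labels")
        if not np.all(np.isfinite(w)):
            raise ConnectivityError("weights contain non-finite values")
        asym = float(np.max(np.abs(w - w.T))) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ConnectivityError(f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL})")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if self.kind not in MATRIX_KINDS:
            raise ConnectivityError(f"unknown matrix kind {self.kind!r}")
        lo = -1.0 if self.kind == "correlation" else 0.0
        if w.min() < lo - SYMMETRY_TOL or w.max() > 1.0 + SYMMETRY_TOL:
            raise ConnectivityError(f"weights outside [{lo}, 1] for kind={self.kind!r}")
        w = np.clip(w, lo, 1.0)
        if self.kind == "binary" and not np.all((w == 0.0) | (w == 1.0)):
            raise ConnectivityError("binary matrix entries must be 0 or 1")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray, kind: str | None = None) -> "ConnectivityMatrix":
        """Return a new matrix with the same labels and new weights."""
        return ConnectivityMatrix(weights, self.node_labels, kind or self.kind)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    covariate: float | None = None


@dataclass(frozen=True)
class StudyDataset:
    """Subjects with group labels plus either node-value vectors or per-subject matrices.

    ``mode="node_values"``: one scalar per node per subject (e.g. cortical
    thickness, FA); connectivity can only be formed on the group level via
    inter-subject correlation.  ``mode="subject_matrices"``: one full
    connectivity matrix per subject (e.g. EEG coherence, resting fMRI).
    """

    subjects: tuple[Subject, ...]
    mode: str
    node_labels: tuple[str, ...]
    node_values: np.ndarray | None = None  # (n_subjects, n_nodes)
    matrices: tuple[ConnectivityMatrix, ...] | None = None

    def __post_init__(self) -> None:
        subs = tuple(self.subjects)
        if not subs:
            raise ConnectivityError("dataset has no subjects")
        ids = [s.subject_id for s in subs]
        if len(set(ids)) != len(ids):
            raise ConnectivityError("duplicate subject ids")
        if self.mode not in ("node_values", "subject_matrices"):
            raise ConnectivityError(f"unknown dataset mode {self.mode!r}")
        labels = tuple(str(lab) for lab in self.node_labels)
        object.__setattr__(self, "subjects", subs)
        object.__setattr__(self, "node_labels", labels)
        if self.mode == "node_values":
            if self.node_values is None:
                raise ConnectivityError("mode=node_values requires node_values")
            x = np.array(self.node_values, dtype=float)
            if x.shape != (len(subs), len(labels)):
                raise ConnectivityError(
                    f"node_values shape {x.shape} != (n_subjects={len(subs)}, n_nodes={len(labels)})"
                )
            if not np.all(np.isfinite(x)):
                raise ConnectivityError("node_values contain non-finite entries")
            x.setflags(write=False)
            object.__setattr__(self, "node_values", x)
        else:
            if self.matrices is None or len(self.matrices) != len(subs):
                raise ConnectivityError("mode=subject_matrices requires one matrix per subject")
            mats = tuple(self.matrices)
            for s, m in zip(subs, mats):
                if m.node_labels != labels:
                    raise ConnectivityError(
                        f"subject {s.subject_id!r}: node labels differ from dataset labels"
                    )
            object.__setattr__(self, "matrices", mats)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({s.group for s in self.subjects}))

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.subjects) if s.group == group], dtype=int)
        if idx.size == 0:
            raise ConnectivityError(f"no subjects in group {group!r}")
        return idx

    def two_groups(self) -> tuple[str, str]:
        """The two group labels (sorted); error unless exactly two groups."""
        g = self.groups
        if len(g) != 2:
            raise ConnectivityError(f"two-group procedure requires exactly 2 groups, found {len(g)}: {g}")
        return g[0], g[1]

    def covariates(self) -> np.ndarray:
        cov = [s.covariate for s in self.subjects]
        if any(c is None for c in cov):
            missing = [s.subject_id for s in self.subjects if s.covariate is None]
            raise ConnectivityError(f"covariate missing for subjects {missing}")
        return np.array(cov, dtype=float)


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered, uniformly spaced threshold values plus the convention that built them."""

    lower: float
    upper: float
    values: np.ndarray
    convention: str
    increment: float

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ConnectivityError("threshold grid must be a non-empty 1-d sequence")
        if np.any(np.diff(v) <= 0):
            raise ConnectivityError("threshold values must be strictly increasing")
        if self.lower > v[0] + 1e-12 or v[-1] > self.upper + 1e-12:
            raise ConnectivityError("threshold values outside [lower, upper]")
        if self.increment <= 0:
            raise ConnectivityError("increment must be positive")
        if v.size > 1 and np.max(np.abs(np.diff(v) - self.increment)) > 1e-9:
            raise ConnectivityError("consecutive thresholds do not differ by the stated increment")
        if self.convention not in GRID_CONVENTIONS:
            raise ConnectivityError(f"unknown grid convention {self.convention!r}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self) -> Iterator[float]:
        return iter(float(t) for t in self.values)


def make_threshold_grid(
    lower: float, upper: float, count: int, convention: str = "closed_omit_top"
) -> ThresholdGrid:
    """Build a uniform threshold grid over ``[lower, upper]``.

    Conventions
    -----------
    ``closed_omit_top``
        Divide ``[lower, upper]`` into ``count`` steps of size
        ``(upper - lower)/count`` and drop the top endpoint (the sparsest
        network), yielding ``count`` thresholds starting at ``lower``.
    ``half_open``
        Enumerate ``lower, lower+inc, ...`` strictly below ``upper`` with
        ``inc = (upper - lower)/count`` — numerically the same ``count``
        values, recorded as a half-open enumeration.
    ``closed_inclusive``
        ``count`` thresholds including both endpoints
        (``inc = (upper - lower)/(count - 1)``).

    The convention is recorded in the result because mixing conventions
    silently changes how many networks enter downstream statistics.
    """
    if not (math.isfinite(lower) and math.isfinite(upper)):
        raise ConnectivityError("grid bounds must be finite")
    if lower >= upper:
        raise ConnectivityError(f"lower ({lower}) must be below upper ({upper})")
    if count < 1:
        raise ConnectivityError("count must be >= 1")
    if convention not in GRID_CONVENTIONS:
        raise ConnectivityError(f"unknown grid convention {convention!r}")
    if count == 1:
        values = np.array([lower], dtype=float)
        inc = upper - lower
    elif convention == "closed_inclusive":
        inc = (upper - lower) / (count - 1)
        values = lower + inc * np.arange(count)
    else:  # closed_omit_top and half_open share the spacing
        inc = (upper - lower) / count
        values = lower + inc * np.arange(count)
    return ThresholdGrid(lower=float(lower), upper=float(upper), values=values,
                         convention=convention, increment=float(inc))


def grid_from_increment(
    lower: float, upper: float, increment: float, convention: str = "closed_omit_top"
) -> ThresholdGrid:
    """Grid specified the way papers usually print it: bounds plus increment."""
    if increment <= 0:
        raise ConnectivityError("increment must be positive")
    span = upper - lower
    if span <= 0:
        raise ConnectivityError(f"lower ({lower}) must be below upper ({upper})")
    count = int(round(span / increment))
    if convention == "closed_inclusive":
        count += 1
    if count < 1:
        raise ConnectivityError("increment larger than the grid range")
    return make_threshold_grid(lower, upper, count, convention)


def _correlation(x: np.ndarray, method: str) -> tuple[np.ndarray, list[int]]:
    """Column-wise correlation with zero-variance columns zeroed out.

    Returns the correlation matrix and the indices of degenerate columns.
    """
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x, axis=0)
    sd = x.std(axis=0)
    degenerate = [int(i) for i in np.flatnonzero(sd == 0.0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    if degenerate:
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r, degenerate


def internode_correlation(
    dataset: StudyDataset, group: str, method: str = "pearson"
) -> ConnectivityMatrix:
    """Inter-subject correlation network for one group.

    Each edge is the correlation, across the group's subjects, of the scalar
    values of a node pair.  This is the only way to obtain connectivity when
    each subject contributes a single value per region (sMRI thickness, FA),
    and it yields exactly one network per group.

    Pearson is the default; ``method="spearman"`` rank-transforms first.
    Zero-variance nodes are flagged with :class:`ZeroVarianceWarning` and
    their correlations set to 0.
    """
    if method not in ("pearson", "spearman"):
        raise ConnectivityError(f"unknown correlation method {method!r}")
    if dataset.mode != "node_values":
        raise ConnectivityError("internode_correlation requires a node_values dataset")
    idx = dataset.group_indices(group)
    if idx.size < 3:
        raise ConnectivityError(
            f"insufficient subjects: group {group!r} has {idx.size}, need >= 3"
        )
    x = dataset.node_values[idx]
    r, degenerate = _correlation(x, method)
    if degenerate:
        names = [dataset.node_labels[i] for i in degenerate]
        warnings.warn(
            f"zero-variance nodes in group {group!r}: {names}; correlations set to 0",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    return ConnectivityMatrix(r, dataset.node_labels, kind="correlation")


def mean_connectivity(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-subject matrices (the group-level matrix)."""
    if not matrices:
        raise ConnectivityError("mean of an empty matrix list")
    first = matrices[0]
    for m in matrices[1:]:
        if m.node_labels != first.node_labels:
            raise ConnectivityError("matrices have mismatched node labels")
        if m.kind != first.kind:
            raise ConnectivityError("matrices have mismatched kinds")
    mean = np.mean([m.weights for m in matrices], axis=0)
    return ConnectivityMatrix(mean, first.node_labels, first.kind)


def apply_threshold(
    matrix: ConnectivityMatrix,
    tau: float,
    binarize: bool = False,
    absolute: bool = False,
) -> ConnectivityMatrix:
    """Keep edges with weight >= tau; zero the rest.

    By default the *signed* weight is compared, so for tau > 0 negative
    correlations are always removed.  ``absolute=True`` compares |weight|
    instead.  ``binarize=True`` sets surviving edges to 1 (kind becomes
    ``"binary"``); otherwise weights are retained, matching the practice of
    feeding thresholded matrices to weighted-network software.
    """
    if not math.isfinite(tau):
        raise ConnectivityError("tau must be finite")
    w = matrix.weights
    crit = np.abs(w) if absolute else w
    mask = crit >= tau
    np.fill_diagonal(mask, False)
    if binarize:
        out = np.where(mask, 1.0, 0.0)
        return ConnectivityMatrix(out, matrix.node_labels, kind="binary")
    out = np.where(mask, w, 0.0)
    return ConnectivityMatrix(out, matrix.node_labels, kind=matrix.kind)


def positive_part(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Drop non-positive edges (weights <= 0 become 0).

    Used for unthresholded weighted analyses of correlation matrices, where
    inverse-weight path costs and weighted triplet values are undefined for
    negative edges.
    """
    w = np.where(matrix.weights > 0.0, matrix.weights, 0.0)
    return ConnectivityMatrix(w, matrix.node_labels, kind=matrix.kind)
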