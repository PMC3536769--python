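"""Group-level permutation (Edgington / Monte-Carlo) tests of network metrics.

When connectivity exists only on the group level (one inter-subject
correlation network per group), parametric tests have nothing valid to work
with — but exchangeability of subjects under the null does.  The test
statistic is the difference in a small-world parameter between the two
group-level networks; its null distribution is built by randomly reassigning
subjects to groups (preserving group sizes), rebuilding the group networks
and recomputing the statistic.  With B random relabelings the Monte-Carlo
p-value uses the add-the-observed correction p = (1 + #exceedances)/(B + 1),
so p is never 0 and has floor 1/(B+1) (e.g. 0.001 at B = 999).  Ties count
as exceedances (conservative).  When the number of distinct relabelings is
<= B the full permutation group is enumerated instead and p is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .connectivity import (
    ConnectivityError,
    StudyDataset,
    ThresholdGrid,
    _correlation,
)
from .graph_metrics import DEFAULT_CONFIG, MetricConfig, _metrics_from_weights

SIDEDNESS = ("two_sided", "one_sided_upper", "one_sided_lower")


class DegeneratePermutationError(RuntimeError):
    """More than 5% of permutations produced an undefined metric."""

    def __init__(self, metric: str, offending: Sequence[int], total: int):
        self.metric = metric
        self.offending = list(offending)
        super().__init__(
            f"metric {metric!r} undefined (inconsistent graph) in "
            f"{len(self.offending)}/{total} permutations; offending permutation "
            f"indices: {self.offending[:20]}{'...' if len(self.offending) > 20 else ''}"
        )


@dataclass(frozen=True)
class PermutationResult:
    """Observed group difference, Monte-Carlo null distribution and p per metric."""

    observed_diff: Mapping[str, float]
    null_diffs: Mapping[str, np.ndarray]
    p: Mapping[str, float]
    B: int
    seed: int
    tau: float | None
    sidedness: str
    exhaustive: bool
    groups: tuple[str, str]
    n_undefined: Mapping[str, int]
    config: MetricConfig

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "tau": self.tau,
            "B": self.B,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "exhaustive": self.exhaustive,
            "observed_diff": dict(self.observed_diff),
            "p": dict(self.p),
            "n_undefined": dict(self.n_undefined),
            "config": self.config.to_dict(),
        }


def _group_weights(dataset: StudyDataset, idx: np.ndarray, tau: float | None) -> np.ndarray:
    """Group-level weight matrix for the subjects in ``idx``.

    node_values mode: inter-subject Pearson correlation across the subjects;
    subject_matrices mode: element-wise mean matrix.  Thresholded at tau when
    given, otherwise restricted to positive edges (weighted unthresholded
    analysis).
    """
    if dataset.mode == "node_values":
        w, _ = _correlation(dataset.node_values[idx], "pearson")
    else:
        w = np.mean([dataset.matrices[i].weights for i in idx], axis=0)
    if tau is not None:
        w = np.where(w >= tau, w, 0.0)
        np.fill_diagonal(w, 0.0)
    else:
        w = np.where(w > 0.0, w, 0.0)
    return w


def _statistic(
    dataset: StudyDataset,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    tau: float | None,
    config: MetricConfig,
) -> dict[str, float]:
    include_edges = tau is not None  # unthresholded: edge-count comparison obsolete
    stat_a = _metrics_from_weights(_group_weights(dataset, idx_a, tau), config, include_edges)
    stat_b = _metrics_from_weights(_group_weights(dataset, idx_b, tau), config, include_edges)
    return {m: stat_a[m] - stat_b[m] for m in stat_a}


def _relabelings(
    n: int, n_a: int, B: int, seed: int
) -> tuple[list[tuple[np.ndarray, np.ndarray]], bool]:
    """Relabeling sequence: exhaustive when C(n, n_a) <= B, else B Monte-Carlo draws."""
    total = math.comb(n, n_a)
    if total <= B:
        out = []
        allidx = np.arange(n)
        for combo in combinations(range(n), n_a):
            ia = np.array(combo, dtype=int)
            ib = np.setdiff1d(allidx, ia, assume_unique=True)
            out.append((ia, ib))
        return out, True
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(B):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_a]), np.sort(perm[n_a:])))
    return out, False


def _exceedances(null: np.ndarray, obs: float, sidedness: str) -> np.ndarray:
    if sidedness == "two_sided":
        return np.abs(null) >= abs(obs)
    if sidedness == "one_sided_upper":
        return null >= obs
    return null <= obs


def _test_from_relabelings(
    dataset: StudyDataset,
    relabelings: list[tuple[np.ndarray, np.ndarray]],
    exhaustive: bool,
    tau: float | None,
    config: MetricConfig,
    seed: int,
    sidedness: str,
) -> PermutationResult:
    ga, gb = dataset.two_groups()
    idx_a = dataset.group_indices(ga)
    idx_b = dataset.group_indices(gb)
    observed = _statistic(dataset, idx_a, idx_b, tau, config)
    metrics = list(observed)
    for m, v in observed.items():
        if not np.isfinite(v):
            raise ConnectivityError(
                f"observed statistic for {m!r} is undefined (inconsistent group network at tau={tau})"
            )
    nulls = {m: np.empty(len(relabelings)) for m in metrics}
    for b, (ia, ib) in enumerate(relabelings):
        diff = _statistic(dataset, ia, ib, tau, config)
        for m in metrics:
            nulls[m][b] = diff[m]
    p: dict[str, float] = {}
    n_undef: dict[str, int] = {}
    total = len(relabelings)
    for m in metrics:
        nd = nulls[m]
        undef = ~np.isfinite(nd)
        n_undef[m] = int(undef.sum())
        if n_undef[m] > 0.05 * total:
            raise DegeneratePermutationError(m, np.flatnonzero(undef).tolist(), total)
        valid = nd[~undef]
        exceed = int(_exceedances(valid, observed[m], sidedness).sum())
        if exhaustive:
            # identity relabeling is in the enumeration, so p >= 1/total already
            p[m] = exceed / valid.size
        else:
            p[m] = (exceed + 1) / (valid.size + 1)
    return PermutationResult(
        observed_diff=observed,
        null_diffs={m: nulls[m] for m in metrics},
        p=p,
        B=total,
        seed=seed,
        tau=tau,
        sidedness=sidedness,
        exhaustive=exhaustive,
        groups=(ga, gb),
        n_undefined=n_undef,
        config=config,
    )


def permutation_group_test(
    dataset: StudyDataset,
    tau: float | None = None,
    config: MetricConfig = DEFAULT_CONFIG,
    B: int = 1000,
    seed: int | None = None,
    sidedness: str = "two_sided",
) -> PermutationResult:
    """Edgington-style group-level permutation test of metric differences.

    Parameters
    ----------
    dataset
        Two-group study; the group-level network is the inter-subject
        correlation matrix (node_values mode) or the mean subject matrix.
    tau
        Threshold applied to the group-level matrix.  ``None`` analyzes the
        unthresholded weighted network (edge count omitted, non-positive
        edges dropped).
    B
        Number of Monte-Carlo relabelings (>= 19); exhaustive enumeration is
        used automatically when the permutation group is no larger than B.
    seed
        Mandatory RNG seed — permutation results must be reproducible.
    sidedness
        ``"two_sided"`` (default, on |difference|) or one-sided variants.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible permutation tests")
    if B < 19:
        raise ValueError("B must be >= 19 (p floor 1/(B+1) above 0.05 is useless)")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    ga, _ = dataset.two_groups()
    n_a = dataset.group_indices(ga).size
    relab, exhaustive = _relabelings(dataset.n_subjects, n_a, B, seed)
    return _test_from_relabelings(dataset, relab, exhaustive, tau, config, seed, sidedness)


@dataclass(frozen=True)
class PermutationSweep:
    """Per-threshold permutation results sharing one relabeling sequence."""

    results: tuple[PermutationResult, ...]
    dropped: tuple[tuple[float, str], ...]
    grid: ThresholdGrid


def permutation_sweep(
    dataset: StudyDataset,
    grid: ThresholdGrid,
    config: MetricConfig = DEFAULT_CONFIG,
    B: int = 1000,
    seed: int | None = None,
    sidedness: str = "two_sided",
) -> PermutationSweep:
    """Run the permutation test at every grid threshold.

    The identical subject-relabeling sequence (same seed) is reused across
    thresholds so that per-threshold results are directly comparable.
    Thresholds where the observed group networks are inconsistent or where
    more than 5% of permutations are degenerate are dropped and listed.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible permutation tests")
    if B < 19:
        raise ValueError("B must be >= 19")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    ga, _ = dataset.two_groups()
    n_a = dataset.group_indices(ga).size
    relab, exhaustive = _relabelings(dataset.n_subjects, n_a, B, seed)
    results: list[PermutationResult] = []
    dropped: list[tuple[float, str]] = []
    for tau in grid:
        try:
            results.append(
                _test_from_relabelings(dataset, relab, exhaustive, tau, config, seed, sidedness)
            )
        except (DegeneratePermutationError, ConnectivityError) as exc:
            dropped.append((tau, str(exc)))
    if dropped:
        warnings.warn(
            f"permutation sweep dropped {len(dropped)} of {len(grid)} thresholds",
            UserWarning, stacklevel=2,
        )
    return PermutationSweep(results=tuple(results), dropped=tuple(dropped), grid=grid)
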