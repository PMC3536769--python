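"""Parametric group comparisons of small-world parameters.

Implements the multiple-thresholds approach (MTA) — thresholding each group's
single network over a grid and treating the per-threshold metrics as samples
in an independent-samples t-test — together with the per-subject route (one
network per subject, a genuine sample per group) and a simple covariate
regression.

The MTA is reproduced *as practiced*, caveat included: the thresholded
networks are nested, hence not independent samples, and the number of
thresholds m is an arbitrary analyst choice that directly inflates t and
deflates p while Cohen's d stays put.  Every :class:`MTAResult` carries a
machine-readable statement of this.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .connectivity import (
    ConnectivityError,
    ConnectivityMatrix,
    StudyDataset,
    ThresholdGrid,
    apply_threshold,
    positive_part,
)
from .graph_metrics import DEFAULT_CONFIG, MetricConfig, network_metrics

METRIC_NAMES = ("n_edges", "clustering", "path_length")

MTA_CAVEAT = (
    "Per-threshold network metrics are nested, non-independent pseudo-replications "
    "of a single group-level network; parametric p-values computed from them are "
    "not valid inferential statistics and scale with the arbitrary number of "
    "thresholds. Report effect sizes, or use a group-level permutation test."
)


class DegenerateSamplesWarning(UserWarning):
    """A test statistic was degenerate (zero pooled variance with unequal means)."""


@dataclass(frozen=True)
class TTestResult:
    """Two-sample Student t-test with pooled variance, plus Cohen's d."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    d: float
    n_a: int
    n_b: int
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "mean_a": self.mean_a, "mean_b": self.mean_b, "d": self.d,
            "n_a": self.n_a, "n_b": self.n_b, "note": self.note,
        }


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS regression of a per-subject metric on a covariate."""

    slope: float
    intercept: float
    r: float
    p: float
    stderr: float
    n: int


def _check_sample(x, name: str, min_size: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_size:
        raise ValueError(f"sample {name} needs >= {min_size} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"sample {name} contains non-finite values")
    return x


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    df = x.size + y.size - 2
    ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    return math.sqrt(ss / df)


def cohens_d(x, y) -> float:
    """Standardized mean difference (mean_x - mean_y) / pooled SD.

    The pooled SD uses df = n_x + n_y - 2.  Unlike p-values, d does not grow
    with sample size, which is why it is the recommended companion statistic
    for multiple-thresholds analyses.  A zero pooled SD with unequal means
    yields a signed infinity and a warning.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    sd = _pooled_sd(x, y)
    diff = float(x.mean() - y.mean())
    if sd == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means; d is infinite",
                      DegenerateSamplesWarning, stacklevel=2)
        return math.copysign(math.inf, diff)
    return diff / sd


def t_test_independent(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (Student pooled by default).

    ``equal_var=False`` switches to Welch's test (Welch–Satterthwaite df);
    Cohen's d always uses the pooled SD.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    n_a, n_b = int(x.size), int(y.size)
    ma, mb = float(x.mean()), float(y.mean())
    sd = _pooled_sd(x, y)
    note = None
    if sd == 0.0:
        if ma == mb:
            return TTestResult(0.0, float(n_a + n_b - 2), 1.0, ma, mb, 0.0, n_a, n_b,
                               note="both samples constant and equal")
        warnings.warn("zero pooled variance with unequal means; t is infinite",
                      DegenerateSamplesWarning, stacklevel=2)
        t = math.copysign(math.inf, ma - mb)
        return TTestResult(t, float(n_a + n_b - 2), 0.0, ma, mb, t, n_a, n_b,
                           note="zero pooled variance, unequal means")
    d = (ma - mb) / sd
    if equal_var:
        df = float(n_a + n_b - 2)
        se = sd * math.sqrt(1.0 / n_a + 1.0 / n_b)
        t = (ma - mb) / se
    else:
        va, vb = x.var(ddof=1) / n_a, y.var(ddof=1) / n_b
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        note = "welch"
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, min(p, 1.0), ma, mb, float(d), n_a, n_b, note=note)


@dataclass(frozen=True)
class MTAResult:
    """Output of the multiple-thresholds comparison.

    ``per_threshold_metrics`` is a tidy table (one row per threshold per
    group); ``tests`` maps metric name to the t-test over the per-threshold
    series; ``dropped_thresholds`` lists (tau, reason) for thresholds where
    either group's network was inconsistent; ``caveat`` states the
    non-independence of the samples.
    """

    grid: ThresholdGrid
    per_threshold_metrics: "object"  # pandas.DataFrame
    tests: Mapping[str, TTestResult]
    dropped_thresholds: tuple[tuple[float, str], ...]
    labels: tuple[str, str]
    config: MetricConfig
    caveat: str = MTA_CAVEAT


def multiple_thresholds_compare(
    matrix_a: ConnectivityMatrix,
    matrix_b: ConnectivityMatrix,
    grid: ThresholdGrid,
    config: MetricConfig = DEFAULT_CONFIG,
    labels: tuple[str, str] = ("A", "B"),
) -> MTAResult:
    """Replicate the multiple-thresholds approach for two group-level networks.

    Each matrix is thresholded at every grid value, the three small-world
    parameters computed, and per metric the two per-threshold series are
    compared with an independent-samples t-test — m thresholds play the role
    of m "subjects" per group.  Thresholds at which either network is
    inconsistent (edgeless or disconnected) are dropped and reported, as is
    standard practice for sparse networks.
    """
    import pandas as pd

    if matrix_a.node_labels != matrix_b.node_labels:
        raise ConnectivityError("group matrices have mismatched node labels")
    rows = []
    series: dict[str, dict[str, list[float]]] = {
        m: {labels[0]: [], labels[1]: []} for m in METRIC_NAMES
    }
    dropped: list[tuple[float, str]] = []
    for tau in grid:
        mm = {}
        for lab, mat in zip(labels, (matrix_a, matrix_b)):
            nm = network_metrics(apply_threshold(mat, tau), config)
            mm[lab] = nm
            rows.append({"threshold": tau, "group": lab, **{k: v for k, v in nm.to_dict().items() if k != "config"}})
        bad = [lab for lab in labels if not mm[lab].consistent]
        if bad:
            dropped.append((tau, f"inconsistent network for group(s) {bad}"))
            continue
        for m in METRIC_NAMES:
            for lab in labels:
                series[m][lab].append(getattr(mm[lab], m) if m != "n_edges" else float(mm[lab].n_edges))
    n_retained = len(series[METRIC_NAMES[0]][labels[0]])
    if n_retained < 2:
        raise ConnectivityError(
            f"grid too small after consistency filtering: {n_retained} of {len(grid)} thresholds retained"
        )
    tests = {
        m: t_test_independent(series[m][labels[0]], series[m][labels[1]])
        for m in METRIC_NAMES
    }
    return MTAResult(
        grid=grid,
        per_threshold_metrics=pd.DataFrame(rows),
        tests=tests,
        dropped_thresholds=tuple(dropped),
        labels=labels,
        config=config,
    )


@dataclass(frozen=True)
class SingleSubjectResult(Mapping):
    """Per-metric t-tests from per-subject networks; mapping metric -> TTestResult."""

    tests: Mapping[str, TTestResult]
    per_subject: "object"  # pandas.DataFrame
    excluded: tuple[tuple[str, str], ...]
    groups: tuple[str, str]
    tau: float | None
    config: MetricConfig

    def __getitem__(self, key):
        return self.tests[key]

    def __iter__(self):
        return iter(self.tests)

    def __len__(self):
        return len(self.tests)


def _per_subject_metrics(
    dataset: StudyDataset, tau: float | None, config: MetricConfig
):
    """Tidy per-subject metric table; inconsistent subjects flagged."""
    import pandas as pd

    if dataset.mode != "subject_matrices":
        raise ConnectivityError("per-subject analysis requires subject_matrices mode")
    rows = []
    for sub, mat in zip(dataset.subjects, dataset.matrices):
        g = apply_threshold(mat, tau) if tau is not None else positive_part(mat)
        nm = network_metrics(g, config)
        rows.append({
            "subject_id": sub.subject_id, "group": sub.group, "covariate": sub.covariate,
            "n_edges": float(nm.n_edges), "clustering": nm.clustering,
            "path_length": nm.path_length, "consistent": nm.consistent,
        })
    return pd.DataFrame(rows)


def single_subject_compare(
    dataset: StudyDataset,
    tau: float | None = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> SingleSubjectResult:
    """Compare groups using one network per subject (a genuine sample).

    With ``tau`` given, each subject's matrix is thresholded first and all
    three metrics are tested.  Without ``tau`` the unthresholded weighted
    matrices are used (non-positive edges dropped); every such network has
    the same edge support size, so the edge-count comparison is obsolete and
    omitted.  Subjects whose network is inconsistent are excluded with a
    warning; a group shrinking below 2 subjects is an error.
    """
    ga, gb = dataset.two_groups()
    table = _per_subject_metrics(dataset, tau, config)
    excluded = tuple(
        (r.subject_id, f"inconsistent network at tau={tau}")
        for r in table.itertuples() if not r.consistent
    )
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} subject(s) with inconsistent networks: "
            f"{[s for s, _ in excluded]}",
            UserWarning, stacklevel=2,
        )
    kept = table[table["consistent"]]
    metric_list = list(METRIC_NAMES) if tau is not None else ["clustering", "path_length"]
    tests = {}
    for m in metric_list:
        xa = kept.loc[kept["group"] == ga, m].to_numpy()
        xb = kept.loc[kept["group"] == gb, m].to_numpy()
        if xa.size < 2 or xb.size < 2:
            raise ConnectivityError(
                f"group reduced below 2 subjects after exclusions ({ga}: {xa.size}, {gb}: {xb.size})"
            )
        tests[m] = t_test_independent(xa, xb)
    return SingleSubjectResult(
        tests=tests, per_subject=table, excluded=excluded,
        groups=(ga, gb), tau=tau, config=config,
    )


def metric_covariate_regression(
    dataset: StudyDataset,
    metric: str,
    config: MetricConfig = DEFAULT_CONFIG,
    tau: float | None = None,
) -> RegressionResult:
    """OLS regression of a per-subject small-world parameter on the covariate.

    This is the continuous-score analogue of the single-subject group
    comparison (e.g. network metric vs. intelligence test score).
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    dataset.covariates()  # raises if any missing
    table = _per_subject_metrics(dataset, tau, config)
    kept = table[table["consistent"]]
    if len(kept) < 4:
        raise ConnectivityError(f"regression needs >= 4 usable subjects, got {len(kept)}")
    cov = kept["covariate"].to_numpy(dtype=float)
    y = kept[metric].to_numpy(dtype=float)
    if np.ptp(cov) == 0.0:
        raise ConnectivityError("covariate is constant; regression undefined")
    if np.ptp(y) == 0.0:
        # flat response: slope exactly 0, correlation undefined -> r = 0
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, 0.0, int(len(kept)))
    res = stats.linregress(cov, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue),
        p=float(res.pvalue), stderr=float(res.stderr), n=int(len(kept)),
    )
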