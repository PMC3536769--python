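"""Synthetic data generators and type-I-error experiments.

Two generators emulate a two-group neuroimaging study with no true group
difference:

* node values — one independent standard-normal scalar per brain region per
  subject (84 regions, 30 subjects per group by default), the situation in
  which connectivity can only be computed on the group level via
  inter-subject correlation;
* subject networks — one valid correlation matrix per subject, obtained by
  correlating independent standard-normal surrogate series (length 100 by
  default) across nodes, which guarantees symmetry, unit-bounded entries and
  positive semidefiniteness.

On top of the generators sit replicated experiments: the multiple-thresholds
analysis across threshold ranges and threshold counts m, and rejection-rate
(type-I error) studies of the three analysis approaches on null data.  All
randomness flows from an explicit master seed; replicate i uses the child
seed derived from ``numpy.random.SeedSequence([master_seed, i])``, so any
single replicate can be re-run in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .compare import METRIC_NAMES, multiple_thresholds_compare, single_subject_compare
from .connectivity import (
    ConnectivityError,
    ConnectivityMatrix,
    StudyDataset,
    Subject,
    internode_correlation,
    make_threshold_grid,
)
from .graph_metrics import DEFAULT_CONFIG, MetricConfig
from .permutation import DegeneratePermutationError, permutation_group_test

#: the three threshold ranges of the simulated multiple-thresholds experiment
DEFAULT_RANGES = ((0.01, 0.06), (0.50, 0.54), (0.86, 0.91))
DEFAULT_M_VALUES = (10, 25, 50)

APPROACHES = ("mta", "permutation", "single_subject")


@dataclass(frozen=True)
class SimulationSpec:
    """Study-shape parameters for the synthetic generators.

    Defaults are the simulated study conditions: two groups of 30 subjects,
    84 brain regions; subject networks built from surrogate series of
    length 100.
    """

    n_per_group: int = 30
    n_nodes: int = 84
    mode: str = "node_values"
    series_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.mode not in ("node_values", "subject_matrices"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "subject_matrices" and self.series_length < self.n_nodes:
            raise ValueError(
                "series_length must be >= n_nodes (shorter series give rank-deficient, "
                "degenerate correlation matrices)"
            )


def _subjects(n_per_group: int) -> tuple[Subject, ...]:
    subs = []
    for g, label in enumerate(("group1", "group2")):
        for i in range(n_per_group):
            subs.append(Subject(subject_id=f"s{g * n_per_group + i:03d}", group=label))
    return tuple(subs)


def _node_labels(n_nodes: int) -> tuple[str, ...]:
    return tuple(f"node{i:03d}" for i in range(n_nodes))


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: SeedSequence([master_seed, index])."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_node_values(spec: SimulationSpec) -> StudyDataset:
    """Null dataset: one standard-normal value per node per subject, two groups."""
    if spec.mode != "node_values":
        raise ValueError("spec.mode must be 'node_values'")
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal((2 * spec.n_per_group, spec.n_nodes))
    return StudyDataset(
        subjects=_subjects(spec.n_per_group),
        mode="node_values",
        node_labels=_node_labels(spec.n_nodes),
        node_values=x,
    )


def generate_subject_networks(spec: SimulationSpec) -> StudyDataset:
    """Null dataset: one valid correlation matrix per subject.

    Each subject's matrix is the node-by-node Pearson correlation of
    independent standard-normal surrogate series of length
    ``spec.series_length`` — off-diagonal entries are approximately
    N(0, 1/series_length) and the matrix is positive semidefinite by
    construction.
    """
    if spec.mode != "subject_matrices":
        raise ValueError("spec.mode must be 'subject_matrices'")
    rng = np.random.default_rng(spec.seed)
    labels = _node_labels(spec.n_nodes)
    mats = []
    for _ in range(2 * spec.n_per_group):
        series = rng.standard_normal((spec.series_length, spec.n_nodes))
        r = np.corrcoef(series, rowvar=False)
        np.fill_diagonal(r, 0.0)
        mats.append(ConnectivityMatrix(np.clip(r, -1.0, 1.0), labels, kind="correlation"))
    return StudyDataset(
        subjects=_subjects(spec.n_per_group),
        mode="subject_matrices",
        node_labels=labels,
        matrices=tuple(mats),
    )


def generate(spec: SimulationSpec) -> StudyDataset:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "node_values":
        return generate_node_values(spec)
    return generate_subject_networks(spec)


def demo_study(mode: str = "subject_matrices", seed: int = 7, covariate: bool = True) -> StudyDataset:
    """Tiny deterministic fixture dataset: 6 nodes, 8 subjects (4 per group).

    Subject matrices mix a shared component into the surrogate series
    (expected pairwise correlation ~0.4) so the networks stay well connected
    under mild thresholds — a convenience for examples and tests, not a null
    generator.
    """
    spec = SimulationSpec(n_per_group=4, n_nodes=6, mode=mode, series_length=24, seed=seed)
    if mode == "subject_matrices":
        rng = np.random.default_rng(seed)
        labels = _node_labels(spec.n_nodes)
        mats = []
        for _ in range(2 * spec.n_per_group):
            noise = rng.standard_normal((spec.series_length, spec.n_nodes))
            shared = rng.standard_normal((spec.series_length, 1))
            series = np.sqrt(0.6) * noise + np.sqrt(0.4) * shared
            r = np.corrcoef(series, rowvar=False)
            np.fill_diagonal(r, 0.0)
            mats.append(ConnectivityMatrix(np.clip(r, -1.0, 1.0), labels, kind="correlation"))
        ds = StudyDataset(subjects=_subjects(spec.n_per_group), mode=mode,
                          node_labels=labels, matrices=tuple(mats))
    else:
        ds = generate(spec)
    if not covariate:
        return ds
    rng = np.random.default_rng(seed + 1)
    cov = rng.normal(20.0, 5.0, ds.n_subjects)
    subs = tuple(replace(s, covariate=float(c)) for s, c in zip(ds.subjects, cov))
    return StudyDataset(
        subjects=subs, mode=ds.mode, node_labels=ds.node_labels,
        node_values=ds.node_values, matrices=ds.matrices,
    )


def replicate_mta_experiment(
    spec: SimulationSpec,
    ranges: Sequence[tuple[float, float]] = DEFAULT_RANGES,
    m_values: Sequence[int] = DEFAULT_M_VALUES,
    config: MetricConfig = DEFAULT_CONFIG,
):
    """One simulated multiple-thresholds experiment over (range x m) cells.

    Generates a null node-values dataset, builds the two group-level
    inter-subject correlation networks, and for every threshold range and
    every number of thresholds m runs the multiple-thresholds comparison.
    Returns a tidy DataFrame with one row per (range, m, metric).
    """
    import pandas as pd

    if not ranges or not m_values:
        raise ValueError("ranges and m_values must be non-empty")
    ds = generate_node_values(replace(spec, mode="node_values"))
    ga, gb = ds.two_groups()
    mat_a = internode_correlation(ds, ga)
    mat_b = internode_correlation(ds, gb)
    rows = []
    for lower, upper in ranges:
        for m in m_values:
            grid = make_threshold_grid(lower, upper, m, "closed_omit_top")
            try:
                res = multiple_thresholds_compare(mat_a, mat_b, grid, config, labels=(ga, gb))
            except ConnectivityError as exc:
                for metric in METRIC_NAMES:
                    rows.append({"lower": lower, "upper": upper, "m": m, "metric": metric,
                                 "t": np.nan, "df": np.nan, "p": np.nan, "d": np.nan,
                                 "n_retained": 0, "error": str(exc)})
                continue
            n_retained = len(grid) - len(res.dropped_thresholds)
            for metric, tt in res.tests.items():
                rows.append({"lower": lower, "upper": upper, "m": m, "metric": metric,
                             "t": tt.t, "df": tt.df, "p": tt.p, "d": tt.d,
                             "n_retained": n_retained, "error": None})
    return pd.DataFrame(rows)


def mta_multi_m_study(
    n_replicates: int,
    spec: SimulationSpec = SimulationSpec(),
    threshold_range: tuple[float, float] = (0.01, 0.06),
    m_values: Sequence[int] = DEFAULT_M_VALUES,
    config: MetricConfig = DEFAULT_CONFIG,
    seed: int = 0,
):
    """Replicated null MTA study within one range, across threshold counts m.

    Each replicate draws a fresh null dataset (child seed i) and analyzes the
    *same* pair of group networks with every m, so the effect of m is
    isolated from sampling noise.  Returns a tidy DataFrame (replicate, m,
    metric, t, p, d) from which rejection rates, mean |t| and mean |d| per m
    are computed.
    """
    import pandas as pd

    frames = []
    for i in range(n_replicates):
        rep_spec = replace(spec, mode="node_values", seed=child_seed(seed, i))
        df = replicate_mta_experiment(rep_spec, ranges=[threshold_range],
                                      m_values=m_values, config=config)
        df.insert(0, "replicate", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TypeIErrorReport:
    """Measured false-positive rate of an analysis approach on null data."""

    approach: str
    settings: Mapping[str, object]
    n_replicates: int
    n_excluded: int
    rejection_rate: Mapping[str, float]
    rejection_ci: Mapping[str, tuple[float, float]]
    alpha: float
    seeds: tuple[int, ...]
    replicates: "object"  # pandas.DataFrame, one row per replicate

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "settings": dict(self.settings),
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
            "rejection_rate": dict(self.rejection_rate),
            "rejection_ci": {k: list(v) for k, v in self.rejection_ci.items()},
            "alpha": self.alpha,
        }


def _one_null_replicate(
    spec: SimulationSpec, approach: str, settings: Mapping, alpha: float, rep_seed: int
) -> dict[str, bool]:
    ds_spec = replace(spec, seed=rep_seed)
    if approach == "mta":
        df = replicate_mta_experiment(
            replace(ds_spec, mode="node_values"),
            ranges=[(settings["lower"], settings["upper"])],
            m_values=[settings["m"]],
            config=settings.get("config", DEFAULT_CONFIG),
        )
        if df["error"].notna().any():
            raise ConnectivityError(str(df.loc[df["error"].notna(), "error"].iloc[0]))
        # parametric decision rule: p < alpha
        return {r.metric: bool(r.p < alpha) for r in df.itertuples()}
    if approach == "permutation":
        ds = generate(ds_spec)
        res = permutation_group_test(
            ds, tau=settings.get("tau"), config=settings.get("config", DEFAULT_CONFIG),
            B=settings.get("B", 199), seed=child_seed(rep_seed, 1),
            sidedness=settings.get("sidedness", "two_sided"),
        )
        # attainable p-values are k/(B+1): reject at p <= alpha
        return {m: bool(res.p[m] <= alpha) for m in res.p}
    if approach == "single_subject":
        ds = generate_subject_networks(replace(ds_spec, mode="subject_matrices"))
        res = single_subject_compare(ds, tau=settings.get("tau"),
                                     config=settings.get("config", DEFAULT_CONFIG))
        return {m: bool(res[m].p < alpha) for m in res}
    raise ValueError(f"unknown approach {approach!r}; choose from {APPROACHES}")


def type1_error_experiment(
    spec: SimulationSpec,
    approach: str,
    settings: Mapping,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> TypeIErrorReport:
    """Measure the false-positive rate of an approach on replicated null data.

    Every replicate generates a dataset with no group difference by
    construction, applies the approach, and records whether each metric's
    test rejects at ``alpha``.  Replicates that degenerate (inconsistent
    graphs beyond tolerance) are excluded and counted.  Clopper-Pearson 95%
    intervals accompany each rate.
    """
    import pandas as pd
    from scipy.stats import binomtest

    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; choose from {APPROACHES}")
    if n_replicates < 50:
        raise ValueError("n_replicates must be >= 50 for a usable rate estimate")
    rows = []
    seeds = []
    n_excluded = 0
    for i in range(n_replicates):
        rep_seed = child_seed(seed, i)
        seeds.append(rep_seed)
        try:
            rej = _one_null_replicate(spec, approach, settings, alpha, rep_seed)
        except (ConnectivityError, DegeneratePermutationError) as exc:
            n_excluded += 1
            rows.append({"replicate": i, "seed": rep_seed, "excluded": True,
                         "reason": str(exc)})
            continue
        rows.append({"replicate": i, "seed": rep_seed, "excluded": False,
                     "reason": None, **{f"reject_{m}": v for m, v in rej.items()}})
    table = pd.DataFrame(rows)
    if n_excluded:
        warnings.warn(f"{n_excluded} of {n_replicates} replicates excluded as degenerate",
                      UserWarning, stacklevel=2)
    kept = table[~table["excluded"]]
    if kept.empty:
        raise ConnectivityError("all replicates degenerate; no rate to report")
    metric_cols = [c for c in kept.columns if c.startswith("reject_")]
    rates = {}
    cis = {}
    for c in metric_cols:
        k = int(kept[c].sum())
        n = int(len(kept))
        rates[c.removeprefix("reject_")] = k / n
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
        cis[c.removeprefix("reject_")] = (float(ci.low), float(ci.high))
    return TypeIErrorReport(
        approach=approach, settings=dict(settings), n_replicates=n_replicates,
        n_excluded=n_excluded, rejection_rate=rates, rejection_ci=cis,
        alpha=alpha, seeds=tuple(seeds), replicates=table,
    )
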