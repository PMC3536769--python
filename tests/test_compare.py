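"""t-tests, Cohen's d, the multiple-thresholds replica and the per-subject route."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from netperm import (
    ConnectivityError,
    ConnectivityMatrix,
    DEFAULT_CONFIG,
    MetricConfig,
    MTA_CAVEAT,
    SimulationSpec,
    StudyDataset,
    Subject,
    apply_threshold,
    cohens_d,
    demo_study,
    generate_subject_networks,
    make_threshold_grid,
    metric_covariate_regression,
    mta_multi_m_study,
    multiple_thresholds_compare,
    network_metrics,
    single_subject_compare,
    t_test_independent,
)
from netperm.compare import DegenerateSamplesWarning

from _oracles import pooled_t

finite_floats = st.floats(-50, 50, allow_nan=False)
samples = st.lists(finite_floats, min_size=3, max_size=12)


class TestTTest:
    def test_identical_samples_null(self):
        r = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p, r.d) == (0.0, 1.0, 0.0)

    def test_hand_case_unit_pooled_sd(self):
        r = t_test_independent([1, 2, 3], [4, 5, 6])
        # pooled SD = 1, mean diff = -3
        assert r.df == 4
        assert r.d == pytest.approx(-3.0)
        assert abs(r.d) == pytest.approx(3.0)
        t, df, d = pooled_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(t, abs=1e-12)

    def test_df_for_25_and_34_subjects(self, rng):
        r = t_test_independent(rng.standard_normal(25), rng.standard_normal(34))
        assert r.df == 57

    @given(x=samples, y=samples)
    def test_agrees_with_scipy_and_closed_form(self, x, y):
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        r = t_test_independent(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
        t, df, d = pooled_t(x, y)
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.df == df
        assert r.d == pytest.approx(d, abs=1e-10)

    @given(x=samples, y=samples)
    def test_swap_flips_t_keeps_p(self, x, y):
        a = t_test_independent(x, y)
        b = t_test_independent(y, x)
        assert a.t == pytest.approx(-b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_welch_matches_scipy(self, rng):
        x = rng.standard_normal(10)
        y = 2.0 * rng.standard_normal(20) + 1.0
        r = t_test_independent(x, y, equal_var=False)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_unequal_means_sentinel(self):
        with pytest.warns(DegenerateSamplesWarning):
            r = t_test_independent([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(r.t) and r.p == 0.0


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_case(self):
        # deviations give pooled SD = sqrt(2); d = (1 - 2)/sqrt(2)
        assert cohens_d([0, 2], [1, 3]) == pytest.approx(-1 / math.sqrt(2))

    @given(x=samples, y=samples, shift=finite_floats)
    def test_location_invariance(self, x, y, shift):
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        d0 = cohens_d(x, y)
        d1 = cohens_d(np.add(x, shift), np.add(y, shift))
        assert d1 == pytest.approx(d0, abs=1e-8)

    @given(x=samples, y=samples, scale=st.floats(0.1, 20))
    def test_scale_invariance(self, x, y, scale):
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        d0 = cohens_d(x, y)
        d1 = cohens_d(np.multiply(x, scale), np.multiply(y, scale))
        assert d1 == pytest.approx(d0, abs=1e-8)


def _hand_matrices():
    labels = ("a", "b", "c", "d")
    def build(vals):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        w[iu] = vals
        return ConnectivityMatrix(w + w.T, labels, kind="coherence")
    # ordered pairs: ab ac ad bc bd cd
    a = build([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
    b = build([0.85, 0.75, 0.65, 0.55, 0.45, 0.35])
    return a, b


class TestMultipleThresholds:
    def test_identical_matrices_all_null(self):
        a, _ = _hand_matrices()
        grid = make_threshold_grid(0.3, 0.6, 5)
        res = multiple_thresholds_compare(a, a, grid)
        for tt in res.tests.values():
            assert tt.t == 0.0 and tt.p == 1.0

    def test_edge_count_t_matches_hand_computation(self):
        a, b = _hand_matrices()
        grid = make_threshold_grid(0.3, 0.6, 3)  # taus 0.3, 0.4, 0.5
        res = multiple_thresholds_compare(a, b, grid)
        # edge counts >= tau: A -> 6, 6, 5 ; B -> 6, 5, 4
        t, df, d = pooled_t([6, 6, 5], [6, 5, 4])
        assert res.tests["n_edges"].t == pytest.approx(t, abs=1e-12)
        assert res.tests["n_edges"].df == df

    def test_series_match_per_threshold_network_metrics(self):
        a, b = _hand_matrices()
        grid = make_threshold_grid(0.3, 0.6, 3)
        res = multiple_thresholds_compare(a, b, grid)
        for tau in grid:
            nm = network_metrics(apply_threshold(a, tau), DEFAULT_CONFIG)
            row = res.per_threshold_metrics.query("threshold == @tau and group == 'A'")
            assert row["clustering"].iloc[0] == pytest.approx(nm.clustering)

    def test_caveat_embedded(self):
        a, b = _hand_matrices()
        res = multiple_thresholds_compare(a, b, make_threshold_grid(0.3, 0.6, 3))
        assert res.caveat == MTA_CAVEAT
        assert "not valid" in res.caveat

    def test_inconsistent_thresholds_dropped_and_listed(self):
        a, b = _hand_matrices()
        grid = make_threshold_grid(0.3, 0.95, 10)  # top taus leave edgeless graphs
        res = multiple_thresholds_compare(a, b, grid)
        assert len(res.dropped_thresholds) > 0
        retained = len(grid) - len(res.dropped_thresholds)
        assert res.tests["n_edges"].n_a == retained

    def test_grid_too_small_after_filtering(self):
        a, b = _hand_matrices()
        grid = make_threshold_grid(0.91, 0.99, 3)  # everything edgeless
        with pytest.raises(ConnectivityError, match="grid too small"):
            multiple_thresholds_compare(a, b, grid)

    def test_more_thresholds_inflate_t_but_not_d(self):
        """Mean |t| grows with the number of thresholds m; mean |d| stays put."""
        df = mta_multi_m_study(
            30,
            SimulationSpec(n_per_group=15, n_nodes=40),
            threshold_range=(0.01, 0.1),
            m_values=(10, 50),
            seed=99,
        )
        sub = df[df.metric.isin(["n_edges", "clustering"])]
        by_m = sub.groupby("m").apply(
            lambda g: pytest.approx is not None
            and np.nanmean(np.abs(g.t[np.isfinite(g.t)])),
            include_groups=False,
        )
        assert by_m[50] > by_m[10]
        d_by_m = sub.groupby("m").apply(
            lambda g: np.nanmean(np.abs(g.d[np.isfinite(g.d)])), include_groups=False
        )
        assert abs(d_by_m[50] - d_by_m[10]) / d_by_m[10] < 0.25


class TestSingleSubject:
    def test_shared_matrix_all_null(self, triangle):
        subs = tuple(
            Subject(f"s{i}", "g1" if i < 3 else "g2") for i in range(6)
        )
        ds = StudyDataset(subjects=subs, mode="subject_matrices",
                          node_labels=triangle.node_labels,
                          matrices=(triangle,) * 6)
        res = single_subject_compare(ds, tau=0.2)
        for tt in res.tests.values():
            assert tt.t == 0.0 and tt.p == 1.0

    def test_unthresholded_omits_edge_count(self):
        ds = demo_study(seed=3)
        res = single_subject_compare(ds)
        assert set(res.keys()) == {"clustering", "path_length"}
        res_tau = single_subject_compare(ds, tau=0.1)
        assert "n_edges" in res_tau.keys()

    def test_planted_clustering_effect_detected(self):
        """Shifting one group's weights up by 0.2 is detected with power >= 0.9."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = SimulationSpec(n_per_group=30, n_nodes=20, mode="subject_matrices",
                                  series_length=50, seed=seed)
            ds = generate_subject_networks(spec)
            shifted = []
            for sub, m in zip(ds.subjects, ds.matrices):
                if sub.group == "group2":
                    w = np.clip(m.weights + 0.2, -1.0, 1.0)
                    np.fill_diagonal(w, 0.0)
                    m = ConnectivityMatrix(w, m.node_labels, m.kind)
                shifted.append(m)
            ds2 = StudyDataset(subjects=ds.subjects, mode="subject_matrices",
                               node_labels=ds.node_labels, matrices=tuple(shifted))
            if single_subject_compare(ds2)["clustering"].p < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_group_reduced_below_two_errors(self):
        # high tau leaves every network edgeless -> all subjects excluded
        ds = demo_study(seed=3)
        with pytest.raises(ConnectivityError):
            with pytest.warns(UserWarning):
                single_subject_compare(ds, tau=0.99)


class TestRegression:
    def test_constant_metric_zero_slope(self, triangle):
        subs = tuple(Subject(f"s{i}", "g1", covariate=float(i)) for i in range(5))
        ds = StudyDataset(subjects=subs, mode="subject_matrices",
                          node_labels=triangle.node_labels, matrices=(triangle,) * 5)
        res = metric_covariate_regression(ds, "clustering")
        assert res.slope == 0.0

    def test_perfectly_linear_metric(self):
        ds = demo_study(seed=5)
        base = single_subject_compare(ds, tau=0.05)
        cvals = 2.0 * base.per_subject["clustering"].to_numpy()
        subs = tuple(
            Subject(s.subject_id, s.group, covariate=float(c))
            for s, c in zip(ds.subjects, cvals)
        )
        ds2 = StudyDataset(subjects=subs, mode="subject_matrices",
                           node_labels=ds.node_labels, matrices=ds.matrices)
        res = metric_covariate_regression(ds2, "clustering", tau=0.05)
        assert abs(res.r) == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)

    def test_matches_closed_form_least_squares(self):
        ds = demo_study(seed=7)
        res = metric_covariate_regression(ds, "clustering")
        tab = single_subject_compare(ds).per_subject
        tab = tab[tab["consistent"]]
        x = tab["covariate"].to_numpy(float)
        y = tab["clustering"].to_numpy(float)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)

    def test_constant_covariate_error(self, triangle):
        subs = tuple(Subject(f"s{i}", "g1", covariate=1.0) for i in range(5))
        ds = StudyDataset(subjects=subs, mode="subject_matrices",
                          node_labels=triangle.node_labels, matrices=(triangle,) * 5)
        with pytest.raises(ConnectivityError, match="constant"):
            metric_covariate_regression(ds, "clustering")

    def test_missing_covariate_error(self):
        ds = demo_study(seed=3, covariate=False)
        with pytest.raises(ConnectivityError, match="covariate"):
            metric_covariate_regression(ds, "clustering")
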