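"""Unit and property tests for the windowed Granger-causality estimator."""

import math

import numpy as np
import pytest

from stgc.errors import (
    ConfigurationError,
    DegenerateSeriesError,
    SingularDesignError,
)
from stgc.granger import (
    build_edge_matrix,
    fit_mvar,
    gc_permutation_null,
    pairwise_gc,
    roi_gc,
    select_window_length,
    windowed_gc,
)
from stgc.timeseries import ROITimeSeries, WindowingScheme

# ---------------------------------------------------------------------------
# independent oracle: minimal windowed GC reimplementation (lstsq-based)
# ---------------------------------------------------------------------------


def _oracle_gc(y, x, p):
    y = y - y.mean()
    x = x - x.mean()
    T = y.size
    yt = y[p:]
    ones = np.ones(T - p)
    ry = np.column_stack([y[p - k : T - k] for k in range(1, p + 1)] + [ones])
    rx = np.column_stack([x[p - k : T - k] for k in range(1, p + 1)])
    br, *_ = np.linalg.lstsq(ry, yt, rcond=None)
    rss_r = np.sum((yt - ry @ br) ** 2)
    full = np.column_stack([ry[:, :-1], rx, ones])
    bf, *_ = np.linalg.lstsq(full, yt, rcond=None)
    rss_f = np.sum((yt - full @ bf) ** 2)
    return max(0.0, math.log(rss_r / rss_f))


def _oracle_order(y, x, orders):
    pmax = max(orders)
    y = y - y.mean()
    x = x - x.mean()
    T = y.size
    yt = y[pmax:]
    n = yt.size
    best, bestp = np.inf, min(orders)
    for p in sorted(orders):
        design = np.column_stack(
            [y[pmax - k : T - k] for k in range(1, p + 1)]
            + [x[pmax - k : T - k] for k in range(1, p + 1)]
            + [np.ones(n)]
        )
        b, *_ = np.linalg.lstsq(design, yt, rcond=None)
        rss = np.sum((yt - design @ b) ** 2)
        bic = n * math.log(rss / n) + (2 * p + 1) * math.log(n)
        if bic < best:
            best, bestp = bic, p
    return bestp


def _oracle_windowed_gc_avg(x, y, window_length, orders=(1, 2, 3, 4, 5)):
    m = x.size // window_length
    gcs = []
    for w in range(m):
        sl = slice(w * window_length, (w + 1) * window_length)
        p = _oracle_order(y[sl], x[sl], orders)
        gcs.append(_oracle_gc(y[sl], x[sl], p))
    return float(np.mean(gcs))


# ---------------------------------------------------------------------------
# MVAR fitting
# ---------------------------------------------------------------------------


class TestFitMVAR:
    def test_noise_free_recursion_recovered_exactly(self):
        x = np.empty(50)
        x[0] = 1.0
        for t in range(1, 50):
            x[t] = 0.9 * x[t - 1]
        model = fit_mvar(x[None, :], order=1)
        assert model.coefficients[0, 0, 0] == pytest.approx(0.9, abs=1e-10)
        assert model.residual_covariance[0, 0] == pytest.approx(0.0, abs=1e-18)
        assert model.n_effective == 49

    def test_white_noise_coefficients_near_zero(self, rng):
        T = 5000
        z = rng.standard_normal((2, T))
        model = fit_mvar(z, order=1)
        assert np.all(np.abs(model.coefficients) < 3 / np.sqrt(T))

    def test_bivariate_var1_recovery(self, rng):
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        T = 10000
        z = np.zeros((2, T))
        e = rng.standard_normal((2, T))
        for t in range(1, T):
            z[:, t] = A @ z[:, t - 1] + e[:, t]
        model = fit_mvar(z, order=1)
        np.testing.assert_allclose(model.coefficients[0], A, atol=0.05)

    def test_duplicated_channel_raises_singularity(self, rng):
        z = rng.standard_normal(100)
        with pytest.raises(SingularDesignError, match="channels"):
            fit_mvar(np.vstack([z, z]), order=1)


# ---------------------------------------------------------------------------
# pairwise GC
# ---------------------------------------------------------------------------


class TestPairwiseGC:
    def test_closed_form_variance_ratio(self, rng, coupled_pair_factory):
        """y_t = 0.4 x_{t-1} + e with white x: GC = ln(1 + 0.16 var x / var e)."""
        x, y = coupled_pair_factory(rng, 10000, 0.4)
        gc = pairwise_gc(x, y, order=1)
        assert gc == pytest.approx(math.log(1 + 0.16), abs=0.02)

    def test_null_mean_scales_as_one_over_T(self, rng):
        T = 52
        gcs = [
            pairwise_gc(rng.standard_normal(T), rng.standard_normal(T), 1)
            for _ in range(1000)
        ]
        # E[GC] ~ q / n for q = 1 extra regressor
        assert np.mean(gcs) == pytest.approx(1.0 / (T - 1), rel=0.4)

    def test_reverse_direction_below_null_quantile(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 10000, 0.4)
        gc_rev = pairwise_gc(y, x, order=1)
        null = [
            pairwise_gc(rng.permutation(y), x, order=1) for _ in range(99)
        ]
        assert gc_rev <= np.quantile(null, 0.95)

    def test_non_negative_on_random_inputs(self, rng):
        """In-sample GC of nested least-squares models is always >= 0."""
        for _ in range(1000):
            T = rng.integers(20, 60)
            p = int(rng.integers(1, 4))
            gc = pairwise_gc(rng.standard_normal(T), rng.standard_normal(T), p)
            assert gc >= 0.0

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            pairwise_gc(np.ones(50), np.arange(50.0), 1)

    def test_noise_free_target_returns_inf_with_warning(self):
        # y is exactly linear in its own and x's lag: zero full-model residual
        x = np.sin(np.arange(60.0))
        y = np.empty(60)
        y[0] = 0.3
        for t in range(1, 60):
            y[t] = 0.5 * y[t - 1] + 0.2 * x[t - 1]
        with pytest.warns(UserWarning, match="degenerate"):
            assert pairwise_gc(x, y, 1) == math.inf


# ---------------------------------------------------------------------------
# windowed GC
# ---------------------------------------------------------------------------


class TestWindowedGC:
    def test_single_window_reduces_to_classic_gc(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 100, 0.5)
        scheme = WindowingScheme(window_length=100, n_windows=1)
        res = windowed_gc(x, y, scheme, order_range=(2,))
        assert res.gc_avg == pytest.approx(pairwise_gc(x, y, 2), abs=1e-12)

    def test_invariants_of_result(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        res = windowed_gc(x, y, scheme)
        assert res.gc_avg == pytest.approx(np.mean(res.per_window_gc))
        assert res.objective_j == pytest.approx(res.gc_err + 1.0 / res.gc_avg)
        assert all(g >= 0 for g in res.per_window_gc)
        assert len(res.per_window_gc) == 4

    def test_stationary_windows_consistent_with_full_series(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.6)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        res = windowed_gc(x, y, scheme, order_range=(1,))
        full = pairwise_gc(x, y, 1)
        # each window estimates the same stationary GC up to sampling error
        assert res.gc_avg == pytest.approx(full, abs=0.15)

    def test_regime_change_raises_late_window_gc(self, rng):
        """Coupling off in windows 1-2, on in 3-4: per-window GC rises."""
        T = 208
        x = rng.standard_normal(T)
        e = rng.standard_normal(T)
        y = np.zeros(T)
        for t in range(1, T):
            c = 0.6 if t >= 104 else 0.0
            y[t] = c * x[t - 1] + e[t]
        scheme = WindowingScheme(window_length=52, n_windows=4)
        res = windowed_gc(x, y, scheme)
        early = np.mean(res.per_window_gc[:2])
        late = np.mean(res.per_window_gc[2:])
        assert late > early
        xn, yn = rng.standard_normal(T), rng.standard_normal(T)
        control = windowed_gc(xn, yn, scheme)
        assert res.gc_avg > control.gc_avg

    def test_matches_independent_oracle(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.4)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        res = windowed_gc(x, y, scheme)
        assert res.gc_avg == pytest.approx(_oracle_windowed_gc_avg(x, y, 52), abs=1e-9)

    def test_short_window_for_order_range_rejected(self, rng):
        scheme = WindowingScheme(window_length=10, n_windows=4)
        with pytest.raises(ConfigurationError):
            windowed_gc(rng.standard_normal(40), rng.standard_normal(40), scheme)


class TestSelectWindowLength:
    def test_single_candidate_returned(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        best, results = select_window_length(x, y, [52])
        assert best == 52
        assert set(results) == {52}

    def test_stationary_data_gives_valid_answer(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        best, results = select_window_length(x, y, [26, 52, 104])
        assert best in {26, 52, 104}
        for res in results.values():
            assert math.isfinite(res.objective_j)

    def test_non_divisor_candidate_truncated_from_start(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        _, results = select_window_length(x, y, [60])
        # 208 // 60 = 3 windows over the last 180 points
        assert len(results[60].per_window_gc) == 3

    def test_regime_length_recovered_majority_of_replicates(self, rng):
        """Planted 52-point coupling regimes are identified from {26, 52, 104}."""
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            T = 208
            x = rng.standard_normal(T)
            e = rng.standard_normal(T)
            y = np.zeros(T)
            for t in range(1, T):
                on = (t // 52) % 2 == 1
                y[t] = (0.9 if on else 0.0) * x[t - 1] + e[t]
            best, _ = select_window_length(x, y, [26, 52, 104])
            hits += best == 52
        assert hits >= 0.7 * n_rep


# ---------------------------------------------------------------------------
# ROI level
# ---------------------------------------------------------------------------


def _make_roi(name, data, n_copies=1):
    data = np.atleast_2d(data)
    if n_copies > 1:
        data = np.tile(data, (n_copies, 1))
    ids = [(i, 0, 0) for i in range(data.shape[0])]
    return ROITimeSeries(name, ids, data)


class TestRoiGC:
    def test_single_voxel_rois_reduce_to_windowed_gc(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        got = roi_gc(_make_roi("a", x), _make_roi("b", y), scheme)
        assert got == pytest.approx(windowed_gc(x, y, scheme).gc_avg, abs=1e-12)

    def test_identical_voxel_copies_equal_single_voxel(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        single = roi_gc(_make_roi("a", x), _make_roi("b", y), scheme)
        tripled = roi_gc(_make_roi("a", x, n_copies=3), _make_roi("b", y), scheme)
        assert tripled == pytest.approx(single, abs=1e-12)

    def test_matches_brute_force_pair_loop(self, rng):
        scheme = WindowingScheme(window_length=52, n_windows=4)
        src = _make_roi("a", rng.standard_normal((5, 208)))
        tgt = _make_roi("b", rng.standard_normal((5, 208)))
        got = roi_gc(src, tgt, scheme)
        brute = np.mean(
            [
                _oracle_windowed_gc_avg(xi, yj, 52)
                for xi in src.data
                for yj in tgt.data
            ]
        )
        assert got == pytest.approx(brute, abs=1e-9)

    def test_mismatched_lengths_rejected(self, rng):
        scheme = WindowingScheme(window_length=52, n_windows=4)
        with pytest.raises(Exception, match="length"):
            roi_gc(
                _make_roi("a", rng.standard_normal(208)),
                _make_roi("b", rng.standard_normal(104)),
                scheme,
            )


class TestEdgeMatrix:
    def test_two_rois_definitional(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.5)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        rois = [_make_roi("a", x), _make_roi("b", y)]
        em = build_edge_matrix(rois, scheme)
        assert em.gc[0, 0] == 0 and em.gc[1, 1] == 0
        assert em.edge("a", "b") == pytest.approx(roi_gc(rois[0], rois[1], scheme))
        assert em.edge("b", "a") == pytest.approx(roi_gc(rois[1], rois[0], scheme))

    def test_ten_rois_have_90_directed_edges(self, rng):
        scheme = WindowingScheme(window_length=26, n_windows=2)
        rois = [_make_roi(f"r{i}", rng.standard_normal(52)) for i in range(10)]
        em = build_edge_matrix(rois, scheme, order_range=(1,))
        off_diag = em.gc[~np.eye(10, dtype=bool)]
        assert off_diag.size == 90
        assert np.all(off_diag >= 0)

    def test_invariant_under_roi_relabelling(self, rng):
        scheme = WindowingScheme(window_length=52, n_windows=2)
        rois = [_make_roi(f"r{i}", rng.standard_normal((2, 104))) for i in range(3)]
        em = build_edge_matrix(rois, scheme, order_range=(1, 2))
        perm = [2, 0, 1]
        em_p = build_edge_matrix([rois[i] for i in perm], scheme, order_range=(1, 2))
        for i, pi in enumerate(perm):
            for j, pj in enumerate(perm):
                assert em_p.gc[i, j] == pytest.approx(em.gc[pi, pj], abs=1e-12)

    def test_duplicate_names_rejected(self, rng):
        scheme = WindowingScheme(window_length=26, n_windows=2)
        rois = [_make_roi("same", rng.standard_normal(52)) for _ in range(2)]
        with pytest.raises(ConfigurationError, match="duplicated"):
            build_edge_matrix(rois, scheme)


class TestPermutationNull:
    def test_null_sample_bounds_coupled_statistic(self, rng, coupled_pair_factory):
        x, y = coupled_pair_factory(rng, 208, 0.6)
        scheme = WindowingScheme(window_length=52, n_windows=4)
        observed = windowed_gc(x, y, scheme).gc_avg
        null = gc_permutation_null(x, y, scheme, n_permutations=49, rng=rng)
        assert observed > np.quantile(null, 0.95)
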