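import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from spritemds import (
    BinnedCluster,
    ContactMatrix,
    GenomeBinning,
    SpanThresholds,
    chromosome_features,
    cluster_span,
    degree_distance_table,
    pooled_quantile_thresholds,
    procrustes_align,
    region_dominance,
    regress,
)


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestProcrustes:
    def test_similarity_transform_gives_zero_rmse(self, rng):
        X = rng.standard_normal((12, 3))
        R = Rotation.from_euler("xyz", [37, 11, -5], degrees=True).as_matrix()
        Y = 2.5 * X @ R.T + np.array([1.0, -2.0, 3.0])
        assert procrustes_align(X, Y).rmse < 1e-10

    def test_reflection_allowed(self, rng):
        X = rng.standard_normal((10, 3))
        Y = X * np.array([-1.0, 1.0, 1.0])
        assert procrustes_align(X, Y).rmse < 1e-10

    def test_self_alignment_zero_and_symmetric_zero(self, rng):
        X = rng.standard_normal((8, 3))
        Y = 0.5 * X @ random_rotation(rng)
        assert procrustes_align(X, X).rmse == 0
        assert procrustes_align(X, Y).rmse < 1e-10
        assert procrustes_align(Y, X).rmse < 1e-10

    def test_invariant_to_transforming_either_argument(self, rng):
        X = rng.standard_normal((9, 3))
        Y = rng.standard_normal((9, 3))
        base = procrustes_align(X, Y).rmse
        Yt = 1.7 * Y @ random_rotation(rng) + 4.2
        assert np.isclose(procrustes_align(X, Yt).rmse, base, atol=1e-9)

    def test_matches_direct_search_oracle(self):
        """Numerical minimization over rotation/scale/translation agrees."""
        X = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1.5, 0], [0.3, 0.2, 2.0]])
        Y = np.array([[0.1, 0, 0], [1.2, -0.1, 0], [0, 1.4, 0.2], [0.5, 0.1, 1.7]])

        def objective(params, mirror):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            if mirror:
                rot = rot @ np.diag([1.0, 1.0, -1.0])
            s, t = params[3], params[4:]
            return np.sum((X - (s * Y @ rot.T + t)) ** 2)

        best = np.inf
        rng = np.random.default_rng(1)
        for mirror in (False, True):
            for _ in range(40):
                x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), [1.0], np.zeros(3)])
                res = minimize(objective, x0, args=(mirror,), method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
                best = min(best, res.fun)
        oracle_rmse = np.sqrt(best / len(X))
        assert np.isclose(procrustes_align(X, Y).rmse, oracle_rmse, atol=1e-6)

    def test_mismatched_point_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            procrustes_align(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))

    def test_degenerate_query_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_align(X, np.ones((5, 3)))

    def test_rotation_is_orthogonal(self, rng):
        X, Y = rng.standard_normal((7, 3)), rng.standard_normal((7, 3))
        res = procrustes_align(X, Y)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-10)
        assert np.isclose(abs(np.linalg.det(res.rotation)), 1.0)


class TestSpansAndQuantiles:
    def test_span_arithmetic(self, binning25):
        assert cluster_span(BinnedCluster("chr1", (0, 19)), binning25) == 19 * 25_000
        assert cluster_span(BinnedCluster("chr1", (4,)), binning25) == 0
        b400 = GenomeBinning("chr1", 600 * 25_000, 25_000)
        assert cluster_span(BinnedCluster("chr1", (0, 400)), b400) == 10_000_000
        assert cluster_span(BinnedCluster("chr1", (10, 11, 500)), b400) == 490 * 25_000

    def test_quintiles_of_1_to_100(self):
        th = pooled_quantile_thresholds(np.arange(1.0, 101.0))
        assert np.allclose(th, [20.8, 40.6, 60.4, 80.2])

    def test_constant_spans(self):
        th = pooled_quantile_thresholds([7.0] * 10)
        assert np.all(th == 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_quantile_thresholds([])


class TestChromosomeFeatures:
    def test_hand_counted_percentages(self, binning25):
        ks = [2] * 7 + [3, 4, 12]
        clusters = [BinnedCluster("chr1", tuple(range(k))) for k in ks]
        th = SpanThresholds(upper_quintile=1e12, upper_decile=1e12)
        f = chromosome_features(clusters, th, binning25)
        assert f.n_clusters == 10
        assert f.pct_many_gt3 == 20.0
        assert f.pct_many_gt10 == 10.0
        assert f.pct_long == 0.0  # all spans below the threshold

    def test_zero_clusters_marked_undefined(self, binning25):
        f = chromosome_features([], SpanThresholds(1.0, 2.0), binning25)
        assert f.n_clusters == 0 and np.isnan(f.pct_many_gt3) and np.isnan(f.pct_long)

    def test_matches_brute_force_recount(self, rng, binning25):
        clusters = []
        for _ in range(1000):
            m = int(rng.integers(1, 10))
            bins = tuple(sorted(rng.choice(20, size=m, replace=False).tolist()))
            clusters.append(BinnedCluster("chr1", bins))
        spans = [cluster_span(c, binning25) for c in clusters]
        th = SpanThresholds.from_spans(spans)
        f = chromosome_features(clusters, th, binning25)
        n = len(clusters)
        assert f.pct_many_gt3 == 100 * sum(c.k > 3 for c in clusters) / n
        assert f.pct_many_gt10 == 100 * sum(c.k > 10 for c in clusters) / n
        assert f.pct_long == 100 * sum(sp > th.upper_quintile for sp in spans) / n
        assert f.pct_long_decile == 100 * sum(sp > th.upper_decile for sp in spans) / n

    def test_order_invariance(self, rng, binning25):
        clusters = [
            BinnedCluster("chr1", tuple(sorted(rng.choice(20, size=3, replace=False).tolist())))
            for _ in range(30)
        ] + [BinnedCluster("chr1", (0, 9))] * 10
        th = SpanThresholds(100_000.0, 200_000.0)
        a = chromosome_features(clusters, th, binning25)
        b = chromosome_features(clusters[::-1], th, binning25)
        assert a == b


class TestRegress:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        res = regress(2 * x + 1, x)
        assert np.isclose(res.slopes["feature"], 2.0)
        assert res.p_values["feature"] < 1e-12
        assert np.isclose(res.intercept, 1.0)

    def test_matches_closed_form_ols(self):
        # worked 5-point dataset, hand OLS: b = Sxy/Sxx, t = b/se
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1.9, 3.8, 4.1, 5.3])
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        resid = yc - slope * xc
        se = np.sqrt(resid @ resid / 3 / (xc @ xc))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(slope / se), df=3)
        res = regress(y, x)
        assert np.isclose(res.slopes["feature"], slope, atol=1e-12)
        assert np.isclose(res.p_values["feature"], p, atol=1e-12)

    def test_length_adjustment_changes_slope(self, rng):
        lengths = rng.uniform(50, 250, size=22)
        x = lengths * 0.01 + rng.normal(0, 0.3, 22)
        y = 0.002 * lengths + rng.normal(0, 0.05, 22)
        un = regress(y, x)
        adj = regress(y, x, adjust_length=True, lengths=lengths)
        assert "length_bp" in adj.slopes
        assert not np.isclose(un.slopes["feature"], adj.slopes["feature"])

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_type_one_error_calibration(self, rng):
        """Permutation of independent y: ~5% of slopes significant at 0.05."""
        n, reps = 22, 500
        x = rng.standard_normal(n)
        hits = 0
        for _ in range(reps):
            y = rng.standard_normal(n)
            hits += regress(y, x).p_values["feature"] < 0.05
        assert 0.04 * reps * 0.8 <= hits <= 0.06 * reps * 1.25  # 4-6% band with slack


class TestDegreeDistanceTable:
    def test_single_cluster_lands_in_right_cell(self):
        c = BinnedCluster("chr1", (0, 600, 1200))  # span 30 Mb at 25 kb, k=3
        table = degree_distance_table([c], 25_000)
        assert table.counts.loc["25-50", "3-mers"] == 1
        assert table.total == 1

    def test_grand_total_conservation(self, rng):
        clusters = [
            BinnedCluster("chr1", tuple(sorted(rng.choice(2000, size=int(m), replace=False).tolist())))
            for m in rng.integers(1, 20, size=200)
        ]
        assert degree_distance_table(clusters, 25_000).total == 200

    def test_matches_brute_force_recount(self, rng):
        breaks = list(range(0, 251, 25))
        strata = [(2, 2), (3, 3), (4, 10), (11, 100), (101, None)]
        clusters = []
        for _ in range(1000):
            m = int(rng.integers(1, 150))
            bins = tuple(sorted(rng.choice(9000, size=m, replace=False).tolist()))
            clusters.append(BinnedCluster("chr1", bins))
        table = degree_distance_table(clusters, 25_000)
        expected = np.zeros((10, 5), dtype=int)
        for c in clusters:
            span_mb = (c.bins[-1] - c.bins[0]) * 25_000 / 1e6
            row = min(int(span_mb // 25), 9)
            col = next(
                i for i, (lo, hi) in enumerate(strata) if lo <= c.k <= (hi or 10**9)
            )
            expected[row, col] += 1
        assert np.array_equal(table.counts.values, expected)

    def test_overflow_goes_to_final_row(self, caplog):
        c = BinnedCluster("chr1", (0, 11_000))  # 275 Mb span at 25 kb
        with caplog.at_level("WARNING"):
            table = degree_distance_table([c], 25_000)
        assert table.counts.loc["225-250", "2-mers"] == 1
        assert "final row" in caplog.text


class TestRegionDominance:
    def make_matrix(self, values):
        return ContactMatrix(values, "chr6", 25_000, "N-W")

    def test_planted_hot_block_is_strict_max(self):
        V = np.ones((30, 30))
        V[3:6, 20:24] += 50
        V[20:24, 3:6] += 50
        res = region_dominance(self.make_matrix(V), (3, 6), (20, 24), (0, 30), diag_exclusion=2)
        assert res.is_strict_max and res.rank == 1

    def test_constant_matrix_all_ties(self):
        V = np.ones((20, 20))
        res = region_dominance(self.make_matrix(V), (0, 2), (10, 12), (0, 20), diag_exclusion=1)
        assert not res.is_strict_max
        assert res.rank == 1  # tied, nothing strictly greater

    def test_rank_matches_exhaustive_enumeration(self, rng):
        V = rng.random((25, 25))
        V = (V + V.T) / 2
        h, w, excl = 3, 4, 2
        res = region_dominance(self.make_matrix(V), (1, 4), (10, 14), (0, 25), excl)
        sums = []
        for r in range(0, 25 - h + 1):
            for c in range(0, 25 - w + 1):
                if c >= r + h:
                    gap = c - (r + h - 1)
                elif r >= c + w:
                    gap = r - (c + w - 1)
                else:
                    gap = 0
                if gap > excl:
                    sums.append(((r, c), V[r : r + h, c : c + w].sum()))
        designated = V[1:4, 10:14].sum()
        rank = 1 + sum(1 for (pos, s) in sums if s > designated + 1e-12)
        assert np.isclose(res.designated_sum, designated)
        assert res.rank == rank
        assert res.n_windows == len(sums)

    def test_window_in_exclusion_band_rejected(self):
        V = np.ones((20, 20))
        with pytest.raises(ValueError, match="exclusion"):
            region_dominance(self.make_matrix(V), (3, 6), (4, 7), (0, 20), diag_exclusion=2)

    def test_window_larger_than_locus_rejected(self):
        V = np.ones((20, 20))
        with pytest.raises(ValueError):
            region_dominance(self.make_matrix(V), (0, 6), (10, 12), (0, 5), 0)
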