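"""CRQA: embedding, recurrence matrix, index quantification, calibration."""

import numpy as np
import pytest

from dyadsync.core import (CalibrationError, InputError, NormalizationError,
                           ParameterError, UniformSeries)
from dyadsync.crqa import (EmbeddingParams, RecurrencePlot, calibrate_radius,
                           cross_recurrence, crqa_metrics, embed, quantify)
from oracles import crqa_oracle


class TestEmbed:
    def test_two_dimensional_unit_delay(self):
        states = embed(np.array([1, 2, 3, 4, 5.0]), m=2, tau=1)
        np.testing.assert_array_equal(
            states, [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_one_dimensional_embedding_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(embed(x, 1, 3).ravel(), x)

    @pytest.mark.parametrize("n,m,tau", [(20, 3, 2), (15, 4, 3), (10, 2, 4)])
    def test_state_count_formula(self, rng, n, m, tau):
        assert embed(rng.normal(size=n), m, tau).shape == (n - (m - 1) * tau, m)

    def test_too_short_series_raises(self):
        with pytest.raises(InputError):
            embed(np.arange(5.0), m=3, tau=3)


class TestCrossRecurrence:
    def test_identical_series_recur_on_the_main_diagonal(self, rng):
        a = UniformSeries(rng.normal(size=40), 3.0)
        p = EmbeddingParams(m=3, tau=2, radius=0.05)
        rp = cross_recurrence(a, a, p)
        assert np.diagonal(rp.matrix).all()
        m = quantify(rp, lmin=2)
        assert m.lmax == rp.shape[0]

    def test_well_separated_series_never_recur(self):
        a = UniformSeries(np.zeros(20), 1.0)
        b = UniformSeries(np.full(20, 100.0), 1.0)
        p = EmbeddingParams(m=2, tau=1, radius=1.0, normalize="none")
        assert not cross_recurrence(a, b, p).matrix.any()

    def test_matrix_matches_brute_force_distances(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        p = EmbeddingParams(m=3, tau=2, radius=0.8, normalize="none")
        rp = cross_recurrence(a, b, p)
        ea, eb = embed(a, 3, 2), embed(b, 3, 2)
        for i in range(ea.shape[0]):
            for j in range(eb.shape[0]):
                d = np.sqrt(((ea[i] - eb[j]) ** 2).sum())
                assert rp.matrix[i, j] == (d <= 0.8)

    def test_zscore_makes_rr_shift_invariant(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        p = EmbeddingParams(radius=0.7)
        m1 = crqa_metrics(UniformSeries(a, 3.0), UniformSeries(b, 3.0), p)
        m2 = crqa_metrics(UniformSeries(a + 42.0, 3.0),
                          UniformSeries(b + 42.0, 3.0), p)
        assert m1.rr == pytest.approx(m2.rr)

    def test_constant_series_with_zscore_raises(self):
        a = UniformSeries(np.ones(20), 1.0)
        with pytest.raises(NormalizationError):
            cross_recurrence(a, a, EmbeddingParams())

    def test_theiler_window_blanks_the_central_band(self, rng):
        a = UniformSeries(rng.normal(size=40), 3.0)
        p = EmbeddingParams(m=2, tau=1, radius=5.0, theiler=3)
        rp = cross_recurrence(a, a, p)
        i, j = np.indices(rp.shape)
        assert not rp.matrix[np.abs(i - j) < 3].any()


class TestQuantify:
    def test_single_full_diagonal_five_by_five(self):
        m = quantify(RecurrencePlot(np.eye(5, dtype=bool)), lmin=2)
        assert m.rr == pytest.approx(0.2)
        assert m.det == pytest.approx(1.0)
        assert m.l_mean == pytest.approx(5.0)
        assert m.lmax == 5
        assert m.entr == pytest.approx(0.0)
        assert np.isnan(m.t2)

    def test_column_run_starts_define_second_type_recurrence_time(self):
        col = np.zeros((10, 3), dtype=bool)
        col[[1, 2, 3, 7, 8], 1] = True  # runs start at rows 1 and 7
        m = quantify(RecurrencePlot(col), lmin=2)
        assert m.t2 == pytest.approx(6.0)

    def test_all_zero_matrix_yields_missing_not_zero(self):
        m = quantify(RecurrencePlot(np.zeros((6, 6), dtype=bool)))
        assert m.rr == 0.0
        assert m.lmax == 0
        assert np.isnan(m.det) and np.isnan(m.l_mean)
        assert np.isnan(m.t2) and np.isnan(m.entr)

    def test_random_matrices_match_enumeration_oracle(self, rng):
        for density in (0.05, 0.2, 0.4):
            for _ in range(10):
                mat = rng.random((30, 30)) < density
                got = quantify(RecurrencePlot(mat), lmin=2).as_dict()
                expected = crqa_oracle(mat, lmin=2)
                for key in expected:
                    np.testing.assert_equal(got[key], expected[key])

    def test_det_bookkeeping_identity(self, rng):
        mat = rng.random((40, 40)) < 0.3
        m = quantify(RecurrencePlot(mat), lmin=2)
        points_on_lines = m.det * mat.sum()
        assert points_on_lines == pytest.approx(round(points_on_lines))


class TestCalibrateRadius:
    def make_pairs(self, rng, n_pairs=4, n=120):
        return [(UniformSeries(rng.normal(size=n), 3.0),
                 UniformSeries(rng.normal(size=n), 3.0))
                for _ in range(n_pairs)]

    def test_bisection_attains_target_rr(self, rng):
        pairs = self.make_pairs(rng)
        p = EmbeddingParams()
        eps = calibrate_radius(pairs, p, target_rr=0.05)
        rrs = [crqa_metrics(a, b, EmbeddingParams(radius=eps)).rr
               for a, b in pairs]
        assert np.mean(rrs) == pytest.approx(0.05, rel=0.10)

    def test_radius_monotone_in_target(self, rng):
        pairs = self.make_pairs(rng)
        eps_small = calibrate_radius(pairs, target_rr=0.03)
        eps_large = calibrate_radius(pairs, target_rr=0.20)
        assert eps_large >= eps_small

    def test_identical_pair_saturates_at_full_recurrence(self, rng):
        a = UniformSeries(rng.normal(size=60), 3.0)
        eps = calibrate_radius([(a, a)], target_rr=1.0)
        assert crqa_metrics(a, a, EmbeddingParams(radius=eps)).rr == 1.0

    def test_empty_dataset_raises(self):
        with pytest.raises(InputError):
            calibrate_radius([], target_rr=0.05)
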