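"""Signal preprocessing, connectivity, Fisher z, and seed-FC group tests."""

import numpy as np
import pytest
from scipy import stats

from connsweep import (
    PreprocessConfig,
    SeedFCMap,
    SubjectTimeSeries,
    correlation_matrix,
    fisher_z,
    group_fc_tests,
    preprocess,
    seed_fc_map,
)
from connsweep.preprocess import bandpass_ideal

TR = 2.34


def make_ts(data, tr=TR, **kw):
    return SubjectTimeSeries(subject_id="s", group="A", data=np.asarray(data, float),
                             tr_seconds=tr, **kw)


class TestPreprocess:
    def test_constant_column_zeroed_by_detrend(self, rng):
        x = rng.standard_normal((60, 3))
        x[:, 1] = 5.0
        out = preprocess(make_ts(x), PreprocessConfig(discard_initial=0,
                                                      include_global_signal=False))
        assert np.abs(out.data[:, 1]).max() < 1e-10

    def test_discards_initial_volumes(self, rng):
        x = rng.standard_normal((120, 4))
        out = preprocess(make_ts(x), PreprocessConfig(discard_initial=4,
                                                      include_global_signal=False))
        assert out.n_timepoints == 116

    @pytest.mark.parametrize(
        "freq,lo,hi", [(0.04, 0.95, 1.05), (0.15, 0.0, 0.05)]
    )
    def test_passband_and_stopband_gain(self, freq, lo, hi):
        t = np.arange(116) * TR
        # bin-aligned frequency nearest the target, so leakage doesn't blur the check
        k = round(freq * 116 * TR)
        f = k / (116 * TR)
        x = np.sin(2 * np.pi * f * t)[:, None]
        y = bandpass_ideal(x, TR, 0.01, 0.08)
        ratio = np.abs(y).max() / np.abs(x).max()
        assert lo <= ratio <= hi

    def test_band_above_nyquist_raises(self, rng):
        ts = make_ts(rng.standard_normal((50, 2)))
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(ts, PreprocessConfig(band_high_hz=0.5))

    def test_filter_is_idempotent(self, rng):
        x = rng.standard_normal((116, 5))
        once = bandpass_ideal(x, TR, 0.01, 0.08)
        twice = bandpass_ideal(once, TR, 0.01, 0.08)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        x = rng.standard_normal((80, 6))
        reg = rng.standard_normal((80, 3))
        out = preprocess(
            make_ts(x),
            PreprocessConfig(discard_initial=0, include_global_signal=True),
            nuisance_regressors=reg,
        )
        assert np.abs(reg.T @ out.data).max() < 1e-8

    def test_regressor_row_mismatch_raises(self, rng):
        x = rng.standard_normal((80, 4))
        with pytest.raises(ValueError, match="regressors"):
            preprocess(make_ts(x), PreprocessConfig(discard_initial=4),
                       nuisance_regressors=rng.standard_normal((50, 2)))

    def test_stored_confounds_used_automatically(self, rng):
        conf = rng.standard_normal((80, 2))
        x = rng.standard_normal((80, 4)) + conf @ rng.standard_normal((2, 4))
        ts = make_ts(x, confounds=conf)
        out = preprocess(ts, PreprocessConfig(discard_initial=0,
                                              include_global_signal=False))
        assert np.abs(conf.T @ out.data).max() < 1e-8


class TestCorrelation:
    def test_identical_columns_give_r_one(self, rng):
        c = rng.standard_normal(50)
        x = np.column_stack([c, c, rng.standard_normal(50)])
        conn = correlation_matrix(make_ts(x))
        assert conn.r_matrix[0, 1] == pytest.approx(1.0)

    def test_negated_column_gives_r_minus_one(self, rng):
        c = rng.standard_normal(50)
        conn = correlation_matrix(make_ts(np.column_stack([c, -c])))
        assert conn.r_matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self, rng):
        x = rng.standard_normal((40, 4))
        conn = correlation_matrix(make_ts(x))
        for i in range(4):
            for j in range(i + 1, 4):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert conn.r_matrix[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_raises_naming_roi(self, rng):
        x = rng.standard_normal((40, 3))
        x[:, 2] = 1.0
        with pytest.raises(ValueError, match="ROI003"):
            correlation_matrix(make_ts(x))

    def test_affine_rescaling_invariance(self, rng):
        x = rng.standard_normal((60, 4))
        conn1 = correlation_matrix(make_ts(x))
        x2 = x.copy()
        x2[:, 1] = 3.5 * x2[:, 1] + 7.0
        conn2 = correlation_matrix(make_ts(x2))
        np.testing.assert_allclose(conn1.r_matrix, conn2.r_matrix, atol=1e-12)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected,tol",
        [(0.0, 0.0, 0.0), (np.tanh(1.0), 1.0, 1e-4), (-0.5, -0.54931, 1e-5)],
    )
    def test_closed_form_values(self, r, expected, tol):
        assert fisher_z(r) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_odd_function(self, rng):
        r = rng.uniform(-0.99, 0.99, 25)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-14)

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_matrix_diagonal_left_at_zero(self, rng):
        r = rng.uniform(-0.8, 0.8, (4, 4))
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, 0.0)
        z = fisher_z(r)
        assert (np.diag(z) == 0).all()
        assert z[0, 1] == pytest.approx(np.arctanh(r[0, 1]))


class TestSeedFC:
    def test_duplicate_target_triggers_error_path(self, rng):
        s = rng.standard_normal(60)
        x = np.column_stack([s, s, rng.standard_normal(60)])
        with pytest.raises(ValueError):
            seed_fc_map(make_ts(x), seed_rois=[1])

    def test_two_seed_rois_equal_to_target_error_path(self, rng):
        s = rng.standard_normal(60)
        x = np.column_stack([s, s, s])
        with pytest.raises(ValueError):
            seed_fc_map(make_ts(x), seed_rois=[1, 2])

    def test_planted_correlation_recovered_in_z(self):
        from connsweep import simulate_subject
        from connsweep.cohort import CohortSpec, BaseGraphConfig, NuisanceConfig

        spec = CohortSpec(
            n_rois=3, n_volumes=5000, ar_coefficient=0.0,
            nuisance=NuisanceConfig(0.0, 0.0, 0.0),
            base_graph=BaseGraphConfig(neighbors_k=2, rewire_prob=0.0),
            effect_rois=(),
        )
        cov = np.eye(3)
        cov[0, 1] = cov[1, 0] = 0.6
        subj = simulate_subject(cov, spec, subject_seed=5)
        fc = seed_fc_map(subj, seed_rois=[1])
        assert np.arctanh(0.55) <= fc.z_values[0] <= np.arctanh(0.65)


class TestGroupFCTests:
    def _maps(self, z):
        return [SeedFCMap(seed_label="s", z_values=row) for row in z]

    def test_identical_groups_give_t_zero_p_one(self, rng):
        z = rng.standard_normal((4, 6))
        out = group_fc_tests(self._maps(z), self._maps(z))
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p_uncorrected"], 1.0)

    def test_zero_variance_degenerate_gives_nan_not_raise(self):
        za = np.zeros((3, 2))
        zb = np.ones((3, 2))
        out = group_fc_tests(self._maps(za), self._maps(zb))
        assert np.isnan(out["p_uncorrected"]).all() or np.isinf(np.abs(out["t"])).all()

    def test_mismatched_lengths_raise(self, rng):
        with pytest.raises(ValueError):
            group_fc_tests(self._maps(rng.standard_normal((3, 5))),
                           self._maps(rng.standard_normal((3, 4))))

    def test_type_i_error_calibration(self, rng):
        # 1000 null simulations at n = 17 vs 16; alpha 0.05
        n_sim = 1000
        rejections = 0
        for _ in range(n_sim):
            za = rng.standard_normal((17, 1))
            zb = rng.standard_normal((16, 1))
            t, p = stats.ttest_ind(za, zb, axis=0, equal_var=True)
            out = group_fc_tests(self._maps(za), self._maps(zb))
            assert out["p_uncorrected"].iloc[0] == pytest.approx(p[0])
            if out["p_uncorrected"].iloc[0] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_sim <= 0.065

    def test_fdr_is_monotone_in_p(self, rng):
        za = rng.standard_normal((10, 8))
        zb = rng.standard_normal((9, 8)) + 0.5
        out = group_fc_tests(self._maps(za), self._maps(zb))
        order = np.argsort(out["p_uncorrected"].to_numpy())
        q_sorted = out["q_fdr"].to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()
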