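"""Sparsity sweep, AUC integration, permutation inference, and correlations."""

import numpy as np
import pandas as pd
import pytest

from connsweep import (
    MetricCurve,
    SparsityGrid,
    auc,
    correlate_training,
    flag_changed_regions,
    permutation_test,
    permutation_test_table,
    run_sweep,
)
from connsweep import CohortSpec, correlation_matrix, generate_cohort, preprocess
from connsweep.nulls import NullConfig
from connsweep.preprocess import PreprocessConfig


class TestGrid:
    def test_default_grid_has_33_points(self):
        grid = SparsityGrid()
        vals = grid.values()
        assert vals.size == 33
        assert vals[0] == pytest.approx(0.10)
        assert vals[-1] == pytest.approx(0.42)

    def test_single_point_grid(self):
        grid = SparsityGrid(s_min=0.2, s_max=0.2, s_step=0.01)
        assert grid.n_points == 1


@pytest.fixture(scope="module")
def small_subject_conn():
    from connsweep import BaseGraphConfig

    spec = CohortSpec(
        n_group_a=1, n_group_b=1, n_rois=40,
        base_graph=BaseGraphConfig(neighbors_k=6, rewire_prob=0.1),
        effect_rois=(), seed=21,
    )
    subjects, _ = generate_cohort(spec)
    return correlation_matrix(preprocess(subjects[0], PreprocessConfig()))


class TestRunSweep:
    def test_curve_counts(self, small_subject_conn):
        sw = run_sweep(small_subject_conn, SparsityGrid(), null_cfg=NullConfig(n_null=3), seed=2)
        assert len(sw.global_curves) == 7
        assert len(sw.nodal_curves) == 3
        assert all(v.size == 33 for v in sw.global_curves.values())
        assert all(v.shape == (40, 33) for v in sw.nodal_curves.values())

    def test_single_point_grid_curves(self, small_subject_conn):
        grid = SparsityGrid(s_min=0.2, s_max=0.2, s_step=0.01)
        sw = run_sweep(small_subject_conn, grid, null_cfg=None)
        assert all(v.size == 1 for v in sw.global_curves.values())

    def test_e_glob_curve_nondecreasing_in_sparsity(self, small_subject_conn):
        sw = run_sweep(small_subject_conn, SparsityGrid(), null_cfg=None)
        assert (np.diff(sw.global_curves["e_glob"]) >= -1e-12).all()


class TestAUC:
    def test_constant_curve(self):
        grid = SparsityGrid()
        rec = auc(MetricCurve("c_p", np.ones(33)), grid)
        assert rec.auc == pytest.approx(0.32)

    def test_linear_curve_exact(self):
        grid = SparsityGrid()
        rec = auc(MetricCurve("x", grid.values()), grid)
        assert rec.auc == pytest.approx(0.5 * (0.10 + 0.42) * 0.32, abs=1e-12)

    def test_trapezoid_converges_to_riemann_at_halved_step(self, rng):
        f = lambda s: np.sin(8 * s) + s**2
        coarse = SparsityGrid(0.10, 0.42, 0.01)
        fine = SparsityGrid(0.10, 0.42, 0.005)
        a_coarse = float(auc(f(coarse.values()), coarse))
        a_fine = float(auc(f(fine.values()), fine))
        # trapezoid error is O(step^2): halving the step quarters the error
        exact = a_fine + (a_fine - a_coarse) / 3  # Richardson limit
        assert abs(a_coarse - exact) < 4.5 * abs(a_fine - exact) + 1e-12

    def test_nonfinite_curve_flagged(self):
        grid = SparsityGrid()
        vals = np.ones(33)
        vals[5] = np.inf
        rec = auc(MetricCurve("l_p", vals), grid)
        assert rec.flagged_nonfinite and np.isnan(rec.auc)


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        res = permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=100, seed=1)
        assert res.observed_diff == 0.0
        assert res.p_two_sided == 1.0

    def test_exhaustive_three_vs_three(self):
        # C(6,3) = 20 splits; |diff| = 1 attained by exactly 2 of them
        res = permutation_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], n_perm=1000, seed=1)
        assert res.exhaustive
        assert res.p_two_sided == pytest.approx(0.1)

    def test_affine_invariance(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(7)
        p1 = permutation_test(a, b, n_perm=500, seed=3).p_two_sided
        p2 = permutation_test(5.0 * a - 2.0, 5.0 * b - 2.0, n_perm=500, seed=3).p_two_sided
        assert p1 == pytest.approx(p2)

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(9) + 0.6
        res_ex = permutation_test(a, b, n_perm=10**6, seed=1)  # exhaustive (92378 splits)
        assert res_ex.exhaustive
        p_mc = permutation_test(a, b, n_perm=2000, seed=2)
        assert not p_mc.exhaustive
        assert abs(p_mc.p_two_sided - res_ex.p_two_sided) <= 2 / np.sqrt(2000) + 1e-9

    def test_add_one_correction_never_zero(self, rng):
        a = rng.standard_normal(10) + 50
        b = rng.standard_normal(10)
        res = permutation_test(a, b, n_perm=200, seed=4)
        assert res.p_two_sided > 0

    def test_type_i_calibration(self, rng):
        n_sim, n_perm = 1000, 1000
        rej = 0
        for k in range(n_sim):
            a = rng.standard_normal(17)
            b = rng.standard_normal(16)
            if permutation_test(a, b, n_perm=n_perm, seed=k).p_two_sided < 0.05:
                rej += 1
        assert 0.035 <= rej / n_sim <= 0.065

    def test_table_matches_scalar(self, rng):
        a = pd.DataFrame(rng.standard_normal((6, 3)), columns=list("xyz"))
        b = pd.DataFrame(rng.standard_normal((5, 3)), columns=list("xyz"))
        tbl = permutation_test_table(a, b, n_perm=10**5, seed=1)  # exhaustive (462)
        for col in "xyz":
            res = permutation_test(a[col], b[col], n_perm=10**5, seed=9)
            assert tbl.loc[col, "p"] == pytest.approx(res.p_two_sided)


class TestFlagging:
    def _tables(self, p_by_metric):
        out = {}
        for m, pvals in p_by_metric.items():
            out[m] = pd.DataFrame(
                {"metric": m, "observed_diff": np.ones(len(pvals)), "p": pvals,
                 "direction": "A>B"},
                index=[f"R{i}" for i in range(len(pvals))],
            )
        return out

    def test_all_p_one_flags_nothing(self):
        tables = self._tables({m: np.ones(4) for m in ("degree", "efficiency", "betweenness")})
        assert flag_changed_regions(tables).empty

    def test_single_sub_threshold_region_flagged(self):
        p = np.full(4, 0.9)
        p[2] = 0.04
        tables = self._tables({"degree": p, "efficiency": np.full(4, 0.9),
                               "betweenness": np.full(4, 0.9)})
        flagged = flag_changed_regions(tables)
        assert list(flagged.index) == ["R2"]

    def test_union_rule_over_metrics(self):
        tables = self._tables({"degree": np.array([0.9, 0.9]),
                               "efficiency": np.array([0.01, 0.9]),
                               "betweenness": np.array([0.9, 0.03])})
        flagged = flag_changed_regions(tables)
        assert list(flagged.index) == ["R0", "R1"]


class TestCorrelateTraining:
    def test_perfect_proportionality(self):
        years = np.array([8.0, 10.0, 12.0, 14.0, 16.0])
        aucs = pd.DataFrame({"r1": 2.0 * years})
        out = correlate_training(aucs, years)
        assert out.loc["r1", "r"] == pytest.approx(1.0)
        assert out.loc["r1", "p"] < 1e-6

    def test_constant_training_gives_nan(self):
        aucs = pd.DataFrame({"r1": [1.0, 2.0, 3.0]})
        out = correlate_training(aucs, [5.0, 5.0, 5.0])
        assert np.isnan(out.loc["r1", "r"])

    def test_bonferroni_uses_family_divisor(self, rng):
        x = rng.standard_normal((17, 4))
        years = rng.standard_normal(17)
        out = correlate_training(pd.DataFrame(x), years, alpha_family=0.05,
                                 n_comparisons=110)
        assert ((out["p"] < 0.05 / 110) == out["significant_bonferroni"]).all()

    def test_critical_value_calibration(self, rng):
        # |r| must exceed the two-sided 0.05 critical value ~0.482 at n = 17
        from scipy import stats

        tcrit = stats.t.ppf(0.975, 15)
        rcrit = np.sqrt(tcrit**2 / (tcrit**2 + 15))
        n_sim = 1000
        hits = 0
        for k in range(n_sim):
            x = rng.standard_normal((17, 1))
            y = rng.standard_normal(17)
            out = correlate_training(pd.DataFrame(x), y)
            r, p = out["r"].iloc[0], out["p"].iloc[0]
            assert (p < 0.05) == (abs(r) > rcrit - 1e-12)
            if abs(r) > rcrit:
                hits += 1
        assert 0.035 <= hits / n_sim <= 0.065
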