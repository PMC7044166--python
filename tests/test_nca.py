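import numpy as np
import pytest

import quantpk as q
from quantpk.nca import NCAError


class TestCmaxTmax:
    def test_argmax(self, make_profile):
        p = make_profile([0, 1, 2, 4], [0, 10, 50, 30])
        assert q.cmax_tmax(p) == (50.0, 2.0)

    def test_tie_broken_earliest(self, make_profile):
        p = make_profile([0, 1, 2, 4], [0, 10, 50, 50])
        assert q.cmax_tmax(p) == (50.0, 2.0)

    def test_dense_grid_matches_closed_form(self):
        params = q.PKParams(ka=1.0, ke=0.1, V_F=1.0, dose=1000.0)
        t = np.round(np.linspace(0, 48, 4801), 6)
        c = q.simulate_parent(params, t)
        prof = q.ConcentrationTimeProfile("s", "g", "TAM", t, c,
                                          np.zeros_like(t, bool), 1000.0)
        _, tmax = q.cmax_tmax(prof)
        closed = np.log(params.ka / params.ke) / (params.ka - params.ke)
        assert abs(tmax - closed) <= 0.01  # one grid step

    def test_all_blq_errors(self, make_profile):
        p = make_profile([0, 1], [0, 0], blq=[True, True])
        with pytest.raises(NCAError):
            q.cmax_tmax(p)


class TestTerminalKel:
    def test_exact_exponential_tail(self, make_profile):
        t = np.array([0.0, 12.0, 24.0, 48.0])
        c = np.where(t > 0, 100.0 * np.exp(-0.1 * t), 0.0)
        p = make_profile(t, c, blq=(t == 0))
        fit = q.terminal_kel(p)
        assert fit.kel == pytest.approx(0.1, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 3

    def test_published_kel_gives_printed_half_life(self):
        assert q.half_life(0.0386) == pytest.approx(17.95, abs=0.005)

    def test_noisy_tail_recovery_within_10pct(self, dsv_params, paper_times):
        rng = np.random.default_rng(42)
        errs = []
        truth = q.simulate_parent(dsv_params, paper_times)
        for _ in range(200):
            measured, blq = q.add_assay_noise(truth, 0.05, 0.0, 20.0, rng)
            prof = q.ConcentrationTimeProfile(
                "s", "I", "DSV", paper_times, np.where(blq, 0, measured), blq,
                dsv_params.dose)
            fit = q.terminal_kel(prof)
            errs.append(abs(fit.kel - dsv_params.ke) / dsv_params.ke)
        assert np.median(errs) < 0.10

    def test_rising_tail_errors(self, make_profile):
        p = make_profile([0, 1, 2, 4, 8, 12], [0, 50, 10, 11, 12, 13])
        with pytest.raises(NCAError, match="slope"):
            q.terminal_kel(p)

    def test_too_few_points_errors(self, make_profile):
        p = make_profile([0, 1, 2], [0, 10, 5])
        with pytest.raises(NCAError):
            q.terminal_kel(p)

    def test_fixed_window_override(self, make_profile, dsv_params, paper_times):
        c = q.simulate_parent(dsv_params, paper_times)
        p = make_profile(paper_times, c, blq=(c == 0), analyte="DSV",
                         dose=dsv_params.dose)
        fit = q.terminal_kel(p, window=(12.0, 48.0))
        assert fit.n_points == 3
        assert fit.kel == pytest.approx(dsv_params.ke, rel=1e-3)


class TestHalfLife:
    def test_unit(self):
        assert q.half_life(0.693) == 1.0

    def test_uses_0693_not_ln2(self):
        assert q.half_life(1.0) == 0.693
        assert q.half_life(1.0, constant=np.log(2)) == np.log(2)

    def test_involution(self):
        rng = np.random.default_rng(1)
        for x in rng.uniform(0.1, 100, size=20):
            assert q.half_life(0.693 / x) == pytest.approx(x, rel=1e-12)

    def test_nonpositive_errors(self):
        with pytest.raises(NCAError):
            q.half_life(0.0)


class TestAUC:
    def test_triangle(self, make_profile):
        assert q.auc_trapezoid(make_profile([0, 1], [0, 2])) == 1.0

    def test_rectangle(self, make_profile):
        t = [0, 6, 12, 24, 48]
        assert q.auc_trapezoid(make_profile(t, [10] * 5)) == 480.0

    def test_dense_exponential_and_coarse_overestimate(self, make_profile):
        analytic = 1000.0 * (1 - np.exp(-4.8))
        t_dense = np.linspace(0, 48, 2001)
        dense = q.auc_trapezoid(make_profile(t_dense, 100 * np.exp(-0.1 * t_dense)))
        assert dense == pytest.approx(analytic, rel=5e-3)
        t_coarse = np.array([0, 0.25, 0.5, 1, 2, 4, 5, 12, 24, 48.0])
        coarse = q.auc_trapezoid(make_profile(t_coarse, 100 * np.exp(-0.1 * t_coarse)))
        assert coarse > analytic  # convexity of exponential decay

    def test_additive_over_split(self, make_profile, rng):
        t = np.sort(rng.uniform(0.1, 48, size=9))
        t = np.concatenate([[0.0], t])
        c = rng.uniform(0, 100, size=10)
        full = q.auc_trapezoid(make_profile(t, c))
        k = 5
        left = np.trapezoid(c[:k + 1], t[:k + 1])
        right = np.trapezoid(c[k:], t[k:])
        assert full == pytest.approx(left + right, rel=1e-12)

    def test_brute_force_oracle(self, make_profile, rng):
        t = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 48, size=9))])
        c = rng.uniform(0, 100, size=10)
        brute = sum((t[i + 1] - t[i]) * (c[i] + c[i + 1]) / 2 for i in range(9))
        assert q.auc_trapezoid(make_profile(t, c)) == pytest.approx(brute, rel=1e-12)


class TestExtrapolation:
    def test_zero_tail(self):
        auc, pct = q.auc_extrapolate(900.0, 0.0, 0.1)
        assert auc == 900.0 and pct == 0.0

    def test_arithmetic(self):
        auc, pct = q.auc_extrapolate(900.0, 10.0, 0.1)
        assert auc == 1000.0 and pct == pytest.approx(10.0)

    def test_full_run_close_to_closed_form(self, tam_params, paper_times,
                                           make_noise_free_profile):
        prof = make_noise_free_profile(tam_params, paper_times)
        res = q.run_nca(prof)
        assert res.auc_0_inf == pytest.approx(
            tam_params.dose / (tam_params.V_F * tam_params.ke), rel=0.05)

    def test_bad_kel_errors(self):
        with pytest.raises(NCAError):
            q.auc_extrapolate(900.0, 10.0, 0.0)


class TestClearance:
    def test_table_inputs(self):
        assert q.clearance(10e6, 3878.94) == pytest.approx(10e6 / 3878.94)
        assert q.clearance(10e6, 3878.94) == pytest.approx(2578.0, rel=2e-4)

    def test_identity_and_scaling(self):
        assert q.clearance(100.0, 100.0) == 1.0
        assert q.clearance(100.0, 50.0) == 2.0 * q.clearance(100.0, 100.0)

    def test_nonpositive_errors(self):
        with pytest.raises(NCAError):
            q.clearance(0.0, 1.0)


class TestRunNCA:
    def test_composition_and_invariants(self, dsv_params, paper_times,
                                        make_noise_free_profile):
        prof = make_noise_free_profile(dsv_params, paper_times, analyte="DSV")
        res = q.run_nca(prof)
        assert res.auc_0_inf >= res.auc_0_t
        assert res.t_half == pytest.approx(0.693 / res.kel, rel=1e-12)
        assert 0 <= res.extrap_pct < 100
        assert res.kel == pytest.approx(dsv_params.ke, rel=0.05)
        assert res.cl_f == pytest.approx(dsv_params.dose / res.auc_0_inf, rel=1e-12)

    def test_metabolite_has_no_clearance(self, tam_params, paper_times,
                                         make_noise_free_profile):
        prof = make_noise_free_profile(tam_params, paper_times, analyte="TOH",
                                       metabolite=True)
        assert q.run_nca(prof).cl_f is None

    def test_blq_point_after_last_quantifiable_is_ignored(self, make_profile):
        t = np.array([0, 1, 2, 4, 12, 24, 48.0])
        c = np.array([0, 50, 80, 60, 30, 15, 0.0])
        base = make_profile(t, c, blq=(c == 0))
        t2 = np.append(t, 72.0)
        c2 = np.append(c, 0.0)
        blq2 = np.append(c == 0, True)
        extended = make_profile(t2, c2, blq=blq2)
        a, b = q.run_nca(base), q.run_nca(extended)
        assert (a.cmax, a.tmax, a.kel, a.auc_0_t, a.auc_0_inf) == \
               (b.cmax, b.tmax, b.kel, b.auc_0_t, b.auc_0_inf)


class TestGroupStats:
    def test_rb_trivial_and_published(self):
        assert q.relative_bioavailability(100.0, 100.0) == 100.0
        assert q.relative_bioavailability(4662.32, 4268.14) == pytest.approx(109.0, rel=0.005)
        assert q.relative_bioavailability(3507.87, 3878.94) == pytest.approx(90.0, rel=0.005)

    def test_rb_bootstrap_mode(self, rng):
        a = np.array([100.0, 110, 90, 105, 95])
        mean, sd = q.relative_bioavailability(a, a, mode="bootstrap_pairs",
                                              rng=rng, n_boot=4000)
        assert mean == pytest.approx(100.0, abs=2.0)
        assert sd > 0

    def test_mr_trivial_and_published(self):
        assert q.metabolite_ratio(50.0, 50.0) == 100.0
        assert q.metabolite_ratio(4727.49, 3878.94) == pytest.approx(121.86, abs=0.05)
        assert q.metabolite_ratio(4547.03, 3507.87) == pytest.approx(129.65, abs=0.05)

    def test_identical_groups(self):
        cmp_ = q.compare_groups([1.0, 2, 3], [1.0, 2, 3])
        assert cmp_.t_stat == 0.0 and cmp_.p_value == 1.0 and not cmp_.significant

    def test_shifted_groups_significant(self):
        cmp_ = q.compare_groups([1.0, 2, 3], [11.0, 12, 13])
        assert cmp_.significant
        # textbook pooled t: diff / (sp * sqrt(2/n)) with sp = 1
        assert cmp_.t_stat == pytest.approx(10.0 / (1.0 * np.sqrt(2 / 3)), rel=1e-9)

    def test_zero_variance_equal_means_p1(self):
        cmp_ = q.compare_groups([5.0, 5.0], [5.0, 5.0])
        assert cmp_.p_value == 1.0

    def test_type_i_error_rate(self, rng):
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            if q.compare_groups(a, b).significant:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)


class TestTable5:
    def _results(self, seed):
        ds = q.simulate_study(q.default_design(seed=seed), q.default_base_params())
        single, combo = {}, {}
        for p in ds.profiles:
            r = q.run_nca(p)
            (combo if r.group == "III" else single).setdefault(r.analyte, []).append(r)
        return single, combo

    def test_structure(self):
        single, combo = self._results(11)
        df = q.build_table5(single, combo)
        assert set(df.analyte) == {"DSV", "TAM", "TOH"}
        params = set(df.parameter)
        assert {"cmax", "tmax", "t_half", "auc_0_inf", "cl_f", "rb_pct",
                "mr_pct_single", "mr_pct_combo"} <= params
        # no CL/F row for the metabolite
        assert not ((df.analyte == "TOH") & (df.parameter == "cl_f")).any()

    def test_formatting_marks_significance(self):
        single, combo = self._results(11)
        df = q.build_table5(single, combo)
        text = q.format_table5(df)
        assert "R.B." in text or "rb_pct" in text
        assert "+/-" in text
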