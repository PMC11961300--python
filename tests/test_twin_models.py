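"""Twin-model engine: expected covariances, ML fitting, LRT/AIC
selection, profile CIs and heritability."""

import numpy as np
import pytest
from scipy import stats

from archtwin.simulate import (
    GeneratorConfig,
    VarianceShares,
    pairs_to_frame,
    simulate_pairs,
)
from archtwin.twin_models import (
    FitResult,
    GroupedTwinData,
    PathParams,
    TwinModelSpec,
    expected_cov,
    fit,
    heritability,
    lrt,
    profile_ci,
    select_model,
    standardized_shares,
    twin_icc,
)


def make_data(shares, seed=0, n_pairs=None, include_os=False, **kw):
    n_pairs = n_pairs or ({"MZF": 45, "MZM": 45, "DZF": 33, "DZM": 33, "DZOS": 32}
                          if include_os else
                          {"MZF": 45, "MZM": 45, "DZF": 49, "DZM": 49})
    cfg = GeneratorConfig(shares_f=shares, seed=seed, n_pairs=n_pairs, **kw)
    return GroupedTwinData.from_frame(pairs_to_frame(simulate_pairs(cfg)))


def pooled_params(**shares):
    p = {k.upper(): np.sqrt(v) for k, v in shares.items()}
    return PathParams(paths_f=p, paths_m=p)


class TestExpectedCov:
    def test_pure_additive_identities(self):
        p = pooled_params(a=1.0)
        assert expected_cov(p, "DZF")[0, 1] == pytest.approx(0.5, abs=1e-15)
        assert expected_cov(p, "MZF")[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_pure_dominance_dz_quarter(self):
        p = pooled_params(d=1.0)
        assert expected_cov(p, "DZM")[0, 1] == pytest.approx(0.25, abs=1e-15)
        assert expected_cov(p, "MZM")[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_pure_shared_environment_equal_mz_dz(self):
        p = pooled_params(c=1.0)
        for g in ("MZF", "MZM", "DZF", "DZM", "DZOS"):
            assert expected_cov(p, g)[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_pure_e_uncorrelated_everywhere(self):
        p = pooled_params(e=1.0)
        for g in ("MZF", "DZF", "DZOS"):
            assert expected_cov(p, g)[0, 1] == 0.0

    def test_opposite_sex_covariance_formula(self):
        p = PathParams(paths_f={"A": 2.0, "C": 1.0, "E": 0.5},
                       paths_m={"A": 1.0, "C": 0.8, "E": 1.0}, rA=0.4)
        want = 0.4 * 2.0 * 1.0 + 1.0 * 1.0 * 0.8
        assert expected_cov(p, "DZOS")[0, 1] == pytest.approx(want, abs=1e-12)

    def test_matrices_symmetric_psd_and_mz_geq_dz(self, rng):
        for _ in range(100):
            raw = rng.uniform(0.05, 1.0, size=3)
            p = pooled_params(a=raw[0], c=raw[1], e=raw[2])
            mz, dz = expected_cov(p, "MZF"), expected_cov(p, "DZF")
            for m in (mz, dz):
                assert m[0, 1] == m[1, 0]
                assert np.all(np.linalg.eigvalsh(m) >= -1e-12)
            assert mz[0, 1] >= dz[0, 1]


class TestTwinICC:
    def test_identical_pair_values_give_one(self):
        pairs = np.column_stack([np.arange(10.0), np.arange(10.0)])
        data = GroupedTwinData({"MZF": pairs})
        assert twin_icc(data, "MZ", n_boot=50).estimate == pytest.approx(1.0, abs=1e-12)

    def test_six_pair_hand_dataset_matches_anova_oracle(self):
        pairs = np.array([[3.0, 4.0], [5.0, 5.5], [2.0, 1.0],
                          [6.0, 7.0], [4.5, 4.0], [1.0, 2.5]])
        # independent route: one-way F statistic per pair-group,
        # ICC = (F - 1)/(F + 1) for two members per group
        F = stats.f_oneway(*[pairs[i] for i in range(6)]).statistic
        oracle = (F - 1) / (F + 1)
        data = GroupedTwinData({"DZM": pairs})
        assert twin_icc(data, "DZ", n_boot=10).estimate == pytest.approx(
            oracle, abs=1e-12)

    def test_pure_additive_dz_icc_near_half(self):
        data = make_data(VarianceShares(a2=1.0, e2=0.0), seed=3,
                         n_pairs={"DZF": 25000, "DZM": 25000})
        assert twin_icc(data, "DZ", n_boot=10).estimate == pytest.approx(0.5, abs=0.02)

    def test_bootstrap_mean_close_to_estimate(self):
        data = make_data(VarianceShares(a2=0.7, e2=0.3), seed=4)
        res = twin_icc(data, "MZ", n_boot=500, seed=11)
        assert res.replicates.mean() == pytest.approx(res.estimate,
                                                      abs=2 * res.boot_se)

    def test_zero_variance_rejected(self):
        data = GroupedTwinData({"MZF": np.ones((5, 2))})
        with pytest.raises(ZeroDivisionError):
            twin_icc(data, "MZ", n_boot=5)


class TestSpecValidation:
    def test_e_always_required(self):
        with pytest.raises(ValueError, match="E is always included"):
            TwinModelSpec(("A", "C"))

    def test_c_d_confounded(self):
        with pytest.raises(ValueError, match="confounded"):
            TwinModelSpec(("A", "C", "D", "E"))

    def test_qualitative_auto_correlation(self):
        assert TwinModelSpec(("A", "C", "E"), "qualitative").free_correlation == "rA"
        assert TwinModelSpec(("A", "D", "E"), "qualitative").free_correlation == "rD"
        assert TwinModelSpec(("C", "E"), "qualitative").free_correlation == "rC"

    def test_parameter_counts(self):
        assert TwinModelSpec(("A", "E")).n_parameters(("F", "M")) == 4
        assert TwinModelSpec(("A", "C", "E"), "quantitative").n_parameters(("F", "M")) == 8
        assert TwinModelSpec(("A", "C", "E"), "qualitative").n_parameters(("F", "M")) == 9


class TestFit:
    def test_ae_recovery_close_to_truth(self):
        data = make_data(VarianceShares(a2=0.85, e2=0.15), seed=1,
                         n_pairs={"MZF": 2000, "MZM": 2000, "DZF": 2000, "DZM": 2000})
        f = fit(TwinModelSpec(("A", "E")), data, seed=0)
        assert f.components["pooled"].shares["A"] == pytest.approx(0.85, abs=0.03)

    def test_independence_limit_gives_pure_e(self):
        data = make_data(VarianceShares(e2=1.0), seed=2,
                         n_pairs={"MZF": 3000, "DZF": 3000})
        f = fit(TwinModelSpec(("A", "E")), data, seed=0)
        assert f.components["pooled"].shares["A"] < 0.05
        assert f.components["pooled"].shares["E"] > 0.95

    def test_optimum_dominates_generating_parameters(self):
        from archtwin.twin_models import _loglik_groups

        truth_shares = VarianceShares(a2=0.6, e2=0.4)
        for seed in range(5):
            data = make_data(truth_shares, seed=seed)
            f = fit(TwinModelSpec(("A", "E")), data, seed=0)
            truth = PathParams(paths_f={"A": np.sqrt(0.6), "E": np.sqrt(0.4)},
                               paths_m={"A": np.sqrt(0.6), "E": np.sqrt(0.4)})
            ll_truth = _loglik_groups(data, {"F": 0.0, "M": 0.0}, truth)
            assert f.loglik >= ll_truth - 1e-6

    def test_standardized_shares_sum_to_one_h2_in_unit_interval(self):
        data = make_data(VarianceShares(a2=0.5, c2=0.2, e2=0.3), seed=7,
                         include_os=True)
        for spec in (TwinModelSpec(("A", "C", "E")),
                     TwinModelSpec(("A", "C", "E"), "quantitative"),
                     TwinModelSpec(("A", "C", "E"), "qualitative")):
            f = fit(spec, data, seed=0)
            for vc in f.components.values():
                assert sum(vc.shares.values()) == pytest.approx(1.0, abs=1e-8)
                assert 0.0 <= vc.h2 <= 1.0

    def test_nesting_chain_loglik_monotone(self):
        for seed in (11, 12, 13):
            data = make_data(VarianceShares(a2=0.5, c2=0.2, e2=0.3), seed=seed)
            ace = fit(TwinModelSpec(("A", "C", "E")), data, seed=0)
            ae = fit(TwinModelSpec(("A", "E")), data, seed=0)
            e = fit(TwinModelSpec(("E",)), data, seed=0)
            assert ace.loglik >= ae.loglik - 1e-6
            assert ae.loglik >= e.loglik - 1e-6

    def test_fit_deterministic_given_seed(self):
        data = make_data(VarianceShares(a2=0.7, e2=0.3), seed=5)
        f1 = fit(TwinModelSpec(("A", "E")), data, seed=9)
        f2 = fit(TwinModelSpec(("A", "E")), data, seed=9)
        assert f1.loglik == f2.loglik
        assert f1.components["pooled"].shares == f2.components["pooled"].shares

    def test_recovers_covariance_sampled_directly_from_model(self, rng):
        # oracle equivalence: data drawn straight from the expected
        # covariance matrices, then refitted
        p = pooled_params(a=np.sqrt(0.6), e=np.sqrt(0.4))
        groups = {}
        for g, n in (("MZF", 20000), ("DZF", 20000)):
            groups[g] = rng.multivariate_normal([0, 0], expected_cov(p, g), size=n)
        data = GroupedTwinData(groups)
        f = fit(TwinModelSpec(("A", "E")), data, seed=0)
        for g in groups:
            emp = np.cov(groups[g].T)
            mod = expected_cov(f.params, g)
            assert np.allclose(mod, emp, atol=4 * 1.0 / np.sqrt(20000) * 2)

    def test_group_minimum_size_enforced(self):
        data = GroupedTwinData({"MZF": np.random.default_rng(0).normal(size=(2, 2)),
                                "DZF": np.random.default_rng(1).normal(size=(50, 2))})
        with pytest.raises(ValueError, match="fewer than 3"):
            fit(TwinModelSpec(("A", "E")), data)


class TestLRT:
    def _mock(self, loglik, k, spec=None):
        return FitResult(spec=spec or TwinModelSpec(("A", "E")), data=None,
                         means={}, params=pooled_params(a=1.0), loglik=loglik,
                         k=k, components={}, grad_norm=0.0, n_starts=1, seed=0)

    def test_identical_fits_chi2_zero_p_one(self):
        full, sub = self._mock(-100.0, 4), self._mock(-100.0, 3)
        chi2, df, p = lrt(full, sub)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_hand_example_chi2_five(self):
        full, sub = self._mock(-100.0, 4), self._mock(-102.5, 3)
        chi2, df, p = lrt(full, sub)
        assert chi2 == pytest.approx(5.0, abs=1e-12)
        assert p == pytest.approx(0.0253, abs=2e-4)

    def test_nesting_violation_detected(self):
        full, sub = self._mock(-105.0, 4), self._mock(-100.0, 3)
        with pytest.raises(ValueError, match="nesting violated"):
            lrt(full, sub)

    def test_boundary_null_rejection_rate_conservative(self):
        # AE truth, ACE vs AE: testing c2 = 0 on the boundary makes the
        # naive chi-square test conservative
        rej = 0
        reps = 200
        for i in range(reps):
            data = make_data(VarianceShares(a2=0.6, e2=0.4), seed=5000 + i,
                             n_pairs={"MZF": 60, "MZM": 60, "DZF": 60, "DZM": 60})
            ace = fit(TwinModelSpec(("A", "C", "E")), data, seed=0, n_starts=2)
            ae = fit(TwinModelSpec(("A", "E")), data, seed=0, n_starts=2)
            _, _, p = lrt(ace, ae)
            rej += p < 0.05
        assert rej / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestProfileCI:
    def test_interval_contains_mle(self):
        data = make_data(VarianceShares(a2=0.8, e2=0.2), seed=21)
        f = fit(TwinModelSpec(("A", "E")), data, seed=0)
        lo, hi = profile_ci(f, "A")
        assert lo <= f.components["pooled"].shares["A"] <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 1000):
            data = make_data(VarianceShares(a2=0.7, e2=0.3), seed=22,
                             n_pairs={"MZF": n // 2, "DZF": n // 2})
            f = fit(TwinModelSpec(("A", "E")), data, seed=0)
            lo, hi = profile_ci(f, "A")
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_e_only_model_degenerate_interval(self):
        data = make_data(VarianceShares(e2=1.0), seed=23)
        f = fit(TwinModelSpec(("E",)), data, seed=0)
        assert profile_ci(f, "E") == (1.0, 1.0)

    def test_sex_specific_fit_uses_bootstrap_interval(self):
        data = make_data(VarianceShares(a2=0.7, e2=0.3), seed=24, include_os=True)
        f = fit(TwinModelSpec(("A", "E"), "quantitative"), data, seed=0)
        cis = profile_ci(f, "A", n_boot=60)
        assert set(cis) <= {"F", "M"}
        for s, (lo, hi) in cis.items():
            assert lo <= f.components[s].shares["A"] + 1e-9
            assert hi >= f.components[s].shares["A"] - 1e-9


class TestSelectionAndHeritability:
    def test_e_only_data_selects_e(self):
        data = make_data(VarianceShares(e2=1.0), seed=31,
                         n_pairs={"MZF": 500, "MZM": 500, "DZF": 500, "DZM": 500})
        sel = select_model(data, seed=0)
        assert sel.best.spec.components == frozenset({"E"})
        assert heritability(sel.best) == 0.0

    def test_ce_data_selects_ce_and_reports_zero_h2(self):
        data = make_data(VarianceShares(c2=0.5, e2=0.5), seed=32,
                         n_pairs={"MZF": 1500, "MZM": 1500, "DZF": 1500, "DZM": 1500})
        sel = select_model(data, seed=0)
        assert sel.best.spec.components == frozenset({"C", "E"})
        assert heritability(sel.best) == 0.0

    def test_heritability_arithmetic(self):
        p = PathParams(paths_f={"A": 2.0, "E": 1.0}, paths_m={"A": 2.0, "E": 1.0})
        assert standardized_shares(p, "F")["A"] == pytest.approx(0.8, abs=1e-12)

    def test_selection_trace_records_every_decision(self):
        data = make_data(VarianceShares(a2=0.8, e2=0.2), seed=33, include_os=True)
        sel = select_model(data, seed=0)
        events = {t["event"] for t in sel.trace}
        assert {"fit", "lrt", "sex_structure", "aic_selection"} <= events
        aic = [t for t in sel.trace if t["event"] == "aic_selection"][0]
        assert aic["winner"] == sel.best.spec.name

    def test_quantitative_sex_differences_detected(self):
        # strongly sex-differing variance shares should reject the pooled model
        cfg = GeneratorConfig(
            shares_f=VarianceShares(a2=0.85, e2=0.15),
            shares_m=VarianceShares(a2=0.30, e2=0.70),
            sd_f=1.0, sd_m=2.0, seed=34,
            n_pairs={"MZF": 800, "MZM": 800, "DZF": 800, "DZM": 800, "DZOS": 800})
        data = GroupedTwinData.from_frame(pairs_to_frame(simulate_pairs(cfg)))
        sel = select_model(data, seed=0)
        assert sel.best.spec.sex_structure in ("quantitative", "qualitative")
        h2 = heritability(sel.best)
        assert isinstance(h2, dict) and h2["F"] > h2["M"]
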