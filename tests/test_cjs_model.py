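import numpy as np
import pytest
from scipy.special import logit

from terrapop.cjs_model import (
    CJSError,
    build_design,
    fit,
    negloglik,
)
from terrapop.synthetic_data import constant_template, simulate_capture_histories

from conftest import cjs_probability_oracle, make_set


def const_beta(phi, p):
    return np.array([logit(phi), logit(p)])


class TestBuildDesign:
    def test_intercept_only_parameter_count(self):
        ehs = make_set(["101"])
        d = build_design(ehs, (), ())
        assert d.n_params == 2

    def test_interval_lengths_from_years(self):
        ehs = make_set(["11"], years=[2003, 2006])
        d = build_design(ehs, (), ())
        assert d.interval_lengths.tolist() == [3.0]

    def test_unknown_covariate_errors(self):
        ehs = make_set(["101"])
        with pytest.raises(CJSError, match="unknown survival covariate"):
            build_design(ehs, ("moon_phase",), ())

    def test_hurricane_aliased_with_year_factor(self):
        # a full year factor absorbs any interval indicator, so the
        # hurricane column must be reported as aliased
        years = [2001, 2002, 2003, 2006, 2007]
        hurricane = [False, False, False, True, False]
        effort = [10.0, 5.0, 20.0, 8.0, 30.0]
        ehs = make_set(["11000", "01100", "00110", "00011"], years=years,
                       hurricane=hurricane, effort=effort)
        d = build_design(ehs, ("sex", "year", "hurricane"), ("sex", "effort"))
        assert d.aliased == ["phi:hurricane"]

    def test_no_aliasing_without_year_factor(self):
        years = [2001, 2002, 2003, 2006, 2007]
        hurricane = [False, False, False, True, False]
        effort = [10.0, 5.0, 20.0, 8.0, 30.0]
        ehs = make_set(["11000", "01100", "00110", "00011"], years=years,
                       hurricane=hurricane, effort=effort)
        d = build_design(ehs, ("sex", "trend", "hurricane"), ("sex", "effort"))
        assert d.aliased == []


class TestNegloglik:
    @pytest.mark.parametrize(
        "history, phi, p, prob",
        [
            ("11", 0.5, 0.5, 0.25),  # survive then detected
            ("10", 0.5, 0.5, 0.75),  # dead, or alive and missed
            ("101", 0.8, 0.6, 0.8 * 0.4 * 0.8 * 0.6),
        ],
    )
    def test_closed_form_histories(self, history, phi, p, prob):
        ehs = make_set([history])
        d = build_design(ehs, (), ())
        assert negloglik(const_beta(phi, p), d, ehs) == pytest.approx(-np.log(prob), abs=1e-9)

    def test_gap_exponentiates_annual_survival(self):
        # a 3-year interval at annual phi = 0.9 contributes 0.9^3
        ehs = make_set(["11"], years=[2003, 2006])
        d = build_design(ehs, (), ())
        nll = negloglik(const_beta(0.9, 1 - 1e-12), d, ehs)
        assert nll == pytest.approx(-np.log(0.9**3), abs=1e-6)

    def test_empty_set_errors(self):
        ehs = make_set(["101"])
        d = build_design(ehs, (), ())
        empty = make_set(["101"])
        empty.individuals = []
        with pytest.raises(CJSError, match="empty"):
            negloglik(np.zeros(2), d, empty)

    def test_duplicating_set_doubles_negloglik(self):
        hists = ["1010", "0110", "1101"]
        ehs = make_set(hists, sexes=["female", "male", "female"])
        both = make_set(hists * 2, sexes=["female", "male", "female"] * 2)
        d = build_design(ehs, ("sex",), ("sex",))
        beta = np.array([0.4, -0.2, 0.1, 0.3])
        assert negloglik(beta, d, both) == pytest.approx(
            2 * negloglik(beta, d, ehs), rel=1e-12
        )

    def test_order_invariant(self):
        hists = ["1010", "0110", "1101"]
        sexes = ["female", "male", "female"]
        ehs = make_set(hists, sexes=sexes)
        rev = make_set(hists[::-1], sexes=sexes[::-1])
        d = build_design(ehs, ("sex",), ())
        beta = np.array([0.2, -0.5, 0.1])
        assert negloglik(beta, d, ehs) == pytest.approx(negloglik(beta, d, rev), rel=1e-12)


class TestOracleEquivalence:
    """The chi-recursion likelihood must agree with death-time enumeration."""

    def test_exhaustive_single_histories(self):
        rng = np.random.default_rng(0)
        for k in (2, 3, 4):
            years = list(range(2001, 2001 + k))
            for code in range(1, 2**k):
                hist = format(code, f"0{k}b")
                for sex in ("female", "male"):
                    ehs = make_set([hist], sexes=[sex])
                    d = build_design(ehs, ("sex",), ("sex",))
                    beta = rng.normal(scale=0.8, size=d.n_params)
                    phi_f = float(1 / (1 + np.exp(-(beta[0]))))
                    phi_m = float(1 / (1 + np.exp(-(beta[0] + beta[1]))))
                    p_f = float(1 / (1 + np.exp(-(beta[2]))))
                    p_m = float(1 / (1 + np.exp(-(beta[2] + beta[3]))))
                    prob = cjs_probability_oracle(
                        ehs,
                        phi_annual=[[phi_f] * (k - 1), [phi_m] * (k - 1)],
                        p=[[p_f] * k, [p_m] * k],
                    )
                    assert negloglik(beta, d, ehs) == pytest.approx(
                        -np.log(prob), abs=1e-9
                    )

    def test_random_multi_individual_sets_with_gaps(self):
        rng = np.random.default_rng(12)
        for trial in range(30):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(1, 6))
            years = [2001]
            for _ in range(k - 1):
                years.append(years[-1] + int(rng.integers(1, 4)))
            hists = []
            sexes = []
            for _ in range(n):
                code = int(rng.integers(1, 2**k))
                hists.append(format(code, f"0{k}b"))
                sexes.append("female" if rng.random() < 0.5 else "male")
            ehs = make_set([h for h in hists], sexes=sexes, years=years)
            d = build_design(ehs, ("year",), ("time",) if k > 2 else ())
            beta = rng.normal(scale=0.7, size=d.n_params)
            from terrapop.cjs_model import _real_rates

            phi_int, p = _real_rates(beta, d)
            dt = np.diff(years)
            phi_annual = phi_int ** (1.0 / dt[None, :])
            p_full = np.concatenate([np.zeros((2, 1)), p], axis=1)
            prob = cjs_probability_oracle(ehs, phi_annual, p_full)
            assert negloglik(beta, d, ehs) == pytest.approx(-np.log(prob), abs=1e-9)


class TestFit:
    def test_two_occasion_saturated_matches_m_array(self):
        # with two occasions only phi*p is identified and equals the
        # fraction of first-occasion releases re-detected
        hists = ["11"] * 4 + ["10"] * 6
        ehs = make_set(hists)
        d = build_design(ehs, (), ())
        f = fit(ehs, d)
        phi_hat = f.real_phi.estimate.iloc[0]
        p_hat = f.real_p.estimate.iloc[0]
        assert phi_hat * p_hat == pytest.approx(0.4, abs=1e-4)
        assert not f.real_phi.estimable.iloc[0]
        assert not f.real_p.estimable.iloc[0]

    def test_terminal_confounding_flagged(self):
        # fully time-varying model: last phi and last p are confounded
        tpl = constant_template(3, 400, 0.8, 0.6)
        ehs = simulate_capture_histories(tpl, seed=2)
        d = build_design(ehs, ("year",), ("time",))
        f = fit(ehs, d)
        phi_f = f.real_phi[f.real_phi.sex == "female"].set_index("year_start")
        p_f = f.real_p[f.real_p.sex == "female"].set_index("year")
        assert bool(phi_f.loc[2001, "estimable"])
        assert not bool(phi_f.loc[2002, "estimable"])
        assert bool(p_f.loc[2002, "estimable"])
        assert not bool(p_f.loc[2003, "estimable"])

    def test_single_fit_recovers_truth_within_ci(self):
        tpl = constant_template(8, 800, 0.85, 0.5)
        ehs = simulate_capture_histories(tpl, seed=11)
        f = fit(ehs, build_design(ehs, (), ()))
        phi_row = f.real_phi.iloc[0]
        p_row = f.real_p.iloc[0]
        assert phi_row.lcl <= 0.85 <= phi_row.ucl
        assert p_row.lcl <= 0.5 <= p_row.ucl
        assert phi_row.estimable and p_row.estimable

    def test_aic_identity(self):
        tpl = constant_template(5, 200, 0.8, 0.5)
        ehs = simulate_capture_histories(tpl, seed=3)
        d = build_design(ehs, (), ())
        f = fit(ehs, d)
        assert f.aic == pytest.approx(2 * d.n_params - 2 * f.loglik, rel=1e-12)

    def test_low_bias_at_scale(self):
        # bias of annual survival below 0.02 at N=2000, 10 occasions
        tpl = constant_template(10, 2000, 0.8, 0.6)
        ests = []
        for seed in range(5):
            ehs = simulate_capture_histories(tpl, seed=seed)
            f = fit(ehs, build_design(ehs, (), ()))
            ests.append(f.real_phi.estimate.iloc[0])
        assert abs(np.mean(ests) - 0.8) < 0.02


class TestRealParams:
    def test_link_identity_and_ci_ordering(self):
        tpl = constant_template(6, 500, 0.85, 0.5)
        ehs = simulate_capture_histories(tpl, seed=9)
        f = fit(ehs, build_design(ehs, ("sex",), ("effort",)))
        for tab in (f.real_phi, f.real_p):
            assert ((tab.lcl <= tab.estimate) & (tab.estimate <= tab.ucl)).all()
            assert ((tab.lcl >= 0) & (tab.ucl <= 1)).all()

    def test_inverse_logit_values(self):
        from scipy.special import expit

        assert expit(0.0) == pytest.approx(0.5)
        # eta = 2.1972 is the logit of 0.9
        assert expit(2.1972) == pytest.approx(0.900, abs=1e-3)
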