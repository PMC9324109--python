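import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from jcelottery.core import JCEForm, JCEParams, sample_fitness
from jcelottery.ode import (
    expected_offspring,
    hyper_H,
    mean_away_survival,
    ode_rhs,
    run_ode,
)


def series_aH(a: float, terms: int = 200) -> float:
    """Independent alternating-series oracle for a*H(a), summed in
    50-digit arithmetic term by term."""
    import mpmath

    with mpmath.workdps(50):
        x = mpmath.mpf(a)
        total = mpmath.fsum(
            (-1) ** (k - 1) * x**k / (mpmath.factorial(k) * k * k) for k in range(1, terms)
        )
        return float(total)


class TestHyperH:
    def test_h_zero_is_one(self):
        assert hyper_H(0.0) == 1.0

    @pytest.mark.parametrize("a", [0.25, 0.5, 1.0, 2.75, 4.6])
    def test_matches_series_oracle(self, a):
        assert hyper_H(a) == pytest.approx(series_aH(a) / a, abs=1e-10)

    @pytest.mark.parametrize("a, expected", [(1.0, 0.89121), (0.5, 0.94182)])
    def test_printed_values(self, a, expected):
        assert hyper_H(a) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("a", [0.5, 3.0, 20.0, 40.0])
    def test_matches_arbitrary_precision_3f3(self, a):
        import mpmath

        assert hyper_H(a) == pytest.approx(float(mpmath.hyper([1, 1, 1], [2, 2, 2], -a)), rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hyper_H(-0.1)


def params(form, a, g=0.172, v=10.0):
    if JCEForm[form].distance_decay:
        return JCEParams(JCEForm[form], a=a, g=g, v=v)
    return JCEParams(JCEForm[form], a=a, g=g, r=v * math.sqrt(2.0))


class TestExpectedOffspring:
    @pytest.mark.parametrize("form", ["NF", "AF", "ND", "AD"])
    def test_rare_species_escapes_predation(self, form):
        p = params(form, a=1.5)
        off = expected_offspring(JCEForm[form], 1e-9, 1.0, p, D=1.0)
        assert off.away / 1e-9 == pytest.approx(1.0, rel=1e-4)

    def test_nf_away_value(self):
        # e^(-p E_F) + e^(-a)(1 - e^(-p E_F)) at p=1/300, E_F=108.07
        off = expected_offspring(JCEForm.NF, 1 / 300, 1.0, params("NF", 0.5), D=1.0)
        assert off.away == pytest.approx(2.9366e-3, rel=2e-4)

    def test_af_away_factor(self):
        off = expected_offspring(JCEForm.AF, 1 / 300, 1.0, params("AF", 0.5), D=1.0)
        assert off.away / (1 / 300) == pytest.approx(0.86786, abs=2e-5)

    def test_ad_away_factor_uses_hypergeometric(self):
        off = expected_offspring(JCEForm.AD, 1 / 300, 1.0, params("AD", 1.0), D=1.0)
        assert off.away / (1 / 300) == pytest.approx(0.72538, abs=2e-5)

    def test_af_away_equals_poisson_mgf_monte_carlo(self):
        # E[e^(-aK)], K ~ Poisson(p E_F), vs the closed form e^(-(1-e^-a) p E_F)
        a, p = 0.8, 0.05
        jp = params("AF", a)
        lam = p * jp.E_F
        rng = np.random.default_rng(42)
        draws = np.exp(-a * rng.poisson(lam, size=1_000_000))
        se = draws.std() / math.sqrt(len(draws))
        closed = mean_away_survival(JCEForm.AF, p, jp)
        assert abs(draws.mean() - closed) < 3 * se

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            expected_offspring(JCEForm.AD, 1.2, 1.0, params("AD", 1.0), D=1.0)


class TestMeanAwaySurvival:
    @pytest.mark.parametrize("form", ["NF", "AF", "ND", "AD"])
    def test_no_conspecifics_no_predation(self, form):
        assert mean_away_survival(JCEForm[form], 0.0, params(form, 2.0)) == pytest.approx(1.0)

    def test_fixed_forms_converge_at_strong_predation(self):
        # at 1-e^-a = 0.99 nearly all offspring near any conspecific die,
        # so additive accumulation adds almost nothing
        aA = -math.log(1 - 0.99)
        an = aA * (1 + params("NF", aA).E_F / 300)  # normalised non-additive baseline
        ps = np.linspace(0.0, 1.0, 101)
        nf = mean_away_survival(JCEForm.NF, ps, params("NF", an))
        af = mean_away_survival(JCEForm.AF, ps, params("AF", aA))
        assert np.max(np.abs(nf - af)) < 0.01

    def test_additive_decay_kills_more_than_nonadditive_at_high_p(self):
        aA = -math.log(1 - 0.4)
        E = params("AD", aA).E_D
        an = aA * (1 + E / 300)
        ad = mean_away_survival(JCEForm.AD, 0.5, params("AD", aA))
        nd = mean_away_survival(JCEForm.ND, 0.5, params("ND", an))
        assert ad < nd

    def test_nd_closed_form_tracks_quadrature(self):
        # the ND closed form is a second-order expansion; it should track the
        # exact nearest-neighbour expectation closely at community-scale p
        for a in (0.5, 1.0, 2.75):
            for p in (1 / 300, 0.05, 0.3):
                jp = params("ND", a)
                closed = mean_away_survival(JCEForm.ND, p, jp, nd_mode="closed")
                exact = mean_away_survival(JCEForm.ND, p, jp, nd_mode="quadrature")
                assert closed == pytest.approx(exact, rel=0.05)


class TestOdeRhs:
    def test_symmetric_community_is_stationary(self):
        p = np.full(10, 0.1)
        Y = np.ones(10)
        dp = ode_rhs(p, Y, params("AD", 1.0), D=0.5)
        assert np.allclose(dp, 0.0, atol=1e-15)

    @given(
        st.integers(2, 30),
        st.sampled_from(["NF", "AF", "ND", "AD"]),
        st.floats(0.0, 3.0),
        st.floats(0.0, 1.0),
        st.integers(0, 1000),
    )
    def test_total_proportion_conserved(self, n, form, a, D, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        Y = np.exp(rng.normal(0, 0.5, n))
        dp = ode_rhs(p, Y, params(form, a), D=D)
        assert abs(dp.sum()) < 1e-12

    def test_no_jce_limit_is_replicator_dynamics(self):
        # a=0, D=1: dp_i/dt = delta p_i (Y_i / sum p_n Y_n - 1)
        Y = np.array([2.0, 1.0])
        p = np.array([0.5, 0.5])
        dp = ode_rhs(p, Y, params("AD", 0.0), D=1.0, delta=1.0)
        assert dp[0] == pytest.approx(1 / 6, abs=1e-12)
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(7))
        Y = np.exp(rng.normal(0, 1, 7))
        dp = ode_rhs(p, Y, params("NF", 0.0), D=1.0, delta=0.3)
        expected = 0.3 * p * (Y / (p * Y).sum() - 1.0)
        assert np.allclose(dp, expected, atol=1e-13)


class TestRunOde:
    def test_competitive_exclusion_without_jces(self):
        Y = np.array([1.5, 1.2, 1.0, 0.9])
        res = run_ode(Y, params("AD", 0.0), D=1.0, t_end=2000.0)
        assert res.richness == 1
        assert res.p.argmax() == 0

    def test_symmetric_community_retains_everyone(self):
        Y = np.ones(20)
        res = run_ode(Y, params("NF", 1.0), D=0.5, t_end=500.0)
        assert res.richness == 20
        assert np.allclose(res.p, 0.05, atol=1e-9)

    def test_simplex_conserved_along_trajectory(self):
        Y = sample_fitness(50, 0.5, seed=4)
        res = run_ode(Y, params("AD", 1.0), D=0.5, t_end=1000.0)
        assert abs(res.p.sum() - 1.0) < 1e-6
        assert res.shannon <= math.log(50)
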