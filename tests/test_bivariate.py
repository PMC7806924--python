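import numpy as np
import pytest
from scipy.stats import chi2

from pedherit import (
    CohortSpec,
    CorrelationStructure,
    TraitGenSpec,
    decompose_rho_p,
    fit_bivariate,
    fit_polygenic,
    lrt_correlation,
    simulate_cohort,
)
from pedherit.traits import TraitSpec, prepare_trait


def _cohort_pair(seed, rho_g, rho_e, h2=(0.58, 0.64), n_families=150):
    traits = [
        TraitGenSpec("t1", 1.0, 1.0, h2[0]),
        TraitGenSpec("t2", 1.0, 1.0, h2[1]),
    ]
    corr = CorrelationStructure.from_pairs(
        ["t1", "t2"], {("t1", "t2"): rho_g}, {("t1", "t2"): rho_e}
    )
    coh = simulate_cohort(
        CohortSpec(n_nuclear_families=n_families, seed=seed), traits, corr, seed=seed
    )
    p1 = prepare_trait(coh.phenotypes, TraitSpec("t1", covariates=[]))
    p2 = prepare_trait(coh.phenotypes, TraitSpec("t2", covariates=[]))
    return p1.values, p2.values, coh.kinship


class TestDecomposeRhoP:
    @pytest.mark.parametrize(
        "h2_1,h2_2,rho_g,rho_e,expected",
        [
            (0.58, 0.64, 0.62, -0.19, 0.3039),
            (0.98, 0.64, 0.24, -0.08, 0.1833),
            (1.0, 1.0, 0.37, -0.9, 0.37),   # fully heritable limit
            (0.0, 0.0, 0.9, -0.25, -0.25),  # fully environmental limit
        ],
    )
    def test_worked_values(self, h2_1, h2_2, rho_g, rho_e, expected):
        assert decompose_rho_p(h2_1, h2_2, rho_g, rho_e) == pytest.approx(
            expected, abs=1e-4
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decompose_rho_p(1.2, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            decompose_rho_p(0.5, 0.5, 1.5, 0.0)


class TestFitBivariate:
    def test_identical_traits_pin_correlations_at_one(self):
        y1, _, kin = _cohort_pair(101, rho_g=0.0, rho_e=0.0, n_families=60)
        fit = fit_bivariate(y1, y1.copy(), kin, tests=False, ci=False)
        assert fit.rho_p == pytest.approx(1.0, abs=1e-2)
        assert fit.rho_g == pytest.approx(1.0, abs=1e-2)
        assert fit.rho_e == pytest.approx(1.0, abs=1e-2)
        assert any("boundary" in f for f in fit.boundary_flags)

    def test_trait_order_symmetry(self):
        y1, y2, kin = _cohort_pair(103, rho_g=0.62, rho_e=-0.19)
        f12 = fit_bivariate(y1, y2, kin, tests=False, ci=False)
        f21 = fit_bivariate(y2, y1, kin, tests=False, ci=False)
        assert f12.rho_g == pytest.approx(f21.rho_g, abs=1e-4)
        assert f12.rho_e == pytest.approx(f21.rho_e, abs=1e-4)
        assert f12.rho_p == pytest.approx(f21.rho_p, abs=1e-4)

    def test_decomposition_identity_holds_exactly(self):
        y1, y2, kin = _cohort_pair(105, rho_g=0.4, rho_e=0.1)
        fit = fit_bivariate(y1, y2, kin, tests=False, ci=False)
        implied = decompose_rho_p(fit.h2_1, fit.h2_2, fit.rho_g, fit.rho_e)
        assert abs(fit.rho_p - implied) < 1e-10

    def test_independent_traits_estimates_near_zero(self):
        # scale large enough that per-trait h2 (hence rho_g) is identified
        rgs, rps = [], []
        for seed in range(6):
            y1, y2, kin = _cohort_pair(200 + seed, rho_g=0.0, rho_e=0.0,
                                       n_families=300)
            fit = fit_bivariate(y1, y2, kin, tests=False, ci=False)
            rgs.append(fit.rho_g)
            rps.append(fit.rho_p)
        assert abs(np.mean(rgs)) < 0.12
        assert abs(np.mean(rps)) < 0.06

    def test_marginals_consistent_with_univariate(self):
        y1, y2, kin = _cohort_pair(301, rho_g=0.62, rho_e=-0.19, n_families=300)
        fit = fit_bivariate(y1, y2, kin, tests=False, ci=False)
        u1 = fit_polygenic(y1, kin)
        u2 = fit_polygenic(y2, kin)
        assert fit.h2_1 == pytest.approx(u1.h2, abs=0.02)
        assert fit.h2_2 == pytest.approx(u2.h2, abs=0.02)

    def test_recovery_of_generative_correlations(self):
        rgs, res = [], []
        for seed in range(6):
            y1, y2, kin = _cohort_pair(400 + seed, rho_g=0.62, rho_e=-0.19,
                                       n_families=300)
            fit = fit_bivariate(y1, y2, kin, tests=False, ci=False)
            rgs.append(fit.rho_g)
            res.append(fit.rho_e)
        assert np.mean(rgs) == pytest.approx(0.62, abs=0.1)
        assert np.mean(res) == pytest.approx(-0.19, abs=0.1)

    def test_wald_cis_bracket_estimates(self):
        y1, y2, kin = _cohort_pair(501, rho_g=0.62, rho_e=-0.19, n_families=300)
        fit = fit_bivariate(y1, y2, kin, tests=True, ci=True)
        lo, hi = fit.ci_rho_g
        assert lo < fit.rho_g < hi
        assert -1 <= lo and hi <= 1
        assert 0 < fit.p_rho_g <= 1

    def test_power_against_strong_genetic_correlation(self):
        ps = []
        for seed in range(5):
            y1, y2, kin = _cohort_pair(600 + seed, rho_g=0.62, rho_e=-0.19,
                                       n_families=300)
            fit = fit_bivariate(y1, y2, kin, tests=("rho_g",), ci=False)
            ps.append(fit.p_rho_g)
        assert np.median(ps) < 0.05


class TestLrtCorrelation:
    def test_chi2_reference_value(self):
        lam = chi2.isf(0.05, df=1)  # 3.841
        assert lrt_correlation(lam / 2, 0.0) == pytest.approx(0.05, abs=1e-6)

    def test_negative_lambda_clamps_to_one(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert lrt_correlation(0.0, 1.0) == 1.0
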