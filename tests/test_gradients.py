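"""Selection gradients: closed forms vs finite-difference oracles, limits, signs."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from senesce.demography import (
    GompertzMakehamParams,
    LifeHistory,
    certain_mortality_age,
    get_species,
    reproduction_rate,
    survival,
)
from senesce.fitness import DemographicScenario, apply_density_dependence, lrs
from senesce.gradients import (
    NegligibleSenescenceError,
    dlrs_dR,
    dr_dR,
    finite_difference,
    generic_gradient,
    gradient_r0_limit,
    hamilton_gradient,
    r0_limit_closed_form,
    selection_gradient,
    senescence_kernel,
)

HUMAN = get_species("human")
WHALE = get_species("killer_whale")

#: Negligible-senescence organism used in the selection-surface analysis.
GRAY_DOT = LifeHistory(GompertzMakehamParams(0.001, 0.0, 0.0025), xs=10.0, zeta=0.1)


class TestKernel:
    def test_vanishes_at_birth(self):
        assert senescence_kernel(0.071, 0.0) == 0.0

    def test_small_argument_series_matches_exact(self):
        # straddle the series/exact switch at Rx = 1e-4
        for R, x in [(1e-6, 50.0), (1e-5, 9.0), (0.01, 0.02)]:
            exact = (math.exp(R * x) * (1 - R * x) - 1) / R**2
            assert senescence_kernel(R, x) == pytest.approx(exact, rel=1e-6)

    def test_limit_is_negative_half_x_squared(self):
        x = np.array([1.0, 10.0, 50.0])
        assert np.allclose(senescence_kernel(0.0, x), -0.5 * x * x, rtol=1e-12)


class TestSenescenceRateGradients:
    def test_zero_when_no_internal_risk(self):
        lh = LifeHistory(GompertzMakehamParams(0.0, 0.2, 0.02), xs=5.0, zeta=0.1)
        assert dlrs_dR(lh).value == 0.0

    @pytest.mark.parametrize("name", ["human", "killer_whale", "yellow_baboon", "lion"])
    def test_closed_forms_match_finite_differences(self, name):
        lh = get_species(name)
        assert dlrs_dR(lh).value == pytest.approx(
            finite_difference(lh, "R", "lrs", fix_truncation=True), rel=1e-4
        )
        assert dr_dR(lh).value == pytest.approx(
            finite_difference(lh, "R", "euler_lotka_r", fix_truncation=True), rel=1e-4
        )

    def test_non_positive_on_random_sets(self, random_life_histories):
        for lh in random_life_histories:
            assert dlrs_dR(lh).value <= 0.0
            assert dr_dR(lh).value <= 0.0

    def test_negligible_senescence_redirects(self):
        with pytest.raises(NegligibleSenescenceError):
            dlrs_dR(GRAY_DOT)
        with pytest.raises(NegligibleSenescenceError):
            dr_dR(GRAY_DOT)

    def test_equilibrated_gradient_strengthens_near_certain_death(self):
        # raising R until x_d closes in on xs makes regulated selection stronger
        dd = DemographicScenario("dd_reproduction")
        at_own = dlrs_dR(apply_density_dependence(HUMAN, dd)).value
        high = HUMAN.with_params(R=0.6)  # x_d within ~1.4x of maturity
        at_high = dlrs_dR(apply_density_dependence(high, dd)).value
        assert at_high < at_own < 0.0

    def test_method_metadata(self):
        g = dlrs_dR(HUMAN)
        assert (g.parameter, g.estimator, g.method) == ("R", "lrs", "closed_form")


class TestNegligibleSenescenceLimit:
    def test_closed_form_matches_untruncated_quadrature(self):
        c = GRAY_DOT.params.G + GRAY_DOT.params.M
        val, _ = quad(lambda x: x * x * math.exp(-c * x), GRAY_DOT.xs, np.inf)
        expected = -0.5 * GRAY_DOT.params.G * GRAY_DOT.zeta * val
        assert r0_limit_closed_form(GRAY_DOT) == pytest.approx(expected, rel=1e-9)

    def test_limit_continuous_with_small_R_gradient(self):
        # Eq-form gradient at R = 1e-6 approaches the R = 0 limit
        near = dlrs_dR(GRAY_DOT.with_params(R=1e-6)).value
        at = gradient_r0_limit(GRAY_DOT, "lrs").value
        assert near == pytest.approx(at, rel=1e-3)

    def test_numeric_limit_tracks_closed_form(self):
        # truncation at survivorship 1e-4 leaves a sub-percent tail
        assert gradient_r0_limit(GRAY_DOT, "lrs").value == pytest.approx(
            r0_limit_closed_form(GRAY_DOT), rel=1e-2
        )

    def test_zero_without_internal_risk(self):
        lh = LifeHistory(GompertzMakehamParams(0.0, 0.0, 0.02), xs=5.0, zeta=0.1)
        assert gradient_r0_limit(lh, "lrs").value == 0.0

    def test_requires_negligible_senescence(self):
        with pytest.raises(ValueError, match="R = 0"):
            gradient_r0_limit(HUMAN, "lrs")

    def test_regulated_selection_strengthens_with_maturity_age(self):
        # at demographic equilibrium, later maturity means stronger selection
        # against senescence (its magnitude grows with xs)
        dd = DemographicScenario("dd_reproduction")
        values = [
            gradient_r0_limit(
                apply_density_dependence(GRAY_DOT.with_params(xs=xs), dd), "lrs"
            ).value
            for xs in (5.0, 10.0, 20.0)
        ]
        assert values[0] > values[1] > values[2]

    def test_euler_lotka_limit_nonzero_for_whale(self):
        # selection on senescence does not vanish at negligible senescence
        frozen = WHALE.with_params(R=0.0)
        assert gradient_r0_limit(frozen, "euler_lotka_r").value < -1e-3


class TestHamiltonGradient:
    def test_zero_beyond_certain_mortality(self):
        assert hamilton_gradient(HUMAN, 150.0) == 0.0

    def test_instantaneous_change_constant_before_maturity(self):
        a0 = hamilton_gradient(HUMAN, 0.0, change="instantaneous")
        axs = hamilton_gradient(HUMAN, HUMAN.xs, change="instantaneous")
        assert a0 == pytest.approx(axs, rel=1e-10)
        assert abs(hamilton_gradient(HUMAN, 30.0, change="instantaneous")) < abs(a0)

    def test_magnitude_shrinks_with_onset_age(self):
        vals = [hamilton_gradient(HUMAN, a) for a in (13.0, 20.0, 40.0, 60.0)]
        assert all(v < 0 for v in vals)
        assert np.all(np.diff([abs(v) for v in vals]) < 0)

    def test_permanent_change_matches_finite_difference_oracle(self):
        # oracle: r under mu -> mu + eps for x >= a, via dense bisection
        a, eps = 20.0, 1e-6
        x_trunc = certain_mortality_age(HUMAN.params)
        x = np.arange(HUMAN.xs, x_trunc, 1e-3)
        lm = survival(HUMAN.params, x) * reproduction_rate(HUMAN, x)

        def growth_rate(e):
            bumped = lm * np.exp(-e * np.clip(x - a, 0.0, None))

            def f(r):
                return np.trapezoid(np.exp(-r * x) * bumped, x) - 1.0

            return brentq(f, -1.0, 1.0, xtol=1e-14)

        oracle = (growth_rate(eps) - growth_rate(-eps)) / (2 * eps)
        assert hamilton_gradient(HUMAN, a) == pytest.approx(oracle, rel=1e-5)


class TestGenericGradients:
    def test_sign_contract(self, species):
        for lh in species.values():
            assert generic_gradient(lh, "G", "lrs").value < 0
            assert generic_gradient(lh, "M", "lrs").value < 0
            assert generic_gradient(lh, "xs", "lrs").value < 0
            assert generic_gradient(lh, "zeta", "lrs").value > 0

    def test_lrs_linear_in_zeta(self):
        g = generic_gradient(HUMAN, "zeta", "lrs")
        assert g.value == pytest.approx(lrs(HUMAN).value / HUMAN.zeta, rel=1e-6)

    def test_external_regulation_leaves_gradients_unchanged(self, species):
        # full compensation: M+r with r = 0 reproduces the unregulated weights
        for lh in species.values():
            dd = apply_density_dependence(lh, DemographicScenario("dd_external"))
            T = certain_mortality_age(dd.params)
            assert dr_dR(dd, x_trunc=T).value == pytest.approx(
                dr_dR(lh, x_trunc=T).value, rel=1e-6
            )
            assert finite_difference(dd, "M", "euler_lotka_r", fix_truncation=True) == pytest.approx(
                finite_difference(lh, "M", "euler_lotka_r", fix_truncation=True), rel=1e-4
            )

    def test_dispatcher_routes_by_parameter(self):
        assert selection_gradient(HUMAN, "R").method == "closed_form"
        assert selection_gradient(GRAY_DOT, "R").method == "r0_limit"
        assert selection_gradient(HUMAN, "M").method == "finite_difference"

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            generic_gradient(HUMAN, "R")
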