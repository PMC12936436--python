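"""Evolutionary feedback: curvatures, co-evolution maps, masks, transforms."""

import numpy as np
import pytest

from senesce.demography import (
    GompertzMakehamParams,
    LifeHistory,
    certain_mortality_age,
    get_species,
    survival,
)
from senesce.feedback import (
    approx_positive_feedback_condition,
    feedback_map,
    log_modulus,
    mixed_derivative,
    mixed_derivative_reversed,
    second_derivative_R,
)
from senesce.fitness import lrs
from senesce.tradeoff import rmax_rule

HUMAN = get_species("human")
WHALE = get_species("killer_whale")


class TestLogModulus:
    @pytest.mark.parametrize("v, expected", [(0.0, 0.0), (9.0, 1.0), (-99.0, -2.0)])
    def test_reference_points(self, v, expected):
        assert log_modulus(v) == pytest.approx(expected)

    def test_odd_and_sign_preserving(self):
        v = np.array([-1000.0, -0.5, 0.0, 0.5, 1000.0])
        assert np.allclose(log_modulus(-v), -log_modulus(v))
        assert np.all(np.sign(log_modulus(v)) == np.sign(v))


class TestSecondDerivative:
    @pytest.mark.parametrize(
        "name, positive",
        [("human", True), ("killer_whale", True), ("yellow_baboon", False), ("lion", False)],
    )
    def test_feedback_sign_at_small_R(self, name, positive):
        lh = get_species(name).with_params(R=0.001)
        d2 = second_derivative_R(lh, "lrs")
        assert (d2 > 0) == positive

    @pytest.mark.parametrize("name", ["human", "killer_whale", "yellow_baboon", "lion"])
    def test_always_negative_when_maturity_meets_certain_death(self, name):
        lh = get_species(name)
        high = lh.with_params(R=0.9 * rmax_rule(lh))
        assert second_derivative_R(high, "lrs") < 0

    def test_matches_direct_second_difference_of_fitness(self):
        # raw-fitness curvature vs second central difference of LRS itself
        # (both on the base point's integration window)
        h = 1e-4
        R = HUMAN.params.R
        T = certain_mortality_age(HUMAN.params)

        def L(RR):
            return lrs(HUMAN.with_params(R=RR), x_trunc=T).value

        direct = (L(R + h) - 2 * L(R) + L(R - h)) / h**2
        chained = second_derivative_R(HUMAN, "lrs", equilibrate=False)
        assert chained == pytest.approx(direct, rel=1e-2)

    def test_equilibrated_is_log_fitness_curvature(self):
        h = 1e-4
        R = HUMAN.params.R
        T = certain_mortality_age(HUMAN.params)

        def logL(RR):
            return np.log(lrs(HUMAN.with_params(R=RR), x_trunc=T).value)

        direct = (logL(R + h) - 2 * logL(R) + logL(R - h)) / h**2
        assert second_derivative_R(HUMAN, "lrs") == pytest.approx(direct, rel=1e-2)


class TestMixedDerivative:
    def test_symmetric_in_differentiation_order(self):
        for other in ("G", "M"):
            ab = mixed_derivative(HUMAN, other)
            ba = mixed_derivative_reversed(HUMAN, other)
            assert ab == pytest.approx(ba, rel=1e-3)

    @pytest.mark.parametrize(
        "name, positive", [("human", True), ("killer_whale", True),
                           ("yellow_baboon", False), ("lion", False)]
    )
    def test_internal_risk_coevolution_sign_at_low_R(self, name, positive):
        # positive R-G feedback at low senescence only where G dominates M
        lh = get_species(name).with_params(R=0.01)
        assert (mixed_derivative(lh, "G") > 0) == positive

    def test_strehler_mildvan_regime(self):
        # external risk dominating internal risk => negative R-G feedback,
        # the between-population negative association of G and R
        rng = np.random.default_rng(7)
        neg = total = 0
        while total < 20:
            M = 10 ** rng.uniform(-2.5, -1)
            G = M * 10 ** rng.uniform(-3, -0.3)
            xs = rng.uniform(1, 12)
            R = 10 ** rng.uniform(np.log10(0.05), np.log10(0.4))
            params = GompertzMakehamParams(G, R, M)
            if survival(params, xs) <= 0.01:
                continue
            if xs > 0.7 * certain_mortality_age(params):
                continue
            total += 1
            neg += mixed_derivative(LifeHistory(params, xs=xs, zeta=0.1), "G") < 0
        assert neg / total >= 0.8

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            mixed_derivative(HUMAN, "R")


class TestFeedbackMap:
    def test_mask_activates_exactly_at_nonviable_cells(self):
        G_grid = np.geomspace(1e-4, 1e-2, 4)
        R_grid = np.linspace(0.05, 1.2, 5)  # top rows beyond human Rmax = 0.748
        fmap = feedback_map(HUMAN, ("G", G_grid), ("R", R_grid), "second_R")
        for i, R in enumerate(R_grid):
            for j, G in enumerate(G_grid):
                nonviable = survival(GompertzMakehamParams(G, R, HUMAN.params.M), HUMAN.xs) <= 1e-4
                assert fmap.mask[i, j] == nonviable
                assert np.isnan(fmap.values[i, j]) == nonviable

    def test_species_cell_matches_single_evaluation(self):
        G_grid = np.array([1e-4, HUMAN.params.G, 1e-3])
        R_grid = np.array([0.05, HUMAN.params.R, 0.1])
        fmap = feedback_map(HUMAN, ("G", G_grid), ("R", R_grid), "second_R")
        assert fmap.values[1, 1] == pytest.approx(second_derivative_R(HUMAN), rel=1e-9)
        assert np.sign(fmap.values[1, 1]) == 1.0  # human dot: positive feedback

    def test_values_independent_of_grid_resolution(self):
        coarse = feedback_map(
            HUMAN, ("G", np.array([HUMAN.params.G])), ("R", np.array([0.05, 0.071]))
        )
        fine = feedback_map(
            HUMAN, ("G", np.array([HUMAN.params.G])), ("R", np.array([0.03, 0.05, 0.06, 0.071]))
        )
        assert coarse.values[1, 0] == pytest.approx(fine.values[3, 0], rel=1e-12)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            feedback_map(HUMAN, ("G", np.array([1e-3, 1e-4])), ("R", np.array([0.1])))
        with pytest.raises(ValueError, match="negative"):
            feedback_map(HUMAN, ("G", np.array([-1e-4, 1e-3])), ("R", np.array([0.1])))
        with pytest.raises(ValueError, match="derivative"):
            feedback_map(HUMAN, ("G", np.array([1e-4])), ("R", np.array([0.1])), "third_R")

    def test_dataframe_roundtrip_with_mask_as_nan(self, tmp_path):
        fmap = feedback_map(
            HUMAN, ("G", np.array([1e-4, 1e-3])), ("R", np.array([0.05, 1.2]))
        )
        path = tmp_path / "map.tsv"
        fmap.to_tsv(path)
        import pandas as pd

        back = pd.read_csv(path, sep="\t", index_col=0)
        assert back.shape == (2, 2)
        assert back.isna().to_numpy().sum() == fmap.mask.sum()


class TestApproximateConditions:
    def test_killer_whale_flags_positive_feedback(self):
        near, away = approx_positive_feedback_condition(WHALE)
        assert near and away

    def test_zero_external_risk_always_flags(self):
        lh = LifeHistory(GompertzMakehamParams(1e-5, 0.1, 0.0), xs=5.0, zeta=0.1)
        assert approx_positive_feedback_condition(lh)[0]

    def test_alternative_reading_available(self):
        # squared-M grouping is far more permissive at small M
        lh = get_species("lion")
        assert not approx_positive_feedback_condition(lh, g_reading="half")[0]
        assert approx_positive_feedback_condition(lh, g_reading="squared")[0]
        with pytest.raises(ValueError):
            approx_positive_feedback_condition(lh, g_reading="cubed")

    def test_rule_agrees_with_computed_curvature(self):
        # the near-zero-R rule of thumb vs the sign of the actual feedback
        rng = np.random.default_rng(20250925)
        agree = n = 0
        while n < 60:
            G = 10 ** rng.uniform(-5, -1.3)
            M = 10 ** rng.uniform(-5, -1)
            xs = rng.uniform(1, 15)
            params = GompertzMakehamParams(G, 0.001, M)
            if survival(params, xs) <= 0.05:
                continue
            lh = LifeHistory(params, xs=xs, zeta=0.1)
            n += 1
            near, _ = approx_positive_feedback_condition(lh)
            agree += near == (second_derivative_R(lh) > 0)
        assert agree / n >= 0.9
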