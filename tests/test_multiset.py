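"""Multi-set scenario model and the closed-form total selection response."""

import io

import numpy as np
import pytest
from scipy.stats import norm

from truncsel import (
    BLUE,
    BLUP,
    DegenerateSelectionError,
    InvalidInputError,
    Scenario,
    SetParams,
    blup_total_response_closed_form,
    derive_scale_and_slope,
    post_selection_composition,
    read_scenario_csv,
    solve_identical_threshold,
    threshold_for_proportion,
    total_response,
    total_selected_proportion,
    within_set_response,
)
from conftest import random_scenario


class TestSetParamsAndScales:
    def test_blue_scale_and_slope(self):
        s = SetParams("a", 0.5, 0.0, 1.0, BLUE, 0.36)
        sigma, b = derive_scale_and_slope(s)
        assert sigma == pytest.approx(1 / 0.6, abs=1e-12)
        assert round(sigma, 2) == 1.67
        assert b == 0.36

    def test_blup_scale_and_slope(self):
        s = SetParams("a", 0.5, 0.0, 1.0, BLUP, 0.9)
        assert derive_scale_and_slope(s) == (pytest.approx(0.9), 1.0)

    def test_perfect_blue_coincides_with_perfect_blup(self):
        blue = SetParams("a", 0.5, 0.0, 1.3, BLUE, 1.0)
        blup = SetParams("a", 0.5, 0.0, 1.3, BLUP, 1.0)
        assert derive_scale_and_slope(blue) == derive_scale_and_slope(blup)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pi=0.0),
            dict(pi=1.2),
            dict(sigma_u=0.0),
            dict(sigma_u=-1.0),
            dict(accuracy=0.0),
            dict(accuracy=1.5),
            dict(criterion="GEBV"),
        ],
    )
    def test_rejects_degenerate_parameters(self, kwargs):
        base = dict(label="a", pi=0.5, mu=0.0, sigma_u=1.0, criterion=BLUP, accuracy=0.5)
        base.update(kwargs)
        with pytest.raises(InvalidInputError):
            SetParams(**base)

    def test_scenario_rejects_bad_proportions_and_budget(self):
        s1 = SetParams("a", 0.5, 0.0, 1.0, BLUP, 0.5)
        s2 = SetParams("b", 0.3, 0.0, 1.0, BLUP, 0.5)
        with pytest.raises(InvalidInputError):
            Scenario([s1, s2], 0.1)  # proportions sum to 0.8
        with pytest.raises(InvalidInputError):
            Scenario([s1, SetParams("a", 0.5, 1.0, 1.0, BLUP, 0.5)], 0.1)  # dup label
        s2 = SetParams("b", 0.5, 0.0, 1.0, BLUP, 0.5)
        with pytest.raises(InvalidInputError):
            Scenario([s1, s2], 0.0)
        with pytest.raises(InvalidInputError):
            Scenario([s1, s2], 1.0)


class TestTotalSelectedProportion:
    def test_mixture_collapses_for_identical_sets(self):
        s = SetParams("a", 0.5, 0.2, 1.0, BLUP, 0.7)
        s2 = SetParams("b", 0.5, 0.2, 1.0, BLUP, 0.7)
        scenario = Scenario([s, s2], 0.1)
        t = 1.3
        single = float(norm.sf((t - 0.2) / s.sigma_sc))
        assert total_selected_proportion([t, t], scenario) == pytest.approx(single, rel=1e-12)

    def test_worked_example_budget(self, blue_scenario):
        assert total_selected_proportion([1.77, 1.77], blue_scenario) == pytest.approx(
            0.10, abs=5e-4
        )

    def test_threshold_count_mismatch(self, blue_scenario):
        with pytest.raises(InvalidInputError):
            total_selected_proportion([1.77], blue_scenario)

    def test_three_set_mixture_matches_direct_sum(self):
        rng = np.random.default_rng(7)
        scenario = random_scenario(rng, BLUE, n_sets=3)
        t = rng.uniform(-1, 2, size=3)
        expected = sum(
            float(norm.sf((t[k] - s.mu) / s.sigma_sc)) * s.pi
            for k, s in enumerate(scenario.sets)
        )
        assert total_selected_proportion(t, scenario) == pytest.approx(expected, rel=1e-12)


class TestComposition:
    def test_extreme_example_composition(self, extreme_scenario):
        t = [
            threshold_for_proportion(0.45, mu=0.0, sigma=1.0),
            threshold_for_proportion(0.0125, mu=2.0, sigma=2.0),
        ]
        gamma = post_selection_composition(t, extreme_scenario)
        assert gamma[0] == pytest.approx(0.90, abs=0.005)

    def test_equal_sets_keep_initial_proportions(self):
        sets = [
            SetParams("a", 0.3, 0.0, 1.0, BLUP, 0.6),
            SetParams("b", 0.7, 0.0, 1.0, BLUP, 0.6),
        ]
        scenario = Scenario(sets, 0.2)
        gamma = post_selection_composition([0.8, 0.8], scenario)
        np.testing.assert_allclose(gamma, [0.3, 0.7], rtol=1e-12)

    def test_worked_example_identical_threshold_composition(self, blue_scenario):
        gamma = post_selection_composition([1.77, 1.77], blue_scenario)
        assert gamma[0] == pytest.approx(0.72, abs=0.005)

    def test_normalization_exact(self, blue_scenario):
        gamma = post_selection_composition([2.2, 0.4], blue_scenario)
        assert gamma.sum() == 1.0

    def test_degenerate_selection_raises(self, blue_scenario):
        with pytest.raises(DegenerateSelectionError):
            post_selection_composition([900.0, 900.0], blue_scenario)


class TestWithinSetResponse:
    def test_worked_blue_set(self, blue_scenario):
        t = solve_identical_threshold(blue_scenario).thresholds[0]
        s = SetParams("P1", 0.5, 0.0, 1.0, BLUE, 0.36)
        assert within_set_response(t, s) == pytest.approx(0.94, abs=0.005)

    def test_worked_blup_set(self, blup_scenario):
        t = solve_identical_threshold(blup_scenario).thresholds[0]
        s = SetParams("P2", 0.5, 0.0, 1.0, BLUP, 0.9)
        assert within_set_response(t, s) == pytest.approx(1.42, abs=0.005)

    def test_no_selection_no_response(self):
        s = SetParams("a", 0.5, 0.0, 1.0, BLUE, 0.5)
        assert within_set_response(s.mu - 8 * s.sigma_sc, s) < 1e-10


class TestTotalResponse:
    def test_worked_blue_example(self, blue_scenario):
        t = solve_identical_threshold(blue_scenario).thresholds[0]
        res = total_response([t, t], blue_scenario)
        assert res.deltaG_tot == pytest.approx(1.19, abs=0.005)
        assert res.outcomes[0].deltaG == pytest.approx(0.94, abs=0.005)
        assert res.outcomes[1].deltaG == pytest.approx(1.82, abs=0.005)

    def test_extreme_example_negative_response(self, extreme_scenario):
        t = [
            threshold_for_proportion(0.45, mu=0.0, sigma=1.0),
            threshold_for_proportion(0.0125, mu=2.0, sigma=2.0),
        ]
        res = total_response(t, extreme_scenario)
        assert res.deltaG_tot == pytest.approx(-0.70, abs=0.005)

    def test_single_set_reduces_to_breeders_equation(self):
        s = SetParams("only", 1.0, 1.5, 0.8, BLUE, 0.49)
        scenario = Scenario([s], 0.2)
        res = total_response([2.0], scenario)
        assert res.deltaG_tot == pytest.approx(within_set_response(2.0, s), rel=1e-12)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(11)
        scenario = random_scenario(rng, BLUE, n_sets=3)
        t = rng.uniform(-1, 2, size=3)
        res = total_response(t, scenario)
        perm = [2, 0, 1]
        swapped = Scenario([scenario.sets[k] for k in perm], scenario.alpha_T)
        res_p = total_response(t[perm], swapped)
        assert res_p.deltaG_tot == pytest.approx(res.deltaG_tot, rel=1e-12)
        assert res_p.alpha_tot == pytest.approx(res.alpha_tot, rel=1e-12)

    def test_single_set_limit_of_two_set_scenario(self):
        eps = 1e-9
        main = SetParams("big", 1 - eps, 0.5, 1.2, BLUE, 0.64)
        minor = SetParams("tiny", eps, -1.0, 0.7, BLUP, 0.8)
        scenario = Scenario([main, minor], 0.15)
        t = 1.9
        res = total_response([t, t], scenario)
        assert res.deltaG_tot == pytest.approx(within_set_response(t, main), abs=1e-6)

    def test_blue_direct_form_with_budget_prefactor(self, blue_scenario):
        """The direct per-set density form of the BLUE response (tail terms
        carrying a 1/alpha_Tot prefactor) coincides with the composition-
        weighted breeder's-equation form and gives 1.19 on the reference
        scenario."""
        t = np.array([1.77, 1.77])
        res = total_response(t, blue_scenario)
        z = (t - blue_scenario.mus) / blue_scenario.sigmas
        direct = (
            np.dot(
                blue_scenario.slopes * blue_scenario.sigmas * norm.pdf(z),
                blue_scenario.pis,
            )
            / res.alpha_tot
            + np.dot(blue_scenario.mus, res.gammas - blue_scenario.pis)
        )
        assert res.deltaG_tot == pytest.approx(direct, rel=1e-12)
        assert direct == pytest.approx(1.19, abs=0.005)


class TestBlupClosedForm:
    def test_worked_blup_example(self, blup_scenario):
        t_star = solve_identical_threshold(blup_scenario).thresholds[0]
        assert blup_total_response_closed_form(t_star, blup_scenario) == pytest.approx(
            1.36, abs=0.005
        )

    def test_identical_sets_collapse_to_single_intensity(self):
        sets = [
            SetParams("a", 0.4, 0.3, 1.0, BLUP, 0.7),
            SetParams("b", 0.6, 0.3, 1.0, BLUP, 0.7),
        ]
        scenario = Scenario(sets, 0.2)
        t_star = solve_identical_threshold(scenario).thresholds[0]
        sigma = sets[0].sigma_sc
        from truncsel import selection_intensity

        assert blup_total_response_closed_form(t_star, scenario) == pytest.approx(
            sigma * selection_intensity(0.2), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_composition_form_on_random_scenarios(self, seed):
        rng = np.random.default_rng(100 + seed)
        scenario = random_scenario(rng, BLUP)
        t_star = solve_identical_threshold(scenario).thresholds[0]
        closed = blup_total_response_closed_form(t_star, scenario)
        general = total_response(np.full(2, t_star), scenario).deltaG_tot
        assert closed == pytest.approx(general, abs=1e-10)

    def test_rejects_mixed_criteria(self, blue_scenario):
        with pytest.raises(InvalidInputError):
            blup_total_response_closed_form(1.0, blue_scenario)


class TestScenarioCSV:
    def test_round_trip(self, blue_scenario):
        from truncsel.scenario import scenario_to_frame

        buf = io.StringIO(scenario_to_frame(blue_scenario).to_csv(index=False))
        loaded = read_scenario_csv(buf, alpha_T=0.10)
        assert loaded == blue_scenario

    def test_missing_column_named_in_error(self):
        with pytest.raises(InvalidInputError, match="sigma_u"):
            read_scenario_csv(io.StringIO("label,pi,mu\na,1,0\n"), alpha_T=0.1)
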