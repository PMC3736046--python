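import math

import numpy as np
import pytest

from gompspan import (
    GompertzParams,
    KMCurve,
    StudyDesign,
    UndefinedCorrelationError,
    UnderdeterminedFitError,
    fit_three_param,
    generate_study,
    goodness_of_fit,
    half_life,
    km_estimate,
    params_from_half_life,
    sensitivity_rank,
    sequential_fit,
    survival_pct,
)

LN2 = math.log(2.0)


def model_curve(params, times, group="g"):
    """A noiseless step curve whose points lie exactly on the model."""
    times = np.asarray(times, dtype=float)
    return KMCurve(
        group=group,
        start_age=times[0] - 1.0,
        times=times,
        survival_pct=survival_pct(params, times),
        n_at_start=len(times),
    )


class TestThreeParamFit:
    def test_noiseless_points_are_reproduced(self):
        true = GompertzParams(LN2, 1.5, 1.5 * 25.1)
        times = np.linspace(22.0, 27.5, 20)
        curve = model_curve(true, times)
        fitted = fit_three_param(curve)
        resid = survival_pct(fitted, times) - curve.survival_pct
        assert np.max(np.abs(resid)) < 1e-6
        # (P1, P3) individually sit on a ridge; the identifiable quantities
        # are the rate and the 50%-crossing
        assert half_life(fitted) == pytest.approx(25.1, abs=1e-6)
        assert fitted.P2 == pytest.approx(1.5, rel=1e-5)

    def test_recovers_half_life_from_synthetic_cohort(self):
        design = StudyDesign(
            start_age=21.5, groups=(("g", 200, 25.1),), seed=17
        )
        curve = km_estimate(generate_study(design)["g"])
        fitted = fit_three_param(curve)
        assert half_life(fitted) == pytest.approx(25.1, abs=0.3)

    def test_two_distinct_times_is_underdetermined(self):
        curve = KMCurve("g", 21.5, np.array([23.0, 24.0]),
                        np.array([50.0, 0.0]), 2)
        with pytest.raises(UnderdeterminedFitError):
            fit_three_param(curve)


class TestSensitivityRank:
    def test_zero_spread_gives_tie_break_order(self):
        p = GompertzParams(0.01, 1.0, 20.0)
        assert sensitivity_rank({"a": p, "b": p}) == ("P1", "P3", "P2")

    def test_relative_spread_example(self):
        stage1 = {
            "a": GompertzParams(0.01, 1.0, 20.0),
            "b": GompertzParams(0.011, 1.5, 21.0),
        }
        order = sensitivity_rank(stage1)
        # relative spreads: P1 ~0.095, P3 ~0.049, P2 = 0.4
        assert order[-1] == "P2"
        assert order == ("P3", "P1", "P2")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_rank({"a": GompertzParams(0.01, 1.0, 20.0)})


class TestSequentialFit:
    def test_identical_groups_give_identical_outputs(self):
        design = StudyDesign(start_age=21.5, groups=(("a", 30, 25.1),), seed=3)
        cohort = generate_study(design)["a"]
        curve = km_estimate(cohort)
        twin = KMCurve("b", curve.start_age, curve.times,
                       curve.survival_pct, curve.n_at_start)
        result = sequential_fit({"a": curve, "b": twin}, order="paper")
        assert result.final_params["a"] == result.final_params["b"]
        assert result.per_group_P2["a"] == result.per_group_P2["b"]
        # both groups agreeing on the averaged parameters means the
        # constrained stages reproduce the stage-1 fit quality
        c1, _, c3 = result.stage_costs["a"]
        assert c3 == pytest.approx(c1, rel=1e-4, abs=1e-6)

    def test_recovers_group_rates_sharing_scale_and_offset(self):
        # truth shares P1 and P3; groups differ only in the rate of aging
        p3 = 40.0
        laws = {
            "control": GompertzParams(LN2, p3 / 25.1, p3),
            "BMT": GompertzParams(LN2, p3 / 26.5, p3),
        }
        design = StudyDesign(
            start_age=21.5,
            groups=(("control", 500, laws["control"]), ("BMT", 500, laws["BMT"])),
            seed=9,
        )
        curves = {g: km_estimate(c) for g, c in generate_study(design).items()}
        result = sequential_fit(curves, order="paper")
        for group, law in laws.items():
            assert half_life(result.final_params[group]) == pytest.approx(
                half_life(law), abs=0.3
            )

    def test_paper_order_is_recorded(self, paper_cohorts):
        curves = {g: km_estimate(c) for g, c in paper_cohorts.items()}
        result = sequential_fit(curves, order="paper")
        assert result.sensitivity_order == ("P1", "P3", "P2")
        assert result.shared_P1 > 0
        assert set(result.per_group_P2) == {"control", "BMT"}

    def test_explicit_order_accepted_and_validated(self, paper_cohorts):
        curves = {g: km_estimate(c) for g, c in paper_cohorts.items()}
        result = sequential_fit(curves, order=("P1", "P2", "P3"))
        assert result.sensitivity_order == ("P1", "P2", "P3")
        with pytest.raises(ValueError):
            sequential_fit(curves, order=("P1", "P1", "P2"))

    def test_auto_order_comes_from_stage1_spread(self, paper_cohorts):
        curves = {g: km_estimate(c) for g, c in paper_cohorts.items()}
        result = sequential_fit(curves, order="auto")
        assert sorted(result.sensitivity_order) == ["P1", "P2", "P3"]

    def test_single_group_rejected(self, paper_cohorts):
        curve = km_estimate(paper_cohorts["control"])
        with pytest.raises(ValueError):
            sequential_fit({"control": curve})

    def test_size_weighted_average_matches_plain_mean_for_equal_groups(self):
        design = StudyDesign(
            groups=(("control", 40, 25.1), ("BMT", 40, 26.5)), seed=12
        )
        curves = {g: km_estimate(c) for g, c in generate_study(design).items()}
        plain = sequential_fit(curves, order="paper")
        weighted = sequential_fit(curves, order="paper", weighted=True)
        assert weighted.shared_P1 == pytest.approx(plain.shared_P1, rel=1e-9)
        assert weighted.shared_P3 == pytest.approx(plain.shared_P3, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_constraints_cannot_reduce_residual(self, seed):
        """Stages 2 and 3 add constraints, so the per-group squared residual
        cannot fall below the free three-parameter fit."""
        design = StudyDesign(
            groups=(("control", 40, 25.1), ("BMT", 40, 26.5)), seed=seed
        )
        curves = {g: km_estimate(c) for g, c in generate_study(design).items()}
        result = sequential_fit(curves, order="paper")
        for c1, c2, c3 in result.stage_costs.values():
            assert c3 >= c1 - 1e-9
            assert c2 >= c1 - 1e-9


class TestGoodnessOfFit:
    def test_perfect_fit_is_one(self):
        p = GompertzParams(LN2, 1.5, 1.5 * 25.1)
        curve = model_curve(p, np.linspace(22.0, 27.0, 10))
        assert goodness_of_fit(curve, p) == pytest.approx(1.0, abs=1e-12)

    def test_constant_observations_undefined(self):
        curve = KMCurve("g", 21.5, np.array([22.0, 23.0, 24.0]),
                        np.array([50.0, 50.0, 50.0]), 4)
        with pytest.raises(UndefinedCorrelationError):
            goodness_of_fit(curve, GompertzParams(LN2, 1.5, 37.65))

    def test_single_point_undefined(self):
        curve = KMCurve("g", 21.5, np.array([23.0]), np.array([0.0]), 1)
        with pytest.raises(UndefinedCorrelationError):
            goodness_of_fit(curve, GompertzParams(LN2, 1.5, 37.65))

    def test_matches_textbook_pearson_formula(self, paper_cohorts):
        curve = km_estimate(paper_cohorts["control"])
        params = params_from_half_life(25.1)
        r = goodness_of_fit(curve, params)
        y = curve.survival_pct
        f = survival_pct(params, curve.times)
        n = len(y)
        num = n * np.sum(y * f) - np.sum(y) * np.sum(f)
        den = math.sqrt(
            (n * np.sum(y**2) - np.sum(y) ** 2)
            * (n * np.sum(f**2) - np.sum(f) ** 2)
        )
        assert r == pytest.approx(num / den, abs=1e-12)
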