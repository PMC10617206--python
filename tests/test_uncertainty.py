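import numpy as np
import pytest

from meatcost.exceptions import (
    ConfigurationError,
    EmptyInputError,
    InvalidParameterError,
)
from meatcost.exposure import PrevalenceVector
from meatcost.relative_risk import DoseResponseRR
from meatcost.uncertainty import (
    DrawMatrix,
    PIFStratum,
    SimulationConfig,
    draw_prevalence,
    joint_draws,
    run_monte_carlo,
    summarize,
)

MEDIANS = np.array([35.0, 100.0, 170.0, 240.0, 330.0])


def make_stratum(
    p=(0.5, 0.25, 0.12, 0.08, 0.05),
    n_effective=2000.0,
    rr=1.15,
    ci=(1.05, 1.26),
    sex="male",
):
    baseline = PrevalenceVector(
        exposure="red_meat",
        sex=sex,
        period="t",
        p=np.array(p),
        n_effective=n_effective,
        medians=MEDIANS[: len(p)],
    )
    cf = np.zeros(len(p))
    cf[0] = 1.0
    return PIFStratum(
        exposure="red_meat",
        sex=sex,
        baseline=baseline,
        counterfactual=cf,
        dose_rr=DoseResponseRR("red_meat", sex, rr, ci[0], ci[1], 100.0),
        ref=35.0,
    )


class TestDrawPrevalence:
    def test_boundary_proportions_are_degenerate(self, rng):
        pv = PrevalenceVector("red_meat", "male", "t", np.array([1.0, 0.0]), 500.0)
        draws = draw_prevalence(pv, rng, size=200)
        assert np.all(draws == np.array([1.0, 0.0]))

    def test_infinite_sample_size_returns_point(self, rng):
        pv = PrevalenceVector(
            "red_meat", "male", "t", np.array([0.3, 0.7]), float("inf")
        )
        assert draw_prevalence(pv, rng).tolist() == [0.3, 0.7]

    def test_missing_effective_size_raises(self, rng):
        pv = PrevalenceVector("red_meat", "male", "t", np.array([0.3, 0.7]), None)
        with pytest.raises(ConfigurationError):
            draw_prevalence(pv, rng)

    def test_draws_renormalize_to_one(self, rng):
        pv = PrevalenceVector(
            "red_meat", "male", "t", np.array([0.5, 0.3, 0.2]), 50.0
        )
        draws = draw_prevalence(pv, rng, size=5000)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_binomial_spread_follows_sampling_formula(self, rng):
        n = 4000.0
        p = np.array([0.3, 0.4, 0.2, 0.1])
        pv = PrevalenceVector("red_meat", "male", "t", p, n)
        draws = draw_prevalence(pv, rng, size=10_000)
        binom_var = p * (1 - p) / n
        for i, p0 in enumerate(p):
            # delta-method sd of the renormalized category proportion
            grad_sq = np.full(p.size, p0**2)
            grad_sq[i] = (1 - p0) ** 2
            expected_sd = np.sqrt(np.sum(grad_sq * binom_var))
            assert np.std(draws[:, i]) == pytest.approx(expected_sd, rel=0.05)

    def test_dirichlet_mode_sums_to_one(self, rng):
        pv = PrevalenceVector(
            "red_meat", "male", "t", np.array([0.5, 0.3, 0.2]), 200.0
        )
        draws = draw_prevalence(pv, rng, mode="dirichlet", size=1000)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(draws >= 0)


class TestRunMonteCarlo:
    def test_zero_variance_inputs_collapse_to_point_estimate(self):
        s = make_stratum(n_effective=float("inf"), rr=1.15, ci=(1.15, 1.15))
        dm = run_monte_carlo([s], SimulationConfig(n_iterations=500, seed=3))
        assert np.all(dm.draws == s.point_pif())

    def test_same_seed_reproduces_bitwise(self):
        strata = [make_stratum(sex="male"), make_stratum(sex="female")]
        cfg = SimulationConfig(n_iterations=2000, seed=11)
        a = run_monte_carlo(strata, cfg)
        b = run_monte_carlo(strata, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_truncation_keeps_draws_in_unit_interval(self):
        # a counterfactual *increasing* risk makes raw PIF negative often
        s = make_stratum()
        worse = PIFStratum(
            exposure=s.exposure,
            sex=s.sex,
            baseline=s.baseline,
            counterfactual=np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
            dose_rr=s.dose_rr,
            ref=s.ref,
        )
        dm = run_monte_carlo([worse], SimulationConfig(n_iterations=1000, seed=5))
        assert dm.draws.min() >= 0.0
        assert dm.draws.max() <= 1.0

    def test_duplicate_strata_rejected(self):
        with pytest.raises(ConfigurationError):
            run_monte_carlo(
                [make_stratum(), make_stratum()], SimulationConfig(n_iterations=10)
            )

    def test_no_strata_rejected(self):
        with pytest.raises(EmptyInputError):
            run_monte_carlo([], SimulationConfig(n_iterations=10))

    def test_interval_narrows_with_larger_effective_sample(self):
        cfg = SimulationConfig(n_iterations=4000, seed=2)
        widths = []
        for n_eff in (500.0, 5000.0):
            s = make_stratum(n_effective=n_eff, ci=(1.15, 1.15))
            summary = summarize(run_monte_carlo([s], cfg), cfg)
            widths.append(summary["p97.5"].iloc[0] - summary["p2.5"].iloc[0])
        assert widths[1] < widths[0]


class TestSummarize:
    def test_constant_draws_give_flat_summary(self):
        dm = DrawMatrix(np.full((100, 1), 0.25), ("x",))
        cfg = SimulationConfig(n_iterations=100)
        row = summarize(dm, cfg).iloc[0]
        assert row.tolist() == [0.25, 0.25, 0.25]

    def test_linear_interpolation_median(self):
        draws = np.linspace(0.0, 1.0, 11)[:, None]
        dm = DrawMatrix(draws, ("x",))
        cfg = SimulationConfig(n_iterations=11)
        assert summarize(dm, cfg)["p50"].iloc[0] == pytest.approx(0.5)

    def test_empty_draws_raise(self):
        dm = DrawMatrix(np.empty((0, 1)), ("x",))
        with pytest.raises(EmptyInputError):
            summarize(dm, SimulationConfig(n_iterations=1))


def test_joint_draws_match_manual_combination():
    draws = np.array([[0.1, 0.2], [0.0, 0.5], [0.3, 0.3]])
    dm = DrawMatrix(draws, ("a", "b"))
    joint = joint_draws(dm, {"j": ["a", "b"]})
    expected = 1 - (1 - draws[:, 0]) * (1 - draws[:, 1])
    np.testing.assert_allclose(joint.column("j"), expected, atol=1e-15)


def test_config_validation():
    with pytest.raises(InvalidParameterError):
        SimulationConfig(n_iterations=0)
    with pytest.raises(InvalidParameterError):
        SimulationConfig(percentiles=(97.5, 50.0, 2.5))
    with pytest.raises(InvalidParameterError):
        SimulationConfig(prevalence_draw_mode="bootstrap")
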