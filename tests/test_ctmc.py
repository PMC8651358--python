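"""Generator construction, matrix exponentials, sojourn times, probabilities."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import expm as scipy_expm

from drmsm._expm import expm_batch
from drmsm.ctmc import (
    TRANSITIONS,
    CovariateModel,
    CovariateSchedule,
    ScheduleError,
    build_generator,
    generator_from_rates,
    homogeneous_model,
    interval_probability,
    pdr_probability,
    sojourn_reduction,
    sojourn_time,
    time_average_rate_matrix,
    transition_matrix,
)

from conftest import TRUTH_RATES


def random_generator_stack(seed, n=40, scale=1.0):
    rng = np.random.default_rng(seed)
    A = np.triu(rng.random((n, 5, 5)) * scale, 1)
    A[..., np.arange(5), np.arange(5)] = -A.sum(-1)
    return A


class TestExpmBatch:
    @pytest.mark.parametrize("scale", [0.05, 1.0, 8.0, 60.0])
    def test_agrees_with_scipy(self, scale):
        A = random_generator_stack(1, scale=scale)
        np.testing.assert_allclose(expm_batch(A), scipy_expm(A), atol=1e-12)

    def test_single_matrix_and_empty_stack(self):
        A = random_generator_stack(2, n=1)[0]
        np.testing.assert_allclose(expm_batch(A), scipy_expm(A), atol=1e-13)
        assert expm_batch(np.zeros((0, 5, 5))).shape == (0, 5, 5)

    def test_repeated_diagonal_entries(self):
        # Equal diagonal rates break spectral closed forms; scaling-and-squaring must not.
        q = 0.2
        A = np.array([[-q, q, 0.0], [0.0, -q, q], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(expm_batch(A), scipy_expm(A), atol=1e-13)


class TestBuildGenerator:
    def test_null_effects_reproduce_baseline(self, homogeneous_truth):
        Q = build_generator(homogeneous_truth, {})
        for (r, s), q in TRUTH_RATES.items():
            assert Q[r - 1, s - 1] == pytest.approx(q, rel=1e-12)

    def test_hispanic_hazard_ratio_multiplies_rates(self):
        model = CovariateModel(
            theta=homogeneous_model(TRUTH_RATES).theta,
            beta=np.array([np.log(1.31)]),
            covariates=("hispanic",),
            centering={"hispanic": 0.0},
        )
        Q = build_generator(model, {"hispanic": 1.0})
        assert Q[0, 1] == pytest.approx(0.209 * 1.31, rel=1e-10)
        assert Q[0, 1] == pytest.approx(0.27379, abs=5e-6)
        Q0 = build_generator(model, {"hispanic": 0.0})
        assert Q0[0, 1] == pytest.approx(0.209, rel=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_rows_conserve_and_structure_holds(self, seed):
        rng = np.random.default_rng(seed)
        model = CovariateModel(
            theta=rng.normal(-2, 1, 10),
            beta=rng.normal(0, 0.3, 2),
            covariates=("a", "b"),
            centering={"a": 1.0, "b": 0.0},
        )
        Q = build_generator(model, {"a": rng.normal(), "b": rng.normal()})
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(Q[np.tril_indices(5, k=-1)] == 0.0)
        assert np.all(Q[4] == 0.0)
        off = Q[np.triu_indices(5, k=1)]
        assert np.all(off >= 0)

    def test_dimension_mismatch_raises(self, hba1c_model):
        with pytest.raises(ValueError, match="missing covariate"):
            build_generator(hba1c_model, {"age": 50.0})


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, homogeneous_truth):
        Q = build_generator(homogeneous_truth, {})
        np.testing.assert_array_equal(transition_matrix(Q, 0.0), np.eye(5))

    def test_negative_time_raises(self, homogeneous_truth):
        with pytest.raises(ValueError):
            transition_matrix(build_generator(homogeneous_truth, {}), -0.5)

    def test_two_state_closed_form(self):
        # Only severe -> PDR active at the study's rate 0.172.
        model = homogeneous_model({(4, 5): 0.172})
        P = transition_matrix(build_generator(model, {}), 1.0)
        assert P[3, 4] == pytest.approx(1 - math.exp(-0.172), abs=1e-9)
        assert P[3, 4] == pytest.approx(0.15802, abs=5e-6)
        assert P[3, 3] == pytest.approx(0.84198, abs=5e-6)

    def test_rate_half_over_two_years(self):
        model = homogeneous_model({(4, 5): 0.5})
        P = transition_matrix(build_generator(model, {}), 2.0)
        assert P[3, 4] == pytest.approx(1 - math.exp(-1.0), abs=1e-9)

    def test_probability_structure(self, homogeneous_truth):
        P = transition_matrix(build_generator(homogeneous_truth, {}), 3.7)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((P >= 0) & (P <= 1))
        assert np.all(P[np.tril_indices(5, k=-1)] == 0.0)


class TestIntervalProbability:
    def test_degenerate_interval_is_identity(self, hba1c_model, hba1c_schedule):
        np.testing.assert_array_equal(
            interval_probability(hba1c_model, hba1c_schedule, 1.0, 1.0), np.eye(5)
        )

    def test_semigroup_identity(self, hba1c_model, hba1c_schedule):
        for t_mid in (0.5, 2.0, 3.7):
            P_full = interval_probability(hba1c_model, hba1c_schedule, 0.0, 5.0)
            P_split = interval_probability(
                hba1c_model, hba1c_schedule, 0.0, t_mid
            ) @ interval_probability(hba1c_model, hba1c_schedule, t_mid, 5.0)
            np.testing.assert_allclose(P_full, P_split, atol=1e-10)

    def test_identical_segments_match_single_exponential(self, homogeneous_truth):
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 1.0, 2.0]), values=np.zeros((2, 0)), names=()
        )
        P = interval_probability(homogeneous_truth, sched, 0.0, 2.0)
        Q = build_generator(homogeneous_truth, {})
        np.testing.assert_allclose(P, transition_matrix(Q, 2.0), atol=1e-12)

    def test_piecewise_two_state_closed_form(self):
        # severe->PDR rate 0.5 on [0,1) then 1.0 on [1,2): survival e^-0.5 * e^-1.
        model = CovariateModel(
            theta=homogeneous_model({(4, 5): 0.5}).theta,
            beta=np.array([math.log(2.0)]),
            covariates=("x",),
            centering={"x": 0.0},
        )
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 1.0, 2.0]),
            values=np.array([[0.0], [1.0]]),
            names=("x",),
        )
        P = interval_probability(model, sched, 0.0, 2.0)
        assert P[3, 4] == pytest.approx(1 - math.exp(-1.5), abs=1e-10)
        assert P[3, 4] == pytest.approx(0.77687, abs=5e-6)

    def test_extension_carries_last_covariates(self, hba1c_model, hba1c_schedule):
        # Beyond the last visit the HbA1c stays at 11.0.
        P = interval_probability(hba1c_model, hba1c_schedule, 5.0, 8.0)
        shifted = hba1c_model.rates({"hba1c": 11.0})
        Q = generator_from_rates(shifted)
        np.testing.assert_allclose(P, transition_matrix(Q, 3.0), atol=1e-12)

    def test_uncovered_interval_raises(self, hba1c_model, hba1c_schedule):
        with pytest.raises(ScheduleError):
            interval_probability(hba1c_model, hba1c_schedule, -1.0, 2.0)


def _sojourn_quadrature(lam_of_t, t0, horizon, points):
    """Independent oracle: adaptive quadrature of the survival function."""

    def surv(t):
        val, _ = quad(lam_of_t, t0, t, points=points, limit=200)
        return math.exp(-val)

    val, _ = quad(surv, t0, t0 + horizon, points=points, limit=200)
    return val


class TestSojournTime:
    def test_constant_rate_closed_form(self, flat_schedule):
        model = homogeneous_model({(4, 5): 0.172})
        S = sojourn_time(model, flat_schedule, 4, horizon=20.0)
        assert S == pytest.approx((1 - math.exp(-0.172 * 20)) / 0.172, abs=1e-10)
        assert S == pytest.approx(5.62753, abs=5e-6)

    def test_piecewise_rates_match_quadrature(self):
        # Exit rate 0.5 on [0,1) then 1.0 afterwards, long horizon.
        model = CovariateModel(
            theta=homogeneous_model({(4, 5): 0.5}).theta,
            beta=np.array([math.log(2.0)]),
            covariates=("x",),
            centering={"x": 0.0},
        )
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 1.0, 60.0]),
            values=np.array([[0.0], [1.0]]),
            names=("x",),
        )
        S = sojourn_time(model, sched, 4, horizon=60.0)
        expected = (1 - math.exp(-0.5)) / 0.5 + math.exp(-0.5) * 1.0
        assert S == pytest.approx(expected, abs=1e-8)
        assert S == pytest.approx(1.39347, abs=5e-6)

    def test_quadrature_oracle_on_multi_segment_schedule(self, hba1c_model, hba1c_schedule):
        for state in (1, 2, 3, 4):
            S = sojourn_time(hba1c_model, hba1c_schedule, state, horizon=20.0)
            cols = [j for j, (r, _) in enumerate(TRANSITIONS) if r == state]

            def lam(t):
                h = 9.7 if t < 2.0 else 11.0
                return float(hba1c_model.rates({"hba1c": h})[cols].sum())

            oracle = _sojourn_quadrature(lam, 0.0, 20.0, points=[2.0, 5.0])
            assert S == pytest.approx(oracle, abs=1e-8)

    def test_zero_exit_rate_returns_horizon(self, flat_schedule):
        model = homogeneous_model({})
        assert sojourn_time(model, flat_schedule, 2, horizon=17.0) == pytest.approx(
            17.0, rel=1e-12
        )

    def test_infinite_horizon_limit_is_inverse_rate(self):
        lam = 0.25
        model = homogeneous_model({(3, 4): lam})
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 300 / lam]), values=np.zeros((1, 0)), names=()
        )
        S = sojourn_time(model, sched, 3, horizon=200 / lam)
        assert abs(S - 1 / lam) / (1 / lam) < 1e-6

    def test_absorbing_state_raises(self, homogeneous_truth, flat_schedule):
        with pytest.raises(ValueError):
            sojourn_time(homogeneous_truth, flat_schedule, 5)

    def test_truncation_diagnostics(self, flat_schedule):
        model = homogeneous_model({(4, 5): 0.172})
        S, diag = sojourn_time(model, flat_schedule, 4, horizon=20.0, return_diagnostics=True)
        assert diag["survival_at_horizon"] == pytest.approx(math.exp(-3.44), rel=1e-10)
        assert diag["tail_bound"] == pytest.approx(math.exp(-3.44) / 0.172, rel=1e-10)
        # sojourn + tail equals the infinite-horizon value for a constant rate
        assert S + diag["tail_bound"] == pytest.approx(1 / 0.172, rel=1e-10)


class TestSojournReduction:
    def test_null_coefficient_gives_zero_reduction(self, flat_schedule):
        model = CovariateModel(
            theta=homogeneous_model(TRUTH_RATES).theta,
            beta=np.array([0.0]),
            covariates=("hba1c",),
            centering={"hba1c": 9.7},
        )
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 30.0]), values=np.array([[9.7]]), names=("hba1c",)
        )
        pct, yrs = sojourn_reduction(model, sched, 1, "hba1c")
        assert pct == pytest.approx(0.0, abs=1e-12)
        assert yrs == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("h", [1.05, 1.1, 1.31, 2.0])
    def test_homogeneous_percent_is_closed_form_for_any_state(self, h):
        # With one shared hazard ratio and a constant schedule, the percent
        # reduction is (1 - 1/h)*100 regardless of the baseline rate, in the
        # long-horizon limit.
        model = CovariateModel(
            theta=homogeneous_model(TRUTH_RATES).theta,
            beta=np.array([math.log(h)]),
            covariates=("z",),
            centering={"z": 0.0},
        )
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 4000.0]), values=np.array([[0.0]]), names=("z",)
        )
        for state in (1, 2, 3, 4):
            pct, yrs = sojourn_reduction(model, sched, state, "z", horizon=4000.0)
            assert pct == pytest.approx((1 - 1 / h) * 100, rel=1e-6)
            assert yrs > 0

    def test_piecewise_schedule_matches_quadrature(self, hba1c_model, hba1c_schedule):
        state = 2
        pct, yrs = sojourn_reduction(hba1c_model, hba1c_schedule, state, "hba1c", 1.0,
                                     horizon=20.0)
        cols = [j for j, (r, _) in enumerate(TRANSITIONS) if r == state]

        def lam(shift):
            def f(t):
                h = (9.7 if t < 2.0 else 11.0) + shift
                return float(hba1c_model.rates({"hba1c": h})[cols].sum())

            return f

        S0 = _sojourn_quadrature(lam(0.0), 0.0, 20.0, points=[2.0])
        S1 = _sojourn_quadrature(lam(1.0), 0.0, 20.0, points=[2.0])
        assert pct == pytest.approx((1 - S1 / S0) * 100, abs=1e-8)
        assert yrs == pytest.approx(S0 - S1, abs=1e-8)

    def test_unknown_covariate_raises(self, hba1c_model, hba1c_schedule):
        with pytest.raises(ValueError, match="not in model"):
            sojourn_reduction(hba1c_model, hba1c_schedule, 1, "age")


class TestPdrProbability:
    def test_zero_window_is_zero(self, homogeneous_truth, flat_schedule):
        for state in (1, 2, 3, 4):
            assert pdr_probability(homogeneous_truth, flat_schedule, state, window=0.0) == 0.0

    def test_severe_one_year_closed_form(self, flat_schedule):
        model = homogeneous_model({(4, 5): 0.172})
        p = pdr_probability(model, flat_schedule, 4, window=1.0)
        assert p == pytest.approx(1 - math.exp(-0.172), abs=1e-9)

    def test_monotone_in_window(self, homogeneous_truth, flat_schedule):
        for state in (1, 2, 3, 4):
            probs = [
                pdr_probability(homogeneous_truth, flat_schedule, state, window=w)
                for w in (0.5, 1.0, 2.0, 4.0, 7.0, 12.0)
            ]
            assert np.all(np.diff(probs) > 0)


class TestTimeAverageRateMatrix:
    def test_homogeneous_single_patient_equals_generator(self, homogeneous_truth, flat_schedule):
        mean_Q, sd_Q = time_average_rate_matrix(homogeneous_truth, [flat_schedule])
        np.testing.assert_allclose(
            mean_Q, build_generator(homogeneous_truth, {}), atol=1e-12
        )
        np.testing.assert_array_equal(sd_Q, 0.0)

    def test_two_equal_segments_average_arithmetically(self):
        # q45 = 0.1 on the first half, 0.3 on the second -> 0.2 average.
        model = CovariateModel(
            theta=homogeneous_model({(4, 5): 0.1}).theta,
            beta=np.array([math.log(3.0)]),
            covariates=("x",),
            centering={"x": 0.0},
        )
        sched = CovariateSchedule(
            breakpoints=np.array([0.0, 1.0, 2.0]),
            values=np.array([[0.0], [1.0]]),
            names=("x",),
        )
        mean_Q, _ = time_average_rate_matrix(model, [sched])
        assert mean_Q[3, 4] == pytest.approx(0.2, rel=1e-12)

    def test_matches_direct_quadrature(self, hba1c_model, hba1c_schedule):
        mean_Q, _ = time_average_rate_matrix(hba1c_model, [hba1c_schedule])
        for j, (r, s) in enumerate(TRANSITIONS):
            def q_rs(t):
                h = 9.7 if t < 2.0 else 11.0
                return float(hba1c_model.rates({"hba1c": h})[j])

            val, _ = quad(q_rs, 0.0, 5.0, points=[2.0])
            assert mean_Q[r - 1, s - 1] == pytest.approx(val / 5.0, abs=1e-10)

    def test_overrides_force_covariates(self, hba1c_model, hba1c_schedule):
        mean_Q, _ = time_average_rate_matrix(
            hba1c_model, [hba1c_schedule], overrides={"hba1c": 9.7}
        )
        np.testing.assert_allclose(
            mean_Q, build_generator(hba1c_model, {"hba1c": 9.7}), atol=1e-12
        )

    def test_empty_schedule_set_raises(self, hba1c_model):
        with pytest.raises(ValueError):
            time_average_rate_matrix(hba1c_model, [])


class TestSerialization:
    def test_json_round_trip(self, hba1c_model, tmp_path):
        path = tmp_path / "model.json"
        hba1c_model.to_json(path)
        back = CovariateModel.from_json(path)
        np.testing.assert_array_equal(back.theta, hba1c_model.theta)
        np.testing.assert_array_equal(back.beta, hba1c_model.beta)
        assert back.covariates == hba1c_model.covariates
        assert back.centering == hba1c_model.centering
        doc = json.loads(path.read_text())
        assert doc["states"][4] == "PDR"
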