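import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import KNOWN_POLYS
from naive_oracles import naive_kalman_filter
from tcore.ekf import (
    EKFModelSpec,
    EKFParams,
    EKFState,
    ObsChannel,
    SeedModel,
    ekf_predict,
    ekf_update,
    fit_ekf_params,
    fit_observation_model,
    fit_process_model,
    fit_seed_regression,
    load_params,
    predict_trial,
    save_params,
    seed_tc,
)
from tcore.simulate import SubjectProfile


def _profile(sex="male", subject_id="s1"):
    return SubjectProfile(
        subject_id=subject_id, sex=sex, age=30, height=175.0, mass=70.0
    )


def _params(**over):
    base = dict(
        seed=SeedModel(b0=36.9, b_female=0.2),
        channels=(ObsChannel("skin_temp_mean", (4.0, 0.8), 0.05),),
        q=1e-4,
    )
    base.update(over)
    return EKFParams(**base)


def _minute_frame(channel_values, tc_gt=None, trial_id="t1", subject_id="s1"):
    n = len(next(iter(channel_values.values())))
    frame = pd.DataFrame(
        {
            "trial_id": [trial_id] * n,
            "subject_id": [subject_id] * n,
            "minute": np.arange(n),
            **channel_values,
        }
    )
    frame["tc_gt"] = np.nan if tc_gt is None else np.asarray(tc_gt, dtype=float)
    frame["excluded"] = False
    return frame


class TestChannels:
    def test_polynomial_evaluation_and_jacobian(self):
        ch = ObsChannel("hr_mean", (1348.0, -108.0, 2.0), 1.0)
        assert ch.h(37.0) == pytest.approx(1348.0 - 108.0 * 37 + 2.0 * 37**2)
        assert ch.jacobian(37.0) == pytest.approx(-108.0 + 4.0 * 37)  # 40

    def test_linear_channel_jacobian_is_slope(self):
        ch = ObsChannel("skin_temp_mean", (4.0, 0.8), 0.05)
        assert ch.jacobian(36.0) == 0.8
        assert ch.jacobian(39.0) == 0.8

    def test_degree_above_two_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            ObsChannel("x", (1.0, 1.0, 1.0, 1.0), 1.0)

    def test_nonpositive_noise_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ObsChannel("x", (1.0, 1.0), 0.0)


class TestParamsValidation:
    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            _params(q=0.0)

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            _params(channels=())

    def test_state_requires_positive_variance(self):
        with pytest.raises(ValueError):
            EKFState(tc_hat=37.0, variance=0.0)


class TestSeed:
    def test_seed_tc_by_sex(self):
        p = _params()
        assert seed_tc(_profile("male"), p) == pytest.approx(36.9)
        assert seed_tc(_profile("female"), p) == pytest.approx(37.1)

    def test_seed_regression_recovers_group_means_exactly(self):
        # two trials per sex; OLS on a binary input reproduces group means
        rows = []
        profiles = {}
        for i, (sex, tc0) in enumerate(
            [("male", 36.85), ("male", 36.95), ("female", 37.05), ("female", 37.15)]
        ):
            sid = f"s{i}"
            profiles[sid] = _profile(sex, sid)
            rows.append(
                _minute_frame({"skin_temp_mean": [33.0, 33.0]}, [tc0, tc0 + 0.1], f"t{i}", sid)
            )
        seed = fit_seed_regression(pd.concat(rows, ignore_index=True), profiles)
        assert seed.b0 == pytest.approx(36.9, abs=1e-12)
        assert seed.b_female == pytest.approx(0.2, abs=1e-12)

    def test_single_sex_training_set_warns_and_uses_intercept_only(self):
        profiles = {"s0": _profile("male", "s0"), "s1": _profile("male", "s1")}
        frame = pd.concat(
            [
                _minute_frame({"skin_temp_mean": [33.0]}, [36.8], "t0", "s0"),
                _minute_frame({"skin_temp_mean": [33.0]}, [37.0], "t1", "s1"),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="single-sex"):
            seed = fit_seed_regression(frame, profiles)
        assert seed.b0 == pytest.approx(36.9)
        assert seed.b_female == 0.0

    def test_no_reference_data_rejected(self):
        frame = _minute_frame({"skin_temp_mean": [33.0, 33.0]})
        with pytest.raises(ValueError):
            fit_seed_regression(frame, {"s1": _profile()})


class TestObservationFit:
    def test_noiseless_linear_channel_recovered_exactly(self):
        tc = np.linspace(36.5, 39.0, 40)
        frame = _minute_frame({"skin_temp_mean": 4.0 + 0.8 * tc}, tc)
        (ch,) = fit_observation_model(frame, [("skin_temp_mean", 1)])
        assert ch.coeffs[0] == pytest.approx(4.0, abs=1e-8)
        assert ch.coeffs[1] == pytest.approx(0.8, abs=1e-8)
        assert ch.r == pytest.approx(1e-12)  # floored residual variance

    def test_noiseless_quadratic_channel_recovered(self):
        tc = np.linspace(36.5, 39.0, 40)
        c0, c1, c2 = KNOWN_POLYS["hr"]
        frame = _minute_frame({"hr_mean": c0 + c1 * tc + c2 * tc**2}, tc)
        (ch,) = fit_observation_model(frame, [("hr_mean", 2)])
        fitted = np.polynomial.polynomial.polyval(tc, np.asarray(ch.coeffs))
        assert np.allclose(fitted, c0 + c1 * tc + c2 * tc**2, atol=1e-6)

    def test_noise_variance_estimate_matches_residuals(self):
        rng = np.random.default_rng(0)
        tc = np.linspace(36.5, 39.0, 500)
        z = 4.0 + 0.8 * tc + rng.normal(0, 0.2, 500)
        frame = _minute_frame({"skin_temp_mean": z}, tc)
        (ch,) = fit_observation_model(frame, [("skin_temp_mean", 1)])
        assert ch.r == pytest.approx(0.04, rel=0.2)

    def test_constant_reference_rejected(self):
        frame = _minute_frame({"skin_temp_mean": [33.0, 33.1, 33.2]}, [37.0, 37.0, 37.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_observation_model(frame, [("skin_temp_mean", 1)])

    def test_unknown_column_rejected(self):
        frame = _minute_frame({"skin_temp_mean": [33.0, 33.1]}, [37.0, 37.5])
        with pytest.raises(ValueError, match="nope"):
            fit_observation_model(frame, [("nope", 1)])


class TestProcessFit:
    def test_random_walk_q_is_increment_variance(self):
        tc = [37.0, 37.1, 37.3, 37.2]
        frame = _minute_frame({"skin_temp_mean": [33.0] * 4}, tc)
        _, q = fit_process_model(frame)
        assert q == pytest.approx(np.var(np.diff(tc)))

    def test_increments_do_not_cross_trial_boundaries(self):
        f1 = _minute_frame({"skin_temp_mean": [33.0] * 2}, [37.0, 37.1], "t1")
        f2 = _minute_frame({"skin_temp_mean": [33.0] * 2}, [39.0, 39.1], "t2")
        _, q = fit_process_model(pd.concat([f1, f2], ignore_index=True))
        # both trials have the same increment 0.1; a boundary-crossing bug
        # would see a spurious +1.9 jump and inflate q enormously
        assert q == pytest.approx(1e-8)  # var([0.1, 0.1]) = 0, floored

    def test_drift_coefficient_recovered_from_noiseless_ramp(self):
        intensity = np.array([0.4, 0.4, 0.8, 0.8, 0.8, 0.4])
        tc = np.concatenate([[37.0], 37.0 + np.cumsum(0.02 * intensity[1:])])
        frame = _minute_frame(
            {"skin_temp_mean": [33.0] * 6, "intensity_mean": intensity}, tc
        )
        drift, q = fit_process_model(frame, ["intensity_mean"])
        assert drift["intensity_mean"] == pytest.approx(0.02, abs=1e-10)
        assert q == pytest.approx(1e-8)


class TestFilterSteps:
    def test_random_walk_predict_only_inflates_variance(self):
        p = _params()
        s = ekf_predict(EKFState(37.0, 0.25), p, {})
        assert s.tc_hat == 37.0
        assert s.variance == pytest.approx(0.25 + 1e-4)

    def test_drift_predict_shifts_mean(self):
        p = _params(drift={"intensity_mean": 0.02})
        s = ekf_predict(EKFState(37.0, 0.25), p, {"intensity_mean": 0.8})
        assert s.tc_hat == pytest.approx(37.016)

    def test_missing_drift_feature_is_an_error(self):
        p = _params(drift={"intensity_mean": 0.02})
        with pytest.raises(KeyError, match="intensity_mean"):
            ekf_predict(EKFState(37.0, 0.25), p, {})

    def test_single_linear_update_hand_arithmetic(self):
        # identity channel z = Tc + noise: H=1, K = 0.25/(0.25+0.05) = 5/6
        p = _params(channels=(ObsChannel("c", (0.0, 1.0), 0.05),))
        s = ekf_update(EKFState(37.0, 0.25), {"c": 37.6}, p)
        assert s.tc_hat == pytest.approx(37.0 + (5.0 / 6.0) * 0.6)
        assert s.variance == pytest.approx((1.0 - 5.0 / 6.0) * 0.25)

    def test_nan_observation_skipped(self):
        p = _params()
        s0 = EKFState(37.0, 0.25)
        s = ekf_update(s0, {"skin_temp_mean": np.nan}, p)
        assert s.tc_hat == s0.tc_hat and s.variance == s0.variance

    def test_update_never_inflates_variance(self):
        p = _params(
            channels=(
                ObsChannel("a", (0.0, 1.0), 0.05),
                ObsChannel("b", (4.0, 0.8), 0.1),
            )
        )
        s = ekf_update(EKFState(37.0, 0.25), {"a": 37.4, "b": 33.8}, p)
        assert s.variance <= 0.25

    @given(
        st.floats(36.0, 40.0),
        st.floats(36.0, 40.0),
        st.floats(0.01, 1.0),
        st.floats(0.001, 1.0),
    )
    def test_posterior_between_prior_and_observation(self, tc0, z, var, r):
        # single identity channel: the update is a convex combination
        p = _params(channels=(ObsChannel("c", (0.0, 1.0), r),))
        s = ekf_update(EKFState(tc0, var), {"c": z}, p)
        lo, hi = min(tc0, z), max(tc0, z)
        assert lo - 1e-9 <= s.tc_hat <= hi + 1e-9

    def test_sequential_updates_match_joint_kalman_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        c0 = np.array([0.0, 4.0])
        c1 = np.array([1.0, 0.8])
        r = np.array([0.05, 0.02])
        tc_true = 37.0 + 0.03 * np.arange(n)
        z = c0 + c1[None, :] * tc_true[:, None] + rng.normal(0, 0.1, (n, 2))
        p = _params(
            channels=(
                ObsChannel("a", (0.0, 1.0), 0.05),
                ObsChannel("b", (4.0, 0.8), 0.02),
            ),
            q=1e-3,
        )
        state = EKFState(36.9, 0.25)
        means = []
        for t in range(n):
            state = ekf_predict(state, p, {})
            state = ekf_update(state, {"a": z[t, 0], "b": z[t, 1]}, p)
            means.append(state.tc_hat)
        oracle_means, _ = naive_kalman_filter(
            36.9, 0.25, z, np.zeros((n, 0)), c0, c1, r, np.array([]), 1e-3
        )
        assert np.max(np.abs(np.asarray(means) - oracle_means)) < 1e-10


class TestPredictTrial:
    def test_one_estimate_per_minute_and_causal_order(self):
        p = _params()
        frame = _minute_frame({"skin_temp_mean": np.linspace(33.0, 34.0, 10)})
        out = predict_trial(frame, p, _profile())
        assert len(out) == 10
        assert list(out["minute"]) == list(range(10))
        assert np.isfinite(out["tc_hat"]).all()

    def test_bias_offset_shifts_emitted_estimates_only(self):
        frame = _minute_frame({"skin_temp_mean": np.linspace(33.0, 34.5, 15)})
        base = predict_trial(frame, _params(bias_offset=0.0), _profile())
        shifted = predict_trial(frame, _params(bias_offset=0.1), _profile())
        assert np.allclose(shifted["tc_hat"], base["tc_hat"] + 0.1)
        assert np.allclose(shifted["variance"], base["variance"])

    def test_all_channels_missing_minute_passes_state_through(self):
        vals = np.array([33.0, np.nan, 33.0])
        frame = _minute_frame({"skin_temp_mean": vals})
        out = predict_trial(frame, _params(q=1e-4), _profile())
        # minute 1 has only the time update: the estimate is unchanged
        assert out.loc[1, "tc_hat"] == pytest.approx(out.loc[0, "tc_hat"])
        assert out.loc[1, "variance"] == pytest.approx(out.loc[0, "variance"] + 1e-4)

    def test_shuffled_minute_rows_give_same_result(self):
        frame = _minute_frame({"skin_temp_mean": np.linspace(33.0, 34.0, 12)})
        base = predict_trial(frame, _params(), _profile())
        perm = predict_trial(
            frame.sample(frac=1.0, random_state=3), _params(), _profile()
        )
        pd.testing.assert_frame_equal(
            base.reset_index(drop=True), perm.reset_index(drop=True)
        )

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_trial(_minute_frame({"skin_temp_mean": []}), _params(), _profile())

    def test_converges_to_truth_with_informative_channel(self):
        # identity channel with small noise: estimate locks on within minutes
        tc_true = np.full(30, 38.2)
        frame = _minute_frame({"c": tc_true})
        p = _params(channels=(ObsChannel("c", (0.0, 1.0), 0.01),))
        out = predict_trial(frame, p, _profile())
        assert abs(out["tc_hat"].iloc[-1] - 38.2) < 0.01


class TestEndToEndFit:
    def test_fit_on_known_polynomial_cohort_recovers_linear_channels(
        self, frame_known, profiles_known
    ):
        spec = EKFModelSpec()
        params = fit_ekf_params(frame_known, profiles_known, spec)
        by_name = {c.name: c for c in params.channels}
        st_ch = by_name["skin_temp_mean"]
        assert st_ch.coeffs[1] == pytest.approx(KNOWN_POLYS["skin_temp"][1], abs=0.05)
        rh_ch = by_name["skin_rh_mean"]
        assert rh_ch.coeffs[1] == pytest.approx(KNOWN_POLYS["skin_rh"][1], abs=0.6)

    def test_save_load_round_trip_is_exact(self, tmp_path):
        p = _params(drift={"intensity_mean": 0.0213}, bias_offset=0.05)
        path = save_params(p, tmp_path / "params.json")
        back = load_params(path)
        assert back == p


def test_structure_signature_detects_mismatch():
    a = _params()
    b = _params(channels=(ObsChannel("other", (0.0, 1.0), 0.1),))
    assert a.structure() != b.structure()
    assert a.structure() == _params(q=0.5).structure()
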