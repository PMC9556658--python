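"""Tests of the history-kernel psychometric model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from choicehist.history import (build_history_design, exp_basis,
                                fit_history_model, kernel_summary,
                                simulate_history_observer)


class TestExpBasis:
    def test_near_uniform_for_large_tau(self):
        b = exp_basis(K=7, taus=(1e9,))
        assert np.allclose(b[0], 1 / 7, atol=1e-6)

    def test_concentrates_on_lag1_for_small_tau(self):
        b = exp_basis(K=7, taus=(1e-3,))
        assert b[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(b[0, 1:] < 1e-6)

    def test_matches_direct_evaluation(self):
        b = exp_basis(K=7, taus=(2.0,))
        raw = np.exp(-np.arange(7) / 2.0)
        assert np.allclose(b[0], raw / raw.sum())

    @given(K=st.integers(1, 10), tau=st.floats(0.1, 20))
    def test_nonnegative_and_decreasing(self, K, tau):
        b = exp_basis(K=K, taus=(tau,))
        assert np.all(b >= 0)
        assert np.all(np.diff(b[0]) <= 1e-15)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            exp_basis(7, taus=(0.0,))


class TestDesign:
    def test_constant_choices_give_unit_features(self):
        df = simulate_history_observer(100, seed=0)
        df["choice"] = 1
        des = build_history_design(df)
        choice_feats = des.features[des.valid, 3:]
        assert np.allclose(choice_feats, 1.0)  # basis rows are unit-sum

    def test_features_match_brute_force_reconstruction(self):
        df = simulate_history_observer(300, seed=1, block_size=60)
        des = build_history_design(df)
        basis = des.basis
        ch = df["choice"].to_numpy(dtype=float)
        st_ = df["stimulus"].to_numpy(dtype=float)
        blk = df["block"].to_numpy()
        for t in [75, 120, 250]:
            lags_c = np.array([ch[t - k] if blk[t - k] == blk[t] else 0.0
                               for k in range(1, 8)])
            lags_s = np.array([st_[t - k] if blk[t - k] == blk[t] else 0.0
                               for k in range(1, 8)])
            assert np.allclose(des.features[t, :3], basis @ lags_s)
            assert np.allclose(des.features[t, 3:], basis @ lags_c)

    def test_block_starts_are_masked(self):
        df = simulate_history_observer(200, seed=2, block_size=50)
        des = build_history_design(df, K=7)
        starts = df.index[df["trial"] <= 7]
        assert not des.valid[starts].any()
        assert des.valid[df.index[df["trial"] > 7]].all()

    def test_unsorted_input_rejected(self):
        df = simulate_history_observer(50, seed=3)
        with pytest.raises(ValueError):
            build_history_design(df.iloc[::-1].reset_index(drop=True))


class TestFit:
    def test_logistic_identity_at_zero(self):
        # all-zero predictors with zero bias and lapses predict exactly 0.5
        assert expit(0.0) == 0.5

    def test_omega_reconstruction_identity(self):
        df = simulate_history_observer(3000, omega_choice=0.3 * 0.5 ** np.arange(7),
                                       seed=4, block_size=500)
        fit = fit_history_model(build_history_design(df), compute_se=False)
        for cls in ("stimulus", "choice"):
            assert np.allclose(fit.omega[cls],
                               fit.basis_coefs[cls] @ exp_basis(7), atol=1e-12)

    def test_nesting_property(self):
        df = simulate_history_observer(4000, omega_choice=0.4 * 0.6 ** np.arange(7),
                                       gamma_lapse=0.02, lambda_lapse=0.02,
                                       seed=5, block_size=500)
        fit = fit_history_model(build_history_design(df), compute_se=False)
        assert fit.loglik >= fit.loglik_nohistory

    def test_sign_flip_invariance(self):
        df = simulate_history_observer(6000, omega_choice=0.4 * 0.6 ** np.arange(7),
                                       gamma_lapse=0.02, lambda_lapse=0.02,
                                       seed=6, block_size=500)
        flipped = df.copy()
        for col in ("stimulus", "choice", "coherence_delta"):
            flipped[col] = -flipped[col]
        f1 = fit_history_model(build_history_design(df), compute_se=False)
        f2 = fit_history_model(build_history_design(flipped), compute_se=False)
        assert np.allclose(f1.omega["choice"], f2.omega["choice"], atol=0.02)
        assert f1.alpha_sens == pytest.approx(f2.alpha_sens, abs=0.05)

    def test_sensitivity_recovered_with_graded_levels(self):
        df = simulate_history_observer(10_000, alpha=1.0, seed=7,
                                       block_size=500,
                                       intensity_levels=(0.5, 1.0, 2.0))
        fit = fit_history_model(build_history_design(df, zscore_intensity=False),
                                compute_se=False)
        assert fit.alpha_sens == pytest.approx(1.0, rel=0.10)


class TestKernelSummary:
    def _fits(self, omegas, seeds):
        fits = {}
        for sid, (om, sd) in enumerate(zip(omegas, seeds)):
            df = simulate_history_observer(4000, omega_choice=om,
                                           gamma_lapse=0.02, lambda_lapse=0.02,
                                           seed=sd, block_size=500)
            fits[sid] = fit_history_model(build_history_design(df),
                                          compute_se=False)
        return fits

    def test_group_mean_recovers_generative_kernel(self):
        om = 0.4 * 0.6 ** np.arange(7)
        fits = self._fits([om] * 6, range(6))
        summ = kernel_summary(fits)
        ch = summ[(summ["class"] == "choice")].set_index("lag")
        for k in (1, 2):
            assert abs(ch.loc[k, "mean_weight"] - om[k - 1]) <= 3 * ch.loc[k, "sem"]

    def test_choice_parity_under_global_sign_flip(self):
        om = 0.4 * 0.6 ** np.arange(7)
        df = simulate_history_observer(4000, omega_choice=om, seed=11,
                                       block_size=500)
        flipped = df.copy()
        for col in ("stimulus", "choice", "coherence_delta"):
            flipped[col] = -flipped[col]
        f1 = fit_history_model(build_history_design(df), compute_se=False)
        f2 = fit_history_model(build_history_design(flipped), compute_se=False)
        s1 = kernel_summary({0: f1, 1: f1})
        s2 = kernel_summary({0: f2, 1: f2})
        m1 = s1[s1["class"] == "choice"]["mean_weight"].to_numpy()
        m2 = s2[s2["class"] == "choice"]["mean_weight"].to_numpy()
        assert np.allclose(m1, m2, atol=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kernel_summary({})


class TestOutcomeSplit:
    def test_split_classes_reassemble_plain_features(self):
        df = simulate_history_observer(2000, omega_choice=0.3 * 0.5 ** np.arange(7),
                                       seed=21, block_size=500)
        plain = build_history_design(df)
        split = build_history_design(df, split_by_outcome=True)
        assert split.classes == ("stimulus_correct", "stimulus_error",
                                 "choice_correct", "choice_error")
        B = plain.basis.shape[0]
        # correct + error components sum to the unsplit features
        stim_sum = split.features[:, :B] + split.features[:, B:2 * B]
        choice_sum = split.features[:, 2 * B:3 * B] + split.features[:, 3 * B:]
        assert np.allclose(stim_sum, plain.features[:, :B])
        assert np.allclose(choice_sum, plain.features[:, B:])

    def test_winstay_loseswitch_agent_separates_outcome_kernels(self):
        # agent repeats after correct, alternates after errors: the fitted
        # outcome-split choice kernels should have opposite lag-1 signs
        import pandas as pd

        rng = np.random.default_rng(22)
        n = 8000
        stim = rng.choice([-1.0, 1.0], n)
        choice = np.empty(n)
        for t in range(n):
            bias = 0.0
            if t > 0:
                prev_ok = 1.0 if choice[t - 1] == stim[t - 1] else -1.0
                bias = 0.6 * prev_ok * choice[t - 1]
            p = expit(bias + 1.0 * stim[t])
            choice[t] = 1.0 if rng.random() < p else -1.0
        df = pd.DataFrame({
            "subject_id": 1, "session": 1, "block": np.arange(n) // 1000 + 1,
            "trial": np.arange(n) % 1000 + 1, "stimulus": stim.astype(int),
            "coherence_delta": stim, "choice": choice.astype(int),
            "rt": 1.0, "action": "right",
            "outcome": np.where(choice == stim, "correct", "error"),
            "choice_hand_map": "right"})
        fit = fit_history_model(build_history_design(df, split_by_outcome=True),
                                compute_se=False)
        assert fit.omega["choice_correct"][0] > 0.2
        assert fit.omega["choice_error"][0] < -0.2
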