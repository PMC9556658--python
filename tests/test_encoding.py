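"""Tests of the mixed-effects encoding models, FDR, and signal preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from choicehist.encoding import (fdr_adjust, fit_encoding,
                                 fit_group_interaction,
                                 flip_motor_lateralization, residualize_alpha,
                                 timeresolved_encoding)
from choicehist.experiments import brute_force_bh


def _synthetic_panel(rng, n_subjects=20, n_trials=150, effect=0.0,
                     icept_sd=1.0, noise_sd=1.0, group_effects=None):
    """Direct panel generator: y = icept_s + effect_s * c_prev + noise."""
    frames, sigs = [], []
    for s in range(1, n_subjects + 1):
        grp = "repeater" if s <= n_subjects // 2 else "alternator"
        eff = effect if group_effects is None else group_effects[grp]
        c = rng.choice([-1.0, 1.0], n_trials)
        stim = rng.choice([-1, 1], n_trials)
        icept = rng.normal(0, icept_sd)
        y = icept + eff * np.r_[0.0, c[:-1]] + rng.normal(0, noise_sd, n_trials)
        frames.append(pd.DataFrame({
            "subject_id": s, "session": 1, "block": 1,
            "trial": np.arange(1, n_trials + 1), "stimulus": stim,
            "choice": c.astype(int), "rt": 1.0,
            "outcome": np.where(c == stim, "correct", "error"),
            "choice_hand_map": "right"}))
        sigs.append(pd.DataFrame({"y": y}))
    labels = {s: ("repeater" if s <= n_subjects // 2 else "alternator")
              for s in range(1, n_subjects + 1)}
    return (pd.concat(frames, ignore_index=True),
            pd.concat(sigs, ignore_index=True), labels)


class TestMixedModel:
    def test_history_effect_recovered_within_3se(self, rng):
        trials, sig, _ = _synthetic_panel(rng, n_subjects=30, n_trials=300,
                                          effect=0.8)
        res = fit_encoding(trials, sig, "y")
        assert abs(res.estimates["c_prev"] - 0.8) <= 3 * res.se["c_prev"]

    def test_type1_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = []
        for _ in range(500):
            trials, sig, _ = _synthetic_panel(rng, n_subjects=8, n_trials=40)
            res = fit_encoding(trials, sig, "y")
            rejections.append(res.p_values["c_prev"] < 0.05)
        assert 0.03 <= np.mean(rejections) <= 0.07

    def test_subject_offset_leaves_fixed_slopes_invariant(self, rng):
        # a constant added to one subject's signal is absorbed by that
        # subject's random intercept; within-subject slopes are unchanged up
        # to the (slight) re-weighting from the re-estimated variance
        # components
        trials, sig, _ = _synthetic_panel(rng, n_subjects=10, n_trials=200,
                                          effect=0.5)
        res1 = fit_encoding(trials, sig, "y")
        sig2 = sig.copy()
        sig2.loc[trials["subject_id"] == 3, "y"] += 5.0
        res2 = fit_encoding(trials, sig2, "y")
        for term in ("s", "c_prev"):
            assert res1.estimates[term] == pytest.approx(
                res2.estimates[term], abs=2e-3)
        assert abs(res2.estimates["Intercept"]
                   - res1.estimates["Intercept"] - 0.5) < 0.05

    def test_matches_pooled_ols_when_no_subject_variance(self, rng):
        trials, sig, _ = _synthetic_panel(rng, n_subjects=10, n_trials=200,
                                          effect=0.5, icept_sd=0.0)
        res = fit_encoding(trials, sig, "y")
        import statsmodels.formula.api as smf
        df = pd.DataFrame({
            "y": sig["y"], "s": trials["stimulus"].astype(float),
            "c_prev": trials.groupby(["subject_id", "session", "block"])
            ["choice"].shift(1)}).dropna()
        ols = smf.ols("y ~ s + c_prev", df).fit()
        assert res.estimates["c_prev"] == pytest.approx(
            ols.params["c_prev"], abs=5e-3)


class TestGroupInteraction:
    def test_repeater_only_effect_detected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(10):
            trials, sig, labels = _synthetic_panel(
                rng, n_subjects=24, n_trials=200,
                group_effects={"repeater": 0.6, "alternator": 0.0})
            res = fit_group_interaction(trials, sig, "y", labels)
            hits += (res.estimates["g:c_prev"] > 0
                     and res.p_values["g:c_prev"] < 0.05)
        assert hits >= 9  # power > 0.8

    def test_equal_effects_interaction_covers_zero(self, rng):
        trials, sig, labels = _synthetic_panel(
            rng, n_subjects=24, n_trials=200,
            group_effects={"repeater": 0.5, "alternator": 0.5})
        res = fit_group_interaction(trials, sig, "y", labels)
        assert abs(res.estimates["g:c_prev"]) <= 3 * res.se["g:c_prev"]

    def test_label_flip_negates_interaction(self, rng):
        trials, sig, labels = _synthetic_panel(
            rng, n_subjects=16, n_trials=120,
            group_effects={"repeater": 0.6, "alternator": 0.0})
        flipped = {s: ("repeater" if g == "alternator" else "alternator")
                   for s, g in labels.items()}
        r1 = fit_group_interaction(trials, sig, "y", labels)
        r2 = fit_group_interaction(trials, sig, "y", flipped)
        assert r1.estimates["g:c_prev"] == pytest.approx(
            -r2.estimates["g:c_prev"], abs=1e-8)

    def test_single_group_rejected(self, rng):
        trials, sig, labels = _synthetic_panel(rng, n_subjects=6, n_trials=50)
        only_rep = {s: "repeater" for s in labels}
        with pytest.raises(ValueError):
            fit_group_interaction(trials, sig, "y", only_rep)


class TestFDR:
    def test_all_rejected_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.all(q <= 0.05)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_agrees_with_brute_force(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 15)))
            assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_in_p_rank(self, ps):
        p = np.array(ps)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestResidualization:
    def test_identical_signals_residualize_to_zero(self, rng):
        g = rng.standard_normal(500)
        res = residualize_alpha(g, g)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_orthogonality_within_subject(self, rng):
        subj = np.repeat([1, 2, 3], 400)
        g = rng.standard_normal(1200)
        a = 0.7 * g + rng.standard_normal(1200)
        res = residualize_alpha(a, g, subjects=subj)
        for s in (1, 2, 3):
            m = subj == s
            assert abs(np.corrcoef(res[m], g[m])[0, 1]) < 1e-10

    def test_specific_code_survives_global_removal(self, rng):
        n = 6000
        prev_choice = rng.choice([-1.0, 1.0], n)
        err = rng.choice([0.0, 1.0], n)
        global_comp = -1.0 * err + 0.3 * rng.standard_normal(n)
        alpha = 0.5 * prev_choice * err + global_comp + rng.standard_normal(n)
        res = residualize_alpha(alpha, global_comp)
        X = np.column_stack([np.ones(n), prev_choice * err, err])
        beta, *_ = np.linalg.lstsq(X, res, rcond=None)
        resid = res - X @ beta
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X))
                     * resid.var())
        assert abs(beta[2]) <= 3 * se[2]          # error term projected out
        assert abs(beta[1] - 0.5) <= 3 * se[1]    # history code preserved

    def test_zero_variance_global_passthrough(self, rng):
        a = rng.standard_normal(100)
        with pytest.warns(UserWarning):
            out = residualize_alpha(a, np.zeros(100))
        assert np.array_equal(out, a)


class TestMotorFlip:
    def test_left_hand_sign_contract(self):
        b = np.array([1.0, -2.0])
        assert np.array_equal(
            flip_motor_lateralization(b, np.array(["left", "left"])), -b)
        assert np.array_equal(
            flip_motor_lateralization(b, np.array(["right", "right"])), b)

    def test_double_flip_is_identity(self, rng):
        b = rng.standard_normal(50)
        hands = rng.choice(["left", "right"], 50)
        once = flip_motor_lateralization(b, hands)
        twice = flip_motor_lateralization(once, hands)
        assert np.array_equal(twice, b)

    def test_unknown_hand_rejected(self):
        with pytest.raises(ValueError):
            flip_motor_lateralization(np.ones(2), np.array(["right", "both"]))

    def test_common_sign_recovered_after_flip(self, small_cohort):
        trials, signals, _ = small_cohort
        flipped = flip_motor_lateralization(
            signals["beta_motor_ref"].to_numpy(),
            trials["choice_hand_map"].to_numpy())
        prev = trials.groupby(["subject_id", "session", "block"])[
            "choice"].shift(1).to_numpy()
        m = ~np.isnan(prev)
        slope = np.polyfit(prev[m], flipped[m], 1)[0]
        assert slope > 0  # uniform positive previous-action code


class TestTimeResolved:
    def test_constant_effect_all_bins_significant(self, rng):
        trials, sig, _ = _synthetic_panel(rng, n_subjects=20, n_trials=200,
                                          effect=0.8)
        bins = {f"t{i}": sig["y"] + rng.normal(0, 0.1, len(sig))
                for i in range(6)}
        out = timeresolved_encoding(trials, bins)
        assert out["significant"].all()

    def test_bin_permutation_permutes_coefficients(self, rng):
        trials, sig, _ = _synthetic_panel(rng, n_subjects=10, n_trials=100,
                                          effect=0.5)
        bins = {f"t{i}": sig["y"] * (0.5 + 0.25 * i) for i in range(4)}
        out1 = timeresolved_encoding(trials, bins).set_index("bin")
        perm = dict(reversed(list(bins.items())))
        out2 = timeresolved_encoding(trials, perm).set_index("bin")
        assert np.allclose(out1["estimate"], out2["estimate"].loc[out1.index])

    def test_lag_specificity(self, rng):
        # lag-1-only signal shows no lag-2 code
        n_subj, n_tr = 20, 300
        frames, ys = [], []
        for s in range(1, n_subj + 1):
            c = rng.choice([-1.0, 1.0], n_tr)
            y = 0.8 * np.r_[0.0, c[:-1]] + rng.standard_normal(n_tr)
            frames.append(pd.DataFrame({
                "subject_id": s, "session": 1, "block": 1,
                "trial": np.arange(1, n_tr + 1),
                "stimulus": rng.choice([-1, 1], n_tr),
                "choice": c.astype(int)}))
            ys.append(pd.DataFrame({"y": y}))
        trials = pd.concat(frames, ignore_index=True)
        sig = pd.concat(ys, ignore_index=True)
        df = pd.DataFrame({
            "y": sig["y"].to_numpy(),
            "s": trials["stimulus"].astype(float).to_numpy(),
            "subject": trials["subject_id"].to_numpy(),
            "c_prev": trials.groupby(["subject_id"])["choice"].shift(2)
            .to_numpy()}).dropna()
        import statsmodels.formula.api as smf
        res = smf.mixedlm("y ~ s + c_prev", df, groups=df["subject"]).fit()
        assert abs(res.params["c_prev"]) <= 3 * res.bse["c_prev"]
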