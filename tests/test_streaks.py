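"""Tests of streak extraction, criterion shifts, and the streak ANOVAs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from choicehist.streaks import (extract_streaks, mixed_streak_anova,
                                repeating_bias_curve, sdt_criterion,
                                streak_anova)


class TestCriterion:
    def test_symmetric_rates_give_zero(self):
        assert sdt_criterion(0.5, 0.5) == pytest.approx(0.0)

    def test_normal_quantile_evaluation(self):
        h = stats.norm.cdf(1.0)  # 0.8413...
        assert sdt_criterion(h, 0.5) == pytest.approx(-0.5, abs=1e-9)

    @given(h=st.floats(0.05, 0.95), f=st.floats(0.05, 0.95))
    def test_mirror_identity(self, h, f):
        # swapping response labels (H' = 1-F, F' = 1-H) negates the criterion
        assert sdt_criterion(1 - f, 1 - h) == pytest.approx(
            -sdt_criterion(h, f), abs=1e-10)

    def test_extreme_rates_are_shrunk(self):
        c = sdt_criterion(1.0, 0.5, n_signal=20, n_noise=20)
        assert np.isfinite(c)
        assert c == pytest.approx(-0.5 * stats.norm.ppf(1 - 1 / 40), abs=1e-9)


def _trials(choices, stim=None, sid=1, block=None):
    n = len(choices)
    if stim is None:
        stim = np.resize([1, -1], n)
    if block is None:
        block = np.ones(n, dtype=int)
    return pd.DataFrame({
        "subject_id": sid, "session": 1, "block": block,
        "trial": np.arange(1, n + 1), "stimulus": stim, "choice": choices,
        "outcome": np.where(np.array(choices) == np.array(stim),
                            "correct", "error")})


def brute_force_events(choices, max_len=5):
    """Independent enumeration of (length, end, final trial) events."""
    ch = list(choices)
    n = len(ch)
    events = []
    for t in range(n - 1):
        for L in range(1, max_len + 1):
            if t - L + 1 >= 0 and len({*ch[t - L + 1:t + 1]}) == 1:
                events.append((L, "repeat", t))
            if (t - L >= 0 and ch[t] != ch[t - 1]
                    and len({*ch[t - L:t]}) == 1):
                events.append((L, "alternate", t))
    return sorted(events)


class TestExtraction:
    def test_toy_sequence_has_length2_alternate_event(self):
        # ...+1,+1,+1 then a deviant -1: the deviation after a 2-repetition
        # streak is measured at the following trial
        ev = extract_streaks(_trials([1, 1, 1, -1, 1]))
        alt = ev[ev["end"] == "alternate"]
        assert set(alt["length"]) == {1, 2, 3}
        assert (alt["final_choice"] == -1).all()
        assert (alt["measure_idx"] == 4).all()

    def test_alternating_sequence_only_length1(self):
        ev = extract_streaks(_trials([1, -1, 1, -1, 1, -1]))
        assert set(ev["length"]) == {1}

    def test_matches_brute_force_on_random_trials(self, rng):
        ch = rng.choice([-1, 1], 1000)
        trials = _trials(ch, block=np.repeat([1, 2], 500))
        ev = extract_streaks(trials)
        got = sorted(zip(ev["length"], ev["end"], ev["measure_idx"] - 1))
        want = []
        for b in (0, 1):
            seg = ch[b * 500:(b + 1) * 500]
            want += [(L, e, t + b * 500) for (L, e, t) in brute_force_events(seg)]
        assert got == sorted(want)

    def test_disjoint_cells_for_fixed_length_ge2(self, rng):
        ch = rng.choice([-1, 1], 600)
        ev = extract_streaks(_trials(ch))
        for L in range(2, 6):
            sub = ev[ev["length"] == L]
            assert sub["measure_idx"].is_unique

    def test_streaks_do_not_cross_blocks(self):
        trials = _trials([1, 1, 1, 1, 1, 1], block=[1, 1, 1, 2, 2, 2])
        ev = extract_streaks(trials)
        assert ev["length"].max() <= 3


class TestBiasCurve:
    def test_unbiased_cohort_bias_near_zero(self):
        from choicehist.synthetic import generate_cohort
        trials, _, _ = generate_cohort(n_subjects=40, repeater_fraction=0.5,
                                       trials_per_session=400, n_sessions=1,
                                       seed=71)
        # neutralize history: resample choices as coin flips
        rng = np.random.default_rng(8)
        trials = trials.copy()
        trials["choice"] = rng.choice([-1, 1], len(trials))
        trials["outcome"] = np.where(trials["choice"] == trials["stimulus"],
                                     "correct", "error")
        bias = repeating_bias_curve(extract_streaks(trials), trials)
        for _, d in bias.groupby(["length", "end"]):
            x = d["repeating_bias"]
            if len(x) >= 10:
                assert abs(x.mean()) < 3 * stats.sem(x)

    def test_sign_flip_symmetry(self, small_cohort):
        trials, _, _ = small_cohort
        flipped = trials.copy()
        flipped["choice"] = -flipped["choice"]
        flipped["stimulus"] = -flipped["stimulus"]
        b1 = repeating_bias_curve(extract_streaks(trials), trials)
        b2 = repeating_bias_curve(extract_streaks(flipped), flipped)
        m = b1.merge(b2, on=["subject_id", "length", "end"], suffixes=("", "_f"))
        assert np.allclose(m["repeating_bias"], m["repeating_bias_f"], atol=1e-9)

    def test_length1_tracks_repetition_probability(self):
        from choicehist.synthetic import generate_cohort
        trials, _, _ = generate_cohort(n_subjects=20, repeater_fraction=0.5,
                                       trials_per_session=500, n_sessions=1,
                                       seed=72)
        bias = repeating_bias_curve(extract_streaks(trials), trials)
        l1 = bias[(bias["length"] == 1) & (bias["end"] == "repeat")]
        pr = trials.groupby("subject_id")["choice"].apply(
            lambda c: np.mean(c.to_numpy()[1:] == c.to_numpy()[:-1]))
        merged = l1.set_index("subject_id")["repeating_bias"].align(pr, join="inner")
        rho = stats.spearmanr(merged[0], merged[1]).statistic
        assert rho > 0.9

    def test_outcome_conditioning_partitions_events(self, small_cohort):
        # every event's final trial is either correct or an error, so the
        # outcome-conditioned event sets partition the full set
        trials, _, _ = small_cohort
        ev = extract_streaks(trials)
        pos = trials.index.get_indexer(ev["measure_idx"].to_numpy()) - 1
        outcome = trials["outcome"].to_numpy()[pos]
        assert len(ev) == (outcome == "correct").sum() + (outcome == "error").sum()
        b_c = repeating_bias_curve(ev, trials, "correct")
        b_e = repeating_bias_curve(ev, trials, "error")
        b_all = repeating_bias_curve(ev, trials, "any")
        assert not b_c.empty and not b_e.empty
        assert b_c["n_events"].sum() + b_e["n_events"].sum() <= b_all["n_events"].sum()


def _gaussian_bias_table(rng, n_subjects, inter=0.0, length_effect=0.0,
                         noise=1.0):
    rows = []
    for s in range(n_subjects):
        for L in range(1, 6):
            for e, esign in (("repeat", 1), ("alternate", -1)):
                val = (length_effect * L + inter * L * esign
                       + rng.normal(0, noise))
                rows.append({"subject_id": s, "length": L, "end": e,
                             "repeating_bias": val})
    return pd.DataFrame(rows)


class TestAnova:
    def test_interaction_pvalue_uniform_under_null(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            tab = _gaussian_bias_table(rng, 12)
            labels = {s: ("repeater" if s < 6 else "alternator")
                      for s in range(12)}
            res = mixed_streak_anova(tab, labels).set_index("effect")
            pvals.append(res.loc["length*end", "p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        assert 0.01 < np.mean(np.array(pvals) < 0.05) < 0.10

    def test_injected_interaction_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            tab = _gaussian_bias_table(rng, 30, inter=0.15)
            res = streak_anova(tab).set_index("Source")
            hits += res.loc["length * end", "p_unc"] < 0.05
        assert hits >= 17  # power > 0.8

    def test_main_effect_only_does_not_trigger_interaction(self):
        rng = np.random.default_rng(7)
        false_hits = 0
        for _ in range(20):
            tab = _gaussian_bias_table(rng, 20, length_effect=0.5)
            res = streak_anova(tab).set_index("Source")
            false_hits += res.loc["length * end", "p_unc"] < 0.05
        assert false_hits <= 3

    def test_three_way_interaction_under_group_difference(self):
        rng = np.random.default_rng(8)
        tabs = []
        for s in range(30):
            inter = 0.3 if s < 15 else 0.0
            t = _gaussian_bias_table(rng, 1, inter=inter)
            t["subject_id"] = s
            tabs.append(t)
        tab = pd.concat(tabs, ignore_index=True)
        labels = {s: ("repeater" if s < 15 else "alternator") for s in range(30)}
        res = mixed_streak_anova(tab, labels).set_index("effect")
        assert res.loc["length*end*group", "p"] < 0.01

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(9)
        tab = _gaussian_bias_table(rng, 1)
        with pytest.raises(ValueError):
            streak_anova(tab)
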