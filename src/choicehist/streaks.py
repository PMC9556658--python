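"""Multi-trial build-up of history bias: streaks and SDT criterion shifts.

Choice-repetition sequences of increasing length are extracted and the
"repeating bias" is quantified as the shift of the signal-detection criterion
on the trial following the sequence, sign-flipped so that positive always
means "toward the final choice of the sequence".

Sequence convention (nested, trial-count): a repeat-ending event of length L
at measurement trial t+1 requires choices t-L+1..t to be identical; an
alternate-ending event of length L requires choices t-L..t-1 identical and
choice_t to deviate. Events of different lengths therefore overlap (a length-3
streak also contributes length-1 and length-2 events), but for a fixed length
of 2 or more each measurement trial belongs to at most one (length, end)
cell. The length-1 repeat-ending cell contains every trial, so its bias value
reflects each observer's overall repetition probability (the length-1
alternate cell, every trial following a deviation, overlaps with it).
Sequences never cross block or session boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sdt_criterion",
    "extract_streaks",
    "repeating_bias_curve",
    "streak_anova",
    "mixed_streak_anova",
]


def sdt_criterion(hit_rate: float, fa_rate: float, n_signal: int | None = None,
                  n_noise: int | None = None) -> float:
    """SDT criterion ``c = -0.5 * (Phi^-1(H) + Phi^-1(F))``.

    Rates of exactly 0 or 1 are shrunk by the log-linear rule (add 0.5
    pseudo-counts, i.e. 1/(2N)) when trial counts are supplied, else clipped
    at 1/(2*100).
    """
    def _fix(r, n):
        if 0.0 < r < 1.0:
            return r
        if n is None:
            n = 100
        return np.clip(r, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))

    h = _fix(float(hit_rate), n_signal)
    f = _fix(float(fa_rate), n_noise)
    return float(-0.5 * (stats.norm.ppf(h) + stats.norm.ppf(f)))


def extract_streaks(trials: pd.DataFrame, max_len: int = 5) -> pd.DataFrame:
    """Index streak events and their measurement trials.

    Returns one row per (event, length): columns ``subject_id``, ``length``,
    ``end`` ("repeat"/"alternate"), ``final_choice`` (the choice of the last
    trial of the sequence), ``measure_idx`` (positional index into ``trials``
    of the following trial). Events are nested across lengths; streaks do not
    cross block or session boundaries.
    """
    frames = []
    grp_ids = trials.groupby(["subject_id", "session", "block"], sort=False)
    for (sid, _, _), d in grp_ids:
        ch = d["choice"].to_numpy()
        idx = d.index.to_numpy()
        n = ch.size
        if n < 2:
            continue
        # run[t]: length of the run of identical choices ending at trial t
        pos = np.arange(n)
        reset = np.ones(n, dtype=bool)
        reset[1:] = ch[1:] != ch[:-1]
        last_reset = np.maximum.accumulate(np.where(reset, pos, 0))
        run = pos - last_reset + 1
        deviant = np.zeros(n, dtype=bool)
        deviant[1:] = ch[1:] != ch[:-1]
        has_next = pos < n - 1
        for L in range(1, max_len + 1):
            rep = has_next & (run >= L)
            t_rep = pos[rep]
            alt = has_next & deviant
            alt[1:] &= run[:-1] >= L
            alt[0] = False
            t_alt = pos[alt]
            if t_rep.size:
                frames.append(pd.DataFrame({
                    "subject_id": sid, "length": L, "end": "repeat",
                    "final_choice": ch[t_rep], "measure_idx": idx[t_rep + 1]}))
            if t_alt.size:
                frames.append(pd.DataFrame({
                    "subject_id": sid, "length": L, "end": "alternate",
                    "final_choice": ch[t_alt], "measure_idx": idx[t_alt + 1]}))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "length", "end",
                                     "final_choice", "measure_idx"])
    return pd.concat(frames, ignore_index=True)


def repeating_bias_curve(streaks: pd.DataFrame, trials: pd.DataFrame,
                         condition_on_outcome: str = "any") -> pd.DataFrame:
    """Per-subject criterion shift toward the final choice, by (length, end).

    For each cell, the criterion on the measurement trials is computed from
    hit and false-alarm rates (P("stronger" report | stimulus category)),
    separately for sequences ending in a "stronger" vs "weaker" choice;
    criteria following "weaker" finals are sign-flipped (and "stronger" ones
    negated) so positive bias always points toward the final choice. The two
    final-choice identities are then averaged, weighted by event count.

    ``condition_on_outcome`` restricts events by the outcome of the final
    trial of the sequence ("correct", "error", or "any").
    """
    if condition_on_outcome not in ("any", "correct", "error"):
        raise ValueError("condition_on_outcome must be any|correct|error")
    ev = streaks.copy()
    if condition_on_outcome != "any":
        # outcome of the trial preceding the measurement trial
        final_idx = ev["measure_idx"].to_numpy()
        pos = trials.index.get_indexer(final_idx) - 1
        final_outcome = trials["outcome"].to_numpy()[pos]
        ev = ev[final_outcome == condition_on_outcome]
    stim = trials["stimulus"]
    resp = trials["choice"]
    rows = []
    for (sid, L, end), d in ev.groupby(["subject_id", "length", "end"]):
        parts = []
        weights = []
        for fc, dd in d.groupby("final_choice"):
            s = stim.loc[dd["measure_idx"]].to_numpy()
            r = resp.loc[dd["measure_idx"]].to_numpy()
            n_sig = int((s > 0).sum())
            n_noi = int((s < 0).sum())
            if n_sig == 0 or n_noi == 0:
                continue
            hit = (r[s > 0] > 0).mean()
            fa = (r[s < 0] > 0).mean()
            c = sdt_criterion(hit, fa, n_sig, n_noi)
            # negative criterion = liberal toward "stronger": toward a +1
            # final choice; flip after "weaker" finals
            parts.append(-c if fc > 0 else c)
            weights.append(len(dd))
        if parts:
            rows.append({"subject_id": sid, "length": L, "end": end,
                         "repeating_bias": np.average(parts, weights=weights),
                         "n_events": int(sum(weights))})
    return pd.DataFrame(rows)


def streak_anova(bias_table: pd.DataFrame) -> pd.DataFrame:
    """Within-subject repeated-measures ANOVA: length x end on repeating bias.

    Subjects with incomplete cells are dropped listwise. Uses pingouin's
    two-way repeated-measures ANOVA.
    """
    import pingouin as pg

    wide = bias_table.pivot_table(index="subject_id", columns=["length", "end"],
                                  values="repeating_bias")
    full = wide.dropna()
    if len(full) < 2:
        raise ValueError("need at least 2 subjects with complete cells")
    long = full.stack(list(range(full.columns.nlevels)), future_stack=True).rename(
        "repeating_bias").reset_index()
    return pg.rm_anova(data=long, dv="repeating_bias",
                       within=["length", "end"], subject="subject_id",
                       detailed=True)


def mixed_streak_anova(bias_table: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Split-plot ANOVA with subgroup as the between-subject factor.

    Classical sums-of-squares partition for a two-within (length, end), one
    between (group) design, with the within-effects F-ratios formed against
    their effect-by-subject(group) interactions. Returns a tidy table of F
    statistics and p-values for all main effects and interactions.
    """
    df = bias_table.copy()
    df["group"] = df["subject_id"].map(labels)
    df = df[df["group"].notna()]
    wide = df.pivot_table(index=["subject_id", "group"],
                          columns=["length", "end"], values="repeating_bias")
    wide = wide.dropna()
    if wide.index.get_level_values("group").nunique() < 2:
        raise ValueError("need both subgroups present")
    subjects = wide.index.get_level_values("subject_id").to_numpy()
    groups = wide.index.get_level_values("group").to_numpy()
    lengths = wide.columns.get_level_values("length").to_numpy()
    ends = wide.columns.get_level_values("end").to_numpy()
    Y = wide.to_numpy()
    n_s = Y.shape[0]
    u_g = np.unique(groups)
    u_l = np.unique(lengths)
    u_e = np.unique(ends)
    a, b, c = len(u_g), len(u_l), len(u_e)

    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    cell = {}

    def mean_where(gm=None, lm=None, em=None):
        rows = np.ones(n_s, bool) if gm is None else groups == gm
        cols = np.ones(Y.shape[1], bool)
        if lm is not None:
            cols &= lengths == lm
        if em is not None:
            cols &= ends == em
        return Y[np.ix_(rows, cols)].mean()

    n_per_group = {g: (groups == g).sum() for g in u_g}
    # between-subject stratum
    ss_g = sum(n_per_group[g] * b * c * (mean_where(gm=g) - grand) ** 2 for g in u_g)
    ss_subj = b * c * sum((subj_mean[i] - mean_where(gm=groups[i])) ** 2
                          for i in range(n_s))
    df_g, df_subj = a - 1, n_s - a

    def ss_factor(levels, axis_vals):
        return n_s * (Y.shape[1] // len(levels)) * sum(
            (Y[:, axis_vals == lv].mean() - grand) ** 2 for lv in levels)

    ss_l = ss_factor(u_l, lengths)
    ss_e = ss_factor(u_e, ends)

    def ss_inter2(levels1, vals1, levels2_groups=False):
        # interaction of a within factor with group
        tot = 0.0
        for g in u_g:
            for lv in levels1:
                m = Y[np.ix_(groups == g, vals1 == lv)].mean()
                tot += n_per_group[g] * (Y.shape[1] // len(levels1)) * (
                    m - mean_where(gm=g) - Y[:, vals1 == lv].mean() + grand) ** 2
        return tot

    ss_gl = ss_inter2(u_l, lengths)
    ss_ge = ss_inter2(u_e, ends)

    ss_le = 0.0
    for lv in u_l:
        for ev in u_e:
            m = Y[:, (lengths == lv) & (ends == ev)].mean()
            ss_le += n_s * (m - Y[:, lengths == lv].mean()
                            - Y[:, ends == ev].mean() + grand) ** 2

    ss_gle = 0.0
    for g in u_g:
        for lv in u_l:
            for ev in u_e:
                m = Y[np.ix_(groups == g, (lengths == lv) & (ends == ev))].mean()
                exp = (mean_where(g, lv, None) + mean_where(g, None, ev)
                       + Y[:, (lengths == lv) & (ends == ev)].mean()
                       - mean_where(gm=g) - Y[:, lengths == lv].mean()
                       - Y[:, ends == ev].mean() + grand)
                ss_gle += n_per_group[g] * (m - exp) ** 2

    ss_total = ((Y - grand) ** 2).sum()
    # error strata: within-factor x subject(group) residuals
    ss_l_err = 0.0
    for i in range(n_s):
        for lv in u_l:
            m = Y[i, lengths == lv].mean()
            ss_l_err += c * (m - subj_mean[i] - mean_where(groups[i], lv, None)
                             + mean_where(gm=groups[i])) ** 2
    ss_e_err = 0.0
    for i in range(n_s):
        for ev in u_e:
            m = Y[i, ends == ev].mean()
            ss_e_err += b * (m - subj_mean[i] - mean_where(groups[i], None, ev)
                             + mean_where(gm=groups[i])) ** 2
    explained = (ss_g + ss_subj + ss_l + ss_gl + ss_l_err + ss_e + ss_ge
                 + ss_e_err + ss_le + ss_gle)
    ss_le_err = max(ss_total - explained, 0.0)

    df_l, df_e = b - 1, c - 1
    rows = []

    def add(name, ss, dfn, ss_err, dfe):
        ms, mse = ss / dfn, ss_err / dfe
        F = ms / mse if mse > 0 else np.nan
        rows.append({"effect": name, "SS": ss, "df1": dfn, "df2": dfe,
                     "F": F, "p": stats.f.sf(F, dfn, dfe) if np.isfinite(F) else np.nan})

    add("group", ss_g, df_g, ss_subj, df_subj)
    add("length", ss_l, df_l, ss_l_err, df_l * df_subj)
    add("length*group", ss_gl, df_l * df_g, ss_l_err, df_l * df_subj)
    add("end", ss_e, df_e, ss_e_err, df_e * df_subj)
    add("end*group", ss_ge, df_e * df_g, ss_e_err, df_e * df_subj)
    add("length*end", ss_le, df_l * df_e, ss_le_err, df_l * df_e * df_subj)
    add("length*end*group", ss_gle, df_l * df_e * df_g, ss_le_err,
        df_l * df_e * df_subj)
    return pd.DataFrame(rows)
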