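"""Seeded validation studies: parameter recovery, calibration, model checks.

Each function runs a self-contained simulate-and-recover (or calibration)
study at a fixed seed and returns a flat dict of scalar metrics. These are
the computations behind the acceptance checks, the test suite, and the
numbered analysis drivers; problem sizes are chosen to finish on a single
desktop CPU core in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import encoding as enc
from . import history as hist
from . import mediation as med
from . import streaks as stk
from .ddm import (CollapsingBound, DDMParams, compare_bound_models,
                  constant_bound_density, fit_ddm, fpt_density_grid,
                  simulate_ddm, trialwise_params)
from .psychometrics import (WeibullPsychometric, staircase_2up1down,
                            weibull_psychometric)
from .synthetic import generate_cohort, simulate_mediation_data

STANDARD_BOUND = CollapsingBound(a=1.8, form="weibull", shape=3.0, scale=1.5)


def _seed_stream(seed, n):
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31 - 1)


# ---------------------------------------------------------------- DDM checks

def solver_validation(seed: int = 0, n_sim: int = 100_000,
                      sim_dt: float = 1e-4) -> dict:
    """Solver vs analytic series (constant bound) and vs simulator (collapse).

    Returns the sup-norm density error against the closed-form
    constant-bound first-passage density, the mass deficit of the solved
    density, and a chi-square goodness-of-fit comparison between simulated
    response times and the solver distribution under a Weibull collapsing
    bound (decile bins per choice).
    """
    v, a, z = 1.0, 1.5, 0.5
    grid = fpt_density_grid(np.array([v]), np.array([z]), CollapsingBound(a=a),
                            t_max=3.0)
    t = grid.t_grid[1:]
    sup = max(
        np.max(np.abs(grid.g_upper[0, 0, 1:]
                      - constant_bound_density(t, v, a, z, upper=True))),
        np.max(np.abs(grid.g_lower[0, 0, 1:]
                      - constant_bound_density(t, v, a, z, upper=False))),
    )

    vb, zb = 0.8, 0.45
    gridb = fpt_density_grid(np.array([vb]), np.array([zb]), STANDARD_BOUND,
                             t_max=4.0)
    mass = np.trapezoid(gridb.g_upper[0, 0] + gridb.g_lower[0, 0],
                        gridb.t_grid)
    ch, rt, _ = simulate_ddm(vb, np.full(n_sim, zb), STANDARD_BOUND,
                             dt=sim_dt, seed=seed)
    chi2, dof = 0.0, 0
    tg = gridb.t_grid
    for sign, g in ((1, gridb.g_upper[0, 0]), (-1, gridb.g_lower[0, 0])):
        cdf = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(tg))])
        tot = cdf[-1]
        edges = np.interp(np.linspace(0.1, 0.9, 9) * tot, cdf, tg)
        edges = np.concatenate([[0.0], edges, [np.inf]])
        obs, _ = np.histogram(rt[ch == sign], edges)
        cdf_at = np.append(np.interp(edges[:-1], tg, cdf), tot)
        expected = np.diff(cdf_at) * n_sim
        chi2 += float(np.sum((obs - expected) ** 2 / expected))
        dof += obs.size
    dof -= 1
    return {"supnorm_error": float(sup), "mass_deficit": float(abs(1 - mass)),
            "chi2": chi2, "chi2_dof": dof,
            "chi2_p": float(stats.chi2.sf(chi2, dof)), "n_sim": n_sim}


def _inject_outliers(rng, choices, rts, frac=0.05, deadline=3.0):
    """Replace a fraction of trials with the assumed uniform contaminant."""
    out = rng.random(choices.size) < frac
    choices = choices.copy()
    rts = rts.copy()
    choices[out] = rng.choice([-1, 1], int(out.sum()))
    rts[out] = rng.uniform(0.0, deadline, int(out.sum()))
    return choices, rts


def ddm_regression_recovery(seed: int = 0, n_reps: int = 20,
                            n_trials: int = 5000, v_gamma: float = 0.15,
                            z_beta: float = -0.10) -> dict:
    """Recovery of neural regression weights on drift bias and starting point.

    Generates trials (with the assumed 5% uniform contaminant) under a
    positive gamma weight on drift and a negative beta weight on starting
    point (others zero), refits the full model, and summarizes sign recovery
    and magnitude error across replicates.
    """
    seeds = _seed_stream(seed, 2 * n_reps)
    true = DDMParams(v0=0.05, v_s=0.6, z0=0.5, t0=0.3, bound=STANDARD_BOUND,
                     v_weights=(v_gamma, 0.0, 0.0),
                     z_weights=(0.0, 0.0, z_beta))
    v_est, z_est, signs = [], [], []
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[2 * r])
        stim = rng.choice([-1.0, 1.0], n_trials)
        X = rng.standard_normal((n_trials, 3))
        v_t, z_t = trialwise_params(true, stim, X)
        ch, rt, _ = simulate_ddm(v_t, z_t, true.bound, t0=true.t0,
                                 seed=int(seeds[2 * r + 1]))
        ch, rt = _inject_outliers(rng, ch, rt)
        fit = fit_ddm(ch, rt, stim, regressors=X, targets=("v", "z"))
        v_hat = fit.params.v_weights[0]
        z_hat = fit.params.z_weights[2]
        v_est.append(v_hat)
        z_est.append(z_hat)
        signs.append(v_hat > 0 and z_hat < 0)
    v_med, z_med = float(np.median(v_est)), float(np.median(z_est))
    return {
        "sign_recovery_rate": float(np.mean(signs)),
        "v_gamma_median": v_med, "z_beta_median": z_med,
        "v_gamma_median_rel_err": float(abs(v_med - v_gamma) / abs(v_gamma)),
        "z_beta_median_rel_err": float(abs(z_med - z_beta) / abs(z_beta)),
        "n_reps": n_reps, "n_trials": n_trials,
    }


def bound_model_recovery(seed: int = 0, n_reps: int = 20,
                         n_trials: int = 5000,
                         gen_form: str = "weibull") -> dict:
    """Does AIC ranking identify the generating bound geometry?"""
    seeds = _seed_stream(seed, 2 * n_reps)
    if gen_form == "weibull":
        bound = STANDARD_BOUND
    elif gen_form == "static":
        bound = CollapsingBound(a=1.8)
    else:
        bound = CollapsingBound(a=1.8, form="linear", shape=0.8, scale=0.1)
    true = DDMParams(v0=0.0, v_s=0.6, z0=0.5, t0=0.3, bound=bound)
    first, ties_ok = [], []
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[2 * r])
        stim = rng.choice([-1.0, 1.0], n_trials)
        v_t, z_t = trialwise_params(true, stim)
        ch, rt, _ = simulate_ddm(v_t, z_t, bound, t0=true.t0,
                                 seed=int(seeds[2 * r + 1]))
        ch, rt = _inject_outliers(rng, ch, rt)
        ranking, _ = compare_bound_models(ch, rt, stim)
        first.append(ranking[0][0])
        # "tied first": within 2 AIC of the winner
        aics = {f: a for f, a, _ in ranking}
        ties_ok.append(aics[gen_form] - ranking[0][1] <= 2.0)
    return {
        "rank1_rate": float(np.mean([f == gen_form for f in first])),
        "rank1_or_tied_rate": float(np.mean(ties_ok)),
        "n_reps": n_reps, "n_trials": n_trials, "gen_form": gen_form,
    }


# ------------------------------------------------------------ history kernel

def history_kernel_recovery(seed: int = 0, n_reps: int = 40,
                            n_trials: int = 10_000,
                            w1: float = 0.5, decay: float = 0.5) -> dict:
    """Sign and ordering recovery of the lag-1 choice kernel."""
    seeds = _seed_stream(seed, n_reps)
    om = w1 * decay ** np.arange(7)
    ok_sign, ok_largest, lag1 = [], [], []
    for r in range(n_reps):
        df = hist.simulate_history_observer(
            n_trials, alpha=1.0, omega_choice=om, gamma_lapse=0.02,
            lambda_lapse=0.02, seed=int(seeds[r]), block_size=500)
        fit = hist.fit_history_model(hist.build_history_design(df),
                                     compute_se=False)
        w = fit.omega["choice"]
        lag1.append(w[0])
        ok_sign.append(w[0] > 0)
        ok_largest.append(np.argmax(w) == 0)
    return {
        "lag1_sign_rate": float(np.mean(ok_sign)),
        "lag1_largest_rate": float(np.mean(ok_largest)),
        "lag1_mean": float(np.mean(lag1)), "lag1_true": float(om[0]),
        "n_reps": n_reps, "n_trials": n_trials,
    }


def history_null_coverage(seed: int = 0, n_trials: int = 10_000,
                          n_reps: int = 8) -> dict:
    """Null-observer fits: 95% kernel CIs should cover zero ~95% of the time."""
    seeds = _seed_stream(seed, n_reps)
    coverage, alpha_err, ll_gain = [], [], []
    for r in range(n_reps):
        df = hist.simulate_history_observer(
            n_trials, alpha=1.0, seed=int(seeds[r]), block_size=500,
            intensity_levels=(0.5, 1.0, 2.0))
        fit = hist.fit_history_model(hist.build_history_design(
            df, zscore_intensity=False))
        w = np.concatenate([fit.omega["choice"], fit.omega["stimulus"]])
        se = np.concatenate([fit.omega_se["choice"], fit.omega_se["stimulus"]])
        coverage.append(np.mean(np.abs(w) <= 1.96 * se))
        alpha_err.append(abs(fit.alpha_sens - 1.0))
        ll_gain.append(fit.loglik - fit.loglik_nohistory)
    return {
        "kernel_coverage": float(np.mean(coverage)),
        "alpha_rel_err": float(np.mean(alpha_err)),
        "min_loglik_gain": float(np.min(ll_gain)),
        "n_reps": n_reps, "n_trials": n_trials,
    }


# ---------------------------------------------------------------- mediation

def _mediation_cohort(seed, n_subjects, n_trials, a_paths, b_paths,
                      c_prime=0.0):
    seeds = _seed_stream(seed, n_subjects)
    fits = []
    for s in range(n_subjects):
        d = simulate_mediation_data(n_trials, a_paths=a_paths,
                                    b_paths=b_paths, c_prime=c_prime,
                                    s0=0.8, seed=int(seeds[s]))
        d = d.rename(columns={"m1": "beta", "m2": "alpha", "m3": "gamma"})
        fits.append(med.fit_mediation_subject(d, subject_id=s))
    return fits


def mediation_type1(seed: int = 0, n_cohorts: int = 500,
                    n_subjects: int = 20, n_trials: int = 300,
                    alpha: float = 0.05) -> dict:
    """Type-I error of the group test on the gamma indirect path under null."""
    seeds = _seed_stream(seed, n_cohorts)
    rejections = []
    for c in range(n_cohorts):
        fits = _mediation_cohort(int(seeds[c]), n_subjects, n_trials,
                                 (0, 0, 0), (0, 0, 0))
        g = med.group_mediation(fits)
        p = g.loc[(g["group"] == "all") & (g["path"] == "indirect_gamma"),
                  "p"].iloc[0]
        rejections.append(p < alpha)
    return {"type1_error": float(np.mean(rejections)), "n_cohorts": n_cohorts,
            "n_subjects": n_subjects, "n_trials": n_trials}


def mediation_recovery(seed: int = 0, n_subjects: int = 30,
                       n_trials: int = 1200, a: float = 0.5,
                       b: float = 0.5) -> dict:
    """Recovery of the standardized indirect effect a*b through gamma."""
    fits = _mediation_cohort(seed, n_subjects, n_trials, (0, 0, a), (0, 0, b))
    tab = med.mediation_table(fits)
    est = tab["indirect_gamma"]
    se = stats.sem(est)
    truth = a * b
    return {
        "indirect_gamma_mean": float(est.mean()),
        "indirect_gamma_true": truth,
        "abs_err_in_se": float(abs(est.mean() - truth) / se),
        "other_paths_max_abs": float(
            tab[["indirect_beta", "indirect_alpha"]].abs().mean().max()),
        "n_subjects": n_subjects, "n_trials": n_trials,
    }


# ------------------------------------------------------------------- streaks

def streak_bias_study(seed: int = 0, n_subjects: int = 60,
                      trials_per_session: int = 600, n_sessions: int = 1,
                      repeater_fraction: float = 1.0):
    """One cohort's streak-bias table and within-group ANOVA."""
    trials, _, agents = generate_cohort(
        n_subjects=n_subjects, repeater_fraction=repeater_fraction,
        trials_per_session=trials_per_session, n_sessions=n_sessions,
        seed=seed)
    ev = stk.extract_streaks(trials)
    bias = stk.repeating_bias_curve(ev, trials)
    anova = stk.streak_anova(bias)
    labels = {s: a.subgroup for s, a in agents.items()}
    return bias, anova, labels


def streak_interaction_power(seed: int = 0, n_cohorts: int = 20,
                             n_subjects: int = 60,
                             trials_per_session: int = 600,
                             alpha: float = 0.05) -> dict:
    """Power to detect the length x end interaction in repeater cohorts.

    Also summarizes the directional pattern: bias increasing with length for
    repeat-ending sequences and lower for alternate-ending ones.
    """
    seeds = _seed_stream(seed, n_cohorts)
    detected, pattern_ok = [], []
    for c in range(n_cohorts):
        bias, anova, _ = streak_bias_study(int(seeds[c]), n_subjects,
                                           trials_per_session,
                                           repeater_fraction=1.0)
        p = anova.set_index("Source").loc["length * end", "p_unc"]
        detected.append(p < alpha)
        m = bias.groupby(["end", "length"])["repeating_bias"].mean()
        slope_rep = np.polyfit(np.arange(1, 6), m["repeat"].to_numpy(), 1)[0]
        pattern_ok.append(slope_rep > 0
                          and m["repeat"].mean() > m["alternate"].mean())
    return {"interaction_power": float(np.mean(detected)),
            "pattern_rate": float(np.mean(pattern_ok)),
            "n_cohorts": n_cohorts, "n_subjects": n_subjects}


# ----------------------------------------------------------------- staircase

def staircase_convergence(seed: int = 0, n_trials: int = 4000) -> dict:
    """Accuracy at the converged 2-up-1-down level vs the sqrt(0.5) target."""
    observer = WeibullPsychometric(delta=0.5, gamma_lapse=0.0, alpha_thr=8.0,
                                   beta_slope=3.0)
    _, levels = staircase_2up1down(observer, start=20.0, step=0.1,
                                   n_trials=n_trials, seed=seed)
    tail = levels[n_trials // 2:]
    acc = float(np.mean(weibull_psychometric(tail, observer)))
    return {"accuracy_at_convergence": acc,
            "target": float(np.sqrt(0.5)),
            "converged_level_mean": float(tail.mean()),
            "n_trials": n_trials}


# ----------------------------------------------------------------------- FDR

def brute_force_bh(p: np.ndarray, alpha_grid: int = 10_000) -> np.ndarray:
    """Independent step-up oracle: q_i = min over alpha of levels rejecting i.

    Computes q-values directly from the definition of the step-up rule
    (smallest nominal level at which each p-value would be rejected),
    scanning ranks explicitly rather than using the closed-form cummin.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    for rank_target, idx in enumerate(order, start=1):
        # smallest q such that running step-up at level q rejects this p:
        # step-up rejects the largest k with p_(k) <= q k / m, covering all
        # smaller ranks
        best = np.inf
        ps = p[order]
        for k in range(rank_target, m + 1):
            best = min(best, ps[k - 1] * m / k)
        q[idx] = min(best, 1.0)
    return q


def fdr_agreement(seed: int = 0, n_vectors: int = 1000,
                  max_len: int = 12) -> dict:
    """Agreement between the package BH adjustment and the brute-force oracle."""
    rng = np.random.default_rng(seed)
    max_abs = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        q1 = enc.fdr_adjust(p)
        q2 = brute_force_bh(p)
        max_abs = max(max_abs, float(np.max(np.abs(q1 - q2))))
    return {"max_abs_difference": max_abs, "n_vectors": n_vectors}


# -------------------------------------------------------------- encoding

def encoding_cohort_study(seed: int = 0, n_subjects: int = 60,
                          trials_per_session: int = 600,
                          n_sessions: int = 1) -> dict:
    """Cohort-level encoding results: history codes and subgroup interaction."""
    trials, signals, agents = generate_cohort(
        n_subjects=n_subjects, trials_per_session=trials_per_session,
        n_sessions=n_sessions, seed=seed)
    labels = {s: a.subgroup for s, a in agents.items()}
    gamma = enc.fit_encoding(trials, signals, "gamma_ips23_test")
    inter = enc.fit_group_interaction(trials, signals, "gamma_ips23_test",
                                      labels)
    beta_ref = signals["beta_motor_ref"].to_numpy()
    beta_flipped = enc.flip_motor_lateralization(
        beta_ref, trials["choice_hand_map"].to_numpy())
    beta = enc.fit_encoding(trials, pd.DataFrame({"beta": beta_flipped}),
                            "beta")
    return {
        "gamma_prev_choice_estimate": float(gamma.estimates["c_prev"]),
        "gamma_prev_choice_p": float(gamma.p_values["c_prev"]),
        "group_interaction_estimate": float(inter.estimates["g:c_prev"]),
        "group_interaction_p": float(inter.p_values["g:c_prev"]),
        "beta_prev_action_estimate": float(beta.estimates["c_prev"]),
        "beta_prev_action_p": float(beta.p_values["c_prev"]),
        "n_subjects": n_subjects,
    }
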