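"""Weibull psychometric fitting, adaptive staircase, and subgroup labels.

The accuracy psychometric for the two-interval comparison is a cumulative
Weibull of the absolute coherence difference c,

    psi(c) = delta + (1 - delta - gamma) * (1 - exp(-(c / alpha)**beta)),

with guess rate delta (fixed at 0.5: two alternatives), lapse rate gamma,
threshold alpha and slope beta. Thresholding uses a 2-up-1-down staircase
(0.1% steps), whose accuracy fixed point is sqrt(0.5) ~ 70.7% correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "WeibullPsychometric",
    "SubgroupLabel",
    "weibull_psychometric",
    "fit_weibull",
    "staircase_2up1down",
    "repetition_probability",
    "classify_subgroups",
]

STANDARD_LEVELS = (1.25, 2.5, 5.0, 10.0, 20.0, 30.0)  # % coherence difference


@dataclass(frozen=True)
class WeibullPsychometric:
    delta: float = 0.5        # guess rate (chance performance)
    gamma_lapse: float = 0.0  # lapse rate
    alpha_thr: float = 5.0    # threshold, % coherence
    beta_slope: float = 2.0   # slope

    def __post_init__(self):
        if not (0 <= self.delta < 1 and 0 <= self.gamma_lapse < 1):
            raise ValueError("guess and lapse rates must lie in [0, 1)")
        if self.alpha_thr <= 0 or self.beta_slope <= 0:
            raise ValueError("threshold and slope must be positive")

    def __call__(self, c):
        return weibull_psychometric(c, self)


@dataclass(frozen=True)
class SubgroupLabel:
    subject_id: int
    p_repeat: float
    label: str                 # repeater | alternator | excluded
    blockwise_p: float         # t-test of block-wise P(repeat) vs 0.5
    blockwise_significant: bool
    flagged: bool = False      # degenerate or undefined block-wise test


def weibull_psychometric(c, params: WeibullPsychometric):
    """Probability correct at absolute coherence difference ``c`` (>= 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("coherence difference must be non-negative")
    p = params.delta + (1 - params.delta - params.gamma_lapse) * (
        1 - np.exp(-((c / params.alpha_thr) ** params.beta_slope)))
    return p if p.ndim else float(p)


class DegenerateFitError(RuntimeError):
    pass


def fit_weibull(coherences, correct, delta: float = 0.5,
                lapse_max: float = 0.1, n_starts: int = 5, seed: int = 0,
                target: float = 0.7):
    """Maximum-likelihood Weibull fit with the guess rate pinned.

    Returns ``(params, threshold)`` where ``threshold`` is the coherence at
    which the fitted curve crosses ``target`` proportion correct. Uses
    Nelder-Mead with multiple starts (the lapse/slope trade-off can be
    multimodal); the lapse is constrained to [0, ``lapse_max``].

    Raises ``DegenerateFitError`` on all-correct or all-error data.
    """
    c = np.asarray(coherences, dtype=float)
    y = np.asarray(correct, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least two distinct coherence levels")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary")
    if y.min() == y.max():
        raise DegenerateFitError(
            f"all trials {'correct' if y[0] else 'error'}: the psychometric "
            "slope/threshold are unidentifiable")

    def nll(theta):
        log_alpha, log_beta, lapse_u = theta
        pars = WeibullPsychometric(delta, lapse_max * expit(lapse_u),
                                   np.exp(log_alpha), np.exp(np.clip(log_beta, -3, 3)))
        p = np.clip(weibull_psychometric(c, pars), 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    rng = np.random.default_rng(seed)
    best = None
    base = np.array([np.log(np.median(np.unique(c))), np.log(2.0), logit(0.2)])
    for i in range(n_starts):
        x0 = base if i == 0 else base + rng.normal(0, [0.7, 0.5, 1.0])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxfev": 2000})
        if best is None or res.fun < best.fun:
            best = res
    la, lb, lu = best.x
    params = WeibullPsychometric(delta, lapse_max * expit(lu),
                                 float(np.exp(la)), float(np.exp(np.clip(lb, -3, 3))))
    threshold = threshold_at(params, target)
    return params, threshold


def threshold_at(params: WeibullPsychometric, target: float = 0.7) -> float:
    """Coherence at which the Weibull crosses ``target`` proportion correct."""
    top = 1 - params.delta - params.gamma_lapse
    frac = (target - params.delta) / top
    if not 0 < frac < 1:
        return np.nan
    return float(params.alpha_thr * (-np.log(1 - frac)) ** (1 / params.beta_slope))


def staircase_2up1down(observer: WeibullPsychometric, start: float,
                       step: float = 0.1, n_trials: int = 100, seed=None,
                       n_reversals_used: int = 6):
    """2-up-1-down adaptive staircase against a simulated Weibull observer.

    Coherence increases by ``step`` after each error and decreases by
    ``step`` after two consecutive correct responses; the threshold estimate
    is the mean coherence at the last ``n_reversals_used`` reversals (all
    reversals if fewer occurred). Converges to the ~70.7%-correct level (the
    sqrt(0.5) fixed point).

    Returns ``(threshold, trajectory)`` with the per-trial coherence levels.
    """
    if start <= 0:
        raise ValueError("staircase must start at positive coherence")
    rng = np.random.default_rng(seed)
    level = float(start)
    levels = np.empty(n_trials)
    correct_streak = 0
    direction = 0
    reversals = []
    for t in range(n_trials):
        levels[t] = level
        correct = rng.random() < weibull_psychometric(level, observer)
        if correct:
            correct_streak += 1
            move = -1 if correct_streak >= 2 else 0
            if move:
                correct_streak = 0
        else:
            correct_streak = 0
            move = 1
        if move:
            if direction and move != direction:
                reversals.append(level)
            direction = move
            level = max(level + move * step, step)
    used = reversals[-n_reversals_used:] if reversals else [level]
    return float(np.mean(used)), levels


def repetition_probability(choices) -> float:
    """Fraction of trials repeating the previous choice."""
    c = np.asarray(choices)
    if c.size < 2:
        raise ValueError("need at least 2 choices")
    return float(np.mean(c[1:] == c[:-1]))


def classify_subgroups(trials, block_cols=("session", "block")) -> list[SubgroupLabel]:
    """Label each subject repeater/alternator from pooled P(repeat).

    Pooled repetition probability is computed across both sessions; a subject
    at exactly 0.5 is excluded from subgroup analyses. ``blockwise_p`` is a
    two-sided one-sample t-test of per-block repetition probabilities against
    0.5 (flagged when undefined: a single block or zero variance).
    """
    labels = []
    for sid, d in trials.groupby("subject_id"):
        per_block = d.groupby(list(block_cols))["choice"].apply(
            lambda c: repetition_probability(c.to_numpy()))
        pooled = float(np.mean([
            repetition_probability(g["choice"].to_numpy())
            for _, g in d.groupby(list(block_cols))]))
        if pooled > 0.5:
            label = "repeater"
        elif pooled < 0.5:
            label = "alternator"
        else:
            label = "excluded"
        flagged = False
        if len(per_block) < 2 or np.allclose(per_block.var(ddof=1), 0):
            p = np.nan
            flagged = True
        else:
            p = float(stats.ttest_1samp(per_block, 0.5).pvalue)
        labels.append(SubgroupLabel(
            subject_id=sid, p_repeat=pooled, label=label, blockwise_p=p,
            blockwise_significant=bool(p < 0.05) if np.isfinite(p) else False,
            flagged=flagged))
    return labels
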