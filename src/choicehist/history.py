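"""History-dependent psychometric model with lag-resolved kernels.

The probability of a "stronger" report is a lapse-mixed logistic of the
signed stimulus intensity plus a bias term that is a linear combination of
the previous K stimuli and choices:

    P(r_t = 1 | s_t, h_t) = gamma + (1 - gamma - lambda) *
                            g( delta' + delta_hist(h_t) + alpha * s_t ),
    delta_hist(h_t) = sum_k omega_k h_kt,          g(x) = 1 / (1 + e^-x),

with K = 7 lags for each history class (previous stimuli, previous choices),
each projected onto B = 3 exponentially decaying basis functions to
regularize the lag profile. Positive choice weights omega indicate a tendency
to repeat. Parameters are estimated by penalized maximum likelihood on a
smooth reparameterization (lapses through scaled logits); the optimization is
started from the fitted no-history model so the likelihood can never fall
below the nested model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "exp_basis",
    "HistoryDesign",
    "build_history_design",
    "HistoryKernelFit",
    "fit_history_model",
    "kernel_summary",
    "simulate_history_observer",
]

DEFAULT_TAUS = (1.0, 2.5, 6.25)  # geometric ladder of decay constants (lags)
# Lapses are bounded well below the theoretical 0.5 ceiling: with a single
# stimulus intensity per observer (threshold testing), large lapse rates and
# extreme sensitivity are observationally equivalent, and the bound removes
# that degeneracy.
MAX_LAPSE = 0.1


def exp_basis(K: int = 7, taus=DEFAULT_TAUS) -> np.ndarray:
    """(B, K) matrix of exponentially decaying basis rows, each unit-sum.

    Entry (b, k) is proportional to exp(-(k - 1) / tau_b) for lag k = 1..K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if np.any(taus <= 0):
        raise ValueError("decay constants must be positive")
    lags = np.arange(K, dtype=float)
    B = np.exp(-lags[None, :] / taus[:, None])
    return B / B.sum(axis=1, keepdims=True)


@dataclass
class HistoryDesign:
    """Basis-projected history features aligned with the trial table.

    ``features`` has one column per (class, basis) pair in the order
    stimulus-basis-1..B then choice-basis-1..B; rows whose history window
    crosses a block boundary are masked out via ``valid``.
    """

    features: np.ndarray
    stimulus_intensity: np.ndarray
    responses: np.ndarray  # 1 for "stronger", 0 for "weaker"
    valid: np.ndarray
    basis: np.ndarray
    K: int
    classes: tuple = ("stimulus", "choice")


def build_history_design(trials: pd.DataFrame, K: int = 7,
                         basis: np.ndarray | None = None,
                         zscore_intensity: bool = True,
                         split_by_outcome: bool = False) -> HistoryDesign:
    """Construct the lagged stimulus/choice design for the history model.

    ``trials`` must be sorted by subject, session, block, trial; history
    never crosses block boundaries, so the first K trials of every block are
    masked. Stimuli and choices enter with signed (-1/+1) coding; the signed
    stimulus intensity is the coherence delta, z-scored per subject by
    default.

    With ``split_by_outcome`` the stimulus and choice history classes are
    each split by the outcome of the past trial (win-stay/lose-switch
    parameterization): four feature classes instead of two, with e.g.
    ``choice_correct`` holding the lagged choice on previously-correct trials
    and zero elsewhere.
    """
    if basis is None:
        basis = exp_basis(K)
    if basis.shape[1] != K:
        raise ValueError("basis must have K columns")
    key = ["subject_id", "session", "block", "trial"]
    if not trials[key].apply(tuple, axis=1).is_monotonic_increasing:
        raise ValueError("trials must be sorted by subject/session/block/trial")
    n = len(trials)
    stim = trials["stimulus"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy(dtype=float)
    if split_by_outcome:
        correct = (trials["outcome"].to_numpy() == "correct").astype(float)
        base_series = {
            "stimulus_correct": stim * correct,
            "stimulus_error": stim * (1 - correct),
            "choice_correct": choice * correct,
            "choice_error": choice * (1 - correct),
        }
    else:
        base_series = {"stimulus": stim, "choice": choice}
    classes = tuple(base_series)
    lagged = {cls: np.zeros((n, K)) for cls in classes}
    valid = np.ones(n, dtype=bool)
    grp = trials.groupby(["subject_id", "session", "block"]).ngroup().to_numpy()
    for k in range(1, K + 1):
        same_block = np.zeros(n, dtype=bool)
        same_block[k:] = grp[k:] == grp[:-k]
        for cls, series in base_series.items():
            lagged[cls][k:, k - 1] = np.where(same_block[k:], series[:-k], 0.0)
        valid &= np.concatenate([np.zeros(k, dtype=bool), same_block[k:]])
    feats = np.column_stack([lagged[cls] @ basis.T for cls in classes])
    intensity = trials["coherence_delta"].to_numpy(dtype=float)
    if zscore_intensity:
        s = pd.Series(intensity)
        zs = s.groupby(trials["subject_id"].to_numpy()).transform(
            lambda x: (x - x.mean()) / (x.std(ddof=0) or 1.0))
        intensity = zs.to_numpy()
    responses = (choice > 0).astype(float)
    return HistoryDesign(features=feats, stimulus_intensity=intensity,
                         responses=responses, valid=valid, basis=basis, K=K,
                         classes=classes)


@dataclass
class HistoryKernelFit:
    alpha_sens: float
    delta_prime: float
    gamma_lapse: float
    lambda_lapse: float
    basis_coefs: dict
    omega: dict                       # lag-resolved kernels per class
    omega_se: dict
    loglik: float
    loglik_nohistory: float
    converged: bool
    n_trials: int
    diagnostics: dict = field(default_factory=dict)


def _unpack(theta, n_feat, max_lapse=MAX_LAPSE):
    alpha, delta_p = theta[0], theta[1]
    gamma = max_lapse * expit(theta[2])
    lam = max_lapse * expit(theta[3])
    coefs = theta[4:4 + n_feat]
    return alpha, delta_p, gamma, lam, coefs


def _nll(theta, X, s, y, penalty, max_lapse=MAX_LAPSE):
    alpha, delta_p, gamma, lam, coefs = _unpack(theta, X.shape[1], max_lapse)
    core = expit(delta_p + alpha * s + X @ coefs)
    p = gamma + (1 - gamma - lam) * core
    p = np.clip(p, 1e-10, 1 - 1e-10)
    ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    return -ll + penalty * np.sum(coefs ** 2)


def fit_history_model(design: HistoryDesign, penalty: float = 1e-4,
                      compute_se: bool = True,
                      max_lapse: float = MAX_LAPSE) -> HistoryKernelFit:
    """Penalized MLE of the lapse-mixed history psychometric model."""
    m = design.valid
    X = design.features[m]
    s = design.stimulus_intensity[m]
    y = design.responses[m]
    if X.shape[0] < X.shape[1] + 4:
        raise ValueError("not enough valid trials to fit the history model")
    n_feat = X.shape[1]

    # nested no-history fit provides both the start point and the reference
    # log-likelihood (guarantees the nesting inequality)
    def nll0(th):
        return _nll(np.concatenate([th, np.zeros(n_feat)]), X, s, y, 0.0,
                    max_lapse)

    th0 = np.array([1.0, 0.0, logit(0.02 / max_lapse), logit(0.02 / max_lapse)])
    res0 = minimize(nll0, th0, method="Nelder-Mead",
                    options={"maxfev": 4000, "xatol": 1e-6, "fatol": 1e-8})
    ll0 = -nll0(res0.x)

    start = np.concatenate([res0.x, np.zeros(n_feat)])
    res = minimize(_nll, start, args=(X, s, y, penalty, max_lapse),
                   method="L-BFGS-B", options={"maxiter": 2000})
    # polish with a simplex pass in case L-BFGS stops at a poor point
    res2 = minimize(_nll, res.x, args=(X, s, y, penalty, max_lapse),
                    method="Nelder-Mead",
                    options={"maxfev": 6000, "xatol": 1e-6, "fatol": 1e-8})
    theta = res2.x if res2.fun < res.fun else res.x
    alpha, delta_p, gamma, lam, coefs = _unpack(theta, n_feat, max_lapse)
    ll = -_nll(theta, X, s, y, 0.0, max_lapse)

    B = design.basis.shape[0]
    classes = design.classes
    coef_split = {cls: coefs[i * B:(i + 1) * B] for i, cls in enumerate(classes)}
    omega = {cls: design.basis.T @ coef_split[cls] for cls in classes}

    omega_se = {cls: np.full(design.K, np.nan) for cls in classes}
    if compute_se:
        try:
            H = _num_hessian(
                lambda th: _nll(th, X, s, y, penalty, max_lapse), theta)
            cov = np.linalg.pinv(H)
            for i, cls in enumerate(classes):
                sl = slice(4 + i * B, 4 + (i + 1) * B)
                cov_c = cov[sl, sl]
                omega_se[cls] = np.sqrt(np.maximum(
                    np.einsum("bk,bc,ck->k", design.basis, cov_c, design.basis),
                    0.0))
        except np.linalg.LinAlgError:
            pass

    return HistoryKernelFit(
        alpha_sens=float(alpha), delta_prime=float(delta_p),
        gamma_lapse=float(gamma), lambda_lapse=float(lam),
        basis_coefs=coef_split, omega=omega, omega_se=omega_se,
        loglik=float(ll), loglik_nohistory=float(ll0),
        converged=bool(res.success or res2.success),
        n_trials=int(m.sum()),
        diagnostics={"nll_optimizer": float(min(res.fun, res2.fun))})


def _num_hessian(fun, x, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei) - fun(x + ej) + f0) / eps ** 2
    return H


def kernel_summary(fits: dict, labels: dict | None = None) -> pd.DataFrame:
    """Group-mean kernels with per-lag t-tests against zero.

    ``fits`` maps subject -> HistoryKernelFit; ``labels`` optionally maps
    subject -> subgroup for per-group summaries. Returns a tidy frame with
    one row per (group, class, lag).
    """
    rows = []
    for sid, fit in fits.items():
        grp = labels.get(sid, "all") if labels else "all"
        for cls, om in fit.omega.items():
            for k, w in enumerate(om, start=1):
                rows.append({"subject_id": sid, "group": grp, "class": cls,
                             "lag": k, "weight": w})
    tidy = pd.DataFrame(rows)
    if tidy.empty:
        raise ValueError("no fits supplied")
    out = []
    for (grp, cls, lag), d in tidy.groupby(["group", "class", "lag"]):
        w = d["weight"].to_numpy()
        if w.size >= 2 and np.std(w, ddof=1) > 0:
            t, p = stats.ttest_1samp(w, 0.0)
        else:
            t, p = np.nan, np.nan
        out.append({"group": grp, "class": cls, "lag": lag,
                    "mean_weight": w.mean(),
                    "sem": stats.sem(w) if w.size >= 2 else np.nan,
                    "t": t, "p": p, "n": w.size})
    return pd.DataFrame(out)


def simulate_history_observer(n_trials: int, alpha: float = 1.0,
                              delta_prime: float = 0.0,
                              omega_choice=None, omega_stim=None,
                              gamma_lapse: float = 0.0,
                              lambda_lapse: float = 0.0,
                              K: int = 7, seed=None,
                              block_size: int | None = None,
                              intensity_levels=(1.0,)) -> pd.DataFrame:
    """Generate trials directly from the history psychometric model.

    The generative mirror of the fitted model, used for parameter-recovery
    checks. Signed intensities are drawn from ``intensity_levels`` with
    balanced categories; a single level matches the threshold-tested task,
    while graded levels make sensitivity and lapses separately identifiable.
    The history bias enters lagged signed categories, as in the fit.
    """
    rng = np.random.default_rng(seed)
    omega_choice = np.zeros(K) if omega_choice is None else np.asarray(omega_choice, float)
    omega_stim = np.zeros(K) if omega_stim is None else np.asarray(omega_stim, float)
    if block_size is None:
        block_size = n_trials
    stim = rng.choice([-1.0, 1.0], n_trials)
    levels = rng.choice(np.asarray(intensity_levels, dtype=float), n_trials)
    intensity = stim * levels
    choice = np.empty(n_trials)
    block = np.arange(n_trials) // block_size
    for t in range(n_trials):
        bias = delta_prime
        for k in range(1, K + 1):
            if t - k >= 0 and block[t - k] == block[t]:
                bias += omega_stim[k - 1] * stim[t - k]
                bias += omega_choice[k - 1] * choice[t - k]
        p = gamma_lapse + (1 - gamma_lapse - lambda_lapse) * expit(
            bias + alpha * intensity[t])
        choice[t] = 1.0 if rng.random() < p else -1.0
    return pd.DataFrame({
        "subject_id": 1, "session": 1, "block": block + 1,
        "trial": np.arange(n_trials) % block_size + 1,
        "stimulus": stim.astype(int), "coherence_delta": intensity,
        "choice": choice.astype(int),
        "rt": np.full(n_trials, 1.0),
        "action": np.where(choice > 0, "right", "left"),
        "outcome": np.where(choice == stim, "correct", "error"),
        "choice_hand_map": "right",
    })
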