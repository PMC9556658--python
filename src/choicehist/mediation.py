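"""Single-trial mediation of choice history through neural signals.

Per subject, three candidate mediators (motor beta, parietal alpha residual,
parietal gamma) are regressed on the previous choice (linear models, the two
stimulus-sensitive signals also receive the current stimulus), and the
current choice is regressed on all mediators, the previous choice, and the
stimulus by logistic regression:

    beta  ~ a1 * c_prev + s1 * s
    alpha ~ a2 * c_prev + s2 * s
    gamma ~ a3 * c_prev
    c     ~ b1 * beta + b2 * alpha + b3 * gamma + c' * c_prev + s0 * s

The indirect effect through mediator k is a_k * b_k, the direct effect is
c', and the total is sum_k a_k b_k + c'. Coefficients are standardized:
linear paths by sd(x)/sd(y), logistic paths on the latent-response scale
(residual variance pi^2/3). Group-level inference is by t-tests across the
per-subject standardized coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MediationFit",
    "fit_mediation_subject",
    "mediation_table",
    "group_mediation",
    "ab_path_decomposition",
]

MEDIATORS = ("beta", "alpha", "gamma")


@dataclass
class MediationFit:
    """Standardized path coefficients for one subject."""

    subject_id: int
    a: dict            # previous choice -> mediator, per mediator
    b: dict            # mediator -> choice (latent scale), per mediator
    s_paths: dict      # stimulus covariate paths
    c_prime: float
    n_trials: int
    flagged: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def indirect(self) -> dict:
        return {k: self.a[k] * self.b[k] for k in self.a}

    @property
    def total(self) -> float:
        return sum(self.indirect.values()) + self.c_prime


def _standardized_logistic(X: np.ndarray, y01: np.ndarray, names,
                           ridge_on_separation: bool = True):
    """Logistic fit with latent-scale standardized coefficients."""
    Xc = sm.add_constant(X, has_constant="add")
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, Xc).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False) or np.any(
                    np.abs(res.params) > 50):
                raise sm.tools.sm_exceptions.PerfectSeparationError
            coefs = res.params[1:]
        except Exception:
            if not ridge_on_separation:
                raise
            flagged = True
            res = sm.Logit(y01, Xc).fit_regularized(alpha=1.0, L1_wt=0.0,
                                                    disp=0, maxiter=500)
            coefs = np.asarray(res.params)[1:]
    lin = X @ coefs
    sd_latent = np.sqrt(np.var(lin) + np.pi ** 2 / 3)
    sx = X.std(axis=0)
    coefs_std = coefs * sx / sd_latent
    return dict(zip(names, coefs_std)), flagged


def fit_mediation_subject(data: pd.DataFrame, subject_id: int = 0,
                          mediator_cols=("beta", "alpha", "gamma"),
                          zscore_mediators: bool = True) -> MediationFit:
    """Two-stage estimation of the mediation system for one subject.

    ``data`` needs columns ``prev_choice`` and ``choice`` (coded -1/+1),
    ``stimulus`` (-1/+1), and the three mediator columns (order: beta,
    alpha, gamma). Rows with missing previous choice must be dropped
    beforehand. On separation in the logistic stage, a ridge-penalized fit is
    used and the result is flagged.
    """
    d = data.dropna(subset=["prev_choice", "choice", "stimulus",
                            *mediator_cols])
    c_prev = d["prev_choice"].to_numpy(dtype=float)
    stim = d["stimulus"].to_numpy(dtype=float)
    choice01 = (d["choice"].to_numpy(dtype=float) > 0).astype(float)
    med = d[list(mediator_cols)].to_numpy(dtype=float)
    if zscore_mediators:
        med = (med - med.mean(axis=0)) / med.std(axis=0)

    a_paths, s_paths = {}, {}
    stim_in_model = {0: True, 1: True, 2: False}  # gamma: c_prev only
    for k, name in enumerate(MEDIATORS):
        cols = [c_prev, stim] if stim_in_model[k] else [c_prev]
        X = np.column_stack(cols)
        Xc = sm.add_constant(X, has_constant="add")
        res = sm.OLS(med[:, k], Xc).fit()
        sy = med[:, k].std()
        a_paths[name] = float(res.params[1] * c_prev.std() / sy)
        if stim_in_model[k]:
            s_paths[f"s_{name}"] = float(res.params[2] * stim.std() / sy)

    Xout = np.column_stack([med, c_prev, stim])
    names = [*MEDIATORS, "c_prime", "s0"]
    coefs, flagged = _standardized_logistic(Xout, choice01, names)
    b_paths = {k: coefs[k] for k in MEDIATORS}
    s_paths["s0"] = coefs["s0"]
    return MediationFit(subject_id=subject_id, a=a_paths, b=b_paths,
                        s_paths=s_paths, c_prime=coefs["c_prime"],
                        n_trials=len(d), flagged=flagged)


def mediation_table(fits: list[MediationFit]) -> pd.DataFrame:
    """Tidy per-subject path table (one row per subject)."""
    rows = []
    for f in fits:
        row = {"subject_id": f.subject_id, "c_prime": f.c_prime,
               "total": f.total, "flagged": f.flagged}
        for k in MEDIATORS:
            row[f"a_{k}"] = f.a[k]
            row[f"b_{k}"] = f.b[k]
            row[f"indirect_{k}"] = f.indirect[k]
        rows.append(row)
    return pd.DataFrame(rows)


def group_mediation(fits: list[MediationFit], labels: dict | None = None,
                    ) -> pd.DataFrame:
    """Group-level t-tests of standardized paths against zero.

    One-sample t-tests per path for the complete group and within each
    subgroup; two-sample Welch tests between repeaters and alternators when
    labels are given.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 subjects")
    tab = mediation_table(fits)
    if labels is not None:
        tab["group"] = tab["subject_id"].map(labels)
    paths = ([f"indirect_{k}" for k in MEDIATORS]
             + [f"a_{k}" for k in MEDIATORS]
             + [f"b_{k}" for k in MEDIATORS] + ["c_prime", "total"])
    rows = []

    def one_sample(d, grp):
        for p in paths:
            x = d[p].to_numpy()
            t, pv = stats.ttest_1samp(x, 0.0) if x.size >= 2 else (np.nan, np.nan)
            rows.append({"group": grp, "path": p, "mean": x.mean(),
                         "sem": stats.sem(x) if x.size >= 2 else np.nan,
                         "t": t, "p": pv, "df": x.size - 1, "n": x.size})

    one_sample(tab, "all")
    if labels is not None:
        groups = [g for g in tab["group"].dropna().unique()]
        for g in groups:
            sub = tab[tab["group"] == g]
            if sub.empty:
                raise ValueError(f"empty subgroup {g}")
            one_sample(sub, g)
        if len(groups) == 2:
            g1, g2 = sorted(groups)
            for p in paths:
                x1 = tab.loc[tab["group"] == g1, p]
                x2 = tab.loc[tab["group"] == g2, p]
                t, pv = stats.ttest_ind(x1, x2, equal_var=False)
                rows.append({"group": f"{g1}-vs-{g2}", "path": p,
                             "mean": x1.mean() - x2.mean(), "sem": np.nan,
                             "t": t, "p": pv, "df": np.nan,
                             "n": len(x1) + len(x2)})
    return pd.DataFrame(rows)


def ab_path_decomposition(fits: list[MediationFit], labels: dict | None = None,
                          ) -> pd.DataFrame:
    """Separate group tests on a-paths and b-paths per mediator.

    Enables attributing a group difference in mediation to the effect of the
    previous choice on the neural signal (a) versus the effect of the neural
    signal on the next choice (b).
    """
    full = group_mediation(fits, labels)
    mask = full["path"].str.match(r"^[ab]_")
    out = full[mask].copy()
    out["path_type"] = out["path"].str[0]
    out["mediator"] = out["path"].str[2:]
    return out
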