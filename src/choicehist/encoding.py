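"""Mixed-effects encoding models of single-trial neural power.

Each (region, band, window) signal is modeled as a linear mixed model with a
per-subject random intercept,

    n ~ 1 + s + c_prev + (1 | subject)                 (base model)
    n ~ 1 + s + g * c_prev + (1 | subject)             (subgroup interaction)

with s the stimulus category, c_prev the previous choice and g the subgroup,
all coded -1/+1. P-values across the tested family of signals are corrected
by Benjamini-Hochberg FDR at 0.05. Utilities handle the two signal-specific
preprocessing steps: projecting the global (error-related) alpha component
out of the parietal alpha signal, and referencing motor beta lateralization
to the hand that reports "stronger".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "EncodingResult",
    "encoding_frame",
    "fit_encoding",
    "fit_group_interaction",
    "timeresolved_encoding",
    "fdr_adjust",
    "residualize_alpha",
    "flip_motor_lateralization",
]


@dataclass
class EncodingResult:
    """Fixed effects of one encoding model."""

    signal: str
    estimates: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    q_values: pd.Series | None = None
    fallback_ols: bool = False
    extra: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.estimates, "se": self.se,
                            "ci_low": self.ci_low, "ci_high": self.ci_high,
                            "p": self.p_values})
        if self.q_values is not None:
            out["q"] = self.q_values
        return out


def encoding_frame(trials: pd.DataFrame, signals: pd.DataFrame,
                   signal_col: str, labels: dict | None = None) -> pd.DataFrame:
    """Aligned modeling frame with -1/+1 coded predictors.

    Drops trials without a previous trial in the same block, and (if labels
    are supplied) subjects without a repeater/alternator label.
    """
    df = pd.DataFrame({
        "y": signals[signal_col].to_numpy(),
        "s": trials["stimulus"].to_numpy(dtype=float),
        "subject": trials["subject_id"].to_numpy(),
    })
    df["c_prev"] = trials.groupby(
        ["subject_id", "session", "block"])["choice"].shift(1).to_numpy()
    if labels is not None:
        g = trials["subject_id"].map(labels)
        df["g"] = g.map({"repeater": 1.0, "alternator": -1.0}).to_numpy()
    df = df.dropna()
    # power-modulation outliers are removed upstream of modeling
    return df[np.abs(df["y"]) <= 500].reset_index(drop=True)


def _fit_mixed(df: pd.DataFrame, formula: str, signal: str) -> EncodingResult:
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for the mixed model")
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"])
            res = model.fit(reml=True)
            singular = (not res.converged) or np.any(~np.isfinite(res.bse_fe))
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            res = None
    if singular:
        # singular random-intercept fit: subject-clustered robust OLS
        fallback = True
        ols = smf.ols(formula, df).fit(cov_type="cluster",
                                       cov_kwds={"groups": df["subject"]})
        names = list(ols.params.index)
        est, se, p = ols.params, ols.bse, ols.pvalues
    else:
        names = [n for n in res.params.index if n != "Group Var"]
        est = res.params[names]
        se = res.bse[names]
        p = res.pvalues[names]
    ci_low = est - 1.96 * se
    ci_high = est + 1.96 * se
    return EncodingResult(signal=signal, estimates=est, se=se, ci_low=ci_low,
                          ci_high=ci_high, p_values=p, fallback_ols=fallback)


def fit_encoding(trials: pd.DataFrame, signals: pd.DataFrame, signal_col: str,
                 ) -> EncodingResult:
    """Base history-encoding model ``y ~ 1 + s + c_prev + (1 | subject)``."""
    df = encoding_frame(trials, signals, signal_col)
    return _fit_mixed(df, "y ~ s + c_prev", signal_col)


def fit_group_interaction(trials: pd.DataFrame, signals: pd.DataFrame,
                          signal_col: str, labels: dict) -> EncodingResult:
    """Subgroup model ``y ~ 1 + s + g * c_prev + (1 | subject)``.

    ``labels`` maps subject -> "repeater"/"alternator" (others dropped);
    the ``g:c_prev`` coefficient tests the subgroup difference in history
    coding.
    """
    df = encoding_frame(trials, signals, signal_col, labels=labels)
    if df.empty or df["g"].nunique() < 2:
        raise ValueError("both subgroups must be present")
    return _fit_mixed(df, "y ~ s + g * c_prev", signal_col)


def timeresolved_encoding(trials: pd.DataFrame, binned_signals: dict,
                          term: str = "c_prev", labels: dict | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-time-bin encoding fits with FDR correction across bins.

    ``binned_signals`` maps bin label -> per-trial signal DataFrame column
    (a Series aligned with ``trials``). Returns a tidy frame with the
    coefficient time course for ``term`` and an FDR-corrected significance
    mask.
    """
    rows = []
    for bin_label, series in binned_signals.items():
        sig = pd.DataFrame({"y": np.asarray(series)})
        if labels is None:
            res = fit_encoding(trials, sig, "y")
        else:
            res = fit_group_interaction(trials, sig, "y", labels)
        rows.append({"bin": bin_label,
                     "estimate": res.estimates[term],
                     "se": res.se[term],
                     "p": res.p_values[term]})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    q = sm.stats.multipletests(p, method="fdr_bh")[1]
    return q


def annotate_family_fdr(results: list[EncodingResult], term: str = "c_prev",
                        ) -> pd.DataFrame:
    """FDR across a family of fitted signals for one model term."""
    p = np.array([r.p_values[term] for r in results])
    q = fdr_adjust(p)
    for r, qi in zip(results, q):
        if r.q_values is None:
            r.q_values = pd.Series(np.nan, index=r.p_values.index)
        r.q_values[term] = qi
    return pd.DataFrame({"signal": [r.signal for r in results],
                         "estimate": [r.estimates[term] for r in results],
                         "p": p, "q": q})


def residualize_alpha(alpha_signal, global_signal, subjects=None):
    """Remove the global (error-related) alpha component by linear projection.

    Within each subject, the component of ``alpha_signal`` explained by
    ``global_signal`` (including an intercept) is subtracted; the residual is
    orthogonal to the global regressor within subject. A zero-variance global
    regressor passes the signal through unchanged (flagged via a warning).
    """
    a = np.asarray(alpha_signal, dtype=float)
    g = np.asarray(global_signal, dtype=float)
    if a.shape != g.shape:
        raise ValueError("signals must be aligned")
    if subjects is None:
        subjects = np.zeros(a.size, dtype=int)
    subjects = np.asarray(subjects)
    out = np.empty_like(a)
    for s in np.unique(subjects):
        m = subjects == s
        gs = g[m]
        if np.var(gs) == 0:
            warnings.warn(f"zero-variance global regressor for subject {s}; "
                          "passing alpha through unchanged")
            out[m] = a[m]
            continue
        X = np.column_stack([np.ones(gs.size), gs])
        beta, *_ = np.linalg.lstsq(X, a[m], rcond=None)
        out[m] = a[m] - X @ beta
    return out


def flip_motor_lateralization(beta_signal, choice_hand_map):
    """Reference motor lateralization to the "stronger"-reporting hand.

    Raw lateralization is contra-minus-ipsi of the right hand; for subjects
    whose "stronger" choice maps to the left hand the sign is flipped so the
    convention is uniform across subjects. Applying the flip twice is the
    identity.
    """
    b = np.asarray(beta_signal, dtype=float)
    hands = np.asarray(choice_hand_map)
    valid = np.isin(hands, ("left", "right"))
    if not valid.all():
        raise ValueError("choice_hand_map entries must be 'left' or 'right'")
    return np.where(hands == "right", b, -b)
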