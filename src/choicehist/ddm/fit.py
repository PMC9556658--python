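"""Maximum-likelihood and MCMC fitting of the collapsing-bound model.

Fits use "stimulus coding": response-time distributions are labeled by choice
identity (upper bound = "stronger"), so stimulus-independent biases in drift
or starting point are identifiable. Estimation is staged: the base
accumulation parameters are fit first with all regressor weights at zero, the
weights are then fit conditional on the base parameters, and an optional
joint polish refines everything together. A random-walk Metropolis sampler
over the same likelihood provides posterior summaries when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .bounds import CollapsingBound
from .likelihood import DEADLINE, DDMParams, fpt_likelihood

__all__ = ["DDMFit", "fit_ddm", "compare_bound_models", "fit_bound_modulation"]

# fitting-resolution defaults: coarser than the validation grid, adequate for
# optimization (the likelihood surface is smooth at this resolution)
FIT_DT = 8e-3
FIT_NSPACE = 80

_SHAPE_LO, _SHAPE_HI = 0.5, 8.0


class _ParamMap:
    """Bijection between a free-parameter vector and DDMParams."""

    def __init__(self, bound_form, n_v_w, n_z_w, n_a_w, fixed=None):
        self.bound_form = bound_form
        self.n_v_w, self.n_z_w, self.n_a_w = n_v_w, n_z_w, n_a_w
        self.fixed = fixed or {}
        names = ["v0", "v_s", "logit_z0", "logit_t0", "log_a"]
        if bound_form == "weibull":
            names += ["shape_u", "log_scale"]
        elif bound_form == "linear":
            names += ["log_slope"]
        names += [f"vw{j}" for j in range(n_v_w)]
        names += [f"zw{j}" for j in range(n_z_w)]
        names += [f"aw{j}" for j in range(n_a_w)]
        self.names = [nm for nm in names if nm not in self.fixed]

    def to_params(self, theta) -> DDMParams:
        d = dict(self.fixed)
        d.update(zip(self.names, theta))
        bound = CollapsingBound(
            a=float(np.exp(np.clip(d["log_a"], -2.5, 2.5))),
            form=self.bound_form,
            shape=(_SHAPE_LO + (_SHAPE_HI - _SHAPE_LO) * expit(d["shape_u"]))
            if self.bound_form == "weibull"
            else (float(np.exp(d["log_slope"])) if self.bound_form == "linear" else 0.0),
            scale=float(np.exp(np.clip(d.get("log_scale", 0.0), -4, 6)))
            if self.bound_form == "weibull" else
            (0.1 if self.bound_form == "linear" else 1.0),
        )
        return DDMParams(
            v0=d["v0"], v_s=d["v_s"],
            z0=float(expit(np.clip(d["logit_z0"], -4, 4))),
            t0=float(expit(d["logit_t0"])),
            bound=bound,
            v_weights=tuple(d[f"vw{j}"] for j in range(self.n_v_w)),
            z_weights=tuple(d[f"zw{j}"] for j in range(self.n_z_w)),
            a_weights=tuple(d[f"aw{j}"] for j in range(self.n_a_w)),
        )

    def from_params(self, p: DDMParams):
        b = p.bound
        d = {
            "v0": p.v0, "v_s": p.v_s,
            "logit_z0": float(logit(p.z0)),
            "logit_t0": float(logit(np.clip(p.t0, 1e-3, 0.999))),
            "log_a": float(np.log(b.a)),
        }
        if self.bound_form == "weibull":
            frac = np.clip((b.shape - _SHAPE_LO) / (_SHAPE_HI - _SHAPE_LO),
                           1e-3, 1 - 1e-3)
            d["shape_u"] = float(logit(frac))
            d["log_scale"] = float(np.log(b.scale))
        elif self.bound_form == "linear":
            d["log_slope"] = float(np.log(max(b.shape, 1e-3)))
        for j, w in enumerate(p.v_weights):
            d[f"vw{j}"] = w
        for j, w in enumerate(p.z_weights):
            d[f"zw{j}"] = w
        for j, w in enumerate(p.a_weights):
            d[f"aw{j}"] = w
        return np.array([d[nm] for nm in self.names])


@dataclass
class DDMFit:
    """Fitted model with point estimates and fit diagnostics."""

    params: DDMParams
    loglik: float
    n_trials: int
    n_free: int
    converged: bool
    message: str = ""
    method: str = "mle"
    posterior: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.n_free - 2 * self.loglik


def _initial_params(choices, rts, stimulus, bound_form) -> DDMParams:
    choices = np.asarray(choices)
    stimulus = np.asarray(stimulus)
    rts = np.asarray(rts, dtype=float)
    acc = np.clip(np.mean(choices == np.sign(stimulus)), 0.55, 0.95)
    a0 = 1.5
    v_s0 = float(logit(acc) / a0)
    t00 = float(np.clip(0.5 * np.quantile(rts, 0.1), 0.05, 0.6))
    q90 = max(np.quantile(rts, 0.9) - t00, 0.3)
    if bound_form == "weibull":
        bound = CollapsingBound(a=a0, form="weibull", shape=3.0,
                                scale=float(q90 ** 3 / 1.2))
    elif bound_form == "linear":
        bound = CollapsingBound(a=a0, form="linear", shape=float(0.7 * a0 / q90),
                                scale=0.1)
    else:
        bound = CollapsingBound(a=a0)
    return DDMParams(v0=0.0, v_s=v_s0, z0=0.5, t0=t00, bound=bound)


def _nm(fun, x0, maxfev):
    return minimize(fun, x0, method="Nelder-Mead",
                    options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-4,
                             "adaptive": True})


def fit_ddm(choices, rts, stimulus, regressors=None, targets=("v", "z"),
            bound_form: str = "weibull", method: str = "mle",
            polish: bool = False, deadline: float = DEADLINE,
            dt: float = FIT_DT, n_space: int = FIT_NSPACE,
            mcmc_samples: int = 2000, seed: int = 0,
            start: DDMParams | None = None) -> DDMFit:
    """Fit the diffusion model, optionally with trialwise regressors.

    Parameters
    ----------
    regressors
        (n_trials, k) matrix of z-scored single-trial covariates (neural
        signals or the signed previous choice). ``targets`` selects which
        accumulation parameters they enter: ``"v"`` (drift bias), ``"z"``
        (starting point via logistic link), ``"a"`` (bound height via log
        link).
    method
        ``"mle"`` (staged Nelder-Mead, default) or ``"mcmc"``
        (random-walk Metropolis over the same likelihood; one tenth of the
        samples is discarded as burn-in).
    """
    choices = np.asarray(choices)
    rts = np.asarray(rts, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    X = None if regressors is None else np.atleast_2d(np.asarray(regressors, float))
    if X is not None and X.shape[0] != choices.size:
        X = X.T
    k = 0 if X is None else X.shape[1]
    n_v_w = k if "v" in targets else 0
    n_z_w = k if "z" in targets else 0
    n_a_w = k if "a" in targets else 0

    def nll(params: DDMParams) -> float:
        try:
            return -fpt_likelihood(params, choices, rts, stimulus, X,
                                   deadline=deadline, dt=dt, n_space=n_space)
        except (ValueError, FloatingPointError):
            return 1e12

    init = start if start is not None else _initial_params(choices, rts,
                                                           stimulus, bound_form)
    # stage A: base parameters, weights pinned at zero
    base_map = _ParamMap(bound_form, 0, 0, 0)
    resA = _nm(lambda th: nll(base_map.to_params(th)),
               base_map.from_params(init), maxfev=2500)
    base = base_map.to_params(resA.x)
    loglik = -resA.fun
    converged = bool(resA.success)
    message = resA.message

    params = base.with_(v_weights=(0.0,) * n_v_w, z_weights=(0.0,) * n_z_w,
                        a_weights=(0.0,) * n_a_w)
    if n_v_w + n_z_w + n_a_w > 0:
        # stage B: regressor weights conditional on base parameters
        full_map = _ParamMap(bound_form, n_v_w, n_z_w, n_a_w)
        base_theta = dict(zip(base_map.names, base_map.from_params(base)))
        w_map = _ParamMap(bound_form, n_v_w, n_z_w, n_a_w, fixed=base_theta)
        resB = _nm(lambda th: nll(w_map.to_params(th)),
                   w_map.from_params(params), maxfev=250 * (n_v_w + n_z_w + n_a_w))
        params = w_map.to_params(resB.x)
        loglik = -resB.fun
        converged = converged and bool(resB.success)
        if polish:
            resC = _nm(lambda th: nll(full_map.to_params(th)),
                       full_map.from_params(params), maxfev=600)
            if -resC.fun > loglik:
                params = full_map.to_params(resC.x)
                loglik = -resC.fun

    pmap = _ParamMap(bound_form, n_v_w, n_z_w, n_a_w)
    n_free = len(pmap.names)

    fit = DDMFit(params=params, loglik=loglik, n_trials=choices.size,
                 n_free=n_free, converged=converged, message=str(message),
                 method=method)
    if method == "mcmc":
        fit = _metropolis(nll, pmap, params, fit, mcmc_samples, seed)
    return fit


def _metropolis(nll, pmap, start_params, fit: DDMFit, n_samples, seed):
    """Random-walk Metropolis over the transformed parameter vector."""
    rng = np.random.default_rng(seed)
    theta = pmap.from_params(start_params)
    d = theta.size
    scale = 0.05
    cur = -nll(pmap.to_params(theta))
    burn = max(1, n_samples // 10)
    keep = np.empty((n_samples - burn, d))
    n_acc = 0
    for i in range(n_samples):
        prop = theta + scale * rng.standard_normal(d)
        lp = -nll(pmap.to_params(prop))
        if np.log(rng.random()) < lp - cur:
            theta, cur = prop, lp
            n_acc += 1
        if i < burn and (i + 1) % 50 == 0:
            rate = n_acc / (i + 1)
            scale *= np.exp(1.0 * (rate - 0.25))
        if i >= burn:
            keep[i - burn] = theta
    sums = {}
    for j, nm in enumerate(pmap.names):
        col = keep[:, j]
        sums[nm] = {
            "mean": float(col.mean()),
            "ci_low": float(np.quantile(col, 0.025)),
            "ci_high": float(np.quantile(col, 0.975)),
        }
    fit.posterior = {"summary": sums, "accept_rate": n_acc / n_samples,
                     "n_samples": n_samples}
    # posterior-mean parameters as point estimate
    fit.params = pmap.to_params(keep.mean(axis=0))
    fit.loglik = -nll(fit.params)
    return fit


def compare_bound_models(choices, rts, stimulus, regressors=None,
                         forms=("static", "linear", "weibull"), **kw):
    """Fit each bound geometry to the same data and rank by AIC.

    Returns ``(ranking, fits)`` where ``ranking`` is a list of
    ``(form, aic, loglik)`` sorted best-first.
    """
    fits = {}
    for form in forms:
        fits[form] = fit_ddm(choices, rts, stimulus, regressors=regressors,
                             bound_form=form, **kw)
    ranking = sorted(((f, fits[f].aic, fits[f].loglik) for f in fits),
                     key=lambda r: r[1])
    return ranking, fits


def fit_bound_modulation(choices, rts, stimulus, regressors,
                         bound_form: str = "weibull", **kw) -> DDMFit:
    """Fit trialwise bound-height modulation ``a_t = a * exp(sum w_j n_j)``.

    The log link keeps the bound positive for any finite regressor value.
    Weights are estimated conditional on base parameters fit without
    modulation.
    """
    return fit_ddm(choices, rts, stimulus, regressors=regressors,
                   targets=("a",), bound_form=bound_form, **kw)
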