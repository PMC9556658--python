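"""Trialwise parameter maps and the mixture first-passage likelihood.

Drift on each trial is an affine function of the stimulus category and
z-scored neural regressors; the starting point receives the regressors through
a logistic link so it can never leave (0, 1):

    v_t = v0 + v_s * s_t + sum_j vw_j * n_jt
    z_t = logistic( logit(z0) + sum_j zw_j * n_jt )

The likelihood mixes the diffusion first-passage density with a small
contaminant channel, uniform over choices and response times up to the task
deadline: 5% of trials are treated as outliers by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .bounds import CollapsingBound
from .solver import fpt_density_grid

__all__ = ["DDMParams", "trialwise_params", "fpt_likelihood"]

DEADLINE = 3.0  # task response deadline in seconds


@dataclass(frozen=True)
class DDMParams:
    """Accumulation parameters with per-regressor bias weights.

    ``v_weights`` and ``z_weights`` hold one weight per neural regressor (in
    the column order of the regressor matrix); ``a_weights`` optionally
    modulates the bound height through a log link, ``a_t = a * exp(sum w n)``.
    """

    v0: float = 0.0
    v_s: float = 1.0
    z0: float = 0.5
    t0: float = 0.3
    bound: CollapsingBound = field(default_factory=lambda: CollapsingBound(a=1.8))
    v_weights: tuple = ()
    z_weights: tuple = ()
    a_weights: tuple = ()
    outlier_frac: float = 0.05

    def __post_init__(self) -> None:
        vals = (self.v0, self.v_s, self.z0, self.t0, *self.v_weights,
                *self.z_weights, *self.a_weights)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite DDM parameter")
        if not 0.0 < self.z0 < 1.0:
            raise ValueError("baseline starting point z0 must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time must be >= 0")
        if not 0.0 <= self.outlier_frac <= 0.2:
            raise ValueError("outlier fraction must lie in [0, 0.2]")

    def with_(self, **kw) -> "DDMParams":
        return replace(self, **kw)


def _regressor_matrix(regressors, n):
    if regressors is None:
        return np.zeros((n, 0))
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("regressor rows must match the number of trials")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite neural regressor")
    return X


def trialwise_params(params: DDMParams, stimulus, regressors=None):
    """Per-trial drift and starting point implied by ``params``.

    Returns ``(v_t, z_t)`` and, when bound weights are present, the log bound
    scale ``u_t`` as a third element.
    """
    s = np.asarray(stimulus, dtype=float)
    X = _regressor_matrix(regressors, s.size)
    vw = np.asarray(params.v_weights, dtype=float)
    zw = np.asarray(params.z_weights, dtype=float)
    if X.shape[1] < max(vw.size, zw.size, len(params.a_weights)):
        raise ValueError("fewer regressor columns than weights")
    v_t = params.v0 + params.v_s * s
    if vw.size:
        v_t = v_t + X[:, : vw.size] @ vw
    zlin = np.full(s.size, logit(params.z0))
    if zw.size:
        zlin = zlin + X[:, : zw.size] @ zw
    z_t = expit(zlin)
    if params.a_weights:
        aw = np.asarray(params.a_weights, dtype=float)
        u_t = X[:, : aw.size] @ aw
        return v_t, z_t, u_t
    return v_t, z_t


def _param_grid(values, max_exact=8, n_nodes=9, lo=None, hi=None):
    uniq = np.unique(values)
    if uniq.size <= max_exact:
        return uniq
    vmin = uniq[0] if lo is None else max(uniq[0], lo)
    vmax = uniq[-1] if hi is None else min(uniq[-1], hi)
    return np.linspace(vmin, vmax, n_nodes)


def fpt_likelihood(params: DDMParams, choices, rts, stimulus, regressors=None,
                   deadline: float = DEADLINE, dt: float = 4e-3,
                   n_space: int | None = None, n_v_nodes: int = 9,
                   n_z_nodes: int = 9, n_a_nodes: int = 7,
                   return_trialwise: bool = False):
    """Log-likelihood of choices and RTs under the collapsing-bound model.

    The first-passage density is tabulated on a (drift, start[, bound-scale])
    grid by the forward solver and interpolated at each trial's parameters;
    per-trial densities are mixed with ``outlier_frac`` of a uniform
    contaminant over (0, deadline) x {choices}.
    """
    choices = np.asarray(choices)
    rts = np.asarray(rts, dtype=float)
    n = choices.size
    tw = trialwise_params(params, stimulus, regressors)
    v_t, z_t = tw[0], tw[1]
    u_t = tw[2] if len(tw) == 3 else None

    eps = 1e-4
    z_t = np.clip(z_t, eps, 1 - eps)
    v_grid = _param_grid(v_t)
    z_grid = _param_grid(np.clip(z_t, 0.02, 0.98), n_nodes=n_z_nodes)
    # solve out to the slowest observed response (bounded), so no process
    # mass silently falls off the grid and biases bound-shape comparisons
    t_max = min(float(np.max(rts)), 10.0) + 2 * dt
    tau = rts - params.t0

    if u_t is None:
        grid = fpt_density_grid(v_grid, z_grid, params.bound, t_max=t_max,
                                dt=dt, n_space=n_space)
        f = np.where(
            choices > 0,
            grid.density(v_t, z_t, tau, upper=True),
            grid.density(v_t, z_t, tau, upper=False),
        )
    else:
        u_grid = _param_grid(u_t, max_exact=n_a_nodes, n_nodes=n_a_nodes)
        f = np.zeros(n)
        planes = []
        for u in u_grid:
            b = params.bound
            scaled = CollapsingBound(a=b.a * np.exp(u), form=b.form,
                                     shape=b.shape, scale=b.scale)
            planes.append(fpt_density_grid(v_grid, z_grid, scaled,
                                           t_max=t_max, dt=dt,
                                           n_space=n_space))
        # linear interpolation across the bound-scale axis
        if u_grid.size == 1:
            iu = np.zeros(n, dtype=int)
            wu = np.zeros(n)
        else:
            iu = np.clip(np.searchsorted(u_grid, u_t) - 1, 0, u_grid.size - 2)
            wu = np.clip((u_t - u_grid[iu]) / (u_grid[iu + 1] - u_grid[iu]), 0, 1)
        for du in (0, 1):
            w = (1 - wu) if du == 0 else wu
            idx = np.minimum(iu + du, u_grid.size - 1)
            for k in range(u_grid.size):
                sel = idx == k
                if not np.any(sel):
                    continue
                g = planes[k]
                f[sel] += w[sel] * np.where(
                    choices[sel] > 0,
                    g.density(v_t[sel], z_t[sel], tau[sel], upper=True),
                    g.density(v_t[sel], z_t[sel], tau[sel], upper=False),
                )

    f = np.where(tau > 0, np.maximum(f, 0.0), 0.0)
    of = params.outlier_frac
    # contaminant channel: uniform over choices x (0, deadline]; zero beyond
    # the deadline so the mixture stays a proper density
    lik = (1.0 - of) * f + of * (rts <= deadline) / (2.0 * deadline)
    lik = np.maximum(lik, 1e-300)
    ll = np.log(lik)
    if return_trialwise:
        return float(ll.sum()), ll
    return float(ll.sum())
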