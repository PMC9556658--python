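"""Closed-form results for the constant-bound diffusion model.

These serve as independent cross-checks for the numerical forward solver and
the Monte-Carlo simulator. The first-passage density uses the classical dual
series representation (small-time image expansion and large-time eigenfunction
expansion), switching to whichever needs fewer terms at the requested
accuracy. Conventions: unit diffusion noise, bounds at 0 and ``a``, start at
``z * a`` with ``z`` in (0, 1), drift ``v``; the upper bound is "stronger".
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "constant_bound_density",
    "prob_upper",
    "mean_decision_time",
]


def _f0_small(tp: float, w: float, err: float) -> float:
    """Image-method series for the standardized lower-bound density."""
    # number of terms per Navarro & Fuss (2009)
    if np.pi * tp * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tp * np.log(2.0 * np.sqrt(2.0 * np.pi * tp) * err))
        ks = max(ks, np.sqrt(tp) + 1.0)
    else:
        ks = 2.0
    K = int(np.ceil(ks))
    ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + K % 2 + 1)
    x = w + 2.0 * ks_range
    return float(np.sum(x * np.exp(-(x ** 2) / (2.0 * tp))) / np.sqrt(2.0 * np.pi * tp ** 3))


def _f0_large(tp: float, w: float, err: float) -> float:
    """Eigenfunction series for the standardized lower-bound density."""
    if np.pi * tp * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tp * err) / (np.pi ** 2 * tp))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(tp)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tp))
    K = int(np.ceil(kl))
    k = np.arange(1, K + 1)
    return float(np.pi * np.sum(k * np.exp(-(k ** 2) * np.pi ** 2 * tp / 2.0) * np.sin(k * np.pi * w)))


def _density_lower_one(t: float, v: float, a: float, z: float, err: float) -> float:
    if t <= 0.0:
        return 0.0
    tp = t / a ** 2
    # term-count heuristics decide which series converges faster here
    if np.pi * tp * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tp * np.log(2.0 * np.sqrt(2.0 * np.pi * tp) * err))
        kl = np.sqrt(-2.0 * np.log(np.pi * tp * err) / (np.pi ** 2 * tp))
    else:
        ks, kl = 2.0, 1.0 / (np.pi * np.sqrt(tp))
    f0 = _f0_small(tp, z, err) if ks < kl else _f0_large(tp, z, err)
    return max(f0, 0.0) * np.exp(-v * a * z - v ** 2 * t / 2.0) / a ** 2


def constant_bound_density(t, v: float, a: float, z: float, upper: bool = True,
                           err: float = 1e-12):
    """First-passage-time density at the upper or lower constant bound.

    Parameters
    ----------
    t
        Decision time(s) in seconds (non-decision time excluded).
    v, a, z
        Drift, bound separation, relative starting point.
    upper
        Density for absorption at the upper ("stronger") bound if True.
    """
    if not 0.0 < z < 1.0:
        raise ValueError("relative starting point z must lie in (0, 1)")
    if a <= 0:
        raise ValueError("bound separation a must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if upper:
        vv, ww = -v, 1.0 - z
    else:
        vv, ww = v, z
    out = np.array([_density_lower_one(ti, vv, a, ww, err) for ti in t])
    return out if out.size > 1 else float(out[0])


def prob_upper(v: float, a: float, z: float) -> float:
    """Probability of absorption at the upper bound."""
    if abs(v) < 1e-12:
        return z
    x0 = z * a
    return float((1.0 - np.exp(-2.0 * v * x0)) / (1.0 - np.exp(-2.0 * v * a)))


def mean_decision_time(v: float, a: float, z: float) -> float:
    """Mean first-passage time (either bound), constant separation."""
    x0 = z * a
    if abs(v) < 1e-12:
        return float(x0 * (a - x0))
    pu = prob_upper(v, a, z)
    return float(a * pu / v - x0 / v)
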