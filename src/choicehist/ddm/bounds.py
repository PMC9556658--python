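"""Decision-bound geometries for the diffusion model.

The accumulator lives on ``[0, a]`` with the upper bound mapped to "stronger"
choices. Time-varying bounds collapse symmetrically toward the midline
``a/2``: the *separation* ``s(t)`` shrinks while the center stays put, so the
starting-point fraction ``z`` always refers to the initial separation.

Three separation profiles are supported:

* ``static``:   s(t) = a
* ``linear``:   s(t) = max(a - slope * t, floor)
* ``weibull``:  s(t) = a * exp(-t**shape / scale)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FORM_STATIC = 0
FORM_LINEAR = 1
FORM_WEIBULL = 2

_FORM_CODES = {"static": FORM_STATIC, "linear": FORM_LINEAR, "weibull": FORM_WEIBULL}


@dataclass(frozen=True)
class CollapsingBound:
    """Bound-separation profile.

    Parameters
    ----------
    a
        Initial boundary separation (> 0), in units of the unit-variance
        diffusion noise.
    form
        One of ``static``, ``linear``, ``weibull``.
    shape
        Collapse shape exponent (Weibull) or separation decrease per second
        (linear). Ignored for static bounds.
    scale
        Collapse timescale (Weibull) or separation floor (linear).
    """

    a: float
    form: str = "static"
    shape: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"bound separation a must be positive, got {self.a}")
        if self.form not in _FORM_CODES:
            raise ValueError(f"unknown bound form {self.form!r}")
        if self.form == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("weibull bound requires shape > 0 and scale > 0")
        if self.form == "linear" and (self.shape < 0 or self.scale < 0):
            raise ValueError("linear bound requires slope >= 0 and floor >= 0")

    @property
    def form_code(self) -> int:
        return _FORM_CODES[self.form]

    def as_tuple(self) -> tuple[int, float, float, float]:
        """Numeric encoding consumed by the numba kernels."""
        return (self.form_code, self.a, self.shape, self.scale)

    def separation(self, t):
        """Bound separation at time(s) ``t`` (seconds, >= 0)."""
        return weibull_bound(t, self)


def weibull_bound(t, bound: CollapsingBound):
    """Evaluate the bound separation ``b(t)`` for any supported form.

    For the Weibull form this is ``a * exp(-t**shape / scale)``, which equals
    ``a`` at ``t = 0`` and decays monotonically for positive shape and scale.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("bound separation is only defined for t >= 0")
    if bound.form == "static":
        out = np.full_like(t, bound.a)
    elif bound.form == "linear":
        out = np.maximum(bound.a - bound.shape * t, bound.scale)
    else:
        out = bound.a * np.exp(-(t ** bound.shape) / bound.scale)
    return out if out.ndim else float(out)
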