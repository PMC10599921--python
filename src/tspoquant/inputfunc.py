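"""Arterial input function representation and the analytic curve families.

The metabolite-corrected parent-plasma input function is represented as a
densely sampled curve on a uniform 1-s grid together with the fitted
parameters of every processing stage (calibration factor, plasma-over-blood,
parent fraction, post-peak tri-exponential, delay).  Evaluation is linear
interpolation on the grid; a fitted time delay shifts the curve so that
``parent_plasma_at(t)`` returns the concentration the tissue saw at time t.

Curve families
--------------
* plasma-over-blood: exponential approach to a constant,
  ``POB(t) = c_inf - (c_inf - c0) * exp(-lam * t)``
* parent fraction: two-parameter decreasing Hill sigmoid,
  ``pf(t) = 1 / (1 + (t / t50) ** h)`` (pf(0) = 1, pf(t50) = 1/2)
* post-peak smoothing: tri-exponential ``sum_i A_i * exp(-lam_i * t)``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "pob_curve",
    "parent_fraction_curve",
    "triexp_curve",
    "ArterialInput",
]


def pob_curve(t, c0: float, c_inf: float, lam: float):
    """Plasma-over-blood ratio: exponential approach from c0 to c_inf."""
    t = np.asarray(t, dtype=float)
    return c_inf - (c_inf - c0) * np.exp(-lam * t)


def parent_fraction_curve(t, t50: float, h: float):
    """Fraction of plasma activity that is intact parent tracer.

    Monotone decreasing Hill sigmoid with pf(0) = 1 and pf(t50) = 0.5.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        out = 1.0 / (1.0 + np.where(t > 0, (t / t50) ** h, 0.0))
    return out


def triexp_curve(t, amps, lams):
    """Sum of decaying exponentials ``sum_i amps[i] * exp(-lams[i] * t)``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for a, l in zip(amps, lams):
        out += a * np.exp(-l * t)
    return out


@dataclass
class ArterialInput:
    """Sampled arterial curves driving the kinetic model.

    Attributes
    ----------
    t : uniform time grid in seconds, starting at 0.
    parent_plasma : metabolite-corrected parent-plasma activity (kBq/ml).
    whole_blood : whole-blood activity (kBq/ml), used for the Vb term.
    delay_s : fitted blood-to-tissue delay, positive when the tissue of
        interest sees the tracer ``delay_s`` seconds after the blood-sampling
        site; evaluation at tissue time t reads the stored curves at
        ``t - delay_s``.
    params : per-stage fit parameters and diagnostic flags.
    """

    t: np.ndarray
    parent_plasma: np.ndarray
    whole_blood: np.ndarray
    delay_s: float = 0.0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        if not (self.t.shape == self.parent_plasma.shape == self.whole_blood.shape):
            raise ValueError("t, parent_plasma and whole_blood must share a shape")

    # Evaluation ----------------------------------------------------------
    def _eval(self, samples: np.ndarray, t) -> np.ndarray:
        tq = np.asarray(t, dtype=float) - self.delay_s
        return np.interp(tq, self.t, samples, left=0.0, right=float(samples[-1]))

    def parent_plasma_at(self, t):
        """Parent-plasma activity at tissue time ``t`` (delay applied)."""
        return self._eval(self.parent_plasma, t)

    def whole_blood_at(self, t):
        """Whole-blood activity at tissue time ``t`` (delay applied)."""
        return self._eval(self.whole_blood, t)

    def with_delay(self, delay_s: float) -> "ArterialInput":
        """Copy of this input with the delay replaced."""
        return replace(self, delay_s=float(delay_s), params=dict(self.params))

    @property
    def t_end(self) -> float:
        return float(self.t[-1])
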