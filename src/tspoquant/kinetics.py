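"""Reversible two-tissue compartment modelling of dynamic PET.

Model
-----
With a metabolite-corrected parent-plasma input Cp(t) and whole-blood
activity Cb(t), the tissue impulse response of the reversible 2TCM is

    h(t) = K1 / (a2 - a1) * [(k3 + k4 - a1) e^(-a1 t) + (a2 - k3 - k4) e^(-a2 t)]
    a1,2 = ((k2 + k3 + k4) -/+ sqrt((k2 + k3 + k4)^2 - 4 k2 k4)) / 2

and the measured concentration is

    C_model(t) = (1 - Vb) * (h * Cp)(t) + Vb * Cb(t)

with the fractional blood volume Vb fixed (default 5%).  The primary outcome
is the total volume of distribution VT = (K1/k2) * (1 + k3/k4).

Numerics: the convolution is evaluated exactly against a piecewise-linear
representation of the input on a uniform grid (closed-form integral per
segment, first-order recursion), and the model is compared to data as the
frame-interval average, not a mid-frame sample — long late frames make
mid-point sampling biased.  Rate constants are per minute at the API surface
(K1 in ml cm^-3 min^-1); time is in seconds internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.optimize import least_squares

from .frames import FrameSchedule, weights_from_schedule
from .inputfunc import ArterialInput

__all__ = [
    "TwoTCMFit",
    "twotcm_predict",
    "fit_twotcm",
    "onetcm_predict",
    "fit_onetcm",
    "logan_vt",
    "total_volume_of_distribution",
    "DEFAULT_STARTS",
]

#: Multi-start initial values for (K1, k2, k3, k4) in (ml/cm3/min, 1/min ...).
DEFAULT_STARTS: tuple[tuple[float, float, float, float], ...] = (
    (0.1, 0.1, 0.05, 0.05),
    (0.3, 0.2, 0.1, 0.02),
    (0.05, 0.02, 0.01, 0.01),
)

_BOUNDS = (1e-6, 10.0)


def total_volume_of_distribution(K1: float, k2: float, k3: float, k4: float) -> float:
    """VT = (K1/k2)(1 + k3/k4); equilibrium tissue-to-plasma ratio (ml/cm^3)."""
    return (K1 / k2) * (1.0 + k3 / k4)


def exp_conv(alpha: float, f: np.ndarray, dt: float) -> np.ndarray:
    """Convolution of exp(-alpha t) with a piecewise-linear signal.

    ``f`` is sampled on a uniform grid of step ``dt``; the integral over each
    linear segment is closed-form, so the only approximation is the linear
    interpolation of ``f`` itself.  The resulting first-order recursion is
    evaluated with a linear filter for speed.
    """
    f = np.asarray(f, dtype=float)
    n = f.size
    if n == 0:
        return f.copy()
    if alpha * dt < 1e-12:
        # alpha -> 0 limit: plain running trapezoid integral
        incr = 0.5 * (f[:-1] + f[1:]) * dt
        return np.concatenate([[0.0], np.cumsum(incr)])
    E = np.exp(-alpha * dt)
    J0 = (1.0 - E) / alpha                 # \int_0^dt e^{-a(dt-u)} du
    J1 = (dt - J0) / alpha                 # \int_0^dt u e^{-a(dt-u)} du
    g = (f[1:] - f[:-1]) / dt
    b = f[:-1] * J0 + g * J1
    y = np.empty(n)
    y[0] = 0.0
    y[1:] = _signal.lfilter([1.0], [1.0, -E], b)
    return y


def _rates_per_second(k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Eigenvalues a1 <= a2 (s^-1) of the two-tissue system."""
    k2s, k3s, k4s = k2 / 60.0, k3 / 60.0, k4 / 60.0
    s = k2s + k3s + k4s
    disc = s * s - 4.0 * k2s * k4s
    if disc < 0:
        if disc < -1e-18:
            raise ValueError("complex eigenvalues: discriminant < 0")
        disc = 0.0
    root = np.sqrt(disc)
    return 0.5 * (s - root), 0.5 * (s + root)


def _tissue_curve(
    params: Sequence[float], cp: np.ndarray, dt: float
) -> np.ndarray:
    """(h * Cp)(t) on the grid for params (K1, k2, k3, k4) in per-minute units."""
    K1, k2, k3, k4 = params
    a1, a2 = _rates_per_second(k2, k3, k4)
    K1s = K1 / 60.0
    k34 = (k3 + k4) / 60.0
    if a2 - a1 < 1e-14:
        a2 = a1 + 1e-12  # degenerate repeated-root guard
    phi1 = K1s * (k34 - a1) / (a2 - a1)
    phi2 = K1s * (a2 - k34) / (a2 - a1)
    return phi1 * exp_conv(a1, cp, dt) + phi2 * exp_conv(a2, cp, dt)


def _frame_average(curve: np.ndarray, t_grid: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average of a gridded curve over each frame interval (trapezoid)."""
    dt = t_grid[1] - t_grid[0]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve[:-1] + curve[1:]) * dt)])
    start_int = np.interp(schedule.start, t_grid, cum)
    end_int = np.interp(schedule.end, t_grid, cum)
    return (end_int - start_int) / schedule.duration


class _PreparedInput:
    """Input curves pre-sampled on the prediction grid (per delay)."""

    def __init__(self, input_model: ArterialInput, t_end: float, dt: float):
        self.dt = float(dt)
        self.t = np.arange(0.0, t_end + 0.5 * dt, dt)
        self.cp = input_model.parent_plasma_at(self.t)
        self.cb = input_model.whole_blood_at(self.t)


def twotcm_predict(
    params: Sequence[float],
    input_model: ArterialInput,
    schedule: FrameSchedule,
    vb: float = 0.05,
    dt: float = 0.5,
    _prepared: _PreparedInput | None = None,
) -> np.ndarray:
    """Frame-averaged 2TCM prediction for ``params = (K1, k2, k3, k4)``.

    K1 in ml cm^-3 min^-1, k2..k4 in min^-1, Vb unitless.  Returns one value
    per frame of ``schedule`` in the units of the input curves (kBq/ml).
    """
    prep = _prepared or _PreparedInput(input_model, schedule.total_duration, dt)
    ct = _tissue_curve(params, prep.cp, prep.dt)
    model = (1.0 - vb) * ct + vb * prep.cb
    return _frame_average(model, prep.t, schedule)


def onetcm_predict(
    params: Sequence[float],
    input_model: ArterialInput,
    schedule: FrameSchedule,
    vb: float = 0.05,
    dt: float = 0.5,
    _prepared: _PreparedInput | None = None,
) -> np.ndarray:
    """Frame-averaged 1-tissue model (K1, k2) with fractional blood volume.

    Independent single-exponential implementation; also the reduction of the
    2TCM at k3 = k4 = 0.
    """
    K1, k2 = params
    prep = _prepared or _PreparedInput(input_model, schedule.total_duration, dt)
    ct = (K1 / 60.0) * exp_conv(k2 / 60.0, prep.cp, prep.dt)
    model = (1.0 - vb) * ct + vb * prep.cb
    return _frame_average(model, prep.t, schedule)


@dataclass
class TwoTCMFit:
    """Result of a weighted 2TCM fit to one regional TAC."""

    K1: float
    k2: float
    k3: float
    k4: float
    vb: float
    vt: float
    weighted_sse: float
    converged: bool
    covariance: np.ndarray | None = None
    vt_variance: float = float("nan")
    region: str | None = None

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.K1, self.k2, self.k3, self.k4)


def _vt_variance(params: np.ndarray, cov: np.ndarray) -> float:
    K1, k2, k3, k4 = params
    grad = np.array(
        [
            (1.0 + k3 / k4) / k2,
            -(K1 / k2**2) * (1.0 + k3 / k4),
            K1 / (k2 * k4),
            -K1 * k3 / (k2 * k4**2),
        ]
    )
    return float(grad @ cov @ grad)


def fit_twotcm(
    tac: np.ndarray,
    input_model: ArterialInput,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    vb_fixed: float = 0.05,
    dt: float = 1.0,
    starts: Sequence[Sequence[float]] = DEFAULT_STARTS,
    region: str | None = None,
) -> TwoTCMFit:
    """Weighted nonlinear least-squares 2TCM fit with fixed blood volume.

    Multi-start (3 default starts) trust-region fit of (K1, k2, k3, k4) with
    bounds [1e-6, 10]; the lowest weighted SSE wins, ties broken by lower VT
    variance.  If every start fails the fit is flagged non-convergent with
    NaN VT and the pipeline continues.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != schedule.n_frames:
        raise ValueError("TAC length must match schedule")
    if tac.size < 8:
        raise ValueError("need at least 8 frames for a 4-parameter fit")
    if weights is None:
        weights = weights_from_schedule(schedule)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    sw = np.sqrt(weights)
    prep = _PreparedInput(input_model, schedule.total_duration, dt)

    def resid(p):
        return sw * (
            twotcm_predict(p, input_model, schedule, vb=vb_fixed, _prepared=prep) - tac
        )

    candidates = []
    for x0 in starts:
        try:
            sol = least_squares(
                resid,
                x0=np.clip(x0, *_BOUNDS),
                bounds=_BOUNDS,
                ftol=1e-10,
                xtol=1e-10,
                gtol=1e-10,
                method="trf",
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(2.0 * sol.cost)
        # Gauss-Newton covariance for diagnostics and the VT-variance tie-break
        cov = None
        vt_var = float("inf")
        try:
            jtj = sol.jac.T @ sol.jac
            dof = max(tac.size - 4, 1)
            cov = np.linalg.pinv(jtj) * sse / dof
            vt_var = _vt_variance(sol.x, cov)
        except Exception:
            pass
        candidates.append((sse, vt_var, sol.x, cov, sol.status > 0))

    if not candidates:
        return TwoTCMFit(
            *(float("nan"),) * 4,
            vb=vb_fixed,
            vt=float("nan"),
            weighted_sse=float("nan"),
            converged=False,
            region=region,
        )
    # lowest SSE; SSE ties (within 1e-10 relative) broken by lower VT variance
    best_sse = min(c[0] for c in candidates)
    tol = 1e-10 * max(best_sse, 1e-30)
    tied = [c for c in candidates if c[0] <= best_sse + tol]
    sse, vt_var, x, cov, ok = min(tied, key=lambda c: c[1])
    K1, k2, k3, k4 = (float(v) for v in x)
    return TwoTCMFit(
        K1,
        k2,
        k3,
        k4,
        vb=vb_fixed,
        vt=total_volume_of_distribution(K1, k2, k3, k4),
        weighted_sse=sse,
        converged=bool(ok),
        covariance=cov,
        vt_variance=vt_var,
        region=region,
    )


def fit_onetcm(
    tac: np.ndarray,
    input_model: ArterialInput,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    vb_fixed: float = 0.05,
    dt: float = 0.5,
    x0: Sequence[float] = (0.1, 0.1),
) -> tuple[float, float, float]:
    """1-tissue + blood-volume fit; returns (K1, k2, weighted SSE)."""
    tac = np.asarray(tac, dtype=float)
    if weights is None:
        weights = weights_from_schedule(schedule)
    sw = np.sqrt(np.asarray(weights, dtype=float))
    prep = _PreparedInput(input_model, schedule.total_duration, dt)

    def resid(p):
        return sw * (
            onetcm_predict(p, input_model, schedule, vb=vb_fixed, _prepared=prep) - tac
        )

    sol = least_squares(resid, x0=np.asarray(x0), bounds=_BOUNDS, method="trf", ftol=1e-12)
    return float(sol.x[0]), float(sol.x[1]), float(2.0 * sol.cost)


def logan_vt(
    tac: np.ndarray,
    input_model: ArterialInput,
    schedule: FrameSchedule,
    t_star: float = 1800.0,
    vb: float = 0.05,
) -> float:
    """Logan graphical-analysis VT estimate (validation oracle for the 2TCM).

    Regresses int_0^T C_T / C_T(T) on int_0^T Cp / C_T(T) over frames with
    mid time >= ``t_star``; for a reversible tracer the late-time slope is VT.
    The known fractional blood volume is removed from the measured TAC first
    (``vb = 0`` disables the correction).  Note the estimate carries the
    method's intrinsic negative bias when tissue equilibration is slow
    relative to the scan (see the methods note).
    """
    tac = np.asarray(tac, dtype=float)
    if vb > 0:
        cb_frames = _frame_average(
            input_model.whole_blood_at(
                tg_ := np.arange(0.0, schedule.total_duration + 0.5, 0.5)
            ),
            tg_,
            schedule,
        )
        tac = (tac - vb * cb_frames) / (1.0 - vb)
    mid = schedule.mid
    if t_star >= schedule.total_duration:
        raise ValueError("t_star is beyond the last frame")
    late = mid >= t_star
    if late.sum() < 4:
        raise ValueError("need at least 4 frames beyond t_star")
    # cumulative tissue integral to each frame mid (frame values are averages)
    cum_frame_end = np.cumsum(tac * schedule.duration)
    cum_frame_start = cum_frame_end - tac * schedule.duration
    int_ct_mid = cum_frame_start + tac * (mid - schedule.start)
    # cumulative plasma integral on a fine grid
    tg = np.arange(0.0, schedule.total_duration + 0.5, 0.5)
    cp = input_model.parent_plasma_at(tg)
    cum_cp = np.concatenate([[0.0], np.cumsum(0.5 * (cp[:-1] + cp[1:]) * 0.5)])
    int_cp_mid = np.interp(mid, tg, cum_cp)
    y = int_ct_mid[late] / tac[late]
    x = int_cp_mid[late] / tac[late]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
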