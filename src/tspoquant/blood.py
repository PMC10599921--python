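"""Arterial input-function assembly from continuous and discrete blood data.

Processing chain (in this fixed order, each stage's parameters recorded):

1. calibrate the 1 Hz continuous whole-blood detector against the discrete
   whole-blood samples drawn at 5, 10 and 15 min;
2. merge the calibrated continuous curve (0-900 s) with the later discrete
   samples into a whole-blood curve covering the scan;
3. fit plasma-over-blood to an exponential-approach-to-a-constant;
4. fit the parent (unmetabolised tracer) fraction to a decreasing sigmoid;
5. multiply: parent plasma = pf(t) * POB(t) * whole blood(t);
6. smooth the post-peak portion with a tri-exponential fit;
7. fit a blood-to-tissue time delay against the early whole-brain TAC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .frames import FrameSchedule
from .inputfunc import ArterialInput, parent_fraction_curve, pob_curve, triexp_curve
from .kinetics import fit_onetcm

logger = logging.getLogger(__name__)

__all__ = [
    "BloodData",
    "calibrate_continuous",
    "merge_blood",
    "fit_plasma_over_blood",
    "fit_parent_fraction",
    "assemble_input_function",
    "fit_delay",
    "build_input_function",
]

CALIBRATION_TIMES_S = (300.0, 600.0, 900.0)


@dataclass
class BloodData:
    """Raw blood tables for one subject (the CSV dialects of the generator)."""

    continuous: pd.DataFrame       # time_s, whole_blood_kBq_per_ml (1 Hz, 0-900 s)
    discrete: pd.DataFrame         # time_s, whole_blood_kBq_per_ml, plasma_kBq_per_ml
    parent_fraction: pd.DataFrame  # time_s, parent_fraction

    def __post_init__(self):
        for name, df, cols in (
            ("continuous", self.continuous, ("time_s", "whole_blood_kBq_per_ml")),
            ("discrete", self.discrete,
             ("time_s", "whole_blood_kBq_per_ml", "plasma_kBq_per_ml")),
            ("parent_fraction", self.parent_fraction, ("time_s", "parent_fraction")),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")
            t = df["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} times must be strictly increasing")
        pf = self.parent_fraction["parent_fraction"].to_numpy(dtype=float)
        if np.any((pf < 0) | (pf > 1)):
            raise ValueError("parent fractions must lie in [0, 1]")

    @classmethod
    def from_dir(cls, directory, subject_id: str) -> "BloodData":
        from pathlib import Path

        d = Path(directory)
        return cls(
            continuous=pd.read_csv(d / f"{subject_id}_blood_continuous.csv"),
            discrete=pd.read_csv(d / f"{subject_id}_blood_discrete.csv"),
            parent_fraction=pd.read_csv(d / f"{subject_id}_parent_fraction.csv"),
        )


def calibrate_continuous(
    continuous: pd.DataFrame,
    discrete: pd.DataFrame,
    window_s: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Scale the continuous detector onto the discrete whole-blood samples.

    The factor is the mean over the three overlap times (5, 10, 15 min) of
    discrete / local continuous average (+/- ``window_s``); e.g. a detector
    reading 1.25x too high yields a factor of 0.8.
    """
    tc = continuous["time_s"].to_numpy(dtype=float)
    vc = continuous["whole_blood_kBq_per_ml"].to_numpy(dtype=float)
    td = discrete["time_s"].to_numpy(dtype=float)
    vd = discrete["whole_blood_kBq_per_ml"].to_numpy(dtype=float)
    ratios = []
    for t_cal in CALIBRATION_TIMES_S:
        i = np.argmin(np.abs(td - t_cal))
        if abs(td[i] - t_cal) > 1.0:
            raise ValueError(f"no discrete sample at calibration time {t_cal} s")
        sel = np.abs(tc - t_cal) <= window_s
        if not np.any(sel):
            raise ValueError(f"continuous data do not cover {t_cal} s")
        local = float(np.mean(vc[sel]))
        if local <= 0:
            raise ValueError(f"continuous value <= 0 at calibration time {t_cal} s")
        ratios.append(vd[i] / local)
    factor = float(np.mean(ratios))
    calibrated = continuous.copy()
    calibrated["whole_blood_kBq_per_ml"] = vc * factor
    return calibrated, factor


def merge_blood(
    calibrated_continuous: pd.DataFrame,
    discrete: pd.DataFrame,
    gap_warn_s: float = 900.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge calibrated continuous (0-900 s) with later discrete samples.

    Returns piecewise-linear curve nodes ``(t, value)``: the continuous
    samples verbatim up to 900 s, then the discrete whole-blood points, so
    the junction value equals the continuous endpoint.
    """
    tc = calibrated_continuous["time_s"].to_numpy(dtype=float)
    vc = calibrated_continuous["whole_blood_kBq_per_ml"].to_numpy(dtype=float)
    t_join = tc[-1]
    td = discrete["time_s"].to_numpy(dtype=float)
    vd = discrete["whole_blood_kBq_per_ml"].to_numpy(dtype=float)
    late = td > t_join
    t = np.concatenate([tc, td[late]])
    v = np.concatenate([vc, vd[late]])
    gaps = np.diff(t)
    if np.any(gaps > gap_warn_s):
        logger.warning("whole-blood curve has a sampling gap > %.0f s", gap_warn_s)
    return t, v


def fit_plasma_over_blood(discrete: pd.DataFrame) -> dict:
    """Fit POB(t) = c_inf - (c_inf - c0) exp(-lam t) to the discrete ratios.

    For given lam the model is linear in (c0, c_inf), so lam is profiled on
    a grid with exact linear sub-fits.  With the first plasma sample at
    5 min, c0 is weakly identified whenever the ratio equilibrates faster
    than the sampling (a flat likelihood valley trading c0 against lam), so
    among statistically indistinguishable optima the solution whose c0 is
    closest to the earliest measured ratio is preferred — the least violent
    extrapolation below the sampled range.  A nonlinear polish is accepted
    only when it improves the residual sum of squares materially, which
    keeps noiseless recovery exact.  Degenerate (constant-ratio) data fall
    back to a flagged constant model.
    """
    t = discrete["time_s"].to_numpy(dtype=float)
    wb = discrete["whole_blood_kBq_per_ml"].to_numpy(dtype=float)
    pl = discrete["plasma_kBq_per_ml"].to_numpy(dtype=float)
    ok = (wb > 0) & (pl > 0)
    if ok.sum() < 4:
        raise ValueError("need at least 4 samples with positive plasma and blood")
    t, ratio = t[ok], pl[ok] / wb[ok]
    mean_ratio = float(np.mean(ratio))
    if np.ptp(ratio) < 1e-12:  # exactly constant data: c0 = c_inf, any lam
        return {"c0": mean_ratio, "c_inf": mean_ratio, "lam": 0.0,
                "rss": 0.0, "fallback_constant": False, "constant": True}

    r_first = float(ratio[0])
    lam_grid = np.concatenate([[0.0], np.logspace(-4.5, np.log10(0.05), 60)])
    cands = []
    for lam in lam_grid:
        e = np.exp(-lam * t)
        A = np.column_stack([e, 1.0 - e])
        coef, *_ = np.linalg.lstsq(A, ratio, rcond=None)
        c0, cinf = float(coef[0]), float(coef[1])
        if c0 < 0 or cinf < 0:
            continue
        rss = float(np.sum((A @ coef - ratio) ** 2))
        cands.append((rss, abs(c0 - r_first), c0, cinf, float(lam)))
    if not cands:
        logger.warning("plasma-over-blood fit failed; using constant ratio")
        resid = ratio - mean_ratio
        return {"c0": mean_ratio, "c_inf": mean_ratio, "lam": 0.0,
                "rss": float(resid @ resid), "fallback_constant": True,
                "constant": True}
    rss_min = min(c[0] for c in cands)
    tol = 0.02 * rss_min + 1e-15
    near = [c for c in cands if c[0] <= rss_min + tol]
    _, _, c0, cinf, lam = min(near, key=lambda c: c[1])
    # polish from the chosen seed; accept only a material rss improvement
    try:
        popt, _ = curve_fit(
            pob_curve, t, ratio, p0=(c0, cinf, max(lam, 1e-5)),
            bounds=([0.0, 0.0, 0.0], [10.0, 10.0, 0.1]), maxfev=20000,
        )
        rss_p = float(np.sum((pob_curve(t, *popt) - ratio) ** 2))
        rss_s = float(np.sum((pob_curve(t, c0, cinf, lam) - ratio) ** 2))
        if rss_p < rss_s - tol:
            c0, cinf, lam = (float(v) for v in popt)
    except RuntimeError:
        pass
    rss = float(np.sum((pob_curve(t, c0, cinf, lam) - ratio) ** 2))
    return {"c0": c0, "c_inf": cinf, "lam": lam, "rss": rss,
            "fallback_constant": False, "constant": False}


def fit_parent_fraction(parent_fraction: pd.DataFrame) -> dict:
    """Fit pf(t) = 1 / (1 + (t/t50)^h) to the measured parent fractions."""
    t = parent_fraction["time_s"].to_numpy(dtype=float)
    pf = parent_fraction["parent_fraction"].to_numpy(dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 parent-fraction measurements")
    if np.ptp(pf) < 1e-12:
        logger.warning("parent fractions are constant; degenerate sigmoid fit")
        return {"t50": float("inf"), "h": 1.0, "constant": True,
                "constant_value": float(pf[0]), "rss": 0.0}
    popt, _ = curve_fit(
        parent_fraction_curve, t, pf,
        p0=(float(np.median(t)), 2.0),
        bounds=([1.0, 0.01], [1e6, 20.0]),
        maxfev=20000,
    )
    resid = pf - parent_fraction_curve(t, *popt)
    return {"t50": float(popt[0]), "h": float(popt[1]), "constant": False,
            "rss": float(resid @ resid)}


def _eval_pob(params: dict, t: np.ndarray) -> np.ndarray:
    if params.get("constant"):
        return np.full_like(np.asarray(t, dtype=float), params["c0"])
    return pob_curve(t, params["c0"], params["c_inf"], params["lam"])


def _eval_pf(params: dict, t: np.ndarray) -> np.ndarray:
    if params.get("constant"):
        return np.full_like(np.asarray(t, dtype=float), params["constant_value"])
    return parent_fraction_curve(t, params["t50"], params["h"])


def _fit_multiexp(t, y, n_exp: int):
    """Log-space least-squares fit of a sum of decaying exponentials.

    ``t`` is relative time from the curve peak.  Fitting log(model) against
    log(data) equalises the relative error across the two decades the curve
    spans; amplitudes are seeded by non-negative least squares at several
    candidate decay triplets and the best log-SSE solution wins.  The first
    minute after the peak is up-weighted so the smoothed curve joins the
    pre-peak segment continuously (a pure exponential sum cannot reproduce
    the zero slope at the peak itself).
    """
    from scipy.optimize import nnls

    y_peak = float(y.max())
    eps = 1e-6 * y_peak
    logy = np.log(np.clip(y, eps, None))
    w = 1.0 + 9.0 * np.exp(-t / 60.0)
    lam_starts = {
        3: [(1 / 30, 1 / 300, 1 / 3000), (1 / 60, 1 / 600, 1 / 6000),
            (1 / 15, 1 / 150, 1 / 2000)],
        2: [(1 / 60, 1 / 1000), (1 / 150, 1 / 3000)],
    }[n_exp]

    def resid(x):
        return w * (
            np.log(np.clip(triexp_curve(t, x[:n_exp], x[n_exp:]), eps, None)) - logy
        )

    best = None
    for lam0 in lam_starts:
        basis = np.column_stack([np.exp(-l * t) for l in lam0])
        amp0, _ = nnls(basis, y)
        amp0 = np.clip(amp0, 1e-6 * y_peak, None)
        x0 = np.concatenate([amp0, lam0])
        try:
            sol = least_squares(
                resid, x0,
                bounds=(np.full(2 * n_exp, 1e-12),
                        np.concatenate([np.full(n_exp, 100 * y_peak),
                                        np.full(n_exp, 1.0)])),
                ftol=1e-14, xtol=1e-14, max_nfev=20000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def assemble_input_function(
    wb_nodes: tuple[np.ndarray, np.ndarray],
    pob_params: dict,
    pf_params: dict,
    t_end: float = 5400.0,
    dt: float = 1.0,
    calibration_factor: float = 1.0,
) -> ArterialInput:
    """Compose and smooth the metabolite-corrected parent-plasma input.

    parent plasma = pf(t) * POB(t) * whole blood(t); the portion after the
    peak is replaced by a tri-exponential fit (bi-exponential fallback,
    flagged), the pre-peak portion stays the piecewise-linear product.
    """
    t_wb, v_wb = wb_nodes
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    wb = np.interp(t, t_wb, v_wb, left=0.0, right=float(v_wb[-1]))
    total_plasma = wb * _eval_pob(pob_params, t)
    parent_raw = total_plasma * _eval_pf(pf_params, t)
    # locate the peak on a lightly smoothed copy so measurement noise does
    # not pin it to a spike; the curve itself stays as measured
    k = 5
    pad = k // 2
    padded = np.concatenate([parent_raw[pad:0:-1], parent_raw,
                             parent_raw[-2:-2 - pad:-1]])
    smooth = np.convolve(padded, np.ones(k) / k, mode="valid")
    i_peak = int(np.argmax(smooth))
    t_peak = float(t[i_peak])

    post = slice(i_peak, None)
    t_rel = t[post] - t_peak
    n_exp, fallback = 3, False
    sol = _fit_multiexp(t_rel, parent_raw[post], 3)
    if sol is None or not sol.success or not np.all(np.isfinite(sol.x)):
        logger.warning("tri-exponential smoothing failed; bi-exponential fallback")
        n_exp, fallback = 2, True
        sol = _fit_multiexp(t_rel, parent_raw[post], 2)
    amps, lams = sol.x[:n_exp], sol.x[n_exp:]
    smoothed = parent_raw.copy()
    smoothed[post] = triexp_curve(t_rel, amps, lams)
    smoothed = np.clip(smoothed, 0.0, None)
    peak_gap = abs(smoothed[i_peak] - parent_raw[i_peak]) / max(parent_raw[i_peak], 1e-12)
    if peak_gap > 0.01:
        logger.warning("input curve discontinuity at the peak: %.2f%%", 100 * peak_gap)

    return ArterialInput(
        t=t,
        parent_plasma=smoothed,
        whole_blood=wb,
        delay_s=0.0,
        params={
            "calibration_factor": calibration_factor,
            "pob": pob_params,
            "pf": pf_params,
            "triexp": {"amps": [float(a) for a in amps],
                       "lams": [float(l) for l in lams],
                       "n_exp": n_exp, "fallback_biexp": fallback,
                       "peak_time_s": t_peak, "peak_continuity_gap": float(peak_gap)},
            "unsmoothed_integral": float(np.trapezoid(parent_raw, t)),
        },
    )


def fit_delay(
    input_model: ArterialInput,
    whole_brain_tac: np.ndarray,
    schedule: FrameSchedule,
    search_s: float = 30.0,
    step_s: float = 0.5,
    window_s: float = 120.0,
    vb: float = 0.05,
) -> tuple[float, dict]:
    """Grid-search the blood-to-tissue delay on the early whole-brain TAC.

    For each candidate delay a 1-tissue + blood-volume model is fitted to
    the frames inside the first ``window_s`` seconds; the delay minimising
    the weighted SSE wins, ties broken toward smaller |delay|.  Returns
    (delay_s, diagnostics); a minimum at the grid boundary is flagged.
    """
    keep = schedule.end <= window_s + 1e-9
    if keep.sum() < 6:
        raise ValueError("whole-brain TAC must cover the first 120 s with >= 6 frames")
    sub_sched = FrameSchedule(schedule.start[keep], schedule.duration[keep])
    tac = np.asarray(whole_brain_tac, dtype=float)[keep]
    deltas = np.arange(-search_s, search_s + 0.5 * step_s, step_s)
    sses = np.empty(deltas.size)
    for i, d in enumerate(deltas):
        shifted = input_model.with_delay(d)
        _, _, sse = fit_onetcm(tac, shifted, sub_sched, vb_fixed=vb, dt=0.25)
        sses[i] = sse
    best_sse = sses.min()
    # ties (numerically equal SSE) resolved toward the smallest |delay|
    tied = np.flatnonzero(sses <= best_sse * (1.0 + 1e-9) + 1e-300)
    best = tied[np.argmin(np.abs(deltas[tied]))]
    delay = float(deltas[best])
    at_boundary = best in (0, deltas.size - 1)
    if at_boundary:
        logger.warning("delay search minimum at grid boundary (%.1f s)", delay)
    return delay, {"sse": float(sses[best]), "at_boundary": bool(at_boundary),
                   "grid": (float(-search_s), float(search_s), float(step_s))}


def build_input_function(
    blood: BloodData,
    whole_brain_tac: np.ndarray | None = None,
    schedule: FrameSchedule | None = None,
    t_end: float = 5400.0,
) -> ArterialInput:
    """Run the full chain: calibrate, merge, fit POB and parent fraction,
    multiply, smooth, and (if a whole-brain TAC is given) fit the delay."""
    calibrated, factor = calibrate_continuous(blood.continuous, blood.discrete)
    wb_nodes = merge_blood(calibrated, blood.discrete)
    pob = fit_plasma_over_blood(blood.discrete)
    pf = fit_parent_fraction(blood.parent_fraction)
    model = assemble_input_function(wb_nodes, pob, pf, t_end=t_end,
                                    calibration_factor=factor)
    if whole_brain_tac is not None:
        if schedule is None:
            raise ValueError("schedule required to fit the delay")
        delay, diag = fit_delay(model, whole_brain_tac, schedule)
        model = model.with_delay(delay)
        model.params["delay"] = {"delay_s": delay, **diag}
    return model
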