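"""Synthetic cohort generator with known ground truth.

Emulates the study's data at ROI level so that every downstream stage is
testable without any acquisition: dynamic PET as regional time-activity
curves on the 26-frame / 90-min schedule, continuous (1 Hz, first 15 min)
plus discrete arterial blood with plasma-over-blood and parent-fraction
measurements, per-subject dosimetry (injected activity 294-374 MBq, body
weight), block-design BOLD ROI sessions with motion regressors, and a
controllable between-subject correlation between regional SUVR and ROI
activation.

The generator's defaults define the simulated study conditions: 11 subjects
(4 rCI, 5 rNC, 2 with unknown cognitive status who carry arterial blood
data instead of BOLD), a tracer input shaped as a linear rise to a 60 s
peak followed by a tri-exponential washout, and regional 2TCM parameters
around K1 = 0.10 ml cm^-3 min^-1, k2 = 0.05, k3 = k4 = 0.03 min^-1
(VT = 4 ml/cm^3), scaled so whole-brain SUV(60-90 min) is ~1 g/ml for a
reference dosing of 337 MBq / 85 kg.  All simulated activities are treated
as decay-corrected; no decay term appears anywhere.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FrameSchedule, make_frame_schedule
from .inputfunc import ArterialInput, parent_fraction_curve, pob_curve
from .kinetics import twotcm_predict, total_volume_of_distribution, _PreparedInput
from .regions import DEFAULT_VOLUMES_ML, REFERENCE_REGION
from . import fmri

__all__ = [
    "BloodTruth",
    "BloodNoise",
    "RegionTruth",
    "BoldNoise",
    "CohortConfig",
    "SubjectData",
    "CohortDataset",
    "simulate_blood_data",
    "simulate_subject_tacs",
    "simulate_bold_session",
    "simulate_cohort",
    "write_cohort",
    "make_phantom",
    "DISCRETE_SAMPLE_MIN",
    "PARENT_FRACTION_SAMPLE_MIN",
]

#: discrete whole-blood/plasma sample times (minutes after scan start)
DISCRETE_SAMPLE_MIN = (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90)
#: parent-fraction measurement times (minutes)
PARENT_FRACTION_SAMPLE_MIN = (5, 10, 20, 30, 50, 70, 90)

_REFERENCE_DOSE_MBQ = 337.0
_REFERENCE_WEIGHT_KG = 85.0


# ---------------------------------------------------------------------------
# ground-truth parameterisations


@dataclass(frozen=True)
class BloodTruth:
    """True arterial curves: whole blood, plasma-over-blood, parent fraction.

    The whole-blood curve rises linearly from 0 to ``peak_kbq_ml`` at
    ``peak_time_s`` and decays tri-exponentially afterwards.  ``delay_s`` is
    the blood-to-tissue arrival delay (positive = the tissue sees the tracer
    after the blood-sampling site; the measured blood tables stay on the
    sampling clock); ``calibration_bias`` multiplies the continuous detector
    to exercise the calibration stage.
    """

    peak_time_s: float = 60.0
    peak_kbq_ml: float = 39.5
    decay_fractions: tuple[float, ...] = (0.72, 0.20, 0.08)
    decay_tau_s: tuple[float, ...] = (40.0, 300.0, 3600.0)
    pob_c0: float = 1.0
    pob_cinf: float = 1.6
    pob_lambda: float = 0.01
    pf_t50_s: float = 1200.0
    pf_hill: float = 2.0
    delay_s: float = 0.0
    calibration_bias: float = 1.0

    def whole_blood(self, t):
        t = np.asarray(t, dtype=float)
        rise = self.peak_kbq_ml * np.clip(t, 0.0, None) / self.peak_time_s
        td = np.clip(t - self.peak_time_s, 0.0, None)
        decay = self.peak_kbq_ml * sum(
            f * np.exp(-td / tau) for f, tau in zip(self.decay_fractions, self.decay_tau_s)
        )
        return np.where(t < self.peak_time_s, rise, decay)

    def plasma_over_blood(self, t):
        return pob_curve(t, self.pob_c0, self.pob_cinf, self.pob_lambda)

    def parent_fraction(self, t):
        return parent_fraction_curve(t, self.pf_t50_s, self.pf_hill)

    def parent_plasma(self, t):
        return self.whole_blood(t) * self.plasma_over_blood(t) * self.parent_fraction(t)

    def to_input(self, t_end: float = 5400.0, dt: float = 1.0,
                 amplitude: float = 1.0) -> ArterialInput:
        """Sample the true curves into an :class:`ArterialInput` (no delay)."""
        t = np.arange(0.0, t_end + 0.5 * dt, dt)
        return ArterialInput(
            t=t,
            parent_plasma=amplitude * self.parent_plasma(t),
            whole_blood=amplitude * self.whole_blood(t),
            delay_s=0.0,
            params={"source": "ground_truth", "amplitude": amplitude},
        )


@dataclass(frozen=True)
class BloodNoise:
    """Multiplicative CVs for blood measurements; all zero -> exact curves."""

    continuous_cv: float = 0.02
    discrete_cv: float = 0.02
    parent_fraction_sd: float = 0.02

    def __post_init__(self):
        if min(self.continuous_cv, self.discrete_cv, self.parent_fraction_sd) < 0:
            raise ValueError("noise scales must be >= 0")

    def scaled(self, s: float) -> "BloodNoise":
        return BloodNoise(self.continuous_cv * s, self.discrete_cv * s,
                          self.parent_fraction_sd * s)


@dataclass(frozen=True)
class RegionTruth:
    """True 2TCM parameters and nominal volume for one region."""

    K1: float
    k2: float
    k3: float
    k4: float
    vb: float = 0.05
    volume_ml: float = 10.0

    @property
    def vt(self) -> float:
        return total_volume_of_distribution(self.K1, self.k2, self.k3, self.k4)


def _default_region_truth() -> dict[str, RegionTruth]:
    # mild deterministic regional heterogeneity around the base parameter set;
    # cerebellum stays at base so whole-brain SUVR lands near 1
    base = dict(K1=0.10, k2=0.05, k3=0.03, k4=0.03, vb=0.05)
    k1_mult = {
        "frontal": 1.00, "occipital": 1.04, "temporal": 0.98, "parietal": 1.01,
        "hippocampus": 0.96, "amygdala": 0.97, "insula": 1.02, "striatum": 1.03,
        "thalamus": 1.05, "pallidum": 0.99, "cerebellum": 1.00,
    }
    out = {}
    for name, vol in DEFAULT_VOLUMES_ML.items():
        out[name] = RegionTruth(
            K1=base["K1"] * k1_mult[name], k2=base["k2"], k3=base["k3"],
            k4=base["k4"], vb=base["vb"], volume_ml=vol,
        )
    return out


@dataclass(frozen=True)
class BoldNoise:
    """AR(1) measurement noise and motion model for BOLD sessions."""

    ar1_phi: float = 0.3
    sigma_frac: float = 0.003      # innovation SD as a fraction of baseline
    motion_step_sd: float = 0.02   # random-walk step of the motion traces
    motion_coupling: float = 0.5   # signal units per unit of motion trace

    def scaled(self, s: float) -> "BoldNoise":
        return BoldNoise(self.ar1_phi, self.sigma_frac * s,
                         self.motion_step_sd * s, self.motion_coupling)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    ``rho`` is the target between-subject Pearson correlation between a
    region's SUVR and its BOLD activation (same value for every
    non-reference region unless a dict is given).  ``group_effect_psc`` /
    ``group_effect_uptake`` are additive/multiplicative rCI-vs-rNC effects,
    both 0 by default (the null regime).  ``noise_scale = 0`` switches every
    noise source off while keeping between-subject biology.
    """

    n_rci: int = 4
    n_rnc: int = 5
    n_unknown: int = 2            # arterial-blood arm, no BOLD session
    rho: float | dict = 0.0
    uptake_cv: float = 0.10       # between-subject SD of regional uptake multipliers
    psc_mean: float = 0.8         # mean % signal change per region
    psc_between_sd: float = 0.3   # between-subject SD of psc
    group_effect_uptake: float = 0.0
    group_effect_psc: float = 0.0
    tac_noise_sd0: float = 0.5    # kBq/ml per sqrt(kBq/ml / s); 0 = noiseless
    blood_noise: BloodNoise = field(default_factory=BloodNoise)
    bold_noise: BoldNoise = field(default_factory=BoldNoise)
    blood_truth: BloodTruth = field(default_factory=BloodTruth)
    noise_scale: float = 1.0
    biology_scale: float = 1.0    # 0 freezes between-subject variability
    tac_dt_s: float = 1.0         # convolution grid step for TAC synthesis
    regions: tuple | None = None  # subset of the default region set (None = all)

    def noiseless(self) -> "CohortConfig":
        return replace(self, noise_scale=0.0)


def _rho_for(config: CohortConfig, region: str) -> float:
    rho = config.rho
    r = float(rho.get(region, 0.0)) if isinstance(rho, dict) else float(rho)
    if abs(r) > 1.0:
        raise ValueError("|rho| must be <= 1")
    return r


def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject generator from a stable hash of (master seed, subject id)."""
    h = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h]))


# ---------------------------------------------------------------------------
# single-modality simulators


def simulate_blood_data(
    truth: BloodTruth,
    noise: BloodNoise | None = None,
    seed: int | np.random.Generator = 0,
    amplitude: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Simulate the arterial blood tables for one subject.

    Returns ``continuous`` (1 Hz, 0-900 s, with the truth's calibration bias
    applied), ``discrete`` (whole blood + plasma at the 12 sample times) and
    ``parent_fraction`` (7 time points), all on the blood-sampling clock
    (the tissue lags them by ``truth.delay_s``).  Values are clipped at 0.
    """
    noise = noise or BloodNoise()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_cont = np.arange(0.0, 901.0, 1.0)
    wb_cont = amplitude * truth.whole_blood(t_cont)
    cont = truth.calibration_bias * wb_cont
    if noise.continuous_cv > 0:
        cont = cont * (1.0 + noise.continuous_cv * rng.standard_normal(cont.size))
    continuous = pd.DataFrame(
        {"time_s": t_cont, "whole_blood_kBq_per_ml": np.clip(cont, 0.0, None)}
    )

    t_disc = 60.0 * np.asarray(DISCRETE_SAMPLE_MIN, dtype=float)
    wb_d = amplitude * truth.whole_blood(t_disc)
    pl_d = wb_d * truth.plasma_over_blood(t_disc)
    if noise.discrete_cv > 0:
        wb_d = wb_d * (1.0 + noise.discrete_cv * rng.standard_normal(wb_d.size))
        pl_d = pl_d * (1.0 + noise.discrete_cv * rng.standard_normal(pl_d.size))
    discrete = pd.DataFrame(
        {
            "time_s": t_disc,
            "whole_blood_kBq_per_ml": np.clip(wb_d, 0.0, None),
            "plasma_kBq_per_ml": np.clip(pl_d, 0.0, None),
        }
    )

    t_pf = 60.0 * np.asarray(PARENT_FRACTION_SAMPLE_MIN, dtype=float)
    pf = truth.parent_fraction(t_pf)
    if noise.parent_fraction_sd > 0:
        pf = pf + noise.parent_fraction_sd * rng.standard_normal(pf.size)
    parent_fraction = pd.DataFrame(
        {"time_s": t_pf, "parent_fraction": np.clip(pf, 0.0, 1.0)}
    )
    return {"continuous": continuous, "discrete": discrete,
            "parent_fraction": parent_fraction}


def simulate_subject_tacs(
    region_truth: dict[str, RegionTruth],
    input_model: ArterialInput,
    schedule: FrameSchedule,
    noise_sd0: float = 0.0,
    seed: int | np.random.Generator = 0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Frame-averaged 2TCM TACs for every region, plus count-statistics noise.

    The noise is zero-mean Gaussian with SD ``noise_sd0 *
    sqrt(C / frame_duration)`` — the standard proxy for PET count
    statistics, where long frames and low activity average down.  Returns a
    long table (frame_start_s, frame_duration_s, region,
    concentration_kBq_per_ml).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prep = _PreparedInput(input_model, schedule.total_duration, dt)
    rows = []
    for name, rt in region_truth.items():
        tac = twotcm_predict((rt.K1, rt.k2, rt.k3, rt.k4), input_model, schedule,
                             vb=rt.vb, _prepared=prep)
        if noise_sd0 > 0:
            sd = noise_sd0 * np.sqrt(np.clip(tac, 1e-6, None) / schedule.duration)
            tac = tac + sd * rng.standard_normal(tac.size)
        rows.append(
            pd.DataFrame(
                {
                    "frame_start_s": schedule.start,
                    "frame_duration_s": schedule.duration,
                    "region": name,
                    "concentration_kBq_per_ml": tac,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_bold_session(
    psc_by_roi: dict[str, float],
    noise: BoldNoise | None = None,
    seed: int | np.random.Generator = 0,
    baseline: float = 1000.0,
    tr: float = fmri.TR_DEFAULT,
    n_volumes: int = fmri.N_VOLUMES_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block-design BOLD ROI series (161 volumes, TR 2 s, five cycles).

    ``signal = baseline * (1 + psc/100 * x_c) + motion-coupled drift + AR(1)
    noise`` where ``x_c`` is the convolved task regressor, range-normalised
    and mean-centred, so that the first-level psc estimator is exactly
    unbiased in the noiseless limit.  Returns (bold long table, motion
    table).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    noise = noise or BoldNoise()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = fmri.convolved_task_regressor(fmri.default_task_onsets(), tr=tr, n_volumes=n_volumes)
    u = (x - x.min()) / (x.max() - x.min())
    x_c = u - u.mean()

    motion = np.cumsum(
        noise.motion_step_sd * rng.standard_normal((n_volumes, 6)), axis=0
    ) if noise.motion_step_sd > 0 else np.zeros((n_volumes, 6))
    drift = noise.motion_coupling * motion.sum(axis=1)

    bold_rows = []
    for roi, psc in psc_by_roi.items():
        if not np.isfinite(psc):
            raise ValueError("effect size must be finite")
        clean = baseline * (1.0 + psc / 100.0 * x_c)
        if noise.sigma_frac > 0:
            innov = noise.sigma_frac * baseline * rng.standard_normal(n_volumes)
            e = np.empty(n_volumes)
            e[0] = innov[0] / np.sqrt(1.0 - noise.ar1_phi**2)
            for i in range(1, n_volumes):
                e[i] = noise.ar1_phi * e[i - 1] + innov[i]
            series = clean + drift + e
        else:
            series = clean + drift
        bold_rows.append(
            pd.DataFrame(
                {"volume_index": np.arange(n_volumes), "roi": roi, "signal": series}
            )
        )
    bold = pd.concat(bold_rows, ignore_index=True)
    motion_df = pd.DataFrame(
        motion,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    motion_df.insert(0, "volume_index", np.arange(n_volumes))
    return bold, motion_df


# ---------------------------------------------------------------------------
# whole-cohort simulation


@dataclass
class SubjectData:
    subject_id: str
    group: str                    # rCI | rNC | unknown
    age: float
    body_weight_kg: float
    injected_activity_mbq: float
    injected_mass_ug: float
    tacs: pd.DataFrame
    blood: dict[str, pd.DataFrame] | None = None
    bold: pd.DataFrame | None = None
    motion: pd.DataFrame | None = None


@dataclass
class CohortDataset:
    subjects: list[SubjectData]
    schedule: FrameSchedule
    config: CohortConfig
    seed: int
    ground_truth: dict

    @property
    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age_years": s.age,
                    "weight_kg": s.body_weight_kg,
                    "injected_MBq": s.injected_activity_mbq,
                    "injected_mass_ug": s.injected_mass_ug,
                }
                for s in self.subjects
            ]
        )


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    schedule: FrameSchedule | None = None) -> CohortDataset:
    """Generate a complete synthetic study dataset with saved ground truth.

    Subjects are 4 rCI + 5 rNC with BOLD sessions and ``n_unknown``
    arterial-blood subjects without BOLD (and without fMRI-coupled draws in
    the correlation analysis).  For every non-reference region a latent
    bivariate-normal pair couples the subject's regional uptake multiplier
    (applied to K1, hence to SUVR via the cerebellar ratio) and the
    subject's ROI activation, inducing a between-subject Pearson correlation
    of approximately ``rho``.
    """
    config = config or CohortConfig()
    schedule = schedule or make_frame_schedule()
    region_truth = _default_region_truth()
    if config.regions is not None:
        wanted = set(config.regions) | {REFERENCE_REGION}
        unknown = wanted - set(region_truth)
        if unknown:
            raise ValueError(f"unknown regions {sorted(unknown)}")
        region_truth = {k: v for k, v in region_truth.items() if k in wanted}
    ns = float(config.noise_scale)
    bs = float(config.biology_scale)
    blood_noise = config.blood_noise.scaled(ns)
    bold_noise = config.bold_noise.scaled(ns)
    tac_sd0 = config.tac_noise_sd0 * ns

    groups = (
        ["rCI"] * config.n_rci + ["rNC"] * config.n_rnc + ["unknown"] * config.n_unknown
    )
    subjects: list[SubjectData] = []
    gt_subjects = {}
    region_names = list(region_truth)
    coupled = [r for r in region_names if r != REFERENCE_REGION]

    for idx, group in enumerate(groups):
        sid = f"sub-{idx + 1:03d}"
        rng = subject_rng(seed, sid)
        age = float(np.clip(rng.normal(68.5, 7.5), 50.0, 80.0))
        weight = float(np.clip(rng.normal(85.0, 16.0), 55.0, 130.0))
        injected = float(rng.uniform(294.0, 374.0))
        mass = float(rng.uniform(2.68, 8.88))
        amplitude = (injected / _REFERENCE_DOSE_MBQ) / (weight / _REFERENCE_WEIGHT_KG)

        # latent cross-modal coupling draws, one pair per coupled region
        uptake_mult = {REFERENCE_REGION: 1.0}
        psc_true = {}
        for region in coupled:
            r = _rho_for(config, region)
            u = rng.standard_normal()
            v = r * u + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal()
            mult = 1.0 + bs * config.uptake_cv * u
            if group == "rCI":
                mult *= 1.0 + config.group_effect_uptake
            uptake_mult[region] = float(np.clip(mult, 0.05, None))
            psc = config.psc_mean + bs * config.psc_between_sd * v
            if group == "rCI":
                psc += config.group_effect_psc
            psc_true[region] = float(psc)
        psc_true[REFERENCE_REGION] = config.psc_mean

        subj_regions = {
            name: replace(rt, K1=rt.K1 * uptake_mult[name])
            for name, rt in region_truth.items()
        }
        true_input = config.blood_truth.to_input(
            t_end=schedule.total_duration, amplitude=amplitude
        ).with_delay(config.blood_truth.delay_s)
        tacs = simulate_subject_tacs(
            subj_regions, true_input, schedule, noise_sd0=tac_sd0, seed=rng,
            dt=config.tac_dt_s,
        )

        blood = bold = motion = None
        if group == "unknown":
            blood = simulate_blood_data(
                config.blood_truth, blood_noise, seed=rng, amplitude=amplitude
            )
        else:
            bold, motion = simulate_bold_session(psc_true, bold_noise, seed=rng)

        subjects.append(
            SubjectData(
                subject_id=sid, group=group, age=age, body_weight_kg=weight,
                injected_activity_mbq=injected, injected_mass_ug=mass,
                tacs=tacs, blood=blood, bold=bold, motion=motion,
            )
        )
        gt_subjects[sid] = {
            "group": group,
            "amplitude": amplitude,
            "uptake_multipliers": uptake_mult,
            "true_psc": psc_true,
            "true_vt": {n: rt.vt for n, rt in subj_regions.items()},
        }

    ground_truth = {
        "seed": int(seed),
        "config": _config_dict(config),
        "region_truth": {n: asdict(rt) for n, rt in region_truth.items()},
        "subjects": gt_subjects,
    }
    return CohortDataset(
        subjects=subjects, schedule=schedule, config=config, seed=int(seed),
        ground_truth=ground_truth,
    )


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    if isinstance(config.rho, dict):
        d["rho"] = {k: float(v) for k, v in config.rho.items()}
    return d


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> Path:
    """Write the cohort as the CSV/JSON file layout consumed by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.subject_table.to_csv(outdir / "subjects.csv", index=False)
    for s in dataset.subjects:
        s.tacs.to_csv(outdir / f"{s.subject_id}_tac.csv", index=False)
        if s.blood is not None:
            s.blood["continuous"].to_csv(
                outdir / f"{s.subject_id}_blood_continuous.csv", index=False
            )
            s.blood["discrete"].to_csv(
                outdir / f"{s.subject_id}_blood_discrete.csv", index=False
            )
            s.blood["parent_fraction"].to_csv(
                outdir / f"{s.subject_id}_parent_fraction.csv", index=False
            )
        if s.bold is not None:
            s.bold.to_csv(outdir / f"{s.subject_id}_bold.csv", index=False)
            s.motion.to_csv(outdir / f"{s.subject_id}_motion.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True)
    return outdir


def make_phantom(
    tacs_by_region: dict[str, np.ndarray],
    voxels_per_region: int = 8,
) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Paint per-region TACs into a toy 4-D image + integer label map.

    Returns ``(image4d, labelmap, label_table)`` for exercising the ROI
    extraction layer; every voxel of a region carries the region's TAC
    exactly.
    """
    names = list(tacs_by_region)
    n_frames = len(next(iter(tacs_by_region.values())))
    nvox = voxels_per_region * len(names)
    side = int(np.ceil(nvox ** (1.0 / 3.0)))
    image = np.zeros((side, side, side, n_frames))
    labels = np.zeros((side, side, side), dtype=int)
    flat_idx = np.arange(side**3)
    table = {}
    for li, name in enumerate(names, start=1):
        sel = flat_idx[(li - 1) * voxels_per_region: li * voxels_per_region]
        coords = np.unravel_index(sel, (side, side, side))
        labels[coords] = li
        image[coords[0], coords[1], coords[2], :] = np.asarray(tacs_by_region[name])
        table[li] = name
    return image, labels, table
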