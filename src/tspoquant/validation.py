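"""Monte-Carlo calibration studies of the statistical machinery.

These routines generate data under known conditions and measure operating
characteristics: type-I error of the two-sample t and Pearson tests, the
first-level GLM's null Z rate and percent-signal-change recovery, and the
calibration of the generator's cross-modal SUVR-activation coupling.  They
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fmri
from .cohort import BoldNoise, CohortConfig, simulate_bold_session, simulate_cohort
from .regions import REFERENCE_REGION
from .semiquant import regional_outcomes
from .stats import pearson_correlation, two_sample_ttest

__all__ = [
    "ttest_type1_rate",
    "pearson_type1_rate",
    "glm_null_z_rate",
    "glm_psc_recovery",
    "cohort_coupling_correlations",
    "FAST_MC_REGIONS",
]

#: reduced region set used for Monte-Carlo problem sizing (reference included)
FAST_MC_REGIONS = ("hippocampus", "amygdala", "frontal")


def ttest_type1_rate(
    n_sims: int = 2000, n1: int = 6, n2: int = 4,
    variant: str = "student_pooled", alpha: float = 0.05, seed: int = 0,
) -> float:
    """Fraction of null (equal-mean Gaussian) simulations with p < alpha."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = rng.standard_normal(n1)
        b = rng.standard_normal(n2)
        hits += two_sample_ttest(a, b, variant=variant).p < alpha
    return hits / n_sims


def pearson_type1_rate(
    n_sims: int = 2000, n: int = 9, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I rate of the Pearson test on independent Gaussian pairs."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        res = pearson_correlation(rng.standard_normal(n), rng.standard_normal(n))
        hits += res.p_value < alpha
    return hits / n_sims


def glm_null_z_rate(
    n_sims: int = 500, threshold: float = 1.96, seed: int = 0,
    noise: BoldNoise | None = None,
) -> float:
    """|Z| > threshold rate for zero-effect BOLD sessions (generator noise)."""
    noise = noise or BoldNoise()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        bold, motion = simulate_bold_session(
            {"roi": 0.0}, noise, seed=int(rng.integers(2**31))
        )
        design = fmri.build_design(
            motion=motion.drop(columns=["volume_index"]).to_numpy()
        )
        res = fmri.fit_first_level(bold["signal"].to_numpy(), design)
        hits += abs(res.z) > threshold
    return hits / n_sims


def glm_psc_recovery(psc_true: float = 1.0, seed: int = 0) -> float:
    """Recovered percent signal change from a noiseless session."""
    bold, _ = simulate_bold_session(
        {"roi": psc_true}, BoldNoise(sigma_frac=0.0, motion_step_sd=0.0), seed=seed
    )
    res = fmri.fit_first_level(bold["signal"].to_numpy(), fmri.build_design())
    return res.percent_signal_change


def _cohort_correlations_once(config: CohortConfig, seed: int) -> dict[str, float]:
    """Sample SUVR-vs-psc Pearson r per coupled region for one cohort."""
    ds = simulate_cohort(config, seed=seed)
    suvr: dict[str, list[float]] = {}
    psc: dict[str, list[float]] = {}
    for s in ds.subjects:
        if s.bold is None:
            continue
        out = regional_outcomes(
            s.tacs, ds.schedule, s.injected_activity_mbq, s.body_weight_kg,
            composites=False,
        )
        motion = s.motion.drop(columns=["volume_index"]).to_numpy()
        design = fmri.build_design(motion=motion)
        for roi, df in s.bold.groupby("roi", sort=False):
            if roi == REFERENCE_REGION:
                continue
            res = fmri.fit_first_level(
                df.sort_values("volume_index")["signal"].to_numpy(), design
            )
            row = out.loc[out["region"] == roi, "SUVR"]
            suvr.setdefault(roi, []).append(float(row.iloc[0]))
            psc.setdefault(roi, []).append(res.percent_signal_change)
    return {
        roi: float(np.corrcoef(suvr[roi], psc[roi])[0, 1]) for roi in suvr
    }


def cohort_coupling_correlations(
    rho: float,
    n_cohorts: int = 500,
    seed: int = 0,
    regions: tuple = FAST_MC_REGIONS,
) -> pd.DataFrame:
    """Sample cross-modal correlations over many simulated cohorts.

    Runs the full measurement path (TAC synthesis -> SUVR, BOLD synthesis ->
    GLM psc, Pearson across the 9 BOLD subjects) for ``n_cohorts``
    independent cohorts at coupling ``rho`` and returns one row per cohort
    with the sample r per coupled region.
    """
    config = CohortConfig(rho=rho, regions=regions)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_cohorts):
        rows.append(_cohort_correlations_once(config, seed=int(rng.integers(2**31))))
    return pd.DataFrame(rows)
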