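"""Group statistics and the cross-modal PET-fMRI correlation analysis.

Between-group comparisons use two-sample t-tests (pooled-variance Student
by default, Welch by flag), computable both from raw values and from
printed summary statistics (mean, SD, n).  The whole-cohort cross-modal
analysis correlates each region's SUVR with the same region's BOLD
activation across subjects using Pearson's method, with two-sided p from
the t distribution with n - 2 df.  No multiple-testing correction is
applied by default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "ttest_from_summary",
    "two_sample_ttest",
    "pearson_correlation",
    "permutation_pvalue",
    "pet_fmri_correlation",
    "cohort_summary",
    "apply_fdr",
]


@dataclass
class GroupComparison:
    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    variant: str  # student_pooled | welch


@dataclass
class CorrelationResult:
    region: str
    n: int
    pearson_r: float
    p_value: float


def ttest_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "student_pooled",
    variable: str = "",
) -> GroupComparison:
    """Two-sample t-test from printed group summaries (mean, SD, n).

    ``variant='student_pooled'`` is the classical equal-variance Student
    test (df = n1 + n2 - 2); ``'welch'`` uses the Welch-Satterthwaite
    approximation.  Degenerate input (both SDs zero, equal means) yields
    t = 0, p = 1.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if min(sd1, sd2) < 0:
        raise ValueError("SDs must be >= 0")
    equal_var = variant == "student_pooled"
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if sd1 == 0 and sd2 == 0:
        t, p = (0.0, 1.0) if mean1 == mean2 else (float("inf"), 0.0)
        df = float(n1 + n2 - 2)
    else:
        res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                       equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        if equal_var:
            df = float(n1 + n2 - 2)
        else:
            v1, v2 = sd1**2 / n1, sd2**2 / n2
            df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    return GroupComparison(variable, mean1, sd1, n1, mean2, sd2, n2, t, df, p, variant)


def two_sample_ttest(
    values1, values2, variant: str = "student_pooled", variable: str = ""
) -> GroupComparison:
    """Two-sample t-test from raw values; matches the summary route exactly."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if min(a.size, b.size) < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("each group needs >= 2 finite values")
    return ttest_from_summary(
        float(np.mean(a)), float(np.std(a, ddof=1)), a.size,
        float(np.mean(b)), float(np.std(b, ddof=1)), b.size,
        variant=variant, variable=variable,
    )


def pearson_correlation(x, y, region: str = "") -> CorrelationResult:
    """Pearson r with two-sided p (t distribution, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(region, int(x.size), float("nan"), float("nan"))
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(region, int(x.size), float(r), float(p))


def permutation_pvalue(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p for the Pearson correlation (exchangeable y).

    Independent route used to cross-check the t-based p-value.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += abs(np.mean(xc * yc[perm])) >= r_obs - 1e-12
    return (hits + 1) / (n_perm + 1)


def pet_fmri_correlation(
    outcomes: pd.DataFrame,
    activation: pd.DataFrame,
    pet_value: str = "SUVR",
    activation_metric: str = "psc",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-region Pearson correlation between PET uptake and BOLD activation.

    ``outcomes`` has columns (subject_id, region, SUVR, ...); ``activation``
    has (subject_id, roi, psc, z, beta).  Pairing is on subject_id within
    each region; subjects missing either modality are excluded pairwise,
    and the per-region n is reported.
    """
    act = activation.rename(columns={"roi": "region"})
    merged = outcomes.merge(act, on=["subject_id", "region"], how="inner")
    rows = []
    for region, df in merged.groupby("region", sort=False):
        df = df.dropna(subset=[pet_value, activation_metric])
        if len(df) < min_n:
            continue
        res = pearson_correlation(
            df[pet_value].to_numpy(), df[activation_metric].to_numpy(), region
        )
        rows.append({"region": region, "n": res.n, "r": res.pearson_r,
                     "p": res.p_value})
    return pd.DataFrame(rows, columns=["region", "n", "r", "p"])


def cohort_summary(subjects: pd.DataFrame) -> dict:
    """Demographics: mean/SD age (n-1 denominator), group counts, dose range."""
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    ages = subjects["age_years"].to_numpy(dtype=float)
    summary = {
        "n": int(len(subjects)),
        "mean_age_years": float(np.mean(ages)),
        "sd_age_years": float(np.std(ages, ddof=1)) if len(ages) > 1 else None,
        "group_counts": subjects["group"].value_counts().to_dict(),
    }
    if "injected_MBq" in subjects.columns:
        inj = subjects["injected_MBq"].dropna()
        if len(inj):
            summary["injected_MBq_range"] = (float(inj.min()), float(inj.max()))
    return summary


def apply_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values (off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                   alpha=alpha, method="fdr_bh")
    return p_adj
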