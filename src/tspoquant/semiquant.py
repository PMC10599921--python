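"""Semi-quantitative PET outcomes: SUV (60-90 min) and cerebellar SUVR.

SUV = duration-weighted mean concentration over the frames whose mid time
falls inside the window (default 3600-5400 s), normalised by injected
activity per body weight, in g/ml; SUVR divides by the cerebellar
pseudoreference SUV.  Composite regions (cortex, subcortex, whole brain)
are volume-weighted means of their members, with SUVR recomputed from the
composite SUV rather than averaging member SUVRs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .frames import FrameSchedule
from .regions import COMPOSITES, REFERENCE_REGION, RegionDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "compute_suv",
    "compute_suvr",
    "composite_regions",
    "regional_outcomes",
    "extract_regional_tacs",
    "load_nifti_pair",
    "SUV_WINDOW_DEFAULT",
]

SUV_WINDOW_DEFAULT = (3600.0, 5400.0)


def compute_suv(
    tac: np.ndarray,
    schedule: FrameSchedule,
    injected_activity_mbq: float,
    body_weight_kg: float,
    window_s: tuple[float, float] = SUV_WINDOW_DEFAULT,
    method: str = "midtime",
) -> float:
    """Standardised uptake value (g/ml) over a late time window.

    ``method='midtime'`` (default) selects frames with mid time in
    [window[0], window[1]); ``method='overlap'`` weights every frame by its
    overlap with the window (sensitivity alternative; on the default
    schedule the two differ by well under 1%).
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    tac = np.asarray(tac, dtype=float)
    lo, hi = window_s
    if method == "midtime":
        sel = (schedule.mid >= lo) & (schedule.mid < hi)
        if not np.any(sel):
            raise ValueError("no frame mid-times inside the SUV window")
        w = schedule.duration[sel]
        mean_conc = float(np.sum(tac[sel] * w) / np.sum(w))
    elif method == "overlap":
        overlap = np.clip(
            np.minimum(schedule.end, hi) - np.maximum(schedule.start, lo), 0.0, None
        )
        if overlap.sum() <= 0:
            raise ValueError("no frame overlaps the SUV window")
        mean_conc = float(np.sum(tac * overlap) / np.sum(overlap))
    else:
        raise ValueError(f"unknown SUV method {method!r}")
    # kBq/ml * g / kBq -> g/ml
    return mean_conc * (body_weight_kg * 1000.0) / (injected_activity_mbq * 1000.0)


def compute_suvr(outcomes: pd.DataFrame, reference: str = REFERENCE_REGION) -> pd.DataFrame:
    """Add an SUVR column: SUV ratio to the pseudoreference region.

    Operates per subject if a ``subject_id`` column is present.  The
    reference region's SUVR is exactly 1.
    """
    def _one(df: pd.DataFrame) -> pd.DataFrame:
        ref = df.loc[df["region"] == reference, "SUV"]
        if ref.empty:
            raise ValueError(f"reference region {reference!r} not present")
        ref_suv = float(ref.iloc[0])
        if ref_suv <= 0:
            raise ValueError("reference SUV must be positive")
        out = df.copy()
        out["SUVR"] = out["SUV"] / ref_suv
        out.loc[out["region"] == reference, "SUVR"] = 1.0
        return out

    if "subject_id" in outcomes.columns:
        return (
            outcomes.groupby("subject_id", group_keys=False, sort=False)[outcomes.columns]
            .apply(_one)
            .reset_index(drop=True)
        )
    return _one(outcomes)


def composite_regions(
    outcomes: pd.DataFrame,
    definitions: tuple[RegionDefinition, ...] = COMPOSITES,
    volumes: dict[str, float] | None = None,
    reference: str = REFERENCE_REGION,
) -> pd.DataFrame:
    """Append volume-weighted composite rows (cortex, subcortex, whole brain).

    Composite SUV (and VT when present) is the volume-weighted mean of the
    member regions; SUVR is recomputed from the composite SUV against the
    subject's reference SUV.  A composite with a missing member is skipped
    with a warning.
    """
    from .regions import DEFAULT_VOLUMES_ML

    volumes = volumes or DEFAULT_VOLUMES_ML

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        rows = [df]
        ref_suv = float(df.loc[df["region"] == reference, "SUV"].iloc[0])
        for comp in definitions:
            sub = df[df["region"].isin(comp.members)]
            if len(sub) < len(comp.members):
                logger.warning("composite %s skipped: missing members", comp.name)
                continue
            w = np.array([volumes[m] for m in sub["region"]])
            row = {c: sub.iloc[0][c] for c in df.columns if c not in
                   ("region", "SUV", "SUVR", "VT")}
            row["region"] = comp.name
            row["SUV"] = float(np.sum(sub["SUV"].to_numpy() * w) / w.sum())
            if "VT" in sub.columns and sub["VT"].notna().all():
                row["VT"] = float(np.sum(sub["VT"].to_numpy() * w) / w.sum())
            row["SUVR"] = row["SUV"] / ref_suv
            rows.append(pd.DataFrame([row]))
        return pd.concat(rows, ignore_index=True)

    if "subject_id" in outcomes.columns:
        return (
            outcomes.groupby("subject_id", group_keys=False, sort=False)[outcomes.columns]
            .apply(_one)
            .reset_index(drop=True)
        )
    return _one(outcomes)


def regional_outcomes(
    tacs: pd.DataFrame,
    schedule: FrameSchedule,
    injected_activity_mbq: float,
    body_weight_kg: float,
    subject_id: str | None = None,
    window_s: tuple[float, float] = SUV_WINDOW_DEFAULT,
    reference: str = REFERENCE_REGION,
    composites: bool = True,
) -> pd.DataFrame:
    """SUV + SUVR table from a long TAC table for one subject."""
    rows = []
    for region, df in tacs.groupby("region", sort=False):
        tac = df.sort_values("frame_start_s")["concentration_kBq_per_ml"].to_numpy()
        rows.append(
            {
                "region": region,
                "SUV": compute_suv(tac, schedule, injected_activity_mbq,
                                   body_weight_kg, window_s),
            }
        )
    out = pd.DataFrame(rows)
    if subject_id is not None:
        out.insert(0, "subject_id", subject_id)
    out = compute_suvr(out, reference)
    if composites:
        out = composite_regions(out, reference=reference)
    return out


def extract_regional_tacs(
    dynamic_image: np.ndarray,
    labelmap: np.ndarray,
    label_table: dict[int, str],
) -> dict[str, np.ndarray]:
    """Mean TAC per labelled region from a 4-D image (x, y, z, frame).

    Voxels labelled 0 are ignored; an empty region is skipped with a
    warning.
    """
    dynamic_image = np.asarray(dynamic_image)
    labelmap = np.asarray(labelmap)
    if dynamic_image.shape[:3] != labelmap.shape:
        raise ValueError("image and label map spatial dimensions differ")
    out: dict[str, np.ndarray] = {}
    for label, name in label_table.items():
        mask = labelmap == int(label)
        if not np.any(mask):
            logger.warning("region %s has no voxels; skipped", name)
            continue
        out[name] = dynamic_image[mask].mean(axis=0)
    return out


def load_nifti_pair(image_path, labelmap_path):
    """Load a 4-D NIfTI image and 3-D integer label map as arrays."""
    import nibabel as nib

    img = np.asarray(nib.load(str(image_path)).dataobj, dtype=float)
    lab = np.asarray(nib.load(str(labelmap_path)).dataobj).astype(int)
    return img, lab
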