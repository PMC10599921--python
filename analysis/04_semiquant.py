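"""Compute SUV (60-90 min) and cerebellum-normalised SUVR for every subject.

Adds the volume-weighted composite regions (cortex, subcortex, whole brain)
and merges the blood-arm VT values when available.  Writes
results/pipeline/outcomes.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from tspoquant.pipeline import load_schedule_from_tacs
from tspoquant.semiquant import regional_outcomes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    subjects = pd.read_csv(args.cohort / "subjects.csv")
    frames = []
    for row in subjects.itertuples():
        tacs = pd.read_csv(args.cohort / f"{row.subject_id}_tac.csv")
        schedule = load_schedule_from_tacs(tacs)
        frames.append(regional_outcomes(
            tacs, schedule, row.injected_MBq, row.weight_kg,
            subject_id=row.subject_id,
        ))
    outcomes = pd.concat(frames, ignore_index=True)
    kin_path = args.out / "kinetics.csv"
    if kin_path.exists():
        kin = pd.read_csv(kin_path)
        outcomes = outcomes.merge(
            kin[["subject_id", "region", "VT_ml_per_cm3"]].rename(
                columns={"VT_ml_per_cm3": "VT"}),
            on=["subject_id", "region"], how="left",
        )
    outcomes.to_csv(args.out / "outcomes.csv", index=False)
    wb = outcomes[outcomes.region == "whole_brain"]
    print(f"{len(outcomes)} subject-region outcomes")
    print(f"whole-brain SUV  mean {wb['SUV'].mean():.3f} g/ml "
          f"(range {wb['SUV'].min():.3f}-{wb['SUV'].max():.3f})")
    print(f"whole-brain SUVR mean {wb['SUVR'].mean():.3f} "
          f"(range {wb['SUVR'].min():.3f}-{wb['SUVR'].max():.3f})")
    print(f"wrote {args.out / 'outcomes.csv'}")


if __name__ == "__main__":
    main()
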