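"""Published reference-cohort tables used as fixture inputs.

The study that this pipeline emulates printed two small tables that serve
as worked-example inputs here: the demographic/imaging table for the 11
recruited patients (ages, body weights, TSPO genotype, reported cognitive
status, whether a CRT fMRI session was performed), and the per-group
summaries (mean, SD, n) of the ten neurocognitive test scores.  These are
inputs to :func:`tspoquant.stats.cohort_summary` and
:func:`tspoquant.stats.ttest_from_summary`; no imaging data accompany them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_demographics", "reference_cognitive_scores"]

_DEMOGRAPHICS = [
    # patient, age (y), weight (kg), genotype, reported status, fMRI performed
    ("001", 77, 71.9, "high_affinity", "rCI", True),
    ("002", 59, 99.7, "high_affinity", "rCI", True),
    ("003", 74, 75.3, "high_affinity", "rCI", True),
    ("004", 78, 122.7, "high_affinity", "rCI", True),
    ("101", 57, 77.0, "high_affinity", "rNC", True),
    ("102", 65, 95.9, "high_affinity", "rNC", True),
    ("103", 67, 73.9, "high_affinity", "rNC", True),
    ("104", 67, 89.9, "high_affinity", "rNC", True),
    ("105", 73, 68.7, "high_affinity", "rNC", True),
    ("106", 69, 69.4, "high_affinity", "rNC", False),   # arterial-blood arm
    ("107", 68, 82.5, "high_affinity", "not_recorded", False),  # arterial-blood arm
]

# test name, rNC mean, rNC SD, rNC n, rCI mean, rCI SD, rCI n,
# higher_is_worse (scores where a higher value indicates lower performance)
_COGNITIVE = [
    ("similarities", 36.5, 5.36, 6, 31.3, 5.37, 4, True),
    ("matrix_reasoning", 23.5, 2.81, 6, 18.0, 7.62, 4, False),
    ("digit_span", 20.7, 4.97, 6, 16.8, 3.77, 4, False),
    ("peoples_recall", 19.5, 6.19, 6, 20.0, 9.2, 4, False),
    ("peoples_delayed_recall", 7.0, 4.0, 6, 7.0, 5.8, 4, False),
    ("logical_memory_retention", 86.6, 22.25, 6, 75.5, 17.46, 4, False),
    ("logical_memory_recognition", 23.3, 4.27, 6, 23.5, 4.65, 4, False),
    ("color_word_reading", 22.8, 6.65, 6, 25.0, 1.41, 4, True),
    ("color_word_naming", 29.2, 3.31, 6, 38.8, 7.27, 4, True),
    ("verbal_fluency", 52.8, 13.85, 6, 40.5, 8.74, 4, False),
]


def reference_demographics() -> pd.DataFrame:
    """Demographic/imaging table of the 11-patient reference cohort."""
    df = pd.DataFrame(
        _DEMOGRAPHICS,
        columns=["subject_id", "age_years", "weight_kg", "genotype", "group",
                 "fmri_performed"],
    )
    return df


def reference_cognitive_scores() -> pd.DataFrame:
    """Per-group neurocognitive score summaries of the reference cohort."""
    return pd.DataFrame(
        _COGNITIVE,
        columns=["test", "rnc_mean", "rnc_sd", "rnc_n",
                 "rci_mean", "rci_sd", "rci_n", "higher_is_worse"],
    )
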