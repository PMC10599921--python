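"""Default brain-region table and composite definitions.

Regions mirror a standard anatomical atlas set used for regional TSPO
quantification: four cortical lobes, hippocampus, amygdala, insular cortex,
the subcortical striatum / thalamus / pallidum, and the cerebellum (the
pseudoreference).  Nominal volumes (ml) are adult gray-matter-scale values
used only for composite volume weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RegionDefinition",
    "DEFAULT_REGIONS",
    "DEFAULT_VOLUMES_ML",
    "CORTEX_MEMBERS",
    "SUBCORTEX_MEMBERS",
    "REFERENCE_REGION",
    "COMPOSITES",
]

REFERENCE_REGION = "cerebellum"

#: region -> nominal volume in ml (composite weighting only)
DEFAULT_VOLUMES_ML: dict[str, float] = {
    "frontal": 180.0,
    "occipital": 80.0,
    "temporal": 130.0,
    "parietal": 120.0,
    "hippocampus": 7.0,
    "amygdala": 3.0,
    "insula": 15.0,
    "striatum": 17.0,
    "thalamus": 14.0,
    "pallidum": 4.0,
    "cerebellum": 130.0,
}

DEFAULT_REGIONS: tuple[str, ...] = tuple(DEFAULT_VOLUMES_ML)

CORTEX_MEMBERS: tuple[str, ...] = (
    "occipital",
    "temporal",
    "frontal",
    "parietal",
    "insula",
    "hippocampus",
    "amygdala",
)
SUBCORTEX_MEMBERS: tuple[str, ...] = ("pallidum", "striatum", "thalamus")


@dataclass(frozen=True)
class RegionDefinition:
    """A (possibly composite) region: name, member regions, nominal volume."""

    name: str
    members: tuple[str, ...]
    volume_ml: float


def _composite(name: str, members: tuple[str, ...]) -> RegionDefinition:
    return RegionDefinition(
        name, members, sum(DEFAULT_VOLUMES_ML[m] for m in members)
    )


#: cortex / subcortex averages and whole brain (union of all atlas regions)
COMPOSITES: tuple[RegionDefinition, ...] = (
    _composite("cortex", CORTEX_MEMBERS),
    _composite("subcortex", SUBCORTEX_MEMBERS),
    _composite("whole_brain", DEFAULT_REGIONS),
)
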