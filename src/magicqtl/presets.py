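"""Calibration presets for the three evaluation sets.

The presets carry the variance-component structure, trait means and trial
designs of the study the package models: a 608-line eight-founder maize
MAGIC population ("whole_magic"), a 56-line extreme subset evaluated per
se ("ivs"), and 52 testcross hybrids of that subset to an unrelated
tester ("hvs").  Components are on the plot-data scale in squared trait
units (tunnel length cm², grain yield (g/plant)² for inbreds and
(Mg/ha · 10⁻¹)² for hybrids).

``environments``/``replicates`` describe the trials actually contributing
to each trait: tunnel length is only measurable under borer infestation,
so protected (insecticide-treated) trials count for yield but not for
tunnel length.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TraitPreset:
    """Variance components (with SEs) and scale for one trait in one set."""

    vg: float
    vgxe: float
    vres: float
    vg_se: float
    vgxe_se: float
    vres_se: float
    mean: float
    value_range: tuple[float, float]
    environments: int  # environments phenotyped for this trait
    replicates: int  # replicates per environment

    @property
    def vp(self) -> float:
        return self.vg + self.vgxe + self.vres


PRESETS: dict[str, dict[str, TraitPreset]] = {
    "whole_magic": {
        "tunnel_length": TraitPreset(21, 7, 91, 4, 5, 5, 35.0, (0, 59), 2, 1),
        "grain_yield": TraitPreset(78, 3, 186, 10, 6, 9, 42.4, (0, 114), 2, 1),
    },
    "ivs": {
        "tunnel_length": TraitPreset(107, 38, 75, 30, 17, 12, 25.0, (6, 63), 2, 2),
        "grain_yield": TraitPreset(229, 174, 582, 70, 65, 61, 73.3, (20, 117), 4, 2),
    },
    "hvs": {
        "tunnel_length": TraitPreset(21, 17, 119, 9, 12, 13, 29.0, (16, 40), 4, 2),
        "grain_yield": TraitPreset(118, 40, 396, 33, 31, 37, 76.0, (46, 94), 6, 2),
    },
}

# number of genotypes evaluated per set (extreme subset + checks)
SET_SIZES = {"whole_magic": 608, "ivs": 64, "hvs": 56}


def get_preset(set_id: str, trait: str) -> TraitPreset:
    try:
        return PRESETS[set_id][trait]
    except KeyError:
        raise KeyError(f"no preset for set {set_id!r}, trait {trait!r}") from None
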