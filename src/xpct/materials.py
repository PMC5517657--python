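"""Optical constants of the phantom materials.

X-ray refraction is described by the complex refractive index
``n = 1 - delta + i*beta``: ``delta`` (the refractive-index decrement) is
proportional to electron density and drives phase contrast, ``beta`` drives
absorption.  The preset tables below are plausible soft-tissue values anchored
on water at 30 keV (delta ~ 2.6e-7, beta ~ 1.1e-10) with blood/contrast and
neuron somata denser than parenchyma (vessels and somata image bright) and
osmium-stained membranes given roughly tenfold absorption.  Values at other
energies are scaled as ``delta ~ 1/E^2`` and ``beta ~ 1/E^3.5``
(photoelectric-dominated regime).

Exact values are a modelling choice; every quantification step downstream is
histogram-calibrated, so only the ordering and rough separation of the
presets matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Material label ids used in LabeledVolume grids.
BACKGROUND = 0  # embedding medium: agar (micro) or resin (nano)
WHITE_MATTER = 1
GREY_MATTER = 2
VESSEL = 3  # vessel / capillary lumen (blood, residual contrast)
NEURON = 4  # motor-neuron soma
MEMBRANE = 5  # osmium-stained cell membrane (nano)
MYELIN = 6
AIR = 7  # outside the embedding column (vacuum)

LABEL_NAMES = {
    BACKGROUND: "background",
    WHITE_MATTER: "parenchyma-white",
    GREY_MATTER: "parenchyma-grey",
    VESSEL: "vessel-lumen",
    NEURON: "neuron-soma",
    MEMBRANE: "osmium-membrane",
    MYELIN: "myelin",
    AIR: "air",
}

_REFERENCE_ENERGY_KEV = 30.0

# (delta, beta) at 30 keV.
_BASE_30KEV = {
    "agar": (2.50e-7, 1.10e-10),
    "resin": (2.55e-7, 1.15e-10),
    "parenchyma-white": (2.45e-7, 1.05e-10),
    "parenchyma-grey": (2.60e-7, 1.20e-10),
    "blood-contrast": (3.60e-7, 2.00e-10),
    "neuron-soma": (3.10e-7, 1.50e-10),
    "osmium-membrane": (3.30e-7, 1.30e-9),
    "myelin": (2.35e-7, 0.95e-10),
}

_DELTA_EXP = 2.0
_BETA_EXP = 3.5


def material_constants(name: str, energy_kev: float) -> tuple[float, float]:
    """delta, beta of a named preset material at the given energy (keV)."""
    if name not in _BASE_30KEV:
        raise KeyError(f"unknown material preset {name!r}")
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    d0, b0 = _BASE_30KEV[name]
    s = _REFERENCE_ENERGY_KEV / energy_kev
    return d0 * s**_DELTA_EXP, b0 * s**_BETA_EXP


@dataclass(frozen=True)
class MaterialTable:
    """Per-label (delta, beta) lookup at a fixed working energy."""

    energy_kev: float
    table: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lbl, (d, b) in self.table.items():
            if d < 0 or b < 0:
                raise ValueError(f"negative optical constant for label {lbl}")
            if lbl != BACKGROUND and b > 0 and not np.isfinite(d / b):
                raise ValueError(f"non-finite delta/beta for label {lbl}")

    @classmethod
    def preset(cls, energy_kev: float = 30.0, mode: str = "micro") -> "MaterialTable":
        """Standard preset: agar-embedded at 30 keV (micro) or
        resin-embedded at 17 keV (nano)."""
        background = "agar" if mode == "micro" else "resin"
        names = {
            BACKGROUND: background,
            WHITE_MATTER: "parenchyma-white",
            GREY_MATTER: "parenchyma-grey",
            VESSEL: "blood-contrast",
            NEURON: "neuron-soma",
            MEMBRANE: "osmium-membrane",
            MYELIN: "myelin",
        }
        table = {lbl: material_constants(nm, energy_kev) for lbl, nm in names.items()}
        table[AIR] = (0.0, 0.0)
        return cls(energy_kev=energy_kev, table=table)

    def delta(self, label: int) -> float:
        return self.table[label][0]

    def beta(self, label: int) -> float:
        return self.table[label][1]

    def delta_beta_ratio(self, label: int) -> float:
        d, b = self.table[label]
        return d / b

    def labels(self) -> list[int]:
        return sorted(self.table)
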