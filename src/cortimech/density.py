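"""Apparent mass density and bone mineral density by ashing (BMDA).

The specimen volume comes from digital-calliper readings (four repeats per
axis, means multiplied), the wet mass from eight balance readings (four
before and four after the resonance measurement).  BMDA divides the
post-furnace ash mass by the same volume.  Units: mm, mg, mg/mm^3.
"""

from __future__ import annotations

import numpy as np

from .records import DensityRecord

__all__ = ["specimen_volume", "mass_density", "ash_density"]


def specimen_volume(record: DensityRecord) -> float:
    """Volume (mm^3) = product of the per-axis means of the calliper repeats."""
    return float(np.prod(record.calliper_mm.mean(axis=1)))


def mass_density(record: DensityRecord) -> float:
    """Apparent wet mass density rho = mean(8 masses) / volume (mg/mm^3)."""
    return float(record.masses_mg.mean()) / specimen_volume(record)


def ash_density(record: DensityRecord) -> float:
    """Bone mineral density by ashing = ash mass / volume (mg/mm^3).

    The ash mass cannot exceed the wet mass; a record violating that is
    rejected as a measurement error.
    """
    if record.ash_mass_mg is None:
        raise ValueError("record has no ash mass")
    if record.ash_mass_mg > record.masses_mg.mean():
        raise ValueError("ash mass exceeds wet mass")
    return float(record.ash_mass_mg) / specimen_volume(record)
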