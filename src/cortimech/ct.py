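"""Micro-CT pore segmentation and porosity.

Porosity is the total pore volume divided by the total sample volume.
Pores (vascular canals) image darker than mineralised bone; a grayscale
threshold inside the sample mask separates them.  The default threshold is
Otsu's criterion on the in-mask histogram, with a bimodality guard so a
pore-free (unimodal) volume is not split in half; a fixed threshold can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .records import CTVolume

__all__ = [
    "PorosityResult",
    "segment_pores",
    "porosity",
    "pore_morphometry",
]


@dataclass
class PorosityResult:
    porosity: float
    pore_voxels: int
    sample_voxels: int
    threshold: float
    method: str
    pore_volume_mm3: float = np.nan
    sample_volume_mm3: float = np.nan

    def summary(self) -> str:
        return "\n".join([
            "Micro-CT porosity", "-" * 38,
            f"method        : {self.method} (threshold {self.threshold:.1f})",
            f"pore voxels   : {self.pore_voxels}",
            f"sample voxels : {self.sample_voxels}",
            f"porosity      : {100 * self.porosity:.2f} %",
        ])


def segment_pores(volume: CTVolume, method: str = "otsu",
                  threshold: float | None = None,
                  min_separation: float = 3.0,
                  min_component_voxels: int = 0) -> tuple[np.ndarray, float]:
    """Binary pore mask of in-mask voxels darker than the threshold.

    method="otsu" picks the threshold by Otsu's criterion on the in-mask
    intensities; if the two resulting classes are separated by less than
    ``min_separation`` pooled within-class standard deviations the
    histogram is judged unimodal (no pores) and an empty mask is returned.
    method="fixed" uses the supplied ``threshold`` directly.
    ``min_component_voxels`` optionally despeckles the mask (off by
    default).  Returns (mask, threshold_used).
    """
    mask = volume.sample_mask
    if not mask.any():
        raise ValueError("sample mask is empty")
    vals = volume.voxels[mask].astype(float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        thr = float(threshold_otsu(vals))
        low, high = vals[vals < thr], vals[vals >= thr]
        if low.size and high.size:
            pooled_sd = np.sqrt((low.var() * low.size + high.var() * high.size)
                                / vals.size)
            if high.mean() - low.mean() < min_separation * max(pooled_sd, 1e-12):
                return np.zeros(volume.voxels.shape, dtype=bool), thr
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    pores = (volume.voxels < thr) & mask
    if min_component_voxels > 0 and pores.any():
        lab = label(pores, connectivity=1)
        keep = np.bincount(lab.ravel()) >= min_component_voxels
        keep[0] = False
        pores = keep[lab]
    return pores, thr


def porosity(pore_mask: np.ndarray, sample_mask: np.ndarray,
             voxel_size_um: float = np.nan, threshold: float = np.nan,
             method: str = "") -> PorosityResult:
    """Porosity = pore voxel count / sample voxel count."""
    sample_mask = np.asarray(sample_mask, dtype=bool)
    pore_mask = np.asarray(pore_mask, dtype=bool) & sample_mask
    n_sample = int(sample_mask.sum())
    if n_sample == 0:
        raise ValueError("sample mask is empty")
    n_pore = int(pore_mask.sum())
    vx_mm3 = (voxel_size_um * 1e-3) ** 3
    return PorosityResult(
        porosity=n_pore / n_sample, pore_voxels=n_pore,
        sample_voxels=n_sample, threshold=threshold, method=method,
        pore_volume_mm3=n_pore * vx_mm3, sample_volume_mm3=n_sample * vx_mm3)


def pore_morphometry(pore_mask: np.ndarray,
                     voxel_size_um: float) -> np.ndarray:
    """Equivalent transverse-plane diameters (um) of connected pore canals.

    Pores are labelled as 3-D connected components (6-connectivity); each
    component's mean cross-sectional area in the transverse plane (grid
    axes 0-1, perpendicular to the canal axis) gives an equivalent circular
    diameter d = 2 sqrt(A / pi).
    """
    pore_mask = np.asarray(pore_mask, dtype=bool)
    if not pore_mask.any():
        return np.array([])
    lab = label(pore_mask, connectivity=1)
    diams = []
    for region in regionprops(lab):
        z0, z1 = region.bbox[2], region.bbox[5]
        mean_area = region.area / (z1 - z0)
        diams.append(2.0 * np.sqrt(mean_area / np.pi) * voxel_size_um)
    return np.array(diams)
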