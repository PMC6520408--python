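"""Compression stress-strain analysis: apparent modulus and strength.

A load-displacement record with two LVDT channels is converted to stress
and strain (stress = load / cross-section, strain = channel mean / gauge
length).  The compression apparent elastic modulus (CAEM) is the maximum
ordinary-least-squares slope over sliding windows of 0.2% strain placed at
every candidate origin on the loading ramp; the ultimate compressive
strength (UCS) is the peak stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import LoadDisplacementRecord

__all__ = [
    "StressStrainCurve",
    "CompressionResult",
    "to_stress_strain",
    "sliding_window_modulus",
    "ultimate_strength",
    "CompressionTest",
]

#: Sliding-window width, in absolute strain (0.2%).
DEFAULT_WINDOW = 0.002


@dataclass
class StressStrainCurve:
    strain: np.ndarray   # dimensionless
    stress: np.ndarray   # MPa
    specimen_id: str = ""
    area_mm2: float = np.nan
    gauge_mm: float = np.nan

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.size != self.stress.size:
            raise ValueError("strain and stress must share length")


@dataclass
class CompressionResult:
    """Apparent modulus (GPa), winning window origin, UCS (MPa)."""

    caem: float
    window_origin: float
    ucs: float
    strain_at_ucs: float
    window: float = DEFAULT_WINDOW

    def summary(self) -> str:
        return "\n".join([
            "Compression test", "-" * 38,
            f"CAEM            : {self.caem:.3f} GPa",
            f"window origin   : {self.window_origin:.5f} strain "
            f"(width {self.window:.4f})",
            f"UCS             : {self.ucs:.2f} MPa",
            f"strain at UCS   : {self.strain_at_ucs:.5f}",
        ])


def _final_ramp_start(displacement: np.ndarray, load: np.ndarray) -> int:
    """Index where the final ramp to failure begins.

    Used when no segment labels are present: walk back from the load peak
    to the last point at (or below) the displacement floor that precedes
    a monotone rise to the peak.
    """
    i_peak = int(np.argmax(load))
    d = displacement[:i_peak + 1]
    floor = d.min() + 0.02 * (d[i_peak] - d.min())
    below = np.nonzero(d <= floor)[0]
    return int(below[-1]) if below.size else 0


def to_stress_strain(record: LoadDisplacementRecord,
                     dims_mm: tuple[float, float, float]) -> StressStrainCurve:
    """Convert a two-channel compression record to stress and strain.

    ``dims_mm`` are the specimen edge lengths (w1, w2, L); the cross-section
    is w1*w2 and the gauge length L (the study specimens are 3 x 3 x 6 mm,
    loaded along the 6-mm axis).  Strain uses the mean of the two LVDT
    channels.  Preconditioning cycles and the initial toe ramp are removed,
    keeping the final ramp to failure (post-peak points are retained for the
    strength reading).
    """
    if record.displacement2 is None:
        raise ValueError("compression record needs two displacement channels")
    w1, w2, L = dims_mm
    area = w1 * w2
    disp = 0.5 * (record.displacement + record.displacement2)
    if record.segments is not None and "ramp" in set(record.segments):
        keep = record.segments == "ramp"
        disp, load = disp[keep], record.load[keep]
    else:
        i0 = _final_ramp_start(disp, record.load)
        disp, load = disp[i0:], record.load[i0:]
    disp = disp - disp[0]
    return StressStrainCurve(strain=disp / L, stress=load / area,
                             specimen_id=record.specimen_id,
                             area_mm2=area, gauge_mm=L)


def sliding_window_modulus(curve: StressStrainCurve,
                           window: float = DEFAULT_WINDOW,
                           stride: int = 1) -> tuple[float, float]:
    """Maximum OLS slope over strain windows of fixed width.

    Best-fit straight lines are computed over every window of ``window``
    strain, with origins at every ``stride``-th recorded sample (default:
    exhaustive).  Windows extending past the stress peak are excluded so
    post-yield softening never enters the modulus search.  Returns
    (modulus in GPa, winning window origin strain).
    """
    eps, sig = curve.strain, curve.stress
    i_peak = int(np.argmax(sig))
    eps_lo, eps_hi = eps[0], eps[i_peak]
    if eps_hi - eps_lo < window:
        raise ValueError("loading curve shorter than one strain window")
    # prefix sums for O(1) OLS slope per window
    n = i_peak + 1
    x, y = eps[:n], sig[:n]
    cx = np.concatenate([[0], np.cumsum(x)])
    cy = np.concatenate([[0], np.cumsum(y)])
    cxx = np.concatenate([[0], np.cumsum(x * x)])
    cxy = np.concatenate([[0], np.cumsum(x * y)])
    ends = np.searchsorted(x, x + window, side="right")
    best_slope, best_origin = -np.inf, x[0]
    for i in range(0, n, stride):
        if x[i] + window > x[n - 1] + 1e-12:
            break  # window would extend past the stress peak
        j = min(ends[i], n)
        k = j - i
        if k < 3:
            continue
        sx = cx[j] - cx[i]
        sy = cy[j] - cy[i]
        sxx = cxx[j] - cxx[i]
        sxy = cxy[j] - cxy[i]
        denom = k * sxx - sx * sx
        if denom <= 0:
            continue
        slope = (k * sxy - sx * sy) / denom
        if slope > best_slope:
            best_slope, best_origin = slope, x[i]
    if not np.isfinite(best_slope):
        raise ValueError("no complete strain window on the loading curve")
    return best_slope / 1e3, float(best_origin)  # MPa/strain -> GPa


def ultimate_strength(curve: StressStrainCurve) -> tuple[float, float]:
    """Peak stress on the ramp to failure (MPa) and the strain there."""
    i = int(np.argmax(curve.stress))
    return float(curve.stress[i]), float(curve.strain[i])


class CompressionTest:
    """Stress-strain model of one compression-to-failure record."""

    def __init__(self, record: LoadDisplacementRecord,
                 dims_mm: tuple[float, float, float],
                 window: float = DEFAULT_WINDOW, stride: int = 1):
        self.curve = to_stress_strain(record, dims_mm)
        self.window = window
        self.stride = stride

    def fit(self) -> CompressionResult:
        caem, origin = sliding_window_modulus(self.curve, self.window,
                                              self.stride)
        ucs, eps_u = ultimate_strength(self.curve)
        return CompressionResult(caem=caem, window_origin=origin, ucs=ucs,
                                 strain_at_ucs=eps_u, window=self.window)
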