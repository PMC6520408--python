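"""Oliver-Pharr analysis of spherical depth-sensing indentation.

The apparent elastic modulus is extracted from the unloading branch of a
load-displacement curve:

1. power-law fit of the upper unloading portion, P = alpha (h - h_f)^m;
2. contact stiffness S = dP/dh at peak depth;
3. contact depth for a sphere, h_c = (h_max + h_f) / 2;
4. contact area A = 2 pi R h_c;
5. reduced modulus E_r = (sqrt(pi)/2) S / sqrt(A);
6. sample modulus from 1/E_r = (1 - nu^2)/E + (1 - nu_i^2)/E_i.

The study protocol uses a 6-mm-diameter sapphire tip (E_i = 420 GPa,
nu_i = 0.24), bone Poisson ratio 0.33, 16 indents on a 4x4 grid 200 um
apart, with the sample value taken as the mean of the four central indents.

Units: records carry load in N and displacement in mm; depths are reported
in um, stiffness in N/um, areas in mm^2, moduli in GPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .records import LoadDisplacementRecord

__all__ = [
    "TipSpec",
    "SAPPHIRE_TIP",
    "UnloadingFit",
    "IndentationResult",
    "GridResult",
    "correct_compliance",
    "fit_unloading",
    "unloading_stiffness",
    "contact_depth",
    "contact_area",
    "reduced_modulus",
    "sample_modulus",
    "SphericalIndentation",
    "analyze_grid",
]

MM_TO_UM = 1e3


@dataclass(frozen=True)
class TipSpec:
    """Spherical indenter tip: radius (mm), modulus (GPa), Poisson ratio."""

    radius_mm: float
    E_gpa: float
    nu: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("tip radius must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("tip Poisson ratio must lie in (0, 0.5)")
        if self.E_gpa <= 0:
            raise ValueError("tip modulus must be positive")


#: The study's 6-mm-diameter sapphire tip.
SAPPHIRE_TIP = TipSpec(radius_mm=3.0, E_gpa=420.0, nu=0.24)

#: Poisson ratio assigned to bone.
BONE_POISSON = 0.33


@dataclass
class UnloadingFit:
    """Power-law fit P = alpha (h - h_f)^m of the upper unloading curve."""

    alpha: float      # N / um^m
    m: float
    h_f: float        # residual depth, um
    fit_range: tuple[float, float]  # load fractions of P_max
    rms_residual: float             # N
    converged: bool = True

    def __post_init__(self):
        if self.converged:
            if self.m < 1 or self.h_f < 0 or self.alpha <= 0:
                raise ValueError("invalid unloading fit parameters")

    def load(self, h_um):
        return self.alpha * np.clip(h_um - self.h_f, 0, None) ** self.m


@dataclass
class IndentationResult:
    """Per-indent Oliver-Pharr quantities."""

    P_max: float   # N
    h_max: float   # um
    S: float       # N/um
    h_c: float     # um
    A: float       # mm^2
    E_r: float     # GPa
    E: float       # GPa
    nu: float
    fit: UnloadingFit | None = None
    flag: str = ""  # "" = usable, else reason ("uninterpretable", ...)

    @property
    def usable(self) -> bool:
        return self.flag == ""

    def summary(self) -> str:
        rows = [("P_max", f"{self.P_max:.3f} N"),
                ("h_max", f"{self.h_max:.3f} um"),
                ("S", f"{self.S:.4f} N/um"),
                ("h_c", f"{self.h_c:.3f} um"),
                ("A", f"{self.A:.5f} mm^2"),
                ("E_r", f"{self.E_r:.3f} GPa"),
                ("E", f"{self.E:.3f} GPa")]
        out = ["Spherical indentation (Oliver-Pharr)", "-" * 38]
        out += [f"{k:<6}: {v}" for k, v in rows]
        if self.flag:
            out.append(f"flag  : {self.flag}")
        return "\n".join(out)


def correct_compliance(record: LoadDisplacementRecord,
                       machine_compliance: float) -> LoadDisplacementRecord:
    """Remove the machine-frame contribution from measured displacements.

    ``machine_compliance`` is in mm/N; displacement' = displacement - c * P.
    """
    if machine_compliance < 0:
        raise ValueError("machine compliance must be non-negative")
    return LoadDisplacementRecord(
        record.time, record.load,
        record.displacement - machine_compliance * record.load,
        record.displacement2, record.segments, record.specimen_id)


def fit_unloading(record: LoadDisplacementRecord,
                  fit_fraction: tuple[float, float] = (0.5, 0.95),
                  min_points: int = 10) -> UnloadingFit:
    """Fit P = alpha (h - h_f)^m on the upper portion of the unloading curve.

    The fit window is the load band ``fit_fraction`` (fractions of P_max on
    the unloading segment; default 50-95% avoids both the peak-load creep
    shoulder and final-contact artefacts).  Bounded nonlinear least squares
    in (alpha, m, h_f); h_f is constrained below the smallest depth in the
    window and initialised from a linear extrapolation of the lowest
    unloading points.
    """
    if record.segments is not None and "unload" in set(record.segments):
        seg = record.segment("unload")
    else:
        seg = record
    if len(seg) < min_points:
        raise ValueError("unloading segment needs at least 10 points")
    P = seg.load
    h = seg.displacement * MM_TO_UM
    P_max = P.max()
    lo, hi = fit_fraction
    sel = (P >= lo * P_max) & (P <= hi * P_max)
    if sel.sum() < min_points:
        return UnloadingFit(np.nan, np.nan, np.nan, fit_fraction, np.nan,
                            converged=False)
    Pw, hw = P[sel], h[sel]

    # h_f initial guess: linear extrapolation of the low-load tail to P = 0.
    order = np.argsort(P)
    tail = order[:max(min_points, len(seg) // 5)]
    slope, intercept = np.polyfit(P[tail], h[tail], 1)
    hf0 = np.clip(intercept, 0.0, hw.min() * 0.999)
    m0 = 1.5
    a0 = P_max / max(hw.max() - hf0, 1e-9) ** m0

    def resid(x):
        la, m, hf = x
        return np.exp(la) * np.clip(hw - hf, 1e-12, None) ** m - Pw

    best = None
    for m_start in (m0, 1.2, 1.8):
        try:
            sol = least_squares(
                resid, [np.log(a0), m_start, hf0],
                bounds=([-30, 1.0, 0.0], [30, 4.0, hw.min() * 0.9999]))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return UnloadingFit(np.nan, np.nan, np.nan, fit_fraction, np.nan,
                            converged=False)
    la, m, hf = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return UnloadingFit(float(np.exp(la)), float(m), float(hf),
                        fit_fraction, rms)


def unloading_stiffness(fit: UnloadingFit, h_max: float) -> float:
    """Contact stiffness S = dP/dh at peak depth (N/um), from the fit."""
    return fit.alpha * fit.m * (h_max - fit.h_f) ** (fit.m - 1)


def contact_depth(h_max: float, h_f: float) -> float:
    """Spherical contact depth h_c = (h_max + h_f) / 2 (um)."""
    return 0.5 * (h_max + h_f)


def contact_area(radius_mm: float, h_c_um: float) -> float:
    """Spherical contact area A = 2 pi R h_c (mm^2)."""
    return 2 * np.pi * radius_mm * (h_c_um / MM_TO_UM)


def reduced_modulus(S: float, A: float) -> float:
    """Reduced modulus E_r = (sqrt(pi)/2) S / sqrt(A) (GPa).

    S in N/um, A in mm^2.
    """
    S_si = S * 1e6        # N/m
    A_si = A * 1e-6       # m^2
    return np.sqrt(np.pi) / 2 * S_si / np.sqrt(A_si) / 1e9


def sample_modulus(E_r: float, nu: float, tip: TipSpec) -> float:
    """Sample modulus from the reduced modulus and the tip constants (GPa)."""
    inv = 1.0 / E_r - (1 - tip.nu ** 2) / tip.E_gpa
    if inv <= 0:
        raise ValueError(
            "reduced modulus exceeds the rigid-tip bound: tip compliance "
            "alone cannot account for the measured contact stiffness")
    return (1 - nu ** 2) / inv


class SphericalIndentation:
    """Oliver-Pharr model for one spherical indentation record.

    Parameters
    ----------
    record : load-displacement trace with ``load``/``hold``/``unload``
        segment labels (or at minimum an unloading branch).
    tip : indenter tip constants (default: the sapphire study tip).
    nu : Poisson ratio assumed for the sample.
    machine_compliance : frame compliance, mm/N, subtracted first.
    drift_correction : estimate a thermal-drift rate from the final part of
        the hold segment and subtract it from unloading displacements.
    fit_fraction : load band of the unloading curve used for the power-law
        fit.
    """

    def __init__(self, record: LoadDisplacementRecord,
                 tip: TipSpec = SAPPHIRE_TIP, nu: float = BONE_POISSON,
                 machine_compliance: float = 0.0,
                 drift_correction: bool = False,
                 fit_fraction: tuple[float, float] = (0.5, 0.95)):
        self.record = correct_compliance(record, machine_compliance)
        self.tip = tip
        self.nu = nu
        self.drift_correction = drift_correction
        self.fit_fraction = fit_fraction

    def _drift_rate(self) -> float:
        """Drift rate (mm/s) from the final 30 s of the hold segment."""
        try:
            hold = self.record.segment("hold")
        except (ValueError, KeyError):
            return 0.0
        if len(hold) < 10:
            return 0.0
        t = hold.time
        sel = t >= t.max() - 30.0
        if sel.sum() < 5:
            sel = slice(None)
        return float(np.polyfit(t[sel], hold.displacement[sel], 1)[0])

    def fit(self) -> IndentationResult:
        rec = self.record
        if self.drift_correction:
            rate = self._drift_rate()
            if rate != 0.0 and rec.segments is not None:
                disp = rec.displacement.copy()
                m = rec.segments == "unload"
                t0 = rec.time[m].min() if m.any() else rec.time.max()
                disp[m] -= rate * (rec.time[m] - t0)
                rec = LoadDisplacementRecord(rec.time, rec.load, disp,
                                             rec.displacement2, rec.segments,
                                             rec.specimen_id)
        P_max = float(rec.load.max())
        h_max = float(rec.displacement.max()) * MM_TO_UM
        try:
            fit = fit_unloading(rec, self.fit_fraction)
        except ValueError as err:
            return IndentationResult(P_max, h_max, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, self.nu, None,
                                     flag=f"uninterpretable: {err}")
        if not fit.converged:
            return IndentationResult(P_max, h_max, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, self.nu, fit,
                                     flag="uninterpretable: fit failed")
        S = unloading_stiffness(fit, h_max)
        h_c = contact_depth(h_max, fit.h_f)
        A = contact_area(self.tip.radius_mm, h_c)
        E_r = reduced_modulus(S, A)
        try:
            E = sample_modulus(E_r, self.nu, self.tip)
        except ValueError as err:
            return IndentationResult(P_max, h_max, S, h_c, A, E_r, np.nan,
                                     self.nu, fit, flag=str(err))
        return IndentationResult(P_max, h_max, S, h_c, A, E_r, E, self.nu,
                                 fit)


@dataclass
class GridResult:
    """Per-indent results for a 4x4 grid plus the central-four summary."""

    results: list[IndentationResult]
    sample_modulus: float    # mean E of usable central indents, GPa
    central_indices: tuple[int, ...]
    n_central_used: int

    def summary(self) -> str:
        lines = ["4x4 indentation grid", "-" * 38]
        for i, r in enumerate(self.results):
            tag = "C" if i in self.central_indices else " "
            e = f"{r.E:6.2f}" if np.isfinite(r.E) else "  nan "
            lines.append(f"[{i:2d}]{tag} E = {e} GPa {r.flag}")
        lines.append(f"sample modulus (central mean, n={self.n_central_used})"
                     f" = {self.sample_modulus:.3f} GPa")
        return "\n".join(lines)


#: Row-major indices of the four central positions of a 4x4 grid.
CENTRAL_FOUR = (5, 6, 9, 10)

#: Grid spacing of the study protocol, um.
GRID_SPACING_UM = 200.0


def analyze_grid(records: list[LoadDisplacementRecord],
                 tip: TipSpec = SAPPHIRE_TIP, nu: float = BONE_POISSON,
                 **kwargs) -> GridResult:
    """Analyse 16 indents (row-major 4x4 grid) and summarise the sample.

    The sample modulus is the mean of the four central positions; indents
    flagged uninterpretable (e.g. pore strikes) are excluded from that mean.
    The peripheral twelve are analysed and retained but never enter the
    summary.
    """
    if len(records) != 16:
        raise ValueError("expected 16 indentation records (4x4 grid)")
    results = [SphericalIndentation(r, tip, nu, **kwargs).fit()
               for r in records]
    central = [results[i] for i in CENTRAL_FOUR]
    usable = [r.E for r in central if r.usable and np.isfinite(r.E)]
    if not usable:
        warnings.warn("no usable central indents; sample modulus undefined",
                      RuntimeWarning, stacklevel=2)
        mean_e = np.nan
    else:
        mean_e = float(np.mean(usable))
    return GridResult(results, mean_e, CENTRAL_FOUR, len(usable))
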