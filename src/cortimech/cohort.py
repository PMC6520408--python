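"""Synthetic cohort of femoral-neck cortical bone specimens.

Generates virtual 3 x 3 x 6 mm specimens whose ground truth carries the
statistical structure of the study population -- right-skewed cortical
porosity between 2.4% and 40%, and strictly monotone negative
porosity -> stiffness/strength coupling -- and synthesises the raw signal
every analysis stage consumes: spherical indentation and compression
load-displacement curves, through-transmission ultrasound pulses, resonance
spectra, micro-CT volumes with cylindrical vascular pores, and
calliper/mass readings.

Ground-truth links (configurable):

* modulus      E3 = E0 (1 - p)^k          (power-law stiffness-porosity law)
* strength     UCS = S0 (1 - p)^q
* density      rho = rho_tissue (1 - p) + rho_fluid p   (two-phase mixture)
* ash density  BMDA = ash_fraction * rho_tissue * (1 - p)
* full tensor  reference orthotropic bone tensor scaled so its E3 matches

One master seed drives everything; each specimen carries a deterministically
derived child seed, and each modality generator draws from an independent
stream of that child, so cohorts and signals are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .elastic import REFERENCE_CORTICAL, ElasticConstants
from .records import (CTVolume, DensityRecord, LoadDisplacementRecord,
                      ResonanceSpectrum, UltrasoundTrace)
from .indentation import SAPPHIRE_TIP, BONE_POISSON, TipSpec
from .rus import forward_frequencies

__all__ = [
    "CohortConfig",
    "VirtualSpecimen",
    "NoiseLevels",
    "IndentationProtocol",
    "generate_cohort",
    "synth_indentation_curve",
    "synth_indentation_grid",
    "synth_compression_curve",
    "synth_ultrasound_trace",
    "synth_ultrasound_repeats",
    "synth_rus_spectrum",
    "synth_ct_volume",
    "synth_density_record",
    "sample_pore_field",
    "rasterize_pore_field",
    "cohort_to_csv",
]

# per-modality RNG stream tags (mixed with the specimen child seed)
_STREAM = {"indent": 1, "compress": 2, "bwus": 3, "rus": 4, "ct": 5,
           "density": 6, "grid": 7}


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class NoiseLevels:
    """Per-modality noise magnitudes (all additive Gaussian unless noted)."""

    indent_disp_sd_um: float = 0.01     # indentation displacement noise
    indent_creep_um: float = 0.1        # hold-segment creep amplitude
    lvdt_sd_mm: float = 2e-4            # per-channel LVDT noise
    lvdt_tilt_mm_per_n: float = 2e-6    # antisymmetric channel perturbation
    trace_noise_sd: float = 1e-3        # ultrasound noise floor (amplitude 1)
    tof_jitter_rel: float = 0.005       # repositioning jitter on the TOF
    freq_noise_rel: float = 0.003       # multiplicative resonance noise
    mode_dropout: float = 0.1           # probability a mode goes undetected
    ct_noise_sd: float = 10.0           # grayscale noise (bone 200, pore 50)
    calliper_sd_mm: float = 0.02
    mass_sd_mg: float = 0.2
    heterogeneity_rel: float = 0.10     # within-sample modulus scatter (grid)

    @classmethod
    def zero(cls) -> "NoiseLevels":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generator settings.

    Porosity is drawn from a log-normal truncated to ``porosity_range``
    (median ``porosity_median``), reproducing the right-skewed study
    distribution in which a single highly porous, trabecularised specimen
    can appear.
    """

    n_specimens: int = 20
    porosity_range: tuple[float, float] = (0.024, 0.40)
    porosity_median: float = 0.093
    porosity_log_sd: float = 0.8
    tissue_modulus_E0: float = 23.0      # GPa
    porosity_exponent_k: float = 1.9
    strength_scale_S0: float = 160.0     # MPa
    strength_exponent_q: float = 2.1
    rho_tissue: float = 2.0              # mg/mm^3
    rho_fluid: float = 1.0               # mg/mm^3
    ash_fraction: float = 0.55           # ash mass / tissue mass
    dims_mm: tuple[float, float, float] = (3.0, 3.0, 6.0)
    dim_jitter_sd_mm: float = 0.02       # sample-cutting tolerance
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    seed: int = 0

    def __post_init__(self):
        low, high = self.porosity_range
        if not (0 <= low < high < 1):
            raise ConfigurationError("need 0 <= low < high < 1 for porosity")
        if not (low < self.porosity_median < high):
            raise ConfigurationError("porosity_median must lie in the range")
        for name in ("tissue_modulus_E0", "strength_scale_S0", "rho_tissue",
                     "rho_fluid", "ash_fraction", "porosity_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_specimens < 1:
            raise ConfigurationError("need at least one specimen")
        if any(d <= 0 for d in self.dims_mm):
            raise ConfigurationError("dimensions must be positive")


@dataclass(frozen=True)
class VirtualSpecimen:
    """Ground-truth description of one virtual specimen."""

    id: str
    dims_mm: tuple[float, float, float]
    porosity_true: float
    E3_true: float                 # GPa
    C33_true: float                # GPa
    Cij_true: ElasticConstants
    ucs_true: float                # MPa
    rho_true: float                # mg/mm^3
    ash_density_true: float        # mg/mm^3
    seed: int

    def __post_init__(self):
        if not 0 <= self.porosity_true <= 0.5:
            raise ValueError("porosity_true must lie in [0, 0.5]")
        if any(d <= 0 for d in self.dims_mm):
            raise ValueError("dimensions must be positive")
        if not self.Cij_true.is_positive_definite():
            raise ValueError("Cij_true must be positive-definite")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def _specimen_from_porosity(config: CohortConfig, i: int, p: float,
                            dims: tuple[float, float, float],
                            seed: int) -> VirtualSpecimen:
    E3 = config.tissue_modulus_E0 * (1 - p) ** config.porosity_exponent_k
    scale = E3 / REFERENCE_CORTICAL.E3
    cij = REFERENCE_CORTICAL.scaled(scale)
    return VirtualSpecimen(
        id=f"S{i + 1:02d}",
        dims_mm=dims,
        porosity_true=p,
        E3_true=E3,
        C33_true=cij.c33,
        Cij_true=cij,
        ucs_true=config.strength_scale_S0 * (1 - p) ** config.strength_exponent_q,
        rho_true=config.rho_tissue * (1 - p) + config.rho_fluid * p,
        ash_density_true=config.ash_fraction * config.rho_tissue * (1 - p),
        seed=seed,
    )


def generate_cohort(config: CohortConfig) -> list[VirtualSpecimen]:
    """Draw a reproducible cohort of virtual specimens."""
    rng = np.random.default_rng(config.seed)
    low, high = config.porosity_range
    mu, sd = np.log(config.porosity_median), config.porosity_log_sd
    a = (np.log(low) - mu) / sd
    b = (np.log(high) - mu) / sd
    logp = truncnorm.rvs(a, b, loc=mu, scale=sd,
                         size=config.n_specimens, random_state=rng)
    porosities = np.exp(logp)
    children = np.random.SeedSequence(config.seed).spawn(config.n_specimens)
    specimens = []
    for i, p in enumerate(porosities):
        dims = tuple(np.asarray(config.dims_mm)
                     + config.dim_jitter_sd_mm * rng.standard_normal(3))
        child_seed = int(children[i].generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        specimens.append(_specimen_from_porosity(config, i, float(p),
                                                 dims, child_seed))
    return specimens


# ---------------------------------------------------------------------------
# spherical indentation


@dataclass(frozen=True)
class IndentationProtocol:
    """Loading programme of the depth-sensing indentation machine."""

    preload_n: float = 2e-4       # tip-engagement preload
    load_rate_n_s: float = 0.1
    peak_n: float = 10.0
    hold_s: float = 60.0
    unload_rate_n_s: float = 0.3
    sample_hz: float = 10.0
    tip: TipSpec = SAPPHIRE_TIP


def _reduced_modulus_nmm2(E_gpa: float, nu: float, tip: TipSpec) -> float:
    inv = (1 - nu ** 2) / E_gpa + (1 - tip.nu ** 2) / tip.E_gpa
    return 1e3 / inv  # N/mm^2


def synth_indentation_curve(spec: VirtualSpecimen,
                            protocol: IndentationProtocol = IndentationProtocol(),
                            noise: NoiseLevels | None = None,
                            modulus_gpa: float | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> LoadDisplacementRecord:
    """Hertzian load-displacement curve with hold creep and noise.

    The loading branch follows P = (4/3) E* sqrt(R) h^(3/2); the hold adds
    logarithmic creep; unloading is elastic from the crept depth, i.e. a
    power law P = alpha (h - h_f)^(3/2) with h_f equal to the accumulated
    creep.  With zero creep and zero noise the unloading branch exactly
    retraces the loading power law (h_f = 0).
    """
    noise = spec_noise(spec, noise)
    rng = rng if rng is not None else spec.rng("indent")
    E = modulus_gpa if modulus_gpa is not None else spec.E3_true
    if E <= 0:
        raise ValueError("sample modulus must be positive")
    tip = protocol.tip
    k = (4.0 / 3.0) * _reduced_modulus_nmm2(E, BONE_POISSON, tip) \
        * np.sqrt(tip.radius_mm)                     # N / mm^(3/2)

    dt = 1.0 / protocol.sample_hz
    # loading: preload -> peak
    t_load = (protocol.peak_n - protocol.preload_n) / protocol.load_rate_n_s
    t1 = np.append(np.arange(0.0, t_load, dt), t_load)  # end exactly at peak
    P1 = protocol.preload_n + protocol.load_rate_n_s * t1
    h1 = (P1 / k) ** (2.0 / 3.0)
    # hold with logarithmic creep
    tau = 5.0
    t2 = np.arange(dt, protocol.hold_s + dt / 2, dt)
    creep_mm = noise.indent_creep_um * 1e-3
    creep = creep_mm * np.log1p(t2 / tau) / np.log1p(protocol.hold_s / tau)
    P2 = np.full(t2.size, protocol.peak_n)
    h2 = h1[-1] + creep
    h_f = creep[-1] if t2.size else 0.0
    # elastic unload from the crept depth
    t_unl = protocol.peak_n / protocol.unload_rate_n_s
    t3 = np.arange(dt, t_unl + dt / 2, dt)
    P3 = np.clip(protocol.peak_n - protocol.unload_rate_n_s * t3, 0.0, None)
    h3 = h_f + (P3 / k) ** (2.0 / 3.0)

    t = np.concatenate([t1, t1[-1] + t2, t1[-1] + protocol.hold_s + t3])
    P = np.concatenate([P1, P2, P3])
    h = np.concatenate([h1, h2, h3])
    seg = np.concatenate([np.full(t1.size, "load", dtype=object),
                          np.full(t2.size, "hold", dtype=object),
                          np.full(t3.size, "unload", dtype=object)])
    if noise.indent_disp_sd_um > 0:
        h = h + rng.normal(0.0, noise.indent_disp_sd_um * 1e-3, h.size)
    return LoadDisplacementRecord(t, P, h, segments=seg,
                                  specimen_id=spec.id)


def synth_indentation_grid(spec: VirtualSpecimen,
                           protocol: IndentationProtocol = IndentationProtocol(),
                           noise: NoiseLevels | None = None,
                           ) -> list[LoadDisplacementRecord]:
    """Sixteen grid indents with within-sample modulus heterogeneity."""
    noise = spec_noise(spec, noise)
    rng = spec.rng("grid")
    records = []
    for _ in range(16):
        local_E = spec.E3_true * max(
            1.0 + noise.heterogeneity_rel * rng.standard_normal(), 0.05)
        records.append(synth_indentation_curve(
            spec, protocol, noise, modulus_gpa=local_E, rng=rng))
    return records


def spec_noise(spec: VirtualSpecimen,
               noise: NoiseLevels | None) -> NoiseLevels:
    return noise if noise is not None else NoiseLevels()


# ---------------------------------------------------------------------------
# compression


def synth_compression_curve(spec: VirtualSpecimen,
                            noise: NoiseLevels | None = None,
                            n_points: int = 2000,
                            ) -> LoadDisplacementRecord:
    """Compression-to-failure record with two LVDT channels.

    Stress-strain shape: quadratic toe to 0.2% strain, linear region of
    slope E3_true, parabolic hardening to the peak at ucs_true, then linear
    post-peak softening.  Ten preconditioning displacement cycles precede
    the final ramp.  The two displacement channels are the true displacement
    plus/minus a load-proportional antisymmetric perturbation (platen tilt)
    plus independent noise.
    """
    noise = spec_noise(spec, noise)
    rng = spec.rng("compress")
    w1, w2, L = spec.dims_mm
    area = w1 * w2
    E = spec.E3_true * 1e3           # MPa
    ucs = spec.ucs_true
    eps0 = 0.002
    sig0 = E * eps0 / 2.0
    sig_y = 0.8 * ucs
    if sig_y <= sig0:
        raise ValueError("specimen too weak for the assumed curve shape")
    eps_y = eps0 + (sig_y - sig0) / E
    eps_u = eps_y + 2.0 * (ucs - sig_y) / E
    eps_end = eps_u + 0.004

    def stress(eps):
        s = np.empty_like(eps)
        toe = eps < eps0
        s[toe] = E * eps[toe] ** 2 / (2 * eps0)
        lin = (eps >= eps0) & (eps < eps_y)
        s[lin] = sig0 + E * (eps[lin] - eps0)
        hard = (eps >= eps_y) & (eps <= eps_u)
        s[hard] = ucs - (ucs - sig_y) * ((eps_u - eps[hard]) / (eps_u - eps_y)) ** 2
        soft = eps > eps_u
        s[soft] = ucs - 0.1 * E * (eps[soft] - eps_u)
        return s

    eps = np.linspace(0.0, eps_end, n_points)
    eps[np.argmin(np.abs(eps - eps_u))] = eps_u  # grid hits the peak exactly
    sig = stress(eps)
    disp = eps * L
    load = sig * area
    rate_mm_s = 0.03  # 1.8 mm/min displacement rate
    t_ramp = disp / rate_mm_s

    # preconditioning: initial ramp to 0.01 mm then 10 cycles at 0.5 Hz
    fs = 100.0
    t_pre = np.arange(0.0, 1.0 / 3.0, 1.0 / fs)
    d_pre_ramp = rate_mm_s * t_pre
    t_cyc = np.arange(0.0, 20.0, 1.0 / fs)
    d_cyc = 0.005 * (1 - np.cos(2 * np.pi * 0.5 * t_cyc)) + 0.0
    d_pre = np.concatenate([d_pre_ramp, 0.01 - d_cyc])
    t_pre_all = np.concatenate([t_pre, t_pre[-1] + 1.0 / fs + t_cyc])
    # small-strain elastic response during preconditioning
    load_pre = stress(np.clip(d_pre / L, 0, None)) * area

    t = np.concatenate([t_pre_all, t_pre_all[-1] + 1.0 + t_ramp])
    d_true = np.concatenate([d_pre, disp])
    load_all = np.concatenate([load_pre, load])
    seg = np.concatenate([np.full(t_pre_all.size, "precondition", dtype=object),
                          np.full(eps.size, "ramp", dtype=object)])
    tilt = noise.lvdt_tilt_mm_per_n * load_all
    ch1 = d_true + tilt
    ch2 = d_true - tilt
    if noise.lvdt_sd_mm > 0:
        ch1 = ch1 + rng.normal(0, noise.lvdt_sd_mm, ch1.size)
        ch2 = ch2 + rng.normal(0, noise.lvdt_sd_mm, ch2.size)
    return LoadDisplacementRecord(t, load_all, ch1, displacement2=ch2,
                                  segments=seg, specimen_id=spec.id)


# ---------------------------------------------------------------------------
# bulk-wave ultrasound


def synth_ultrasound_trace(spec: VirtualSpecimen,
                           sampling_rate: float = 100e6,
                           noise: NoiseLevels | None = None,
                           tof_s: float | None = None,
                           rng: np.random.Generator | None = None,
                           centre_frequency: float = 5e6,
                           ) -> UltrasoundTrace:
    """Received pulse: quiet noise floor, then a Gabor pulse at the TOF.

    The arrival time is L3 / sqrt(C33 / rho) in SI units.  The pulse is a
    Gaussian-windowed 5 MHz tone truncated three envelope widths before its
    centre, so with zero noise the first nonzero sample marks the arrival.
    """
    noise = spec_noise(spec, noise)
    rng = rng if rng is not None else spec.rng("bwus")
    if tof_s is None:
        v = np.sqrt(spec.C33_true * 1e9 / (spec.rho_true * 1000.0))
        tof_s = spec.dims_mm[2] * 1e-3 / v
    duration = 2.5 * tof_s + 1e-6
    n = max(int(np.ceil(duration * sampling_rate)), 64)
    t = np.arange(n) / sampling_rate
    sigma = 0.15e-6
    centre = tof_s + 3 * sigma
    s = np.where(
        t >= tof_s,
        np.exp(-0.5 * ((t - centre) / sigma) ** 2)
        * np.cos(2 * np.pi * centre_frequency * (t - tof_s)),
        0.0)
    if noise.trace_noise_sd > 0:
        s = s + rng.normal(0.0, noise.trace_noise_sd, n)
    return UltrasoundTrace(s, sampling_rate, axis=3, specimen_id=spec.id)


def synth_ultrasound_repeats(spec: VirtualSpecimen, n_repeats: int = 6,
                             sampling_rate: float = 100e6,
                             noise: NoiseLevels | None = None,
                             ) -> list[UltrasoundTrace]:
    """Six repositioned measurements: TOF jittered by the configured sd."""
    noise = spec_noise(spec, noise)
    rng = spec.rng("bwus")
    v = np.sqrt(spec.C33_true * 1e9 / (spec.rho_true * 1000.0))
    tof = spec.dims_mm[2] * 1e-3 / v
    traces = []
    for _ in range(n_repeats):
        jit = tof * (1.0 + noise.tof_jitter_rel * rng.standard_normal())
        traces.append(synth_ultrasound_trace(spec, sampling_rate, noise,
                                             tof_s=jit, rng=rng))
    return traces


# ---------------------------------------------------------------------------
# resonant ultrasound spectroscopy


def synth_rus_spectrum(spec: VirtualSpecimen, n_modes: int = 24,
                       noise: NoiseLevels | None = None,
                       basis_order: int = 6,
                       ) -> ResonanceSpectrum:
    """Measured resonance spectrum: forward model + noise + mode dropout.

    Multiplicative Gaussian noise perturbs each frequency; each mode is
    independently dropped with the configured probability, emulating peaks
    undetected in the damped measured response.  Order is preserved.
    """
    noise = spec_noise(spec, noise)
    rng = spec.rng("rus")
    f = forward_frequencies(spec.Cij_true, spec.rho_true, spec.dims_mm,
                            basis_order, n_modes).frequencies
    if noise.freq_noise_rel > 0:
        f = np.sort(f * (1.0 + noise.freq_noise_rel
                         * rng.standard_normal(f.size)))
    if noise.mode_dropout > 0:
        keep = rng.random(f.size) >= noise.mode_dropout
        if keep.sum() < 2:
            keep[:] = True
        f = f[keep]
    return ResonanceSpectrum(f, specimen_id=spec.id)


# ---------------------------------------------------------------------------
# micro-CT


def sample_pore_field(target_porosity: float, region_um: tuple[float, float],
                      rng: np.random.Generator,
                      eval_voxel_um: float = 7.0,
                      diameter_mean_um: float = 36.5,
                      diameter_sd_um: float = 6.0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous transverse pore field: circle centres (um) and radii (um).

    Straight axis-3-aligned cylinders reduce to circles in the transverse
    plane.  Haversian-canal diameters are drawn around 29-44 um.  Circles
    are added (overlaps unioned) until the rasterised solid/pore fraction
    at ``eval_voxel_um`` reaches the target.  Centres may fall slightly
    outside the region so edge-clipped canals carry no bias.
    """
    if not 0 <= target_porosity < 1:
        raise ValueError("target porosity must lie in [0, 1)")
    lx, ly = region_um
    centres, radii = [], []
    if target_porosity == 0:
        return np.empty((0, 2)), np.empty(0)
    margin = diameter_mean_um
    nx = max(int(round(lx / eval_voxel_um)), 1)
    ny = max(int(round(ly / eval_voxel_um)), 1)
    occ = np.zeros((nx, ny), dtype=bool)
    xs = (np.arange(nx) + 0.5) * eval_voxel_um
    ys = (np.arange(ny) + 0.5) * eval_voxel_um
    frac = 0.0
    max_pores = 100000
    while frac < target_porosity and len(radii) < max_pores:
        cx = rng.uniform(-margin, lx + margin)
        cy = rng.uniform(-margin, ly + margin)
        d = np.clip(rng.normal(diameter_mean_um, diameter_sd_um), 15.0, 80.0)
        r = d / 2.0
        centres.append((cx, cy))
        radii.append(r)
        i0, i1 = np.searchsorted(xs, [cx - r, cx + r])
        j0, j1 = np.searchsorted(ys, [cy - r, cy + r])
        if i1 > i0 and j1 > j0:
            dx = xs[i0:i1, None] - cx
            dy = ys[None, j0:j1] - cy
            occ[i0:i1, j0:j1] |= dx ** 2 + dy ** 2 <= r ** 2
            frac = occ.mean()
    return np.array(centres), np.array(radii)


def rasterize_pore_field(centres: np.ndarray, radii: np.ndarray,
                         region_um: tuple[float, float],
                         voxel_size_um: float) -> np.ndarray:
    """Transverse boolean pore mask of the continuous field at a voxel size."""
    lx, ly = region_um
    nx = max(int(round(lx / voxel_size_um)), 1)
    ny = max(int(round(ly / voxel_size_um)), 1)
    xs = (np.arange(nx) + 0.5) * voxel_size_um
    ys = (np.arange(ny) + 0.5) * voxel_size_um
    mask = np.zeros((nx, ny), dtype=bool)
    for (cx, cy), r in zip(centres, radii):
        i0, i1 = np.searchsorted(xs, [cx - r, cx + r])
        j0, j1 = np.searchsorted(ys, [cy - r, cy + r])
        if i1 > i0 and j1 > j0:
            dx = xs[i0:i1, None] - cx
            dy = ys[None, j0:j1] - cy
            mask[i0:i1, j0:j1] |= dx ** 2 + dy ** 2 <= r ** 2
    return mask


BONE_GRAY = 200.0
PORE_GRAY = 50.0


def synth_ct_volume(spec: VirtualSpecimen, voxel_size_um: float = 7.0,
                    region_mm: tuple[float, float, float] = (0.896, 0.896, 0.448),
                    noise: NoiseLevels | None = None,
                    target_porosity: float | None = None,
                    ) -> CTVolume:
    """Grayscale micro-CT volume with axis-3-aligned cylindrical pores.

    ``region_mm`` is the imaged sub-block (transverse x, y, longitudinal z);
    the default keeps volumes small while leaving the porosity estimate
    unbiased, since the canal field is statistically uniform in the
    transverse plane.  The achieved (rasterised, pre-noise) pore fraction is
    recorded in ``true_pore_mask``.  The voxel size should be at most half
    the smallest canal diameter to resolve it (7 um vs ~29 um is ample).
    """
    noise = spec_noise(spec, noise)
    target = spec.porosity_true if target_porosity is None else target_porosity
    min_diam = 15.0
    if voxel_size_um > min_diam / 2:
        raise ValueError("voxel size too coarse to resolve the smallest pores")
    rng = spec.rng("ct")
    lx, ly, lz = (r * 1e3 for r in region_mm)
    centres, radii = sample_pore_field(target, (lx, ly), rng,
                                       eval_voxel_um=voxel_size_um)
    mask2d = rasterize_pore_field(centres, radii, (lx, ly), voxel_size_um)
    nz = max(int(round(lz / voxel_size_um)), 1)
    pores3d = np.repeat(mask2d[:, :, None], nz, axis=2)
    gray = np.where(pores3d, PORE_GRAY, BONE_GRAY)
    if noise.ct_noise_sd > 0:
        gray = gray + rng.normal(0.0, noise.ct_noise_sd, gray.shape)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return CTVolume(gray, voxel_size_um, specimen_id=spec.id,
                    true_pore_mask=pores3d)


# ---------------------------------------------------------------------------
# densitometry


def synth_density_record(spec: VirtualSpecimen,
                         noise: NoiseLevels | None = None) -> DensityRecord:
    """Calliper, mass and ash readings consistent with the ground truth."""
    noise = spec_noise(spec, noise)
    rng = spec.rng("density")
    dims = np.asarray(spec.dims_mm)
    calliper = dims[:, None] + rng.normal(0, noise.calliper_sd_mm, (3, 4)) \
        if noise.calliper_sd_mm > 0 else np.tile(dims[:, None], (1, 4))
    volume = float(np.prod(dims))
    mass = spec.rho_true * volume
    masses = mass + rng.normal(0, noise.mass_sd_mg, 8) \
        if noise.mass_sd_mg > 0 else np.full(8, mass)
    ash = spec.ash_density_true * volume
    if noise.mass_sd_mg > 0:
        ash = ash + rng.normal(0, noise.mass_sd_mg)
    return DensityRecord(calliper, masses, ash, specimen_id=spec.id)


# ---------------------------------------------------------------------------
# cohort I/O


def cohort_to_csv(specimens: list[VirtualSpecimen], path: str | Path) -> None:
    """One row per specimen; ground-truth columns prefixed ``true_``."""
    rows = []
    for s in specimens:
        rows.append({
            "specimen_id": s.id,
            "true_dim1_mm": s.dims_mm[0],
            "true_dim2_mm": s.dims_mm[1],
            "true_dim3_mm": s.dims_mm[2],
            "true_porosity": s.porosity_true,
            "true_E3_gpa": s.E3_true,
            "true_C33_gpa": s.C33_true,
            "true_ucs_mpa": s.ucs_true,
            "true_rho_mgmm3": s.rho_true,
            "true_ash_density_mgmm3": s.ash_density_true,
            "seed": s.seed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
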