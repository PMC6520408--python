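"""End-to-end study pipeline: simulate -> analyse -> assemble -> statistics.

``run_study`` executes the full measurement chain on a synthetic cohort in
the study's stage order (density, RUS, BWUS, CT, indentation, compression,
ashing, statistics), producing the per-specimen cohort table, the
correlation/regression report and a reproducibility manifest.  A stage
failure for one specimen is logged and recorded as a missing value, never
a crash; the RUS column may hold fewer values than the cohort size because
highly porous specimens are gated out (the vibrational model assumes a
homogeneous material).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CohortConfig, VirtualSpecimen, generate_cohort,
                     synth_compression_curve, synth_ct_volume,
                     synth_density_record, synth_indentation_grid,
                     synth_rus_spectrum, synth_ultrasound_repeats,
                     cohort_to_csv)
from .compression import CompressionTest
from .ct import porosity, segment_pores
from .density import ash_density, mass_density
from .elastic import REFERENCE_CORTICAL
from .indentation import analyze_grid
from .rus import RusInversion, RusPrior, homogeneity_gate
from .stats import CorrelationStudy, CorrelationStudyResults
from .ultrasound import analyze_traces

__all__ = ["StudyConfig", "StudyResult", "run_study",
           "quick_measurement_table"]


@dataclass(frozen=True)
class StudyConfig:
    """Settings of one reproducible study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    porosity_gate: float = 0.35      # RUS eligibility cutoff (fraction)
    rus_basis_order: int = 6
    rus_n_modes: int = 24
    rus_prior_rel_sd: float = 0.35
    ct_voxel_um: float = 7.0
    ct_region_mm: tuple[float, float, float] = (0.896, 0.896, 0.448)
    run_rus: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    table: pd.DataFrame
    report: CorrelationStudyResults
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "cohort.csv", index=False)
        (out / "report.txt").write_text(self.report.summary() + "\n")
        self.report.table_summary.to_csv(out / "summary.csv")
        self.report.full_cohort.r.to_csv(out / "correlations.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, default=str))


def _measure_specimen(spec: VirtualSpecimen, config: StudyConfig,
                      log: list) -> dict:
    """All eight measurements for one specimen; failures become NaN."""
    row: dict = {"specimen_id": spec.id}
    timings: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:  # logged missing value, not a crash
            log.append(f"{spec.id}/{name}: {err}")
            warnings.warn(f"{spec.id}: {name} stage failed ({err})",
                          RuntimeWarning, stacklevel=3)
        timings[name] = time.perf_counter() - t0

    # densitometry (wet mass before/after RUS, ashing later in protocol)
    density_record = synth_density_record(spec, config.cohort.noise)

    def density_stage():
        row["density"] = mass_density(density_record)
    stage("density", density_stage)

    # micro-CT porosity (needed for the RUS homogeneity gate)
    def ct_stage():
        vol = synth_ct_volume(spec, config.ct_voxel_um, config.ct_region_mm,
                              config.cohort.noise)
        mask, thr = segment_pores(vol)
        row["ct_porosity"] = 100.0 * porosity(
            mask, vol.sample_mask, vol.voxel_size, thr, "otsu").porosity
    stage("ct", ct_stage)

    # resonant ultrasound spectroscopy (gated on measured porosity)
    def rus_stage():
        por_frac = row.get("ct_porosity", np.nan) / 100.0
        if not config.run_rus:
            row["rus_E3"] = np.nan
            return
        if np.isfinite(por_frac) and not homogeneity_gate(
                por_frac, config.porosity_gate):
            log.append(f"{spec.id}/rus: gated out (porosity "
                       f"{100 * por_frac:.1f}% > "
                       f"{100 * config.porosity_gate:.0f}%)")
            row["rus_E3"] = np.nan
            return
        spectrum = synth_rus_spectrum(spec, config.rus_n_modes,
                                      config.cohort.noise,
                                      config.rus_basis_order)
        prior = RusPrior.from_relative(REFERENCE_CORTICAL,
                                       config.rus_prior_rel_sd)
        rho = row.get("density", spec.rho_true)
        fit = RusInversion(spectrum, rho, spec.dims_mm, prior,
                           basis_order=config.rus_basis_order).fit()
        row["rus_E3"] = fit.E3 if fit.converged else np.nan
    stage("rus", rus_stage)

    # bulk-wave ultrasound
    def bwus_stage():
        traces = synth_ultrasound_repeats(spec, noise=config.cohort.noise)
        rho = row.get("density", spec.rho_true)
        row["bwus_C33"] = analyze_traces(traces, spec.dims_mm[2], rho).c_gpa
    stage("bwus", bwus_stage)

    # spherical indentation (16-indent grid, central-four mean)
    def indentation_stage():
        grid = analyze_grid(synth_indentation_grid(spec,
                                                   noise=config.cohort.noise))
        row["indentation_E"] = grid.sample_modulus
    stage("indentation", indentation_stage)

    # compression to failure
    def compression_stage():
        rec = synth_compression_curve(spec, config.cohort.noise)
        fit = CompressionTest(rec, spec.dims_mm).fit()
        row["compression_E"] = fit.caem
        row["ucs"] = fit.ucs
    stage("compression", compression_stage)

    # ashing
    def ashing_stage():
        row["bmda"] = ash_density(density_record)
    stage("ashing", ashing_stage)

    row["_timings"] = timings
    return row


def run_study(config: StudyConfig | None = None,
              out_dir: str | Path | None = None) -> StudyResult:
    """Run the whole chain; identical config and seed give identical output."""
    config = config or StudyConfig()
    t_start = time.perf_counter()
    log: list[str] = []
    specimens = generate_cohort(config.cohort)
    rows = []
    stage_time: dict[str, float] = {}
    for spec in specimens:
        row = _measure_specimen(spec, config, log)
        for k, v in row.pop("_timings").items():
            stage_time[k] = stage_time.get(k, 0.0) + v
        for truth_col, value in [("true_porosity", spec.porosity_true),
                                 ("true_E3_gpa", spec.E3_true),
                                 ("true_C33_gpa", spec.C33_true),
                                 ("true_ucs_mpa", spec.ucs_true),
                                 ("true_rho_mgmm3", spec.rho_true)]:
            row[truth_col] = value
        rows.append(row)
    table = pd.DataFrame(rows)
    report = CorrelationStudy(table,
                              porosity_cutoff=config.porosity_gate).fit()
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "n_specimens": config.cohort.n_specimens,
        "rus_n": int(table["rus_E3"].notna().sum()),
        "stage_seconds": {k: round(v, 3) for k, v in stage_time.items()},
        "total_seconds": round(time.perf_counter() - t_start, 3),
        "warnings": log,
        "defaults_in_effect": {
            "porosity_gate": config.porosity_gate,
            "rus_basis_order": config.rus_basis_order,
            "ct_voxel_um": config.ct_voxel_um,
            "ct_region_mm": config.ct_region_mm,
        },
    }
    result = StudyResult(table, report, manifest)
    if out_dir is not None:
        result.write(out_dir)
        cohort_to_csv(specimens, Path(out_dir) / "ground_truth.csv")
        manifest["files"] = sorted(p.name for p in Path(out_dir).iterdir())
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
    return result


#: Relative measurement error assigned per column by the quick table
#: builder (statistics-stage fixture; the full chain is `run_study`).
_QUICK_NOISE = {"density": 0.005, "ct_porosity": 0.02, "rus_E3": 0.015,
                "bwus_C33": 0.01, "indentation_E": 0.08,
                "compression_E": 0.03, "ucs": 0.02, "bmda": 0.02}


def quick_measurement_table(specimens: list[VirtualSpecimen],
                            seed: int = 0,
                            porosity_gate: float = 0.35) -> pd.DataFrame:
    """Cohort table from ground truth plus per-column measurement error.

    A fast stand-in for the full per-signal chain, used by the statistics
    stage when only the cohort-level correlation structure matters: each
    measured value is the specimen's ground truth perturbed by the typical
    relative error of its modality.  The RUS gate is still applied.
    """
    rng = np.random.default_rng(seed)

    def noisy(value, col):
        return value * (1.0 + _QUICK_NOISE[col] * rng.standard_normal())

    rows = []
    for s in specimens:
        row = {
            "specimen_id": s.id,
            "density": noisy(s.rho_true, "density"),
            "ct_porosity": 100.0 * noisy(s.porosity_true, "ct_porosity"),
            "rus_E3": (noisy(s.E3_true, "rus_E3")
                       if homogeneity_gate(s.porosity_true, porosity_gate)
                       else np.nan),
            "bwus_C33": noisy(s.C33_true, "bwus_C33"),
            "indentation_E": noisy(s.E3_true, "indentation_E"),
            "compression_E": noisy(s.E3_true, "compression_E"),
            "ucs": noisy(s.ucs_true, "ucs"),
            "bmda": noisy(s.ash_density_true, "bmda"),
        }
        rows.append(row)
    return pd.DataFrame(rows)
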