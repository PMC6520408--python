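"""Generator contracts: determinism, ground-truth links, signal shapes."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cortimech.cohort import (CohortConfig, ConfigurationError, NoiseLevels,
                              generate_cohort, rasterize_pore_field,
                              sample_pore_field, synth_compression_curve,
                              synth_ct_volume, synth_indentation_curve,
                              synth_rus_spectrum, synth_ultrasound_repeats,
                              synth_ultrasound_trace, cohort_to_csv,
                              _specimen_from_porosity)
from cortimech.rus import forward_frequencies


def test_same_seed_identical_cohort_different_seed_differs():
    a = generate_cohort(CohortConfig(seed=5))
    b = generate_cohort(CohortConfig(seed=5))
    c = generate_cohort(CohortConfig(seed=6))
    assert [s.porosity_true for s in a] == [s.porosity_true for s in b]
    assert [s.dims_mm for s in a] == [s.dims_mm for s in b]
    assert [s.porosity_true for s in a] != [s.porosity_true for s in c]


def test_porosities_within_configured_range(default_cohort):
    for s in default_cohort:
        assert 0.024 <= s.porosity_true <= 0.40


def test_zero_porosity_limit():
    cfg = CohortConfig()
    s = _specimen_from_porosity(cfg, 0, 0.0, (3.0, 3.0, 6.0), seed=1)
    assert s.E3_true == pytest.approx(cfg.tissue_modulus_E0)
    assert s.rho_true == pytest.approx(cfg.rho_tissue)
    assert s.ucs_true == pytest.approx(cfg.strength_scale_S0)


def test_porosity_modulus_link_strictly_monotone(default_cohort):
    p = [s.porosity_true for s in default_cohort]
    e = [s.E3_true for s in default_cohort]
    u = [s.ucs_true for s in default_cohort]
    assert spearmanr(p, e).statistic == pytest.approx(-1.0)
    assert spearmanr(p, u).statistic == pytest.approx(-1.0)


def test_invalid_configuration_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(porosity_range=(0.5, 0.2))
    with pytest.raises(ConfigurationError):
        CohortConfig(porosity_range=(0.0, 1.2))
    with pytest.raises(ConfigurationError):
        CohortConfig(tissue_modulus_E0=-3.0)


def test_cohort_csv_has_true_prefixed_columns(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    cohort_to_csv(default_cohort, path)
    import pandas as pd
    df = pd.read_csv(path)
    assert df.shape[0] == len(default_cohort)
    truth_cols = [c for c in df.columns if c.startswith("true_")]
    assert "true_porosity" in truth_cols and "true_E3_gpa" in truth_cols


# -- indentation synthesis --------------------------------------------------


def test_indentation_preload_is_first_recorded_point(specimen, zero_noise):
    rec = synth_indentation_curve(specimen, noise=zero_noise)
    assert rec.load[0] == pytest.approx(2e-4)


def test_indentation_elastic_reversibility(specimen, zero_noise):
    """No creep, no noise: unloading retraces the loading power law."""
    noise = NoiseLevels.zero()
    rec = synth_indentation_curve(specimen, noise=noise)
    load_seg = rec.segment("load")
    unload_seg = rec.segment("unload")
    # interpolate the loading branch at the unloading loads (above the
    # strongly curved low-load toe, where linear interpolation is exact
    # to well under a nanometre)
    order = np.argsort(load_seg.load)
    sel = unload_seg.load >= 0.5
    h_interp = np.interp(unload_seg.load[sel], load_seg.load[order],
                         load_seg.displacement[order])
    assert np.allclose(h_interp, unload_seg.displacement[sel], atol=1e-8)


def test_indentation_peak_matches_hertz_closed_form(zero_noise):
    """6 GPa specimen, sapphire 3-mm tip, 10 N: closed-form Hertz approach."""
    cfg = CohortConfig()
    s = _specimen_from_porosity(cfg, 0, 0.0, (3.0, 3.0, 6.0), seed=1)
    rec = synth_indentation_curve(s, noise=zero_noise, modulus_gpa=6.0)
    e_star = 1.0 / ((1 - 0.33 ** 2) / 6.0 + (1 - 0.24 ** 2) / 420.0)  # GPa
    delta_mm = (9 * 10.0 ** 2 / (16 * 3.0 * (e_star * 1e3) ** 2)) ** (1 / 3)
    assert rec.displacement.max() == pytest.approx(delta_mm, rel=1e-6)
    # the half-space value for these constants is ~7.5 um
    assert rec.displacement.max() * 1e3 == pytest.approx(7.53, abs=0.05)


# -- compression synthesis --------------------------------------------------


def test_compression_peak_load_is_ucs_times_area(specimen, zero_noise):
    rec = synth_compression_curve(specimen, noise=zero_noise)
    area = specimen.dims_mm[0] * specimen.dims_mm[1]
    assert rec.load.max() == pytest.approx(specimen.ucs_true * area)


def test_compression_channel_average_cancels_antisymmetric_tilt(specimen):
    noise = NoiseLevels(lvdt_sd_mm=0.0, lvdt_tilt_mm_per_n=1e-5)
    clean = synth_compression_curve(specimen, noise=NoiseLevels.zero())
    tilted = synth_compression_curve(specimen, noise=noise)
    mean_clean = 0.5 * (clean.displacement + clean.displacement2)
    mean_tilted = 0.5 * (tilted.displacement + tilted.displacement2)
    assert np.allclose(mean_clean, mean_tilted, atol=1e-12)
    assert not np.allclose(tilted.displacement, tilted.displacement2)


# -- ultrasound synthesis ---------------------------------------------------


def test_trace_arrival_at_hand_computed_tof(zero_noise):
    """C33 = 28.8 GPa, rho = 1800 kg/m^3, L = 6 mm -> arrival at 1.5 us."""
    cfg = CohortConfig()
    s = _specimen_from_porosity(cfg, 0, 0.0, (3.0, 3.0, 6.0), seed=1)
    s = type(s)(**{**s.__dict__, "C33_true": 28.8, "rho_true": 1.8,
                   "Cij_true": s.Cij_true})
    tr = synth_ultrasound_trace(s, sampling_rate=100e6, noise=zero_noise)
    nz = np.nonzero(tr.samples)[0][0]
    assert nz / 100e6 == pytest.approx(1.5e-6, abs=1.01e-8)


def test_noiseless_trace_first_nonzero_is_arrival(specimen, zero_noise):
    tr = synth_ultrasound_trace(specimen, noise=zero_noise, tof_s=2.0e-6)
    nz = np.nonzero(tr.samples)[0][0]
    assert nz == int(np.ceil(2.0e-6 * tr.sampling_rate))


def test_six_repeats_jitter_within_configured_sd(specimen):
    noise = NoiseLevels(trace_noise_sd=0.0, tof_jitter_rel=0.005)
    traces = synth_ultrasound_repeats(specimen, noise=noise)
    assert len(traces) == 6
    v = np.sqrt(specimen.C33_true * 1e9 / (specimen.rho_true * 1000.0))
    tof = specimen.dims_mm[2] * 1e-3 / v
    arrivals = [np.nonzero(t.samples)[0][0] / t.sampling_rate for t in traces]
    rel = (np.asarray(arrivals) - tof) / tof
    assert np.all(np.abs(rel) < 5 * 0.005)
    assert np.std(arrivals) > 0  # repositioning actually moves the arrival


# -- resonance synthesis ----------------------------------------------------


def test_rus_spectrum_noiseless_equals_forward_model(specimen, zero_noise):
    spectrum = synth_rus_spectrum(specimen, n_modes=20, noise=zero_noise)
    f = forward_frequencies(specimen.Cij_true, specimen.rho_true,
                            specimen.dims_mm, 6, 20).frequencies
    assert np.allclose(spectrum.frequencies, f)


def test_rus_dropout_retention_rate_and_order(default_cohort):
    noise = NoiseLevels(freq_noise_rel=0.0, mode_dropout=0.2)
    kept = 0
    total = 0
    for s in default_cohort:
        spectrum = synth_rus_spectrum(s, n_modes=30, noise=noise)
        assert np.all(np.diff(spectrum.frequencies) >= 0)
        kept += spectrum.n_modes
        total += 30
    assert kept / total == pytest.approx(0.8, abs=0.06)


def test_rus_frequency_perturbations_bounded(specimen):
    noise = NoiseLevels(freq_noise_rel=0.003, mode_dropout=0.0)
    spectrum = synth_rus_spectrum(specimen, n_modes=20, noise=noise)
    f0 = forward_frequencies(specimen.Cij_true, specimen.rho_true,
                             specimen.dims_mm, 6, 20).frequencies
    rel = np.abs(np.sort(spectrum.frequencies) - f0) / f0
    assert np.all(rel < 5 * 0.003)


# -- CT synthesis -----------------------------------------------------------


def test_ct_zero_porosity_volume_has_no_pores(specimen, zero_noise):
    vol = synth_ct_volume(specimen, noise=zero_noise, target_porosity=0.0,
                          region_mm=(0.35, 0.35, 0.14))
    assert vol.true_pore_mask.sum() == 0
    assert np.all(vol.voxels == 200)


def test_ct_ground_truth_fraction_hits_target(specimen, zero_noise):
    vol = synth_ct_volume(specimen, noise=zero_noise, target_porosity=0.10,
                          region_mm=(0.896, 0.896, 0.112))
    assert vol.true_pore_mask.mean() == pytest.approx(0.10, abs=0.01)


def test_pore_field_fraction_consistent_across_voxel_size(rng):
    """Rasterising one continuous field at 7 and 14 um gives one fraction."""
    centres, radii = sample_pore_field(0.10, (896.0, 896.0), rng)
    f7 = rasterize_pore_field(centres, radii, (896.0, 896.0), 7.0).mean()
    f14 = rasterize_pore_field(centres, radii, (896.0, 896.0), 14.0).mean()
    assert f14 == pytest.approx(f7, abs=0.01)


def test_ct_voxel_size_must_resolve_pores(specimen):
    with pytest.raises(ValueError):
        synth_ct_volume(specimen, voxel_size_um=20.0)
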