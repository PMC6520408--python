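"""Rayleigh-Ritz forward solver, mode pairing, MAP inversion, gate."""

import itertools

import numpy as np
import pytest

from cortimech.cohort import (CohortConfig, NoiseLevels, generate_cohort,
                              synth_rus_spectrum)
from cortimech.elastic import REFERENCE_CORTICAL, ElasticConstants
from cortimech.records import ResonanceSpectrum
from cortimech.rus import (RusInversion, RusPrior, engineering_moduli,
                           forward_frequencies, homogeneity_gate, pair_modes)

from fem_oracle import fem_free_vibration_extrapolated_khz

RHO = 1.8
DIMS = (3.02, 2.97, 6.01)  # slightly off-square, as cut specimens are


class TestForwardSolver:
    def test_frequencies_scale_as_sqrt_of_stiffness(self):
        f1 = forward_frequencies(REFERENCE_CORTICAL, RHO, DIMS, 6, 12)
        f2 = forward_frequencies(REFERENCE_CORTICAL.scaled(4.0), RHO, DIMS,
                                 6, 12)
        assert np.allclose(f2.frequencies, 2.0 * f1.frequencies, rtol=1e-9)

    def test_doubling_dims_halves_frequencies(self):
        f1 = forward_frequencies(REFERENCE_CORTICAL, RHO, DIMS, 6, 12)
        dims2 = tuple(2 * d for d in DIMS)
        f2 = forward_frequencies(REFERENCE_CORTICAL, RHO, dims2, 6, 12)
        assert np.allclose(f2.frequencies, 0.5 * f1.frequencies, rtol=1e-9)

    def test_rigid_body_modes_discarded(self):
        f = forward_frequencies(REFERENCE_CORTICAL, RHO, DIMS, 6, 30)
        # all returned modes are genuinely elastic: far from zero
        assert f.frequencies[0] > 50.0  # kHz

    def test_axis_relabelling_symmetry(self):
        """Swapping axes 1 and 2 with permuted Cij and dims leaves the
        spectrum unchanged."""
        c = REFERENCE_CORTICAL
        swapped = ElasticConstants(c11=c.c22, c22=c.c11, c33=c.c33,
                                   c12=c.c12, c13=c.c23, c23=c.c13,
                                   c44=c.c55, c55=c.c44, c66=c.c66)
        dims_swapped = (DIMS[1], DIMS[0], DIMS[2])
        f1 = forward_frequencies(c, RHO, DIMS, 8, 15).frequencies
        f2 = forward_frequencies(swapped, RHO, dims_swapped, 8, 15).frequencies
        assert np.allclose(f1, f2, rtol=1e-9)

    def test_monotone_convergence_from_above_in_basis_order(self):
        """Rayleigh-Ritz upper-bound property, per mode."""
        prev = None
        for order in (6, 8, 10, 12):
            f = forward_frequencies(ElasticConstants.from_isotropic(20, 0.3),
                                    RHO, (4.0, 4.0, 4.0), order, 12).frequencies
            if prev is not None:
                assert np.all(f <= prev * (1 + 1e-12))
            prev = f

    def test_matches_independent_fem_oracle_on_isotropic_cube(self):
        """Brute-force hexahedral FEM (Richardson-extrapolated) cross-check."""
        c = ElasticConstants.from_isotropic(20.0, 0.3)
        rr = forward_frequencies(c, RHO, (4.0, 4.0, 4.0), 12, 12).frequencies
        fem = fem_free_vibration_extrapolated_khz(20.0, 0.3, RHO,
                                                  (4.0, 4.0, 4.0),
                                                  n_coarse=8, n_fine=12,
                                                  n_modes=12)
        assert np.all(np.abs(rr - fem) / fem < 0.005)

    def test_invalid_inputs_rejected(self):
        indefinite = ElasticConstants(1, 1, 1, 5, 5, 5, 1, 1, 1)
        with pytest.raises(ValueError):
            forward_frequencies(indefinite, RHO, DIMS)
        with pytest.raises(ValueError):
            forward_frequencies(REFERENCE_CORTICAL, RHO, DIMS,
                                basis_order=2, n_modes=100)


class TestEngineeringModuli:
    def test_isotropic_returns_e_on_all_axes(self):
        em = engineering_moduli(ElasticConstants.from_isotropic(17.0, 0.28))
        assert em["E1"] == pytest.approx(17.0)
        assert em["E2"] == pytest.approx(17.0)
        assert em["E3"] == pytest.approx(17.0)

    def test_reference_tensor_round_trips_through_compliance(self):
        C = REFERENCE_CORTICAL.voigt_matrix()
        S = REFERENCE_CORTICAL.compliance_matrix()
        assert np.allclose(np.linalg.inv(S), C)


class TestPairModes:
    def _brute_force(self, f_meas, f_pred):
        n, m = len(f_meas), len(f_pred)
        best, best_cost = None, np.inf
        for comb in itertools.combinations(range(m), n):
            cost = sum(((f_meas[i] - f_pred[j]) / f_meas[i]) ** 2
                       for i, j in enumerate(comb))
            if cost < best_cost:
                best, best_cost = comb, cost
        return np.array(best), best_cost

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            f_pred = np.sort(rng.uniform(100, 500, 8))
            keep = np.sort(rng.choice(8, 5, replace=False))
            f_meas = f_pred[keep] * (1 + 0.01 * rng.standard_normal(5))
            got = pair_modes(f_meas, f_pred)
            want, want_cost = self._brute_force(f_meas, f_pred)
            got_cost = np.sum(((f_meas - f_pred[got]) / f_meas) ** 2)
            assert got_cost == pytest.approx(want_cost, rel=1e-12)

    def test_assignment_strictly_increasing(self, rng):
        f_pred = np.sort(rng.uniform(100, 500, 12))
        f_meas = f_pred[::2] * 1.001
        j = pair_modes(f_meas, f_pred)
        assert np.all(np.diff(j) > 0)


class TestInversion:
    def test_noiseless_round_trip(self):
        truth = REFERENCE_CORTICAL
        spec = forward_frequencies(truth, RHO, DIMS, 6, 24)
        prior = RusPrior.from_relative(truth.scaled(1.1), 0.2)
        res = RusInversion(ResonanceSpectrum(spec.frequencies), RHO, DIMS,
                           prior, basis_order=6).fit()
        assert res.converged
        assert res.rms_relative_misfit < 1e-4
        diag = np.array([0, 1, 2, 6, 7, 8])
        err = np.abs(res.cij_hat.as_array() - truth.as_array()) \
            / truth.as_array()
        assert np.all(err[diag] < 0.01)

    def test_zero_data_weight_returns_prior_mean(self):
        truth = REFERENCE_CORTICAL
        spec = forward_frequencies(truth, RHO, DIMS, 6, 20)
        prior = RusPrior.from_relative(truth, 0.2)
        res = RusInversion(ResonanceSpectrum(spec.frequencies), RHO, DIMS,
                           prior, basis_order=6, data_weight=0.0).fit()
        assert np.allclose(res.cij_hat.as_array(), truth.as_array(),
                           rtol=1e-6)

    def test_too_few_modes_rejected(self):
        spec = ResonanceSpectrum(np.linspace(100, 300, 10))
        prior = RusPrior.from_relative(REFERENCE_CORTICAL, 0.2)
        with pytest.raises(ValueError):
            RusInversion(spec, RHO, DIMS, prior)

    def test_e3_recovery_across_noisy_cohort(self):
        """0.3% frequency noise + 10% dropout: median E3 error under 3%."""
        cohort = generate_cohort(CohortConfig(n_specimens=20, seed=4))
        noise = NoiseLevels(freq_noise_rel=0.003, mode_dropout=0.1)
        errs = []
        for s in cohort:
            spectrum = synth_rus_spectrum(s, n_modes=24, noise=noise,
                                          basis_order=6)
            prior = RusPrior.from_relative(REFERENCE_CORTICAL, 0.35)
            fit = RusInversion(spectrum, s.rho_true, s.dims_mm, prior,
                               basis_order=6).fit()
            errs.append(abs(fit.E3 / s.E3_true - 1.0))
        assert np.median(errs) < 0.03


class TestHomogeneityGate:
    def test_forty_percent_porosity_ineligible(self):
        assert not homogeneity_gate(0.40)

    def test_typical_porosity_eligible(self):
        assert homogeneity_gate(0.09)

    def test_threshold_one_disables_gate(self):
        assert homogeneity_gate(0.999, threshold=1.0)

    def test_invalid_porosity_rejected(self):
        with pytest.raises(ValueError):
            homogeneity_gate(1.5)
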