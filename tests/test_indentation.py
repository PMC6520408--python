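"""Oliver-Pharr chain: unit operations, fit recovery, Hertz round trips."""

import numpy as np
import pytest

from cortimech.cohort import (CohortConfig, NoiseLevels,
                              synth_indentation_curve,
                              _specimen_from_porosity)
from cortimech.indentation import (SAPPHIRE_TIP, SphericalIndentation,
                                   TipSpec, UnloadingFit, analyze_grid,
                                   contact_area, contact_depth,
                                   correct_compliance, fit_unloading,
                                   reduced_modulus, sample_modulus,
                                   unloading_stiffness)
from cortimech.records import LoadDisplacementRecord


def _spec(E=None):
    cfg = CohortConfig()
    return _specimen_from_porosity(cfg, 0, 0.1, (3.0, 3.0, 6.0), seed=3)


def _unload_record(alpha, m, h_f, h_lo, h_hi, n=200, noise=0.0, rng=None):
    h = np.linspace(h_lo, h_hi, n)       # um
    P = alpha * (h - h_f) ** m
    if noise:
        P = P + noise * P.max() * rng.standard_normal(n)
    # store in descending-load order, as an unloading branch is recorded
    return LoadDisplacementRecord(np.arange(n, dtype=float), P[::-1],
                                  h[::-1] / 1e3)


class TestCompliance:
    def test_zero_compliance_is_identity(self, specimen, zero_noise):
        rec = synth_indentation_curve(specimen, noise=zero_noise)
        out = correct_compliance(rec, 0.0)
        assert np.array_equal(out.displacement, rec.displacement)
        assert np.array_equal(out.load, rec.load)

    def test_pointwise_linearity_on_ramp(self):
        P = np.linspace(0, 10, 50)
        rec = LoadDisplacementRecord(np.arange(50.0), P, np.full(50, 0.01))
        out = correct_compliance(rec, 2e-4)
        assert np.allclose(rec.displacement - out.displacement, 2e-4 * P)

    def test_add_then_correct_round_trip(self, specimen, zero_noise):
        rec = synth_indentation_curve(specimen, noise=zero_noise)
        c = 5e-4
        with_frame = LoadDisplacementRecord(
            rec.time, rec.load, rec.displacement + c * rec.load,
            segments=rec.segments)
        back = correct_compliance(with_frame, c)
        assert np.allclose(back.displacement, rec.displacement, atol=1e-15)

    def test_negative_compliance_rejected(self, specimen, zero_noise):
        rec = synth_indentation_curve(specimen, noise=zero_noise)
        with pytest.raises(ValueError):
            correct_compliance(rec, -1e-4)


class TestUnloadingFit:
    @pytest.mark.parametrize("alpha,m,h_f,rtol", [
        (1.0, 1.5, 0.0, 1e-6),
        (0.8, 1.4, 2.0, 1e-4),
    ])
    def test_exact_data_recovered(self, alpha, m, h_f, rtol):
        rec = _unload_record(alpha, m, h_f, h_f + 0.5, 10.0)
        fit = fit_unloading(rec)
        assert fit.converged
        assert fit.alpha == pytest.approx(alpha, rel=rtol)
        assert fit.m == pytest.approx(m, rel=rtol)
        assert fit.h_f == pytest.approx(h_f, abs=10 * rtol)

    def test_noisy_recovery_median_unbiased(self, rng):
        """1% load noise: the median recovered exponent stays within 0.1."""
        ms = []
        for _ in range(100):
            rec = _unload_record(0.8, 1.4, 2.0, 2.5, 10.0, noise=0.01,
                                 rng=rng)
            ms.append(fit_unloading(rec).m)
        assert abs(np.median(ms) - 1.4) < 0.1

    def test_too_few_points_rejected(self):
        rec = _unload_record(1.0, 1.5, 0.0, 0.5, 10.0, n=5)
        with pytest.raises(ValueError):
            fit_unloading(rec)


class TestStiffnessAndGeometry:
    def test_linear_case(self):
        fit = UnloadingFit(1.0, 1.0, 0.0, (0.5, 0.95), 0.0)
        assert unloading_stiffness(fit, 7.3) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        fit = UnloadingFit(1.0, 2.0, 1.0, (0.5, 0.95), 0.0)
        assert unloading_stiffness(fit, 3.0) == pytest.approx(4.0)

    def test_matches_numerical_derivative(self):
        fit = UnloadingFit(0.8, 1.4, 2.0, (0.5, 0.95), 0.0)
        h = 9.0
        eps = 1e-6
        fd = (fit.load(h + eps) - fit.load(h - eps)) / (2 * eps)
        assert unloading_stiffness(fit, h) == pytest.approx(fd, rel=1e-6)

    def test_contact_depth(self):
        assert contact_depth(10.0, 4.0) == pytest.approx(7.0)
        assert contact_depth(5.0, 5.0) == pytest.approx(5.0)
        assert contact_depth(8.0, 0.0) == pytest.approx(4.0)

    def test_contact_area(self):
        assert contact_area(3.0, 0.0) == 0.0
        assert contact_area(3.0, 5.0) == pytest.approx(2 * np.pi * 3 * 0.005)
        assert contact_area(6.0, 5.0) == pytest.approx(2 * contact_area(3.0, 5.0))
        assert contact_area(3.0, 10.0) == pytest.approx(2 * contact_area(3.0, 5.0))


class TestModuli:
    def test_reduced_modulus_cancellation(self):
        # S = 2 N/um, A = pi mm^2: E_r = sqrt(pi)/2 * 2e6/sqrt(pi*1e-6) Pa = 1e9 Pa
        assert reduced_modulus(2.0, np.pi) == pytest.approx(1.0)

    def test_reduced_modulus_area_scaling(self):
        e1 = reduced_modulus(2.0, 1.0)
        e2 = reduced_modulus(2.0, 2.0)
        assert e2 == pytest.approx(e1 / np.sqrt(2))

    def test_rigid_tip_limit(self):
        rigid = TipSpec(3.0, 1e12, 0.24)
        e = sample_modulus(10.0, 0.33, rigid)
        assert e == pytest.approx((1 - 0.33 ** 2) * 10.0, rel=1e-9)

    def test_algebraic_inverse_round_trip(self):
        E, nu = 6.0, 0.33
        inv_er = (1 - nu ** 2) / E + (1 - SAPPHIRE_TIP.nu ** 2) / SAPPHIRE_TIP.E_gpa
        assert sample_modulus(1.0 / inv_er, nu, SAPPHIRE_TIP) == pytest.approx(E)

    def test_super_rigid_reduced_modulus_flagged(self):
        with pytest.raises(ValueError):
            sample_modulus(1e4, 0.33, SAPPHIRE_TIP)


class TestFullPipeline:
    @pytest.mark.parametrize("E", [2.0, 6.0, 12.0, 20.0])
    def test_hertz_round_trip_within_5_percent(self, E, zero_noise):
        rec = synth_indentation_curve(_spec(), noise=zero_noise,
                                      modulus_gpa=E)
        res = SphericalIndentation(rec).fit()
        assert res.usable
        assert res.E == pytest.approx(E, rel=0.05)
        assert res.h_c <= res.h_max

    def test_reduced_modulus_matches_generator_e_star(self, zero_noise):
        rec = synth_indentation_curve(_spec(), noise=zero_noise,
                                      modulus_gpa=6.0)
        res = SphericalIndentation(rec).fit()
        e_star = 1.0 / ((1 - 0.33 ** 2) / 6.0
                        + (1 - 0.24 ** 2) / 420.0)
        assert res.E_r == pytest.approx(e_star, rel=0.05)

    def test_stiffer_specimens_give_larger_s_and_e(self, zero_noise):
        results = [SphericalIndentation(
            synth_indentation_curve(_spec(), noise=zero_noise,
                                    modulus_gpa=E)).fit()
            for E in (3.0, 8.0, 15.0)]
        s_vals = [r.S for r in results]
        e_vals = [r.E for r in results]
        assert s_vals == sorted(s_vals)
        assert e_vals == sorted(e_vals)

    def test_creep_and_drift_correction_tolerated(self):
        noise = NoiseLevels(indent_disp_sd_um=0.005, indent_creep_um=0.2)
        rec = synth_indentation_curve(_spec(), noise=noise)
        res = SphericalIndentation(rec, drift_correction=True).fit()
        assert res.usable
        assert res.E == pytest.approx(_spec().E3_true, rel=0.15)


class TestGrid:
    def _grid_records(self, moduli, zero_noise):
        return [synth_indentation_curve(_spec(), noise=zero_noise,
                                        modulus_gpa=m) for m in moduli]

    def test_identical_indents_summary_equals_common_value(self, zero_noise):
        recs = self._grid_records([6.0] * 16, zero_noise)
        grid = analyze_grid(recs)
        assert grid.sample_modulus == pytest.approx(6.0, rel=0.01)

    def test_central_four_mean(self, zero_noise):
        moduli = [15.0] * 16
        for idx, e in zip((5, 6, 9, 10), (4.0, 5.0, 6.0, 7.0)):
            moduli[idx] = e
        grid = analyze_grid(self._grid_records(moduli, zero_noise))
        assert grid.sample_modulus == pytest.approx(5.5, rel=0.01)
        assert grid.n_central_used == 4

    def test_wrong_count_rejected(self, zero_noise):
        with pytest.raises(ValueError):
            analyze_grid(self._grid_records([6.0] * 15, zero_noise))

    def test_grid_spacing_constant_matches_protocol(self):
        from cortimech.indentation import GRID_SPACING_UM
        assert GRID_SPACING_UM == 200.0
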