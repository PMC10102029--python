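"""Shrinking-droplet release model: forward evaluation, parameter
recovery by nonlinear least squares, and rate-constant comparison."""

import numpy as np
import pytest

import ilrkit as ik
from ilrkit.errors import ValidationError
from ilrkit.units import MOL_S_M2_TO_UMOL_MIN_CM2, S_PER_MIN


def params(phi_max=0.9, t_star_min=60.0, M=0.63902, d0=250e-9, rho0=935.0):
    """Parameters with a chosen droplet lifetime t* (minutes)."""
    g_per_s = 1.0 / (t_star_min * S_PER_MIN)
    k = g_per_s * d0 * rho0 / M
    return ik.ShrinkingDropletParams(phi_max=phi_max, k_mol_s_m2=k,
                                     molar_mass_kg_mol=M, d0_m=d0,
                                     rho0_kg_m3=rho0)


def model_curve(p, t_min, n_total=5000.0):
    phi = ik.release_fraction(p, t_min)
    return ik.ReleaseCurve(np.asarray(t_min, float), phi * n_total)


class TestForwardModel:
    def test_starts_at_zero(self):
        assert ik.release_fraction(params(), 0.0) == 0.0

    def test_direct_arithmetic_midpoint(self):
        # Φ_max = 1, rate group 0.01 min⁻¹, t = 50 min -> 1 - 0.5³ = 0.875
        p = params(phi_max=1.0, t_star_min=100.0)
        assert ik.release_fraction(p, 50.0) == pytest.approx(0.875, rel=1e-12)

    def test_clamped_at_droplet_lifetime(self):
        p = params(phi_max=0.9, t_star_min=60.0)
        for t in (60.0, 61.0, 1e4):
            assert ik.release_fraction(p, t) == pytest.approx(0.9, rel=1e-12)

    def test_continuous_at_lifetime(self):
        p = params(t_star_min=60.0)
        eps = 1e-9
        left = ik.release_fraction(p, 60.0 - eps)
        right = ik.release_fraction(p, 60.0 + eps)
        assert left == pytest.approx(right, abs=1e-7)

    def test_monotone_in_time_and_rate(self):
        t = np.linspace(0, 120, 500)
        phi = ik.release_fraction(params(), t)
        assert np.all(np.diff(phi) >= -1e-15)
        assert np.all(phi <= 0.9 + 1e-12)
        faster = ik.release_fraction(params(t_star_min=30.0), t)
        assert np.all(faster >= phi - 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            ik.release_fraction(params(), -1.0)

    def test_early_time_linearisation(self):
        # t << t*: Φ ≈ 3·Φ_max·g·t, tying the fitted k to the initial slope
        p = params(phi_max=0.9, t_star_min=60.0)
        t = 60.0 / 1000.0
        expected = 3 * 0.9 * (1 / 60.0) * t
        assert ik.release_fraction(p, t) == pytest.approx(expected, rel=2e-3)

    def test_zero_rate_never_releases(self):
        p = ik.ShrinkingDropletParams(0.9, 0.0, 0.639, 250e-9, 935.0)
        assert p.t_star_s == np.inf
        assert ik.release_fraction(p, 1e6) == 0.0


class TestParameterValidation:
    @pytest.mark.parametrize("phi_max", [0.0, -0.1, 1.1])
    def test_phi_max_bounds(self, phi_max):
        with pytest.raises(ValidationError):
            ik.ShrinkingDropletParams(phi_max, 1e-7, 0.639, 250e-9, 935.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            ik.ShrinkingDropletParams(0.9, -1e-7, 0.639, 250e-9, 935.0)


class TestFit:
    def test_noise_free_recovery_to_machine_precision(self):
        p_true = params(phi_max=0.9, t_star_min=60.0)
        t = np.linspace(1.0, 90.0, 90)
        curve = model_curve(p_true, t)
        fit = ik.fit_release_curve(curve, 5000.0, 0.63902, 250e-9, 935.0)
        assert fit.converged
        assert fit.params.phi_max == pytest.approx(0.9, rel=1e-6)
        assert fit.params.k_mol_s_m2 == pytest.approx(p_true.k_mol_s_m2,
                                                      rel=1e-6)
        assert fit.rmse < 1e-8

    def test_noisy_recovery_at_fixed_seed(self):
        p_true = params(phi_max=0.9, t_star_min=60.0)
        t = np.linspace(1.0, 90.0, 90)
        rng = np.random.default_rng(42)
        phi = ik.release_fraction(p_true, t) + rng.normal(0, 0.01, t.size)
        curve = ik.ReleaseCurve(t, phi * 5000.0)
        fit = ik.fit_release_curve(curve, 5000.0, 0.63902, 250e-9, 935.0)
        assert fit.params.phi_max == pytest.approx(0.9, rel=0.02)
        assert fit.params.k_mol_s_m2 == pytest.approx(p_true.k_mol_s_m2,
                                                      rel=0.05)

    def test_recovery_unbiased_over_seeded_replicates(self):
        # 100 noisy replicates at sd 0.01: small median error, no gross bias
        p_true = params(phi_max=0.9, t_star_min=60.0)
        t = np.linspace(1.0, 90.0, 90)
        phi_clean = ik.release_fraction(p_true, t)
        rng = np.random.default_rng(2026)
        rel_errors = []
        for _ in range(100):
            phi = phi_clean + rng.normal(0, 0.01, t.size)
            fit = ik.fit_release_curve(ik.ReleaseCurve(t, phi * 5000.0),
                                       5000.0, 0.63902, 250e-9, 935.0)
            rel_errors.append(fit.params.k_mol_s_m2 / p_true.k_mol_s_m2 - 1)
        rel_errors = np.asarray(rel_errors)
        assert np.median(np.abs(rel_errors)) < 0.05
        assert abs(rel_errors.mean()) < 0.02

    def test_flat_curve_flagged_non_identifiable(self):
        t = np.linspace(0.0, 90.0, 50)
        curve = ik.ReleaseCurve(t, np.zeros_like(t))
        with pytest.warns(UserWarning, match="not identifiable"):
            fit = ik.fit_release_curve(curve, 5000.0, 0.639, 250e-9, 935.0)
        assert not fit.identifiable
        assert fit.params.phi_max < 1e-2

    def test_too_few_points_rejected(self):
        curve = ik.ReleaseCurve(np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValidationError):
            ik.fit_release_curve(curve, 5000.0, 0.639, 250e-9, 935.0)


class TestRateComparison:
    def test_unit_conversion_factor_derivation(self):
        # 1 mol·s⁻¹·m⁻² = 10⁶ µmol · 60 min⁻¹ / 10⁴ cm² = 6×10³
        assert MOL_S_M2_TO_UMOL_MIN_CM2 == pytest.approx(6.0e3)
        umol = 1e6
        per_min = 60.0
        per_cm2 = 1e-4
        assert umol * per_min * per_cm2 == MOL_S_M2_TO_UMOL_MIN_CM2

    def test_identical_rates_give_unit_ratio(self):
        ilr = ik.IlrResult(ilr=6.0e-3, k_umol_min=1.0, area_cm2=1.0)
        k_si = 6.0e-3 / MOL_S_M2_TO_UMOL_MIN_CM2
        fit = ik.MechanisticFit(
            params=ik.ShrinkingDropletParams(0.9, k_si, 0.639, 250e-9, 935.0),
            rmse=0.0, n_points=10, converged=True)
        rep = ik.compare_rate_constants(ilr, fit)
        assert rep["ratio_ilr_to_mechanistic"] == pytest.approx(1.0)

    def test_reported_pure_tricaprylin_ratio(self):
        # ILR 6.3e-3 vs mechanistic 4.1e-3 (display scale) -> ratio 1.54
        ilr = ik.IlrResult(ilr=6.3e-3, k_umol_min=1.0, area_cm2=1.0)
        k_si = 4.1e-3 / MOL_S_M2_TO_UMOL_MIN_CM2
        fit = ik.MechanisticFit(
            params=ik.ShrinkingDropletParams(0.9, k_si, 0.47069, 250e-9,
                                             956.0),
            rmse=0.0, n_points=10, converged=True)
        rep = ik.compare_rate_constants(ilr, fit)
        assert rep["ratio_ilr_to_mechanistic"] == pytest.approx(1.54, abs=0.01)

    def test_zero_mechanistic_rate_ratio_missing(self):
        ilr = ik.IlrResult(ilr=6.3e-3, k_umol_min=1.0, area_cm2=1.0)
        fit = ik.MechanisticFit(
            params=ik.ShrinkingDropletParams(0.9, 0.0, 0.639, 250e-9, 935.0),
            rmse=0.0, n_points=10, converged=True)
        assert ik.compare_rate_constants(ilr, fit)[
            "ratio_ilr_to_mechanistic"] is None
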