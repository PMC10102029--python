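"""Titration record processing: unit conversion, ionization and blank
corrections, and max-slope/lag extraction from lipolysis curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ilrkit as ik
from ilrkit.errors import CoverageError, DataError, ValidationError


def record(t, v, molarity=0.6, ph9=0.0, label="r"):
    return ik.TitrationRecord(np.asarray(t, float), np.asarray(v, float),
                              titrant_molarity=molarity,
                              ph9_titrant_volume_ml=ph9, label=label)


def curve(t, y, **kw):
    return ik.ReleaseCurve(np.asarray(t, float), np.asarray(y, float), **kw)


class TestTitrationRecord:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValidationError):
            record([0, 2, 1], [0, 1, 2])

    def test_large_volume_dip_rejected(self):
        with pytest.raises(DataError):
            record([0, 1, 2], [0.0, 1.0, 0.5])

    def test_small_dip_monotonized(self):
        r = record([0, 1, 2], [0.0, 1.0, 0.999])
        assert np.all(np.diff(r.cumulative_volume_ml) >= 0)


class TestTitrantConversion:
    @pytest.mark.parametrize("ml,molarity,expected_umol", [
        (1.0, 0.6, 600.0),     # 1 mL of 0.6 M NaOH neutralises 600 µmol FA
        (0.0, 0.6, 0.0),
        (2.0, 0.2, 400.0),
    ])
    def test_volume_times_molarity(self, ml, molarity, expected_umol):
        r = record([0, 1], [0.0, ml], molarity=molarity)
        assert ik.titrant_to_ionized_fa(r)[-1] == pytest.approx(expected_umol)

    def test_full_burette_matches_theoretical_release(self):
        # 5 mmol theoretical release needs 5/0.6 = 8.333 mL of 0.6 M titrant
        r = record([0, 90], [0.0, 5.0 / 0.6])
        assert ik.titrant_to_ionized_fa(r)[-1] == pytest.approx(5000.0)


class TestIonizationCorrection:
    @pytest.mark.parametrize("end,ph9,scale", [
        (4000.0, 1000.0, 1.25),
        (2500.0, 2500.0, 2.0),
        (1234.0, 0.0, 1.0),
    ])
    def test_uniform_scaling(self, end, ph9, scale):
        ionized = np.array([0.0, end / 2, end])
        total, s = ik.ionization_correction(ionized, ph9)
        assert s == pytest.approx(scale)
        np.testing.assert_allclose(total, ionized * scale)

    def test_zero_endpoint_with_backtitration_rejected(self):
        with pytest.raises(DataError):
            ik.ionization_correction(np.zeros(3), 100.0)


class TestBlankCorrection:
    def test_zero_blank_is_identity(self):
        s = curve([0, 1, 2], [0, 10, 20])
        b = curve([0, 1, 2], [0, 0, 0])
        out = ik.blank_correction(s, b)
        np.testing.assert_allclose(out.cumulative_fa_umol, [0, 10, 20])

    def test_sample_equal_blank_annihilates(self):
        s = curve([0, 1, 2], [0, 10, 20])
        out = ik.blank_correction(s, s)
        np.testing.assert_allclose(out.cumulative_fa_umol, 0.0)

    def test_blank_interpolated_onto_sample_grid(self):
        s = curve([0, 0.5, 1.0, 1.5, 2.0], [0, 5, 10, 15, 20])
        b = curve([0, 2], [0, 4])  # linear 2 µmol/min on a coarse grid
        out = ik.blank_correction(s, b)
        np.testing.assert_allclose(out.cumulative_fa_umol,
                                   [0, 4, 8, 12, 16])

    def test_short_blank_rejected(self):
        s = curve([0, 1, 2], [0, 10, 20])
        b = curve([0, 1], [0, 1])
        with pytest.raises(CoverageError):
            ik.blank_correction(s, b)

    def test_large_negative_excursion_kept_and_flagged(self):
        s = curve([0, 1, 2], [0, 10, 20])
        b = curve([0, 1, 2], [0, 18, 18])
        out = ik.blank_correction(s, b)
        assert out.cumulative_fa_umol.min() < 0
        assert any("blank exceeds sample" in w for w in out.warnings)

    def test_molarity_differences_cancel_in_umol(self):
        # same chemistry recorded with 0.6 M and with 0.2 M at 3x volume
        t = np.linspace(0, 10, 21)
        fa = 30.0 * t  # µmol
        r06 = record(t, fa / 600.0, molarity=0.6)
        r02 = record(t, fa / 200.0, molarity=0.2)
        np.testing.assert_allclose(ik.titrant_to_ionized_fa(r06),
                                   ik.titrant_to_ionized_fa(r02),
                                   atol=1e-9)


class TestProcessRecord:
    def test_corrections_applied_in_order_and_flagged(self):
        t = np.linspace(0, 10, 11)
        sample = record(t, 0.01 * t, molarity=0.6, ph9=0.025)
        blank = record(t, 0.003 * t, molarity=0.2)
        out = ik.process_record(sample, blank)
        assert out.corrections["ionization"] and out.corrections["blank"]
        # ionization first: sample scaled by (end+ph9)/end, then blank (µmol)
        scale = (0.1 * 600 + 0.025 * 600) / (0.1 * 600)
        expected = 0.01 * t * 600 * scale - 0.003 * t * 200
        np.testing.assert_allclose(out.cumulative_fa_umol, expected,
                                   atol=1e-9)

    @given(molarity=st.floats(0.05, 2.0))
    @settings(deadline=None, max_examples=25)
    def test_release_curve_invariant_to_titrant_molarity(self, molarity):
        t = np.linspace(0, 10, 51)
        fa_umol = 40.0 * t
        rec = record(t, fa_umol / (molarity * 1e3), molarity=molarity)
        out = ik.process_record(rec)
        np.testing.assert_allclose(out.cumulative_fa_umol, fa_umol,
                                   rtol=1e-9, atol=1e-6)


class TestSegmentCurve:
    def test_piecewise_linear_exact_recovery(self):
        # flat until t = 2 min, then slope 100 µmol/min
        t = np.arange(0, 30.05, 0.1)
        y = np.where(t <= 2, 0.0, 100.0 * (t - 2))
        res = ik.segment_curve(curve(t, y))
        assert res.k_umol_min == pytest.approx(100.0, rel=1e-9)
        assert res.lag_time_min == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("window", [3, 7, 11, 15])
    def test_exact_for_any_window_within_ramp(self, window):
        t = np.arange(0, 20.05, 0.1)
        y = np.where(t <= 5, 0.0, 80.0 * (t - 5))
        res = ik.segment_curve(curve(t, y), window_points=window)
        assert res.k_umol_min == pytest.approx(80.0, rel=1e-9)
        assert res.lag_time_min == pytest.approx(5.0, abs=1e-9)

    def test_constant_curve_degenerates(self):
        t = np.arange(0, 30.0, 0.5)
        res = ik.segment_curve(curve(t, np.full_like(t, 7.0)))
        assert res.k_umol_min == 0.0
        assert res.lag_time_min is None

    def test_shrinking_droplet_initial_slope_recovered(self):
        # Φ_max = 1, rate group 0.01 min⁻¹, 5000 µmol total:
        # analytic max derivative 3·Φ_max·g·n = 150 µmol/min at t = 0
        g, n = 0.01, 5000.0
        t = np.arange(0, 90.0, 0.05)
        y = n * (1 - np.maximum(0, 1 - g * t) ** 3)
        res = ik.segment_curve(curve(t, y))  # 11-pt window spans 0.5 min
        assert res.k_umol_min == pytest.approx(150.0, rel=0.02)
        assert res.k_window[0] == 0.0

    def test_plateau_and_extent(self):
        t = np.arange(0, 90.0, 0.5)
        y = np.minimum(100.0 * t, 4500.0)
        res = ik.segment_curve(curve(t, y), theoretical_fa_umol=5000.0)
        assert res.plateau_umol == pytest.approx(4500.0)
        assert res.extent_fraction == pytest.approx(0.9)

    def test_threshold_lag_method(self):
        t = np.arange(0, 30.05, 0.1)
        y = np.where(t <= 2, 0.0, 100.0 * (t - 2))
        res = ik.segment_curve(curve(t, y), lag_method="threshold",
                               theoretical_fa_umol=5000.0)
        # first point with y >= 1% of 5000 µmol = 50 µmol -> t = 2.5
        assert res.lag_time_min == pytest.approx(2.5, abs=0.1 + 1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ik.segment_curve(curve([0, 1, 2], [0, 1, 2]))


class TestCsvIO:
    def test_round_trip_and_seconds_conversion(self, tmp_path):
        p = tmp_path / "titration.csv"
        p.write_text("time_s,cum_volume_ml\n0,0\n60,0.5\n120,1.0\n")
        rec = ik.read_titration_csv(p, titrant_molarity=0.6)
        np.testing.assert_allclose(rec.times_min, [0, 1, 2])

        out = ik.process_record(rec)
        dest = tmp_path / "release.csv"
        ik.write_release_csv(out, dest)
        assert dest.exists()
        assert dest.with_suffix(".provenance.json").exists()

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("minutes,ml\n0,0\n1,1\n")
        with pytest.raises(ValidationError):
            ik.read_titration_csv(p, titrant_molarity=0.6)
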