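"""pH-stat titration processing.

A pH-stat lipolysis run logs cumulative NaOH titrant volume against time;
each mole of titrant neutralises one mole of ionized fatty acid.  Raw
records are converted to corrected cumulative fatty-acid release curves in
two steps, in this order and both in µmol:

1. ionization correction — the end-of-run back-titration to pH 9 measures
   the unionized fatty-acid pool; assuming the ionized/unionized ratio is
   constant over the run, the whole curve is scaled by
   s = (ionized_end + pH9_addition) / ionized_end;
2. blank correction — subtraction of the fatty acids released by digestion
   of the medium's phospholipids, measured in a run without acylglycerols
   (possibly at a different titrant molarity, which cancels in µmol).

The corrected curve is triphasic: a lag phase, a maximum-rate phase whose
slope k (µmol/min) defines the apparent lipolysis rate, and a plateau.
``segment_curve`` extracts k as the maximum sliding-window least-squares
slope, the lag time as the zero-intercept of the tangent through that
window's centroid (the standard pH-stat convention; the threshold-crossing
alternative is available via ``lag_method``), and the plateau level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError, ValidationError

#: Tolerated downward excursion of raw cumulative titrant volume (mL);
#: roughly the burette resolution. Dips within it are monotonized away.
VOLUME_DIP_TOL_ML = 0.005


@dataclass(frozen=True)
class TitrationRecord:
    """One pH-stat vessel: time (min) vs cumulative titrant volume (mL)."""

    times_min: np.ndarray
    cumulative_volume_ml: np.ndarray
    titrant_molarity: float  # mol/L
    ph9_titrant_volume_ml: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.cumulative_volume_ml, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValidationError("times and volumes must be equal-length 1-D")
        if t.size < 2:
            raise ValidationError("a titration record needs >= 2 points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing, >= 0")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise DataError("non-finite values in titration record")
        dips = np.maximum.accumulate(v) - v
        if dips.max(initial=0.0) > VOLUME_DIP_TOL_ML:
            raise DataError(
                f"cumulative titrant volume dips by {dips.max():.4f} mL "
                f"(> {VOLUME_DIP_TOL_ML} mL tolerance) in {self.label!r}")
        if self.titrant_molarity <= 0:
            raise ValidationError("titrant molarity must be > 0")
        if self.ph9_titrant_volume_ml < 0:
            raise ValidationError("pH 9 titrant volume must be >= 0")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "cumulative_volume_ml",
                           np.maximum.accumulate(v))


@dataclass(frozen=True)
class ReleaseCurve:
    """Cumulative fatty-acid release (µmol) vs time (min)."""

    times_min: np.ndarray
    cumulative_fa_umol: np.ndarray
    corrections: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.cumulative_fa_umol, dtype=float)
        if y.shape != t.shape:
            raise ValidationError("times and release must have equal length")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "cumulative_fa_umol", y)


@dataclass(frozen=True)
class RatePhaseResult:
    """Maximum-rate-phase summary of a lipolysis curve."""

    k_umol_min: float
    lag_time_min: float | None
    k_window: tuple[float, float]
    plateau_umol: float
    extent_fraction: float | None = None


def titrant_to_ionized_fa(record: TitrationRecord) -> np.ndarray:
    """Cumulative ionized fatty acid (µmol): volume × molarity, anchored at 0.

    mL × mol/L = mmol/1000 → µmol via ×1000·... (mL·mol/L = µmol×10⁻³·10³);
    numerically: µmol = mL · M · 1000.
    """
    umol = record.cumulative_volume_ml * record.titrant_molarity * 1e3
    return umol - umol[0]


def ionization_correction(ionized_umol: np.ndarray,
                          ph9_addition_umol: float) -> tuple[np.ndarray, float]:
    """Scale an ionized-only curve to total (ionized + unionized) fatty acid.

    Returns (total curve, scale factor s).  s = (end + pH9)/end applied
    uniformly, on the assumption that the ionized/unionized ratio does not
    change during the run.
    """
    ionized_umol = np.asarray(ionized_umol, dtype=float)
    if ph9_addition_umol < 0:
        raise ValidationError("pH 9 addition must be >= 0")
    if ph9_addition_umol == 0:
        return ionized_umol.copy(), 1.0
    end = ionized_umol[-1]
    if end <= 0:
        raise DataError(
            "ionized endpoint is 0 but a pH 9 back-titration volume was "
            "recorded; the ionized/unionized ratio is undefined")
    scale = (end + ph9_addition_umol) / end
    return ionized_umol * scale, scale


def blank_correction(sample: ReleaseCurve, blank: ReleaseCurve,
                     *, negative_tol_umol: float | None = None) -> ReleaseCurve:
    """Subtract the interpolated medium-blank release from a sample curve.

    The blank must span the sample's time range; it is linearly interpolated
    onto the sample grid.  Small negative excursions (within
    ``negative_tol_umol``, default 1% of the sample endpoint) are floored at
    zero; larger ones are preserved and flagged with a warning.
    """
    t = sample.times_min
    if blank.times_min[0] > t[0] or blank.times_min[-1] < t[-1]:
        raise CoverageError(
            f"blank spans [{blank.times_min[0]:g}, {blank.times_min[-1]:g}] "
            f"min but sample needs [{t[0]:g}, {t[-1]:g}] min")
    interp_blank = np.interp(t, blank.times_min, blank.cumulative_fa_umol)
    corrected = sample.cumulative_fa_umol - interp_blank
    warns = list(sample.warnings)
    if negative_tol_umol is None:
        negative_tol_umol = max(1e-9, 0.01 * abs(sample.cumulative_fa_umol[-1]))
    worst = -corrected.min(initial=0.0)
    if worst > 0:
        if worst <= negative_tol_umol:
            corrected = np.maximum(corrected, 0.0)
        else:
            warns.append(
                f"blank exceeds sample by up to {worst:.3g} µmol "
                f"(> {negative_tol_umol:.3g} tolerance); negative values kept")
    return ReleaseCurve(
        times_min=t, cumulative_fa_umol=corrected,
        corrections={**sample.corrections, "blank": True},
        warnings=tuple(warns), label=sample.label)


def process_record(record: TitrationRecord,
                   blank: TitrationRecord | ReleaseCurve | None = None
                   ) -> ReleaseCurve:
    """Full correction pipeline: titrant → ionization scaling → blank.

    The order is fixed: both corrections operate in µmol, ionization first.
    A blank given as a TitrationRecord is itself ionization-corrected with
    its own pH 9 volume before subtraction, so differing titrant molarities
    between sample and blank cancel.
    """
    ionized = titrant_to_ionized_fa(record)
    ph9_umol = record.ph9_titrant_volume_ml * record.titrant_molarity * 1e3
    total, scale = ionization_correction(ionized, ph9_umol)
    curve = ReleaseCurve(
        times_min=record.times_min, cumulative_fa_umol=total,
        corrections={"ionization": True, "ionization_scale": scale},
        label=record.label)
    if blank is None:
        return curve
    if isinstance(blank, TitrationRecord):
        blank = process_record(blank)
    return blank_correction(curve, blank)


def _window_slopes(t: np.ndarray, y: np.ndarray, w: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS slope of every length-w window; returns (slopes, t̄, ȳ)."""
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    tm = tw.mean(axis=1)
    ym = yw.mean(axis=1)
    dt = tw - tm[:, None]
    denom = (dt * dt).sum(axis=1)
    slopes = (dt * (yw - ym[:, None])).sum(axis=1) / denom
    return slopes, tm, ym


def segment_curve(curve: ReleaseCurve, *, window_points: int = 11,
                  smoothing_points: int = 0,
                  theoretical_fa_umol: float | None = None,
                  lag_method: str = "tangent",
                  lag_threshold_fraction: float = 0.01) -> RatePhaseResult:
    """Extract k, lag time, and plateau from a corrected lipolysis curve.

    k is the maximum over sliding windows of the ordinary least-squares
    slope.  ``lag_method="tangent"`` intercepts the maximum-slope tangent
    (through the window centroid) with the zero baseline;
    ``lag_method="threshold"`` takes the first time the release exceeds
    ``lag_threshold_fraction`` of the theoretical release (which must then
    be given).  ``smoothing_points`` > 1 applies a centered moving average
    before slope estimation (default off).
    """
    if window_points < 3:
        raise ValidationError("window_points must be >= 3")
    t = curve.times_min
    y = curve.cumulative_fa_umol
    if t.size < 2 * window_points:
        raise ValidationError(
            f"need >= {2 * window_points} points for window_points="
            f"{window_points}, got {t.size}")
    if smoothing_points > 1:
        kernel = np.ones(smoothing_points) / smoothing_points
        pad = smoothing_points // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[:t.size]

    slopes, tm, ym = _window_slopes(t, y, window_points)
    best = int(np.argmax(slopes))
    k = float(slopes[best])
    window = (float(t[best]), float(t[best + window_points - 1]))

    n_tail = max(1, int(np.ceil(0.1 * t.size)))
    plateau = float(y[-n_tail:].mean())

    lag: float | None
    if k <= 0:
        k = max(k, 0.0)
        lag = None
    elif lag_method == "tangent":
        lag = float(np.clip(tm[best] - ym[best] / k, 0.0, t[-1]))
    elif lag_method == "threshold":
        if theoretical_fa_umol is None:
            raise ValidationError(
                "threshold lag method needs theoretical_fa_umol")
        above = np.nonzero(y >= lag_threshold_fraction * theoretical_fa_umol)[0]
        lag = float(t[above[0]]) if above.size else None
    else:
        raise ValidationError(f"unknown lag_method {lag_method!r}")

    extent = None
    if theoretical_fa_umol is not None and theoretical_fa_umol > 0:
        extent = plateau / theoretical_fa_umol
    return RatePhaseResult(k_umol_min=k, lag_time_min=lag, k_window=window,
                           plateau_umol=plateau, extent_fraction=extent)


# ---------------------------------------------------------------------------
# CSV I/O

def read_titration_csv(path: str | Path, *, titrant_molarity: float,
                       ph9_titrant_volume_ml: float = 0.0,
                       label: str = "") -> TitrationRecord:
    """Read a titration CSV with columns ``time_min`` (or ``time_s``) and
    ``cum_volume_ml``; seconds are converted to minutes."""
    df = pd.read_csv(path)
    if "time_min" in df.columns:
        t = df["time_min"].to_numpy(float)
    elif "time_s" in df.columns:
        t = df["time_s"].to_numpy(float) / 60.0
    else:
        raise ValidationError(
            f"{path}: expected a 'time_min' or 'time_s' column")
    if "cum_volume_ml" not in df.columns:
        raise ValidationError(f"{path}: expected a 'cum_volume_ml' column")
    return TitrationRecord(
        times_min=t, cumulative_volume_ml=df["cum_volume_ml"].to_numpy(float),
        titrant_molarity=titrant_molarity,
        ph9_titrant_volume_ml=ph9_titrant_volume_ml,
        label=label or Path(path).stem)


def write_release_csv(curve: ReleaseCurve, path: str | Path) -> None:
    """Write a release curve CSV plus a JSON provenance sidecar block."""
    pd.DataFrame({"time_min": curve.times_min,
                  "cum_fa_umol": curve.cumulative_fa_umol}).to_csv(
        path, index=False)
    sidecar = Path(path).with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(
        {"label": curve.label, "corrections": curve.corrections,
         "warnings": list(curve.warnings)}, indent=2, sort_keys=True) + "\n")
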