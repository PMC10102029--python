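"""Intrinsic lipolysis rate computation and linear mixing predictions.

The ILR normalises the maximum-rate-phase slope k (µmol/min) of a corrected
lipolysis curve by the total droplet surface area A (cm²):

    ILR = k / A        [µmol·min⁻¹·cm⁻²]

making digestion rates of nanoemulsions with different droplet sizes
directly comparable — the lipolysis analogue of an intrinsic dissolution
rate.  For a mixture, the ILR is predicted as the fatty-acid-fraction
weighted sum of the pure-component ILRs,

    ILR_mix = Σᵢ xᵢ · ILRᵢ,

and the same linear rule can be inverted to estimate the ILR of a component
(e.g. a 1-monoacylglycerol) that cannot be emulsified on its own.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

from .errors import ValidationError
from .titration import RatePhaseResult

FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class IlrResult:
    """ILR of one experiment (stored in base µmol·min⁻¹·cm⁻² units)."""

    ilr: float
    k_umol_min: float
    area_cm2: float
    lag_time_min: float | None = None
    extent_fraction: float | None = None
    formulation_ref: str = ""
    replicate_stats: tuple[float, float] | None = None  # (mean, sd)

    @property
    def ilr_display(self) -> float:
        """ILR on the ×10⁻³ µmol·min⁻¹·cm⁻² report scale."""
        return self.ilr * 1e3


@dataclass(frozen=True)
class MixPrediction:
    """Linear mixing prediction for a multi-component formulation."""

    components: tuple[tuple[str, float, float], ...]  # (name, x, ilr)
    predicted_ilr: float
    experimental_ilr: float | None = None
    relative_deviation_pct: float | None = None

    @property
    def relative_deviation_display(self) -> int | None:
        if self.relative_deviation_pct is None:
            return None
        return round(self.relative_deviation_pct)


def compute_ilr(rate: RatePhaseResult, area_cm2: float,
                formulation_ref: str = "") -> IlrResult:
    """ILR = k / A from a rate-phase result and a total surface area."""
    if area_cm2 <= 0:
        raise ValidationError("surface area must be > 0")
    return IlrResult(
        ilr=rate.k_umol_min / area_cm2,
        k_umol_min=rate.k_umol_min,
        area_cm2=area_cm2,
        lag_time_min=rate.lag_time_min,
        extent_fraction=rate.extent_fraction,
        formulation_ref=formulation_ref)


def aggregate_replicates(results: list[IlrResult],
                         formulation_ref: str = "") -> IlrResult:
    """Mean ± sd ILR over replicate curves (each replicate analysed
    separately, then averaged — not a pooled fit)."""
    if not results:
        raise ValidationError("no replicates to aggregate")
    ilrs = [r.ilr for r in results]
    mean = statistics.fmean(ilrs)
    sd = statistics.stdev(ilrs) if len(ilrs) > 1 else 0.0
    lags = [r.lag_time_min for r in results if r.lag_time_min is not None]
    return IlrResult(
        ilr=mean,
        k_umol_min=statistics.fmean(r.k_umol_min for r in results),
        area_cm2=statistics.fmean(r.area_cm2 for r in results),
        lag_time_min=statistics.fmean(lags) if lags else None,
        formulation_ref=formulation_ref or results[0].formulation_ref,
        replicate_stats=(mean, sd))


def predict_mixed_ilr(components: list[tuple[str, float, float]],
                      ) -> MixPrediction:
    """Predict the ILR of a mixture from (name, fa fraction, pure ILR).

    The prediction is the convex combination Σ xᵢ·ILRᵢ; fractions must sum
    to 1.  Works for any number of components by the same linearity.
    """
    if not components:
        raise ValidationError("no components given")
    total = sum(x for _, x, _ in components)
    if abs(total - 1.0) > FRACTION_TOL:
        raise ValidationError(
            f"fatty-acid fractions must sum to 1, got {total!r}")
    for name, x, ilr in components:
        if x < 0:
            raise ValidationError(f"negative fraction for {name}")
        if ilr < 0:
            raise ValidationError(f"negative ILR for {name}")
    predicted = sum(x * ilr for _, x, ilr in components)
    return MixPrediction(components=tuple(components), predicted_ilr=predicted)


def deviation_report(prediction: MixPrediction, experimental_ilr: float,
                     *, denominator: str = "predicted") -> MixPrediction:
    """Attach the relative deviation (%) between prediction and experiment.

    The deviation is 100·|predicted − experimental| / predicted by default;
    ``denominator="experimental"`` is available but note the two conventions
    differ noticeably when prediction and experiment disagree.
    """
    if denominator == "predicted":
        denom = prediction.predicted_ilr
    elif denominator == "experimental":
        denom = experimental_ilr
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValidationError(
            "relative deviation undefined for a non-positive denominator")
    dev = 100.0 * abs(prediction.predicted_ilr - experimental_ilr) / denom
    return MixPrediction(
        components=prediction.components,
        predicted_ilr=prediction.predicted_ilr,
        experimental_ilr=experimental_ilr,
        relative_deviation_pct=dev)


def invert_component_ilr(mixed_ilr: float,
                         known: tuple[float, float],
                         unknown_fraction: float) -> float:
    """Solve the mixing rule for the unknown component's ILR.

    Given ILR_mix = x_A·ILR_A + x_B·ILR_B with component A known,
    ILR_B = (ILR_mix − x_A·ILR_A) / x_B.  A negative result is physically
    implausible and triggers a warning but is returned as computed.
    """
    x_known, ilr_known = known
    if unknown_fraction <= 0:
        raise ValidationError("unknown component fraction must be > 0")
    if abs(x_known + unknown_fraction - 1.0) > FRACTION_TOL:
        raise ValidationError("fatty-acid fractions must sum to 1")
    ilr_b = (mixed_ilr - x_known * ilr_known) / unknown_fraction
    if ilr_b < 0:
        warnings.warn(
            f"inverted component ILR is negative ({ilr_b:.3g}); the linear "
            "mixing rule is extrapolating beyond physical plausibility",
            stacklevel=2)
    return ilr_b
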