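"""Unit conventions and conversion constants.

Internal unit policy: concentrations in mM, volumes in mL, amounts of fatty
acid in µmol (mmol at the formulation level), times in minutes, droplet
diameters in nm, areas in cm², ILRs in µmol·min⁻¹·cm⁻².  The mechanistic
rate constant is kept in SI (mol·s⁻¹·m⁻²) because that is the unit the
shrinking-droplet literature reports; conversion happens only in reports.
"""

from __future__ import annotations

UMOL_PER_MOL = 1e6
S_PER_MIN = 60.0
CM2_PER_M2 = 1e4
NM_PER_CM = 1e7
M_PER_NM = 1e-9

#: 1 mol·s⁻¹·m⁻² expressed in µmol·min⁻¹·cm⁻²:
#: 1 mol = 1e6 µmol, 1 s⁻¹ = 60 min⁻¹, 1 m⁻² = 1e-4 cm⁻²  →  1e6 · 60 / 1e4
MOL_S_M2_TO_UMOL_MIN_CM2 = UMOL_PER_MOL * S_PER_MIN / CM2_PER_M2

#: Display scale for ILR values in reports (×10⁻³ µmol·min⁻¹·cm⁻²).
ILR_DISPLAY_SCALE = 1e-3


def diluted_concentration(stock_mm: float, stock_volume_ml: float,
                          final_volume_ml: float) -> float:
    """Concentration after dilution of a stock into a final vessel volume.

    E.g. lipolysis medium containing 6 mM sodium taurocholate mixed 1:1
    with nanoemulsion (20 mL + 20 mL) gives 3 mM in the vessel.
    """
    if stock_mm < 0:
        raise ValueError("concentration must be non-negative")
    if stock_volume_ml < 0 or final_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    if final_volume_ml < stock_volume_ml:
        raise ValueError("final volume cannot be smaller than stock volume")
    return stock_mm * stock_volume_ml / final_volume_ml
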