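"""Reported study measurements used as fixture inputs.

The published nanoemulsion panel (composition, DLS diameter, PDI, and the
two digestion rate constants) is included here as *input data*: the ILR
and mechanistic-fit magnitudes in it come from wet-lab pH-stat experiments
and cannot be recomputed at desk scale.  The table drives (a) the linear
mixing-rule predictions, whose arithmetic consequences *are* reproducible,
and (b) the synthetic panel generator, which uses each row's printed
diameter and ILR as ground truth for regression-testing the pipeline.

ILR columns are on the published ×10⁻³ µmol·min⁻¹·cm⁻² display scale.
The 118.5 mM triolein concentration in the last mixture row is reproduced
as printed even though the matching preparation protocol says 118.75 mM;
both appear in the source material and are treated as distinct user inputs.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["name", "dataset", "lipids", "conc_mm", "surfactant_pct",
            "diameter_nm", "diameter_sd_nm", "pdi", "pdi_sd",
            "ilr_e3", "ilr_sd_e3", "mech_e3", "mech_sd_e3"]

_ROWS = [
    # 1. polysorbate 80 concentration series (125 mM tricaprylin)
    ("tricaprylin_ps0.125", 1, ("tricaprylin",), (125.0,), 0.125,
     304, 10, 0.23, 0.01, 8.8, 0.1, None, None),
    ("tricaprylin_ps0.25", 1, ("tricaprylin",), (125.0,), 0.25,
     250, 7, 0.26, 0.006, 6.3, 0.3, None, None),
    ("tricaprylin_ps0.5", 1, ("tricaprylin",), (125.0,), 0.5,
     233, 3, 0.24, 0.007, 5.2, 0.4, None, None),
    ("tricaprylin_ps1", 1, ("tricaprylin",), (125.0,), 1.0,
     211, 4, 0.23, 0.004, 3.6, 0.3, None, None),
    ("tricaprylin_ps1.5", 1, ("tricaprylin",), (125.0,), 1.5,
     204, 5, 0.22, 0.009, 2.9, 0.3, None, None),
    ("tricaprylin_ps2", 1, ("tricaprylin",), (125.0,), 2.0,
     207, 2, 0.22, 0.016, 2.6, 0.4, None, None),
    # 2. pure acylglycerols (125 mM, 0.25% polysorbate 80)
    ("tricaprylin", 2, ("tricaprylin",), (125.0,), 0.25,
     250, 7, 0.26, 0.006, 6.3, 0.3, 4.1, 0.3),
    ("tricaprin", 2, ("tricaprin",), (125.0,), 0.25,
     281, 4, 0.26, 0.002, 2.8, 0.4, 1.8, 0.3),
    ("dilaurin_1_3", 2, ("dilaurin_1_3",), (125.0,), 0.25,
     280, 18, 0.25, 0.016, 2.9, 0.3, 1.8, 0.6),
    ("trilaurin", 2, ("trilaurin",), (125.0,), 0.25,
     298, 12, 0.24, 0.009, 0.9, 0.09, 1.4, 0.2),
    ("triolein", 2, ("triolein",), (125.0,), 0.25,
     400, 10, 0.26, 0.01, 0.26, 0.03, 0.35, 0.04),
    ("trilinolein", 2, ("trilinolein",), (125.0,), 0.25,
     363, 13, 0.23, 0.009, 0.44, 0.04, 0.59, 0.02),
    # 3. binary nanoemulsions
    ("tricaprylin_tricaprin_equal", 3, ("tricaprylin", "tricaprin"),
     (62.5, 62.5), 0.25, 255, 3, 0.23, 0.01, 4.4, 0.2, 3.6, 0.1),
    ("tricaprylin_tricaprin_1to3", 3, ("tricaprylin", "tricaprin"),
     (31.25, 93.75), 0.25, 295, 26, 0.26, 0.014, 3.5, 0.8, 2.2, 0.4),
    ("tricaprylin_triolein_equal", 3, ("tricaprylin", "triolein"),
     (62.5, 62.5), 0.25, 316, 13, 0.23, 0.019, 2.8, 0.1, 1.6, 0.2),
    ("dilaurin_trilaurin_equal", 3, ("dilaurin_1_3", "trilaurin"),
     (62.5, 62.5), 0.25, 282, 8, 0.23, 0.014, 2.1, 0.2, 2.6, 0.03),
    ("trilaurin_monocaprylin_9to1", 3, ("trilaurin", "monocaprylin_1"),
     (112.5, 25.0), 0.25, 216, 8, 0.18, 0.036, 2.3, 0.2, None, None),
    ("trilaurin_monocaprin_19to1", 3, ("trilaurin", "monocaprin_1"),
     (118.75, 12.5), 0.25, 234, 5, 0.19, 0.035, 1.4, 0.07, None, None),
    ("trilaurin_monolaurin_19to1", 3, ("trilaurin", "monolaurin_1"),
     (118.75, 12.5), 0.25, 236, 2, 0.23, 0.005, 1.3, 0.1, None, None),
    ("triolein_monocaprin_19to1", 3, ("triolein", "monocaprin_1"),
     (118.5, 12.5), 0.25, 299, 6, 0.17, 0.033, 0.7, 0.07, None, None),
]

#: Names of the binary triacyl-/diacylglycerol mixtures whose ILRs were both
#: measured and predictable from pure components (no monoacylglycerols).
BINARY_TAG_MIXTURES = (
    "tricaprylin_tricaprin_equal",
    "tricaprylin_tricaprin_1to3",
    "tricaprylin_triolein_equal",
    "dilaurin_trilaurin_equal",
)


def reported_nanoemulsion_table() -> pd.DataFrame:
    """The published nanoemulsion panel as a DataFrame, indexed by row name.

    dataset 1: surfactant series; 2: pure acylglycerols; 3: binary mixes.
    """
    df = pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("name")
    return df


def pure_ilrs() -> dict[str, float]:
    """Reported pure-component ILRs (×10⁻³ scale) keyed by lipid name."""
    df = reported_nanoemulsion_table()
    return {row.lipids[0]: row.ilr_e3
            for row in df[df.dataset == 2].itertuples()}
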