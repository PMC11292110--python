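"""Published reference values for CysLTR1 ligands on an immobilized column.

Literature-reported numbers for the four ligands studied on an
immobilized cysteinyl leukotriene receptor 1 (CysLTR1) column:
zafirlukast, pranlukast, MK-571 and rosmarinic acid. These are inputs to
the desk analyses (parameter extraction from the published best-fit
lines, ligand ranking, capacity-factor arithmetic) and the defaults of
the synthetic-chromatogram generator.

Note: the reported zafirlukast K_A (2.193e5 L/mol) is not the negative
reciprocal of the reported zafirlukast slope (-4.02e-6 implies 2.49e5);
the discrepancy is internal to the source data. The other three ligands
are consistent to <= 0.25%.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ANALYTES",
    "FIT_LINES",
    "REPORTED_K_A",
    "REPORTED_N_A",
    "REPORTED_R",
    "RETENTION_TIMES_MIN",
    "VOID_MARKER",
    "VOID_TIME_MIN",
    "BINDING_FLOW_ML_MIN",
    "INJECTION_VOLUME_L",
    "CONCENTRATION_GRIDS_MM",
    "STABILITY_RSD_PERCENT",
]

ANALYTES = ("zafirlukast", "pranlukast", "mk571", "rosmarinic_acid")

#: best-fit lines of the linearized overload plots, (slope mol/L, intercept mol)
FIT_LINES: dict[str, tuple[float, float]] = {
    "zafirlukast": (-4.02e-6, 2.30e-8),
    "pranlukast": (-2.09e-6, 2.6e-8),
    "mk571": (-2.43e-6, 2.11e-8),
    "rosmarinic_acid": (-1.376e-6, 1.24e-8),
}

#: reported association constants, L/mol
REPORTED_K_A: dict[str, float] = {
    "zafirlukast": 2.193e5,
    "pranlukast": 4.789e5,
    "mk571": 4.272e5,
    "rosmarinic_acid": 7.268e5,
}

#: reported binding-site amounts (intercepts), mol
REPORTED_N_A: dict[str, float] = {
    "zafirlukast": 2.299e-8,
    "pranlukast": 2.598e-8,
    "mk571": 2.094e-8,
    "rosmarinic_acid": 1.237e-8,
}

#: reported correlation coefficients of the linearized fits
REPORTED_R: dict[str, float] = {
    "zafirlukast": 0.9686,
    "pranlukast": 0.9511,
    "mk571": 0.9674,
    "rosmarinic_acid": 0.9771,
}

VOID_MARKER = "sodium_nitrite"
VOID_TIME_MIN = 0.298

#: single-injection retention times on the receptor column, minutes
RETENTION_TIMES_MIN: dict[str, float] = {
    VOID_MARKER: VOID_TIME_MIN,
    "zafirlukast": 5.281,
    "mk571": 7.234,
    "pranlukast": 8.358,
}

BINDING_FLOW_ML_MIN = 0.6
INJECTION_VOLUME_L = 10e-6  # 10 uL

#: concentration series injected per ligand, mM
CONCENTRATION_GRIDS_MM: dict[str, np.ndarray] = {
    "zafirlukast": np.round(np.arange(0.1, 1.05, 0.1), 3),
    "pranlukast": np.round(np.arange(0.2, 1.05, 0.1), 3),
    "mk571": np.round(np.arange(0.3, 1.05, 0.1), 3),
    "rosmarinic_acid": np.round(np.arange(0.3, 1.15, 0.1), 3),
}

#: retention-time RSD of the stability probe over the column lifetime
STABILITY_RSD_PERCENT = 0.5
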