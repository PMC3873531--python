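"""Unit conversions used throughout the simulator.

Geometry is handled in micrometers at the API surface and centimeters inside
the finite-difference machinery.  Drug exposures are micromolar-hours (μM·h)
at the surface and time-integrated molar concentration (mol·s/cm³) internally,
so that wall-flux surface integrals yield amounts (mol) directly.  Oxygen is
carried as partial pressure (mm Hg) and converted to dissolved concentration
(μM) via the solubility coefficient.
"""

from __future__ import annotations

#: cm per μm
CM_PER_UM = 1.0e-4

#: cm³/s per nl/min
CM3_S_PER_NL_MIN = 1.0e-6 / 60.0

#: mol·s/cm³ per μM·h  (1 μM·h = 1e-6 mol/L × 3600 s = 3.6e-3 mol·s/L)
MOL_S_CM3_PER_UM_H = 3.6e-6

#: molar volume of an ideal gas at standard conditions, cm³ O2 per mol
O2_MOLAR_VOLUME_CM3 = 22_414.0

#: pmol per mol
PMOL_PER_MOL = 1.0e12


def pO2_to_uM(pO2_mmHg, alpha: float = 3.1e-5):
    """Convert O2 partial pressure (mm Hg) to dissolved concentration (μM).

    ``alpha`` is the O2 solubility in cm³ O2/cm³/mm Hg.  With the default
    solubility 1 mm Hg corresponds to ≈1.383 μM.
    """
    # cm³O2/cm³ → mol/cm³ → μmol/L: ×1e3 (cm³→L) ×1e6 (mol→μmol)
    return pO2_mmHg * alpha / O2_MOLAR_VOLUME_CM3 * 1.0e9


def uM_to_pO2(o2_uM, alpha: float = 3.1e-5):
    """Inverse of :func:`pO2_to_uM`."""
    return o2_uM * O2_MOLAR_VOLUME_CM3 / (alpha * 1.0e9)


def uM_h_to_mol_s_cm3(auc_uM_h):
    return auc_uM_h * MOL_S_CM3_PER_UM_H


def mol_s_cm3_to_uM_h(auc):
    return auc / MOL_S_CM3_PER_UM_H


def wall_K_to_s_per_cm(K_s_per_um: float) -> float:
    """Intravascular wall resistance K from s/μm to s/cm."""
    return K_s_per_um * 1.0e4
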