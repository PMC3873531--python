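"""Systemic-exposure accounting for effector washed out of a tumor.

Scales the per-volume net transvascular amounts computed by the transport
model to a whole tumor, converts released amounts to bolus-equivalent
plasma AUC contributions via total clearance (worst case: the entire
amount released at once), and expresses the result as a percent elevation
of the measured systemic effector exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["SystemicParameters", "scale_release", "release_to_plasma_auc",
           "percent_plasma_elevation"]


@dataclass(frozen=True)
class SystemicParameters:
    """Whole-body PK constants for one species (metabolite)."""

    V_D: float                  # l/kg, distribution volume
    CL: float                   # l/h/kg, total clearance
    body_weight: float = 0.025  # kg
    tumor_volume: float = 600.0  # mm³
    plasma_free_AUC: float = 0.0  # μM·h, measured systemic exposure

    def __post_init__(self):
        if min(self.V_D, self.CL, self.body_weight, self.tumor_volume) <= 0:
            raise ValueError("all systemic parameters must be positive")


def scale_release(per_volume: float, tumor_volume: float) -> float:
    """Whole-tumor amount (nmol) from per-volume release (pmol/mm³).

    Sign is preserved (negative = extracted from plasma).
    """
    if tumor_volume <= 0:
        raise ValueError("tumor volume must be positive")
    return per_volume * tumor_volume / 1000.0


def release_to_plasma_auc(amount_nmol: float, CL: float,
                          body_weight: float) -> float:
    """Bolus-equivalent plasma AUC (μM·h) of an amount cleared at CL·BW.

    AUC = amount / (CL × BW): nmol/(l/h) = nM·h, /1000 → μM·h.
    """
    if CL <= 0 or body_weight <= 0:
        raise ValueError("CL and body weight must be positive")
    return amount_nmol / (CL * body_weight) / 1000.0


def percent_plasma_elevation(released_auc_by_species: Mapping[str, float],
                             plasma_auc_by_species: Mapping[str, float]) -> float:
    """Percent elevation of systemic exposure: 100·Σreleased/Σplasma.

    Only species present in ``released_auc_by_species`` are summed in the
    numerator; the denominator sums the corresponding measured plasma AUCs.
    """
    total_plasma = sum(plasma_auc_by_species.values())
    if total_plasma <= 0:
        raise ValueError("total plasma AUC must be positive")
    total_released = sum(released_auc_by_species.values())
    return 100.0 * total_released / total_plasma
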