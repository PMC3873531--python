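"""Cell-kill computation: effector PD, radiation LQ with oxygen enhancement.

Drug-induced clonogenic kill follows a log-linear exposure–response,
−log10 SP = a·AUCiE, with potency ``a`` the reciprocal of the intracellular
effector AUC giving 10% survival.  Two potency conventions are supported:
case 1, where ``a`` scales with effector reactivity k_metE (irreversible
binders such as DNA alkylators), and case 2, where ``a`` is independent of
k_metE (reversible inhibitors).

Radiation kill uses the linear-quadratic model with hypoxic coefficients
α_H, β_H and oxygen acting as a dose-modifying factor
f([O2]) = 1 + (OER−1)·[O2]/([O2]+K_ms), pinned by f(0)=1,
f(K_ms)=(1+OER)/2 and f(∞)=OER.  Drug and radiation combine
log-additively; region summaries use log cell kill = −log10(mean SP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .network import ScalarField
from .oxygen import OxygenSolution
from .transport import TransportSolution

__all__ = [
    "PotencyModel", "RadiationParameters", "KillResult", "potency",
    "drug_survival", "radiation_survival", "combine", "log_cell_kill",
    "additional_kill", "selectivity_ratio", "survival_vs_o2",
    "calibrate_no_bystander_potency", "compute_kill",
]


@dataclass(frozen=True)
class PotencyModel:
    """Effector potency convention.

    case 1: a = a_ref·(k_metE/k_metE_ref) — potency scales with reactivity.
    case 2: a = a_ref — potency independent of reactivity.
    """

    case: int = 1
    a_ref: float = 0.200        # (μM·h)⁻¹
    kmetE_ref: float = 0.01     # s⁻¹

    def __post_init__(self):
        if self.case not in (1, 2):
            raise ValueError("case must be 1 or 2")
        if self.a_ref <= 0 or self.kmetE_ref <= 0:
            raise ValueError("a_ref and kmetE_ref must be positive")


def potency(model: PotencyModel, kmetE: float) -> float:
    """Potency a (μM·h)⁻¹ for the given effector loss rate constant."""
    if kmetE <= 0:
        raise ValueError("kmetE must be positive")
    if model.case == 1:
        return model.a_ref * kmetE / model.kmetE_ref
    return model.a_ref


@dataclass(frozen=True)
class RadiationParameters:
    """LQ radiosensitivity under hypoxia with maximal enhancement OER."""

    alpha_H: float = 0.0663     # Gy⁻¹
    beta_H: float = 0.0028      # Gy⁻²
    OER_alpha: float = 2.8
    OER_beta: float = 2.8
    Kms: float = 4.2            # μM, O2 for half-maximum radiosensitization
    dose: float = 15.0          # Gy

    def __post_init__(self):
        if self.OER_alpha < 1 or self.OER_beta < 1:
            raise ValueError("OER must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if min(self.alpha_H, self.beta_H, self.Kms) <= 0:
            raise ValueError("alpha_H, beta_H, Kms must be positive")


def drug_survival(AUCiE: ScalarField, a: float) -> ScalarField:
    """Survival probability field SP = 10^(−a·AUCiE)."""
    sp = np.power(10.0, -a * AUCiE.values)
    return ScalarField(AUCiE.domain, sp, "survival_probability")


def _dose_modifying_factor(o2_uM, params: RadiationParameters, oer: float):
    return 1.0 + (oer - 1.0) * o2_uM / (o2_uM + params.Kms)


def radiation_survival(o2_uM: ScalarField,
                       params: RadiationParameters) -> ScalarField:
    """LQ survival with O2 as a dose-modifying factor on the α and β terms."""
    o2 = o2_uM.values
    fa = _dose_modifying_factor(o2, params, params.OER_alpha)
    fb = _dose_modifying_factor(o2, params, params.OER_beta)
    d = params.dose
    sp = np.exp(-params.alpha_H * fa * d - params.beta_H * (fb * d) ** 2)
    return ScalarField(o2_uM.domain, sp, "survival_probability")


def combine(sp_drug: ScalarField, sp_rad: ScalarField) -> ScalarField:
    """Log-additive combination (independent kill): SP = SP_drug · SP_rad."""
    if sp_drug.values.shape != sp_rad.values.shape:
        raise ValueError("survival fields are on different grids")
    return ScalarField(sp_drug.domain, sp_drug.values * sp_rad.values,
                       "survival_probability")


def log_cell_kill(sp: ScalarField) -> float:
    """Region log cell kill = −log10(mean SP over active voxels)."""
    m = float(sp.active_values().mean())
    return -float(np.log10(m)) if m > 0 else np.inf


def additional_kill(sp_drug: ScalarField, sp_rad: ScalarField) -> float:
    """Drug-induced kill additional to radiation (difference of log kills)."""
    return log_cell_kill(combine(sp_drug, sp_rad)) - log_cell_kill(sp_rad)


def selectivity_ratio(tumor_kill: float, normal_kill: float) -> float:
    """Tumor:normal ratio of log cell kill; +inf (with warning) at zero normal kill."""
    if normal_kill == 0:
        warnings.warn("normal-tissue kill is zero; selectivity undefined (+inf)",
                      stacklevel=2)
        return np.inf
    return tumor_kill / normal_kill


def survival_vs_o2(sp: ScalarField, o2_uM: ScalarField,
                   bin_edges) -> pd.DataFrame:
    """Geometric-mean SP per O2 bin (edge-open outer bins)."""
    spv = sp.active_values()
    o2v = o2_uM.active_values()
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(o2v, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = spv[idx == b]
        gm = float(np.exp(np.mean(np.log(np.maximum(sel, 1e-300))))) \
            if sel.size else np.nan
        rows.append((edges[b], edges[b + 1], sel.size, gm))
    return pd.DataFrame(rows, columns=["bin_left_uM", "bin_right_uM",
                                       "count", "geometric_mean_SP"])


@dataclass
class KillResult:
    """Survival fields and region kill summaries for one simulation arm set."""

    sp_drug: ScalarField
    sp_rad: ScalarField
    sp_combined: ScalarField
    kill_drug: float
    kill_rad: float
    kill_combined: float
    additional_kill: float
    by_o2: pd.DataFrame
    selectivity: Optional[float] = None


def compute_kill(transport: TransportSolution, oxygen: OxygenSolution,
                 a: float, radiation: RadiationParameters,
                 o2_bin_edges=None) -> KillResult:
    """Full PD evaluation of a solved transport/oxygen pair."""
    if transport.AUCiE is None:
        raise ValueError("effector not solved; run solve_effector first")
    sp_d = drug_survival(transport.AUCiE, a)
    sp_r = radiation_survival(oxygen.tissue_O2_uM, radiation)
    sp_c = combine(sp_d, sp_r)
    if o2_bin_edges is None:
        o2_bin_edges = np.concatenate([[0.0], np.logspace(-2, 2, 17)])
    return KillResult(
        sp_drug=sp_d, sp_rad=sp_r, sp_combined=sp_c,
        kill_drug=log_cell_kill(sp_d),
        kill_rad=log_cell_kill(sp_r),
        kill_combined=log_cell_kill(sp_c),
        additional_kill=log_cell_kill(sp_c) - log_cell_kill(sp_r),
        by_o2=survival_vs_o2(sp_d, oxygen.tissue_O2_uM, o2_bin_edges),
    )


def calibrate_no_bystander_potency(target_kill: float,
                                   AUCiE: ScalarField,
                                   sp_rad: ScalarField,
                                   a_bracket=(1e-8, 1e4),
                                   rtol: float = 1e-6) -> float:
    """Potency ``a`` at which additional-to-radiation kill equals ``target_kill``.

    Additional kill is continuous and strictly increasing in ``a`` (the drug
    log-kill field scales linearly with ``a``), so a bracketed root find
    converges to the unique calibrated potency.  Raises if the bracket does
    not contain the target.
    """
    def f(a: float) -> float:
        return additional_kill(drug_survival(AUCiE, a), sp_rad) - target_kill

    lo, hi = a_bracket
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target kill not bracketed by the potency interval")
    return float(brentq(f, lo, hi, rtol=rtol))
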