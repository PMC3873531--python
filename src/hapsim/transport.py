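"""Steady-state prodrug and effector exposure fields (AUC formalism).

For linear PK the time-integrated concentration (AUC) obeys the same
reaction–diffusion equations as concentration, so steady AUC fields fully
describe exposure.  Tissue is two well-mixed compartments: prodrug and
effector diffuse extracellularly (volume-averaged coefficient D_N) and
exchange with cells at first-order rate k_tN; prodrug activation (rate
k_metP, oxygen-inhibited) is intracellular and sources the effector at the
rate prodrug is lost; effector is inactivated intracellularly at k_metE.
The intracellular compartment is eliminated algebraically, leaving one
elliptic equation per species on the voxel grid.

Intravascular prodrug is depleted along each segment by wall flux; effector
released across vessel walls is treated as lost to the circulation (no
blood-borne re-entry downstream).  All internal math runs in mol·s/cm³ so
that wall-flux sums are amounts (mol); the API uses μM·h and pmol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._fd import (Grid, SubsegmentTable, build_blood_topology, build_grid,
                  build_subsegments, solve_coupled_linear, solve_linear)
from .network import ScalarField, TissueDomain, VesselNetwork
from .oxygen import OxygenSolution
from .units import MOL_S_CM3_PER_UM_H, PMOL_PER_MOL, wall_K_to_s_per_cm

__all__ = [
    "ProdrugParameters", "EffectorParameters", "TransportSolution",
    "activation_rate", "intracellular_prodrug", "solve_prodrug",
    "solve_effector", "net_transvascular_per_volume",
]


@dataclass(frozen=True)
class ProdrugParameters:
    """Prodrug PK parameter set (base-model defaults)."""

    auc_inflow: float = 50.0     # μM·h, unbound plasma AUC in feeding vessels
    kmetP_max: float = 0.01      # s⁻¹, activation rate under anoxia
    KO2: float = 0.126           # μM, O2 for half-maximum activation
    ktP: float = 0.1             # s⁻¹, membrane transfer rate constant
    D_P: float = 1.0e-6          # cm²/s, volume-averaged tissue diffusion coeff.
    phi_i: float = 0.4           # intracellular volume fraction
    wall_K: float = 0.1          # s/μm, intravascular resistance (negligible)

    def __post_init__(self):
        for name in ("auc_inflow", "KO2", "D_P", "wall_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ktP < 0 or self.kmetP_max < 0:
            raise ValueError("ktP and kmetP_max must be >= 0")
        if not 0.0 < self.phi_i < 1.0:
            raise ValueError("phi_i must lie in (0, 1)")

    @property
    def phi_e(self) -> float:
        return 1.0 - self.phi_i


@dataclass(frozen=True)
class EffectorParameters:
    """Effector PK parameter set; ``ktE = 0`` disables the bystander effect."""

    kmetE: float = 0.01          # s⁻¹, rate constant for loss of effector
    ktE: float = 0.01            # s⁻¹, membrane transfer (0 ⇒ no bystander)
    D_E: float = 1.0e-6          # cm²/s
    vessel_permeable: bool = True
    auc_inflow: float = 0.0      # μM·h effector arriving in plasma
    wall_K: float = 0.1          # s/μm

    def __post_init__(self):
        if self.kmetE <= 0:
            raise ValueError("kmetE must be positive")
        if self.ktE < 0 or self.auc_inflow < 0 or self.D_E <= 0 or self.wall_K <= 0:
            raise ValueError("effector parameters out of range")


def activation_rate(o2_uM, KO2: float, kmetP_max: float):
    """O2-inhibited prodrug activation rate k_metP = k_metP,max·KO2/(KO2+[O2])."""
    o2 = np.asarray(o2_uM, dtype=float)
    out = kmetP_max * KO2 / (KO2 + o2)
    return out if out.ndim else float(out)


def intracellular_prodrug(AUCeP, ktP: float, kmetP):
    """Steady intracellular prodrug AUC: AUCiP = ktP·AUCeP/(ktP + kmetP)."""
    e = np.asarray(AUCeP, dtype=float)
    k = np.asarray(kmetP, dtype=float)
    denom = ktP + k
    out = np.where(denom > 0, ktP * e / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class TransportSolution:
    """Steady AUC fields plus per-segment transvascular amount accounting.

    ``segment_amounts`` holds the net transvascular amount per vessel
    segment in pmol with the plasma-centric sign convention: negative =
    extracted from plasma into tissue, positive = released into plasma.
    """

    network: VesselNetwork
    domain: TissueDomain
    AUCeP: ScalarField
    AUCiP: ScalarField
    kmetP_per_s: np.ndarray            # activation-rate field (active voxels)
    phi_i: float                       # intracellular volume fraction used
    segment_amounts: pd.DataFrame      # segment_id, prodrug_pmol[, effector_pmol]
    prodrug_balance_error: float
    AUCeE: Optional[ScalarField] = None
    AUCiE: Optional[ScalarField] = None
    effector_balance_error: Optional[float] = None
    effector_produced_pmol: Optional[float] = None
    effector_degraded_pmol: Optional[float] = None


def _field(domain: TissueDomain, grid: Grid, values: np.ndarray,
           quantity: str) -> ScalarField:
    full = np.full(domain.shape, np.nan)
    full[tuple(grid.active_ijk.T)] = np.maximum(values, 0.0)
    return ScalarField(domain, full, quantity)


def _segment_release_pmol(network: VesselNetwork, subs: SubsegmentTable,
                          q_wall: np.ndarray) -> pd.DataFrame:
    """Aggregate wall fluxes to per-segment released amounts (pmol)."""
    rows = []
    for seg in network.segments:
        sl = subs.seg_ptr[seg.id]
        rows.append((seg.id, -float(q_wall[sl].sum()) * PMOL_PER_MOL))
    return pd.DataFrame(rows, columns=["segment_id", "released_pmol"])


def solve_prodrug(network: VesselNetwork, domain: TissueDomain,
                  oxygen_solution: OxygenSolution, params: ProdrugParameters,
                  ) -> TransportSolution:
    """Solve the steady extracellular prodrug AUC field.

    The intracellular compartment is eliminated: the tissue equation is
    0 = D_P ∇²AUCeP − k_eff(x)·AUCeP with
    k_eff = φ_i·k_tP·k_metP(x)/(k_tP + k_metP(x)), coupled to intravascular
    depletion along flow.  The whole system (tissue AUC plus blood AUC per
    subsegment) is linear and solved monolithically in one sparse solve, so
    the extraction bookkeeping closes to machine precision.
    """
    network.validate()
    grid = build_grid(domain)
    subs = build_subsegments(network, grid, D=params.D_P,
                             wall_K_s_per_cm=wall_K_to_s_per_cm(params.wall_K),
                             species="prodrug")
    topo = build_blood_topology(network, subs)
    o2 = oxygen_solution.tissue_O2_uM.values[tuple(grid.active_ijk.T)]
    kmet = activation_rate(o2, params.KO2, params.kmetP_max)
    denom = params.ktP + kmet
    k_eff = np.where(denom > 0,
                     params.phi_i * params.ktP * kmet / np.where(denom > 0, denom, 1.0),
                     0.0)
    vol = grid.voxel_volume_cm3
    inflow = {b.node_id: b.auc_prodrug_uM_h * MOL_S_CM3_PER_UM_H
              for b in network.inflow_boundaries}
    x, _, q_wall = solve_coupled_linear(grid, subs, topo, params.D_P, k_eff,
                                        inflow)
    extracted = float(q_wall.sum())                       # mol, blood→tissue
    metabolized = float(np.sum(k_eff * x) * vol)          # mol
    scale = max(abs(extracted), abs(metabolized), 1e-300)
    balance_err = abs(extracted - metabolized) / scale if metabolized > 0 else 0.0
    auc_e = x / MOL_S_CM3_PER_UM_H
    auc_i = intracellular_prodrug(auc_e, params.ktP, kmet)
    amounts = _segment_release_pmol(network, subs, q_wall)
    amounts = amounts.rename(columns={"released_pmol": "prodrug_pmol"})
    return TransportSolution(
        network=network, domain=domain,
        AUCeP=_field(domain, grid, auc_e, "uM_h"),
        AUCiP=_field(domain, grid, auc_i, "uM_h"),
        kmetP_per_s=kmet,
        phi_i=params.phi_i,
        segment_amounts=amounts,
        prodrug_balance_error=balance_err,
    )


def solve_effector(network: VesselNetwork, domain: TissueDomain,
                   oxygen_solution: OxygenSolution,
                   prodrug_solution: TransportSolution,
                   params: EffectorParameters) -> TransportSolution:
    """Solve the steady effector AUC fields given a solved prodrug field.

    The effector is sourced intracellularly at the rate prodrug is lost,
    r_E(x) = φ_i·k_metP(x)·AUCiP(x); with ``ktE = 0`` (no bystander) the
    field solve is skipped and AUCiE = (k_metP/k_metE)·AUCiP voxelwise.
    Effector crossing into vessels (if permeable) is counted as washed out.
    """
    grid = build_grid(domain)
    phi_i = prodrug_solution.phi_i
    kmet = prodrug_solution.kmetP_per_s
    auci_p = prodrug_solution.AUCiP.values[tuple(grid.active_ijk.T)] \
        * MOL_S_CM3_PER_UM_H
    r_e = phi_i * kmet * auci_p                 # mol/cm³ produced over exposure
    vol = grid.voxel_volume_cm3
    n = grid.n
    amounts = prodrug_solution.segment_amounts.copy()
    if params.ktE == 0.0:
        auci_e = (kmet / params.kmetE) * auci_p
        produced = float(np.sum(r_e) * vol)
        degraded = float(np.sum(phi_i * params.kmetE * auci_e) * vol)
        amounts["effector_pmol"] = 0.0
        sol_auce = _field(domain, grid, np.zeros(n), "uM_h")
        sol_auci = _field(domain, grid, auci_e / MOL_S_CM3_PER_UM_H, "uM_h")
        err = abs(produced - degraded) / max(produced, 1e-300)
        return _with_effector(prodrug_solution, sol_auce, sol_auci, amounts,
                              err, produced, degraded)
    subs = build_subsegments(network, grid, D=params.D_E,
                             wall_K_s_per_cm=wall_K_to_s_per_cm(params.wall_K),
                             species="effector")
    gamma = subs.gamma if params.vessel_permeable else np.zeros_like(subs.gamma)
    gamma_acc = np.zeros(n)
    np.add.at(gamma_acc, subs.voxel, gamma)
    k_eff = phi_i * params.ktE * params.kmetE / (params.ktE + params.kmetE)
    source = (params.ktE / (params.ktE + params.kmetE)) * r_e
    a_blood = params.auc_inflow * MOL_S_CM3_PER_UM_H  # constant: loss-only model
    A = params.D_E * grid.lap_geom + sp.diags(k_eff * vol + gamma_acc)
    rhs = source * vol
    rhs_v = np.zeros(n)
    np.add.at(rhs_v, subs.voxel, gamma * a_blood)
    ce = solve_linear(A, rhs + rhs_v)
    ci = (phi_i * params.ktE * ce + r_e) / (phi_i * (params.ktE + params.kmetE))
    # per-segment washout (tissue → blood positive)
    q_out = gamma * (ce[subs.voxel] - a_blood)
    rows = []
    for seg in network.segments:
        sl = subs.seg_ptr[seg.id]
        rows.append(float(q_out[sl].sum()) * PMOL_PER_MOL)
    amounts["effector_pmol"] = rows
    produced = float(np.sum(r_e) * vol)
    degraded = float(np.sum(phi_i * params.kmetE * ci) * vol)
    washout = float(q_out.sum())
    err = abs(produced - degraded - washout) / max(produced, 1e-300)
    return _with_effector(prodrug_solution,
                          _field(domain, grid, ce / MOL_S_CM3_PER_UM_H, "uM_h"),
                          _field(domain, grid, ci / MOL_S_CM3_PER_UM_H, "uM_h"),
                          amounts, err, produced, degraded)


def _with_effector(base: TransportSolution, auce: ScalarField,
                   auci: ScalarField, amounts: pd.DataFrame, err: float,
                   produced: float, degraded: float) -> TransportSolution:
    return TransportSolution(
        network=base.network, domain=base.domain,
        AUCeP=base.AUCeP, AUCiP=base.AUCiP, kmetP_per_s=base.kmetP_per_s,
        phi_i=base.phi_i, segment_amounts=amounts,
        prodrug_balance_error=base.prodrug_balance_error,
        AUCeE=auce, AUCiE=auci, effector_balance_error=err,
        effector_produced_pmol=produced * PMOL_PER_MOL,
        effector_degraded_pmol=degraded * PMOL_PER_MOL,
    )


def net_transvascular_per_volume(solution: TransportSolution,
                                 species: str) -> float:
    """Net transvascular amount per tissue volume (pmol/mm³).

    ``species`` is ``"prodrug"`` or ``"effector"``.  Negative = net
    extraction from plasma; positive = net release into plasma.
    """
    col = {"prodrug": "prodrug_pmol", "effector": "effector_pmol"}[species]
    if col not in solution.segment_amounts:
        raise ValueError(f"{species} amounts not present; run the {species} solve")
    total = float(solution.segment_amounts[col].sum())
    return total / solution.network.region_volume_mm3
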