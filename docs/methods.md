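# Methods

## Model overview

`hapsim` computes steady-state fields of oxygen, a hypoxia-activated
prodrug (HAP), and its cytotoxic effector in a voxelized 3D tissue
microregion perfused by an explicit microvascular network, then converts
intracellular effector exposure into clonogenic cell kill, alone and
combined with a single radiation dose.

The pharmacokinetic state variable for prodrug and effector is the
time-integrated free concentration (AUC).  For linear kinetics the AUC
obeys the same reaction–diffusion equations as concentration, so one
steady solve captures the whole exposure history; this is what makes a
time-independent ("spatially resolved PK/PD") treatment possible.  The
formalism cannot represent time-dependent phenomena — cycling hypoxia,
reoxygenation, saturable metabolism — and does not try to.

### Oxygen

Blood carries O2 as hemoglobin-bound (Hill binding, coefficient n,
half-saturation P50, red-cell capacity C0, discharge hematocrit H_D) plus
dissolved (solubility α) content.  Along each cylindrical segment the
content flux Q·C(pO2) decreases by the wall flux; at junctions streams mix
flow-weighted.  In tissue, pO2 obeys

    αD ∇²P = M0·P/(P + Km)

with the Krogh diffusion coefficient αD and Michaelis–Menten consumption.
The outer boundary is closed (no-flux), so delivered O2 must equal
consumed O2 at steady state — audited in every solve.

O2 wall exchange is treated as quasi-equilibrium through a small
intravascular resistance (default K = 1e-5 s/μm).  The literature states
intravascular resistance only for drugs; treating the O2 wall as nearly
transparent is this package's choice and is exposed as a parameter.

### Prodrug and effector

Tissue is two well-mixed compartments: extracellular (volume fraction
φ_e = 1 − φ_i), where diffusion happens with volume-averaged coefficient
D_N, and intracellular, exchanging at first-order rate k_tN.  Prodrug
activation is intracellular and O2-inhibited,

    k_metP([O2]) = k_metP,max · KO2 / (KO2 + [O2]),

so activation is half-maximal at [O2] = KO2.  At steady state the
intracellular compartment is eliminated algebraically: the extracellular
prodrug AUC solves a single elliptic equation with effective sink
k_eff = φ_i·k_tP·k_metP/(k_tP + k_metP), and AUC_iP =
k_tP·AUC_eP/(k_tP + k_metP).

The effector is produced intracellularly at exactly the rate prodrug is
lost (r_E = φ_i·k_metP·AUC_iP), is inactivated at k_metE, and exchanges
with the extracellular space at k_tE.  k_tE = 0 is the "no bystander"
limit: the field solve is skipped and AUC_iE = (k_metP/k_metE)·AUC_iP
holds voxel by voxel.  Vessel walls may be permeable to the effector;
effector entering blood is counted as washed out and lost.  A possible
blood-borne bystander effect (re-entry of washed-out effector in
downstream tissue) is deliberately not modeled — washout is a pure loss
term — so washout estimates are conservative upper bounds on the
protective effect of vessels.

All internal transport math runs in time-integrated molar units
(mol·s/cm³) so that wall-flux sums are amounts (mol); the API uses μM·h
and pmol.  Per-segment net transvascular amounts use the plasma-centric
sign convention: negative = extracted from plasma, positive = released
into plasma.

### Pharmacodynamics

Drug kill is log-linear in intracellular effector exposure,
−log10 SP = a·AUC_iE, with potency a the reciprocal exposure for 10%
survival.  Two potency conventions: case 1, a ∝ k_metE (irreversible
binders — faster-reacting effectors are proportionally more toxic), and
case 2, a independent of k_metE (reversible inhibitors).

Radiation kill uses the linear-quadratic model with hypoxic coefficients
α_H, β_H and oxygen as a dose-modifying factor

    f([O2]) = 1 + (OER − 1)·[O2]/([O2] + K_ms),

applied identically to the α and β terms (OER_α = OER_β).  The exact
historical O2-dependence function is not restated in the source
literature; this Alper–Howard–Flanders-type form is adopted here and
pinned by its three anchors f(0) = 1, f(K_ms) = (1+OER)/2, f(∞) = OER.
Drug and radiation combine log-additively (independent action).  Region
summaries use log cell kill = −log10(mean SP); logs are base 10
throughout, with natural log only inside the LQ exponent.
`calibrate_no_bystander_potency` root-finds the potency at which a
no-bystander configuration matches a target additional-to-radiation kill,
exploiting exact monotonicity in a.

### Systemic exposure

Per-volume transvascular amounts scale linearly to a whole tumor (default
600 mm³).  Released amounts convert to bolus-equivalent plasma AUC via
total clearance CL×BW — the worst case in which everything released
enters plasma at once — and are expressed as a percent elevation of the
measured systemic effector AUC.  Body weight is an explicit input
(default 0.025 kg): the published per-row AUC values back-compute to
≈25 g even though the underlying PK study used 18–20 g mice, so the
percent-elevation pathway, not the body weight, is the reproduced
quantity.

## Synthetic networks

The mapped tumor and muscle microvascular networks behind the original
analyses are not public.  The generators emulate their summary statistics
rather than their geometry:

- `generate_tumor_like`: a sparse random parallel array (default 18
  vessels in a 600×500×200 μm box, h = 10 μm → 60×50×20 voxels) with
  log-normal diameters (median 8 μm, σ_log 0.5) and flows (σ_log 1.0),
  total inflow Q/V = 333 nl/min/mm³.  Placement is rejection-sampled so
  ≥10% of tissue lies >50 μm from any vessel with a cap near 110 μm —
  the long-diffusion-distance signature of a poorly perfused tumor.
- `generate_normal_like`: a jittered lattice (spacing 60 μm) of
  near-uniform vessels, Q/V = 824 nl/min/mm³, guaranteeing every point is
  within 50 μm of a vessel — an efficient muscle-style microcirculation.
  Its O2 consumption default (M0 = 1.62e-3 cm³O2/cm³/s) is calibrated
  once so this geometry shows a mildly hypoxic fraction of ≈7.5% (<4 μM)
  with essentially no severe hypoxia, the oxygenation contrast that
  drives tumor-vs-normal selectivity.

Both are parallel arrays with one inflow per vessel: flow conservation is
structural, and the acyclic-topology restriction (trees/parallel arrays)
keeps intravascular transport single-pass.  What these fixtures do *not*
reproduce: mapped-network branching, tortuosity, flow correlations, and
the exact hypoxic fractions of the original regions.  Directional and
oracle-based conclusions transfer; absolute kill numbers do not.

## Numerics

- Grid: regular voxels, value at the center, 7-point Laplacian, no-flux
  outer and mask boundaries.  An optional mask restricts the active
  region (cylinder for the single-vessel oracle; within-50-μm masks for
  muscle-style regions).
- Vessel coupling: segments are subdivided into subsegments no longer
  than h; each couples to the voxel containing its midpoint through a
  series conductance of wall resistance (K, s/μm) and a Peaceman
  well-index term with equivalent grid radius r0 = 0.1985·h (the lattice
  Green's function constant of the transverse 5-point stencil).  For
  vessels at least as thick as r0 the geometric term is dropped
  (wall-limited exchange); the analytic-oracle geometry uses a thin
  vessel where the line-source model is exact to O(h²).
- Oxygen: tissue pO2 and per-subsegment blood content are one coupled
  nonlinear system solved by damped Newton (step capped at the inflow
  pO2, iterates projected onto the physical range).  Newton systems are
  solved by GMRES preconditioned with an LU factorization of an early
  Jacobian, refactored only when GMRES slows down.  Relaxation schemes
  that alternate blood and tissue solves were rejected: with near-total
  extraction the alternation is not a contraction.  Default tolerance
  1e-6 (max pO2 update / max inflow pO2), max 200 iterations;
  non-convergence raises with the residual history attached.
- Prodrug: the analogous coupled system is linear and solved exactly in
  one sparse factorization; the effector solve is a single SPD solve
  (conjugate gradients, Jacobi preconditioner, rtol 1e-10).  Discrete
  mass balances (extracted = metabolized; production = degradation +
  washout) hold to solver precision by construction and are re-audited
  numerically on every solve.
- Blood marching uses outlet-valued (backward-Euler) wall exchange per
  subsegment — unconditionally stable and positivity-preserving even
  when exchange empties the blood within one subsegment.
- Degenerate inputs: zero segment flow means local blood–tissue
  equilibrium and no convective delivery; k_tP = 0 or k_metP,max = 0
  gives zero metabolism and zero kill; M0 = 0 gives a uniform field at
  the inflow pO2.
- Grid resolution is a convergence-tested parameter, not a constant: the
  acceptance suite checks that near-halving h moves the hypoxic fraction
  of the single-vessel fixture by <2 percentage points.

## Parameter defaults

Oxygen (tumor preset): P50 38 mm Hg, n 3, C0 0.5, H_D 0.4, α 3.1e-5
cm³O2/cm³/mmHg, αD 4.2e-10 cm³O2/cm/s/mmHg, M0 5e-4 cm³O2/cm³/s, Km
1 mm Hg, inflow 40 mm Hg.  The tabulated αD and α·D_O2 for the tumor
preset disagree by ~3%; αD is authoritative in the tissue equation and
the consistency check warns only above 5%.

Drug (base Class II): inflow AUC 50 μM·h, k_metP,max 0.01 s⁻¹, KO2
0.126 μM (1.26 μM for the Class I comparator), k_tP 0.1 s⁻¹, k_tE
0.01 s⁻¹ (0 for no-bystander), k_metE 0.01 s⁻¹, D_P = D_E = 1e-6 cm²/s,
φ_i 0.4, wall K 0.1 s/μm.  Potency a = 0.200 (μM·h)⁻¹ with bystander,
0.0414 (μM·h)⁻¹ for the no-bystander comparator (chosen to give similar
average kill at the base activation rate).  Radiation: α_H 0.0663 Gy⁻¹,
β_H 0.0028 Gy⁻², OER 2.8, K_ms 4.2 μM, dose 15 Gy.

Normal-tissue PD uses identical cell parameters (including φ_i): the
selectivity estimates isolate the transport/oxygenation contribution and
assume no intrinsic sensitivity difference.

## Problem sizes

The default tumor fixture is 60×50×20 voxels (h = 10 μm); unit tests use
a 30×25×10 variant of the same generators and the acceptance script runs
the full fixture.  The single-vessel oracle uses 21 and 41 transverse
voxels for the base and refined grids.

## Known limitations

- Acyclic flow only; no loops, no adaptive or pulsatile flow.
- Single generalized effector; no two-metabolite chains, no
  O2-independent (two-electron) off-target activation.
- Washout is loss-only (no recirculation or blood-borne bystander).
- Steady state only; no cycling hypoxia, repair kinetics, cell cycle, or
  fractionated radiation.
- Synthetic fixtures emulate summary statistics of real microvascular
  networks, not their geometry; absolute hypoxic fractions and kill
  levels are fixture properties.
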