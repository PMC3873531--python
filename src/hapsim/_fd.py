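"""Finite-difference discretization shared by the oxygen and drug solvers.

Steady reaction–diffusion on the regular voxel grid of a
:class:`~hapsim.network.TissueDomain`: 7-point Laplacian with no-flux outer
(and mask) boundaries, linear sink terms, and line-source coupling of vessel
segments.  Each segment is subdivided into subsegments no longer than the
grid spacing; each subsegment exchanges solute with the voxel containing
its midpoint through a series conductance of intravascular wall resistance
and a Peaceman well index (equivalent grid radius r0 = 0.1985 h for the
5-point transverse stencil).  For vessels at least as thick as r0 the
geometric term is dropped and exchange is wall-resistance limited.

All matrices are assembled in conductance form (entries cm³/s scaled by the
diffusion coefficient) so that row sums express discrete mass balance
exactly: summing the solved system over voxels yields
(vessel sources) = (volumetric sinks) to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import TissueDomain, VesselNetwork, VesselSegment
from .units import CM_PER_UM

#: equivalent well-block radius of the 5-point Laplacian, in units of h
PEACEMAN_R0 = 0.1985


class ConvergenceError(RuntimeError):
    """Iterative solve failed; carries the residual history."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class Grid:
    """Active-voxel index map plus the geometric part of the Laplacian."""

    domain: TissueDomain
    index_of: np.ndarray      # (nx,ny,nz) int, -1 where inactive
    active_ijk: np.ndarray    # (n_active, 3)
    lap_geom: sp.csr_matrix   # multiply by D (cm²/s) for conductance (cm³/s)

    @property
    def n(self) -> int:
        return self.active_ijk.shape[0]

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.domain.h * CM_PER_UM) ** 3


def build_grid(domain: TissueDomain) -> Grid:
    mask = domain.active_mask
    shape = domain.shape
    index_of = np.full(shape, -1, dtype=np.int64)
    active_ijk = np.argwhere(mask)
    index_of[mask] = np.arange(active_ijk.shape[0])
    h_cm = domain.h * CM_PER_UM
    rows, cols, vals = [], [], []
    n = active_ijk.shape[0]
    diag = np.zeros(n)
    for axis in range(3):
        for off in (-1, 1):
            nb = active_ijk.copy()
            nb[:, axis] += off
            valid = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            j = np.full(n, -1, dtype=np.int64)
            j[valid] = index_of[tuple(nb[valid].T)]
            has = j >= 0
            i_idx = np.nonzero(has)[0]
            rows.append(i_idx)
            cols.append(j[has])
            # face conductance / D: area/h = h (cm); no-flux where neighbor absent
            vals.append(np.full(i_idx.size, -h_cm))
            diag[i_idx] += h_cm
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    lap = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return Grid(domain, index_of, active_ijk, lap)


@dataclass
class SubsegmentTable:
    """Per-subsegment coupling data for one solute.

    ``gamma`` (cm³/s for drugs; cm³O2/s/mmHg for oxygen when built with the
    Krogh diffusion coefficient and a solubility-scaled wall conductance)
    turns a blood–voxel concentration difference into a flux.
    """

    segment_ids: np.ndarray   # segment id per subsegment (march order within segment)
    seg_ptr: dict[int, slice]  # segment id -> slice of its subsegments
    voxel: np.ndarray         # active voxel index per subsegment
    gamma: np.ndarray
    length_cm: np.ndarray


def build_subsegments(network: VesselNetwork, grid: Grid, *, D: float,
                      wall_K_s_per_cm: float, species: str,
                      wall_scale: float = 1.0) -> SubsegmentTable:
    """Subdivide segments (≤ h) and compute blood↔voxel conductances.

    ``wall_scale`` converts the wall-side concentration unit: 1 for drugs
    (mol/cm³ both sides), O2 solubility α for oxygen (flux = α ΔP / K).
    Per-segment wall resistance overrides (s/μm) are honored via
    ``VesselSegment.wall_resistance[species]``.
    """
    domain = grid.domain
    h = domain.h
    r0_um = PEACEMAN_R0 * h
    seg_ids, voxels, gammas, lengths = [], [], [], []
    seg_ptr: dict[int, slice] = {}
    pos = 0
    for seg in network.topological_segments():
        a = network.node(seg.start_node).xyz
        b = network.node(seg.end_node).xyz
        L = float(np.linalg.norm(b - a))
        m = max(1, int(np.ceil(L / h)))
        l_cm = (L / m) * CM_PER_UM
        K_cm = wall_K_s_per_cm
        if species in seg.wall_resistance:
            K_cm = seg.wall_resistance[species] * 1.0e4
        r_cm = seg.radius * CM_PER_UM
        # series resistance: wall + line-source geometric (clamped at 0)
        R_wall = K_cm / (2.0 * np.pi * r_cm * l_cm * wall_scale)
        if seg.radius < r0_um:
            R_geom = np.log(r0_um / seg.radius) / (2.0 * np.pi * D * l_cm)
        else:
            R_geom = 0.0
        gamma = 1.0 / (R_wall + R_geom)
        for k in range(m):
            t = (k + 0.5) / m
            mid = a + t * (b - a)
            ijk = domain.voxel_index(mid)
            v = grid.index_of[ijk]
            if v < 0:
                v = _nearest_active(grid, ijk)
            seg_ids.append(seg.id)
            voxels.append(v)
            gammas.append(gamma)
            lengths.append(l_cm)
        seg_ptr[seg.id] = slice(pos, pos + m)
        pos += m
    return SubsegmentTable(np.asarray(seg_ids), seg_ptr,
                           np.asarray(voxels, dtype=np.int64),
                           np.asarray(gammas), np.asarray(lengths))


def _nearest_active(grid: Grid, ijk: tuple[int, int, int]) -> int:
    """Nearest active voxel to ``ijk`` (vessels must lie in/next to the mask)."""
    mask = grid.domain.active_mask
    if not mask.any():
        raise ValueError("domain has no active voxels")
    act = grid.active_ijk
    d2 = ((act - np.asarray(ijk)) ** 2).sum(axis=1)
    j = int(np.argmin(d2))
    if d2[j] > 9:  # more than 3 voxels away: the vessel is outside the mask
        raise ValueError(f"vessel subsegment at voxel {ijk} far outside active mask")
    return j


def solve_linear(A: sp.csr_matrix, b: np.ndarray, x0: np.ndarray | None = None,
                 rtol: float = 1e-10) -> np.ndarray:
    """Solve the SPD reaction–diffusion system (CG + Jacobi, spsolve fallback)."""
    M = sp.diags(1.0 / A.diagonal())
    x, info = spla.cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=5000, M=M)
    if info != 0:
        x = spla.spsolve(A.tocsc(), b)
    return x


@dataclass
class BloodTopology:
    """Inlet wiring of the subsegment chain along the acyclic flow graph.

    The inlet content of subsegment j is ``(U c)_j`` plus, at inflow
    boundary heads, the boundary value: ``U`` carries within-segment
    predecessors (weight 1) and flow-weighted mixing of parent segment
    outlets at interior junctions.  ``boundary_node[j]`` holds the inflow
    node id where segment heads are fed from a boundary, else -1.
    """

    U: sp.csr_matrix
    boundary_node: np.ndarray
    Q: np.ndarray                # cm³/s per subsegment
    last_sub_of_segment: dict[int, int]
    terminal_segments: list[int]  # segment ids ending at outflow nodes


def build_blood_topology(network: VesselNetwork,
                         subs: SubsegmentTable) -> BloodTopology:
    from .units import CM3_S_PER_NL_MIN
    m = subs.voxel.shape[0]
    boundary_ids = {b.node_id for b in network.inflow_boundaries}
    g = network.flow_graph()
    rows, cols, vals = [], [], []
    boundary_node = np.full(m, -1, dtype=np.int64)
    Q = np.zeros(m)
    last_sub: dict[int, int] = {}
    # flow arriving at each node: list of (last subsegment of parent, Q_parent)
    arrivals: dict[int, list[tuple[int, float]]] = {}
    terminal: list[int] = []
    for seg in network.topological_segments():
        sl = subs.seg_ptr[seg.id]
        q = seg.flow * CM3_S_PER_NL_MIN
        Q[sl] = q
        head = sl.start
        nid = seg.start_node
        if nid in boundary_ids:
            boundary_node[head] = nid
        else:
            par = arrivals.get(nid, [])
            tot = sum(qp for _, qp in par)
            if tot > 0:
                for jp, qp in par:
                    rows.append(head)
                    cols.append(jp)
                    vals.append(qp / tot)
        for j in range(sl.start + 1, sl.stop):
            rows.append(j)
            cols.append(j - 1)
            vals.append(1.0)
        last_sub[seg.id] = sl.stop - 1
        arrivals.setdefault(seg.end_node, []).append((sl.stop - 1, q))
        if g.out_degree(seg.end_node) == 0:
            terminal.append(seg.id)
    U = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return BloodTopology(U, boundary_node, Q, last_sub, terminal)


def assemble_coupled(grid: Grid, subs: SubsegmentTable, topo: BloodTopology,
                     D: float, sink_per_s: np.ndarray,
                     boundary_value: dict[int, float]):
    """Monolithic linear system for a linearly carried solute.

    Unknowns: tissue concentration per active voxel (n) followed by blood
    content at each subsegment outlet (m).  Tissue rows express diffusion +
    first-order sink + wall exchange; blood rows express convective
    transport with implicit (outlet-valued) wall exchange; junction mixing
    is flow-weighted.  Solving the whole thing at once avoids the unstable
    blood↔tissue relaxation and closes mass balances to solver precision.
    """
    n, m = grid.n, subs.voxel.shape[0]
    vol = grid.voxel_volume_cm3
    gamma = subs.gamma
    gamma_acc = np.zeros(n)
    np.add.at(gamma_acc, subs.voxel, gamma)
    A_tt = D * grid.lap_geom + sp.diags(sink_per_s * vol + gamma_acc)
    A_tb = sp.csr_matrix((-gamma, (subs.voxel, np.arange(m))), shape=(n, m))
    # blood row j: (Q_j + γ_j) c_j − γ_j A_v − Q_j (U c)_j = Q_j·boundary_j
    diag_b = topo.Q + gamma
    A_bb = sp.diags(diag_b) - sp.diags(topo.Q) @ topo.U
    A_bt = sp.csr_matrix((gamma, (np.arange(m), subs.voxel)), shape=(m, n))
    A = sp.bmat([[A_tt, A_tb], [-A_bt, A_bb]], format="csc")
    rhs = np.zeros(n + m)
    has_bnd = topo.boundary_node >= 0
    bvals = np.array([boundary_value.get(int(nid), 0.0) if nid >= 0 else 0.0
                      for nid in topo.boundary_node])
    rhs[n:] = np.where(has_bnd, topo.Q * bvals, 0.0)
    return A, rhs


def solve_coupled_linear(grid: Grid, subs: SubsegmentTable, topo: BloodTopology,
                         D: float, sink_per_s: np.ndarray,
                         boundary_value: dict[int, float]):
    """Solve the coupled tissue/blood system; returns (tissue, blood, q_wall)."""
    n, m = grid.n, subs.voxel.shape[0]
    A, rhs = assemble_coupled(grid, subs, topo, D, sink_per_s, boundary_value)
    u = spla.spsolve(A, rhs)
    x, c = u[:n], u[n:]
    q_wall = subs.gamma * (c - x[subs.voxel])
    return x, c, q_wall
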