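"""Microvascular network data model, file I/O, synthetic generation, geometry.

A :class:`VesselNetwork` is the geometric/hemodynamic substrate of every
simulation: nodes in 3D (μm), cylindrical vessel segments with radius and
blood flow (flow direction is start→end), and inflow boundary conditions
(pO2 and prodrug/effector plasma AUC of the feeding vessels).  Networks are
restricted to acyclic flow topologies (trees / parallel arrays) so that
intravascular transport can be computed in a single topological sweep.

The mapped tumor and muscle networks the model was developed on are not
public; :func:`generate_tumor_like` and :func:`generate_normal_like` build
synthetic stand-ins that emulate their summary statistics: tumor-like
regions have heterogeneous vessel diameters and flows and leave a sizable
fraction of tissue farther than 50 μm from the nearest vessel, while
normal-like (muscle-style) regions keep every tissue point within 50 μm of
a vessel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np


class NetworkValidationError(ValueError):
    """A network violates a structural or flow-conservation invariant."""


class NetworkParseError(ValueError):
    """A network file could not be parsed; the message names the line."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    id: int
    position: tuple[float, float, float]  # μm

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class VesselSegment:
    """Cylindrical vessel segment; blood flows from ``start_node`` to ``end_node``."""

    id: int
    start_node: int
    end_node: int
    radius: float          # μm
    flow: float            # nl/min
    wall_resistance: dict[str, float] = field(default_factory=dict)
    # optional per-species intravascular resistance K (s/μm); solvers fall
    # back to the parameter-set default when a species key is absent.


@dataclass(frozen=True)
class InflowBoundary:
    node_id: int
    pO2_mmHg: float
    auc_prodrug_uM_h: float
    auc_effector_uM_h: float = 0.0


@dataclass
class VesselNetwork:
    nodes: list[Node]
    segments: list[VesselSegment]
    inflow_boundaries: list[InflowBoundary]
    region_volume_mm3: float

    # -- lookups ----------------------------------------------------------
    def node(self, node_id: int) -> Node:
        return self._node_map()[node_id]

    def _node_map(self) -> dict[int, Node]:
        if not hasattr(self, "_nmap") or len(self._nmap) != len(self.nodes):
            self._nmap = {n.id: n for n in self.nodes}
        return self._nmap

    def segment_length(self, seg: VesselSegment) -> float:
        a = self.node(seg.start_node).xyz
        b = self.node(seg.end_node).xyz
        return float(np.linalg.norm(b - a))

    @property
    def inflow_node_ids(self) -> set[int]:
        return {b.node_id for b in self.inflow_boundaries}

    def total_inflow(self) -> float:
        """Total blood inflow Q (nl/min) = sum of flows leaving inflow nodes."""
        ids = self.inflow_node_ids
        return sum(s.flow for s in self.segments if s.start_node in ids)

    def flow_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id)
        for s in self.segments:
            g.add_edge(s.start_node, s.end_node, segment=s)
        return g

    def topological_segments(self) -> list[VesselSegment]:
        """Segments ordered so every segment's upstream segments precede it."""
        g = self.flow_graph()
        order = {nid: i for i, nid in enumerate(nx.topological_sort(g))}
        return sorted(self.segments, key=lambda s: order[s.start_node])

    # -- validation -------------------------------------------------------
    def validate(self, flow_rtol: float = 1e-9) -> None:
        if not self.segments:
            raise NetworkValidationError("network has no segments")
        if self.region_volume_mm3 <= 0:
            raise NetworkValidationError("region volume must be positive")
        nmap = self._node_map()
        for s in self.segments:
            if s.start_node not in nmap or s.end_node not in nmap:
                raise NetworkValidationError(
                    f"segment {s.id} references unknown node")
            if s.radius <= 0:
                raise NetworkValidationError(f"segment {s.id}: radius must be > 0")
            if s.flow < 0:
                raise NetworkValidationError(f"segment {s.id}: flow must be >= 0")
            if self.segment_length(s) <= 0:
                raise NetworkValidationError(f"segment {s.id}: zero length")
        g = self.flow_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkValidationError("flow topology contains a cycle")
        inflow_ids = self.inflow_node_ids
        for nid in inflow_ids:
            if nid not in nmap:
                raise NetworkValidationError(f"inflow boundary at unknown node {nid}")
            if g.in_degree(nid) != 0 or g.out_degree(nid) != 1:
                raise NetworkValidationError(
                    f"inflow node {nid} must have exactly one attached segment "
                    f"directed away from it")
        # flow conservation at interior nodes (both inflow and outflow attached)
        for nid in g.nodes:
            if g.in_degree(nid) > 0 and g.out_degree(nid) > 0:
                fin = sum(d["segment"].flow for _, _, d in g.in_edges(nid, data=True))
                fout = sum(d["segment"].flow for _, _, d in g.out_edges(nid, data=True))
                scale = max(fin, fout, 1e-30)
                if abs(fin - fout) > flow_rtol * scale:
                    raise NetworkValidationError(
                        f"flow not conserved at node {nid}: in={fin} out={fout}")
            elif g.in_degree(nid) == 0 and g.out_degree(nid) > 0:
                if nid not in inflow_ids:
                    raise NetworkValidationError(
                        f"source node {nid} has no inflow boundary condition")


# ---------------------------------------------------------------------------
# tissue domain / scalar fields
# ---------------------------------------------------------------------------

@dataclass
class TissueDomain:
    """Voxelized cuboid tissue region.

    ``box`` are the box dimensions (μm), ``h`` the isotropic grid spacing
    (μm); voxels are indexed 0-based with the value taken at the voxel
    center ((i+0.5)h, ...).  ``mask`` optionally restricts the active region
    (e.g. to tissue within 50 μm of a vessel, muscle-style, or to a cylinder
    for the single-vessel validation geometry).
    """

    box: tuple[float, float, float]
    h: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")
        if self.mask is not None and tuple(self.mask.shape) != self.shape:
            raise ValueError("mask shape does not match voxel grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(max(1, round(b / self.h)) for b in self.box)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def active_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask.astype(bool)
        return np.ones(self.shape, dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def voxel_volume_um3(self) -> float:
        return self.h ** 3

    def active_volume_mm3(self) -> float:
        return self.n_active * self.voxel_volume_um3 * 1e-9

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel centers (μm), C-order."""
        nx_, ny_, nz_ = self.shape
        ax = [(np.arange(n) + 0.5) * self.h for n in (nx_, ny_, nz_)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def voxel_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        """Index of the voxel containing ``point`` (clipped to the grid)."""
        return tuple(
            int(np.clip(math.floor(p / self.h), 0, n - 1))
            for p, n in zip(point, self.shape)
        )

    def check_volume_consistency(self, network: VesselNetwork, tol: float = 0.02):
        """Active voxel volume must match the declared region volume within 2%."""
        v = self.active_volume_mm3()
        if abs(v - network.region_volume_mm3) > tol * network.region_volume_mm3:
            raise NetworkValidationError(
                f"active voxel volume {v:.4g} mm³ inconsistent with declared "
                f"region volume {network.region_volume_mm3:.4g} mm³")


@dataclass
class ScalarField:
    """One value per voxel of a :class:`TissueDomain` (NaN outside the mask).

    ``quantity`` tags the physical meaning: ``"pO2_mmHg"``, ``"uM"``,
    ``"uM_h"``, ``"survival_probability"``, ``"distance_um"``.
    """

    domain: TissueDomain
    values: np.ndarray
    quantity: str

    _BOUNDS = {
        "pO2_mmHg": (0.0, None),
        "uM": (0.0, None),
        "uM_h": (0.0, None),
        "distance_um": (0.0, None),
        "survival_probability": (0.0, 1.0),
    }

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.domain.shape:
            raise ValueError("field shape does not match domain grid")
        lo, hi = self._BOUNDS.get(self.quantity, (None, None))
        act = self.active_values()
        if lo is not None and act.size and act.min() < lo - 1e-12:
            raise ValueError(f"{self.quantity} field below lower bound {lo}")
        if hi is not None and act.size and act.max() > hi + 1e-12:
            raise ValueError(f"{self.quantity} field above upper bound {hi}")

    def active_values(self) -> np.ndarray:
        return self.values[self.domain.active_mask]

    def mean(self) -> float:
        return float(self.active_values().mean())

    def min(self) -> float:
        return float(self.active_values().min())

    def max(self) -> float:
        return float(self.active_values().max())


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------
#
# Single text file: a JSON header line block followed by TSV blocks for
# nodes, segments and inflow boundaries, each introduced by a '#' marker.

_NODE_COLS = "id\tx_um\ty_um\tz_um"
_SEG_COLS = "id\tfrom\tto\tradius_um\tflow_nl_min"
_BND_COLS = "node_id\tpO2_mmHg\tauc_prodrug_uM_h\tauc_effector_uM_h"


def save_network(network: VesselNetwork, path) -> None:
    """Write a network to the TSV/JSON text dialect (re-loadable bit-identically)."""
    network.validate()
    header = {
        "format": "hapsim-network-v1",
        "region_volume_mm3": network.region_volume_mm3,
        "units": {"length": "um", "flow": "nl/min", "pO2": "mmHg", "auc": "uM.h"},
    }
    lines = ["#HEADER", json.dumps(header, sort_keys=True)]
    lines.append("#NODES")
    lines.append(_NODE_COLS)
    for n in network.nodes:
        x, y, z = n.position
        lines.append(f"{n.id}\t{x!r}\t{y!r}\t{z!r}")
    lines.append("#SEGMENTS")
    lines.append(_SEG_COLS)
    for s in network.segments:
        lines.append(f"{s.id}\t{s.start_node}\t{s.end_node}\t{s.radius!r}\t{s.flow!r}")
    lines.append("#BOUNDARIES")
    lines.append(_BND_COLS)
    for b in network.inflow_boundaries:
        lines.append(
            f"{b.node_id}\t{b.pO2_mmHg!r}\t{b.auc_prodrug_uM_h!r}\t{b.auc_effector_uM_h!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_network(path) -> VesselNetwork:
    """Load and validate a network from the TSV/JSON text dialect."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    section = None
    header = None
    nodes: list[Node] = []
    segments: list[VesselSegment] = []
    boundaries: list[InflowBoundary] = []
    expect_cols = {"#NODES": _NODE_COLS, "#SEGMENTS": _SEG_COLS, "#BOUNDARIES": _BND_COLS}
    skip_next_header_row = False
    for lineno, line in enumerate(raw, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line not in ("#HEADER",) and line not in expect_cols:
                raise NetworkParseError(f"line {lineno}: unknown section marker {line!r}")
            section = line
            skip_next_header_row = section != "#HEADER"
            continue
        try:
            if section == "#HEADER":
                header = json.loads(line)
            elif section in expect_cols:
                if skip_next_header_row:
                    if line != expect_cols[section]:
                        raise NetworkParseError(
                            f"line {lineno}: expected columns {expect_cols[section]!r}")
                    skip_next_header_row = False
                    continue
                parts = line.split("\t")
                if section == "#NODES":
                    nodes.append(Node(int(parts[0]),
                                      (float(parts[1]), float(parts[2]), float(parts[3]))))
                elif section == "#SEGMENTS":
                    segments.append(VesselSegment(int(parts[0]), int(parts[1]),
                                                  int(parts[2]), float(parts[3]),
                                                  float(parts[4])))
                else:
                    boundaries.append(InflowBoundary(int(parts[0]), float(parts[1]),
                                                     float(parts[2]), float(parts[3])))
            else:
                raise NetworkParseError(f"line {lineno}: content before any section")
        except NetworkParseError:
            raise
        except Exception as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from exc
    if header is None or "region_volume_mm3" not in header:
        raise NetworkParseError("missing JSON header with region_volume_mm3")
    net = VesselNetwork(nodes, segments, boundaries,
                        float(header["region_volume_mm3"]))
    net.validate()
    return net


def save_field(fld: ScalarField, path) -> None:
    """Write a field as TSV (ix, iy, iz, value) with a JSON grid sidecar."""
    path = str(path)
    dom = fld.domain
    act = dom.active_mask
    idx = np.argwhere(act)
    vals = fld.values[act]
    with open(path, "w") as fh:
        fh.write("ix\tiy\tiz\tvalue\n")
        for (i, j, k), v in zip(idx, vals):
            fh.write(f"{i}\t{j}\t{k}\t{float(v)!r}\n")
    sidecar = {
        "box_um": list(dom.box), "h_um": dom.h, "shape": list(dom.shape),
        "quantity": fld.quantity, "masked": dom.mask is not None,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)
        fh.write("\n")


def load_field(path) -> ScalarField:
    """Read a field written by :func:`save_field`."""
    path = str(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    dom = TissueDomain(tuple(meta["box_um"]), meta["h_um"])
    vals = np.full(dom.shape, np.nan)
    mask = np.zeros(dom.shape, dtype=bool)
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            i, j, k, v = line.split("\t")
            vals[int(i), int(j), int(k)] = float(v)
            mask[int(i), int(j), int(k)] = True
    if meta.get("masked"):
        dom = TissueDomain(tuple(meta["box_um"]), meta["h_um"], mask)
    return ScalarField(dom, vals, meta["quantity"])


# ---------------------------------------------------------------------------
# geometry statistics
# ---------------------------------------------------------------------------

def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point (n,3) to the line segment a-b (μm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def distance_to_nearest_vessel(network: VesselNetwork, domain: TissueDomain) -> ScalarField:
    """Per-voxel distance (μm) from voxel center to the nearest vessel *surface*.

    Minimum over segments of (distance to segment axis − radius), floored at 0.
    """
    centers = domain.voxel_centers()
    best = np.full(centers.shape[0], np.inf)
    for s in network.segments:
        a = network.node(s.start_node).xyz
        b = network.node(s.end_node).xyz
        d = _point_segment_distance(centers, a, b) - s.radius
        np.minimum(best, d, out=best)
    vals = np.maximum(best, 0.0).reshape(domain.shape)
    out = np.where(domain.active_mask, vals, np.nan)
    return ScalarField(domain, out, "distance_um")


def perfusion_per_volume(network: VesselNetwork) -> float:
    """Total blood inflow per tissue volume, Q/V (nl/min/mm³)."""
    if network.region_volume_mm3 <= 0:
        raise NetworkValidationError("region volume must be positive")
    return network.total_inflow() / network.region_volume_mm3


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

def generate_krogh(vessel_radius: float, domain_side: float, length: float,
                   flow: float, inflow_pO2: float = 40.0,
                   inflow_auc_prodrug: float = 50.0,
                   inflow_auc_effector: float = 0.0,
                   n_xy: int = 21, cylindrical_mask: bool = False,
                   ) -> tuple[VesselNetwork, TissueDomain]:
    """Single straight vessel through a cuboid (classical Krogh geometry).

    The vessel runs along z through the center of a ``domain_side`` ×
    ``domain_side`` × ``length`` box.  ``n_xy`` sets the transverse voxel
    count (odd keeps the axis on voxel centers).  With
    ``cylindrical_mask=True`` only voxels within ``domain_side/2`` of the
    axis are active and the region volume is the cylinder volume, which
    makes the geometry exactly comparable to the closed-form Krogh-cylinder
    solution.
    """
    if min(vessel_radius, domain_side, length, flow + 1.0) <= 0 or flow < 0:
        raise ValueError("all Krogh geometry arguments must be positive (flow >= 0)")
    if vessel_radius >= domain_side / 2:
        raise ValueError("vessel radius must be smaller than half the domain side")
    h = domain_side / n_xy
    c = domain_side / 2.0
    nodes = [Node(0, (c, c, 0.0)), Node(1, (c, c, length))]
    seg = VesselSegment(0, 0, 1, vessel_radius, flow)
    box = (domain_side, domain_side, length)
    mask = None
    volume = domain_side * domain_side * length * 1e-9  # mm³
    if cylindrical_mask:
        shape = tuple(max(1, round(b / h)) for b in box)
        ax = [(np.arange(n) + 0.5) * h for n in shape]
        X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")
        r2 = (X - c) ** 2 + (Y - c) ** 2
        mask2d = r2 <= (domain_side / 2.0) ** 2
        mask = np.repeat(mask2d[:, :, None], shape[2], axis=2)
        volume = mask.sum() * h ** 3 * 1e-9
    net = VesselNetwork(nodes, [seg],
                        [InflowBoundary(0, inflow_pO2, inflow_auc_prodrug,
                                        inflow_auc_effector)],
                        region_volume_mm3=volume)
    net.validate()
    domain = TissueDomain(box, h, mask)
    return net, domain


@dataclass(frozen=True)
class DiameterDistribution:
    """Log-normal vessel diameter distribution (μm), clipped to [lo, hi]."""
    median: float
    sigma_log: float
    lo: float = 3.0
    hi: float = 25.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d = self.median * np.exp(rng.normal(0.0, self.sigma_log, size=n))
        return np.clip(d, self.lo, self.hi)


def _parallel_array_network(positions_yz: np.ndarray, diameters: np.ndarray,
                            flows: np.ndarray, box: tuple[float, float, float],
                            inflow_pO2: float, inflow_auc_prodrug: float,
                            inflow_auc_effector: float) -> VesselNetwork:
    """Parallel array of vessels spanning the box along x, one inflow each."""
    nodes, segments, boundaries = [], [], []
    for i, ((y, z), d, q) in enumerate(zip(positions_yz, diameters, flows)):
        n0, n1 = 2 * i, 2 * i + 1
        nodes.append(Node(n0, (0.0, float(y), float(z))))
        nodes.append(Node(n1, (box[0], float(y), float(z))))
        segments.append(VesselSegment(i, n0, n1, float(d) / 2.0, float(q)))
        boundaries.append(InflowBoundary(n0, inflow_pO2, inflow_auc_prodrug,
                                         inflow_auc_effector))
    volume = box[0] * box[1] * box[2] * 1e-9
    return VesselNetwork(nodes, segments, boundaries, volume)


def generate_tumor_like(seed: int,
                        n_vessels: int = 18,
                        diameter_distribution: DiameterDistribution | None = None,
                        flow_per_volume: float = 333.0,
                        target_max_vessel_distance: float = 110.0,
                        box: tuple[float, float, float] = (600.0, 500.0, 200.0),
                        h: float = 10.0,
                        inflow_pO2: float = 40.0,
                        inflow_auc_prodrug: float = 50.0,
                        inflow_auc_effector: float = 0.0,
                        flow_sigma_log: float = 1.0,
                        min_far_fraction: float = 0.10,
                        max_attempts: int = 50,
                        ) -> tuple[VesselNetwork, TissueDomain]:
    """Synthetic tumor-style microregion.

    A sparse, randomly placed parallel vessel array with heterogeneous
    (log-normal) diameters and flows, tuned so that a substantial fraction
    (≥ ``min_far_fraction``) of tissue lies more than 50 μm from the nearest
    vessel — emulating the long diffusion distances of a poorly perfused
    tumor region — while the maximum distance stays below
    ``target_max_vessel_distance``.  Total inflow is set to
    ``flow_per_volume × V``.  Deterministic for a given seed.
    """
    if diameter_distribution is None:
        diameter_distribution = DiameterDistribution(median=8.0, sigma_log=0.5)
    rng = np.random.default_rng(seed)
    volume = box[0] * box[1] * box[2] * 1e-9
    q_total = flow_per_volume * volume
    domain = TissueDomain(box, h)
    for _ in range(max_attempts):
        yz = np.column_stack([rng.uniform(5.0, box[1] - 5.0, n_vessels),
                              rng.uniform(5.0, box[2] - 5.0, n_vessels)])
        diam = diameter_distribution.sample(rng, n_vessels)
        w = np.exp(rng.normal(0.0, flow_sigma_log, n_vessels))
        flows = q_total * w / w.sum()
        net = _parallel_array_network(yz, diam, flows, box, inflow_pO2,
                                      inflow_auc_prodrug, inflow_auc_effector)
        dist = distance_to_nearest_vessel(net, domain).active_values()
        if dist.max() <= target_max_vessel_distance and \
                (dist > 50.0).mean() >= min_far_fraction:
            net.validate()
            return net, domain
    raise NetworkValidationError(
        f"could not satisfy distance targets (>50 μm fraction >= {min_far_fraction}, "
        f"max <= {target_max_vessel_distance} μm) in {max_attempts} attempts; "
        f"vessel density and distance targets are mutually infeasible")


def generate_normal_like(seed: int,
                         flow_per_volume: float = 824.0,
                         diameter_distribution: DiameterDistribution | None = None,
                         box: tuple[float, float, float] = (600.0, 500.0, 200.0),
                         h: float = 10.0,
                         spacing: float = 60.0,
                         jitter: float = 4.0,
                         inflow_pO2: float = 50.0,
                         inflow_auc_prodrug: float = 50.0,
                         inflow_auc_effector: float = 0.0,
                         flow_sigma_log: float = 0.25,
                         max_attempts: int = 50,
                         ) -> tuple[VesselNetwork, TissueDomain]:
    """Synthetic normal-tissue (muscle-style) microregion.

    A near-regular lattice of parallel vessels (spacing ≈ ``spacing`` μm with
    small jitter) so that no tissue point is farther than 50 μm from a
    vessel, with narrow diameter and flow distributions and high perfusion.
    Deterministic for a given seed.
    """
    if diameter_distribution is None:
        diameter_distribution = DiameterDistribution(median=6.0, sigma_log=0.15)
    rng = np.random.default_rng(seed)
    volume = box[0] * box[1] * box[2] * 1e-9
    q_total = flow_per_volume * volume
    ny = max(1, round(box[1] / spacing))
    nz = max(1, round(box[2] / spacing))
    ys = (np.arange(ny) + 0.5) * box[1] / ny
    zs = (np.arange(nz) + 0.5) * box[2] / nz
    base = np.array([(y, z) for y in ys for z in zs])
    domain = TissueDomain(box, h)
    for _ in range(max_attempts):
        yz = base + rng.uniform(-jitter, jitter, size=base.shape)
        n = len(yz)
        diam = diameter_distribution.sample(rng, n)
        w = np.exp(rng.normal(0.0, flow_sigma_log, n))
        flows = q_total * w / w.sum()
        net = _parallel_array_network(yz, diam, flows, box, inflow_pO2,
                                      inflow_auc_prodrug, inflow_auc_effector)
        dist = distance_to_nearest_vessel(net, domain).active_values()
        if dist.max() <= 50.0:
            net.validate()
            return net, domain
    raise NetworkValidationError(
        "could not place a lattice with max vessel distance <= 50 μm; "
        "decrease spacing or jitter")
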