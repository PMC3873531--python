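"""Config-driven experiment orchestration: sweeps, paired tissues, reports.

An :class:`ExperimentConfig` names a network preset (or file), parameter
overrides for each block (oxygen / prodrug / effector / radiation /
potency), and an optional one-dimensional parameter sweep.  Every grid
point is backed by a full pipeline run (oxygen → prodrug → effector → PD);
oxygen is re-solved only when a swept parameter affects it.  A paired
normal-tissue network can be carried along to report tumor:normal
selectivity.  Results land in a long-format table (one row per sweep value
and arm) plus a JSON summary stamped with a canonical config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .network import (TissueDomain, VesselNetwork, generate_normal_like,
                      generate_tumor_like, load_network)
from .oxygen import OxygenParameters, OxygenSolution, hypoxic_fraction, solve_oxygen
from .pharmacodynamics import (KillResult, PotencyModel, RadiationParameters,
                               compute_kill, potency, selectivity_ratio)
from .transport import (EffectorParameters, ProdrugParameters,
                        TransportSolution, net_transvascular_per_volume,
                        solve_effector, solve_prodrug)

__all__ = ["ExperimentConfig", "SweepResult", "PipelineResult", "run_pipeline",
           "run_experiment", "flow_modulation", "report",
           "base_class2_config", "class1_config", "washout_sweep_configs"]

log = logging.getLogger("hapsim.experiments")

ARMS = ("drug", "radiation", "combined")

_BLOCK_TYPES = {
    "oxygen": OxygenParameters,
    "prodrug": ProdrugParameters,
    "effector": EffectorParameters,
    "radiation": RadiationParameters,
}


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment (optionally a sweep)."""

    name: str = "experiment"
    seed: int = 1
    network: str = "tumor"              # "tumor" | "normal" | path to file
    network_options: dict = field(default_factory=dict)
    oxygen: dict = field(default_factory=dict)
    prodrug: dict = field(default_factory=dict)
    effector: dict = field(default_factory=dict)
    radiation: dict = field(default_factory=dict)
    potency: dict = field(default_factory=dict)   # case, a_ref, kmetE_ref
    sweep_param: Optional[str] = None   # bare or "block.param"
    sweep_values: list = field(default_factory=list)
    include_normal: bool = False        # paired normal-tissue run
    normal_options: dict = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def resolve_sweep_block(self) -> Optional[str]:
        """Block owning the swept parameter; errors on unknown/ambiguous names."""
        if self.sweep_param is None:
            return None
        if not self.sweep_values:
            raise ValueError("sweep grid must be non-empty")
        name = self.sweep_param
        if "." in name:
            block, param = name.split(".", 1)
            if block not in _BLOCK_TYPES:
                raise ValueError(f"unknown parameter block {block!r}")
            if param not in {f.name for f in dataclasses.fields(_BLOCK_TYPES[block])}:
                raise ValueError(f"{param!r} is not a parameter of block {block!r}")
            return block
        owners = [b for b, t in _BLOCK_TYPES.items()
                  if name in {f.name for f in dataclasses.fields(t)}]
        if not owners:
            raise ValueError(f"swept parameter {name!r} exists in no parameter block")
        if len(owners) > 1:
            raise ValueError(
                f"swept parameter {name!r} is ambiguous across blocks {owners}; "
                f"qualify it as 'block.{name}'")
        return owners[0]

    def param_name(self) -> str:
        return self.sweep_param.split(".", 1)[-1] if self.sweep_param else ""


def _build_params(config: ExperimentConfig):
    o2p = replace(OxygenParameters.tumor()
                  if config.network != "normal" else OxygenParameters.normal(),
                  **config.oxygen)
    pp = replace(ProdrugParameters(), **config.prodrug)
    ep = replace(EffectorParameters(), **config.effector)
    rad = replace(RadiationParameters(), **config.radiation)
    pot = PotencyModel(**config.potency) if config.potency else PotencyModel()
    return o2p, pp, ep, rad, pot


def _build_network(kind: str, seed: int, options: dict,
                   inflow_pO2: float, auc_inflow: float,
                   ) -> tuple[VesselNetwork, TissueDomain]:
    if kind == "tumor":
        return generate_tumor_like(seed, inflow_pO2=inflow_pO2,
                                   inflow_auc_prodrug=auc_inflow, **options)
    if kind == "normal":
        return generate_normal_like(seed, inflow_pO2=inflow_pO2,
                                    inflow_auc_prodrug=auc_inflow, **options)
    net = load_network(kind)
    h = options.get("h", 10.0)
    box = options.get("box")
    if box is None:
        raise ValueError("loading a network file requires network_options.box")
    return net, TissueDomain(tuple(box), h)


@dataclass
class PipelineResult:
    """One full oxygen → transport → kill evaluation."""

    oxygen: OxygenSolution
    transport: TransportSolution
    kill: KillResult
    a: float
    hypoxic_fraction_4uM: float
    severe_hypoxic_fraction_013uM: float
    prodrug_extraction_pmol_mm3: float
    effector_washout_pmol_mm3: float


def run_pipeline(network: VesselNetwork, domain: TissueDomain,
                 oxygen_params: OxygenParameters,
                 prodrug_params: ProdrugParameters,
                 effector_params: EffectorParameters,
                 a: float, radiation_params: RadiationParameters,
                 oxygen_solution: OxygenSolution | None = None,
                 prodrug_solution: TransportSolution | None = None,
                 ) -> PipelineResult:
    """Run the full simulation chain on one network/parameter combination.

    Already-solved oxygen and prodrug stages can be passed in to avoid
    recomputation when only downstream parameters change.
    """
    t0 = time.perf_counter()
    if oxygen_solution is None:
        oxygen_solution = solve_oxygen(network, domain, oxygen_params)
    psol = prodrug_solution
    if psol is None:
        psol = solve_prodrug(network, domain, oxygen_solution, prodrug_params)
    esol = solve_effector(network, domain, oxygen_solution, psol, effector_params)
    kill = compute_kill(esol, oxygen_solution, a, radiation_params)
    log.debug("pipeline run finished in %.2f s", time.perf_counter() - t0)
    return PipelineResult(
        oxygen=oxygen_solution, transport=esol, kill=kill, a=a,
        hypoxic_fraction_4uM=hypoxic_fraction(oxygen_solution, 4.0),
        severe_hypoxic_fraction_013uM=hypoxic_fraction(oxygen_solution, 0.13),
        prodrug_extraction_pmol_mm3=net_transvascular_per_volume(esol, "prodrug"),
        effector_washout_pmol_mm3=net_transvascular_per_volume(esol, "effector"),
    )


@dataclass
class SweepResult:
    """Long-format results table plus provenance (config, hash, residuals)."""

    config: ExperimentConfig
    config_hash: str
    table: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)


def _rows_for(value, param: str, res: PipelineResult,
              normal_res: PipelineResult | None) -> list[dict]:
    kills = {"drug": res.kill.kill_drug, "radiation": res.kill.kill_rad,
             "combined": res.kill.kill_combined}
    sel = None
    if normal_res is not None:
        sel = selectivity_ratio(res.kill.kill_drug, normal_res.kill.kill_drug)
    rows = []
    for arm in ARMS:
        rows.append({
            "sweep_param": param, "sweep_value": value, "arm": arm,
            "log_cell_kill": kills[arm],
            "additional_kill": res.kill.additional_kill
            if arm == "combined" else np.nan,
            "prodrug_extraction_pmol_mm3": res.prodrug_extraction_pmol_mm3,
            "effector_washout_pmol_mm3": res.effector_washout_pmol_mm3,
            "hypoxic_fraction_4uM": res.hypoxic_fraction_4uM,
            "severe_hypoxic_fraction_013uM": res.severe_hypoxic_fraction_013uM,
            "selectivity": sel if arm == "drug" else np.nan,
        })
    return rows


def run_experiment(config: ExperimentConfig) -> SweepResult:
    """Execute a (sweep) experiment; deterministic for a fixed seed."""
    block = config.resolve_sweep_block()
    param = config.param_name()
    o2p, pp, ep, rad, pot = _build_params(config)
    lines = [f"config_hash={config.config_hash()} seed={config.seed}"]
    net, dom = _build_network(config.network, config.seed,
                              config.network_options, o2p.inflow_pO2,
                              pp.auc_inflow)
    normal = None
    if config.include_normal:
        n_o2p = replace(OxygenParameters.normal(),
                        **config.normal_options.get("oxygen", {}))
        nnet, ndom = _build_network(
            "normal", config.seed + 1,
            config.normal_options.get("network_options", {}),
            n_o2p.inflow_pO2, pp.auc_inflow)
        normal = (nnet, ndom, n_o2p)
    values = config.sweep_values if config.sweep_param else [None]
    o2_cache: OxygenSolution | None = None
    o2_cache_n: OxygenSolution | None = None
    psol_cache: dict = {}   # prodrug params -> solved prodrug stage
    psol_cache_n: dict = {}
    rows: list[dict] = []
    for v in values:
        o2p_v, pp_v, ep_v, rad_v = o2p, pp, ep, rad
        if block == "oxygen":
            o2p_v = replace(o2p, **{param: v})
        elif block == "prodrug":
            pp_v = replace(pp, **{param: v})
        elif block == "effector":
            ep_v = replace(ep, **{param: v})
        elif block == "radiation":
            rad_v = replace(rad, **{param: v})
        a = potency(pot, ep_v.kmetE)
        if block == "oxygen" or o2_cache is None:
            o2_cache = solve_oxygen(net, dom, o2p_v)
            psol_cache.clear()
            lines.append(f"oxygen[tumor] iters={len(o2_cache.residual_history)} "
                         f"residual={o2_cache.residual_history[-1]:.3g}")
        if pp_v not in psol_cache:
            psol_cache.clear()
            psol_cache[pp_v] = solve_prodrug(net, dom, o2_cache, pp_v)
        res = run_pipeline(net, dom, o2p_v, pp_v, ep_v, a, rad_v,
                           oxygen_solution=o2_cache,
                           prodrug_solution=psol_cache[pp_v])
        nres = None
        if normal is not None:
            nnet, ndom, n_o2p = normal
            if o2_cache_n is None:
                o2_cache_n = solve_oxygen(nnet, ndom, n_o2p)
                lines.append(
                    f"oxygen[normal] iters={len(o2_cache_n.residual_history)} "
                    f"residual={o2_cache_n.residual_history[-1]:.3g}")
            if pp_v not in psol_cache_n:
                psol_cache_n.clear()
                psol_cache_n[pp_v] = solve_prodrug(nnet, ndom, o2_cache_n, pp_v)
            nres = run_pipeline(nnet, ndom, n_o2p, pp_v, ep_v, a, rad_v,
                                oxygen_solution=o2_cache_n,
                                prodrug_solution=psol_cache_n[pp_v])
        rows.extend(_rows_for(v, param or "(none)", res, nres))
        lines.append(f"value={v} kill_drug={res.kill.kill_drug:.4f} "
                     f"additional={res.kill.additional_kill:.4f} "
                     f"washout={res.effector_washout_pmol_mm3:.4g}")
    table = pd.DataFrame(rows)
    return SweepResult(config, config.config_hash(), table, lines)


def flow_modulation(config: ExperimentConfig, flow_factor: float,
                    inflow_pO2_override: float) -> dict[str, SweepResult]:
    """Paired baseline/flow-modulated runs at matched hypoxic fraction.

    All segment flows are scaled by ``flow_factor`` while the inflow pO2 is
    replaced by ``inflow_pO2_override`` (lower pO2 compensating higher flow
    keeps the hypoxic fraction comparable).
    """
    if flow_factor <= 0:
        raise ValueError("flow factor must be positive")
    base = run_experiment(config)
    o2p, pp, _, _, _ = _build_params(config)
    mod_flow = config.network_options.get(
        "flow_per_volume",
        333.0 if config.network == "tumor" else 824.0) * flow_factor
    mod_cfg = replace(
        config,
        network_options={**config.network_options, "flow_per_volume": mod_flow},
        oxygen={**config.oxygen, "inflow_pO2": inflow_pO2_override},
    )
    modulated = run_experiment(mod_cfg)
    return {"baseline": base, "modulated": modulated}


def report(result: SweepResult, out_dir) -> dict[str, Path]:
    """Write TSV table + JSON summary + run log; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "results.tsv",
        "summary": out / "summary.json",
        "log": out / "run.log",
    }
    cols = ["sweep_param", "sweep_value", "arm", "log_cell_kill",
            "additional_kill", "prodrug_extraction_pmol_mm3",
            "effector_washout_pmol_mm3", "hypoxic_fraction_4uM",
            "severe_hypoxic_fraction_013uM", "selectivity"]
    table = result.table if not result.table.empty else pd.DataFrame(columns=cols)
    table.to_csv(paths["table"], sep="\t", index=False)
    summary = {
        "name": result.config.name,
        "seed": result.config.seed,
        "config_hash": result.config_hash,
        "config": result.config.to_dict(),
        "n_rows": int(len(table)),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, default=str) + "\n")
    paths["log"].write_text("\n".join(result.log_lines) + "\n")
    return paths


# ---------------------------------------------------------------------------
# presets mirroring the study designs
# ---------------------------------------------------------------------------

def base_class2_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """Class II base model: low KO2, bystander on, potency 0.200 (μM·h)⁻¹."""
    cfg = ExperimentConfig(
        name="class2-base", seed=seed,
        prodrug={"KO2": 0.126},
        effector={"ktE": 0.01},
        potency={"case": 1, "a_ref": 0.200, "kmetE_ref": 0.01},
    )
    return replace(cfg, **overrides)


def class1_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """Class I comparator: high KO2, no bystander, potency 0.0414 (μM·h)⁻¹."""
    cfg = ExperimentConfig(
        name="class1", seed=seed,
        prodrug={"KO2": 1.26},
        effector={"ktE": 0.0},
        potency={"case": 1, "a_ref": 0.0414, "kmetE_ref": 0.01},
    )
    return replace(cfg, **overrides)


def washout_sweep_configs(seed: int = 1) -> dict[str, ExperimentConfig]:
    """Washout sensitivity grids: ~10× modulation of each effector parameter."""
    base = base_class2_config(seed)
    return {
        "kmetP_max": replace(base, name="washout-kmetP",
                             sweep_param="kmetP_max",
                             sweep_values=[0.001, 0.01, 0.1, 1.0]),
        "kmetE": replace(base, name="washout-kmetE", sweep_param="kmetE",
                         sweep_values=[0.001, 0.01, 0.1]),
        "ktE": replace(base, name="washout-ktE", sweep_param="ktE",
                       sweep_values=[0.001, 0.01, 0.1]),
        "D_E": replace(base, name="washout-DE",
                       effector={"ktE": 0.1},
                       sweep_param="D_E",
                       sweep_values=[1e-7, 1e-6, 1e-5]),
    }
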