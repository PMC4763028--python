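"""End-to-end planning pipeline: phantom -> trace -> energy -> dose -> plan.

A run is described by a :class:`RunConfig` (loadable from YAML): the phantom
source, the beam list with per-beam energy ("auto" selects from the EP x TS
look-up table), the prescription and DV constraints, and optimizer controls.
``run_pipeline`` executes every stage deterministically and returns the
optimized plan, its metrics and a provenance manifest; ``compare_runs``
builds the paired energy-modulated vs fixed-energy comparison report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beam_model import default_curves, default_profiles
from .dose import accumulate_dose, compute_ddc, concat_ddc, make_beamlet_grid
from .phantom import VoxelPhantom, make_archetype
from .planner import (
    DVConstraint,
    OptimizerControls,
    PlanObjective,
    ciao_init,
    optimize,
)
from .plan_eval import compute_dvh, normalize_plan, plan_metrics
from .raytrace import Ray
from .selector import EnergyTable, assign_beam_energies, build_energy_table

log = logging.getLogger("emxplan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class BeamSpec:
    gantry_deg: float
    energy: str | float = "auto"  # "auto" or a fixed MV


@dataclass
class RunConfig:
    """Declarative description of one planning run."""

    archetype: str = "lung_like"
    seed: int = 0
    spacing_cm: float = 0.5
    phantom_file: Optional[str] = None
    beams: List[BeamSpec] = field(default_factory=list)
    prescription_Gy: float = 50.0
    oar_constraints: Dict[str, List[dict]] = field(default_factory=dict)
    oar_weights: Dict[str, float] = field(default_factory=dict)
    max_iterations: int = 200
    rel_tolerance: float = 1e-5
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("at least one beam is required")
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        for b in self.beams:
            if b.energy != "auto" and float(b.energy) <= 0:
                raise ValueError(f"bad beam energy {b.energy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        beams = [BeamSpec(**b) for b in raw.pop("beams")]
        return cls(beams=beams, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    phantom: VoxelPhantom
    energy_assignments: List[dict]
    weights: np.ndarray
    dose: np.ndarray  # normalized, Gy
    metrics: pd.DataFrame
    manifest: dict
    optimizer_state: object = None


def _objective_from_config(cfg: RunConfig) -> PlanObjective:
    oc = {
        name: tuple(DVConstraint(structure=name, **c) for c in cs)
        for name, cs in cfg.oar_constraints.items()
    }
    return PlanObjective.with_default_target_bounds(
        prescription=cfg.prescription_Gy,
        oar_constraints=oc,
        oar_weights=dict(cfg.oar_weights),
    )


def run_pipeline(
    config: RunConfig,
    energy_table: Optional[EnergyTable] = None,
    output_dir: Optional[str] = None,
) -> RunResult:
    """Execute phantom -> trace -> energy selection -> DDC -> optimize ->
    normalize -> evaluate; optionally write artifacts to ``output_dir``."""
    stage = "phantom"
    try:
        if config.phantom_file:
            phantom = VoxelPhantom.load(config.phantom_file)
        else:
            phantom = make_archetype(
                config.archetype, config.seed, spacing=config.spacing_cm
            )
        iso = phantom.structure_centroid("PTV")

        stage = "energy_selection"
        curves = default_curves()
        profiles = default_profiles()
        angles = [b.gantry_deg for b in config.beams]
        if any(b.energy == "auto" for b in config.beams):
            table = energy_table if energy_table is not None else build_energy_table(curves=curves)
            auto = assign_beam_energies(phantom, angles, table, isocenter=iso)
        else:
            auto = [None] * len(angles)
        assignments = []
        for b, rec in zip(config.beams, auto):
            if b.energy == "auto":
                assignments.append(rec)
            else:
                assignments.append(
                    {"gantry_deg": b.gantry_deg, "ep_cm": None, "ts_cm": None,
                     "energy_MV": float(b.energy), "score_margin": None}
                )
        for rec in assignments:
            log.info(
                "beam %s deg: EP=%s TS=%s -> %s MV (margin %s)",
                rec["gantry_deg"], rec["ep_cm"], rec["ts_cm"],
                rec["energy_MV"], rec["score_margin"],
            )

        stage = "ddc"
        mats = []
        grids = []
        for rec in assignments:
            ray = Ray.from_gantry(rec["gantry_deg"], iso)
            e = int(rec["energy_MV"])
            grid = make_beamlet_grid(phantom, ray, e)
            mats.append(compute_ddc(phantom, grid, curves[e], profiles[e]))
            grids.append(grid)
        A = concat_ddc(mats)

        stage = "optimize"
        obj = _objective_from_config(config)
        init = np.concatenate([ciao_init(g, phantom) for g in grids])
        controls = OptimizerControls(
            max_iterations=config.max_iterations,
            rel_tolerance=config.rel_tolerance,
        )
        x, state = optimize(A, obj, phantom, init, controls)

        stage = "normalize"
        raw = accumulate_dose(A, x)
        dose = normalize_plan(
            raw, phantom.structures["PTV"], config.prescription_Gy,
            phantom.voxel_volume,
        )

        stage = "evaluate"
        metrics = plan_metrics(dose, phantom, config.prescription_Gy,
                               oar_vdose_levels=(5.0, 20.0))
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "emxplan_version": __version__,
            "n_beamlets": int(A.n_beamlets),
            "n_body_voxels": int(len(A.voxel_indices)),
            "optimizer": {
                "iterations": state.iterations,
                "stop_reason": state.stop_reason,
                "final_objective": state.objective_history[-1],
            },
            "energy_assignments": assignments,
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    result = RunResult(
        config=config,
        phantom=phantom,
        energy_assignments=assignments,
        weights=x,
        dose=dose,
        metrics=metrics,
        manifest=manifest,
        optimizer_state=state,
    )
    if output_dir is not None:
        write_artifacts(result, output_dir)
    return result


def write_artifacts(result: RunResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    pd.DataFrame({"weight": result.weights}).to_csv(out / "weights.csv", index=False)
    pd.DataFrame(result.energy_assignments).to_csv(
        out / "energy_assignments.csv", index=False
    )
    vv = result.phantom.voxel_volume
    curves = []
    for name, mask in result.phantom.structures.items():
        if name == "BODY":
            continue
        dvh = compute_dvh(result.dose, mask, vv, name)
        c = dvh.curve()
        c.insert(0, "structure", name)
        curves.append(c)
    pd.concat(curves).to_csv(out / "dvh.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def compare_runs(a: RunResult, b: RunResult) -> pd.DataFrame:
    """Paired comparison (a = baseline) with relative-difference column."""
    from .plan_eval import compare_plans

    return compare_plans(a.metrics, b.metrics)
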