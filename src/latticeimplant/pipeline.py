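"""End-to-end driver: homogenize -> fit surrogate -> optimize -> build lattice.

Each run lands in its own directory with every intermediate artifact (sweep
CSV, surrogate JSON, optimization history, density field VTK, lattice STL)
plus a machine-readable summary and the fully resolved configuration for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fe_solver, fixtures, ga_optimizer, homogenization, lattice_builder, surrogate, vtkio
from .ga_optimizer import GAConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


@dataclass
class PipelineConfig:
    """All knobs of the full design pipeline, with the study's defaults."""

    cell_type: str = "octet"
    cell_size: float = 1.35  # mm
    resolution: int = 24  # homogenization voxels per edge (48 for production runs)
    sweep_densities: tuple = tuple(round(0.1 * k, 10) for k in range(1, 9))
    Es: float = 110000.0  # titanium, MPa
    nus: float = 0.3
    liner: tuple[float, float] = (1000.0, 0.4)  # polyethylene, MPa / -
    cement: tuple[float, float] = (2500.0, 0.3)  # MPa / -
    benchmark: str = "cantilever"  # or "cage"
    benchmark_dims: tuple[int, int, int] = (12, 6, 3)
    cage_refinement: int = 1
    ga: GAConfig = field(default_factory=GAConfig)
    exploit_cubic_symmetry: bool = True
    seed: int = 0
    out_dir: str = "runs/latest"

    def validate(self) -> None:
        lo, hi = self.ga.rho_bounds
        smin, smax = min(self.sweep_densities), max(self.sweep_densities)
        if lo < smin - 1e-12 or hi > smax + 1e-12:
            raise ValueError(
                f"GA density bounds [{lo}, {hi}] outside the surrogate domain "
                f"[{smin}, {smax}] the sweep will produce"
            )
        if self.benchmark not in ("cantilever", "cage"):
            raise ValueError(f"unknown benchmark {self.benchmark!r}")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        if "ga" in payload:
            ga = payload["ga"]
            ga["rho_bounds"] = tuple(ga.get("rho_bounds", (0.2, 0.7)))
            payload["ga"] = GAConfig(**ga)
        for key in ("sweep_densities", "liner", "cement", "benchmark_dims"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()  # before any compute
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.ga = dataclasses.replace(config.ga, seed=config.seed)
    config.to_json(out / "resolved_config.json")
    logger.info("run directory %s, seed %d", out, config.seed)

    stage = "homogenize"
    try:
        rows = homogenization.density_sweep(
            config.cell_type,
            list(config.sweep_densities),
            config.Es,
            config.nus,
            config.resolution,
            exploit_cubic_symmetry=config.exploit_cubic_symmetry,
            l=config.cell_size,
        )
        homogenization.write_sweep_csv(rows, out / "sweep.csv")

        stage = "fit"
        model = surrogate.fit_from_sweep_rows(rows, Es=config.Es, nus=config.nus)
        model.to_json(out / "surrogate.json")
        logger.info("surrogate R2: E %.5f, nu %.5f", model.r2_E, model.r2_nu)

        stage = "benchmark"
        if config.benchmark == "cantilever":
            mesh, case = fixtures.make_cantilever(*config.benchmark_dims)
        else:
            mesh, case = fixtures.make_cage_benchmark(config.cage_refinement)

        stage = "optimize"
        best, history = ga_optimizer.optimize(mesh, None, model, config.ga)
        history.to_csv(out / "history.csv")
        vtkio.write_vtk(out / "density.vtk", mesh, cell_data={"rho": best.rho})

        stage = "analyze"
        asm = fe_solver.assemble(mesh, best.rho, model)
        state = fe_solver.solve(mesh, asm)
        vm = fe_solver.von_mises(state, mesh)
        vtkio.write_vtk(
            out / "solution.vtk",
            mesh,
            cell_data={"rho": best.rho, "von_mises_MPa": vm},
            point_data={"displacement_mm": state.U.reshape(-1, 3)},
        )

        stage = "build_lattice"
        model_lat = lattice_builder.build(mesh, best.rho, config.cell_type)
        lattice_builder.export_stl(model_lat, out / "lattice.stl")
        lattice_builder.export_wireframe(
            model_lat, out / "wireframe_nodes.csv", out / "wireframe_struts.csv"
        )

        stage = "summary"
        summary = {
            "seed": config.seed,
            "final_compliance_Nmm": history.compliance_per_iter[-1]
            if history.compliance_per_iter
            else None,
            "best_compliance_Nmm": float(state.c),
            "volume_fraction": best.mean_density(),
            "min_density": float(best.rho.min()),
            "max_density": float(best.rho.max()),
            "peak_von_mises_MPa": float(vm.max()),
            "iterations": len(history.compliance_per_iter),
            "converged_at": history.converged_at,
            "surrogate_r2_E": model.r2_E,
            "surrogate_r2_nu": model.r2_nu,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as err:  # keep partial artifacts, name the stage
        raise StageError(stage, err) from err
    return out
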