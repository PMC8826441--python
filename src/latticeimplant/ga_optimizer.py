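"""Cellular genetic-algorithm compliance minimization over element densities.

Every macro element carries one binary-coded relative density (a gene); the
whole mesh is the population and evolves in place.  Per generation the FE
model is solved, each element's strain energy ``dc_e = u_e^T k_e u_e``
serves as its fitness, parents are drawn fitness-proportionally for a
uniform crossover, and a directional mutation nudges high-fitness elements
toward higher density and low-fitness elements toward lower density.  A
multiplicative rescaling enforces the volume constraint after every
generation, and the best feasible design seen so far is returned.

Defaults: crossover factor 0.3, mutation factor 0.2, volume fraction 0.4,
density bounds [0.2, 0.7], uniform initialization at the volume constraint,
termination when the compliance change between successive generations drops
below 1e-3 relative to the first generation's compliance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from . import fe_solver
from .fe_solver import MacroMesh, SolutionState


@dataclass
class GAConfig:
    crossover_factor: float = 0.3
    mutation_factor: float = 0.2
    volume_fraction: float = 0.4
    rho_bounds: tuple[float, float] = (0.2, 0.7)
    bits_per_gene: int = 8
    tol: float = 1e-3
    max_iters: int = 80
    seed: int = 0
    #: "self": each element crosses its own gene with a fitness-selected mate
    #: (locality-preserving; crossover_factor -> 0 degenerates to pure
    #: directional mutation). "roulette": both parents fitness-selected.
    parent_mode: str = "self"
    #: consecutive sub-tolerance compliance changes required to declare
    #: convergence (a single quiet generation is routine mutation noise)
    patience: int = 5

    def __post_init__(self) -> None:
        for name in ("crossover_factor", "mutation_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.rho_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("rho_bounds must be an interval inside (0, 1)")
        if not lo <= self.volume_fraction <= hi:
            raise ValueError(
                f"volume fraction {self.volume_fraction} outside density bounds [{lo}, {hi}]"
            )
        if self.bits_per_gene < 1:
            raise ValueError("bits_per_gene must be >= 1")
        if self.parent_mode not in ("self", "roulette"):
            raise ValueError(f"unknown parent mode {self.parent_mode!r}")

    @property
    def levels(self) -> int:
        return 2**self.bits_per_gene

    @property
    def quantization_step(self) -> float:
        lo, hi = self.rho_bounds
        return (hi - lo) / (self.levels - 1)


def encode(rho, cfg: GAConfig) -> np.ndarray:
    """Binary genes for densities; shape (n, bits), most significant bit first.

    Densities are linearly quantized onto ``2**bits`` levels of
    ``[rho_lo, rho_hi]``; out-of-bounds values are clamped with a warning.
    """
    lo, hi = cfg.rho_bounds
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho < lo - 1e-12) or np.any(rho > hi + 1e-12):
        import warnings

        warnings.warn("density outside bounds; clamping before encoding", RuntimeWarning)
    rho = np.clip(rho, lo, hi)
    levels = np.rint((rho - lo) / (hi - lo) * (cfg.levels - 1)).astype(np.int64)
    shifts = np.arange(cfg.bits_per_gene - 1, -1, -1)
    return ((levels[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def decode(genes: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Densities from binary genes (inverse of :func:`encode` up to quantization)."""
    genes = np.atleast_2d(np.asarray(genes, dtype=np.uint8))
    weights = 2 ** np.arange(genes.shape[1] - 1, -1, -1)
    levels = genes @ weights
    lo, hi = cfg.rho_bounds
    return lo + levels / (cfg.levels - 1) * (hi - lo)


@dataclass
class DensityField:
    """The GA design vector: per-element density and its binary genes."""

    rho: np.ndarray
    genes: np.ndarray

    @classmethod
    def from_rho(cls, rho, cfg: GAConfig) -> "DensityField":
        genes = encode(rho, cfg)
        return cls(rho=decode(genes, cfg), genes=genes)

    @property
    def n_elements(self) -> int:
        return len(self.rho)

    def mean_density(self) -> float:
        return float(self.rho.mean())


@dataclass
class OptimizationHistory:
    compliance_per_iter: list = field(default_factory=list)
    volume_per_iter: list = field(default_factory=list)
    converged_at: int | None = None
    seed: int | None = None

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.compliance_per_iter) + 1),
                "compliance_Nmm": self.compliance_per_iter,
                "volume_fraction": self.volume_per_iter,
            }
        ).to_csv(path, index=False)


def fitness(state: SolutionState) -> np.ndarray:
    """Per-element fitness = element strain energy (the compliance sensitivity)."""
    if state.element_energy is None:
        raise ValueError("state is not solved")
    return np.maximum(state.element_energy, 0.0)


def select_parents(fit: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fitness-proportional (roulette-wheel) father/mother indices per element."""
    fit = np.asarray(fit, dtype=float)
    if np.any(fit < 0):
        raise ValueError("fitness must be non-negative")
    total = fit.sum()
    n = len(fit)
    p = np.full(n, 1.0 / n) if total == 0.0 else fit / total
    father = rng.choice(n, size=n, p=p)
    mother = rng.choice(n, size=n, p=p)
    return father, mother


def crossover(gene_a: np.ndarray, gene_b: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform crossover: each bit comes from ``gene_b`` with the crossover factor."""
    gene_a = np.asarray(gene_a, dtype=np.uint8)
    gene_b = np.asarray(gene_b, dtype=np.uint8)
    if gene_a.shape != gene_b.shape:
        raise ValueError("gene length mismatch")
    take_b = rng.random(gene_a.shape) < cfg.crossover_factor
    return np.where(take_b, gene_b, gene_a)


def mutate(
    gene: np.ndarray, fitness_rank, cfg: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Directional mutation.

    With probability ``mutation_factor`` per element, one random 0-bit is set
    (elements at or above the median fitness, pushing the decoded density up)
    or one random 1-bit is cleared (below-median elements, pushing it down).
    """
    genes = np.atleast_2d(np.asarray(gene, dtype=np.uint8)).copy()
    ranks = np.atleast_1d(np.asarray(fitness_rank, dtype=float))
    if np.any(ranks < 0) or np.any(ranks > 1):
        raise ValueError("fitness_rank must lie in [0, 1]")
    hit = rng.random(len(genes)) < cfg.mutation_factor
    for e in np.flatnonzero(hit):
        up = ranks[e] >= 0.5
        candidates = np.flatnonzero(genes[e] == (0 if up else 1))
        if candidates.size:
            genes[e, rng.choice(candidates)] = 1 if up else 0
    return genes if np.asarray(gene).ndim == 2 else genes[0]


def enforce_volume(fld: DensityField, cfg: GAConfig) -> DensityField:
    """Rescale an infeasible field multiplicatively toward the lower bound.

    Feasible fields pass through untouched; otherwise densities are shrunk
    toward ``rho_lo`` until the (re-quantized) mean meets the volume fraction.
    """
    lo, hi = cfg.rho_bounds
    if cfg.volume_fraction < lo:
        raise ValueError("volume fraction below the density lower bound is infeasible")
    if fld.mean_density() <= cfg.volume_fraction + 1e-12:
        return fld
    rho = fld.rho.copy()
    for _ in range(64):
        mean = rho.mean()
        if mean <= cfg.volume_fraction + 1e-12:
            break
        s = (cfg.volume_fraction - lo) / (mean - lo)
        rho = np.clip(lo + s * (rho - lo), lo, hi)
        # floor-quantize so re-encoding cannot push the mean back up
        levels = np.floor((rho - lo) / (hi - lo) * (cfg.levels - 1)).astype(np.int64)
        rho = lo + levels / (cfg.levels - 1) * (hi - lo)
    return DensityField.from_rho(rho, cfg)


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    n = len(values)
    return order / (n - 1) if n > 1 else np.full(n, 1.0)


def optimize(
    mesh: MacroMesh,
    loads=None,
    surrogate=None,
    cfg: GAConfig | None = None,
    *,
    design_mask: np.ndarray | None = None,
    base_E: np.ndarray | None = None,
    base_nu: np.ndarray | None = None,
) -> tuple[DensityField, OptimizationHistory]:
    """Run the GA until the compliance change stalls or ``max_iters`` is hit.

    ``loads`` may be a LoadCase-like object with ``apply(mesh)``; when None
    the loads already attached to the mesh are used.  Returns the best
    feasible design seen (elitist bookkeeping) with the full history.

    ``design_mask`` restricts the evolving densities to a subset of elements
    (e.g. the implant within a bonded implant-bone assembly); the remaining
    elements keep the fixed ``base_E``/``base_nu`` materials.
    """
    if cfg is None:
        cfg = GAConfig()
    if surrogate is None:
        raise ValueError("a density-property surrogate is required")
    lo, hi = cfg.rho_bounds
    slo, shi = surrogate.rho_domain
    if lo < slo - 1e-12 or hi > shi + 1e-12:
        raise ValueError(
            f"rho_bounds {cfg.rho_bounds} outside surrogate domain {surrogate.rho_domain}"
        )
    if loads is not None:
        mesh = loads.apply(mesh)
    rng = np.random.default_rng(cfg.seed)
    history = OptimizationHistory(seed=cfg.seed)
    if design_mask is None:
        design_mask = np.ones(mesh.n_elements, dtype=bool)
    else:
        design_mask = np.asarray(design_mask, dtype=bool)
        if base_E is None or base_nu is None:
            raise ValueError("base_E and base_nu are required with a design mask")
    n_design = int(design_mask.sum())
    logger.info(
        "GA start: seed %d, %d design elements, V0=%.3f", cfg.seed, n_design, cfg.volume_fraction
    )

    fld = DensityField.from_rho(np.full(n_design, cfg.volume_fraction), cfg)
    fld = enforce_volume(fld, cfg)

    def solve_field(f: DensityField) -> SolutionState:
        if design_mask.all():
            asm = fe_solver.assemble(mesh, f.rho, surrogate)
        else:
            E = np.asarray(base_E, dtype=float).copy()
            nu = np.asarray(base_nu, dtype=float).copy()
            E[design_mask] = surrogate.modulus(f.rho)
            nu[design_mask] = surrogate.poisson(f.rho)
            asm = fe_solver.assemble_from_moduli(mesh, E, nu)
        return fe_solver.solve(mesh, asm)

    try:
        state = solve_field(fld)
    except fe_solver.SingularityError:
        raise
    c_prev = state.c
    c_first = state.c
    history.compliance_per_iter.append(state.c)
    history.volume_per_iter.append(fld.mean_density())
    best_field, best_c = fld, state.c

    denom = c_first if c_first > 0 else 1.0
    quiet = 0
    if c_first == 0.0:
        history.converged_at = 2
        history.compliance_per_iter.append(0.0)
        history.volume_per_iter.append(fld.mean_density())
        return best_field, history

    for it in range(2, cfg.max_iters + 1):
        fit = fitness(state)[design_mask]
        ranks = _percentile_ranks(fit)
        father, mother = select_parents(fit, rng)
        father_genes = fld.genes if cfg.parent_mode == "self" else fld.genes[father]
        child = crossover(father_genes, fld.genes[mother], cfg, rng)
        child = mutate(child, ranks, cfg, rng)
        fld = enforce_volume(
            DensityField(rho=decode(child, cfg), genes=child), cfg
        )
        try:
            state = solve_field(fld)
        except fe_solver.SingularityError:
            break  # abort mid-run, history so far is returned
        history.compliance_per_iter.append(state.c)
        history.volume_per_iter.append(fld.mean_density())
        logger.info(
            "iter %3d: compliance %.6g N*mm, volume %.4f", it, state.c, fld.mean_density()
        )
        if state.c < best_c and fld.mean_density() <= cfg.volume_fraction + 1e-6:
            best_field, best_c = fld, state.c
        if abs(state.c - c_prev) / denom < cfg.tol:
            quiet += 1
            if quiet >= cfg.patience:
                history.converged_at = it
                break
        else:
            quiet = 0
        c_prev = state.c
    return best_field, history
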