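"""Evolution strategy with self-adaptation (EASA) for ideotype design.

A (1 + 16) evolution strategy over the eight cultivar parameters: each
generation mutates the parent into 16 candidates using per-parameter
log-normal step-size self-adaptation, evaluates each candidate's 100-year
mean yield and yield CV, discards candidates whose CV exceeds the limit
(default 10%), and selects the highest-mean-yield feasible candidate —
keeping the incumbent parent when no offspring beats it, which makes the
best-so-far trajectory monotone.

Stopping: no improvement larger than ``improve_tol`` for
``no_improve_patience`` consecutive generations, or ``max_generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, CultivarParams, ParameterBounds

#: log-normal self-adaptation learning rate, tau = 1/sqrt(2 n) for n = 8
DEFAULT_TAU = 1.0 / math.sqrt(2.0 * len(PARAM_NAMES))


@dataclass(frozen=True)
class OptimizerConfig:
    n_offspring: int = 16
    cv_limit: float = 0.10  # candidates with yield CV above this are excluded
    max_generations: int = 500
    no_improve_patience: int = 30
    improve_tol: float = 0.01  # t ha^-1
    tau: float = DEFAULT_TAU
    initial_step_frac: float = 0.10  # initial sigma as a fraction of each range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.cv_limit <= 0:
            raise ValueError("cv_limit must be positive")


@dataclass
class CandidateGenome:
    params: CultivarParams
    step_sizes: np.ndarray  # per-parameter mutation scale, parameter units

    def __post_init__(self) -> None:
        self.step_sizes = np.asarray(self.step_sizes, dtype=float)
        if np.any(self.step_sizes <= 0):
            raise ValueError("step sizes must be positive")


@dataclass
class EvaluationRecord:
    genome: CandidateGenome
    mean_yield: float  # t ha^-1
    cv: float
    feasible: bool
    error: str | None = None


@dataclass
class GenerationTrace:
    generation: int
    parent: EvaluationRecord
    offspring: list[EvaluationRecord]
    selected: EvaluationRecord
    best_so_far: float


@dataclass
class OptimizationTrace:
    generations: list[GenerationTrace] = field(default_factory=list)
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        """One row per candidate: generation, index (-1 = parent), parameters,
        mean yield, CV, feasibility, selection flag."""
        rows = []
        for g in self.generations:
            for idx, rec in [(-1, g.parent)] + list(enumerate(g.offspring)):
                row = {"generation": g.generation, "candidate": idx}
                row.update({n: getattr(rec.genome.params, n) for n in PARAM_NAMES})
                row.update({"mean_yield": rec.mean_yield, "cv": rec.cv,
                            "feasible": rec.feasible,
                            "selected": rec is g.selected})
                rows.append(row)
        return pd.DataFrame(rows)


Evaluator = Callable[[CultivarParams], object]
"""Maps cultivar parameters to an object with ``mean_yield`` and ``cv``."""


def initial_genome(params: CultivarParams, bounds: ParameterBounds,
                   cfg: OptimizerConfig) -> CandidateGenome:
    if not bounds.contains(params):
        raise ValueError("initial parameters outside bounds")
    return CandidateGenome(params, cfg.initial_step_frac * bounds.span)


def mutate(parent: CandidateGenome, bounds: ParameterBounds,
           cfg: OptimizerConfig, rng: np.random.Generator) -> list[CandidateGenome]:
    """Generate ``n_offspring`` candidates from a parent.

    Per parameter: sigma' = sigma * exp(tau * N(0,1)), then
    x' = clip(x + sigma' * N(0,1), bounds). Step sizes are kept within
    [1e-6, 1] x the parameter range so self-adaptation cannot collapse
    or explode.
    """
    x = parent.params.as_array()
    span = bounds.span
    offspring = []
    for _ in range(cfg.n_offspring):
        sigma = parent.step_sizes * np.exp(cfg.tau * rng.standard_normal(x.size))
        sigma = np.clip(sigma, 1e-6 * span, span)
        child = bounds.clip(x + sigma * rng.standard_normal(x.size))
        offspring.append(CandidateGenome(CultivarParams.from_array(child), sigma))
    return offspring


def evaluate(genome: CandidateGenome, evaluator: Evaluator,
             cfg: OptimizerConfig) -> EvaluationRecord:
    """Evaluate a candidate; evaluator failures become infeasible records."""
    try:
        result = evaluator(genome.params)
        mean, cv = float(result.mean_yield), float(result.cv)
    except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
        return EvaluationRecord(genome, -math.inf, math.inf, False, error=str(exc))
    return EvaluationRecord(genome, mean, cv, feasible=cv <= cfg.cv_limit)


def select(parent: EvaluationRecord, offspring: list[EvaluationRecord],
           cfg: OptimizerConfig) -> EvaluationRecord:
    """Highest mean yield among feasible offspring and the incumbent parent.

    Infeasible candidates are excluded from selection, and that applies to
    the incumbent too: an infeasible parent (possible only while the search
    has not yet reached the feasible region, i.e. the initial cultivar
    violates the CV cap) is replaced by the best feasible offspring whatever
    its yield. While nothing at all is feasible the search walks toward
    feasibility by selecting the least-violating candidate (lowest CV, ties
    by yield), so it cannot sit on an infeasible incumbent forever. Ties keep
    the incumbent; among tied offspring the lowest index wins, so selection
    is deterministic.
    """
    feasible = [rec for rec in offspring if rec.feasible]
    if parent.feasible:
        best = parent
        for rec in feasible:
            if rec.mean_yield > best.mean_yield:
                best = rec
        return best
    if feasible:
        best = feasible[0]
        for rec in feasible[1:]:
            if rec.mean_yield > best.mean_yield:
                best = rec
        return best
    # approach phase: nothing is feasible yet, so walk toward feasibility by
    # minimizing the violation (lowest CV; ties by yield, then incumbent)
    best = parent
    for rec in offspring:
        if rec.cv < best.cv or (rec.cv == best.cv
                                and rec.mean_yield > best.mean_yield):
            best = rec
    return best


def optimize(initial: CultivarParams, evaluator: Evaluator,
             bounds: ParameterBounds | None = None,
             cfg: OptimizerConfig = OptimizerConfig(),
             ) -> tuple[EvaluationRecord, OptimizationTrace]:
    """Run the evolution strategy from ``initial``; returns (best, trace)."""
    bounds = bounds or ParameterBounds()
    rng = np.random.default_rng(cfg.seed)
    parent = evaluate(initial_genome(initial, bounds, cfg), evaluator, cfg)
    trace = OptimizationTrace()
    # best-so-far tracks the best *feasible* yield; an infeasible initial
    # parent does not set the bar (it only serves as a fallback)
    best_yield = parent.mean_yield if parent.feasible else -math.inf
    stall = 0
    for gen in range(cfg.max_generations):
        offspring = [evaluate(g, evaluator, cfg)
                     for g in mutate(parent.genome, bounds, cfg, rng)]
        selected = select(parent, offspring, cfg)
        if selected.feasible:
            improved = selected.mean_yield - best_yield > cfg.improve_tol
            best_yield = max(best_yield, selected.mean_yield)
        else:
            # approach phase: moving to a less-violating candidate is progress
            improved = selected is not parent
        trace.generations.append(GenerationTrace(
            gen, parent, offspring, selected,
            best_yield if math.isfinite(best_yield) else parent.mean_yield))
        if selected is parent and parent.feasible:
            # stagnation: contract the search (success-rule analogue for 1+lambda)
            parent.genome.step_sizes = np.maximum(
                0.85 * parent.genome.step_sizes, 1e-6 * bounds.span)
        parent = selected
        stall = 0 if improved else stall + 1
        if stall >= cfg.no_improve_patience:
            trace.converged = True
            break
    return parent, trace
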