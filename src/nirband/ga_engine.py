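"""Binary genetic algorithm over latent-component candidates.

Each chromosome is a vector of binary flags over the candidate variables
(1 = selected).  Fitness is the validation RMSE of a least-squares model with
intercept regressing the reference values on the selected score columns:
calibration scores are orthogonal by construction, so ordinary least squares
is stable and equivalent to a full-rank latent-variable fit.

Evolution uses tournament selection (size 2), single-point crossover applied
per parent pair with probability ``p_crossover``, independent per-bit
mutation with probability ``p_mutation``, and elitism (the best individual is
carried unchanged), so the best-so-far fitness trace is non-increasing.  Two
stopping rules apply: a hard iteration ceiling (default 500) and a stall rule
that stops when the best fitness has not changed for ``stall_window``
(default 20) consecutive iterations.  The parametric-scaling scan reruns the
whole evolution for every (crossover %, mutation %) grid cell with a derived
per-cell seed and keeps the cell with minimum best RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GAConfig", "GATrace", "fitness", "evolve", "parametric_scan",
           "WORST_FITNESS"]

#: sentinel fitness for degenerate (all-zero) chromosomes; never wins selection
WORST_FITNESS = float("inf")


@dataclass(frozen=True)
class GAConfig:
    p_crossover: float          # per-pair crossover probability, in (0, 1)
    p_mutation: float           # per-bit flip probability, in [0, 1)
    population_size: int | None = None  # None -> max(20, 2 * n_candidates), even
    max_iterations: int = 500
    stall_window: int = 20
    stall_tolerance: float = 1e-6       # |change in best RMSE| counted as "no change"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_crossover < 1:
            raise ValueError(f"p_crossover must be in (0, 1), got {self.p_crossover}")
        if not 0 <= self.p_mutation < 1:
            raise ValueError(f"p_mutation must be in [0, 1), got {self.p_mutation}")
        if self.population_size is not None and (
                self.population_size < 4 or self.population_size % 2):
            raise ValueError("population_size must be an even integer >= 4")
        if self.max_iterations < 1 or self.stall_window < 1:
            raise ValueError("max_iterations and stall_window must be >= 1")

    @classmethod
    def from_percent(cls, crossover_pct: float, mutation_pct: float, **kw) -> "GAConfig":
        """Build from percent-scale operators, e.g. (50, 1.2) -> (0.5, 0.012)."""
        return cls(p_crossover=crossover_pct / 100.0,
                   p_mutation=mutation_pct / 100.0, **kw)

    def resolve_population(self, n_candidates: int) -> int:
        if self.population_size is not None:
            return self.population_size
        size = max(20, 2 * n_candidates)
        return size + (size % 2)


@dataclass(frozen=True)
class GATrace:
    """Per-iteration best fitness history and the final winner."""

    best_rmsev_per_iteration: np.ndarray
    stop_iteration: int
    stop_reason: str            # "max_iterations" | "stalled"
    best_chromosome: np.ndarray  # binary flags
    best_rmsev: float
    best_r_v: float | None


def fitness(chromosome: np.ndarray, scores_cal: np.ndarray, y_cal: np.ndarray,
            scores_val: np.ndarray, y_val: np.ndarray) -> float:
    """Validation RMSE of the least-squares model on the flagged columns."""
    flags = np.asarray(chromosome, dtype=bool)
    if flags.size != scores_cal.shape[1]:
        raise ValueError("chromosome length must equal the score column count")
    if not flags.any():
        return WORST_FITNESS
    rmse, _ = _fit_and_score(flags, scores_cal, y_cal, scores_val, y_val)
    return rmse


def _fit_and_score(flags, scores_cal, y_cal, scores_val, y_val):
    Ac = np.column_stack([np.ones(scores_cal.shape[0]), scores_cal[:, flags]])
    beta, *_ = np.linalg.lstsq(Ac, y_cal, rcond=None)
    Av = np.column_stack([np.ones(scores_val.shape[0]), scores_val[:, flags]])
    pred = Av @ beta
    rmse = float(np.sqrt(np.mean((pred - y_val) ** 2)))
    return rmse, pred


def _repair(flags: np.ndarray, rng: np.random.Generator) -> None:
    """Give all-zero chromosomes one random flag (in place)."""
    dead = ~flags.any(axis=1)
    for i in np.flatnonzero(dead):
        flags[i, rng.integers(flags.shape[1])] = True


def evolve(scores_cal: np.ndarray, y_cal: np.ndarray, scores_val: np.ndarray,
           y_val: np.ndarray, config: GAConfig, objective=None,
           initial_population: np.ndarray | None = None) -> GATrace:
    """Run the genetic algorithm; bit-reproducible for a fixed seed.

    ``objective`` optionally replaces the default least-squares fitness with
    a callable ``flags -> validation RMSE`` (used e.g. by the full-spectrum
    GA-PLS baseline, whose fitness is a PLS model on the flagged channels);
    the trace's ``best_r_v`` is only available for the default fitness.
    ``initial_population`` optionally replaces the random initial population
    (a boolean matrix, one chromosome per row).
    """
    scores_cal = np.atleast_2d(np.asarray(scores_cal, dtype=float))
    scores_val = np.atleast_2d(np.asarray(scores_val, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    m = scores_cal.shape[1]
    if scores_val.shape[1] != m:
        raise ValueError("calibration and validation score matrices disagree on columns")
    pop_size = config.resolve_population(m)
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def fit_of(row: np.ndarray) -> float:
        key = row.tobytes()
        if key not in cache:
            if objective is not None:
                cache[key] = objective(row) if row.any() else WORST_FITNESS
            else:
                cache[key] = fitness(row, scores_cal, y_cal, scores_val, y_val)
        return cache[key]

    if initial_population is not None:
        pop = np.array(initial_population, dtype=bool)
        if pop.shape != (pop_size, m):
            raise ValueError(f"initial_population must have shape {(pop_size, m)}")
        pop = pop.copy()
    else:
        pop = rng.integers(0, 2, size=(pop_size, m)).astype(bool)
    _repair(pop, rng)

    best_flags: np.ndarray | None = None
    best_fit = WORST_FITNESS
    history: list[float] = []
    stall = 0
    iteration = 0
    stop_reason = "max_iterations"

    while iteration < config.max_iterations:
        iteration += 1
        fits = np.array([fit_of(row) for row in pop])
        gen_best = int(np.argmin(fits))
        improved = best_fit - fits[gen_best] > config.stall_tolerance
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_flags = pop[gen_best].copy()
        history.append(best_fit)
        if iteration > 1:
            stall = 0 if improved else stall + 1
            if stall >= config.stall_window:
                stop_reason = "stalled"
                break

        # next generation: elitism + tournament parents + crossover + mutation
        idx_a = rng.integers(pop_size, size=pop_size)
        idx_b = rng.integers(pop_size, size=pop_size)
        winners = np.where(fits[idx_a] <= fits[idx_b], idx_a, idx_b)
        parents = pop[winners]
        children = parents.copy()
        for i in range(0, pop_size - 1, 2):
            if rng.random() < config.p_crossover and m > 1:
                cut = int(rng.integers(1, m))  # crossover point inside the string
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(), parents[i, cut:].copy())
        if config.p_mutation > 0:
            children ^= rng.random(children.shape) < config.p_mutation
        _repair(children, rng)
        children[0] = best_flags  # elitism
        pop = children

    if best_flags is None:  # unreachable with repair, kept for safety
        raise RuntimeError("no feasible chromosome evaluated")

    best_r_v = None
    if objective is None:
        _, pred = _fit_and_score(best_flags, scores_cal, y_cal, scores_val, y_val)
        from .regression import evaluate as _evaluate
        best_r_v = _evaluate(y_val, pred, which_set="validation").r
    return GATrace(best_rmsev_per_iteration=np.array(history),
                   stop_iteration=iteration, stop_reason=stop_reason,
                   best_chromosome=best_flags, best_rmsev=best_fit,
                   best_r_v=best_r_v)


def derive_cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic independent seed for one scan cell."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def parametric_scan(scores_cal, y_cal, scores_val, y_val,
                    crossover_pct_grid, mutation_pct_grid,
                    base_config: GAConfig
                    ) -> tuple[GAConfig, GATrace, dict[tuple[float, float], GATrace]]:
    """Grid scan over crossover/mutation percentages; returns the best cell.

    Every cell reruns :func:`evolve` with a seed derived from the base
    config's seed and the cell index, so cells are independent yet
    reproducible.  Ties go to the earlier grid cell (row-major order).
    """
    cps = list(crossover_pct_grid)
    mps = list(mutation_pct_grid)
    if not cps or not mps:
        raise ValueError("scan grids must be nonempty")
    traces: dict[tuple[float, float], GATrace] = {}
    best_key: tuple[float, float] | None = None
    best_cfg: GAConfig | None = None
    for idx, (cp, mp) in enumerate((c, m) for c in cps for m in mps):
        cfg = replace(base_config, p_crossover=cp / 100.0, p_mutation=mp / 100.0,
                      seed=derive_cell_seed(base_config.seed, idx))
        trace = evolve(scores_cal, y_cal, scores_val, y_val, cfg)
        traces[(cp, mp)] = trace
        if best_key is None or trace.best_rmsev < traces[best_key].best_rmsev:
            best_key, best_cfg = (cp, mp), cfg
    assert best_cfg is not None
    return best_cfg, traces[best_key], traces
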