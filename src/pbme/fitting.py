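"""Parameter estimation for candidate model structures.

Parameters are fitted with differential evolution, strategy rand/1/bin
(population 50, differential weight F = 0.6, crossover probability
Cr = 0.6), with an objective-evaluation budget of one thousand simulations
per free parameter. The objective is an error function between the observed
and the simulated endogenous trajectory: RMSE, root relative squared error
(RRSE), or weighted RMSE.

The optimizer is deterministic for a fixed seed: the initial population is
drawn uniformly over the declared parameter ranges from the seeded
generator, out-of-bounds mutants are clipped to the boundary, and binomial
crossover forces at least one mutant coordinate per trial vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TimeSeriesDataset, Trajectory, simulate
from .knowledge_library import Library
from .model_space import ModelStructure, ODESystem, compile_to_odes

ERROR_KINDS = ("rmse", "rrse", "wrmse")


class FittingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# error functions
# ---------------------------------------------------------------------------


def error(y, y_hat, kind: str = "rmse", weights=None) -> float:
    """Discrepancy between an observed and a simulated series.

    rmse  = sqrt(sum((y - y_hat)^2) / n)
    rrse  = sqrt(sum((y - y_hat)^2) / sum((y - mean(y))^2))
    wrmse = sqrt(sum(w * (y - y_hat)^2) / sum(w))

    Missing (NaN) observations are skipped; any non-finite simulated value
    makes the error +inf.
    """
    if kind not in ERROR_KINDS:
        raise FittingError(f"unknown error kind {kind!r}")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise FittingError("observed and simulated series differ in length")
    if kind == "wrmse":
        if weights is None:
            raise FittingError("wrmse requires weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0):
            raise FittingError("weights must be non-negative, one per point")
    else:
        w = None

    mask = np.isfinite(y)
    y, y_hat = y[mask], y_hat[mask]
    if w is not None:
        w = w[mask]
        if w.sum() == 0:
            raise FittingError("all weights are zero")
    if y.size == 0:
        raise FittingError("no finite observations")
    if not np.all(np.isfinite(y_hat)):
        return float("inf")

    sq = (y - y_hat) ** 2
    if kind == "rmse":
        return float(np.sqrt(sq.mean()))
    if kind == "wrmse":
        return float(np.sqrt((w * sq).sum() / w.sum()))
    denom = ((y - y.mean()) ** 2).sum()
    if denom == 0:
        raise FittingError("rrse undefined: observed series has zero variance")
    return float(np.sqrt(sq.sum() / denom))


def trajectory_error(
    data: TimeSeriesDataset,
    traj: Trajectory,
    kind: str = "rmse",
    weights=None,
) -> float:
    """Error of a trajectory against a dataset's endogenous observations.

    With several endogenous variables the per-variable errors are averaged.
    A failed trajectory scores +inf.
    """
    if not traj.ok:
        return float("inf")
    errs = [error(data.values(v), traj[v], kind, weights) for v in data.endogenous]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# differential evolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEConfig:
    population: int = 50
    strategy: str = "rand/1/bin"
    F: float = 0.6
    Cr: float = 0.6
    evals_per_param: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.F <= 2:
            raise FittingError("F must be in (0, 2]")
        if not 0 <= self.Cr <= 1:
            raise FittingError("Cr must be in [0, 1]")
        if self.strategy != "rand/1/bin":
            raise FittingError(f"unsupported DE strategy {self.strategy!r}")
        if self.population < 4:
            raise FittingError("population must be at least 4")

    def budget(self, n_params: int) -> int:
        return self.evals_per_param * n_params


@dataclass
class FittedModel:
    """A structure with estimated parameter values and its errors."""

    structure: ModelStructure
    system: ODESystem
    params: np.ndarray
    train_error: float
    val_error: float | None = None
    evaluations: int = 0
    objective: str = "rmse"

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.system.parameter_names, map(float, self.params)))

    def simulate(self, data: TimeSeriesDataset, **kw) -> Trajectory:
        return simulate(self.system, self.params, data, **kw)

    def score(self, data: TimeSeriesDataset, kind: str = "rmse", weights=None) -> float:
        return trajectory_error(data, self.simulate(data), kind, weights)


def differential_evolution(objective, bounds: np.ndarray, cfg: DEConfig, budget: int):
    """Minimize ``objective`` over box ``bounds`` with rand/1/bin DE.

    Returns ``(best_x, best_f, n_evaluations)`` with n_evaluations <= budget.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo > hi):
        raise FittingError("unsatisfiable parameter range (lo > hi)")
    d = len(lo)
    n_pop = min(cfg.population, budget)
    pop = lo + rng.random((n_pop, d)) * (hi - lo)
    fitness = np.array([objective(x) for x in pop])
    evals = n_pop
    while evals < budget:
        for i in range(n_pop):
            if evals >= budget:
                break
            r1, r2, r3 = _pick3(rng, n_pop, i)
            mutant = np.clip(pop[r1] + cfg.F * (pop[r2] - pop[r3]), lo, hi)
            cross = rng.random(d) < cfg.Cr
            cross[rng.integers(d)] = True  # forced crossover index
            trial = np.where(cross, mutant, pop[i])
            f_trial = objective(trial)
            evals += 1
            if f_trial <= fitness[i]:
                pop[i], fitness[i] = trial, f_trial
    best = int(np.argmin(fitness))
    return pop[best].copy(), float(fitness[best]), evals


def _pick3(rng: np.random.Generator, n: int, i: int) -> tuple[int, int, int]:
    idx = [j for j in range(n) if j != i]
    picks = rng.choice(len(idx), size=3, replace=False)
    return tuple(idx[p] for p in picks)


def estimate_parameters(
    lib: Library,
    structure: ModelStructure,
    data: TimeSeriesDataset,
    kind: str = "rmse",
    weights=None,
    cfg: DEConfig = DEConfig(),
) -> FittedModel:
    """Fit a model structure's parameters to training data.

    Returns the best parameter vector found within the declared ranges, with
    the training error re-evaluated at the returned vector. A structure with
    no free parameters is simply simulated (zero optimizer iterations).
    """
    system = compile_to_odes(lib, structure)
    if len(data) == 0:
        raise FittingError("empty training dataset")

    def objective(x: np.ndarray) -> float:
        traj = simulate(system, x, data)
        return trajectory_error(data, traj, kind, weights)

    if not system.parameters:
        return FittedModel(structure, system, np.empty(0), objective(np.empty(0)), objective=kind)

    bounds = structure.bounds
    budget = cfg.budget(len(bounds))
    best_x, best_f, evals = differential_evolution(objective, bounds, cfg, budget)
    return FittedModel(structure, system, best_x, best_f, evaluations=evals, objective=kind)
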