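"""Ensembles of fitted process-based models.

Three constituent-learning strategies are provided:

* **library sampling** — the random-subspace analogue over modeling
  knowledge: each iteration draws a random sub-library (a non-empty subset
  of the leaf alternatives of every open choice template, with probability
  proportional to the induced candidate-model count), fits every candidate
  structure of the sub-library on the training set, and keeps the best model
  by validation (or training) error. A *fast* variant fits every structure
  of the full library exactly once and serves each library sample from that
  pre-fitted pool — distributionally identical when per-structure fitting is
  seeded by structure identity, but with a single fitting pass regardless of
  the ensemble size.
* **bagging** — bootstrap replicates of the training time points, collapsed
  to unique sorted points with multiplicity weights (temporal ordering is
  preserved), fitted with weighted RMSE.
* **boosting** — an AdaBoost.R2-style reweighting of the training points
  with squared loss: points with large current errors gain weight, and the
  per-iteration confidence beta = avg_loss / (1 - avg_loss) both reweights
  the data and weights the constituent.

Each constituent carries a confidence beta >= 0 (low beta = high
confidence): the average of the per-point squared discrepancies normalized
by the worst one, mapped through beta = L / (1 - L). Constituent
trajectories are combined time-point-wise by mean, median, weighted mean or
weighted median, with weights ln(1/beta).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .dynamics import TimeSeriesDataset, Trajectory
from .fitting import DEConfig, FittedModel, estimate_parameters
from .knowledge_library import Library
from .model_space import IncompleteModel, enumerate_structures, sample_library

logger = logging.getLogger(__name__)

BETA_MIN = 1e-9  # floor when a perfect fit (beta = 0) is used in weights
BETA_MAX = 1e9  # cap for failed or saturated fits

SCHEMES = ("average", "weighted-average", "median", "weighted-median")


class EnsembleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# confidence (per-constituent weight)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceReport:
    discrepancies: np.ndarray  # per-point squared discrepancy
    max_disc: float  # (sup_t |y_t - yhat_t|)^2
    avg_loss: float  # mean normalized loss, in [0, 1]
    beta: float  # avg_loss / (1 - avg_loss), capped at BETA_MAX


def _squared_discrepancies(model: FittedModel, data: TimeSeriesDataset) -> np.ndarray | None:
    """Per-time-point squared discrepancy, averaged over endogenous variables."""
    traj = model.simulate(data)
    if not traj.ok:
        return None
    disc = np.zeros(len(data))
    n_vars = 0
    for v in data.endogenous:
        y = data.values(v)
        resid = np.where(np.isfinite(y), np.abs(y - traj[v]), 0.0)
        if not np.all(np.isfinite(resid)):
            return None
        disc += resid**2
        n_vars += 1
    return disc / max(n_vars, 1)


def confidence(model: FittedModel, data: TimeSeriesDataset) -> ConfidenceReport:
    """Loss-derived confidence of a fitted model on a dataset.

    The squared discrepancies are normalized by the largest one, averaged
    over the time points, and mapped through beta = L / (1 - L); a perfect
    fit gets beta = 0 and a failed simulation the worst confidence BETA_MAX.
    """
    if len(data) == 0:
        raise EnsembleError("confidence needs a non-empty dataset")
    disc = _squared_discrepancies(model, data)
    if disc is None:
        return ConfidenceReport(np.full(len(data), np.inf), float("inf"), 1.0, BETA_MAX)
    max_disc = float(disc.max())
    if max_disc == 0.0:
        return ConfidenceReport(disc, 0.0, 0.0, 0.0)
    avg_loss = float(np.mean(disc / max_disc))
    return ConfidenceReport(disc, max_disc, avg_loss, _loss_to_beta(avg_loss))


def _loss_to_beta(avg_loss: float) -> float:
    if avg_loss >= 1.0:
        return BETA_MAX
    return min(avg_loss / (1.0 - avg_loss), BETA_MAX)


# ---------------------------------------------------------------------------
# combining schemes
# ---------------------------------------------------------------------------


def _weights_from_betas(betas) -> np.ndarray:
    """ln(1/beta) weights, floored at zero (beta >= 1 contributes nothing)."""
    b = np.clip(np.asarray(betas, dtype=float), BETA_MIN, BETA_MAX)
    return np.maximum(np.log(1.0 / b), 0.0)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * w.sum())])


def combine(trajectories: list[Trajectory], betas, scheme: str = "average") -> Trajectory:
    """Combine constituent trajectories time-point-wise into one trajectory."""
    if scheme not in SCHEMES:
        raise EnsembleError(f"unknown combining scheme {scheme!r}")
    if not trajectories:
        raise EnsembleError("nothing to combine")
    times = trajectories[0].times
    for traj in trajectories[1:]:
        if not np.array_equal(traj.times, times):
            raise EnsembleError("constituent trajectories are on different time grids")
    if scheme in ("weighted-average", "weighted-median"):
        w = _weights_from_betas(betas)
        if w.sum() == 0:
            raise EnsembleError("all combining weights are zero")
    else:
        w = np.ones(len(trajectories))

    out: dict[str, np.ndarray] = {}
    for name in trajectories[0].values:
        stack = np.vstack([traj[name] for traj in trajectories])
        if scheme == "average":
            out[name] = stack.mean(axis=0)
        elif scheme == "median":
            out[name] = np.median(stack, axis=0)
        elif scheme == "weighted-average":
            out[name] = (w[:, None] * stack).sum(axis=0) / w.sum()
        else:
            out[name] = np.array([_weighted_median(stack[:, j], w) for j in range(stack.shape[1])])
    return Trajectory(times, out, ok=all(t.ok for t in trajectories))


# ---------------------------------------------------------------------------
# the ensemble container
# ---------------------------------------------------------------------------


@dataclass
class Ensemble:
    constituents: list[tuple[FittedModel, float]]  # (model, beta)
    scheme: str = "average"
    method: str = "library-sampling"

    def __post_init__(self) -> None:
        if not self.constituents:
            raise EnsembleError("an ensemble needs at least one constituent")
        if self.scheme not in SCHEMES:
            raise EnsembleError(f"unknown combining scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.constituents)

    @property
    def betas(self) -> list[float]:
        return [b for _, b in self.constituents]

    def simulate(self, data: TimeSeriesDataset, scheme: str | None = None) -> Trajectory:
        """Ensemble prediction: combined constituent simulations.

        Constituents whose simulation fails are dropped from the
        combination; if every one fails the result is flagged not-ok.
        """
        trajs, betas = [], []
        for model, beta in self.constituents:
            traj = model.simulate(data)
            if traj.ok:
                trajs.append(traj)
                betas.append(beta)
        if not trajs:
            times = data.times
            state = self.constituents[0][0].system.state_vars
            return Trajectory(times, {v: np.full_like(times, np.nan) for v in state}, ok=False)
        return combine(trajs, betas, scheme or self.scheme)

    def to_text(self) -> str:
        lines = [f"method: {self.method}", f"scheme: {self.scheme}", f"size: {len(self)}"]
        for i, (model, beta) in enumerate(self.constituents, start=1):
            lines.append(f"constituent {i}:")
            lines.append(f"  structure: {model.structure.key}")
            params = ", ".join(f"{k} = {v:.6g}" for k, v in model.param_dict.items())
            lines.append(f"  parameters: {params}")
            lines.append(f"  train_error: {model.train_error:.6g}")
            if model.val_error is not None:
                lines.append(f"  validation_error: {model.val_error:.6g}")
            lines.append(f"  beta: {beta:.6g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# shared helpers for the learners
# ---------------------------------------------------------------------------


def _structure_seed(base_seed: int, key: str) -> int:
    """Deterministic per-structure DE seed, stable across processes."""
    return zlib.crc32(f"{base_seed}|{key}".encode()) % (2**31)


def _fit_pool(
    lib: Library,
    inc: IncompleteModel,
    data: TimeSeriesDataset,
    cfg: DEConfig,
    kind: str,
    weights=None,
    tag: str = "",
) -> dict[str, FittedModel]:
    """Fit every candidate structure once, seeded by structure identity."""
    pool: dict[str, FittedModel] = {}
    for s in enumerate_structures(lib, inc):
        seed = _structure_seed(cfg.seed, s.key + tag)
        pool[s.key] = estimate_parameters(lib, s, data, kind, weights, replace(cfg, seed=seed))
    return pool


def _rank(models: list[FittedModel], select_data: TimeSeriesDataset, kind: str) -> FittedModel:
    """Best model by error on the selection set; ties break on list order."""
    scores = []
    for m in models:
        if m.val_error is None:
            m.val_error = m.score(select_data, kind)
        scores.append(m.val_error)
    return models[int(np.argmin(scores))]


def _distinct(model: FittedModel, ensemble: list[tuple[FittedModel, float]]) -> bool:
    for other, _ in ensemble:
        if other.structure.key == model.structure.key and np.allclose(
            other.params, model.params, rtol=1e-9, atol=0.0
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# library sampling (Algorithm 1), naive and fast variants
# ---------------------------------------------------------------------------

MAX_ITER_FACTOR = 50  # guard for the without-duplicates loop


def learn_ls_ensemble(
    lib: Library,
    train: TimeSeriesDataset,
    validation: TimeSeriesDataset,
    inc: IncompleteModel,
    allow_duplicates: bool = True,
    k: int = 10,
    cfg: DEConfig = DEConfig(),
    kind: str = "rmse",
    scheme: str = "average",
    seed: int | None = None,
) -> Ensemble:
    """Learn an ensemble by library sampling (naive variant).

    Each iteration samples the library, fits every candidate structure of
    the sample on the training set, and adds the best model on the
    selection set (validation, or training when ``validation is train``)
    together with its confidence. With duplicates allowed the loop runs
    exactly ``k`` times; without, it runs until ``k`` distinct constituents
    are found (or fails after ``MAX_ITER_FACTOR * k`` iterations).
    """
    return _learn_ls(
        lib, train, validation, inc, allow_duplicates, k, cfg, kind, scheme, seed, fast=False
    )


def learn_ls_ensemble_fast(
    lib: Library,
    train: TimeSeriesDataset,
    validation: TimeSeriesDataset,
    inc: IncompleteModel,
    allow_duplicates: bool = True,
    k: int = 10,
    cfg: DEConfig = DEConfig(),
    kind: str = "rmse",
    scheme: str = "average",
    seed: int | None = None,
    pool: dict[str, FittedModel] | None = None,
) -> Ensemble:
    """Library sampling served from one fitting pass over the full library.

    Produces exactly the same constituent sequence as the naive variant for
    the same seeds, because per-structure fitting is seeded by structure
    identity; the number of full fitting passes is 1 regardless of ``k``.
    A pre-fitted ``pool`` (from :func:`fit_full_pool` with the same config)
    may be supplied to skip even that single pass.
    """
    return _learn_ls(
        lib, train, validation, inc, allow_duplicates, k, cfg, kind, scheme, seed, fast=True, pool=pool
    )


def fit_full_pool(
    lib: Library,
    inc: IncompleteModel,
    train: TimeSeriesDataset,
    cfg: DEConfig = DEConfig(),
    kind: str = "rmse",
) -> dict[str, FittedModel]:
    """Fit every candidate structure of the full library once, keyed by identity."""
    return _fit_pool(lib, inc, train, cfg, kind)


def _learn_ls(lib, train, validation, inc, allow_duplicates, k, cfg, kind, scheme, seed, fast, pool=None):
    if k < 1:
        raise EnsembleError("ensemble size k must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    select_data = validation if validation is not None else train
    if fast and pool is None:
        pool = _fit_pool(lib, inc, train, cfg, kind)

    ensemble: list[tuple[FittedModel, float]] = []
    iterations = 0
    while len(ensemble) != k:
        if iterations >= MAX_ITER_FACTOR * k:
            raise EnsembleError(
                f"could not collect {k} distinct constituents in {iterations} iterations "
                f"({len(ensemble)} found); the model space may be too small"
            )
        iterations += 1
        sample = sample_library(lib, inc, rng)
        logger.info("library sample %s (|L_S| = %d, P = %.4g)", sample.subsets, sample.model_count, sample.probability)
        structures = enumerate_structures(lib, inc, restrict=sample.restriction())
        if fast:
            models = [pool[s.key] for s in structures]
        else:
            models = [
                estimate_parameters(
                    lib, s, train, kind, None, replace(cfg, seed=_structure_seed(cfg.seed, s.key))
                )
                for s in structures
            ]
        best = _rank(models, select_data, kind)
        beta = confidence(best, select_data).beta
        logger.info("selected %s (selection error %.6g, beta %.4g)", best.structure.key, best.val_error, beta)
        if allow_duplicates or _distinct(best, ensemble):
            ensemble.append((best, beta))
    return Ensemble(ensemble, scheme=scheme, method="library-sampling" + ("" if allow_duplicates else "-nodup"))


# ---------------------------------------------------------------------------
# bagging and boosting (data-instance sampling)
# ---------------------------------------------------------------------------


def bootstrap_replicate(rng: np.random.Generator, n: int) -> np.ndarray:
    """Multiplicities of a bootstrap replicate of n ordered time points.

    Sampling with replacement is collapsed to per-point counts, so the
    temporal ordering of the retained (count > 0) points is preserved.
    Degenerate replicates with fewer than 2 distinct points are redrawn.
    """
    while True:
        idx = rng.integers(0, n, size=n)
        counts = np.bincount(idx, minlength=n).astype(float)
        if np.count_nonzero(counts) >= 2:
            return counts


def adaboost_update(dist: np.ndarray, losses: np.ndarray, beta: float) -> np.ndarray:
    """Reweight a point distribution by beta^(1 - loss), renormalized.

    With beta < 1 the worst-fit points (loss near 1) gain weight relative
    to the best-fit ones, concentrating subsequent fitting effort there.
    """
    new = dist * np.clip(beta, BETA_MIN, None) ** (1.0 - np.asarray(losses))
    return new / new.sum()


def learn_bagging_ensemble(
    lib: Library,
    train: TimeSeriesDataset,
    validation: TimeSeriesDataset,
    inc: IncompleteModel,
    k: int = 25,
    cfg: DEConfig = DEConfig(),
    scheme: str = "average",
    seed: int | None = None,
) -> Ensemble:
    """Bagging: bootstrap replicates of the training time points.

    Each replicate samples the time points with replacement and collapses
    them to unique, sorted points with multiplicity weights (temporal
    ordering is retained); structures are fitted with multiplicity-weighted
    RMSE and the best model on the validation set joins the ensemble.
    """
    if k < 1:
        raise EnsembleError("ensemble size k must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    select_data = validation if validation is not None else train
    n = len(train)
    ensemble: list[tuple[FittedModel, float]] = []
    for i in range(k):
        counts = bootstrap_replicate(rng, n)
        models = [
            estimate_parameters(
                lib,
                s,
                train,
                "wrmse",
                counts,
                replace(cfg, seed=_structure_seed(cfg.seed, f"{s.key}|bag{i}")),
            )
            for s in enumerate_structures(lib, inc)
        ]
        for m in models:
            m.val_error = None  # fitted on weighted objective; rescore on selection set
        best = _rank(models, select_data, "rmse")
        beta = confidence(best, select_data).beta
        logger.info("bagging iteration %d: selected %s (beta %.4g)", i + 1, best.structure.key, beta)
        ensemble.append((best, beta))
    return Ensemble(ensemble, scheme=scheme, method="bagging")


def learn_boosting_ensemble(
    lib: Library,
    train: TimeSeriesDataset,
    validation: TimeSeriesDataset,
    inc: IncompleteModel,
    k: int = 25,
    cfg: DEConfig = DEConfig(),
    scheme: str = "average",
    seed: int | None = None,
) -> Ensemble:
    """Boosting: AdaBoost.R2-style reweighting of the training points.

    A distribution over the training time points starts uniform; each
    iteration fits all structures with distribution-weighted RMSE, selects
    the best on the validation set, computes per-point normalized squared
    losses and the average loss L, stops early when L >= 0.5, and otherwise
    reweights points by beta^(1 - L_t) with beta = L / (1 - L).
    """
    if k < 1:
        raise EnsembleError("ensemble size k must be >= 1")
    select_data = validation if validation is not None else train
    n = len(train)
    dist = np.full(n, 1.0 / n)
    ensemble: list[tuple[FittedModel, float]] = []
    for i in range(k):
        models = [
            estimate_parameters(
                lib,
                s,
                train,
                "wrmse",
                dist,
                replace(cfg, seed=_structure_seed(cfg.seed, f"{s.key}|boost{i}")),
            )
            for s in enumerate_structures(lib, inc)
        ]
        for m in models:
            m.val_error = None
        best = _rank(models, select_data, "rmse")

        disc = _squared_discrepancies(best, train)
        if disc is None or disc.max() == 0.0:
            losses = np.zeros(n)
            avg_loss = 0.0
        else:
            losses = disc / disc.max()
            avg_loss = float(np.sum(dist * losses))
        if avg_loss >= 0.5:
            if not ensemble:
                warnings.warn("boosting stopped at the first iteration (average loss >= 0.5)", stacklevel=2)
                ensemble.append((best, _loss_to_beta(avg_loss)))
            break
        beta = _loss_to_beta(avg_loss)
        ensemble.append((best, beta))
        logger.info("boosting iteration %d: selected %s (avg loss %.4g, beta %.4g)", i + 1, best.structure.key, avg_loss, beta)
        dist = adaboost_update(dist, losses, beta)
    return Ensemble(ensemble, scheme=scheme, method="boosting")
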