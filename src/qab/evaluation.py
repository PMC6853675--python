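"""Experiment driver and summary statistics for model comparison.

For each bootstrap iteration every model is fitted to the same training draw
and evaluated on the common test set, producing an A x T replicate loss
table per (loss function, active fraction).  Summaries follow the paired
design: mean expected loss, delete-one jackknife standard error of the mean,
a 95% percentile interval over the replicates, and the probability of
optimality — the fraction of iterations on which a model attains the lowest
loss, ties split equally.  Total model scores sum these probabilities over
independent datasets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .datasets import ActivityDataset, FingerprintMatrix, align
from .losses import (
    ActiveSet,
    LossSumVariant,
    RankedPrediction,
    evaluate_losses,
    mse,
    select_actives,
)
from .models import ModelSpec, fit, predict
from .resampling import (
    ResampleDraw,
    SplitSpec,
    kfold_partition,
    quantile_activity_bootstrap,
    standard_bootstrap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateLossTable",
    "ModelScoreSummary",
    "run_experiment",
    "jackknife_se",
    "ci95",
    "probability_optimal",
    "summarize",
    "total_model_score",
]

LOSS_NAMES = ("lmin", "lsum", "mse")
GammaMode = Literal["test_fraction", "dataset_quantile"]
DEFAULT_GAMMA_GRID = (0.1, 0.05, 0.01)  # fractions of the test set labelled active


@dataclass
class ReplicateLossTable:
    """A x T matrix of realized out-of-sample losses.

    Row a holds the losses of every model on bootstrap iteration a — all
    models see the same draw, so rows are paired.  Failed fits are NaN and
    dropped complete-case by the summaries.
    """

    losses: np.ndarray
    model_names: tuple[str, ...]
    loss_name: str
    gamma: float | None = None
    dataset_id: str = ""
    spec: SplitSpec | None = None

    def __post_init__(self) -> None:
        self.losses = np.asarray(self.losses, dtype=float)
        if self.losses.ndim != 2 or self.losses.shape[1] != len(self.model_names):
            raise ValueError("losses must be A x n_models")

    @property
    def n_iterations(self) -> int:
        return self.losses.shape[0]

    def complete_rows(self) -> np.ndarray:
        return self.losses[~np.isnan(self.losses).any(axis=1)]


@dataclass
class ModelScoreSummary:
    """Per-model summary of one replicate loss table."""

    model_names: tuple[str, ...]
    mean_loss: np.ndarray
    jackknife_se: np.ndarray
    ci95: np.ndarray  # n_models x 2
    p_optimal: np.ndarray

    def to_dict(self) -> dict:
        return {
            name: {
                "mean_loss": float(self.mean_loss[t]),
                "jackknife_se": float(self.jackknife_se[t]),
                "ci95": [float(self.ci95[t, 0]), float(self.ci95[t, 1])],
                "p_optimal": float(self.p_optimal[t]),
            }
            for t, name in enumerate(self.model_names)
        }


def jackknife_se(losses: Sequence[float]) -> float:
    """Delete-one jackknife standard error of the mean of the replicates.

    sqrt((A-1)/A * sum_a (m_{-a} - mean of leave-one-out means)^2); for the
    mean statistic this reduces algebraically to s/sqrt(A).
    """
    x = np.asarray(losses, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("jackknife needs at least 2 replicates")
    a = x.size
    loo_means = (x.sum() - x) / (a - 1)
    return float(np.sqrt((a - 1) / a * np.sum((loo_means - loo_means.mean()) ** 2)))


def ci95(losses: Sequence[float]) -> tuple[float, float]:
    """2.5th-97.5th percentile interval of the replicate losses."""
    x = np.asarray(losses, dtype=float)
    if x.size < 20:
        logger.warning("ci95 on only %d replicates; interval is unstable", x.size)
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def probability_optimal(table: ReplicateLossTable) -> np.ndarray:
    """Fraction of paired iterations each model attains the lowest loss.

    Ties at an iteration split the win equally among the tied models;
    iterations with any missing model are excluded.  The vector sums to 1.
    """
    rows = table.complete_rows()
    if rows.shape[0] == 0:
        raise ValueError("no complete iterations")
    mins = rows.min(axis=1, keepdims=True)
    wins = rows == mins
    weights = wins / wins.sum(axis=1, keepdims=True)
    return weights.mean(axis=0)


def summarize(table: ReplicateLossTable) -> ModelScoreSummary:
    rows = table.complete_rows()
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 complete iterations to summarize")
    if rows.shape[0] < table.n_iterations:
        logger.warning(
            "%s: %d/%d iterations incomplete, dropped",
            table.loss_name,
            table.n_iterations - rows.shape[0],
            table.n_iterations,
        )
    return ModelScoreSummary(
        model_names=table.model_names,
        mean_loss=rows.mean(axis=0),
        jackknife_se=np.array([jackknife_se(rows[:, t]) for t in range(rows.shape[1])]),
        ci95=np.array([ci95(rows[:, t]) for t in range(rows.shape[1])]),
        p_optimal=probability_optimal(table),
    )


def total_model_score(per_dataset_p: Sequence[np.ndarray]) -> np.ndarray:
    """Sum per-dataset optimality probabilities (independent datasets)."""
    mats = [np.asarray(p, dtype=float) for p in per_dataset_p]
    if not mats:
        raise ValueError("no datasets")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("model sets differ across datasets")
    return np.sum(mats, axis=0)


def _make_draws(dataset: ActivityDataset, spec: SplitSpec, method: str) -> list[ResampleDraw]:
    if method == "kfold":
        return kfold_partition(dataset, k=5, seed=spec.seed)
    if spec.q >= 1:
        return standard_bootstrap(dataset, spec.n_iterations, spec.seed)
    return quantile_activity_bootstrap(dataset, spec)


def _active_set(
    y_test: np.ndarray,
    gamma: float,
    gamma_mode: GammaMode,
    dataset: ActivityDataset,
    test_idx: np.ndarray,
):
    if gamma_mode == "test_fraction":
        return select_actives(y_test, active_fraction=gamma)
    # dataset-quantile mode: actives are the top floor(N*(1-gamma)) of the
    # whole dataset; with gamma > q they all sit in the test set
    n = len(dataset)
    n_active = math.floor(n * (1 - gamma))
    order = np.argsort(dataset.activities, kind="stable")
    top = set(order[n - n_active :].tolist())
    idx = np.flatnonzero([i in top for i in test_idx])
    if idx.size == 0 or idx.size >= y_test.size:
        raise ValueError(
            f"gamma={gamma} (dataset-quantile mode) names {idx.size} actives "
            f"in a test set of {y_test.size}"
        )
    return ActiveSet(n_active=idx.size, active_indices=idx)


def run_experiment(
    dataset: ActivityDataset,
    fingerprints: FingerprintMatrix,
    models: Sequence[ModelSpec],
    spec: SplitSpec,
    losses: Sequence[str] = LOSS_NAMES,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    gamma_mode: GammaMode = "test_fraction",
    method: str = "auto",
    loss_sum_variant: LossSumVariant = "corrected",
    dataset_id: str = "",
) -> dict[tuple[str, float | None], ReplicateLossTable]:
    """Run the full (models x iterations x losses x gamma) grid.

    Returns one :class:`ReplicateLossTable` per (loss name, gamma) pair,
    keyed ``(loss, gamma)``; mean squared error does not depend on gamma and
    is keyed ``("mse", None)``.  Every model is fitted to the same draw per
    iteration; a model failure on a draw is recorded as NaN (logged) and
    later dropped complete-case.
    """
    unknown = set(losses) - set(LOSS_NAMES)
    if unknown:
        raise ValueError(f"unknown losses {sorted(unknown)}; choose from {LOSS_NAMES}")
    fps = align(dataset, fingerprints)
    X = fps.bits.astype(float)
    y = dataset.activities
    draws = _make_draws(dataset, spec, method)
    rank_losses = [l for l in losses if l != "mse"]

    keys: list[tuple[str, float | None]] = []
    if "mse" in losses:
        keys.append(("mse", None))
    keys.extend((l, g) for l in rank_losses for g in gamma_grid)
    tables = {
        key: np.full((len(draws), len(models)), np.nan) for key in keys
    }

    for a, draw in enumerate(draws):
        X_tr, y_tr = X[draw.train_indices], y[draw.train_indices]
        X_te, y_te = X[draw.test_indices], y[draw.test_indices]
        actives = {
            g: _active_set(y_te, g, gamma_mode, dataset, draw.test_indices)
            for g in gamma_grid
        }
        for t, mspec in enumerate(models):
            try:
                fitted = fit(mspec, X_tr, y_tr)
                pred = predict(fitted, X_te)
            except Exception:
                logger.exception(
                    "%s failed on iteration %d; recorded as missing",
                    mspec.family,
                    a,
                )
                continue
            tie_seed = int(
                np.random.SeedSequence([spec.seed, a, t]).generate_state(1)[0]
                % (2**31)
            )
            rp = RankedPrediction.from_predictions(pred, y_te, tie_seed=tie_seed)
            if "mse" in losses:
                tables[("mse", None)][a, t] = mse(pred, y_te)
            for g in gamma_grid:
                vals = evaluate_losses(rp, actives[g], variant=loss_sum_variant)
                for l in rank_losses:
                    tables[(l, g)][a, t] = vals[l]
        logger.debug("iteration %d/%d done", a + 1, len(draws))

    model_names = tuple(m.family for m in models)
    return {
        (l, g): ReplicateLossTable(
            losses=tables[(l, g)],
            model_names=model_names,
            loss_name=l,
            gamma=g,
            dataset_id=dataset_id,
            spec=spec,
        )
        for (l, g) in keys
    }


def result_record(table: ReplicateLossTable, provenance: dict | None = None) -> dict:
    """JSON-serializable record of one table plus its summary and provenance."""
    summary = summarize(table)
    rec = {
        "dataset_id": table.dataset_id,
        "loss": table.loss_name,
        "gamma": table.gamma,
        "spec": None
        if table.spec is None
        else {
            "q": table.spec.q,
            "gamma": table.spec.gamma,
            "n_iterations": table.spec.n_iterations,
            "seed": table.spec.seed,
        },
        "model_names": list(table.model_names),
        "replicate_losses": [
            [None if np.isnan(v) else float(v) for v in row]
            for row in table.losses
        ],
        "summary": summary.to_dict(),
    }
    if provenance:
        rec["provenance"] = provenance
    return rec


def write_results(
    tables: dict[tuple[str, float | None], ReplicateLossTable],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> list[Path]:
    """One JSON result file per (loss, gamma) table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for (loss, gamma), table in tables.items():
        tag = loss if gamma is None else f"{loss}_gamma{gamma:g}"
        q = table.spec.q if table.spec else "na"
        path = out / f"{table.dataset_id or 'dataset'}_q{q:g}_{tag}.json"
        path.write_text(json.dumps(result_record(table, provenance), indent=1))
        paths.append(path)
    return paths
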