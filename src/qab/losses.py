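"""Out-of-sample losses for ranked activity predictions.

Virtual-screening practice cares about where a model ranks the few truly
potent ("active") test molecules, not about its accuracy on the inactive
bulk.  The two active-rank losses here depend only on the predicted ranks of
the actives:

* ``loss_min`` — normalized rank of the best-ranked active,
  ``min_j Rank(x_j) / (N_test - N_act)``.  0 when an active tops the list,
  1 when all actives are ranked last.
* ``loss_sum`` — normalized sum of all active ranks,
  ``(sum_j Rank(x_j) - N_act (N_act - 1) / 2) / denom``.  With the default
  ``corrected`` denominator ``N_act (N_test - N_act)`` the loss spans [0, 1]
  and coincides with ``loss_min`` when there is a single active.  The
  ``as_printed`` variant uses ``N_act (N_test - N_act - 1)`` instead, whose
  maximum exceeds 1; it is kept only for comparison.

Ranks follow the screening convention: 0 is the molecule with the highest
predicted activity, ``N_test - 1`` the lowest.  Mean squared error is
included as the conventional goodness-of-fit baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RankedPrediction",
    "ActiveSet",
    "assign_ranks",
    "select_actives",
    "loss_min",
    "loss_sum",
    "mse",
    "evaluate_losses",
]

LossSumVariant = Literal["corrected", "as_printed"]


@dataclass(frozen=True)
class RankedPrediction:
    """Predicted and true activities of a test set, with assigned ranks."""

    predicted: np.ndarray
    true_activity: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        pred = np.asarray(self.predicted, dtype=float)
        true = np.asarray(self.true_activity, dtype=float)
        ranks = np.asarray(self.ranks, dtype=int)
        if not (pred.shape == true.shape == ranks.shape) or pred.ndim != 1:
            raise ValueError("predicted, true_activity and ranks must be equal-length vectors")
        n = pred.shape[0]
        if not np.array_equal(np.sort(ranks), np.arange(n)):
            raise ValueError("ranks must be a permutation of 0..n_test-1")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "true_activity", true)
        object.__setattr__(self, "ranks", ranks)

    @classmethod
    def from_predictions(
        cls,
        predicted: np.ndarray,
        true_activity: np.ndarray,
        tie_seed: int = 0,
    ) -> "RankedPrediction":
        return cls(
            predicted=predicted,
            true_activity=true_activity,
            ranks=assign_ranks(predicted, tie_seed=tie_seed),
        )


@dataclass(frozen=True)
class ActiveSet:
    """The test-set molecules counted as active (highest true activity)."""

    n_active: int
    active_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.active_indices, dtype=int)
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")
        if idx.shape != (self.n_active,) or len(set(idx.tolist())) != self.n_active:
            raise ValueError("active_indices must be n_active distinct indices")
        object.__setattr__(self, "active_indices", idx)


def assign_ranks(predicted: np.ndarray, tie_seed: int = 0) -> np.ndarray:
    """Rank predictions descending; 0 = highest predicted activity.

    Ties are broken uniformly at random with ``tie_seed`` so that a
    constant-prediction model earns neither a systematically good nor bad
    rank for any molecule.
    """
    pred = np.asarray(predicted, dtype=float)
    if pred.ndim != 1 or pred.size == 0:
        raise ValueError("predicted must be a non-empty 1-D vector")
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions contain NaN or infinity")
    rng = np.random.default_rng(tie_seed)
    # random secondary key => uniform order within tie groups
    order = np.lexsort((rng.permutation(pred.size), -pred))
    ranks = np.empty(pred.size, dtype=int)
    ranks[order] = np.arange(pred.size)
    return ranks


def select_actives(
    true_activity: np.ndarray,
    active_fraction: float | None = None,
    n_active: int | None = None,
) -> ActiveSet:
    """Pick the top-activity test molecules as the active set.

    Exactly one of ``active_fraction`` (fraction of the test set labelled
    active, count = ceil(fraction * n_test) so at least one molecule is
    named) or an explicit ``n_active`` must be given.  Ties in true activity
    at the threshold are resolved by stable sort order and logged, so the
    set size is exact.
    """
    y = np.asarray(true_activity, dtype=float)
    n_test = y.shape[0]
    if (active_fraction is None) == (n_active is None):
        raise ValueError("give exactly one of active_fraction or n_active")
    if active_fraction is not None:
        if not 0 < active_fraction < 1:
            raise ValueError(f"active_fraction must be in (0,1), got {active_fraction}")
        n_active = math.ceil(active_fraction * n_test)
    assert n_active is not None
    if not 1 <= n_active < n_test:
        raise ValueError(
            f"need 1 <= n_active < n_test, got n_active={n_active}, n_test={n_test}"
        )
    order = np.argsort(y, kind="stable")  # ascending; stable for reproducible ties
    actives = order[-n_active:]
    threshold = y[actives].min()
    if np.sum(y == threshold) > np.sum(y[actives] == threshold):
        logger.warning(
            "activity ties straddle the active threshold %.4g; "
            "active set resolved by sort order",
            threshold,
        )
    return ActiveSet(n_active=n_active, active_indices=np.sort(actives))


def _check_sizes(n_test: int, n_active: int) -> None:
    if n_active < 1:
        raise ValueError("n_active must be >= 1")
    if n_test <= n_active:
        raise ValueError(
            f"test set must be larger than the active set (n_test={n_test}, "
            f"n_active={n_active})"
        )


def loss_min(
    ranks_of_actives: np.ndarray, n_test: int, n_active: int
) -> float:
    """Normalized rank of the best-ranked active molecule, in [0, 1]."""
    _check_sizes(n_test, n_active)
    ranks = np.asarray(ranks_of_actives, dtype=int)
    if ranks.shape != (n_active,):
        raise ValueError("ranks_of_actives must have length n_active")
    return float(ranks.min()) / (n_test - n_active)


def loss_sum(
    ranks_of_actives: np.ndarray,
    n_test: int,
    n_active: int,
    variant: LossSumVariant = "corrected",
) -> float:
    """Normalized sum of all active ranks.

    The minimum possible sum is ``n_active (n_active - 1) / 2`` (actives fill
    the top ranks) and is mapped to 0.  The ``corrected`` denominator
    ``n_active (n_test - n_active)`` maps the maximum sum to exactly 1; the
    ``as_printed`` denominator ``n_active (n_test - n_active - 1)`` is
    slightly smaller, so its maximum is ``(n_test - n_active)/(n_test -
    n_active - 1) > 1``.
    """
    _check_sizes(n_test, n_active)
    ranks = np.asarray(ranks_of_actives, dtype=int)
    if ranks.shape != (n_active,):
        raise ValueError("ranks_of_actives must have length n_active")
    if variant == "corrected":
        denom = n_active * (n_test - n_active)
    elif variant == "as_printed":
        denom = n_active * (n_test - n_active - 1)
    else:
        raise ValueError(f"unknown loss_sum variant {variant!r}")
    if denom <= 0:
        raise ValueError(
            f"degenerate denominator {denom} for n_test={n_test}, n_active={n_active}"
        )
    return (float(ranks.sum()) - n_active * (n_active - 1) / 2) / denom


def mse(predicted: np.ndarray, true: np.ndarray) -> float:
    """Mean squared prediction error."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and true must be equal-length non-empty vectors")
    return float(np.mean((p - t) ** 2))


def evaluate_losses(
    prediction: RankedPrediction,
    actives: ActiveSet,
    variant: LossSumVariant = "corrected",
) -> dict[str, float]:
    """All three losses of one prediction on one test set."""
    n_test = prediction.ranks.shape[0]
    active_ranks = prediction.ranks[actives.active_indices]
    return {
        "lmin": loss_min(active_ranks, n_test, actives.n_active),
        "lsum": loss_sum(active_ranks, n_test, actives.n_active, variant),
        "mse": mse(prediction.predicted, prediction.true_activity),
    }
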