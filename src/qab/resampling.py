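"""Train/test set construction: quantile-activity bootstrap, out-of-bag
bootstrap and K-fold cross-validation.

The quantile-activity bootstrap simulates extrapolation into unexplored
potency space: with molecules sorted ascending by activity and a fraction
``q``, every bootstrap training sample is drawn (with replacement, size
``N_q = floor(N*q)``) from the bottom-``q`` activity quantile, while the
test set is the fixed complement — all molecules more potent than the
training threshold.  Contrast with the standard bootstrap, where training
samples are drawn from the whole dataset and testing uses the out-of-bag
molecules.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from sklearn.model_selection import KFold

from .datasets import ActivityDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "ResampleDraw",
    "quantile_activity_bootstrap",
    "standard_bootstrap",
    "kfold_partition",
    "save_draws",
    "load_draws",
]

DEFAULT_ITERATIONS = 400


@dataclass(frozen=True)
class SplitSpec:
    """The (q, gamma, A, seed) definition of one validation experiment.

    ``q`` is the activity quantile bounding the training pool (1.0 means the
    standard bootstrap), ``gamma`` the activity quantile above which test
    molecules count as active (must exceed ``q`` when ``q < 1``),
    ``n_iterations`` the number of bootstrap replicates A.
    """

    q: float = 1.0
    gamma: float = 0.9
    n_iterations: int = DEFAULT_ITERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if not 0 < self.gamma < 1:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.q < 1 and self.gamma <= self.q:
            raise ValueError(
                f"gamma ({self.gamma}) must exceed q ({self.q}); otherwise the "
                "'actives' would overlap the training quantile"
            )
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class ResampleDraw:
    """One realized train/test draw.

    ``train_indices`` may repeat (bootstrap multiset); ``test_indices`` is an
    ordered set, disjoint from the training indices as sets.
    """

    train_indices: np.ndarray
    test_indices: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        if te.size == 0:
            raise ValueError("test set is empty")
        if len(set(te.tolist())) != te.size:
            raise ValueError("test_indices must be distinct")
        if set(tr.tolist()) & set(te.tolist()):
            raise ValueError("train and test sets overlap")
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)


def _iteration_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One independent, individually reproducible RNG stream per iteration."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def quantile_activity_bootstrap(
    dataset: ActivityDataset, spec: SplitSpec
) -> list[ResampleDraw]:
    """A bootstrap draws training on the bottom-q activity quantile.

    The dataset is stably sorted ascending by activity; the first
    ``N_q = floor(N*q)`` sorted positions form the training pool and the
    remaining ``N - N_q`` positions the test set, which is identical across
    all iterations.  Molecules tied exactly at the boundary activity are
    assigned by sorted index (warned), keeping set sizes exact.  Returned
    indices refer to the dataset's original row order.
    """
    n = len(dataset)
    if spec.q >= 1:
        raise ValueError("q=1 is the standard bootstrap; use standard_bootstrap")
    n_q = math.floor(n * spec.q)
    if n_q < 2 or n - n_q < 2:
        raise ValueError(
            f"degenerate split: N={n}, q={spec.q} gives {n_q} training and "
            f"{n - n_q} testing molecules (need >= 2 each)"
        )
    order = np.argsort(dataset.activities, kind="stable")
    sorted_act = dataset.activities[order]
    if sorted_act[n_q - 1] == sorted_act[n_q]:
        logger.warning(
            "activities tied at the q=%g boundary (value %.4g); molecules "
            "assigned to train/test by sorted index",
            spec.q,
            float(sorted_act[n_q - 1]),
        )
    train_pool = order[:n_q]
    test_idx = order[n_q:]
    draws = []
    for a, rng in enumerate(_iteration_rngs(spec.seed, spec.n_iterations)):
        picks = rng.integers(0, n_q, size=n_q)
        draws.append(
            ResampleDraw(
                train_indices=train_pool[picks],
                test_indices=test_idx,
                iteration=a,
            )
        )
    return draws


def standard_bootstrap(
    dataset: ActivityDataset, n_iterations: int = DEFAULT_ITERATIONS, seed: int = 0
) -> list[ResampleDraw]:
    """Classic bootstrap: train on N draws with replacement, test out-of-bag.

    Draws whose out-of-bag set is empty are rejected and redrawn (logged);
    for N >= 5 this is vanishingly rare (probability N!/N^N).
    """
    n = len(dataset)
    if n < 5:
        raise ValueError(f"standard bootstrap needs N >= 5, got {n}")
    draws = []
    for a, rng in enumerate(_iteration_rngs(seed, n_iterations)):
        while True:
            picks = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), picks)
            if oob.size:
                break
            logger.info("iteration %d: empty out-of-bag set, redrawing", a)
        draws.append(
            ResampleDraw(train_indices=picks, test_indices=oob, iteration=a)
        )
    return draws


def kfold_partition(
    dataset: ActivityDataset, k: int = 5, seed: int = 0
) -> list[ResampleDraw]:
    """Random K-fold partition; draw i trains on the other k-1 folds."""
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} molecules")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        ResampleDraw(train_indices=tr, test_indices=te, iteration=i)
        for i, (tr, te) in enumerate(kf.split(np.arange(n)))
    ]


def save_draws(draws: Iterable[ResampleDraw], path: str | Path) -> None:
    """Serialize draws to JSON-lines for exact reruns."""
    with open(path, "w") as fh:
        for d in draws:
            fh.write(
                json.dumps(
                    {
                        "iteration": d.iteration,
                        "train": d.train_indices.tolist(),
                        "test": d.test_indices.tolist(),
                    }
                )
                + "\n"
            )


def load_draws(path: str | Path) -> list[ResampleDraw]:
    draws = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            draws.append(
                ResampleDraw(
                    train_indices=np.array(rec["train"], dtype=int),
                    test_indices=np.array(rec["test"], dtype=int),
                    iteration=int(rec["iteration"]),
                )
            )
    return draws
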