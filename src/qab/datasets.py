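"""Core in-memory containers shared by every stage of the pipeline.

An :class:`ActivityDataset` holds the molecules and their pIC50 activities —
the universe a train/test split is drawn from.  A :class:`FingerprintMatrix`
is the paired N x P binary design matrix.  Both are thin, validated wrappers
around numpy arrays; all heavy lifting lives in the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ActivityDataset", "FingerprintMatrix", "align"]


@dataclass(frozen=True)
class ActivityDataset:
    """N molecules with pIC50 activities and optional SMILES.

    Parameters
    ----------
    molecule_ids
        Unique molecule identifiers, one per row.
    activities
        pIC50 values (higher = more potent), finite, length N.
    smiles
        Optional SMILES strings aligned with ``molecule_ids``.
    """

    molecule_ids: tuple[str, ...]
    activities: np.ndarray
    smiles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(m) for m in self.molecule_ids)
        object.__setattr__(self, "molecule_ids", ids)
        act = np.asarray(self.activities, dtype=float)
        object.__setattr__(self, "activities", act)
        if act.ndim != 1:
            raise ValueError("activities must be a 1-D vector")
        if len(ids) != act.shape[0]:
            raise ValueError(
                f"{len(ids)} molecule_ids but {act.shape[0]} activities"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if ids.count(m) > 1})
            raise ValueError(f"duplicate molecule_ids: {dupes[:5]}")
        if not np.all(np.isfinite(act)):
            raise ValueError("activities must be finite")
        if any(not m for m in ids):
            raise ValueError("empty molecule_id")
        if self.smiles is not None:
            smi = tuple(self.smiles)
            object.__setattr__(self, "smiles", smi)
            if len(smi) != len(ids):
                raise ValueError("smiles length must match molecule_ids")

    def __len__(self) -> int:
        return len(self.molecule_ids)

    @property
    def is_sorted(self) -> bool:
        """True when index order equals ascending activity order."""
        return bool(np.all(np.diff(self.activities) >= 0))

    def sorted_by_activity(self) -> tuple["ActivityDataset", np.ndarray]:
        """Return a copy sorted ascending by activity and the sort order.

        The sort is stable (ties keep original index order) so repeated runs
        are reproducible.  The returned ``order`` maps sorted positions back
        to original row indices.
        """
        order = np.argsort(self.activities, kind="stable")
        ds = ActivityDataset(
            molecule_ids=tuple(self.molecule_ids[i] for i in order),
            activities=self.activities[order],
            smiles=None
            if self.smiles is None
            else tuple(self.smiles[i] for i in order),
        )
        return ds, order

    def to_frame(self) -> pd.DataFrame:
        data = {"molecule_id": list(self.molecule_ids), "pic50": self.activities}
        if self.smiles is not None:
            data["smiles"] = list(self.smiles)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class FingerprintMatrix:
    """N x P binary fingerprint matrix with row-aligned molecule ids."""

    bits: np.ndarray
    molecule_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        bad = ~np.isin(bits, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary fingerprint entry {bits[r, c]!r} at row {r}, column {c}"
            )
        object.__setattr__(self, "bits", bits.astype(np.uint8))
        ids = tuple(str(m) for m in self.molecule_ids)
        if not ids:
            ids = tuple(f"mol_{i}" for i in range(bits.shape[0]))
        if len(ids) != bits.shape[0]:
            raise ValueError(
                f"{len(ids)} molecule_ids but {bits.shape[0]} fingerprint rows"
            )
        object.__setattr__(self, "molecule_ids", ids)

    @property
    def n_molecules(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def __len__(self) -> int:
        return self.n_molecules

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.bits, columns=[f"fp_{j}" for j in range(self.n_bits)]
        )
        df.insert(0, "molecule_id", list(self.molecule_ids))
        return df


def align(
    dataset: ActivityDataset, fingerprints: FingerprintMatrix
) -> FingerprintMatrix:
    """Reorder fingerprint rows to match the dataset's molecule order.

    Raises ``ValueError`` listing the offending ids when the two sides do not
    cover the same molecules.
    """
    pos = {m: i for i, m in enumerate(fingerprints.molecule_ids)}
    missing = [m for m in dataset.molecule_ids if m not in pos]
    extra = [m for m in fingerprints.molecule_ids if m not in set(dataset.molecule_ids)]
    if missing or extra:
        raise ValueError(
            "fingerprint/activity id mismatch: "
            f"missing fingerprints for {missing[:5]}, "
            f"unmatched fingerprint rows {extra[:5]}"
        )
    order = [pos[m] for m in dataset.molecule_ids]
    return FingerprintMatrix(
        bits=fingerprints.bits[order], molecule_ids=dataset.molecule_ids
    )
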