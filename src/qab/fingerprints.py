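"""Structure standardization and 128-bit radius-2 Morgan fingerprints.

The statistical core never imports this module: precomputed fingerprint
matrices can be loaded from CSV with :func:`load_fingerprint_matrix`, so the
resampling/loss machinery runs with no cheminformatics dependency.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .datasets import ActivityDataset, FingerprintMatrix

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings go through our logger

__all__ = [
    "standardize_structure",
    "morgan_fingerprint",
    "fingerprint_dataset",
    "load_fingerprint_matrix",
    "save_fingerprint_matrix",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 128


def standardize_structure(smiles: str) -> str | None:
    """Canonicalize a SMILES, keeping the largest organic fragment.

    Counterions and solvents are stripped by retaining the fragment with the
    most heavy atoms among fragments that contain at least one carbon
    ("organic").  Returns ``None`` (a rejection) for unparseable input or
    molecules with no organic fragment; callers drop such records and log.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        logger.debug("standardize: unparseable SMILES %r", smiles)
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [
        f
        for f in frags
        if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    ]
    if not organic:
        logger.debug("standardize: no organic fragment in %r", smiles)
        return None
    largest = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    return Chem.MolToSmiles(largest)


def morgan_fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> np.ndarray | None:
    """Hashed binary circular fingerprint of a standardized SMILES.

    Deterministic: the same SMILES always maps to the same length-``n_bits``
    0/1 vector.  Returns ``None`` for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def fingerprint_dataset(
    dataset: ActivityDataset,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[FingerprintMatrix, ActivityDataset]:
    """Standardize and fingerprint every molecule of a curated dataset.

    Molecules that fail standardization or fingerprinting are dropped with a
    logged reason; the returned dataset is the surviving subset, row-aligned
    with the returned fingerprint matrix.
    """
    if dataset.smiles is None:
        raise ValueError("dataset has no SMILES to fingerprint")
    rows, ids, acts, smis = [], [], [], []
    n_dropped = 0
    for mid, act, smi in zip(
        dataset.molecule_ids, dataset.activities, dataset.smiles
    ):
        std = standardize_structure(smi)
        fp = morgan_fingerprint(std, radius, n_bits) if std is not None else None
        if fp is None:
            n_dropped += 1
            logger.info("dropping %s: standardization/fingerprint failed", mid)
            continue
        rows.append(fp)
        ids.append(mid)
        acts.append(act)
        smis.append(std)
    if n_dropped:
        logger.warning("fingerprinting dropped %d molecules", n_dropped)
    if not rows:
        raise ValueError("no molecule survived standardization")
    fps = FingerprintMatrix(bits=np.vstack(rows), molecule_ids=tuple(ids))
    ds = ActivityDataset(
        molecule_ids=tuple(ids), activities=np.array(acts), smiles=tuple(smis)
    )
    return fps, ds


def save_fingerprint_matrix(fps: FingerprintMatrix, path: str | Path) -> None:
    """Write the fingerprint CSV (molecule_id + fp_0..fp_{P-1} columns)."""
    fps.to_frame().to_csv(path, index=False)


def load_fingerprint_matrix(path: str | Path) -> FingerprintMatrix:
    """Load and validate a precomputed fingerprint CSV.

    The table must have a ``molecule_id`` column and P bit columns; any
    entry outside {0, 1} raises with the offending row and column named.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "molecule_id" not in cols:
        raise ValueError(f"{path}: missing molecule_id column")
    idcol = cols["molecule_id"]
    bitcols = [c for c in df.columns if c != idcol]
    if not bitcols:
        raise ValueError(f"{path}: no fingerprint bit columns")
    values = df[bitcols].to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary entry {values[r, c]!r} at row {r}, "
            f"column {bitcols[c]!r}"
        )
    return FingerprintMatrix(
        bits=values.astype(np.uint8), molecule_ids=tuple(df[idcol].astype(str))
    )
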