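"""ChEMBL-style curation of IC50 activity tables.

Reads a molecule-activity export, keeps only high-quality IC50 measurements
(nM units, exact '=' relation, single human protein targets), converts to
pIC50 on the molar scale, and averages replicate measurements per molecule
on the log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ActivityDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RawActivityRecord",
    "FilterLog",
    "filter_records",
    "to_pic50",
    "collapse_replicates",
    "read_activity_csv",
    "write_curated_csv",
    "curate",
]

# log10 of one unit expressed in molar
_UNIT_EXPONENT = {
    "m": 0.0,
    "mm": -3.0,
    "um": -6.0,
    "µm": -6.0,
    "μm": -6.0,
    "nm": -9.0,
    "pm": -12.0,
}

REQUIRED_UNIT = "nm"
REQUIRED_RELATION = "="
REQUIRED_TARGET_TYPE = "single protein"
REQUIRED_ORGANISM = "homo sapiens"


@dataclass(frozen=True)
class RawActivityRecord:
    """One measured IC50 value as exported from an activity database."""

    molecule_id: str
    smiles: str
    value: float
    unit: str
    relation: str
    target_type: str
    organism: str


@dataclass
class FilterLog:
    """Counts of records removed per criterion during filtering."""

    n_input: int = 0
    missing_value_or_unit: int = 0
    bad_unit: int = 0
    bad_relation: int = 0
    bad_target_type: int = 0
    bad_organism: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - (
            self.missing_value_or_unit
            + self.bad_unit
            + self.bad_relation
            + self.bad_target_type
            + self.bad_organism
        )


def _norm(s: object) -> str:
    return str(s).strip().lower() if s is not None else ""


def _is_missing(x: object) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return _norm(x) in ("", "nan", "none")


def filter_records(
    records: list[RawActivityRecord],
) -> tuple[list[RawActivityRecord], FilterLog]:
    """Keep only records passing the four curation criteria.

    A record survives when its unit is nM, its relation is '=', its target
    type is SINGLE PROTEIN and its organism is Homo sapiens (all matched
    case-insensitively after trimming).  Records with a missing or
    non-positive value, or a missing unit, are dropped first.  Input order
    is preserved; counts removed per criterion are returned and logged.
    """
    log = FilterLog(n_input=len(records))
    kept: list[RawActivityRecord] = []
    for rec in records:
        if (
            _is_missing(rec.value)
            or _is_missing(rec.unit)
            or not (isinstance(rec.value, (int, float)) and rec.value > 0)
        ):
            log.missing_value_or_unit += 1
        elif _norm(rec.unit) != REQUIRED_UNIT:
            log.bad_unit += 1
        elif _norm(rec.relation) != REQUIRED_RELATION:
            log.bad_relation += 1
        elif _norm(rec.target_type) != REQUIRED_TARGET_TYPE:
            log.bad_target_type += 1
        elif _norm(rec.organism) != REQUIRED_ORGANISM:
            log.bad_organism += 1
        else:
            kept.append(rec)
    logger.info(
        "curation filter: %d/%d records kept (missing=%d, unit=%d, relation=%d, "
        "target_type=%d, organism=%d)",
        log.n_kept,
        log.n_input,
        log.missing_value_or_unit,
        log.bad_unit,
        log.bad_relation,
        log.bad_target_type,
        log.bad_organism,
    )
    if records and not kept:
        logger.warning("curation filter removed every record")
    return kept, log


def to_pic50(value: float, unit: str = "nM") -> float:
    """Convert an IC50 concentration to pIC50 = -log10(IC50 in molar).

    For nM input this is 9 - log10(value); e.g. 100 nM -> 7.0.  Strictly
    decreasing in ``value``.
    """
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"IC50 value must be a finite number, got {value!r}")
    if value <= 0:
        raise ValueError(f"IC50 must be positive to take a log, got {value!r}")
    key = _norm(unit)
    if key not in _UNIT_EXPONENT:
        raise ValueError(
            f"unknown concentration unit {unit!r}; "
            f"known units: {sorted(set(_UNIT_EXPONENT))}"
        )
    return -(math.log10(value) + _UNIT_EXPONENT[key])


def collapse_replicates(records: list[RawActivityRecord]) -> ActivityDataset:
    """Average replicate measurements per molecule on the pIC50 scale.

    One entry per distinct ``molecule_id``, in order of first appearance;
    the activity is the arithmetic mean of the per-record pIC50 values.
    The first non-missing SMILES seen for a molecule is retained.
    """
    pic50s: dict[str, list[float]] = {}
    smiles: dict[str, str] = {}
    order: list[str] = []
    for rec in records:
        mid = str(rec.molecule_id)
        if mid not in pic50s:
            pic50s[mid] = []
            order.append(mid)
        pic50s[mid].append(to_pic50(rec.value, rec.unit))
        if mid not in smiles and not _is_missing(rec.smiles):
            smiles[mid] = str(rec.smiles).strip()
    return ActivityDataset(
        molecule_ids=tuple(order),
        activities=np.array([float(np.mean(pic50s[m])) for m in order]),
        smiles=tuple(smiles.get(m, "") for m in order) if smiles else None,
    )


_COLUMN_ALIASES = {
    "molecule_id": ("molecule_id", "molecule_chembl_id", "compound_id"),
    "smiles": ("smiles", "canonical_smiles"),
    "value": ("standard_value", "value"),
    "unit": ("standard_units", "standard_unit", "units", "unit"),
    "relation": ("standard_relation", "relation"),
    "target_type": ("target_type",),
    "organism": ("organism", "target_organism"),
}


def _pick(df: pd.DataFrame, field: str) -> str | None:
    cols = {c.lower(): c for c in df.columns}
    for alias in _COLUMN_ALIASES[field]:
        if alias in cols:
            return cols[alias]
    return None


def read_activity_csv(path: str | Path) -> list[RawActivityRecord] | ActivityDataset:
    """Read an activity CSV in either raw or pre-curated form.

    A table with a ``pic50`` column is treated as already curated and
    returned directly as an :class:`ActivityDataset` (filtering bypassed).
    Otherwise the raw export columns are mapped (``canonical_smiles`` doubles
    as the molecule id when no id column is present) and a record list is
    returned for :func:`filter_records`.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "pic50" in cols:
        idcol = _pick(df, "molecule_id") or _pick(df, "smiles")
        if idcol is None:
            raise ValueError(f"{path}: pre-curated CSV needs a molecule_id column")
        smcol = _pick(df, "smiles")
        return ActivityDataset(
            molecule_ids=tuple(df[idcol].astype(str)),
            activities=df[cols["pic50"]].to_numpy(dtype=float),
            smiles=tuple(df[smcol].astype(str)) if smcol else None,
        )

    idcol = _pick(df, "molecule_id") or _pick(df, "smiles")
    valcol = _pick(df, "value")
    if idcol is None or valcol is None:
        raise ValueError(
            f"{path}: need molecule_id (or canonical_smiles) and standard_value columns; "
            f"found {list(df.columns)}"
        )

    def get(row: pd.Series, field: str, default: str = "") -> str:
        col = _pick(df, field)
        return row[col] if col is not None else default

    records = []
    for _, row in df.iterrows():
        try:
            value = float(row[valcol])
        except (TypeError, ValueError):
            value = float("nan")
        records.append(
            RawActivityRecord(
                molecule_id=str(row[idcol]),
                smiles=str(get(row, "smiles", "")),
                value=value,
                unit=str(get(row, "unit", "")),
                relation=str(get(row, "relation", "")),
                target_type=str(get(row, "target_type", "")),
                organism=str(get(row, "organism", "")),
            )
        )
    return records


def write_curated_csv(dataset: ActivityDataset, path: str | Path) -> None:
    """Write the curated (molecule_id, smiles, pic50) CSV the pipeline consumes."""
    df = dataset.to_frame()
    cols = ["molecule_id"] + (["smiles"] if "smiles" in df else []) + ["pic50"]
    df[cols].to_csv(path, index=False)


def curate(path: str | Path) -> tuple[ActivityDataset, FilterLog]:
    """Full curation pipeline: read, filter, convert, collapse replicates."""
    loaded = read_activity_csv(path)
    if isinstance(loaded, ActivityDataset):
        return loaded, FilterLog(n_input=len(loaded))
    kept, log = filter_records(loaded)
    return collapse_replicates(kept), log
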