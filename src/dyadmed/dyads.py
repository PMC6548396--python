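"""Construction of distinguishable dyads and the wide analysis table.

A dyad pairs one heart-failure patient with one nearest relative; the two
members are distinguishable by the role label (the diagnosis defines the
patient role).  The analysis table is wide -- one row per dyad with six score
columns in the fixed order ``(x1, x2, m1, m2, y1, y2)`` where x is perceived
social support, m family health, y family functioning, subscript 1 the
patient and 2 the nearest relative.

Pairing is strictly complete-case: a dyad lacking either role, carrying a
duplicate or extra member, or containing any missing score is wholly excluded
and the exclusion logged with a single reason code.  No imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

ROLES = ("patient", "nearest_relative")
WIDE_COLUMNS = ("x1", "x2", "m1", "m2", "y1", "y2")
SCORE_COLUMNS = ("social_support", "family_health", "family_functioning")

#: exclusion reason codes
REASON_MISSING_MEMBER = "missing_member"
REASON_DUPLICATE_ROLE = "duplicate_role"
REASON_CARDINALITY = "cardinality"
REASON_MISSING_SCORE = "missing_score"
REASON_OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class DyadRecord:
    dyad_id: str
    x1: float  # patient social support
    m1: float  # patient family health
    y1: float  # patient family functioning
    x2: float  # relative social support
    m2: float
    y2: float


@dataclass
class DyadDataset:
    records: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)  # (dyad_id, reason)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def write_exclusion_log(self, path) -> None:
        """Exclusions as JSON lines: {"dyad_id": ..., "reason": ...}."""
        with open(path, "w") as fh:
            for dyad_id, reason in self.exclusions:
                fh.write(json.dumps({"dyad_id": dyad_id, "reason": reason}) + "\n")


def build_dyads(
    individuals: pd.DataFrame,
    score_columns: Sequence[str] = SCORE_COLUMNS,
    check_ranges: dict | None = None,
) -> DyadDataset:
    """Pair scored individual rows into a dyad dataset.

    ``individuals`` must carry ``dyad_id`` and ``role`` columns plus the three
    score columns (support, health, functioning order).  ``check_ranges``
    optionally maps score column -> (lo, hi); out-of-range dyads are excluded.

    Exclusion reasons: ``missing_member``, ``duplicate_role``, ``cardinality``
    (more than two members), ``missing_score``, ``out_of_range``.  The result
    is sorted by dyad id, so row order of the input is irrelevant.
    """
    ds = DyadDataset()
    if len(individuals) == 0:
        return ds

    bad_roles = set(individuals["role"]) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"unknown role value(s): {sorted(bad_roles)}; expected {ROLES}")

    for dyad_id, grp in sorted(individuals.groupby("dyad_id"), key=lambda kv: str(kv[0])):
        dyad_id = str(dyad_id)
        if len(grp) > 2:
            ds.exclusions.append((dyad_id, REASON_CARDINALITY))
            continue
        roles = list(grp["role"])
        if sorted(set(roles)) != sorted(ROLES):
            reason = REASON_DUPLICATE_ROLE if len(roles) == 2 else REASON_MISSING_MEMBER
            ds.exclusions.append((dyad_id, reason))
            continue
        patient = grp[grp["role"] == "patient"].iloc[0]
        relative = grp[grp["role"] == "nearest_relative"].iloc[0]
        vals = [patient[c] for c in score_columns] + [relative[c] for c in score_columns]
        if any(pd.isna(v) for v in vals):
            ds.exclusions.append((dyad_id, REASON_MISSING_SCORE))
            continue
        if check_ranges:
            out = False
            for person in (patient, relative):
                for c in score_columns:
                    lo, hi = check_ranges.get(c, (-np.inf, np.inf))
                    if not lo <= person[c] <= hi:
                        out = True
            if out:
                ds.exclusions.append((dyad_id, REASON_OUT_OF_RANGE))
                continue
        sx, sm, sy = score_columns
        ds.records.append(
            DyadRecord(
                dyad_id=dyad_id,
                x1=float(patient[sx]), m1=float(patient[sm]), y1=float(patient[sy]),
                x2=float(relative[sx]), m2=float(relative[sm]), y2=float(relative[sy]),
            )
        )
    return ds


def to_wide(dataset: DyadDataset) -> tuple[np.ndarray, list]:
    """Dyad dataset -> (n, 6) array in WIDE_COLUMNS order plus dyad-id index."""
    arr = np.array(
        [[r.x1, r.x2, r.m1, r.m2, r.y1, r.y2] for r in dataset.records],
        dtype=float,
    ).reshape(len(dataset), 6)
    return arr, [r.dyad_id for r in dataset.records]


def from_wide(wide: np.ndarray, dyad_ids: Sequence[str] | None = None) -> DyadDataset:
    """Inverse of :func:`to_wide`."""
    wide = np.asarray(wide, dtype=float)
    if wide.ndim != 2 or wide.shape[1] != 6:
        raise SchemaError(f"wide matrix must be (n, 6), got {wide.shape}")
    ids = list(dyad_ids) if dyad_ids is not None else [f"d{i+1:05d}" for i in range(len(wide))]
    ds = DyadDataset()
    for did, (x1, x2, m1, m2, y1, y2) in zip(ids, wide):
        ds.records.append(DyadRecord(str(did), x1, m1, y1, x2, m2, y2))
    return ds


def wide_frame(dataset: DyadDataset) -> pd.DataFrame:
    arr, ids = to_wide(dataset)
    df = pd.DataFrame(arr, columns=list(WIDE_COLUMNS))
    df.insert(0, "dyad_id", ids)
    return df


def read_wide(path, column_map: dict | None = None) -> DyadDataset:
    """Read a dyad-level wide CSV (columns x1,x2,m1,m2,y1,y2 [+ dyad_id])."""
    df = pd.read_csv(path)
    cmap = dict(column_map or {})
    cols = [cmap.get(c, c) for c in WIDE_COLUMNS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"wide CSV missing columns: {missing}")
    idc = cmap.get("dyad_id", "dyad_id")
    ids = df[idc].astype(str).tolist() if idc in df.columns else None
    return from_wide(df[cols].to_numpy(dtype=float), ids)
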