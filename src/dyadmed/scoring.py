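"""Scoring of the FAFHES questionnaire.

The Family Functioning, Health and Social Support (FAFHES) instrument has 62
six-point Likert items (1 = strongly disagree ... 6 = strongly agree) grouped
into three scales -- family functioning (19 items, 4 subscales), family health
(23 items, 5 subscales) and social support (20 items, 3 subscales).  Scale and
subscale scores are raw sums, so the attainable ranges are 19-114, 23-138 and
20-120 respectively, and higher scores mean better functioning.

The instrument's published description does not fix an item order, so this
module adopts a positional convention: items 1-19 are family functioning,
items 20-42 family health, items 43-62 social support, each scale's subscales
laid out consecutively in the order listed in :data:`SUBSCALE_LAYOUT`.  A
column map can override the CSV column naming but not the positional
scale layout.

The five "ill-being" items (feelings of discomfort and bad feelings) are
negatively keyed with respect to "higher is better"; by default they are
reverse-coded (v -> 7 - v) before summation.  Pass ``reverse_illbeing=False``
to score them verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingItemError, RangeError, SchemaError

N_ITEMS = 62
LIKERT_MIN, LIKERT_MAX = 1, 6

#: scale -> ordered (subscale, n_items); positional layout over items 1..62
SUBSCALE_LAYOUT: dict[str, tuple[tuple[str, int], ...]] = {
    "family_functioning": (
        ("family_relationships", 7),
        ("relationships_outside_family", 5),
        ("structural_factors", 4),
        ("family_strengths", 3),
    ),
    "family_health": (
        ("values", 6),
        ("well_being", 4),
        ("knowledge", 5),
        ("ill_being", 5),
        ("activities", 3),
    ),
    "social_support": (
        ("affect", 8),
        ("affirmation", 7),
        ("concrete_aid", 5),
    ),
}

SCALE_ORDER = ("family_functioning", "family_health", "social_support")

SCALE_RANGES: dict[str, tuple[int, int]] = {
    scale: (
        sum(n for _, n in subs) * LIKERT_MIN,
        sum(n for _, n in subs) * LIKERT_MAX,
    )
    for scale, subs in SUBSCALE_LAYOUT.items()
}


def _subscale_slices() -> dict[str, slice]:
    """0-based item slices per subscale under the positional convention."""
    slices: dict[str, slice] = {}
    start = 0
    for scale in SCALE_ORDER:
        for name, count in SUBSCALE_LAYOUT[scale]:
            slices[name] = slice(start, start + count)
            start += count
    assert start == N_ITEMS
    return slices


SUBSCALE_SLICES = _subscale_slices()
#: 0-based indices of the reverse-keyed ill-being items (items 35-39, 1-based)
ILL_BEING_INDICES = tuple(range(SUBSCALE_SLICES["ill_being"].start,
                                SUBSCALE_SLICES["ill_being"].stop))


@dataclass(frozen=True)
class FafhesResponse:
    """One respondent's 62 item responses plus identifiers."""

    respondent_id: str
    items: tuple
    dyad_id: str | None = None
    role: str | None = None

    def validate(self) -> None:
        """Raise if the response violates the instrument invariants."""
        if len(self.items) != N_ITEMS:
            raise SchemaError(
                f"respondent {self.respondent_id}: expected {N_ITEMS} items, "
                f"got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingItemError(
                    f"respondent {self.respondent_id}: item_{i:02d} is missing"
                )
            if not float(v).is_integer() or not LIKERT_MIN <= int(v) <= LIKERT_MAX:
                raise RangeError(
                    f"respondent {self.respondent_id}: item_{i:02d}={v!r} "
                    f"outside Likert range [{LIKERT_MIN}, {LIKERT_MAX}]"
                )


@dataclass(frozen=True)
class ScaleScores:
    respondent_id: str
    social_support: int
    family_health: int
    family_functioning: int
    subscale_scores: Mapping[str, int]
    dyad_id: str | None = None
    role: str | None = None


def score_fafhes(response: FafhesResponse, reverse_illbeing: bool = True) -> ScaleScores:
    """Sum a validated response into scale and subscale scores.

    With ``reverse_illbeing`` the five ill-being items are transformed to
    ``7 - value`` before summation so that every scale runs in the
    "higher is better" direction.
    """
    response.validate()
    items = [int(v) for v in response.items]
    if reverse_illbeing:
        for i in ILL_BEING_INDICES:
            items[i] = (LIKERT_MIN + LIKERT_MAX + 1) - items[i] - 1  # 7 - v
    sub = {name: sum(items[sl]) for name, sl in SUBSCALE_SLICES.items()}
    scale = {
        s: sum(sub[name] for name, _ in SUBSCALE_LAYOUT[s]) for s in SCALE_ORDER
    }
    return ScaleScores(
        respondent_id=response.respondent_id,
        social_support=scale["social_support"],
        family_health=scale["family_health"],
        family_functioning=scale["family_functioning"],
        subscale_scores=sub,
        dyad_id=response.dyad_id,
        role=response.role,
    )


@dataclass
class ValidationReport:
    """Report-only batch validation outcome."""

    issues: list = field(default_factory=list)  # (respondent_id, message)
    valid: list = field(default_factory=list)   # FafhesResponse passing all checks

    @property
    def n_flagged(self) -> int:
        return len({rid for rid, _ in self.issues})


def validate_batch(responses: Iterable[FafhesResponse]) -> ValidationReport:
    """Check every response, flagging failures instead of raising."""
    report = ValidationReport()
    for resp in responses:
        try:
            resp.validate()
        except (SchemaError, RangeError, MissingItemError) as exc:
            report.issues.append((resp.respondent_id, str(exc)))
        else:
            report.valid.append(resp)
    return report


# ---------------------------------------------------------------------------
# CSV interface

DEFAULT_ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))
DEFAULT_ID_COLUMNS = {"respondent_id": "respondent_id",
                      "dyad_id": "dyad_id", "role": "role"}


def read_responses(path, column_map: Mapping[str, str] | None = None) -> list[FafhesResponse]:
    """Read one-row-per-respondent CSV into responses.

    ``column_map`` optionally remaps the default column names
    (``item_01``..``item_62``, ``respondent_id``, ``dyad_id``, ``role``) to
    the names actually present in the file.
    """
    df = pd.read_csv(path)
    cmap = dict(column_map or {})
    def col(name: str) -> str:
        return cmap.get(name, name)

    missing = [col(c) for c in DEFAULT_ITEM_COLUMNS if col(c) not in df.columns]
    if missing:
        raise SchemaError(f"missing item columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    out = []
    for _, row in df.iterrows():
        items = tuple(
            None if pd.isna(row[col(c)]) else row[col(c)]
            for c in DEFAULT_ITEM_COLUMNS
        )
        out.append(
            FafhesResponse(
                respondent_id=str(row[col("respondent_id")]),
                items=items,
                dyad_id=str(row[col("dyad_id")]) if col("dyad_id") in df.columns else None,
                role=str(row[col("role")]) if col("role") in df.columns else None,
            )
        )
    return out


def scores_frame(scores: Sequence[ScaleScores], include_subscales: bool = True) -> pd.DataFrame:
    """Tabulate scored responses, one row per respondent."""
    rows = []
    for s in scores:
        row = {
            "respondent_id": s.respondent_id,
            "dyad_id": s.dyad_id,
            "role": s.role,
            "social_support": s.social_support,
            "family_health": s.family_health,
            "family_functioning": s.family_functioning,
        }
        if include_subscales:
            row.update(s.subscale_scores)
        rows.append(row)
    return pd.DataFrame(rows)


def score_file(path, out_path=None, column_map=None, reverse_illbeing: bool = True) -> pd.DataFrame:
    """Read, validate and score a respondent CSV; invalid rows are dropped.

    Returns the scored table (and writes it to ``out_path`` if given).
    Complete-case behaviour: any respondent failing validation is excluded
    here and the corresponding dyad is later excluded by the dyad builder.
    """
    responses = read_responses(path, column_map=column_map)
    report = validate_batch(responses)
    scored = [score_fafhes(r, reverse_illbeing=reverse_illbeing) for r in report.valid]
    df = scores_frame(scored)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
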