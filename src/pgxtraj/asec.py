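"""ASEC-12 side-effect checklist aggregation.

The 12-item Antidepressant Side Effect Checklist is administered at the
interval periods 3, 5, 7 and 9, once per antidepressant in use.  Items are
binary (reported / not reported) and grouped by presumed pharmacology:
serotonergic (7 items), cholinergic (2) and histaminergic (2); dizziness
belongs to the total count only.

Aggregation is two-stage: within a period the counts of all qualifying
drugs (substrates of the enzyme under analysis, BOTH qualifying for either)
are averaged per patient, then the available period means are averaged
across the four periods, dropping — not zero-imputing — missing periods.

Source files may code items either 1 = reported (canonical) or
0 = reported; the ``coding`` flag converts on read.
"""

from __future__ import annotations

import enum
from typing import Sequence

import numpy as np
import pandas as pd

from .substrates import SubstrateTable, default_substrate_table

__all__ = [
    "ASEC_ITEMS",
    "ASEC_PERIODS",
    "ITEM_COLUMNS",
    "SideEffectCategory",
    "count_side_effects",
    "patient_period_mean",
    "patient_overall_mean",
    "side_effect_profile",
    "normalize_item_coding",
]

ASEC_ITEMS = (
    "insomnia",
    "daytime_sleepiness",
    "restlessness",
    "muscle_spasms",
    "dry_mouth",
    "profuse_sweating",
    "sexual_disorders",
    "nausea",
    "constipation",
    "diarrhoea",
    "weight_gain",
    "dizziness",
)

ASEC_PERIODS = (3, 5, 7, 9)

ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, 13))


class SideEffectCategory(enum.Enum):
    TOTAL = "total"
    SEROTONERGIC = "serotonergic"
    CHOLINERGIC = "cholinergic"
    HISTAMINERGIC = "histaminergic"

    @property
    def items(self) -> tuple[int, ...]:
        """Zero-based item indices belonging to the category."""
        return _CATEGORY_ITEMS[self]


_BY_NAME = {name: i for i, name in enumerate(ASEC_ITEMS)}
_CATEGORY_ITEMS = {
    SideEffectCategory.TOTAL: tuple(range(12)),
    SideEffectCategory.SEROTONERGIC: tuple(
        _BY_NAME[n]
        for n in (
            "insomnia", "restlessness", "muscle_spasms", "profuse_sweating",
            "sexual_disorders", "nausea", "diarrhoea",
        )
    ),
    SideEffectCategory.CHOLINERGIC: (_BY_NAME["dry_mouth"], _BY_NAME["constipation"]),
    SideEffectCategory.HISTAMINERGIC: (
        _BY_NAME["daytime_sleepiness"], _BY_NAME["weight_gain"],
    ),
}


def count_side_effects(
    items: Sequence[int], category: SideEffectCategory = SideEffectCategory.TOTAL
) -> int:
    """Number of reported items (coded 1) within a category."""
    arr = np.asarray(items)
    if arr.shape != (12,):
        raise ValueError(f"expected 12 ASEC items, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("ASEC items must be binary 0/1")
    return int(arr[list(category.items)].sum())


def normalize_item_coding(asec: pd.DataFrame, coding: str = "reported1") -> pd.DataFrame:
    """Return a copy with items coded 1 = reported.

    ``coding`` is ``"reported1"`` (already canonical) or ``"reported0"``
    (questionnaire convention 0 = reported, 1 = not reported).
    """
    cols = [c for c in ITEM_COLUMNS if c in asec.columns]
    if len(cols) != 12:
        missing = set(ITEM_COLUMNS) - set(cols)
        raise ValueError(f"ASEC table missing item columns {sorted(missing)}")
    out = asec.copy()
    out[list(ITEM_COLUMNS)] = out[list(ITEM_COLUMNS)].astype(int)
    if coding == "reported0":
        out[list(ITEM_COLUMNS)] = 1 - out[list(ITEM_COLUMNS)]
    elif coding != "reported1":
        raise ValueError(f"unknown ASEC coding {coding!r}")
    bad = ~out[list(ITEM_COLUMNS)].isin([0, 1]).all(axis=1)
    if bad.any():
        raise ValueError(f"non-binary ASEC items in rows {list(out.index[bad])[:5]}")
    return out


def _qualifying(asec: pd.DataFrame, enzyme: str, table: SubstrateTable) -> pd.DataFrame:
    keep = asec["atc"].map(lambda a: table.is_substrate(a, enzyme))
    return asec.loc[keep]


def _row_counts(asec: pd.DataFrame, category: SideEffectCategory) -> pd.Series:
    cols = [ITEM_COLUMNS[i] for i in category.items]
    return asec[cols].sum(axis=1)


def patient_period_mean(
    asec: pd.DataFrame,
    patient_id,
    period: int,
    enzyme: str,
    category: SideEffectCategory = SideEffectCategory.TOTAL,
    table: SubstrateTable | None = None,
) -> float:
    """Mean count over a patient's qualifying drugs in one period.

    Returns NaN when the patient has no qualifying response in that period.
    Input must already be in canonical coding (see
    :func:`normalize_item_coding`).
    """
    table = table or default_substrate_table()
    sub = asec[(asec["patient_id"] == patient_id) & (asec["period"] == period)]
    sub = _qualifying(sub, enzyme, table)
    if sub.empty:
        return float("nan")
    return float(_row_counts(sub, category).mean())


def patient_overall_mean(
    asec: pd.DataFrame,
    patient_id,
    enzyme: str,
    category: SideEffectCategory = SideEffectCategory.TOTAL,
    table: SubstrateTable | None = None,
) -> float:
    """Across-period mean of the per-period means; NaN periods are dropped."""
    means = [
        patient_period_mean(asec, patient_id, p, enzyme, category, table)
        for p in ASEC_PERIODS
    ]
    means = [m for m in means if not np.isnan(m)]
    return float(np.mean(means)) if means else float("nan")


def side_effect_profile(
    asec: pd.DataFrame,
    enzyme: str,
    category: SideEffectCategory = SideEffectCategory.TOTAL,
    table: SubstrateTable | None = None,
) -> pd.Series:
    """Vectorized per-patient overall means for a whole cohort.

    Equivalent to calling :func:`patient_overall_mean` per patient but in
    two grouped passes; returns a float Series indexed by patient_id
    covering every patient with at least one qualifying response.
    """
    table = table or default_substrate_table()
    sub = _qualifying(asec[asec["period"].isin(ASEC_PERIODS)], enzyme, table)
    if sub.empty:
        return pd.Series(dtype=float, name=category.value)
    counts = _row_counts(sub, category)
    per_period = counts.groupby(
        [sub["patient_id"], sub["period"]]
    ).mean()
    overall = per_period.groupby(level=0).mean()
    overall.name = category.value
    return overall
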