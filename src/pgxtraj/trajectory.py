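"""Longitudinal antidepressant-use trajectories over an 11-period window.

The observation window spans three years before baseline through the 9-year
follow-up of a naturalistic cohort, discretized into 11 ordered medication
assessments: odd periods 1,3,5,7,9 cover the *interval* between visits and
even periods 2,4,6,8,10 plus period 11 capture *current* use at a visit.

A patient enters the analysis with a single index antidepressant: either
exactly one AD in period 1, or exactly one AD at the first period of use in
2..10 with all earlier assessed periods AD-free.  Use is then compared
between successive periods of AD use; when two use periods are separated by
one or more AD-free periods the gap-spanning comparison replaces the
consecutive ones.  A comparison counts as a *switch* when the two periods
share no AD (replacement, not augmentation).  Patients are labelled:

* SWITCHED — any comparison shows a switch;
* DISCONTINUED — use occurs in periods 1–4, no assessed period 5–11 shows
  use, and at least one period ≥ 5 was assessed;
* NOT_CLASSIFIABLE — use confined to periods 1–4 with no assessment ≥ 5
  (lost to follow-up, continuation unknowable);
* MAINTAINED — otherwise (use somewhere in 1–10, no switch).

Unassessed periods are skipped, never imputed as AD-free.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .alleles import MetabolizerStatus
from .substrates import SubstrateTable, default_substrate_table

__all__ = [
    "N_PERIODS",
    "PeriodKind",
    "period_kind",
    "PERIOD_LABELS",
    "MedicationTimeline",
    "ComparisonPair",
    "TrajectoryLabel",
    "eligible_index_ad",
    "comparison_pairs",
    "classify_trajectory",
    "subsample_membership",
    "reasons_table",
    "REASONS",
    "REASON_TRANSITIONS",
]

logger = logging.getLogger(__name__)

N_PERIODS = 11

#: reason codes patients can give for stopping a drug
REASONS = ("symptom_free", "ineffective", "side_effects")

#: (previous interval, visit) pairs at which discontinuation reasons apply
REASON_TRANSITIONS = ((5, 6), (7, 8), (9, 10))


class PeriodKind(enum.Enum):
    INTERVAL = "interval"
    CURRENT = "current"


def period_kind(index: int) -> PeriodKind:
    if not 1 <= index <= N_PERIODS:
        raise ValueError(f"period index {index} outside 1..{N_PERIODS}")
    return PeriodKind.CURRENT if (index % 2 == 0 or index == 11) else PeriodKind.INTERVAL


PERIOD_LABELS = {
    1: "3 years pre-baseline to baseline",
    2: "current at baseline",
    3: "baseline to 1-year FU",
    4: "current at 1-year FU",
    5: "1-year to 2-year FU",
    6: "current at 2-year FU",
    7: "2-year to 4-year FU",
    8: "current at 4-year FU",
    9: "4-year to 6-year FU",
    10: "current at 6-year FU",
    11: "current at 9-year FU",
}


class TrajectoryLabel(enum.Enum):
    MAINTAINED = "MAINTAINED"
    SWITCHED = "SWITCHED"
    DISCONTINUED = "DISCONTINUED"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ComparisonPair:
    earlier: int
    later: int
    gap_spanning: bool

    def __post_init__(self):
        if not self.earlier < self.later:
            raise ValueError("comparison pair must be time-ordered")


@dataclass
class MedicationTimeline:
    """Per-patient AD sets across the 11 periods plus participation flags.

    ``meds`` maps period index → set of ATC codes and may only contain keys
    for assessed periods; unassessed periods carry no information.
    """

    patient_id: str
    meds: dict[int, frozenset[str]] = field(default_factory=dict)
    assessed: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self):
        self.assessed = {p: bool(v) for p, v in self.assessed.items()}
        self.meds = {p: frozenset(v) for p, v in self.meds.items()}
        for p in list(self.meds) + list(self.assessed):
            if not 1 <= p <= N_PERIODS:
                raise ValueError(f"period index {p} outside 1..{N_PERIODS}")
        for p in self.meds:
            if not self.assessed.get(p, False):
                raise ValueError(
                    f"patient {self.patient_id}: medication recorded at "
                    f"unassessed period {p}"
                )

    def assessed_periods(self) -> list[int]:
        # timelines are treated as immutable after construction
        cached = self.__dict__.get("_assessed_cache")
        if cached is None:
            cached = sorted(p for p, ok in self.assessed.items() if ok)
            self.__dict__["_assessed_cache"] = cached
        return cached

    def ad_periods(self) -> list[int]:
        """Assessed periods with at least one AD, in time order."""
        cached = self.__dict__.get("_ad_cache")
        if cached is None:
            cached = [p for p in self.assessed_periods() if self.meds.get(p)]
            self.__dict__["_ad_cache"] = cached
        return cached

    def meds_at(self, period: int) -> frozenset[str]:
        return self.meds.get(period, frozenset())

    @classmethod
    def from_records(
        cls,
        patient_id: str,
        medications: Iterable[tuple[int, str]],
        assessed: Iterable[int] | Mapping[int, bool] | None = None,
    ) -> "MedicationTimeline":
        """Build from (period, atc) pairs; ``assessed`` defaults to all 11."""
        meds: dict[int, set[str]] = {}
        for period, atc in medications:
            meds.setdefault(int(period), set()).add(atc)
        if assessed is None:
            flags = {p: True for p in range(1, N_PERIODS + 1)}
        elif isinstance(assessed, Mapping):
            flags = {int(p): bool(v) for p, v in assessed.items()}
        else:
            flags = {int(p): True for p in assessed}
        return cls(patient_id, {p: frozenset(s) for p, s in meds.items()}, flags)


def eligible_index_ad(timeline: MedicationTimeline) -> Optional[tuple[str, int]]:
    """The single index AD and its start period, or ``None`` if ineligible.

    Eligible patients either used exactly one AD in period 1, or started
    exactly one AD at the first period of use within 2..10 (all earlier
    assessed periods AD-free).  Starting on more than one AD, or never using
    an AD in periods 1–10, makes the patient ineligible — a value, not an
    error.
    """
    for period in timeline.assessed_periods():
        if period > 10:
            break
        current = timeline.meds_at(period)
        if current:
            if len(current) == 1:
                return next(iter(current)), period
            return None
    return None


def comparison_pairs(timeline: MedicationTimeline) -> list[ComparisonPair]:
    """Successive-use comparisons with gap-spanning preference.

    Consecutive assessed periods that both show AD use are compared
    directly; two use periods separated only by AD-free (or unassessed)
    periods form a gap-spanning comparison that supersedes any consecutive
    comparison inside the gap.  Equivalently: adjacent elements of the
    ordered list of AD-use periods.
    """
    use = timeline.ad_periods()
    return [
        ComparisonPair(a, b, gap_spanning=b > a + 1)
        for a, b in zip(use, use[1:])
    ]


def _is_switch(timeline: MedicationTimeline, pair: ComparisonPair) -> bool:
    # replacement, not augmentation: no drug carried over between the periods
    return timeline.meds_at(pair.earlier).isdisjoint(timeline.meds_at(pair.later))


def classify_trajectory(timeline: MedicationTimeline,
                        check_eligibility: bool = True) -> TrajectoryLabel:
    """Label an eligible patient's trajectory; raises if ineligible.

    ``check_eligibility=False`` skips the eligibility re-check when the
    caller has already established it via :func:`eligible_index_ad`.
    """
    if check_eligibility and eligible_index_ad(timeline) is None:
        raise ValueError(
            f"patient {timeline.patient_id} is not an eligible single-AD starter"
        )
    if any(_is_switch(timeline, p) for p in comparison_pairs(timeline)):
        return TrajectoryLabel.SWITCHED
    use = timeline.ad_periods()
    used_late = any(p >= 5 for p in use)
    if not used_late:  # use confined to periods 1-4
        assessed_late = any(p >= 5 for p in timeline.assessed_periods())
        if assessed_late:
            return TrajectoryLabel.DISCONTINUED
        return TrajectoryLabel.NOT_CLASSIFIABLE
    return TrajectoryLabel.MAINTAINED


def subsample_membership(
    index_ad: str, table: SubstrateTable | None = None
) -> frozenset[str]:
    """Enzyme subsamples ({"CYP2D6"}, {"CYP2C19"}, both, or empty) of an AD."""
    return (table or default_substrate_table()).enzymes(index_ad)


def _collapse_for_reasons(status: MetabolizerStatus, enzyme: str) -> str | None:
    if status is MetabolizerStatus.UNKNOWN:
        return None
    if enzyme == "CYP2D6":
        return "NM" if status is MetabolizerStatus.NM else "IM/PM"
    if enzyme == "CYP2C19":
        return "NM" if status is MetabolizerStatus.NM else "IM/PM/UM"
    raise ValueError(f"unsupported enzyme {enzyme!r}")


def reasons_table(
    timelines: Iterable[MedicationTimeline],
    reasons: pd.DataFrame,
    phenotypes: pd.DataFrame,
    table: SubstrateTable | None = None,
) -> pd.DataFrame:
    """Tabulate discontinuation reasons by enzyme and collapsed phenotype.

    For each visit transition (5→6, 7→8, 9→10), patients whose AD set
    emptied (discontinue) or was fully replaced (switch) are selected; each
    event is attributed to the enzyme(s) the prior period's drugs are
    substrates of, and its reason (from ``reasons`` with columns patient_id,
    period, atc, reason, keyed on the visit period and the prior drug)
    counted under the patient's collapsed metabolizer group — NM vs IM/PM
    for CYP2D6, NM vs IM/PM/UM for CYP2C19.  Reason records that match no
    medication change are logged and excluded.

    Returns a DataFrame indexed by (enzyme, group) with one integer column
    per reason.
    """
    table = table or default_substrate_table()
    for col in ("patient_id", "period", "atc", "reason"):
        if col not in reasons.columns:
            raise ValueError(f"reasons table missing column {col!r}")
    bad = set(reasons["reason"]) - set(REASONS)
    if bad:
        raise ValueError(f"unrecognized reason codes {sorted(bad)}")

    rows = {
        ("CYP2D6", g): {r: 0 for r in REASONS} for g in ("NM", "IM/PM")
    }
    rows.update(
        {("CYP2C19", g): {r: 0 for r in REASONS} for g in ("NM", "IM/PM/UM")}
    )

    by_patient: dict[str, pd.DataFrame] = (
        {k: v for k, v in reasons.groupby("patient_id")} if len(reasons) else {}
    )
    matched = pd.Series(False, index=reasons.index)

    for tl in timelines:
        recs = by_patient.get(tl.patient_id)
        if recs is None:
            continue
        for prev, cur in REASON_TRANSITIONS:
            if not (tl.assessed.get(prev) and tl.assessed.get(cur)):
                continue
            before, after = tl.meds_at(prev), tl.meds_at(cur)
            stopped = (bool(before) and not after) or (
                bool(before) and bool(after) and before.isdisjoint(after)
            )
            if not stopped:
                continue
            hits = recs[(recs["period"] == cur) & (recs["atc"].isin(before))]
            matched.loc[hits.index] = True
            enzymes = set().union(*(table.enzymes(a) for a in before))
            for row in hits.itertuples():
                for enzyme in enzymes:
                    col = "cyp2d6" if enzyme == "CYP2D6" else "cyp2c19"
                    if col not in phenotypes.columns or tl.patient_id not in phenotypes.index:
                        continue
                    group = _collapse_for_reasons(
                        phenotypes.loc[tl.patient_id, col], enzyme
                    )
                    if group is not None:
                        rows[(enzyme, group)][row.reason] += 1

    unmatched = reasons.loc[~matched]
    for row in unmatched.itertuples():
        logger.warning(
            "reason record without matching medication change: patient %s "
            "period %s atc %s — excluded", row.patient_id, row.period, row.atc
        )

    out = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["enzyme", "group"])
    return out
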