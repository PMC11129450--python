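"""Trajectory classification: eligibility, comparison pairs, labels,
reason tabulation."""

import numpy as np
import pandas as pd
import pytest

from pgxtraj.alleles import assign_phenotypes
from pgxtraj.synthetic import CohortConfig, generate_cohort
from pgxtraj.trajectory import (
    ComparisonPair,
    MedicationTimeline,
    TrajectoryLabel,
    classify_trajectory,
    comparison_pairs,
    eligible_index_ad,
    period_kind,
    PeriodKind,
    reasons_table,
    subsample_membership,
)

from conftest import (
    CITALOPRAM,
    FLUOXETINE,
    MIRTAZAPINE,
    PAROXETINE,
    SERTRALINE,
    TRYPTOPHAN,
    make_timeline,
)

M, S, D, NC = (TrajectoryLabel.MAINTAINED, TrajectoryLabel.SWITCHED,
               TrajectoryLabel.DISCONTINUED, TrajectoryLabel.NOT_CLASSIFIABLE)


def test_period_structure():
    assert [period_kind(p) for p in (1, 3, 5, 7, 9)] == [PeriodKind.INTERVAL] * 5
    assert [period_kind(p) for p in (2, 4, 6, 8, 10, 11)] == [PeriodKind.CURRENT] * 6
    with pytest.raises(ValueError):
        period_kind(12)


def test_meds_at_unassessed_period_rejected():
    with pytest.raises(ValueError, match="unassessed"):
        MedicationTimeline("p", {3: frozenset({PAROXETINE})}, {3: False})


class TestEligibility:
    def test_single_ad_in_period_one(self):
        tl = make_timeline({1: PAROXETINE})
        assert eligible_index_ad(tl) == (PAROXETINE, 1)

    def test_two_ads_at_start_is_ineligible(self):
        tl = make_timeline({3: {CITALOPRAM, MIRTAZAPINE}})
        assert eligible_index_ad(tl) is None

    def test_never_used_is_ineligible(self):
        tl = make_timeline({})
        assert eligible_index_ad(tl) is None

    def test_start_during_observation(self):
        tl = make_timeline({6: SERTRALINE, 7: SERTRALINE})
        assert eligible_index_ad(tl) == (SERTRALINE, 6)

    def test_use_only_at_period_11_is_ineligible(self):
        tl = make_timeline({11: SERTRALINE})
        assert eligible_index_ad(tl) is None

    def test_unassessed_early_periods_are_skipped(self):
        tl = make_timeline({4: PAROXETINE}, assessed=[1, 4, 5, 6])
        assert eligible_index_ad(tl) == (PAROXETINE, 4)


class TestComparisonPairs:
    def test_gap_spanning_preferred_over_consecutive(self):
        tl = make_timeline({2: PAROXETINE, 3: PAROXETINE, 6: FLUOXETINE})
        # AD-free periods 4 and 5 interleave -> (3, 6) spans the gap
        assert comparison_pairs(tl) == [
            ComparisonPair(2, 3, False),
            ComparisonPair(3, 6, True),
        ]

    def test_consecutive_use_has_no_gap_pairs(self):
        tl = make_timeline({p: PAROXETINE for p in (1, 2, 3)})
        assert comparison_pairs(tl) == [
            ComparisonPair(1, 2, False), ComparisonPair(2, 3, False)
        ]

    def test_single_use_period_yields_nothing(self):
        assert comparison_pairs(make_timeline({4: PAROXETINE})) == []


class TestClassification:
    """Scenario suite covering every schematic trajectory shape."""

    def test_maintained_throughout(self):
        tl = make_timeline({p: SERTRALINE for p in range(1, 11)})
        assert classify_trajectory(tl) is M

    def test_discontinued_before_cutoff(self):
        tl = make_timeline({p: PAROXETINE for p in (2, 3, 4)})
        assert classify_trajectory(tl) is D

    def test_switch_across_gap(self):
        tl = make_timeline({2: CITALOPRAM, 3: CITALOPRAM,
                            **{p: FLUOXETINE for p in range(6, 11)}})
        assert classify_trajectory(tl) is S

    def test_same_ad_restart_across_gap_is_maintained(self):
        tl = make_timeline({2: PAROXETINE, 3: PAROXETINE,
                            **{p: PAROXETINE for p in range(7, 11)}})
        assert classify_trajectory(tl) is M

    def test_late_initiation_is_maintained(self):
        tl = make_timeline({p: SERTRALINE for p in range(6, 12)})
        assert classify_trajectory(tl) is M

    def test_lost_to_followup_not_classifiable(self):
        tl = make_timeline({p: PAROXETINE for p in (1, 2, 3, 4)},
                           assessed=[1, 2, 3, 4])
        assert classify_trajectory(tl) is NC

    def test_consecutive_switch(self):
        tl = make_timeline({2: CITALOPRAM, 3: CITALOPRAM,
                            **{p: FLUOXETINE for p in range(4, 11)}})
        assert classify_trajectory(tl) is S

    def test_augmentation_is_not_a_switch(self):
        # original AD carried forward next to an added AD
        tl = make_timeline({**{p: PAROXETINE for p in range(1, 11)},
                            **{p: {PAROXETINE, MIRTAZAPINE} for p in (5, 6)}})
        assert classify_trajectory(tl) is M

    def test_switch_back_to_original_still_switched(self):
        tl = make_timeline({1: PAROXETINE, 2: PAROXETINE,
                            3: CITALOPRAM, 4: CITALOPRAM,
                            **{p: PAROXETINE for p in range(5, 11)}})
        assert classify_trajectory(tl) is S

    def test_switch_takes_precedence_over_discontinuation(self):
        # switched within 1-4, then nothing: both definitions' preconditions
        # overlap, but a switch occurred somewhere
        tl = make_timeline({1: PAROXETINE, 2: CITALOPRAM})
        assert classify_trajectory(tl) is S

    def test_use_in_period_11_only_after_start_counts_as_maintained(self):
        tl = make_timeline({4: SERTRALINE, 11: SERTRALINE})
        assert classify_trajectory(tl) is M

    def test_period_11_participates_in_switch_detection(self):
        tl = make_timeline({4: SERTRALINE, 11: CITALOPRAM})
        assert classify_trajectory(tl) is S

    def test_ineligible_timeline_raises(self):
        with pytest.raises(ValueError, match="not an eligible"):
            classify_trajectory(make_timeline({}))


class TestClassificationProperties:
    @pytest.mark.parametrize("gap_end", [4, 5, 6, 7, 8])
    def test_gap_length_never_changes_label(self, gap_end):
        same = make_timeline({2: PAROXETINE, 3: PAROXETINE,
                              **{p: PAROXETINE for p in range(gap_end + 1, 11)}})
        other = make_timeline({2: PAROXETINE, 3: PAROXETINE,
                               **{p: FLUOXETINE for p in range(gap_end + 1, 11)}})
        assert classify_trajectory(same) is M
        assert classify_trajectory(other) is S

    def test_record_order_invariance(self):
        records = [(2, CITALOPRAM), (3, CITALOPRAM), (6, FLUOXETINE),
                   (7, FLUOXETINE)]
        rng = np.random.default_rng(42)
        labels = set()
        for _ in range(10):
            perm = [records[i] for i in rng.permutation(len(records))]
            tl = MedicationTimeline.from_records("p", perm)
            labels.add(classify_trajectory(tl))
        assert labels == {S}


@pytest.mark.parametrize(
    "atc,expected",
    [(CITALOPRAM, {"CYP2D6", "CYP2C19"}), (SERTRALINE, {"CYP2C19"}),
     (PAROXETINE, {"CYP2D6"}), (TRYPTOPHAN, set())],
)
def test_subsample_membership(atc, expected):
    assert subsample_membership(atc) == frozenset(expected)


class TestReasonsTable:
    def _phenotypes(self, pids, d6="*1/*1", c19="*1/*1"):
        rows = []
        for pid in pids:
            a, b = d6.split("/")
            rows.append((pid, "CYP2D6", a, b, True))
            a, b = c19.split("/")
            rows.append((pid, "CYP2C19", a, b, True))
        return assign_phenotypes(pd.DataFrame(
            rows, columns=["patient_id", "gene", "allele1", "allele2",
                           "quality_ok"]))

    def test_counts_discontinuers_by_group(self):
        pids = ["p1", "p2", "p3"]
        timelines = [
            make_timeline({p: PAROXETINE for p in (1, 2, 3, 4, 5)},
                          patient_id=pid)
            for pid in pids
        ]
        reasons = pd.DataFrame(
            [(pid, 6, PAROXETINE, "symptom_free") for pid in pids],
            columns=["patient_id", "period", "atc", "reason"],
        )
        out = reasons_table(timelines, reasons, self._phenotypes(pids))
        assert out.loc[("CYP2D6", "NM"), "symptom_free"] == 3
        assert out.loc[("CYP2D6", "NM"), "ineffective"] == 0
        assert out.loc[("CYP2C19", "NM")].sum() == 0  # paroxetine not a substrate

    def test_empty_reasons_gives_zero_table(self):
        timelines = [make_timeline({1: PAROXETINE})]
        reasons = pd.DataFrame(columns=["patient_id", "period", "atc", "reason"])
        out = reasons_table(timelines, reasons, self._phenotypes(["P0"]))
        assert (out.to_numpy() == 0).all()
        assert set(out.index.get_level_values("enzyme")) == {"CYP2D6", "CYP2C19"}

    def test_unmatched_reason_excluded_with_warning(self, caplog):
        timelines = [make_timeline({p: PAROXETINE for p in range(1, 11)},
                                   patient_id="p1")]
        reasons = pd.DataFrame(
            [("p1", 6, PAROXETINE, "side_effects")],
            columns=["patient_id", "period", "atc", "reason"],
        )
        with caplog.at_level("WARNING"):
            out = reasons_table(timelines, reasons, self._phenotypes(["p1"]))
        assert (out.to_numpy() == 0).all()
        assert "without matching medication change" in caplog.text

    def test_generated_reason_mix_recovers_probabilities(self):
        """Multinomial sampling check: generated reason shares sit within
        3 binomial SEs of the configured (0.4, 0.25, 0.35)."""
        probs = {"symptom_free": 0.4, "ineffective": 0.25, "side_effects": 0.35}
        cohort = generate_cohort(CohortConfig(
            n_patients=500, seed=11,
            reason_probs=(0.4, 0.25, 0.35),
        ))
        counts = cohort.reasons["reason"].value_counts()
        n = counts.sum()
        assert n > 50  # enough stop events to test against
        for reason, p in probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(reason, 0) / n - p) < 3 * se
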