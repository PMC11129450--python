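"""Shared fixtures: timeline builders and a tiny hand-crafted cohort."""

from __future__ import annotations

import pandas as pd
import pytest

from pgxtraj.trajectory import MedicationTimeline

# short-hands used throughout the trajectory tests
PAROXETINE = "N06AB05"
CITALOPRAM = "N06AB04"
FLUOXETINE = "N06AB03"
SERTRALINE = "N06AB06"
MIRTAZAPINE = "N06AX11"
TRYPTOPHAN = "N06AX02"


def make_timeline(meds: dict[int, set[str] | str], assessed=None,
                  patient_id="P0") -> MedicationTimeline:
    """Build a timeline from {period: atc or set-of-atc}; periods not in
    ``assessed`` (default: all 11) are unassessed."""
    records = []
    for period, drugs in meds.items():
        if isinstance(drugs, str):
            drugs = {drugs}
        for atc in drugs:
            records.append((period, atc))
    return MedicationTimeline.from_records(patient_id, records, assessed)


@pytest.fixture
def toy_cohort():
    """Six hand-crafted patients covering every trajectory label.

    Returns the (genotypes, medications, participation) frames consumed by
    the pipeline plus the expected label per patient.
    """
    genotypes = []
    for pid, (d6a, d6b, c19a, c19b, ok) in {
        "A": ("*1", "*1", "*1", "*1", True),
        "B": ("*1", "*4", "*1", "*2", True),
        "C": ("*4", "*4", "*2", "*2", True),
        "D": ("*1", "*41", "*17", "*17", True),
        "E": ("*1", "*1", "*1", "*17", True),
        "F": ("*1", "*1", "*1", "*1", False),
    }.items():
        genotypes.append((pid, "CYP2D6", d6a, d6b, ok))
        genotypes.append((pid, "CYP2C19", c19a, c19b, True))
    genotypes = pd.DataFrame(
        genotypes,
        columns=["patient_id", "gene", "allele1", "allele2", "quality_ok"],
    )

    med_specs = {
        "A": {p: PAROXETINE for p in range(1, 12)},           # maintained
        "B": {2: PAROXETINE, 3: PAROXETINE, 4: PAROXETINE},    # discontinued
        "C": {2: CITALOPRAM, 3: CITALOPRAM,
              **{p: FLUOXETINE for p in range(6, 11)}},        # switched (gap)
        "D": {p: SERTRALINE for p in range(5, 12)},            # maintained
        "E": {1: MIRTAZAPINE, 2: MIRTAZAPINE,
              **{p: CITALOPRAM for p in range(3, 12)}},        # switched
        "F": {p: PAROXETINE for p in range(1, 12)},            # maintained
    }
    expected = {
        "A": "MAINTAINED", "B": "DISCONTINUED", "C": "SWITCHED",
        "D": "MAINTAINED", "E": "SWITCHED", "F": "MAINTAINED",
    }
    med_rows = [
        (pid, period, atc)
        for pid, meds in med_specs.items()
        for period, atc in meds.items()
    ]
    medications = pd.DataFrame(med_rows, columns=["patient_id", "period", "atc"])
    participation = pd.DataFrame(
        [(pid, p, True) for pid in med_specs for p in range(1, 12)],
        columns=["patient_id", "period", "assessed"],
    )
    return genotypes, medications, participation, expected
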