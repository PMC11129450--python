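"""End-to-end analysis pipeline: phenotypes → trajectories → statistics.

Orchestrates the full study analysis on the five input tables (genotypes,
medications, participation, ASEC responses, discontinuation reasons):
assigns metabolizer phenotypes, selects eligible single-AD starters,
classifies trajectories, builds the per-enzyme substrate subsamples,
estimates the association of collapsed metabolizer group with
discontinuing/switching, compares side-effect burdens (Mann–Whitney,
NM vs IM/PM), tabulates discontinuation reasons, and computes post-hoc
power from the realized group sizes.  Every selection step is logged as
(step, kept, excluded) so the cohort flow reconciles at each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .alleles import Guideline, MetabolizerStatus, assign_phenotypes
from .asec import SideEffectCategory, normalize_item_coding, side_effect_profile
from .association import AssociationResults, MetabolizerAssociation
from .stats import mann_whitney_u
from .substrates import SubstrateTable, default_substrate_table
from .trajectory import (
    MedicationTimeline,
    TrajectoryLabel,
    classify_trajectory,
    eligible_index_ad,
    reasons_table,
    subsample_membership,
)

__all__ = [
    "RunConfig",
    "PipelineReport",
    "collapse_groups",
    "build_timelines",
    "classify_cohort",
    "run_pipeline_frames",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ENZYMES = ("CYP2D6", "CYP2C19")


@dataclass
class RunConfig:
    """Pipeline options; paths are only needed by the file-based runner."""

    guideline: str = "DPWG"
    allele_mode: str = "paper_compat"
    alpha: float = 0.05
    asec_coding: str = "reported1"
    neither_substrate_eligible: bool = True
    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        Guideline(self.guideline)
        if self.allele_mode not in ("paper_compat", "strict"):
            raise ValueError(f"unknown allele mode {self.allele_mode!r}")
        if self.asec_coding not in ("reported1", "reported0"):
            raise ValueError(f"unknown ASEC coding {self.asec_coding!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def collapse_groups(status: MetabolizerStatus, enzyme: str) -> str | None:
    """Analysis group of a phenotype: CYP2D6 NM vs IM/PM; CYP2C19 adds UM.

    UNKNOWN returns ``None`` (excluded).  UM for CYP2D6 is unreachable from
    the supported allele tables and raises.
    """
    enzyme = enzyme.upper()
    if status is MetabolizerStatus.UNKNOWN:
        return None
    if enzyme == "CYP2D6":
        if status is MetabolizerStatus.UM:
            raise ValueError("CYP2D6 UM cannot arise without duplication calls")
        return "NM" if status is MetabolizerStatus.NM else "IM/PM"
    if enzyme == "CYP2C19":
        if status is MetabolizerStatus.UM:
            return "UM"
        return "NM" if status is MetabolizerStatus.NM else "IM/PM"
    raise ValueError(f"unsupported enzyme {enzyme!r}")


def build_timelines(
    medications: pd.DataFrame, participation: pd.DataFrame
) -> dict[str, MedicationTimeline]:
    """Assemble per-patient timelines from the medications/participation CSVs."""
    assessed_map: dict[str, dict[int, bool]] = {}
    for pid, period, flag in zip(
        participation["patient_id"].astype(str).to_numpy(),
        participation["period"].to_numpy(),
        participation["assessed"].to_numpy(),
    ):
        assessed_map.setdefault(pid, {})[int(period)] = bool(flag)
    meds_map: dict[str, list[tuple[int, str]]] = {pid: [] for pid in assessed_map}
    for pid, period, atc in zip(
        medications["patient_id"].astype(str).to_numpy(),
        medications["period"].to_numpy(),
        medications["atc"].astype(str).to_numpy(),
    ):
        meds_map.setdefault(pid, []).append((int(period), atc))
    return {
        pid: MedicationTimeline.from_records(
            pid, meds_map.get(pid, []), assessed_map.get(pid)
        )
        for pid in meds_map
    }


def classify_cohort(
    timelines: Iterable[MedicationTimeline],
    substrate_table: SubstrateTable | None = None,
    neither_substrate_eligible: bool = True,
    flow: list | None = None,
) -> pd.DataFrame:
    """Select eligible patients and label their trajectories.

    Returns one row per selected patient: index_atc, start_period, label,
    cyp2d6_subsample, cyp2c19_subsample.  NOT_CLASSIFIABLE patients (lost
    to follow-up with use confined to periods 1–4) are excluded, mirroring
    the study's flowchart; the ``flow`` list, when given, accumulates
    (step, kept, excluded) tuples.
    """
    substrate_table = substrate_table or default_substrate_table()
    timelines = list(timelines)
    eligible = []
    for tl in timelines:
        found = eligible_index_ad(tl)
        if found is None:
            continue
        atc, start = found
        if not neither_substrate_eligible and not subsample_membership(
            atc, substrate_table
        ):
            continue
        eligible.append((tl, atc, start))
    if flow is not None:
        flow.append(("eligible single-AD starters", len(eligible),
                     len(timelines) - len(eligible)))

    rows = []
    n_unclassifiable = 0
    for tl, atc, start in eligible:
        label = classify_trajectory(tl, check_eligibility=False)
        if label is TrajectoryLabel.NOT_CLASSIFIABLE:
            n_unclassifiable += 1
            continue
        enzymes = subsample_membership(atc, substrate_table)
        rows.append(
            {
                "patient_id": tl.patient_id,
                "index_atc": atc,
                "start_period": start,
                "label": label.value,
                "cyp2d6_subsample": "CYP2D6" in enzymes,
                "cyp2c19_subsample": "CYP2C19" in enzymes,
            }
        )
    if flow is not None:
        flow.append(("classifiable trajectories", len(rows), n_unclassifiable))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "index_atc", "start_period", "label",
            "cyp2d6_subsample", "cyp2c19_subsample",
        ],
    )


@dataclass
class PipelineReport:
    """All pipeline outputs plus the selection flow log."""

    config: RunConfig
    phenotypes: pd.DataFrame
    trajectories: pd.DataFrame
    associations: dict[str, AssociationResults]
    side_effects: pd.DataFrame
    reasons: pd.DataFrame | None
    flow: list[tuple[str, int, int]] = field(default_factory=list)

    def association_table(self) -> pd.DataFrame:
        frames = [r.estimates for r in self.associations.values()
                  if not r.estimates.empty]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        parts = []
        for step, kept, excluded in self.flow:
            parts.append(f"[flow] {step}: kept {kept}, excluded {excluded}")
        parts.append("")
        for enzyme, result in self.associations.items():
            parts.append(result.summary())
            parts.append("")
        if not self.side_effects.empty:
            parts.append("side-effect comparisons (Mann-Whitney, NM vs IM/PM):")
            parts.append(self.side_effects.to_string(index=False,
                                                     float_format="%.3f"))
        if self.reasons is not None and not self.reasons.empty:
            parts.append("")
            parts.append("reasons for discontinuing (counts):")
            parts.append(self.reasons.to_string())
        return "\n".join(parts)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trajectories.to_csv(outdir / "trajectory.csv", index=False)
        table = self.association_table()
        if not table.empty:
            table.to_csv(outdir / "association_table.csv", index=False,
                         float_format="%.6g")
        if not self.side_effects.empty:
            self.side_effects.to_csv(outdir / "side_effects.csv", index=False,
                                     float_format="%.6g")
        if self.reasons is not None and not self.reasons.empty:
            self.reasons.to_csv(outdir / "reasons_table.csv")
        (outdir / "report.txt").write_text(self.summary() + "\n")


def _enzyme_association(
    trajectories: pd.DataFrame,
    phenotypes: pd.DataFrame,
    enzyme: str,
    alpha: float,
) -> AssociationResults | None:
    col = enzyme.lower()
    flag = f"{col}_subsample"
    sub = trajectories[trajectories[flag]]
    if sub.empty or col not in phenotypes.columns:
        logger.warning("empty %s subsample; association skipped", enzyme)
        return None
    status = phenotypes[col].reindex(sub["patient_id"])
    groups = [
        collapse_groups(s, enzyme) if isinstance(s, MetabolizerStatus) else None
        for s in status
    ]
    data = pd.DataFrame({"group": groups, "label": sub["label"].to_numpy()})
    data = data[data["group"].notna()]
    if data.empty:
        logger.warning("no genotyped patients in %s subsample", enzyme)
        return None
    model = MetabolizerAssociation.from_dataframe(data, enzyme=enzyme)
    return model.fit(alpha=alpha)


def _side_effect_comparisons(
    asec: pd.DataFrame,
    trajectories: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float,
) -> pd.DataFrame:
    rows = []
    for enzyme in ENZYMES:
        col = enzyme.lower()
        if col not in phenotypes.columns:
            continue
        for category in SideEffectCategory:
            profile = side_effect_profile(asec, enzyme, category)
            if profile.empty:
                continue
            status = phenotypes[col].reindex(profile.index)
            groups = pd.Series(
                [
                    collapse_groups(s, enzyme)
                    if isinstance(s, MetabolizerStatus) else None
                    for s in status
                ],
                index=profile.index,
            )
            nm = profile[groups == "NM"]
            impm = profile[groups == "IM/PM"]
            if nm.empty or impm.empty:
                continue
            res = mann_whitney_u(nm.to_numpy(), impm.to_numpy())
            rows.append(
                {
                    "enzyme": enzyme,
                    "category": category.value,
                    "n_nm": len(nm),
                    "n_impm": len(impm),
                    "median_nm": float(nm.median()),
                    "median_impm": float(impm.median()),
                    "u": res.u,
                    "z": res.z,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["enzyme", "category", "n_nm", "n_impm", "median_nm",
                 "median_impm", "u", "z", "p_value"],
    )


def run_pipeline_frames(
    genotypes: pd.DataFrame,
    medications: pd.DataFrame,
    participation: pd.DataFrame,
    asec: pd.DataFrame | None = None,
    reasons: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    substrate_table: SubstrateTable | None = None,
) -> PipelineReport:
    """Run the full analysis on in-memory tables (the library entry point)."""
    config = config or RunConfig()
    substrate_table = substrate_table or default_substrate_table()
    flow: list[tuple[str, int, int]] = []

    phenotypes = assign_phenotypes(
        genotypes, guideline=config.guideline, mode=config.allele_mode
    )
    phenotypes.index = phenotypes.index.astype(str)
    flow.append(("genotyped patients", len(phenotypes), 0))

    timelines = build_timelines(medications, participation)
    trajectories = classify_cohort(
        timelines.values(),
        substrate_table,
        neither_substrate_eligible=config.neither_substrate_eligible,
        flow=flow,
    )

    associations = {}
    for enzyme in ENZYMES:
        result = _enzyme_association(trajectories, phenotypes, enzyme,
                                     config.alpha)
        if result is not None:
            associations[enzyme] = result

    if asec is not None and len(asec):
        asec_norm = normalize_item_coding(asec, config.asec_coding)
        asec_norm["patient_id"] = asec_norm["patient_id"].astype(str)
        side = _side_effect_comparisons(asec_norm, trajectories, phenotypes,
                                        config.alpha)
    else:
        side = pd.DataFrame()

    if reasons is not None and len(reasons):
        reasons = reasons.copy()
        reasons["patient_id"] = reasons["patient_id"].astype(str)
        reason_counts = reasons_table(
            timelines.values(), reasons, phenotypes, substrate_table
        )
    else:
        reason_counts = None

    return PipelineReport(
        config=config,
        phenotypes=phenotypes,
        trajectories=trajectories,
        associations=associations,
        side_effects=side,
        reasons=reason_counts,
        flow=flow,
    )


def run_pipeline(config: RunConfig) -> PipelineReport:
    """File-based runner: read the input CSVs, analyse, write reports."""
    from . import io as pgxio

    if config.input_dir is None:
        raise ValueError("config.input_dir is required for the file runner")
    indir = Path(config.input_dir)
    genotypes = pgxio.read_genotypes(indir / "genotypes.csv")
    medications = pgxio.read_medications(indir / "medications.csv")
    participation = pgxio.read_participation(indir / "participation.csv")
    asec_path = indir / "asec.csv"
    reasons_path = indir / "reasons.csv"
    asec = pgxio.read_asec(asec_path) if asec_path.exists() else None
    reasons = pgxio.read_reasons(reasons_path) if reasons_path.exists() else None
    report = run_pipeline_frames(
        genotypes, medications, participation, asec, reasons, config
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
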