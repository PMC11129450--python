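"""Synthetic cohort generator emulating the study's input tables.

The real cohort data are access-restricted, so every pipeline stage is
exercised on synthetic cohorts drawn to the study's structure:

* diplotypes per gene under Hardy–Weinberg equilibrium at European-like
  star-allele frequencies, with an imputation-failure flag (CYP2D6 only);
* one index antidepressant per patient, drawn with probabilities
  proportional to the study's drug distribution;
* a maintained/switched/discontinued trajectory realized as period-wise
  ATC sets over the 11 assessments, with group-specific switch and
  discontinuation odds optionally tilted by configurable log odds ratios;
* ASEC-12 item indicators at periods 3/5/7/9 and discontinuation reasons
  at the visit transitions 5→6, 7→8, 9→10.

Default allele frequencies are HWE inversions calibrated so phenotype
prevalences approximate the study's (see scripts/calibrate_frequencies.py
and docs/methods.md; the study's CYP2D6 PM/IM split is not exactly
attainable under HWE).  All sampling flows through one
``numpy.random.default_rng(seed)`` in a fixed order, so output is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import (
    AlleleFunctionTable,
    Diplotype,
    Guideline,
    classify_diplotype,
)
from .asec import ASEC_PERIODS, ITEM_COLUMNS, SideEffectCategory, _CATEGORY_ITEMS
from .pipeline import collapse_groups
from .substrates import default_substrate_table
from .trajectory import N_PERIODS, REASONS, REASON_TRANSITIONS

__all__ = ["CohortConfig", "Cohort", "generate_cohort",
           "sample_diplotypes", "simulate_timelines",
           "simulate_asec", "simulate_reasons",
           "DEFAULT_ALLELE_FREQS", "DEFAULT_AD_FREQS"]

# HWE-calibrated defaults (see scripts/calibrate_frequencies.py):
# CYP2C19: q(*2+*3)=0.1264, r(*17)=0.2424 -> PM 1.6 / IM 22.1 / NM 70.4 / UM 5.9 (%)
# CYP2D6:  i(inactive)=0.0882, r(reduced)=0.03 -> NM 83.0 / IM 16.2 / PM 0.8 (%)
DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "CYP2C19": {"*1": 0.6312, "*2": 0.1239, "*3": 0.0025, "*17": 0.2424},
    "CYP2D6": {
        "*1": 0.6500, "*2": 0.2318,
        "*3": 0.0070, "*4": 0.0780, "*6": 0.0032,
        "*10": 0.0060, "*17": 0.0020, "*41": 0.0220,
    },
}

# proportional to the study's per-drug patient counts (total 928)
DEFAULT_AD_FREQS: dict[str, int] = {
    "N06AA09": 53,   # amitriptyline
    "N06AB04": 146,  # citalopram
    "N06AA04": 33,   # clomipramine
    "N06AX21": 9,    # duloxetine
    "N06AB10": 18,   # escitalopram
    "N06AB03": 77,   # fluoxetine
    "N06AB08": 53,   # fluvoxamine
    "N06AA02": 2,    # imipramine
    "N06AA21": 2,    # maprotiline
    "N06AX03": 2,    # mianserin
    "N06AX11": 63,   # mirtazapine
    "N06AG02": 2,    # moclobemide
    "N06AA10": 5,    # nortriptyline
    "N06AB05": 283,  # paroxetine
    "N06AB06": 59,   # sertraline
    "N06AF04": 1,    # tranylcypromine
    "N06AX05": 4,    # trazodone
    "N06AX02": 2,    # tryptophan
    "N06AX16": 114,  # venlafaxine
}

#: trajectory mixture of the realized study sample (maintained, switched,
#: discontinued counts 479/328/121 of 928)
DEFAULT_MIXTURE = (479 / 928, 328 / 928, 121 / 928)

#: per-item report probabilities by pharmacological category
DEFAULT_ASEC_PROBS = {
    "serotonergic": 0.15,
    "cholinergic": 0.15,
    "histaminergic": 0.15,
    "other": 0.10,  # dizziness
}


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_patients: int = 928
    allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_ALLELE_FREQS.items()}
    )
    trajectory_mixture: tuple[float, float, float] = DEFAULT_MIXTURE
    effect_log_or: dict[str, dict[str, float]] = field(default_factory=dict)
    asec_item_prob: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASEC_PROBS)
    )
    reason_probs: tuple[float, float, float] = (0.4, 0.25, 0.35)
    unknown_rate: float = 0.022
    assessed_prob: float = 1.0
    switch_gap_prob: float = 0.3
    ad_freqs: dict[str, int | float] = field(
        default_factory=lambda: dict(DEFAULT_AD_FREQS)
    )
    guideline: str = "DPWG"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for gene, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"{gene} allele frequencies sum to {total}, expected 1"
                )
        if not math.isclose(sum(self.trajectory_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("trajectory mixture must sum to 1")
        if any(p < 0 for p in self.trajectory_mixture):
            raise ValueError("trajectory mixture probabilities must be >= 0")
        if not math.isclose(sum(self.reason_probs), 1.0, abs_tol=1e-9):
            raise ValueError("reason probabilities must sum to 1")
        if not 0.0 <= self.unknown_rate <= 1.0:
            raise ValueError("unknown_rate must lie in [0, 1]")
        if not 0.0 < self.assessed_prob <= 1.0:
            raise ValueError("assessed_prob must lie in (0, 1]")
        Guideline(self.guideline)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["trajectory_mixture"] = list(self.trajectory_mixture)
        out["reason_probs"] = list(self.reason_probs)
        return out


def sample_diplotypes(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw HWE diplotypes for every patient and gene.

    Alleles are drawn independently within and across genes; quality_ok is
    set False with probability ``unknown_rate`` for CYP2D6 only.
    """
    n = config.n_patients
    patient_ids = [f"P{i:06d}" for i in range(n)]
    frames = []
    for gene in sorted(config.allele_freqs):
        freqs = config.allele_freqs[gene]
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        p = p / p.sum()
        draw = rng.choice(len(alleles), size=(n, 2), p=p)
        quality = np.ones(n, dtype=bool)
        if gene.upper() == "CYP2D6" and config.unknown_rate > 0:
            quality = rng.random(n) >= config.unknown_rate
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "gene": gene,
                    "allele1": [alleles[i] for i in draw[:, 0]],
                    "allele2": [alleles[i] for i in draw[:, 1]],
                    "quality_ok": quality,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _phenotype_groups(genotypes: pd.DataFrame, guideline: str) -> pd.DataFrame:
    """Collapsed analysis group per patient and gene from the raw alleles.

    Quality flags are ignored here: the tilt applied by the timeline
    simulator acts on the underlying biology, whereas the pipeline will
    exclude UNKNOWNs at analysis time.
    """
    cache: dict[tuple, str | None] = {}
    records: dict[str, dict[str, str | None]] = {}
    for row in genotypes.itertuples():
        gene = row.gene.upper()
        key = (gene, row.allele1, row.allele2)
        if key not in cache:
            status = classify_diplotype(
                Diplotype(gene, row.allele1, row.allele2, True),
                AlleleFunctionTable.default(gene),
                guideline,
            )
            cache[key] = collapse_groups(status, gene)
        records.setdefault(str(row.patient_id), {})[gene] = cache[key]
    return pd.DataFrame.from_dict(records, orient="index")


def _tilted_mixture(
    base: tuple[float, float, float],
    log_or_switch: float,
    log_or_disc: float,
) -> np.ndarray:
    """Tilt switch/discontinue odds against maintained by the given log-ORs.

    The switched-vs-maintained (and discontinued-vs-maintained) odds are
    multiplied by exp(log OR), so the conditional 2x2 odds ratio between a
    tilted group and the baseline group equals exp(log OR) exactly.
    """
    m, s, d = base
    odds_s = (s / m) * math.exp(log_or_switch)
    odds_d = (d / m) * math.exp(log_or_disc)
    total = 1.0 + odds_s + odds_d
    return np.array([1.0 / total, odds_s / total, odds_d / total])


_LABELS = ("MAINTAINED", "SWITCHED", "DISCONTINUED")


def simulate_timelines(
    config: CohortConfig,
    genotypes: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Realize per-period AD sets consistent with the trajectory definitions.

    Returns (medications, participation, truth) DataFrames; ``truth``
    records the intended label, index drug and start period per patient.

    * maintained: the index AD runs from its start period through period 11;
    * switched: the index AD runs to a uniformly chosen end in 1..9, then —
      optionally after an AD-free gap period — a different AD runs to 11;
    * discontinued: use starts and ends within periods 1..4.

    The per-patient mixture is tilted by ``effect_log_or`` according to the
    patient's collapsed phenotype groups for the enzymes the index AD is a
    substrate of (keys ``"ENZYME:GROUP"``, e.g. ``"CYP2D6:IM/PM"``, values
    ``{"switched": beta, "discontinued": beta}``).
    """
    substrate_table = default_substrate_table()
    groups = _phenotype_groups(genotypes, config.guideline)

    ads = sorted(config.ad_freqs)
    ad_p = np.array([config.ad_freqs[a] for a in ads], dtype=float)
    ad_p /= ad_p.sum()
    enzymes_of = {a: substrate_table.enzymes(a) for a in ads}

    patient_ids = groups.index.tolist()
    n = len(patient_ids)
    index_ads = rng.choice(len(ads), size=n, p=ad_p)

    # per-patient log-OR tilts from the enzymes the index AD is metabolized by
    betas = np.zeros((n, 2))
    if config.effect_log_or:
        by_gene = {gene: groups[gene].to_dict() for gene in groups.columns}
        for k, pid in enumerate(patient_ids):
            for enzyme in enzymes_of[ads[index_ads[k]]]:
                group = by_gene.get(enzyme, {}).get(pid)
                if group is None or (isinstance(group, float) and np.isnan(group)):
                    continue
                effect = config.effect_log_or.get(f"{enzyme}:{group}")
                if effect:
                    betas[k, 0] += effect.get("switched", 0.0)
                    betas[k, 1] += effect.get("discontinued", 0.0)

    # vectorized label draw: one uniform per patient against the cumulative
    # mixture of the patient's tilt stratum
    cum = np.empty((n, 3))
    for key in sorted({(b[0], b[1]) for b in betas}):
        mask = (betas[:, 0] == key[0]) & (betas[:, 1] == key[1])
        cum[mask] = np.cumsum(_tilted_mixture(config.trajectory_mixture, *key))
    u = rng.random(n)
    label_idx = (u[:, None] >= cum).sum(axis=1)  # 0=M, 1=S, 2=D

    def _uniform_int(low: np.ndarray, high: np.ndarray) -> np.ndarray:
        # inclusive bounds, elementwise
        return low + (rng.random(len(low)) * (high - low + 1)).astype(int)

    ones = np.ones(n, dtype=int)
    starts = np.zeros(n, dtype=int)
    ends = np.zeros(n, dtype=int)
    m_mask = label_idx == 0
    s_mask = label_idx == 1
    d_mask = label_idx == 2
    starts[m_mask] = _uniform_int(ones[m_mask], 10 * ones[m_mask])
    ends[m_mask] = N_PERIODS
    starts[d_mask] = _uniform_int(ones[d_mask], 4 * ones[d_mask])
    ends[d_mask] = _uniform_int(starts[d_mask], 4 * ones[d_mask])
    starts[s_mask] = _uniform_int(ones[s_mask], 8 * ones[s_mask])
    ends[s_mask] = _uniform_int(starts[s_mask], 9 * ones[s_mask])
    gaps = np.zeros(n, dtype=int)
    gaps[s_mask] = rng.random(int(s_mask.sum())) < config.switch_gap_prob

    # second drug for switchers: redraw until it differs from the index AD
    seconds = np.full(n, -1, dtype=int)
    pending = np.flatnonzero(s_mask)
    while len(pending):
        draw = rng.choice(len(ads), size=len(pending), p=ad_p)
        seconds[pending] = draw
        pending = pending[draw == index_ads[pending]]

    if config.assessed_prob >= 1.0:
        assessed_all = np.ones((n, N_PERIODS), dtype=bool)
    else:
        assessed_all = rng.random((n, N_PERIODS)) < config.assessed_prob
        assessed_all[:, 0] = True  # eligibility needs period 1 observed

    med_rows: list[tuple[str, int, str]] = []
    part_rows: list[tuple[str, int, bool]] = []
    truth_rows = []
    for k, pid in enumerate(patient_ids):
        index_ad = ads[index_ads[k]]
        label = _LABELS[label_idx[k]]
        use = {p: index_ad for p in range(starts[k], ends[k] + 1)}
        if label == "SWITCHED":
            second = ads[seconds[k]]
            use.update(
                {p: second for p in range(ends[k] + 1 + gaps[k], N_PERIODS + 1)}
            )
        assessed = assessed_all[k]
        for p in range(1, N_PERIODS + 1):
            part_rows.append((pid, p, bool(assessed[p - 1])))
            if assessed[p - 1] and p in use:
                med_rows.append((pid, p, use[p]))
        truth_rows.append(
            {"patient_id": pid, "label": label, "index_atc": index_ad,
             "start_period": int(starts[k])}
        )

    medications = pd.DataFrame(med_rows,
                               columns=["patient_id", "period", "atc"])
    participation = pd.DataFrame(part_rows,
                                 columns=["patient_id", "period", "assessed"])
    truth = pd.DataFrame(truth_rows)
    return medications, participation, truth


def _item_probabilities(config: CohortConfig) -> np.ndarray:
    by_cat = config.asec_item_prob
    if isinstance(by_cat, (int, float)):
        return np.full(12, float(by_cat))
    probs = np.full(12, float(by_cat.get("other", 0.0)))
    for cat in (SideEffectCategory.SEROTONERGIC, SideEffectCategory.CHOLINERGIC,
                SideEffectCategory.HISTAMINERGIC):
        for idx in _CATEGORY_ITEMS[cat]:
            probs[idx] = float(by_cat.get(cat.value, 0.0))
    return probs


def simulate_asec(
    config: CohortConfig,
    medications: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw ASEC-12 indicators for every patient-period-drug on record at
    the checklist periods, items independent with category-specific
    probabilities.  Output uses the canonical coding 1 = reported."""
    probs = _item_probabilities(config)
    rows = medications[medications["period"].isin(ASEC_PERIODS)]
    rows = rows.sort_values(["patient_id", "period", "atc"], kind="stable")
    items = (rng.random((len(rows), 12)) < probs).astype(int)
    out = rows.reset_index(drop=True).copy()
    for j, col in enumerate(ITEM_COLUMNS):
        out[col] = items[:, j]
    return out


def simulate_reasons(
    config: CohortConfig,
    medications: pd.DataFrame,
    participation: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a discontinuation reason for every switch/stop event at the
    visit transitions 5→6, 7→8 and 9→10."""
    sets: dict[str, dict[int, set[str]]] = {}
    for r in medications.itertuples():
        sets.setdefault(str(r.patient_id), {}).setdefault(int(r.period), set()).add(
            str(r.atc)
        )
    assessed = {
        (str(r.patient_id), int(r.period)): bool(r.assessed)
        for r in participation.itertuples()
    }
    reason_idx = np.arange(len(REASONS))
    probs = np.asarray(config.reason_probs, dtype=float)
    rows = []
    for pid in sorted(sets):
        for prev, cur in REASON_TRANSITIONS:
            if not (assessed.get((pid, prev)) and assessed.get((pid, cur))):
                continue
            before = sets[pid].get(prev, set())
            after = sets[pid].get(cur, set())
            stopped = (bool(before) and not after) or (
                bool(before) and bool(after) and not (before & after)
            )
            if not stopped:
                continue
            reason = REASONS[int(rng.choice(reason_idx, p=probs))]
            rows.append(
                {"patient_id": pid, "period": cur,
                 "atc": sorted(before)[0], "reason": reason}
            )
    return pd.DataFrame(rows, columns=["patient_id", "period", "atc", "reason"])


@dataclass
class Cohort:
    """Generated input tables plus the generating truth and provenance."""

    config: CohortConfig
    genotypes: pd.DataFrame
    medications: pd.DataFrame
    participation: pd.DataFrame
    asec: pd.DataFrame
    reasons: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(outdir / "genotypes.csv", index=False)
        self.medications.to_csv(outdir / "medications.csv", index=False)
        self.participation.to_csv(outdir / "participation.csv", index=False)
        self.asec.to_csv(outdir / "asec.csv", index=False)
        self.reasons.to_csv(outdir / "reasons.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        provenance = {"config": self.config.to_dict(), "seed": self.config.seed}
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort; ``seed`` overrides ``config.seed``."""
    config = config or CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    genotypes = sample_diplotypes(config, rng)
    medications, participation, truth = simulate_timelines(config, genotypes, rng)
    asec = simulate_asec(config, medications, rng)
    reasons = simulate_reasons(config, medications, participation, rng)
    return Cohort(config, genotypes, medications, participation, asec,
                  reasons, truth)
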