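"""Star-allele diplotype translation to CYP metabolizer phenotypes.

CYP2D6 and CYP2C19 haplotypes are conventionally named as *star alleles*
(*1, *2, *4, ...), each carrying a known functional class: fully functional,
reduced, inactive, or (CYP2C19 *17 only) increased.  A patient's diplotype —
the unordered pair of star alleles — determines the metabolizer phenotype:

* **CYP2D6** uses a gene-dose (activity-score) scheme: a fully functional
  allele contributes 1, a reduced allele 0.5 and an inactive allele 0.  The
  total dose is binned as PM (0), IM (0.5–1) and NM (1.5–2.5).
* **CYP2C19** uses combination rules: two inactive (or two reduced) alleles →
  PM; exactly one inactive/reduced allele → IM; two fully functional alleles,
  or one fully functional plus one increased allele → NM; two increased
  alleles → UM.  Under the CPIC convention the FULL/INCREASED combination
  (*1/*17) is instead classified UM; DPWG is the default.

Alleles that genotyping cannot resolve (the *5 whole-gene deletion,
duplications such as *1xN) are handled by two policies: ``paper_compat``
(default) maps any allele absent from the function table to *1 before
translation, which inflates NM at the expense of IM/PM/UM; ``strict``
translates such diplotypes to UNKNOWN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AlleleFunction",
    "AlleleFunctionTable",
    "Diplotype",
    "MetabolizerStatus",
    "Guideline",
    "AlleleLookupError",
    "DuplicateAlleleError",
    "UnsupportedDoseError",
    "InvalidDoseError",
    "load_allele_table",
    "gene_dose",
    "cyp2d6_status",
    "cyp2c19_status",
    "classify_diplotype",
    "assign_phenotypes",
]


class AlleleFunction(enum.Enum):
    """Functional class of a star allele."""

    FULL = "full"
    REDUCED = "reduced"
    INACTIVE = "inactive"
    INCREASED = "increased"

    @property
    def dose(self) -> float | None:
        """Gene-dose contribution; ``None`` for INCREASED (no dose defined)."""
        return _DOSES[self]


_DOSES = {
    AlleleFunction.FULL: 1.0,
    AlleleFunction.REDUCED: 0.5,
    AlleleFunction.INACTIVE: 0.0,
    AlleleFunction.INCREASED: None,
}


class MetabolizerStatus(enum.Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    UM = "UM"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Guideline(enum.Enum):
    """Phenotype-assignment convention; they differ only on CYP2C19 *1/*17."""

    DPWG = "DPWG"
    CPIC = "CPIC"


class AlleleLookupError(KeyError):
    """An allele is absent from the function table (strict mode)."""


class DuplicateAlleleError(ValueError):
    """The same star allele is defined twice for one gene."""


class UnsupportedDoseError(ValueError):
    """A dose was requested for an allele class without one (INCREASED)."""


class InvalidDoseError(ValueError):
    """A CYP2D6 gene dose outside the closed set of reachable values."""


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star alleles for one gene of one patient.

    ``quality_ok`` is False when imputation posterior probability did not
    exceed 0.9 for both alleles; such diplotypes translate to UNKNOWN.
    """

    gene: str
    allele1: str
    allele2: str
    quality_ok: bool = True

    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)


# defaults from the pharmacogenetic literature underlying the pipeline
_CYP2D6_DEFAULT = {
    "*1": AlleleFunction.FULL,
    "*2": AlleleFunction.FULL,
    "*3": AlleleFunction.INACTIVE,
    "*4": AlleleFunction.INACTIVE,
    "*6": AlleleFunction.INACTIVE,
    "*10": AlleleFunction.REDUCED,
    "*17": AlleleFunction.REDUCED,
    "*41": AlleleFunction.REDUCED,
}

_CYP2C19_DEFAULT = {
    "*1": AlleleFunction.FULL,
    "*2": AlleleFunction.INACTIVE,
    "*3": AlleleFunction.INACTIVE,
    "*17": AlleleFunction.INCREASED,
}


@dataclass
class AlleleFunctionTable:
    """Per-gene map from star-allele name to :class:`AlleleFunction`."""

    gene: str
    entries: dict[str, AlleleFunction] = field(default_factory=dict)

    @classmethod
    def cyp2d6_default(cls) -> "AlleleFunctionTable":
        return cls("CYP2D6", dict(_CYP2D6_DEFAULT))

    @classmethod
    def cyp2c19_default(cls) -> "AlleleFunctionTable":
        return cls("CYP2C19", dict(_CYP2C19_DEFAULT))

    @classmethod
    def default(cls, gene: str) -> "AlleleFunctionTable":
        gene = gene.upper()
        if gene == "CYP2D6":
            return cls.cyp2d6_default()
        if gene == "CYP2C19":
            return cls.cyp2c19_default()
        raise ValueError(f"no built-in allele table for gene {gene!r}")

    def add(self, allele: str, function: AlleleFunction) -> None:
        if allele in self.entries:
            raise DuplicateAlleleError(
                f"allele {allele} defined twice for {self.gene}"
            )
        self.entries[allele] = function

    def __contains__(self, allele: str) -> bool:
        return allele in self.entries

    def function(self, allele: str, mode: str = "paper_compat") -> AlleleFunction:
        """Look up an allele's functional class.

        In ``paper_compat`` mode an allele absent from the table (an
        unidentifiable *5 deletion or duplication call) is treated as *1.
        In ``strict`` mode the lookup raises :class:`AlleleLookupError`.
        """
        if allele in self.entries:
            return self.entries[allele]
        if mode == "paper_compat":
            try:
                return self.entries["*1"]
            except KeyError as exc:  # table without *1 cannot collapse
                raise AlleleLookupError(
                    f"{self.gene} table has no *1 to collapse {allele} onto"
                ) from exc
        if mode == "strict":
            raise AlleleLookupError(f"unknown {self.gene} allele {allele}")
        raise ValueError(f"unknown allele-collapse mode {mode!r}")


def load_allele_table(
    source, gene: str | None = None
) -> AlleleFunctionTable | dict[str, AlleleFunctionTable]:
    """Load allele function tables from a CSV with columns gene,allele,function.

    Function labels are the lower-case names full/reduced/inactive/increased.
    Returns a single table when ``gene`` is given, else a dict keyed by gene.
    Raises :class:`DuplicateAlleleError` on repeated alleles and ``ValueError``
    on unrecognized function labels.
    """
    df = pd.read_csv(source, dtype=str)
    required = {"gene", "allele", "function"}
    if not required.issubset(df.columns):
        raise ValueError(f"allele table needs columns {sorted(required)}")
    tables: dict[str, AlleleFunctionTable] = {}
    for row in df.itertuples(index=False):
        g = str(row.gene).upper()
        label = str(row.function).strip().lower()
        try:
            func = AlleleFunction(label)
        except ValueError:
            raise ValueError(
                f"unrecognized function label {row.function!r} for "
                f"{g} {row.allele}"
            ) from None
        tables.setdefault(g, AlleleFunctionTable(g)).add(str(row.allele), func)
    if gene is not None:
        gene = gene.upper()
        if gene not in tables:
            raise ValueError(f"gene {gene} not present in allele table source")
        return tables[gene]
    return tables


def gene_dose(
    diplotype: Diplotype,
    table: AlleleFunctionTable | None = None,
    mode: str = "paper_compat",
) -> float:
    """Total CYP2D6 gene dose (activity score) of a diplotype.

    Sums the per-allele doses (FULL 1, REDUCED 0.5, INACTIVE 0).  Raises
    :class:`UnsupportedDoseError` for alleles without a dose (INCREASED) and
    :class:`AlleleLookupError` for unknown alleles in strict mode.
    """
    if table is None:
        table = AlleleFunctionTable.default(diplotype.gene)
    total = 0.0
    for allele in diplotype.alleles():
        func = table.function(allele, mode=mode)
        if func.dose is None:
            raise UnsupportedDoseError(
                f"allele {allele} ({func.value}) carries no gene dose"
            )
        total += func.dose
    return total


#: gene doses reachable from two alleles weighted in {0, 0.5, 1}
_VALID_DOSES = {0.0: MetabolizerStatus.PM,
                0.5: MetabolizerStatus.IM,
                1.0: MetabolizerStatus.IM,
                1.5: MetabolizerStatus.NM,
                2.0: MetabolizerStatus.NM,
                2.5: MetabolizerStatus.NM}


def cyp2d6_status(dose: float) -> MetabolizerStatus:
    """Bin a CYP2D6 gene dose: 0 → PM, 0.5–1 → IM, 1.5–2.5 → NM.

    Doses outside the closed set of reachable values (e.g. 1.25) indicate a
    corrupt allele table and raise :class:`InvalidDoseError` rather than
    being binned silently.
    """
    status = _VALID_DOSES.get(float(dose))
    if status is None:
        raise InvalidDoseError(f"gene dose {dose} is not reachable from valid alleles")
    return status


_LOW = (AlleleFunction.INACTIVE, AlleleFunction.REDUCED)


def cyp2c19_status(
    diplotype: Diplotype,
    table: AlleleFunctionTable | None = None,
    guideline: Guideline | str = Guideline.DPWG,
    mode: str = "paper_compat",
) -> MetabolizerStatus:
    """CYP2C19 phenotype from allele-combination rules (DPWG or CPIC)."""
    if not diplotype.quality_ok:
        return MetabolizerStatus.UNKNOWN
    if table is None:
        table = AlleleFunctionTable.cyp2c19_default()
    guideline = Guideline(guideline) if not isinstance(guideline, Guideline) else guideline
    f1 = table.function(diplotype.allele1, mode=mode)
    f2 = table.function(diplotype.allele2, mode=mode)
    n_low = (f1 in _LOW) + (f2 in _LOW)
    if n_low == 2:
        return MetabolizerStatus.PM
    if n_low == 1:
        return MetabolizerStatus.IM
    funcs = {f1, f2}
    if funcs == {AlleleFunction.INCREASED}:
        return MetabolizerStatus.UM
    if funcs == {AlleleFunction.FULL, AlleleFunction.INCREASED}:
        return (MetabolizerStatus.UM if guideline is Guideline.CPIC
                else MetabolizerStatus.NM)
    # FULL/FULL
    return MetabolizerStatus.NM


def classify_diplotype(
    diplotype: Diplotype,
    table: AlleleFunctionTable | None = None,
    guideline: Guideline | str = Guideline.DPWG,
    mode: str = "paper_compat",
) -> MetabolizerStatus:
    """Translate one diplotype to a metabolizer status, any supported gene."""
    if not diplotype.quality_ok:
        return MetabolizerStatus.UNKNOWN
    gene = diplotype.gene.upper()
    if gene == "CYP2C19":
        return cyp2c19_status(diplotype, table, guideline, mode)
    if gene == "CYP2D6":
        if mode == "strict":
            tbl = table or AlleleFunctionTable.cyp2d6_default()
            if any(a not in tbl for a in diplotype.alleles()):
                return MetabolizerStatus.UNKNOWN
        return cyp2d6_status(gene_dose(diplotype, table, mode=mode))
    raise ValueError(f"unsupported gene {diplotype.gene!r}")


def assign_phenotypes(
    genotypes: pd.DataFrame | Iterable[Diplotype],
    guideline: Guideline | str = Guideline.DPWG,
    mode: str = "paper_compat",
    tables: Mapping[str, AlleleFunctionTable] | None = None,
) -> pd.DataFrame:
    """Translate a cohort's genotype records to a per-patient phenotype table.

    Parameters
    ----------
    genotypes
        DataFrame with columns patient_id, gene, allele1, allele2, quality_ok
        (the genotype CSV schema), or an iterable of :class:`Diplotype` with
        ``patient_id`` supplied via the DataFrame route only.
    guideline, mode
        Passed through to the per-diplotype translation.
    tables
        Optional per-gene override of the built-in allele function tables.

    Returns
    -------
    DataFrame indexed by patient_id with one column per gene (lower-case,
    e.g. ``cyp2d6``) holding :class:`MetabolizerStatus` values.

    Raises
    ------
    ValueError
        On duplicate (patient, gene) records.
    """
    if not isinstance(genotypes, pd.DataFrame):
        genotypes = pd.DataFrame(
            [
                {
                    "patient_id": i,
                    "gene": d.gene,
                    "allele1": d.allele1,
                    "allele2": d.allele2,
                    "quality_ok": d.quality_ok,
                }
                for i, d in enumerate(genotypes)
            ]
        )
    if genotypes.empty:
        return pd.DataFrame(index=pd.Index([], name="patient_id"))
    dup = genotypes.duplicated(subset=["patient_id", "gene"])
    if dup.any():
        bad = genotypes.loc[dup, ["patient_id", "gene"]].iloc[0]
        raise ValueError(
            f"duplicate genotype record for patient {bad.patient_id!r} "
            f"gene {bad.gene!r}"
        )

    # memoized per (gene, allele pair, quality) — cohorts repeat few diplotypes
    cache: dict[tuple, MetabolizerStatus] = {}

    def translate(row) -> MetabolizerStatus:
        key = (row.gene, row.allele1, row.allele2, bool(row.quality_ok))
        if key not in cache:
            table = tables.get(row.gene.upper()) if tables else None
            cache[key] = classify_diplotype(
                Diplotype(row.gene, row.allele1, row.allele2, bool(row.quality_ok)),
                table, guideline, mode,
            )
        return cache[key]

    out = genotypes.assign(status=[translate(r) for r in genotypes.itertuples()])
    wide = out.pivot(index="patient_id", columns="gene", values="status")
    wide.columns = [str(c).lower() for c in wide.columns]
    return wide


def status_counts(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Counts of each metabolizer status per gene column."""
    return pd.DataFrame(
        {col: phenotypes[col].value_counts() for col in phenotypes.columns}
    ).fillna(0).astype(int)
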