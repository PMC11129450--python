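"""ATC-code classification of antidepressants by CYP substrate status.

Antidepressants (WHO ATC group N06A) are classified as substrates of
CYP2C19 only, CYP2D6 only, both enzymes, or neither.  The default table is
shipped as packaged data (``data/substrates.csv``) so users can extend it;
the ATC code is the key and drug names are informational only.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "SubstrateClass",
    "SubstrateTable",
    "default_substrate_table",
    "substrate_class",
    "is_cyp2d6_substrate",
    "is_cyp2c19_substrate",
]

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class SubstrateClass(enum.Enum):
    CYP2C19_ONLY = "CYP2C19_ONLY"
    CYP2D6_ONLY = "CYP2D6_ONLY"
    BOTH = "BOTH"
    NEITHER = "NEITHER"

    @property
    def enzymes(self) -> frozenset[str]:
        return _ENZYMES[self]


_ENZYMES = {
    SubstrateClass.CYP2C19_ONLY: frozenset({"CYP2C19"}),
    SubstrateClass.CYP2D6_ONLY: frozenset({"CYP2D6"}),
    SubstrateClass.BOTH: frozenset({"CYP2C19", "CYP2D6"}),
    SubstrateClass.NEITHER: frozenset(),
}


def validate_atc(atc: str) -> str:
    atc = str(atc).strip().upper()
    if not _ATC_RE.match(atc):
        raise ValueError(f"malformed ATC code {atc!r}")
    return atc


@dataclass
class SubstrateTable:
    """Mapping from ATC code to substrate class; unknown codes are NEITHER."""

    entries: dict[str, SubstrateClass]
    names: dict[str, str]

    @classmethod
    def from_csv(cls, source) -> "SubstrateTable":
        df = pd.read_csv(source, dtype=str)
        required = {"atc", "substrate_class"}
        if not required.issubset(df.columns):
            raise ValueError(f"substrate table needs columns {sorted(required)}")
        entries: dict[str, SubstrateClass] = {}
        names: dict[str, str] = {}
        for row in df.itertuples(index=False):
            atc = validate_atc(row.atc)
            if atc in entries:
                raise ValueError(f"ATC {atc} listed twice in substrate table")
            entries[atc] = SubstrateClass(row.substrate_class)
            names[atc] = getattr(row, "name", "") or ""
        return cls(entries, names)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "atc": list(self.entries),
                "name": [self.names.get(a, "") for a in self.entries],
                "substrate_class": [c.value for c in self.entries.values()],
            }
        ).to_csv(path, index=False)

    def substrate_class(self, atc: str) -> SubstrateClass:
        return self.entries.get(validate_atc(atc), SubstrateClass.NEITHER)

    def enzymes(self, atc: str) -> frozenset[str]:
        return self.substrate_class(atc).enzymes

    def is_substrate(self, atc: str, enzyme: str) -> bool:
        return enzyme.upper() in self.enzymes(atc)

    def __len__(self) -> int:
        return len(self.entries)


_DEFAULT: SubstrateTable | None = None


def default_substrate_table() -> SubstrateTable:
    """The packaged 21-drug table (5 CYP2C19-only, 12 CYP2D6-only, 4 both)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("pgxtraj").joinpath("data/substrates.csv")
        with ref.open("r") as fh:
            _DEFAULT = SubstrateTable.from_csv(fh)
    return _DEFAULT


def substrate_class(atc: str, table: SubstrateTable | None = None) -> SubstrateClass:
    """Substrate class of an ATC code; codes outside the table are NEITHER."""
    return (table or default_substrate_table()).substrate_class(atc)


def is_cyp2d6_substrate(atc: str, table: SubstrateTable | None = None) -> bool:
    return (table or default_substrate_table()).is_substrate(atc, "CYP2D6")


def is_cyp2c19_substrate(atc: str, table: SubstrateTable | None = None) -> bool:
    return (table or default_substrate_table()).is_substrate(atc, "CYP2C19")
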