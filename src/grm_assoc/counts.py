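"""Genotype count tables and coding schemes for biallelic case/control data.

The sufficient statistic for every association test in this package is the
2x3 table of genotype counts (cases and controls over AA, Aa, aa), where
``a`` denotes the counted (effect) allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "Aa", "aa")

#: Genotype codes for the single-slope trend models and the two-term
#: general regression model: additive counts copies of the effect allele,
#: dominant/recessive collapse carrier status, and the dominance-deviation
#: term isolates the heterozygote departure from additivity.
CODING_SCHEMES: dict[str, tuple[float, float, float]] = {
    "additive": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
    "domdev": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class CodingScheme:
    """A named assignment of numeric codes to the (AA, Aa, aa) genotypes."""

    name: str
    codes: tuple[float, float, float]

    @classmethod
    def from_name(cls, name: str) -> "CodingScheme":
        try:
            return cls(name, CODING_SCHEMES[name])
        except KeyError:
            raise ValueError(
                f"unknown coding scheme {name!r}; expected one of {sorted(CODING_SCHEMES)}"
            ) from None


@dataclass(frozen=True)
class GenotypeCounts:
    """Case and control counts per genotype, ordered (AA, Aa, aa).

    Parameters
    ----------
    case_counts, control_counts
        Non-negative integer counts. At least one case and one control in
        total are required for any test to be attempted.
    """

    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self):
        cases = tuple(int(c) for c in self.case_counts)
        controls = tuple(int(c) for c in self.control_counts)
        if len(cases) != 3 or len(controls) != 3:
            raise ValueError("counts must have exactly three genotype classes")
        if any(c < 0 for c in cases + controls):
            raise ValueError("genotype counts must be non-negative")
        if sum(cases) < 1 or sum(controls) < 1:
            raise ValueError("need at least one case and one control")
        object.__setattr__(self, "case_counts", cases)
        object.__setattr__(self, "control_counts", controls)

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (cases_per_genotype, totals_per_genotype) as float arrays."""
        y = np.asarray(self.case_counts, dtype=float)
        n = y + np.asarray(self.control_counts, dtype=float)
        return y, n

    def flipped(self) -> "GenotypeCounts":
        """Counts with the effect allele re-oriented (AA <-> aa)."""
        return GenotypeCounts(self.case_counts[::-1], self.control_counts[::-1])

    def swapped_labels(self) -> "GenotypeCounts":
        """Counts with case and control labels exchanged."""
        return GenotypeCounts(self.control_counts, self.case_counts)


COUNTS_TSV_COLUMNS = [
    "snp_id",
    "case_AA",
    "case_Aa",
    "case_aa",
    "ctrl_AA",
    "ctrl_Aa",
    "ctrl_aa",
]


def read_counts_tsv(path) -> list[tuple[str, GenotypeCounts]]:
    """Read a tab-delimited per-SNP counts table.

    The file must carry the header ``snp_id case_AA case_Aa case_aa
    ctrl_AA ctrl_Aa ctrl_aa``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV is missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        counts = GenotypeCounts(
            (row.case_AA, row.case_Aa, row.case_aa),
            (row.ctrl_AA, row.ctrl_Aa, row.ctrl_aa),
        )
        out.append((str(row.snp_id), counts))
    return out


def write_counts_tsv(path, records: Iterable[tuple[str, GenotypeCounts]]) -> None:
    rows = [
        (snp_id, *c.case_counts, *c.control_counts) for snp_id, c in records
    ]
    pd.DataFrame(rows, columns=COUNTS_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
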