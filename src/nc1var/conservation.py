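"""Residue conservation from a six-chain alignment, and its link to damage.

The six human collagen IV alpha-chain NC1 domains are homologous; a
residue of the alpha-5 chain is called *conserved* when the aligned
column carries the identical amino acid in all six chains (a gap in any
chain makes the column non-conserved).  This module maps alignment
columns back to alpha-5 residue numbers, tests whether predicted
structural damage associates with conservation (Fisher's exact test on
the conserved x damaging 2x2 table), and recomputes the expected damage
spectrum over conserved residues only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from scipy import stats

from .enumeration import SNVariant
from .nullmodel import ContextRateTable, ExpectedSpectrum, expected_spectrum
from .structure import DamageReport


@dataclass(frozen=True)
class ConservationProfile:
    """Per-residue conserved flags for the target chain."""

    target_id: str
    conserved: Mapping[int, bool]          # residue number -> flag
    column_of_residue: Mapping[int, int]   # residue number -> alignment column

    @property
    def n_conserved(self) -> int:
        return sum(self.conserved.values())

    @property
    def n_residues(self) -> int:
        return len(self.conserved)

    def is_conserved(self, residue_number: int) -> bool:
        return self.conserved[residue_number]


def read_alignment(path: str | Path, fmt: str | None = None):
    """Read an aligned FASTA or Clustal file."""
    if fmt is None:
        text = Path(path).read_text()
        fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    return AlignIO.read(str(path), fmt)


def conserved_columns(
    alignment,
    target_chain_id: str,
    first_residue_number: int = 1,
) -> ConservationProfile:
    """Conservation flags for every target-chain residue in the alignment.

    A column is conserved when all sequences carry the same amino acid
    and none has a gap.  Columns where the target itself is gapped do not
    correspond to a target residue and are skipped.
    """
    ids = [rec.id for rec in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sequence IDs in alignment")
    if target_chain_id not in ids:
        raise KeyError(f"target chain {target_chain_id!r} not in alignment")
    target = next(rec for rec in alignment if rec.id == target_chain_id)

    conserved: dict[int, bool] = {}
    columns: dict[int, int] = {}
    residue = first_residue_number - 1
    for col in range(alignment.get_alignment_length()):
        t = target.seq[col]
        if t == "-":
            continue
        residue += 1
        states = {str(rec.seq[col]).upper() for rec in alignment}
        conserved[residue] = len(states) == 1 and "-" not in states
        columns[residue] = col
    return ConservationProfile(target_chain_id, conserved, columns)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows are groups, columns damaging/neutral."""

    a: int  # group 1, damaging
    b: int  # group 1, neutral
    c: int  # group 2, damaging
    d: int  # group 2, neutral

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    sidedness: str = "two-sided",
) -> float:
    """Exact hypergeometric p-value for a 2x2 contingency table."""
    if isinstance(table, ContingencyTable2x2):
        cells = table.as_list()
    else:
        cells = [list(map(int, row)) for row in table]
    (a, b), (c, d) = cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("empty margin: Fisher test undefined")
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(stats.fisher_exact(cells, alternative=sidedness)[1])


def conservation_damage_table(
    reports: Iterable[DamageReport],
    profile: ConservationProfile,
    *,
    exclude_cys: bool = False,
) -> tuple[ContingencyTable2x2, int]:
    """Build the conserved x damaging 2x2 over substitutions with data.

    Returns the table and the count of substitutions dropped because the
    profile does not cover their residue.
    """
    a = b = c = d = 0
    dropped = 0
    for r in reports:
        if not r.has_structural_data:
            continue
        if exclude_cys and r.substitution.ref_aa == "C":
            continue
        res = r.substitution.residue_number
        if res not in profile.conserved:
            dropped += 1
            continue
        if profile.is_conserved(res):
            if r.damaging:
                a += 1
            else:
                b += 1
        else:
            if r.damaging:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d), dropped


def conservation_damage_association(
    reports: Iterable[DamageReport],
    profile: ConservationProfile,
    *,
    exclude_cys: bool = False,
    sidedness: str = "two-sided",
) -> tuple[float, ContingencyTable2x2, int]:
    """Fisher test of damage against conservation over all substitutions."""
    table, dropped = conservation_damage_table(
        reports, profile, exclude_cys=exclude_cys
    )
    return fisher_exact(table, sidedness), table, dropped


def conserved_only_expectation(
    snv_reports: Sequence[tuple[SNVariant, DamageReport]],
    rates: ContextRateTable,
    profile: ConservationProfile,
) -> ExpectedSpectrum:
    """Expected damage spectrum restricted to conserved residues."""
    subset = [
        (snv, rep)
        for snv, rep in snv_reports
        if profile.conserved.get(snv.residue_number, False)
    ]
    if not subset:
        raise ValueError("no SNVs at conserved residues; spectrum undefined")
    return expected_spectrum(subset, rates)


def profile_to_frame(
    profile: ConservationProfile, residues: Mapping[int, str] | None = None
) -> pd.DataFrame:
    rows = [
        {
            "residue": res,
            "aa": (residues or {}).get(res, ""),
            "conserved": flag,
            "column": profile.column_of_residue[res],
        }
        for res, flag in sorted(profile.conserved.items())
    ]
    return pd.DataFrame(rows)
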