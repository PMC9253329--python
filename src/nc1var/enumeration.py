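"""Exhaustive single-nucleotide variant enumeration and splice filtering.

Every codon of a domain admits nine single-nucleotide substitutions
(3 positions x 3 alternate bases).  Enumeration calls each substitution's
consequence (missense / synonymous / nonsense), records the flanking CDS
bases (the context used by the neighbour-dependent substitution-rate
model), deduplicates missense changes to unique amino-acid substitutions
irrespective of the underlying DNA change, and applies a splice-score
exclusion rule: a variant within 3 bases of a canonical splice site is
excluded when its mutant splice score drops at least 15% below wild type.

The splice scorer is pluggable.  The built-in default is a log-odds
position-weight-matrix scorer over packaged donor (9-mer) and acceptor
(23-mer) base-frequency tables; precomputed wild-type/mutant score pairs
can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .reference import CodingSequence, DomainSpan, hgvs_protein_name

NUCLEOTIDES = ("A", "C", "G", "T")
CONSEQUENCES = ("missense", "synonymous", "nonsense")


@dataclass(frozen=True)
class SNVariant:
    """One candidate single-nucleotide substitution in a CDS."""

    codon_index: int
    codon_position: int  # 1..3
    ref_nt: str
    alt_nt: str
    residue_number: int
    ref_aa: str
    alt_aa: str
    consequence: str
    left_context: str
    right_context: str

    def __post_init__(self) -> None:
        if self.ref_nt == self.alt_nt:
            raise ValueError("ref and alt nucleotide identical")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def cds_position(self) -> int:
        """1-based position within the CDS (c. coordinate)."""
        return 3 * self.codon_index + self.codon_position

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.cds_position}{self.ref_nt}>{self.alt_nt}"

    @property
    def hgvs_p(self) -> str:
        if self.consequence == "synonymous":
            return f"p.(=)"
        alt = "*" if self.consequence == "nonsense" else self.alt_aa
        return hgvs_protein_name(self.ref_aa, self.residue_number, alt)

    @property
    def context(self) -> tuple[str, str, str, str]:
        """(left, ref, alt, right) key into a context rate table."""
        return (self.left_context, self.ref_nt, self.alt_nt, self.right_context)


@dataclass(frozen=True)
class AminoAcidSubstitution:
    """A unique amino-acid substitution with its producing SNVs."""

    residue_number: int
    ref_aa: str
    alt_aa: str
    producing_snvs: tuple[SNVariant, ...]

    def __post_init__(self) -> None:
        if not self.producing_snvs:
            raise ValueError("substitution must have at least one producing SNV")
        for v in self.producing_snvs:
            if (v.residue_number, v.ref_aa, v.alt_aa) != (
                self.residue_number,
                self.ref_aa,
                self.alt_aa,
            ):
                raise ValueError("producing SNV does not match substitution")

    @property
    def hgvs_p(self) -> str:
        return hgvs_protein_name(self.ref_aa, self.residue_number, self.alt_aa)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.residue_number, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class SpliceAssessment:
    """Outcome of the splice-score exclusion rule for one SNV."""

    variant: SNVariant
    distance_to_splice_site: int
    wt_score: float | None
    mut_score: float | None
    excluded: bool
    indeterminate: bool = False


def enumerate_snvs(cds: CodingSequence, span: DomainSpan) -> list[SNVariant]:
    """All 9 x n_codons substitutions over ``span``, consequences called.

    Contexts are the immediately adjacent CDS bases; the first and last
    base of the domain take their flank from the surrounding CDS, so the
    span must not abut the very ends of the coding sequence.
    """
    nt = cds.nucleotides
    out: list[SNVariant] = []
    for residue in span.residues():
        ci = cds.codon_index_of(residue)
        codon = cds.codon(ci)
        ref_aa = str(Seq(codon).translate())
        for pos in (1, 2, 3):
            cds_idx = 3 * ci + pos - 1  # 0-based CDS index
            if not 0 < cds_idx < len(nt) - 1:
                raise IndexError(
                    f"residue {residue} base {pos} lacks CDS flanking context"
                )
            ref = codon[pos - 1]
            for alt in NUCLEOTIDES:
                if alt == ref:
                    continue
                mutant = codon[: pos - 1] + alt + codon[pos:]
                alt_aa = str(Seq(mutant).translate())
                if alt_aa == ref_aa:
                    consequence = "synonymous"
                elif alt_aa == "*":
                    consequence = "nonsense"
                else:
                    consequence = "missense"
                out.append(
                    SNVariant(
                        codon_index=ci,
                        codon_position=pos,
                        ref_nt=ref,
                        alt_nt=alt,
                        residue_number=residue,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        consequence=consequence,
                        left_context=nt[cds_idx - 1],
                        right_context=nt[cds_idx + 1],
                    )
                )
    return out


def dedupe_missense(snvs: Iterable[SNVariant]) -> list[AminoAcidSubstitution]:
    """Group missense SNVs into unique amino-acid substitutions.

    The output has one record per (residue, ref, alt) triple; the
    producing SNVs partition the input.  Non-missense input is a contract
    violation.
    """
    groups: dict[tuple[int, str, str], list[SNVariant]] = {}
    for v in snvs:
        if v.consequence != "missense":
            raise ValueError(f"non-missense SNV passed to dedupe_missense: {v.hgvs_c}")
        groups.setdefault((v.residue_number, v.ref_aa, v.alt_aa), []).append(v)
    return [
        AminoAcidSubstitution(res, ref, alt, tuple(vs))
        for (res, ref, alt), vs in sorted(groups.items())
    ]


# ---------------------------------------------------------------------------
# Splice scoring


class PwmSpliceScorer:
    """Log-odds position-weight-matrix splice-site scorer.

    Scores a window against packaged donor (9-mer: exonic -3..-1, intronic
    +1..+6) or acceptor (23-mer: intronic -20..-1, exonic +1..+3) base
    frequencies: score = sum over positions of log2(f_base / 0.25).
    """

    def __init__(self, frequencies: pd.DataFrame):
        # rows: position (0-based), columns: A C G T frequencies
        freqs = frequencies[list(NUCLEOTIDES)].to_numpy(dtype=float)
        if (freqs <= 0).any():
            raise ValueError("PWM frequencies must be positive (use pseudocounts)")
        self._logodds = pd.DataFrame(
            [[math.log2(f / 0.25) for f in row] for row in freqs],
            columns=list(NUCLEOTIDES),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PwmSpliceScorer":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def packaged(cls, site: str) -> "PwmSpliceScorer":
        """Load the packaged donor or acceptor table."""
        if site not in ("donor", "acceptor"):
            raise ValueError("site must be 'donor' or 'acceptor'")
        ref = resources.files("nc1var") / "data" / "splice" / f"{site}_pwm.tsv"
        with resources.as_file(ref) as p:
            return cls.from_tsv(p)

    @property
    def width(self) -> int:
        return len(self._logodds)

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.width:
            raise ValueError(f"window must be {self.width} nt, got {len(window)}")
        return float(
            sum(self._logodds.at[i, b] for i, b in enumerate(window))
        )


def assess_splice(
    variant: SNVariant,
    site_distance: int,
    scorer: Callable[[SNVariant], tuple[float, float]] | None = None,
    *,
    wt_score: float | None = None,
    mut_score: float | None = None,
    drop_fraction: float = 0.15,
    max_distance: int = 3,
) -> SpliceAssessment:
    """Apply the splice-score exclusion rule to one variant.

    A variant is excluded when it lies within ``max_distance`` bases of a
    canonical splice site and the mutant score is at least
    ``drop_fraction`` lower than a strictly positive wild-type score.
    Variants farther away are never assessed; non-positive wild-type
    scores make the percentage drop undefined and flag the assessment
    indeterminate rather than excluding silently.
    """
    if site_distance > max_distance:
        return SpliceAssessment(variant, site_distance, None, None, excluded=False)
    if wt_score is None or mut_score is None:
        if scorer is None:
            raise ValueError("near-site variant needs a scorer or explicit scores")
        wt_score, mut_score = scorer(variant)
    if wt_score <= 0:
        return SpliceAssessment(
            variant, site_distance, wt_score, mut_score,
            excluded=False, indeterminate=True,
        )
    excluded = mut_score <= (1.0 - drop_fraction) * wt_score
    return SpliceAssessment(variant, site_distance, wt_score, mut_score, excluded)


def apply_exclusions(
    substitutions: Iterable[AminoAcidSubstitution],
    assessments: Iterable[SpliceAssessment],
) -> list[AminoAcidSubstitution]:
    """Drop splice-excluded producing SNVs; drop substitutions left empty.

    A substitution survives as long as at least one producing SNV is not
    splice-excluded; partial exclusion just trims its producing set.
    """
    excluded_keys = {
        (a.variant.codon_index, a.variant.codon_position, a.variant.alt_nt)
        for a in assessments
        if a.excluded
    }
    out: list[AminoAcidSubstitution] = []
    for sub in substitutions:
        kept = tuple(
            v
            for v in sub.producing_snvs
            if (v.codon_index, v.codon_position, v.alt_nt) not in excluded_keys
        )
        if kept:
            out.append(replace(sub, producing_snvs=kept))
    return out


# ---------------------------------------------------------------------------
# Exon-boundary sidecar annotation and tabular IO


def read_exon_boundaries(path: str | Path) -> list[dict]:
    """Read a sidecar TSV of exon boundaries in CDS coordinates.

    Columns: ``cds_position`` (1-based last/first exonic base), ``site``
    (donor or acceptor).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cds_position", "site"}
    if not required <= set(df.columns):
        raise ValueError(f"exon annotation needs columns {sorted(required)}")
    bad = set(df["site"]) - {"donor", "acceptor"}
    if bad:
        raise ValueError(f"unknown splice site type(s): {sorted(bad)}")
    return df.to_dict("records")


def distance_to_nearest_site(
    variant: SNVariant, boundaries: Sequence[Mapping]
) -> int:
    """Distance in bases from a variant to the nearest annotated boundary."""
    if not boundaries:
        return 10**9
    return min(abs(variant.cds_position - int(b["cds_position"])) for b in boundaries)


def variants_to_frame(snvs: Iterable[SNVariant]) -> pd.DataFrame:
    rows = [
        {
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "residue": v.residue_number,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "consequence": v.consequence,
            "left_context": v.left_context,
            "right_context": v.right_context,
        }
        for v in snvs
    ]
    return pd.DataFrame(rows)


def write_variant_table(snvs: Iterable[SNVariant], path: str | Path) -> None:
    variants_to_frame(snvs).to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort variant list (LOVD-like TSV).

    Accepts either an ``hgvs_p`` column or ``ref_aa``/``residue``/``alt_aa``
    columns, plus optional ``n_families``, ``label`` and ``source``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "hgvs_p" not in df.columns:
        needed = {"ref_aa", "residue", "alt_aa"}
        if not needed <= set(df.columns):
            raise ValueError("cohort table needs hgvs_p or ref_aa/residue/alt_aa")
        df["hgvs_p"] = [
            hgvs_protein_name(r.ref_aa, int(r.residue), r.alt_aa)
            for r in df.itertuples()
        ]
    if "n_families" not in df.columns:
        df["n_families"] = 1
    return df
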