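"""Reference sequences and the NC1 domain definition.

Collagen IV alpha chains consist of an N-terminal 7S domain, a long
collagenous (Gly-X-Y repeat) domain and a C-terminal non-collagenous NC1
domain.  This module represents coding and protein sequences, locates the
NC1 domain on a protein (the region starting immediately after the final
Gly-X-Y triplet and running to the C-terminus), and provides codon-level
access plus HGVS protein naming.

Residue numbering follows the protein isoform's own coordinates (for the
human alpha-5 chain, kidney isoform 2: e.g. Cys1482); the offset between
string index and residue number is an explicit field, never a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"


class NotCollagenLikeError(ValueError):
    """Raised when a protein contains no Gly-X-Y collagen repeat."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with explicit residue numbering.

    ``numbering_offset`` is added to the 1-based string position to obtain
    the residue number, so residue ``i`` (1-based) of ``residues`` is
    reported as residue ``i + numbering_offset``.
    """

    protein_id: str
    residues: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard amino acid code(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_number(self, index: int) -> int:
        """Residue number of the 0-based string index."""
        return index + 1 + self.numbering_offset

    def index_of(self, residue_number: int) -> int:
        idx = residue_number - 1 - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(f"residue {residue_number} outside {self.protein_id}")
        return idx

    def residue(self, residue_number: int) -> str:
        return self.residues[self.index_of(residue_number)]


@dataclass(frozen=True)
class DomainSpan:
    """Inclusive residue-number span of a protein domain."""

    start_residue: int
    end_residue: int
    label: str = "NC1"

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("span start must not exceed end")

    def __len__(self) -> int:
        return self.end_residue - self.start_residue + 1

    def __contains__(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue

    def residues(self) -> range:
        return range(self.start_residue, self.end_residue + 1)


@dataclass(frozen=True)
class CodingSequence:
    """A CDS with a codon-index-to-residue-number mapping.

    ``nucleotides`` is the spliced coding sequence (may include the stop
    codon).  ``codon_offset_to_protein`` maps 0-based codon index to the
    1-based residue number in isoform coordinates; codons without an entry
    (e.g. the stop codon) are carried but not addressable by residue.
    """

    transcript_id: str
    nucleotides: str
    codon_offset_to_protein: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if set(nt) - set("ACGT"):
            raise ValueError("CDS must contain only ACGT")
        mapping = dict(self.codon_offset_to_protein)
        if not mapping:
            mapping = {i: i + 1 for i in range(len(nt) // 3)}
        object.__setattr__(self, "codon_offset_to_protein", mapping)
        inv: dict[int, int] = {}
        for codon_idx, res in mapping.items():
            if not 0 <= codon_idx < len(nt) // 3:
                raise ValueError(f"codon index {codon_idx} outside CDS")
            if res in inv:
                raise ValueError(f"residue {res} mapped twice")
            inv[res] = codon_idx
        object.__setattr__(self, "_residue_to_codon", inv)

    @classmethod
    def from_cds(
        cls, transcript_id: str, nucleotides: str, first_residue_number: int = 1
    ) -> "CodingSequence":
        """Build from a plain CDS, numbering codons consecutively.

        A trailing stop codon, if present, is kept in the sequence but not
        mapped to a residue.
        """
        nt = nucleotides.upper()
        if len(nt) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if set(nt) - set("ACGT"):
            raise ValueError("CDS must contain only ACGT")
        n_codons = len(nt) // 3
        prot = str(Seq(nt).translate())
        if prot.endswith(STOP):
            n_codons -= 1
        mapping = {i: first_residue_number + i for i in range(n_codons)}
        return cls(transcript_id, nt, mapping)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, codon_index: int) -> str:
        return self.nucleotides[3 * codon_index : 3 * codon_index + 3]

    def codon_index_of(self, residue_number: int) -> int:
        try:
            return self._residue_to_codon[residue_number]  # type: ignore[attr-defined]
        except KeyError:
            raise IndexError(f"residue {residue_number} not mapped on {self.transcript_id}")

    def translate_codon(self, codon_index: int) -> str:
        return str(Seq(self.codon(codon_index)).translate())

    def protein(self, protein_id: str = "") -> ProteinSequence:
        """Translate all mapped codons into a ProteinSequence.

        Requires the mapped residues to be consecutively numbered.
        """
        items = sorted(self.codon_offset_to_protein.items(), key=lambda kv: kv[1])
        numbers = [res for _, res in items]
        if numbers != list(range(numbers[0], numbers[0] + len(numbers))):
            raise ValueError("mapped residues are not consecutive")
        aa = "".join(self.translate_codon(i) for i, _ in items)
        if STOP in aa:
            raise ValueError("internal stop codon in mapped region")
        return ProteinSequence(protein_id or self.transcript_id, aa, numbers[0] - 1)


def define_nc1_domain(protein: ProteinSequence) -> DomainSpan:
    """Locate the NC1 domain: everything after the final Gly-X-Y triplet.

    The final Gly-X-Y is detected as the C-terminal-most position carrying
    Gly in a sustained collagen repeat frame: the last index ``i`` with
    Gly at ``i``, ``i - 3`` and ``i - 6``.  Requiring three in-frame Gly
    keeps the detector robust both to interruptions earlier in the
    collagenous domain and to incidental Gly pairs spaced three apart
    inside the NC1 domain itself.  The domain runs from the residue three
    positions after that Gly (the first residue past the triplet) to the
    protein's final residue.
    """
    seq = protein.residues
    last_gly = None
    for i in range(len(seq) - 1, 5, -1):
        if seq[i] == "G" and seq[i - 3] == "G" and seq[i - 6] == "G":
            last_gly = i
            break
    if last_gly is None:
        raise NotCollagenLikeError(
            f"{protein.protein_id}: no Gly-X-Y collagen repeat found"
        )
    start_idx = last_gly + 3
    if start_idx >= len(seq):
        raise NotCollagenLikeError(
            f"{protein.protein_id}: no residues after the final Gly-X-Y"
        )
    return DomainSpan(
        start_residue=protein.residue_number(start_idx),
        end_residue=protein.residue_number(len(seq) - 1),
        label="NC1",
    )


def codon_at(cds: CodingSequence, residue_number: int) -> str:
    """Return the codon encoding ``residue_number`` (isoform coordinates)."""
    return cds.codon(cds.codon_index_of(residue_number))


def hgvs_protein_name(ref_aa: str, residue_number: int, alt_aa: str) -> str:
    """HGVS p. name with three-letter codes, e.g. ``p.Cys1482Gly``."""
    ref_aa, alt_aa = ref_aa.upper(), alt_aa.upper()
    for aa in (ref_aa, alt_aa):
        if aa not in STANDARD_AA and aa != STOP:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    if ref_aa == alt_aa:
        raise ValueError("synonymous change is not nameable as missense")
    alt3 = "Ter" if alt_aa == STOP else seq3(alt_aa)
    return f"p.{seq3(ref_aa)}{residue_number}{alt3}"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into {record id: upper-case sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def protein_from_fasta(
    path: str | Path, protein_id: str, numbering_offset: int = 0
) -> ProteinSequence:
    records = read_fasta(path)
    if protein_id not in records:
        raise KeyError(f"{protein_id} not found in {path}")
    return ProteinSequence(protein_id, records[protein_id], numbering_offset)


def cds_from_fasta(
    path: str | Path, transcript_id: str, first_residue_number: int = 1
) -> CodingSequence:
    records = read_fasta(path)
    if transcript_id not in records:
        raise KeyError(f"{transcript_id} not found in {path}")
    return CodingSequence.from_cds(transcript_id, records[transcript_id], first_residue_number)
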