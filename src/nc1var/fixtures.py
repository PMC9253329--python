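"""Packaged curated-variant tables and their tallies.

The published database surveys of the collagen IV alpha-5 NC1 domain
(Cys substitutions, buried/non-buried Gly substitutions, observed versus
expected structural-damage counts, and family-level kidney-failure
summaries) are packaged as versioned TSV fixtures with pinned checksums.
They are inputs: the statistical machinery reproduces the published
inferences from these counts, while the database-dependent counts
themselves are curated, not recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

TABLE_FILES = {
    "T1": "cys_variants.tsv",
    "T2": "kidney_failure_summary.tsv",
    "T3a": "damage_vs_expected.tsv",
    "T3b": "damage_vs_expected.tsv",
    "T4": "gly_variants.tsv",
}
ALIASES = {
    "cys_variants": "T1",
    "kidney_failure_summary": "T2",
    "damage_vs_expected_all": "T3a",
    "damage_vs_expected_noncys": "T3b",
    "gly_variants": "T4",
}


@dataclass(frozen=True)
class PaperFixture:
    """One curated table, parsed and checksum-verified."""

    table_id: str
    rows: pd.DataFrame
    sha256: str


def _fixture_bytes(filename: str) -> bytes:
    ref = resources.files("nc1var") / "data" / "fixtures" / filename
    return ref.read_bytes()


def _checksums() -> dict[str, str]:
    ref = resources.files("nc1var") / "data" / "fixtures" / "checksums.json"
    return json.loads(ref.read_text())


def load_paper_fixture(table_id: str, verify: bool = True) -> PaperFixture:
    """Load a curated table by id (T1, T2, T3a, T3b, T4 or long alias)."""
    table_id = ALIASES.get(table_id, table_id)
    if table_id not in TABLE_FILES:
        raise KeyError(f"unknown fixture table {table_id!r}")
    filename = TABLE_FILES[table_id]
    raw = _fixture_bytes(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if verify:
        expected = _checksums()[filename]
        if digest != expected:
            raise ValueError(
                f"fixture {filename} checksum mismatch: {digest} != {expected}"
            )
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t", comment="#")
    if table_id == "T3a":
        df = df[df["cohort"] == "all"].reset_index(drop=True)
    elif table_id == "T3b":
        df = df[df["cohort"] == "noncys"].reset_index(drop=True)
    return PaperFixture(table_id, df, digest)


REAL_CDS_ACCESSION = "NM_033380.3"


def real_cds_path():
    """Packaged slot for the real COL4A5 transcript CDS (user-supplied).

    The kidney isoform-2 coding sequence is not redistributed with the
    package; place a single-record FASTA named ``NM_033380.3.fasta``
    (record id ``NM_033380.3``, CDS only, starting at the initiator ATG)
    under ``nc1var/data/reference/`` to enable analyses of the real gene.
    """
    return resources.files("nc1var") / "data" / "reference" / f"{REAL_CDS_ACCESSION}.fasta"


def load_real_cds():
    """Load the real COL4A5 CDS from the fixture slot, if supplied."""
    from .reference import CodingSequence, read_fasta

    ref = real_cds_path()
    try:
        with resources.as_file(ref) as path:
            if not path.exists():
                raise FileNotFoundError
            records = read_fasta(path)
    except FileNotFoundError:
        raise FileNotFoundError(
            f"real CDS not present: supply {REAL_CDS_ACCESSION}.fasta under "
            "nc1var/data/reference/ (download from NCBI; it is not "
            "redistributed with the package)"
        )
    return CodingSequence.from_cds(REAL_CDS_ACCESSION, records[REAL_CDS_ACCESSION])


def cys_lovd_tally() -> tuple[int, int]:
    """(unique Cys substitutions, families) in the LOVD column."""
    df = load_paper_fixture("T1").rows
    lovd = df[df["db"] == "LOVD"]
    return len(lovd), int(lovd["n_families"].sum())


def buried_gly_lovd_tally() -> tuple[int, int]:
    """(unique buried-Gly substitutions, families) in the LOVD column."""
    df = load_paper_fixture("T4").rows
    sel = df[(df["db"] == "LOVD") & (df["buried"] == "yes")]
    return len(sel), int(sel["n_families"].sum())


def damage_comparison_inputs(cohort: str = "all") -> pd.DataFrame:
    """Observed counts + expected fractions for the enrichment tests.

    Returns the T3 rows for ``cohort`` ("all" or "noncys") with the
    expected percentage converted to a fraction.
    """
    table_id = "T3a" if cohort == "all" else "T3b"
    df = load_paper_fixture(table_id).rows.copy()
    df["expected_p"] = df["expected_pct"] / 100.0
    return df
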