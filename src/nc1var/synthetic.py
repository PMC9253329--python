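"""Synthetic NC1-like domains, cohorts and clinical records.

The generators produce every input the pipeline consumes, with known
ground truth: a 231-residue NC1-like domain carrying 12 Cys residues
paired into 6 intrachain disulphides and 4 buried Gly residues (the
hallmark composition of a collagen IV NC1 domain), a deterministic
back-translated CDS embedded after a Gly-X-Y collagenous stretch, a 3D
model that places designated residues below the burial threshold and
Cys sulphurs within bonding distance, a six-chain alignment with a
designated set of fully conserved columns, pathogenic-database-like and
population-database-like variant cohorts, and family-structured
time-to-kidney-failure records.

The synthetic structure is a compact lattice ball, not a physically
realistic NC1 fold: only burial, bonding and distances matter to the
classification rules.  The default landmark positions (Cys at 1482 ...
1687, buried Gly at 1492, 1510, 1602, 1624) mirror the human alpha-5
chain's isoform-2 numbering so that fixtures and synthetic data share a
coordinate system.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enumeration import AminoAcidSubstitution, enumerate_snvs, dedupe_missense
from .reference import CodingSequence, DomainSpan, ProteinSequence, define_nc1_domain
from .structure import (
    AA1_TO_3,
    Atom,
    DamageReport,
    StructureModel,
)

CYS_POSITIONS = (1482, 1515, 1527, 1533, 1570, 1573, 1592, 1626, 1638, 1644, 1684, 1687)
DISULPHIDE_PAIRS = (
    (1482, 1515), (1527, 1533), (1570, 1573),
    (1592, 1626), (1638, 1644), (1684, 1687),
)
BURIED_GLY = (1492, 1510, 1602, 1624)
EXPOSED_GLY = (1467, 1485, 1500, 1506, 1513, 1560, 1595, 1612, 1615, 1617, 1640, 1642, 1675)

# codon choices for deterministic back-translation
CODONS_FOR = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTG", "TTA"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "AGA"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC", "ACA"],
    "V": ["GTT", "GTC", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}
FILLER_AA = "ADEFHIKLMNPQRSTVWY"  # everything except Gly and Cys


@dataclass(frozen=True)
class SyntheticDomainSpec:
    """Composition and geometry targets for a synthetic NC1-like domain."""

    n_residues: int = 231
    domain_start: int = 1457
    cys_positions: tuple[int, ...] = CYS_POSITIONS
    disulphide_pairs: tuple[tuple[int, int], ...] = DISULPHIDE_PAIRS
    buried_gly_positions: tuple[int, ...] = BURIED_GLY
    exposed_gly_positions: tuple[int, ...] = EXPOSED_GLY
    buried_fraction: float = 0.2     # target fraction of interior residues
    n_conserved: int = 105
    n_collagen_repeats: int = 8      # Gly-X-Y triplets preceding the domain
    lattice_spacing: float = 4.6     # A between residue sites
    n_unresolved_terminal: int = 0   # residues stripped of side chains
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cys_positions) % 2 != 0:
            raise ValueError("Cys count must be even (disulphide pairing)")
        span = range(self.domain_start, self.domain_start + self.n_residues)
        special = (
            list(self.cys_positions)
            + list(self.buried_gly_positions)
            + list(self.exposed_gly_positions)
        )
        if len(set(special)) != len(special):
            raise ValueError("special positions overlap")
        if any(p not in span for p in special):
            raise ValueError("special position outside the domain")
        paired = sorted(itertools.chain.from_iterable(self.disulphide_pairs))
        if paired != sorted(self.cys_positions):
            raise ValueError("disulphide pairs must cover all Cys exactly once")

    @property
    def domain_end(self) -> int:
        return self.domain_start + self.n_residues - 1


@dataclass
class SyntheticDomain:
    """All generated artifacts for one synthetic domain."""

    spec: SyntheticDomainSpec
    protein: ProteinSequence          # full gene product (collagenous + NC1)
    domain_protein: ProteinSequence   # NC1 region only
    cds: CodingSequence
    span: DomainSpan
    structure: StructureModel
    alignment: MultipleSeqAlignment
    conserved_positions: frozenset[int]


def _domain_sequence(spec: SyntheticDomainSpec, rng: np.random.Generator) -> str:
    aa = []
    for res in range(spec.domain_start, spec.domain_end + 1):
        if res in spec.cys_positions:
            aa.append("C")
        elif res in spec.buried_gly_positions or res in spec.exposed_gly_positions:
            aa.append("G")
        else:
            aa.append(FILLER_AA[rng.integers(len(FILLER_AA))])
    return "".join(aa)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(CODONS_FOR[aa][rng.integers(len(CODONS_FOR[aa]))] for aa in protein)


def _lattice_sites(n: int, spacing: float) -> np.ndarray:
    """Residue sites of a three-layer lattice slab, ordered inside-out.

    The slab is three stacked square-lattice discs with identical (x, y)
    footprints; the middle layer's inner sites are occluded from above,
    below and laterally (buried), while both face layers and the rim stay
    solvent-exposed.  A compact ball would bury roughly half the residues
    of a 231-residue domain; the slab keeps the buried fraction near the
    ~20-25% typical of a globular domain this size.  The returned order
    is: middle layer by increasing lateral radius, then the face layers
    by decreasing lateral radius (most exposed last).
    """
    per_layer = n // 3
    n_mid = per_layer + (n - 3 * per_layer)  # remainder joins the middle
    k = 1
    while (2 * k + 1) ** 2 < per_layer + 4:
        k += 1
    grid = np.array(
        [(x, y) for x in range(-k, k + 1) for y in range(-k, k + 1)], dtype=float
    )
    order = np.lexsort((grid[:, 1], grid[:, 0], (grid ** 2).sum(axis=1)))
    grid = grid[order]
    footprint = grid[: max(per_layer, n_mid)]
    mid = np.column_stack([footprint[:n_mid] * spacing, np.zeros(n_mid)])
    top = np.column_stack(
        [footprint[:per_layer] * spacing, np.full(per_layer, spacing)]
    )[::-1]
    bottom = np.column_stack(
        [footprint[:per_layer] * spacing, np.full(per_layer, -spacing)]
    )[::-1]
    # interleave the two face layers, outermost first overall at the end
    faces = np.empty((len(top) + len(bottom), 3))
    faces[0::2] = bottom
    faces[1::2] = top
    return np.vstack([mid, faces[::-1]])


def _build_structure(
    spec: SyntheticDomainSpec, domain_seq: str, rng: np.random.Generator
) -> StructureModel:
    residues = list(range(spec.domain_start, spec.domain_end + 1))
    spacing = spec.lattice_spacing
    sites = _lattice_sites(len(residues), spacing)  # sorted inside-out
    n_sites = len(sites)
    used = np.zeros(n_sites, dtype=bool)
    site_of: dict[int, np.ndarray] = {}

    # each disulphide pair occupies one lattice edge (adjacent inner sites)
    # with pair midpoints kept apart so SG atoms cannot cross-pair
    midpoints: list[np.ndarray] = []
    inner_pool = min(n_sites, 4 * len(spec.disulphide_pairs) + 24)
    for p, q in spec.disulphide_pairs:
        placedpair = False
        for i in range(inner_pool):
            if used[i] or placedpair:
                continue
            for j in range(i + 1, inner_pool):
                if used[j]:
                    continue
                d = np.linalg.norm(sites[i] - sites[j])
                if d > 1.01 * spacing:
                    continue
                mid = (sites[i] + sites[j]) / 2.0
                if any(np.linalg.norm(mid - m) < 0.9 * spacing for m in midpoints):
                    continue
                site_of[p], site_of[q] = sites[i], sites[j]
                used[i] = used[j] = True
                midpoints.append(mid)
                placedpair = True
                break
        if not placedpair:
            raise ValueError(
                "infeasible geometry: cannot place all disulphide pairs "
                "on separated inner lattice edges"
            )

    # buried Gly, then extra interior residues up to the burial target
    n_buried_target = int(round(spec.buried_fraction * spec.n_residues))
    extra_buried = max(0, n_buried_target - len(spec.cys_positions) - len(spec.buried_gly_positions))
    exposed_set = set(spec.exposed_gly_positions)
    fillers = [
        r
        for r in residues
        if r not in site_of
        and r not in spec.buried_gly_positions
        and r not in exposed_set
    ]
    interior_queue = list(spec.buried_gly_positions) + fillers[:extra_buried]
    remaining = fillers[extra_buried:] + sorted(exposed_set)  # exposed Gly outermost
    free_sites = [i for i in range(n_sites) if not used[i]]
    for res, i in zip(interior_queue + remaining, free_sites):
        site_of[res] = sites[i]
    if len(site_of) != len(residues):
        raise RuntimeError("placement bookkeeping error")

    atoms: list[Atom] = []
    sg_positions: dict[int, np.ndarray] = {}
    # disulphide SG atoms sit midway between the partners' sites
    for p, q in spec.disulphide_pairs:
        sp, sq = site_of[p], site_of[q]
        mid = (sp + sq) / 2.0
        w = sq - sp
        w = w / np.linalg.norm(w)
        sg_positions[p] = mid - 1.025 * w
        sg_positions[q] = mid + 1.025 * w

    n_res = len(residues)
    for res in residues:
        aa = domain_seq[res - spec.domain_start]
        p = site_of[res]
        radial = p / np.linalg.norm(p) if np.linalg.norm(p) > 1e-9 else np.array([0.0, 0.0, 1.0])
        # local frame: two fixed unit vectors orthogonal-ish to radial
        t1 = np.cross(radial, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(radial, [0.0, 1.0, 0.0])
        t1 = t1 / np.linalg.norm(t1)
        t2 = np.cross(radial, t1)
        name3 = AA1_TO_3[aa]
        unresolved = res > spec.domain_end - spec.n_unresolved_terminal
        atoms.append(Atom(res, name3, "N", *(p - 1.45 * t1)))
        atoms.append(Atom(res, name3, "CA", *p))
        atoms.append(Atom(res, name3, "C", *(p + 1.52 * t1)))
        atoms.append(Atom(res, name3, "O", *(p + 1.52 * t1 + 1.23 * t2)))
        if aa != "G" and not unresolved:
            if res in sg_positions:
                sg = sg_positions[res]
                cb = p + 1.5 * (sg - p) / np.linalg.norm(sg - p)
                atoms.append(Atom(res, name3, "CB", *cb))
                atoms.append(Atom(res, name3, "SG", *sg, element="S"))
            else:
                atoms.append(Atom(res, name3, "CB", *(p + 1.53 * radial)))
    return StructureModel(atoms, chain_id="A", note="synthetic NC1-like lattice model")


def _build_alignment(
    spec: SyntheticDomainSpec,
    domain_seq: str,
    rng: np.random.Generator,
) -> tuple[MultipleSeqAlignment, frozenset[int]]:
    residues = list(range(spec.domain_start, spec.domain_end + 1))
    must_conserve = set(spec.cys_positions) | set(spec.buried_gly_positions)
    if spec.n_conserved < len(must_conserve):
        raise ValueError("n_conserved smaller than the landmark residue count")
    free = [r for r in residues if r not in must_conserve]
    extra = rng.choice(len(free), size=spec.n_conserved - len(must_conserve), replace=False)
    conserved = must_conserve | {free[i] for i in extra}

    chains = {"alpha5_NC1": domain_seq}
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for other in ("alpha1_NC1", "alpha2_NC1", "alpha3_NC1", "alpha4_NC1", "alpha6_NC1"):
        seq = list(domain_seq)
        for i, res in enumerate(residues):
            if res in conserved:
                continue
            # mutate with probability 1/2 per chain; guaranteed below
            if rng.random() < 0.5:
                choices = alphabet.replace(seq[i], "")
                seq[i] = choices[rng.integers(len(choices))]
        chains[other] = "".join(seq)
    # guarantee every non-conserved column differs somewhere
    for i, res in enumerate(residues):
        if res in conserved:
            continue
        col = {chains[c][i] for c in chains}
        if len(col) == 1:
            s = list(chains["alpha1_NC1"])
            choices = alphabet.replace(s[i], "")
            s[i] = choices[rng.integers(len(choices))]
            chains["alpha1_NC1"] = "".join(s)
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in chains.items()]
    )
    return msa, frozenset(conserved)


def generate_domain(spec: SyntheticDomainSpec = SyntheticDomainSpec()) -> SyntheticDomain:
    """Generate protein, CDS, structure and alignment for one domain spec.

    Deterministic under ``spec.seed``: two calls with the same spec are
    byte-for-byte identical.
    """
    rng = np.random.default_rng(spec.seed)
    domain_seq = _domain_sequence(spec, rng)
    full_seq = "M" + "GPP" * spec.n_collagen_repeats + domain_seq
    offset = spec.domain_start - (2 + 3 * spec.n_collagen_repeats)
    protein = ProteinSequence("synthetic_gene", full_seq, numbering_offset=offset)
    span = define_nc1_domain(protein)
    if (span.start_residue, span.end_residue) != (spec.domain_start, spec.domain_end):
        raise RuntimeError("generated domain span does not match the spec")
    cds_nt = _back_translate(full_seq, rng) + "TAA"
    mapping = {i: protein.residue_number(i) for i in range(len(full_seq))}
    cds = CodingSequence("synthetic_tx", cds_nt, mapping)
    structure = _build_structure(spec, domain_seq, rng)
    msa, conserved = _build_alignment(spec, domain_seq, rng)
    domain_protein = ProteinSequence(
        "alpha5_NC1", domain_seq, numbering_offset=spec.domain_start - 1
    )
    return SyntheticDomain(
        spec=spec,
        protein=protein,
        domain_protein=domain_protein,
        cds=cds,
        span=span,
        structure=structure,
        alignment=msa,
        conserved_positions=conserved,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Sampling model for a variant cohort.

    ``damaging_enrichment`` multiplies the sampling odds of structurally
    damaging substitutions.  With the default domain's ~25% damaging
    base, 3.0 yields a pathogenic-database-like cohort (about half
    damaging), 0.4 a population-database-like cohort (about 12%), and
    1.0 a null cohort matching the unweighted base rate.
    """

    n_variants: int = 86
    damaging_enrichment: float = 3.0
    label_noise: float = 0.05
    source: str = "synthetic_cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.damaging_enrichment <= 0:
            raise ValueError("enrichment must be positive")

    @classmethod
    def pathogenic_like(cls, n_variants: int = 86, seed: int = 0) -> "CohortSpec":
        return cls(n_variants=n_variants, damaging_enrichment=3.0,
                   source="synthetic_lovd_like", seed=seed)

    @classmethod
    def population_like(cls, n_variants: int = 68, seed: int = 0) -> "CohortSpec":
        return cls(n_variants=n_variants, damaging_enrichment=0.4,
                   source="synthetic_gnomad_like", seed=seed)


def generate_cohort(
    reports: Sequence[DamageReport],
    spec: CohortSpec,
) -> pd.DataFrame:
    """Sample unique substitutions into a database-like cohort table.

    Substitutions are drawn without replacement with probability
    proportional to (enrichment if damaging else 1); only substitutions
    with structural data are eligible.  Labels correlate with damage
    status, flipped with probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    eligible = [r for r in reports if r.has_structural_data]
    if spec.n_variants > len(eligible):
        raise ValueError(
            f"requested {spec.n_variants} unique variants, only {len(eligible)} exist"
        )
    weights = np.array(
        [spec.damaging_enrichment if r.damaging else 1.0 for r in eligible]
    )
    idx = rng.choice(
        len(eligible), size=spec.n_variants, replace=False, p=weights / weights.sum()
    )
    rows = []
    for i in sorted(idx):
        r = eligible[i]
        damaging = r.damaging
        if rng.random() < spec.label_noise:
            damaging = not damaging
        label = ("P" if rng.random() < 0.5 else "LP") if damaging else (
            "B" if rng.random() < 0.5 else "LB"
        )
        rows.append(
            {
                "hgvs_p": r.substitution.hgvs_p,
                "residue": r.substitution.residue_number,
                "ref_aa": r.substitution.ref_aa,
                "alt_aa": r.substitution.alt_aa,
                "n_families": 1 + int(rng.poisson(0.7)),
                "label": label,
                "source": spec.source,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical records


@dataclass(frozen=True)
class ClinicalSpec:
    """Family-structured time-to-kidney-failure simulation.

    Event ages are Weibull with the target median (shape 2.5, a
    realistic spread for age-at-kidney-failure); censoring is by an
    independent uniform review age calibrated to the requested fraction.
    """

    n_families: int = 200
    target_median: float = 31.0
    censoring: float = 0.3
    weibull_shape: float = 4.0
    range_fraction: float = 0.05     # families reporting an age range
    female_only_fraction: float = 0.05
    mosaic_fraction: float = 0.01
    family_size_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)  # 1/2/3 males
    group: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring <= 1.0:
            raise ValueError("censoring fraction must be within [0, 1]")
        if self.n_families < 1:
            raise ValueError("need at least one family")


def generate_clinical(spec: ClinicalSpec) -> pd.DataFrame:
    """Individual-level clinical TSV rows for a synthetic cohort."""
    import math

    rng = np.random.default_rng(spec.seed)
    k = spec.weibull_shape
    scale = spec.target_median / (math.log(2.0) ** (1.0 / k))
    mean_t = scale * math.gamma(1.0 + 1.0 / k)
    rows = []
    for f in range(spec.n_families):
        fam = f"{spec.group}_F{f:04d}"
        if rng.random() < spec.female_only_fraction:
            rows.append(
                {
                    "family_id": fam, "individual_id": f"{fam}_1", "sex": "F",
                    "kf_flag": True, "kf_age": round(float(scale * rng.weibull(k)), 1),
                    "kf_age_range": "", "last_review_age": None,
                    "mosaic_flag": False, "extra_variant_flag": False,
                    "group": spec.group,
                }
            )
            continue
        n_males = int(rng.choice([1, 2, 3], p=list(spec.family_size_probs)))
        for j in range(n_males):
            t = float(scale * rng.weibull(k))
            t = max(t, 1.0)
            if spec.censoring >= 1.0:
                censored = True
                review = round(0.9 * t, 1)
            else:
                # independent uniform review age tuned to the target fraction
                upper = 5.0 + max(mean_t - 5.0, 1.0) / max(spec.censoring, 1e-9)
                c = float(rng.uniform(5.0, upper))
                censored = c < t
                review = round(c, 1)
            mosaic = bool(rng.random() < spec.mosaic_fraction)
            use_range = (not censored) and rng.random() < spec.range_fraction
            rows.append(
                {
                    "family_id": fam,
                    "individual_id": f"{fam}_{j + 1}",
                    "sex": "M",
                    "kf_flag": not censored,
                    "kf_age": None if (censored or use_range) else round(t, 1),
                    "kf_age_range": (
                        f"{max(round(t) - 3, 1)}-{round(t) + 3}" if use_range else ""
                    ),
                    "last_review_age": review if censored else None,
                    "mosaic_flag": mosaic,
                    "extra_variant_flag": False,
                    "group": spec.group,
                }
            )
    return pd.DataFrame(rows)


def clinical_frame_to_records(df: pd.DataFrame):
    """Convert a generated clinical frame to IndividualRecord objects."""
    from .clinical import IndividualRecord

    records = []
    for row in df.itertuples():
        rng_field = row.kf_age_range if isinstance(row.kf_age_range, str) else ""
        age_range = None
        if rng_field.strip():
            lo, hi = (float(x) for x in rng_field.split("-"))
            age_range = (lo, hi)
        records.append(
            IndividualRecord(
                family_id=row.family_id,
                sex=row.sex,
                kidney_failure=bool(row.kf_flag),
                age_at_kf=None if pd.isna(row.kf_age) else float(row.kf_age),
                age_range=age_range,
                age_last_review=(
                    None if pd.isna(row.last_review_age) else float(row.last_review_age)
                ),
                mosaic=bool(row.mosaic_flag),
                extra_pathogenic_variants=bool(row.extra_variant_flag),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Artifact writing


def write_domain_artifacts(domain: SyntheticDomain, outdir: str | Path) -> dict:
    """Write FASTA/PDB/alignment files plus a manifest; returns manifest."""
    from Bio import AlignIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": outdir / "synthetic_protein.fasta",
        "cds_fasta": outdir / "synthetic_cds.fasta",
        "structure_pdb": outdir / "synthetic_structure.pdb",
        "alignment_fasta": outdir / "synthetic_alignment.fasta",
    }
    with open(paths["protein_fasta"], "w") as fh:
        fh.write(f">{domain.protein.protein_id}\n{domain.protein.residues}\n")
    with open(paths["cds_fasta"], "w") as fh:
        fh.write(f">{domain.cds.transcript_id}\n{domain.cds.nucleotides}\n")
    domain.structure.to_pdb(paths["structure_pdb"])
    with open(paths["alignment_fasta"], "w") as fh:
        AlignIO.write(domain.alignment, fh, "fasta")
    manifest = {
        "seed": domain.spec.seed,
        "n_residues": domain.spec.n_residues,
        "domain_start": domain.spec.domain_start,
        "files": {k: str(v) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
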