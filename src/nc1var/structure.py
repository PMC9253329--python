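"""Per-residue structural environments and damage classification.

Given a 3D model of the NC1 domain, this module computes solvent
accessibility (Shrake-Rupley, via biotite), detects intrachain disulphide
bonds, assigns backbone dihedrals and a coarse secondary structure, and
classifies candidate amino-acid substitutions against a catalogue of 15
structural-damage features (buried-charge transitions, disulphide
breakage, buried-Gly replacement, steric clash, cavity change, etc.).
The classifier uses deterministic geometric proxies of the published
feature definitions rather than explicit mutant modelling; externally
computed classification tables can be ingested instead where exact
fidelity to a third-party tool is required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enumeration import AminoAcidSubstitution

# --- amino-acid reference data ---------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Theoretical maximum accessible surface areas (A^2), Tien et al. convention
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Mean residue volumes (A^3), used as side-chain bulk proxies
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

FORMAL_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}
HYDROPHOBIC = set("AVLIMFWC")
HYDROPHILIC = set("RNDQEKHSTY")
HBOND_CAPABLE = set("NQSTYHKRDEW")  # side chains with N/O donor/acceptor

CHARGED_GROUP_ATOMS = {
    "R": ("NH1", "NH2", "NE"),
    "K": ("NZ",),
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
}

# Full heavy-atom side-chain complements (for strict completeness checks)
SIDECHAIN_ATOMS = {
    "A": ["CB"], "C": ["CB", "SG"], "D": ["CB", "CG", "OD1", "OD2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"], "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "G": [], "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"], "K": ["CB", "CG", "CD", "CE", "NZ"],
    "L": ["CB", "CG", "CD1", "CD2"], "M": ["CB", "CG", "SD", "CE"],
    "N": ["CB", "CG", "OD1", "ND2"], "P": ["CB", "CG", "CD"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "S": ["CB", "OG"], "T": ["CB", "OG1", "CG2"],
    "V": ["CB", "CG1", "CG2"], "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
}

# The structural-damage feature catalogue.  Deliberately excludes
# "cis Pro replaced": the alpha-5 NC1 domain contains no cis prolines.
FEATURES = (
    "buried_charge_introduced",
    "buried_charge_replaced",
    "buried_charge_switch",
    "buried_gly_replaced",
    "buried_hbond_breakage",
    "buried_hydrophilic_introduced",
    "buried_pro_introduced",
    "buried_salt_bridge_breakage",
    "buried_exposed_switch",
    "cavity_altered",
    "clash",
    "disallowed_phi_psi",
    "disulphide_breakage",
    "gly_in_bend",
    "secondary_structure_altered",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Geometry thresholds for environment building and classification."""

    burial_rsa: float = 0.09          # RSA below which a residue is buried
    disulphide_max_a: float = 2.5     # SG-SG bond distance
    salt_bridge_max_a: float = 5.0    # charged-group heavy-atom distance
    hbond_max_a: float = 3.5          # donor-acceptor distance
    clash_free_base_a3: float = 40.0  # free local volume at RSA 0
    clash_free_per_rsa_a3: float = 400.0  # extra free volume per unit RSA
    cavity_volume_a3: float = 70.0    # |volume change| for cavity_altered
    switch_rsa_margin: float = 0.05   # RSA band around burial threshold
    chain_break_a: float = 2.5        # C(i)-N(i+1) distance above = break
    bend_angle_deg: float = 70.0      # CA(i-2)-CA(i)-CA(i+2) bend criterion


@dataclass(frozen=True)
class Atom:
    residue_number: int
    residue_name: str  # three-letter
    atom_name: str
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class StructureModel:
    """A single-chain protein model as a flat atom list."""

    def __init__(self, atoms: Sequence[Atom], chain_id: str = "A", note: str = ""):
        if not atoms:
            raise ValueError("structure has no atoms")
        for a in atoms:
            if not all(math.isfinite(c) for c in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate in residue {a.residue_number}")
        self.atoms = list(atoms)
        self.chain_id = chain_id
        self.note = note
        self._by_residue: dict[int, list[Atom]] = {}
        for a in self.atoms:
            self._by_residue.setdefault(a.residue_number, []).append(a)

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self._by_residue)

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        return self._by_residue.get(residue_number, [])

    def residue_name(self, residue_number: int) -> str:
        return self._by_residue[residue_number][0].residue_name

    def atom(self, residue_number: int, atom_name: str) -> Atom | None:
        for a in self._by_residue.get(residue_number, []):
            if a.atom_name == atom_name:
                return a
        return None

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_pdb(cls, path: str | Path, chain_id: str | None = None) -> "StructureModel":
        """Read a PDB (or mmCIF) file with gemmi, selecting one chain.

        Only the first model and the first conformer of any alternate
        location are used.
        """
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        st.remove_alternative_conformations()
        st.remove_hydrogens()
        model = st[0]
        chains = [ch.name for ch in model]
        if chain_id is None:
            chain_id = chains[0]
        if chain_id not in chains:
            raise KeyError(f"chain {chain_id!r} not in {chains}")
        atoms = []
        for ch in model:
            if ch.name != chain_id:
                continue
            for res in ch:
                if res.name not in AA3_TO_1:
                    continue
                for at in res:
                    atoms.append(
                        Atom(
                            residue_number=res.seqid.num,
                            residue_name=res.name,
                            atom_name=at.name,
                            x=at.pos.x, y=at.pos.y, z=at.pos.z,
                            element=at.element.name,
                        )
                    )
        return cls(atoms, chain_id=chain_id, note=st.name)

    def to_pdb(self, path: str | Path) -> None:
        """Write a minimal PDB file (single chain, sequential serials)."""
        with open(path, "w") as fh:
            for i, a in enumerate(self.atoms, start=1):
                el = (a.element or a.atom_name[0]).rjust(2)
                name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name} {a.residue_name:>3s} "
                    f"{self.chain_id}{a.residue_number:4d}    "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el}\n"
                )
            fh.write("END\n")

    def to_biotite(self):
        import biotite.structure as struc

        arr = struc.AtomArray(len(self.atoms))
        arr.coord = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=np.float32)
        arr.chain_id = np.array([self.chain_id] * len(self.atoms))
        arr.res_id = np.array([a.residue_number for a in self.atoms])
        arr.res_name = np.array([a.residue_name for a in self.atoms])
        arr.atom_name = np.array([a.atom_name for a in self.atoms])
        arr.element = np.array(
            [a.element or a.atom_name[0] for a in self.atoms]
        )
        arr.hetero = np.array([False] * len(self.atoms))
        return arr


@dataclass
class ResidueEnvironment:
    """Aggregated structural context of one residue."""

    residue_number: int
    aa: str  # one-letter
    sasa: float
    rsa: float
    buried: bool
    disulphide_partner: int | None = None
    salt_bridge_partners: tuple[int, ...] = ()
    sidechain_hbonds: tuple[tuple[int, float], ...] = ()
    phi: float | None = None
    psi: float | None = None
    secondary_structure: str = "loop"  # helix | strand | bend | loop
    resolved: bool = True


@dataclass(frozen=True)
class DamageReport:
    """Structural-damage classification of one substitution."""

    substitution: AminoAcidSubstitution
    triggered_features: frozenset[str]
    provenance: str = "internal"  # internal | external
    has_structural_data: bool = True

    def __post_init__(self) -> None:
        unknown = self.triggered_features - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown damage feature(s): {sorted(unknown)}")

    @property
    def damaging(self) -> bool:
        return bool(self.triggered_features)


# ---------------------------------------------------------------------------
# Geometry


def compute_sasa(
    model: StructureModel, point_number: int = 500
) -> dict[int, tuple[float, float]]:
    """Per-residue accessible surface area and relative accessibility.

    Shrake-Rupley rolling-probe SASA (probe 1.4 A) with single-atom van
    der Waals radii; RSA is the residue SASA divided by the residue
    type's theoretical maximum.
    """
    import biotite.structure as struc

    arr = model.to_biotite()
    atom_sasa = struc.sasa(arr, vdw_radii="Single", point_number=point_number)
    out: dict[int, tuple[float, float]] = {}
    for res in model.residue_numbers:
        mask = arr.res_id == res
        sasa = float(np.nansum(atom_sasa[mask]))
        aa = AA3_TO_1[model.residue_name(res)]
        out[res] = (sasa, sasa / MAX_ASA[aa])
    return out


def detect_disulphides(
    model: StructureModel, config: ClassifierConfig = ClassifierConfig()
) -> set[frozenset[int]]:
    """Cys-Cys pairs with SG atoms within the bonding threshold.

    Pairs are formed greedily by increasing SG-SG distance so that each
    Cys participates in at most one bond.
    """
    sgs = [
        (a.residue_number, a.xyz)
        for a in model.atoms
        if a.residue_name == "CYS" and a.atom_name == "SG"
    ]
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= config.disulphide_max_a:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    pairs: set[frozenset[int]] = set()
    used: set[int] = set()
    for d, r1, r2 in sorted(candidates):
        if r1 in used or r2 in used:
            continue
        pairs.add(frozenset((r1, r2)))
        used.update((r1, r2))
    return pairs


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _assign_sse(
    phi: float | None, psi: float | None, bend_angle: float | None,
    config: ClassifierConfig,
) -> str:
    """Coarse secondary structure from backbone dihedrals and CA curvature."""
    if phi is not None and psi is not None:
        if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            return "helix"
        if -180.0 <= phi <= -40.0 and (psi >= 90.0 or psi <= -160.0):
            return "strand"
    if bend_angle is not None and bend_angle >= config.bend_angle_deg:
        return "bend"
    return "loop"


def build_environment(
    model: StructureModel,
    config: ClassifierConfig = ClassifierConfig(),
    *,
    require_full_sidechains: bool = False,
    sasa_point_number: int = 500,
    secondary_structure: Mapping[int, str] | None = None,
) -> dict[int, ResidueEnvironment]:
    """One ResidueEnvironment per resolved residue of the model.

    Residues missing backbone atoms (or, in strict mode, any heavy
    side-chain atom) are flagged unresolved and carry no geometry.  An
    externally computed secondary-structure assignment may be supplied to
    override the built-in dihedral/curvature heuristic.
    """
    sasa = compute_sasa(model, point_number=sasa_point_number)
    disulphides = detect_disulphides(model, config)
    ss_partner: dict[int, int] = {}
    for pair in disulphides:
        a, b = sorted(pair)
        ss_partner[a], ss_partner[b] = b, a

    residues = model.residue_numbers
    envs: dict[int, ResidueEnvironment] = {}

    # charged-group atom coordinates for salt bridges
    charged_atoms: dict[int, tuple[int, list[np.ndarray]]] = {}
    for res in residues:
        aa = AA3_TO_1[model.residue_name(res)]
        if aa in CHARGED_GROUP_ATOMS:
            coords = [
                model.atom(res, name).xyz
                for name in CHARGED_GROUP_ATOMS[aa]
                if model.atom(res, name) is not None
            ]
            if coords:
                charged_atoms[res] = (FORMAL_CHARGE[aa], coords)

    # polar atoms (N/O) for hydrogen bonding, split backbone/side chain
    polar_all: list[tuple[int, str, np.ndarray]] = []
    for a in model.atoms:
        el = (a.element or a.atom_name[0]).upper()
        if el in ("N", "O"):
            polar_all.append((a.residue_number, a.atom_name, a.xyz))

    for idx, res in enumerate(residues):
        aa = AA3_TO_1[model.residue_name(res)]
        n = model.atom(res, "N")
        ca = model.atom(res, "CA")
        c = model.atom(res, "C")
        missing_backbone = any(at is None for at in (n, ca, c))
        missing_sidechain = aa != "G" and model.atom(res, "CB") is None
        if require_full_sidechains and not missing_backbone:
            present = {a.atom_name for a in model.residue_atoms(res)}
            missing_sidechain = missing_sidechain or not (
                set(SIDECHAIN_ATOMS[aa]) <= present
            )
        if missing_backbone or missing_sidechain:
            envs[res] = ResidueEnvironment(
                residue_number=res, aa=aa, sasa=float("nan"),
                rsa=float("nan"), buried=False, resolved=False,
            )
            continue

        res_sasa, rsa = sasa[res]

        # backbone dihedrals, honouring chain breaks and numbering gaps
        phi = psi = None
        prev_res = residues[idx - 1] if idx > 0 else None
        next_res = residues[idx + 1] if idx + 1 < len(residues) else None
        if prev_res is not None and prev_res == res - 1:
            pc = model.atom(prev_res, "C")
            if pc is not None and np.linalg.norm(pc.xyz - n.xyz) <= config.chain_break_a:
                phi = _dihedral(pc.xyz, n.xyz, ca.xyz, c.xyz)
        if next_res is not None and next_res == res + 1:
            nn = model.atom(next_res, "N")
            if nn is not None and np.linalg.norm(c.xyz - nn.xyz) <= config.chain_break_a:
                psi = _dihedral(n.xyz, ca.xyz, c.xyz, nn.xyz)

        # CA-trace bend angle over i-2, i, i+2; only meaningful where the
        # backbone is covalently continuous through the window
        bend_angle = None
        if phi is not None and psi is not None and idx >= 2 and idx + 2 < len(residues):
            r_m2, r_p2 = residues[idx - 2], residues[idx + 2]
            if r_m2 == res - 2 and r_p2 == res + 2:
                ca_m2, ca_p2 = model.atom(r_m2, "CA"), model.atom(r_p2, "CA")
                cont = True
                for r_a in (r_m2, res + 1):
                    c_a, n_a = model.atom(r_a, "C"), model.atom(r_a + 1, "N")
                    if (
                        c_a is None
                        or n_a is None
                        or np.linalg.norm(c_a.xyz - n_a.xyz) > config.chain_break_a
                    ):
                        cont = False
                if cont and ca_m2 is not None and ca_p2 is not None:
                    u = ca_m2.xyz - ca.xyz
                    v = ca_p2.xyz - ca.xyz
                    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    # deviation of the trace from straight-through
                    bend_angle = 180.0 - math.degrees(
                        math.acos(float(np.clip(cosang, -1.0, 1.0)))
                    )

        if secondary_structure is not None and res in secondary_structure:
            sse = secondary_structure[res]
        else:
            sse = _assign_sse(phi, psi, bend_angle, config)

        # salt bridges: opposite formal charges within threshold
        bridges = []
        if res in charged_atoms:
            q, coords = charged_atoms[res]
            for other, (q2, coords2) in charged_atoms.items():
                if other == res or q2 == q:
                    continue
                dmin = min(
                    float(np.linalg.norm(c1 - c2))
                    for c1 in coords
                    for c2 in coords2
                )
                if dmin <= config.salt_bridge_max_a:
                    bridges.append(other)

        # side-chain hydrogen bonds: polar side-chain atom of this residue
        # within threshold of any polar atom of another residue
        hbonds = []
        own_sidechain_polar = [
            (name, xyz)
            for (r, name, xyz) in polar_all
            if r == res and name not in ("N", "O", "OXT")
        ]
        if own_sidechain_polar and aa in HBOND_CAPABLE:
            best: dict[int, float] = {}
            for _, xyz in own_sidechain_polar:
                for (r2, _, xyz2) in polar_all:
                    if r2 == res:
                        continue
                    d = float(np.linalg.norm(xyz - xyz2))
                    if d <= config.hbond_max_a:
                        best[r2] = min(best.get(r2, d), d)
            hbonds = sorted(best.items())

        envs[res] = ResidueEnvironment(
            residue_number=res,
            aa=aa,
            sasa=res_sasa,
            rsa=rsa,
            buried=rsa < config.burial_rsa,
            disulphide_partner=ss_partner.get(res),
            salt_bridge_partners=tuple(sorted(bridges)),
            sidechain_hbonds=tuple(hbonds),
            phi=phi,
            psi=psi,
            secondary_structure=sse,
        )
    return envs


# ---------------------------------------------------------------------------
# Classification


def _phi_psi_general_allowed(phi: float | None, psi: float | None) -> bool:
    """Whether a backbone conformation is allowed for non-Gly residues.

    Proxy for the general Ramachandran region: positive phi is treated as
    Gly-only territory; undefined dihedrals are treated as allowed.
    """
    if phi is None:
        return True
    return phi < 0.0


def classify_substitution(
    sub: AminoAcidSubstitution,
    env: ResidueEnvironment | None,
    config: ClassifierConfig = ClassifierConfig(),
) -> DamageReport:
    """Evaluate every catalogue feature for one substitution.

    A pure function of (substitution, environment, thresholds).  Residues
    without structural data yield a report flagged accordingly; such
    reports are excluded from downstream denominators.
    """
    if env is None or not env.resolved:
        return DamageReport(sub, frozenset(), has_structural_data=False)
    ref, alt = sub.ref_aa, sub.alt_aa
    if env.aa != ref:
        raise ValueError(
            f"environment residue {env.residue_number} is {env.aa}, "
            f"substitution expects {ref}"
        )
    feats: set[str] = set()
    q_ref = FORMAL_CHARGE.get(ref, 0)
    q_alt = FORMAL_CHARGE.get(alt, 0)
    dvol = RESIDUE_VOLUME[alt] - RESIDUE_VOLUME[ref]

    if ref == "C" and env.disulphide_partner is not None:
        feats.add("disulphide_breakage")
    if env.buried:
        if ref == "G":
            feats.add("buried_gly_replaced")
        if alt == "P" and ref != "P":
            feats.add("buried_pro_introduced")
        if q_ref == 0 and q_alt != 0:
            feats.add("buried_charge_introduced")
        if q_ref != 0 and q_alt == 0:
            feats.add("buried_charge_replaced")
        if q_ref != 0 and q_alt != 0 and q_ref != q_alt:
            feats.add("buried_charge_switch")
        if ref in HYDROPHOBIC and alt in HYDROPHILIC:
            feats.add("buried_hydrophilic_introduced")
        if q_ref != 0 and env.salt_bridge_partners and q_alt != q_ref:
            feats.add("buried_salt_bridge_breakage")
        if env.sidechain_hbonds and alt not in HBOND_CAPABLE:
            feats.add("buried_hbond_breakage")
        if abs(dvol) >= config.cavity_volume_a3:
            feats.add("cavity_altered")
    if (
        abs(env.rsa - config.burial_rsa) <= config.switch_rsa_margin
        and (
            (ref in HYDROPHOBIC and alt in HYDROPHILIC)
            or (ref in HYDROPHILIC and alt in HYDROPHOBIC)
        )
    ):
        feats.add("buried_exposed_switch")
    free_volume = (
        config.clash_free_base_a3 + config.clash_free_per_rsa_a3 * max(env.rsa, 0.0)
    )
    if dvol > free_volume:
        feats.add("clash")
    if ref == "G" and not _phi_psi_general_allowed(env.phi, env.psi):
        feats.add("disallowed_phi_psi")
    if ref == "G" and env.secondary_structure == "bend":
        feats.add("gly_in_bend")
    if alt == "P" and env.secondary_structure in ("helix", "strand"):
        feats.add("secondary_structure_altered")

    return DamageReport(sub, frozenset(feats))


def classify_all(
    subs: Iterable[AminoAcidSubstitution],
    envs: Mapping[int, ResidueEnvironment],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[DamageReport]:
    return [
        classify_substitution(s, envs.get(s.residue_number), config) for s in subs
    ]


# ---------------------------------------------------------------------------
# External classification tables


def load_external_classifications(
    table: pd.DataFrame | str | Path,
) -> list[DamageReport]:
    """Ingest an externally computed damage-classification table.

    Expected columns: ``hgvs_p`` or ``ref_aa``/``residue``/``alt_aa``,
    plus either a ``features`` column (comma-separated catalogue names,
    empty for non-damaging) or one boolean column per catalogue feature.
    Rows naming a feature outside the catalogue are rejected.
    """
    import re

    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", comment="#")
    reports = []
    for _, row in table.iterrows():
        if "residue" in table.columns:
            res, ref, alt = int(row["residue"]), row["ref_aa"], row["alt_aa"]
        else:
            m = re.fullmatch(r"p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})", str(row["hgvs_p"]))
            if not m:
                raise ValueError(f"unparseable protein HGVS: {row['hgvs_p']!r}")
            ref = AA3_TO_1[m.group(1).upper()]
            alt = AA3_TO_1[m.group(3).upper()]
            res = int(m.group(2))
        if "features" in table.columns:
            raw = row["features"]
            names = (
                [f.strip() for f in str(raw).split(",") if f.strip()]
                if pd.notna(raw)
                else []
            )
        else:
            names = [f for f in FEATURES if f in table.columns and bool(row[f])]
            unknown_cols = [
                c
                for c in table.columns
                if c not in FEATURES
                and c not in (
                    "hgvs_p", "residue", "ref_aa", "alt_aa",
                    "has_structural_data", "damaging", "provenance",
                )
            ]
            if unknown_cols:
                raise ValueError(f"unknown feature column(s): {unknown_cols}")
        bad = set(names) - set(FEATURES)
        if bad:
            raise ValueError(f"unknown damage feature(s): {sorted(bad)}")
        has_data = bool(row.get("has_structural_data", True))
        sub = AminoAcidSubstitution(
            res, ref, alt,
            producing_snvs=(_placeholder_snv(res, ref, alt),),
        )
        reports.append(
            DamageReport(
                sub, frozenset(names), provenance="external",
                has_structural_data=has_data,
            )
        )
    return reports


def _placeholder_snv(res: int, ref: str, alt: str):
    """Minimal producing SNV for externally sourced substitutions."""
    from .enumeration import SNVariant

    return SNVariant(
        codon_index=res - 1, codon_position=1, ref_nt="A", alt_nt="C",
        residue_number=res, ref_aa=ref, alt_aa=alt, consequence="missense",
        left_context="A", right_context="A",
    )


def reports_to_frame(reports: Iterable[DamageReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "hgvs_p": r.substitution.hgvs_p,
            "residue": r.substitution.residue_number,
            "ref_aa": r.substitution.ref_aa,
            "alt_aa": r.substitution.alt_aa,
            "damaging": r.damaging,
            "provenance": r.provenance,
            "has_structural_data": r.has_structural_data,
        }
        for f in FEATURES:
            row[f] = f in r.triggered_features
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_table(reports: Iterable[DamageReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)
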