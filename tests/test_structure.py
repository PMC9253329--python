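"""Structural environments and the damage-feature classifier."""

import math

import numpy as np
import pandas as pd
import pytest

from nc1var.enumeration import AminoAcidSubstitution
from nc1var.structure import (
    FEATURES,
    Atom,
    ClassifierConfig,
    DamageReport,
    FORMAL_CHARGE,
    HBOND_CAPABLE,
    HYDROPHILIC,
    HYDROPHOBIC,
    RESIDUE_VOLUME,
    ResidueEnvironment,
    StructureModel,
    build_environment,
    classify_substitution,
    compute_sasa,
    detect_disulphides,
    load_external_classifications,
)

CFG = ClassifierConfig()


def _sub(ref: str, pos: int, alt: str) -> AminoAcidSubstitution:
    from nc1var.structure import _placeholder_snv

    return AminoAcidSubstitution(pos, ref, alt, (_placeholder_snv(pos, ref, alt),))


def _env(ref: str, pos: int = 10, **kw) -> ResidueEnvironment:
    base = dict(
        residue_number=pos, aa=ref, sasa=50.0, rsa=0.5, buried=False,
        disulphide_partner=None, salt_bridge_partners=(), sidechain_hbonds=(),
        phi=-60.0, psi=-45.0, secondary_structure="loop", resolved=True,
    )
    base.update(kw)
    base["buried"] = base["rsa"] < CFG.burial_rsa
    return ResidueEnvironment(**base)


class TestSasa:
    def test_two_sphere_analytic_oracle(self):
        """Shrake-Rupley vs the closed-form cap area of overlapping spheres."""
        probe, r_c = 1.4, 1.7  # single-radius carbon
        d = 4.0
        atoms = [
            Atom(1, "GLY", "CA", 0.0, 0.0, 0.0, element="C"),
            Atom(2, "GLY", "CA", d, 0.0, 0.0, element="C"),
        ]
        sasa = compute_sasa(StructureModel(atoms), point_number=2000)
        R = r_c + probe
        # symmetric overlap: each sphere loses a cap of height h
        h = R - d / 2.0
        expected_each = 4.0 * math.pi * R**2 - 2.0 * math.pi * R * h
        for res in (1, 2):
            assert sasa[res][0] == pytest.approx(expected_each, rel=0.02)

    def test_three_atom_chain_oracle(self):
        probe, r_c = 1.4, 1.7
        d = 4.5
        atoms = [
            Atom(i + 1, "GLY", "CA", i * d, 0.0, 0.0, element="C") for i in range(3)
        ]
        sasa = compute_sasa(StructureModel(atoms), point_number=2000)
        R = r_c + probe
        h = R - d / 2.0
        cap = 2.0 * math.pi * R * h
        full = 4.0 * math.pi * R**2
        assert sasa[1][0] == pytest.approx(full - cap, rel=0.02)
        assert sasa[2][0] == pytest.approx(full - 2 * cap, rel=0.02)
        assert sasa[3][0] == pytest.approx(full - cap, rel=0.02)

    def test_isolated_residue_fully_exposed(self):
        atoms = [
            Atom(1, "GLY", "N", -1.45, 0.0, 0.0, element="N"),
            Atom(1, "GLY", "CA", 0.0, 0.0, 0.0, element="C"),
            Atom(1, "GLY", "C", 1.52, 0.0, 0.0, element="C"),
            Atom(1, "GLY", "O", 1.52, 1.23, 0.0, element="O"),
        ]
        _, rsa = compute_sasa(StructureModel(atoms))[1]
        assert rsa > 0.9

    def test_enclosed_residue_buried(self):
        # a Gly shell-caged at the origin
        atoms = [Atom(1, "GLY", "CA", 0.0, 0.0, 0.0, element="C")]
        golden = (1 + 5**0.5) / 2
        n_shell = 200
        for i in range(n_shell):
            theta = 2 * math.pi * i / golden
            z = 1 - 2 * (i + 0.5) / n_shell
            r = math.sqrt(1 - z * z)
            atoms.append(
                Atom(
                    2 + i, "ALA", "CB",
                    4.0 * r * math.cos(theta), 4.0 * r * math.sin(theta), 4.0 * z,
                    element="C",
                )
            )
        _, rsa = compute_sasa(StructureModel(atoms))[1]
        assert rsa < 0.02


class TestDisulphides:
    def test_bonded_and_unbonded_pairs(self):
        def cys(res, x):
            return [
                Atom(res, "CYS", "CA", x, 0.0, 0.0),
                Atom(res, "CYS", "SG", x + 1.0, 0.0, 0.0, element="S"),
            ]

        near = StructureModel(cys(1, 0.0) + cys(2, 0.05))  # SG-SG 1.05+... ~2.05
        model = StructureModel(cys(1, 0.0) + cys(2, 2.05 - 2.0))
        pairs = detect_disulphides(model)
        assert pairs == {frozenset((1, 2))}
        far = StructureModel(cys(1, 0.0) + cys(2, 4.5 - 2.0))
        # SG atoms 4.5 A apart -> no bond
        far = StructureModel(
            cys(1, 0.0)
            + [
                Atom(2, "CYS", "CA", 4.5, 0.0, 0.0),
                Atom(2, "CYS", "SG", 5.5, 0.0, 0.0, element="S"),
            ]
        )
        assert detect_disulphides(far) == set()

    def test_each_cys_in_at_most_one_pair(self):
        atoms = []
        for res, x in [(1, 0.0), (2, 2.0), (3, 4.0)]:
            atoms += [
                Atom(res, "CYS", "CA", x, 2.0, 0.0),
                Atom(res, "CYS", "SG", x, 0.0, 0.0, element="S"),
            ]
        pairs = detect_disulphides(StructureModel(atoms))
        assert len(pairs) == 1
        (pair,) = pairs
        assert pair == frozenset((1, 2)) or pair == frozenset((2, 3))

    def test_synthetic_domain_pairs(self, domain, environments):
        pairs = detect_disulphides(domain.structure)
        assert pairs == {frozenset(p) for p in domain.spec.disulphide_pairs}
        for p, q in domain.spec.disulphide_pairs:
            assert environments[p].disulphide_partner == q
            assert environments[q].disulphide_partner == p


class TestEnvironments:
    def test_buried_gly_set_matches_planted(self, domain, environments):
        buried_gly = {
            r for r, e in environments.items() if e.aa == "G" and e.buried
        }
        assert buried_gly == set(domain.spec.buried_gly_positions)

    def test_nonburied_gly_count(self, domain, environments):
        exposed = [
            r for r, e in environments.items() if e.aa == "G" and not e.buried
        ]
        assert len(exposed) == 13

    def test_unresolved_residues_flagged(self):
        from nc1var.synthetic import SyntheticDomainSpec, generate_domain

        d = generate_domain(SyntheticDomainSpec(seed=3, n_unresolved_terminal=5))
        envs = build_environment(d.structure)
        tail = range(d.span.end_residue - 4, d.span.end_residue + 1)
        unresolved = {r for r, e in envs.items() if not e.resolved}
        # stripped residues lose their side chains; Gly has none to lose
        assert unresolved == {
            r for r in tail if d.domain_protein.residue(r) != "G"
        }


RULE_CASES = [
    # (ref, alt, env overrides, expected feature, triggered?)
    ("C", "G", dict(rsa=0.02, disulphide_partner=20), "disulphide_breakage", True),
    ("C", "G", dict(rsa=0.02, disulphide_partner=None), "disulphide_breakage", False),
    ("G", "A", dict(rsa=0.02), "buried_gly_replaced", True),
    ("G", "A", dict(rsa=0.50), "buried_gly_replaced", False),
    ("A", "P", dict(rsa=0.02), "buried_pro_introduced", True),
    ("A", "P", dict(rsa=0.50), "buried_pro_introduced", False),
    ("S", "K", dict(rsa=0.02), "buried_charge_introduced", True),
    ("S", "K", dict(rsa=0.30), "buried_charge_introduced", False),
    ("D", "N", dict(rsa=0.02), "buried_charge_replaced", True),
    ("D", "K", dict(rsa=0.02), "buried_charge_switch", True),
    ("L", "S", dict(rsa=0.02), "buried_hydrophilic_introduced", True),
    ("S", "T", dict(rsa=0.02), "buried_hydrophilic_introduced", False),
    ("E", "Q", dict(rsa=0.02, salt_bridge_partners=(30,)), "buried_salt_bridge_breakage", True),
    ("E", "D", dict(rsa=0.02, salt_bridge_partners=(30,)), "buried_salt_bridge_breakage", False),
    ("S", "A", dict(rsa=0.02, sidechain_hbonds=((30, 2.9),)), "buried_hbond_breakage", True),
    ("S", "T", dict(rsa=0.02, sidechain_hbonds=((30, 2.9),)), "buried_hbond_breakage", False),
    ("L", "S", dict(rsa=0.10), "buried_exposed_switch", True),
    ("S", "L", dict(rsa=0.07), "buried_exposed_switch", True),
    ("L", "S", dict(rsa=0.40), "buried_exposed_switch", False),
    ("G", "W", dict(rsa=0.02), "clash", True),
    ("G", "W", dict(rsa=0.60), "clash", False),
    ("W", "G", dict(rsa=0.02), "cavity_altered", True),
    ("A", "S", dict(rsa=0.02), "cavity_altered", False),
    ("G", "A", dict(rsa=0.50, phi=60.0, psi=40.0), "disallowed_phi_psi", True),
    ("G", "A", dict(rsa=0.50, phi=-60.0, psi=-40.0), "disallowed_phi_psi", False),
    ("G", "A", dict(rsa=0.50, secondary_structure="bend"), "gly_in_bend", True),
    ("A", "P", dict(rsa=0.50, secondary_structure="helix"), "secondary_structure_altered", True),
    ("A", "P", dict(rsa=0.50, secondary_structure="loop"), "secondary_structure_altered", False),
]


class TestClassifier:
    def test_catalogue_is_the_fifteen_features(self):
        assert len(FEATURES) == 15
        assert len(set(FEATURES)) == 15
        assert "cis_pro_replaced" not in FEATURES

    @pytest.mark.parametrize("ref,alt,overrides,feature,expected", RULE_CASES)
    def test_each_rule_against_its_definition(self, ref, alt, overrides, feature, expected):
        env = _env(ref, **overrides)
        report = classify_substitution(_sub(ref, 10, alt), env)
        assert (feature in report.triggered_features) is expected

    def test_rules_against_independent_predicates(self):
        """Cross-check the classifier against per-rule oracle predicates."""

        def oracle(ref, alt, env):
            buried = env.rsa < CFG.burial_rsa
            q = FORMAL_CHARGE
            dv = RESIDUE_VOLUME[alt] - RESIDUE_VOLUME[ref]
            feats = set()
            if ref == "C" and env.disulphide_partner is not None:
                feats.add("disulphide_breakage")
            if buried and ref == "G":
                feats.add("buried_gly_replaced")
            if buried and alt == "P" and ref != "P":
                feats.add("buried_pro_introduced")
            if buried and q.get(ref, 0) == 0 and q.get(alt, 0) != 0:
                feats.add("buried_charge_introduced")
            if buried and q.get(ref, 0) != 0 and q.get(alt, 0) == 0:
                feats.add("buried_charge_replaced")
            if buried and q.get(ref, 0) * q.get(alt, 0) < 0:
                feats.add("buried_charge_switch")
            if buried and ref in HYDROPHOBIC and alt in HYDROPHILIC:
                feats.add("buried_hydrophilic_introduced")
            if buried and q.get(ref, 0) != 0 and env.salt_bridge_partners and q.get(alt, 0) != q.get(ref, 0):
                feats.add("buried_salt_bridge_breakage")
            if buried and env.sidechain_hbonds and alt not in HBOND_CAPABLE:
                feats.add("buried_hbond_breakage")
            if abs(env.rsa - CFG.burial_rsa) <= CFG.switch_rsa_margin and (
                (ref in HYDROPHOBIC and alt in HYDROPHILIC)
                or (ref in HYDROPHILIC and alt in HYDROPHOBIC)
            ):
                feats.add("buried_exposed_switch")
            if dv > CFG.clash_free_base_a3 + CFG.clash_free_per_rsa_a3 * env.rsa:
                feats.add("clash")
            if buried and abs(dv) >= CFG.cavity_volume_a3:
                feats.add("cavity_altered")
            if ref == "G" and env.phi is not None and env.phi > 0:
                feats.add("disallowed_phi_psi")
            if ref == "G" and env.secondary_structure == "bend":
                feats.add("gly_in_bend")
            if alt == "P" and env.secondary_structure in ("helix", "strand"):
                feats.add("secondary_structure_altered")
            return feats

        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(400):
            ref, alt = rng.choice(list(aas), size=2, replace=False)
            env = _env(
                ref,
                rsa=float(rng.uniform(0, 0.6)),
                disulphide_partner=int(rng.integers(20, 25)) if rng.random() < 0.3 else None,
                salt_bridge_partners=(30,) if rng.random() < 0.3 else (),
                sidechain_hbonds=((30, 2.9),) if rng.random() < 0.3 else (),
                phi=float(rng.uniform(-180, 180)),
                psi=float(rng.uniform(-180, 180)),
                secondary_structure=str(rng.choice(["helix", "strand", "bend", "loop"])),
            )
            report = classify_substitution(_sub(ref, 10, alt), env)
            assert report.triggered_features == frozenset(oracle(ref, alt, env))

    def test_pure_function(self, substitutions, environments):
        sub = substitutions[100]
        env = environments[sub.residue_number]
        r1 = classify_substitution(sub, env)
        r2 = classify_substitution(sub, env)
        assert r1.triggered_features == r2.triggered_features

    def test_disulphide_feature_exactly_at_cys(self, domain, substitutions, environments, reports):
        flagged = {
            r.substitution.residue_number
            for r in reports
            if "disulphide_breakage" in r.triggered_features
        }
        assert flagged == set(domain.spec.cys_positions)

    def test_buried_gly_feature_exactly_at_planted(self, domain, reports):
        flagged = {
            r.substitution.residue_number
            for r in reports
            if "buried_gly_replaced" in r.triggered_features
        }
        assert flagged == set(domain.spec.buried_gly_positions)

    def test_no_structural_data_report(self):
        report = classify_substitution(_sub("A", 5, "V"), None)
        assert not report.has_structural_data and not report.damaging

    def test_mismatched_environment_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution(_sub("A", 10, "V"), _env("G"))


class TestExternalTables:
    def test_feature_list_roundtrip(self):
        df = pd.DataFrame(
            [
                {"hgvs_p": "p.Cys1570Arg", "features": "disulphide_breakage,clash"},
                {"hgvs_p": "p.Ser1500Thr", "features": ""},
                {"hgvs_p": "p.Gly1492Ala", "features": "buried_gly_replaced"},
            ]
        )
        reports = load_external_classifications(df)
        assert reports[0].triggered_features == {"disulphide_breakage", "clash"}
        assert not reports[1].damaging
        assert reports[2].damaging
        assert all(r.provenance == "external" for r in reports)

    def test_unknown_feature_rejected(self):
        df = pd.DataFrame([{"hgvs_p": "p.Cys1570Arg", "features": "cis_pro_replaced"}])
        with pytest.raises(ValueError):
            load_external_classifications(df)

    def test_report_invariant_damaging_iff_features(self):
        sub = _sub("A", 1, "V")
        assert not DamageReport(sub, frozenset()).damaging
        assert DamageReport(sub, frozenset({"clash"})).damaging
        with pytest.raises(ValueError):
            DamageReport(sub, frozenset({"made_up_feature"}))
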