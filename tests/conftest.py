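"""Shared fixtures: one synthetic domain pipeline, built once per session."""

from __future__ import annotations

import pytest

from nc1var.enumeration import dedupe_missense, enumerate_snvs
from nc1var.nullmodel import ContextRateTable
from nc1var.structure import build_environment, classify_all
from nc1var.synthetic import SyntheticDomainSpec, generate_domain


@pytest.fixture(scope="session")
def domain():
    return generate_domain(SyntheticDomainSpec(seed=1))


@pytest.fixture(scope="session")
def snvs(domain):
    return enumerate_snvs(domain.cds, domain.span)


@pytest.fixture(scope="session")
def missense_snvs(snvs):
    return [v for v in snvs if v.consequence == "missense"]


@pytest.fixture(scope="session")
def substitutions(missense_snvs):
    return dedupe_missense(missense_snvs)


@pytest.fixture(scope="session")
def environments(domain):
    return build_environment(domain.structure)


@pytest.fixture(scope="session")
def reports(substitutions, environments):
    return classify_all(substitutions, environments)


@pytest.fixture(scope="session")
def snv_reports(missense_snvs, reports):
    by_key = {r.substitution.key: r for r in reports}
    return [
        (v, by_key[(v.residue_number, v.ref_aa, v.alt_aa)]) for v in missense_snvs
    ]


@pytest.fixture(scope="session")
def default_rates():
    return ContextRateTable.default()
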