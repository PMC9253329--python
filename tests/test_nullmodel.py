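"""Context rate tables, expected spectra and exact binomial comparisons."""

import math

import pytest

from nc1var.enumeration import SNVariant
from nc1var.nullmodel import (
    ANY_DAMAGE,
    ComparisonResult,
    ContextRateTable,
    binomial_compare,
    bonferroni_threshold,
    compare_cohort,
    expected_spectrum,
    observed_counts,
)
from nc1var.structure import DamageReport
from test_structure import _sub


def _snv(left="A", ref="A", alt="G", right="A", res=1):
    return SNVariant(
        codon_index=res - 1, codon_position=1, ref_nt=ref, alt_nt=alt,
        residue_number=res, ref_aa="K", alt_aa="E", consequence="missense",
        left_context=left, right_context=right,
    )


def _pair(snv, damaging, features=("clash",)):
    rep = DamageReport(
        _sub(snv.ref_aa, snv.residue_number, snv.alt_aa),
        frozenset(features if damaging else ()),
    )
    return (snv, rep)


class TestRateTable:
    def test_completeness_enforced(self):
        rates = {("A", "A", "G", "A"): 1.0}
        with pytest.raises(ValueError, match="incomplete"):
            ContextRateTable(rates)

    def test_default_has_cpg_elevation_and_ts_tv(self):
        t = ContextRateTable.default(transition=4.0, transversion=1.0, cpg_factor=10.0)
        assert t[("A", "C", "T", "G")] == 40.0   # CpG transition
        assert t[("A", "C", "T", "A")] == 4.0    # plain transition
        assert t[("A", "C", "A", "G")] == 1.0    # transversion
        assert t[("C", "G", "A", "T")] == 40.0   # CpG on the other strand

    def test_tsv_roundtrip(self, tmp_path):
        t = ContextRateTable.default()
        path = tmp_path / "rates.tsv"
        t.to_tsv(path)
        t2 = ContextRateTable.from_tsv(path)
        assert t2[("A", "C", "T", "G")] == t[("A", "C", "T", "G")]


class TestExpectedSpectrum:
    def test_uniform_rates_reduce_to_counting(self):
        uniform = ContextRateTable.uniform()
        pairs = [_pair(_snv(res=i), damaging=i < 2) for i in range(10)]
        spec = expected_spectrum(pairs, uniform)
        assert spec.any_damage == pytest.approx(0.2)

    def test_weighted_rates(self):
        # rates (2, 1, 1); only the rate-2 SNV damaging -> e_any = 0.5
        t = ContextRateTable.default(transition=2.0, transversion=1.0, cpg_factor=1.0)
        pairs = [
            _pair(_snv(ref="A", alt="G"), True),    # transition, rate 2
            _pair(_snv(ref="A", alt="C"), False),   # transversion, rate 1
            _pair(_snv(ref="A", alt="T"), False),   # transversion, rate 1
        ]
        spec = expected_spectrum(pairs, t)
        assert spec.any_damage == pytest.approx(0.5)

    def test_toy_gene_against_hand_weighted_sum(self):
        """Independent oracle: explicit rate-weighted tally over all SNVs."""
        t = ContextRateTable.default()
        import numpy as np

        rng = np.random.default_rng(11)
        pairs = []
        for i in range(45):
            snv = _snv(
                left=str(rng.choice(list("ACGT"))),
                ref=str(rng.choice(list("ACT"))),
                alt="G",
                right=str(rng.choice(list("ACGT"))),
                res=i,
            )
            pairs.append(_pair(snv, damaging=bool(rng.random() < 0.3)))
        spec = expected_spectrum(pairs, t)
        num = sum(t[s.context] for s, r in pairs if r.damaging)
        den = sum(t[s.context] for s, _ in pairs)
        assert spec.any_damage == pytest.approx(num / den)
        assert spec.denominator_rate_mass == pytest.approx(den)

    def test_scale_invariance(self):
        pairs = [_pair(_snv(res=i, ref="C", alt="T"), damaging=i % 3 == 0) for i in range(12)]
        s1 = expected_spectrum(pairs, ContextRateTable.default(4, 1, 10))
        s2 = expected_spectrum(pairs, ContextRateTable.default(40, 10, 10))
        assert s1.any_damage == pytest.approx(s2.any_damage)
        for f in s1.per_feature:
            assert s1.per_feature[f] == pytest.approx(s2.per_feature[f])

    def test_no_structural_data_rejected(self):
        snv = _snv()
        rep = DamageReport(
            _sub("K", 1, "E"), frozenset(), has_structural_data=False
        )
        with pytest.raises(ValueError):
            expected_spectrum([(snv, rep)], ContextRateTable.uniform())


def _binom_pmf(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def _oracle_binom(k, n, p, alternative):
    """Brute-force tail sums over the binomial distribution."""
    if alternative == "greater":
        return sum(_binom_pmf(i, n, p) for i in range(k, n + 1))
    if alternative == "less":
        return sum(_binom_pmf(i, n, p) for i in range(0, k + 1))
    pk = _binom_pmf(k, n, p)
    return min(
        1.0,
        sum(
            _binom_pmf(i, n, p)
            for i in range(n + 1)
            if _binom_pmf(i, n, p) <= pk * (1 + 1e-10)
        ),
    )


class TestBinomial:
    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_brute_force_enumeration(self, alternative):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.02, 0.98))
            got = binomial_compare(k, n, p, alternative).p_value
            want = _oracle_binom(k, n, p, alternative)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_mode_of_null_has_two_sided_p_one(self):
        assert binomial_compare(2, 10, 0.2, "two-sided").p_value == pytest.approx(1.0)

    def test_monotone_in_k(self):
        prev = 1.1
        for k in range(0, 21):
            p = binomial_compare(k, 20, 0.3, "greater").p_value
            assert p <= prev + 1e-12
            prev = p

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            binomial_compare(1, 10, 0.0)
        with pytest.raises(ValueError):
            binomial_compare(11, 10, 0.5)


class TestBonferroni:
    def test_published_threshold(self):
        thr = bonferroni_threshold(0.05, 15)
        assert round(thr, 4) == 0.0033

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 20, 0.0025)])
    def test_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


class TestCompareCohort:
    def test_null_composition_gives_large_p(self, snv_reports, default_rates, reports):
        """A cohort that is the whole enumeration matches its own spectrum."""
        spectrum = expected_spectrum(snv_reports, ContextRateTable.uniform())
        with_data = [r for r in reports if r.has_structural_data]
        results = compare_cohort(with_data, spectrum)
        any_damage = next(r for r in results if r.feature == ANY_DAMAGE)
        # observed fraction equals expectation up to SNV-multiplicity weighting
        assert any_damage.p_value > 0.05
        assert not any_damage.significant

    def test_feature_thresholds_use_bonferroni(self, snv_reports, default_rates, reports):
        spectrum = expected_spectrum(snv_reports, default_rates)
        results = compare_cohort(reports, spectrum, alpha=0.05, m_tests=15)
        for r in results:
            if r.feature == ANY_DAMAGE:
                assert r.threshold == 0.05
            else:
                assert r.threshold == pytest.approx(0.05 / 15)

    def test_empty_cohort_rejected(self, snv_reports, default_rates):
        spectrum = expected_spectrum(snv_reports, default_rates)
        with pytest.raises(ValueError):
            compare_cohort([], spectrum)

    def test_observed_counts_drop_missing_structure(self):
        reps = [
            DamageReport(_sub("A", 1, "V"), frozenset({"clash"})),
            DamageReport(_sub("A", 2, "V"), frozenset(), has_structural_data=False),
        ]
        counts, k_any, n = observed_counts(reps)
        assert (k_any, n) == (1, 1)
        assert counts["clash"] == 1
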