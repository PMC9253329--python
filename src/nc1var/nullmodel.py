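"""Neighbour-dependent substitution-rate null model and enrichment tests.

The expected proportion of variants triggering each structural-damage
feature, under neutral mutation, is the rate-weighted fraction of all
possible single-nucleotide substitutions whose product triggers the
feature.  Rates come from a context-dependent model r(left, ref>alt,
right) capturing transition/transversion asymmetry and CpG transition
elevation.  Observed cohort counts are compared with the expected
proportions by the exact binomial test, with a Bonferroni threshold over
the 15 feature-level comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .enumeration import SNVariant
from .structure import FEATURES, DamageReport

NUCLEOTIDES = ("A", "C", "G", "T")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
N_CONTEXTS = 4 * 4 * 3 * 4  # left x ref x alt x right = 192

ANY_DAMAGE = "any_structural_damage"


class ContextRateTable:
    """Relative substitution rates r(left, ref>alt, right), 192 entries."""

    def __init__(self, rates: Mapping[tuple[str, str, str, str], float]):
        complete = {
            (l, ref, alt, r)
            for l, ref, r in itertools.product(NUCLEOTIDES, NUCLEOTIDES, NUCLEOTIDES)
            for alt in NUCLEOTIDES
            if alt != ref
        }
        missing = complete - set(rates)
        extra = set(rates) - complete
        if missing:
            raise ValueError(f"rate table incomplete: {len(missing)} contexts missing")
        if extra:
            raise ValueError(f"rate table has invalid contexts: {sorted(extra)[:3]}...")
        if any(v < 0 for v in rates.values()):
            raise ValueError("rates must be non-negative")
        if not any(v > 0 for v in rates.values()):
            raise ValueError("rate table must contain a positive rate")
        self._rates = dict(rates)

    def __getitem__(self, key: tuple[str, str, str, str]) -> float:
        return self._rates[key]

    def rate(self, variant: SNVariant) -> float:
        return self._rates[variant.context]

    @classmethod
    def uniform(cls) -> "ContextRateTable":
        return cls.default(transition=1.0, transversion=1.0, cpg_factor=1.0)

    @classmethod
    def default(
        cls,
        transition: float = 4.0,
        transversion: float = 1.0,
        cpg_factor: float = 10.0,
    ) -> "ContextRateTable":
        """Parametric neighbour-dependent table.

        Transitions run ``transition``/``transversion`` times faster than
        transversions, and transitions at CpG dinucleotides (C>T with a
        3' G, or G>A with a 5' C) are further elevated ``cpg_factor``-fold,
        reflecting spontaneous deamination of methylated cytosine.
        """
        rates = {}
        for l, ref, r in itertools.product(NUCLEOTIDES, repeat=3):
            for alt in NUCLEOTIDES:
                if alt == ref:
                    continue
                v = transition if (ref, alt) in TRANSITIONS else transversion
                if (ref, alt) == ("C", "T") and r == "G":
                    v *= cpg_factor
                elif (ref, alt) == ("G", "A") and l == "C":
                    v *= cpg_factor
                rates[(l, ref, alt, r)] = v
        return cls(rates)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextRateTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        needed = {"left", "ref", "alt", "right", "rate"}
        if not needed <= set(df.columns):
            raise ValueError(f"rate table needs columns {sorted(needed)}")
        return cls(
            {
                (row.left, row.ref, row.alt, row.right): float(row.rate)
                for row in df.itertuples()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"left": l, "ref": ref, "alt": alt, "right": r, "rate": v}
            for (l, ref, alt, r), v in sorted(self._rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpectedSpectrum:
    """Rate-weighted expected proportion of variants per damage feature."""

    per_feature: Mapping[str, float]
    any_damage: float
    denominator_rate_mass: float

    def __post_init__(self) -> None:
        for name, e in self.per_feature.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"expected proportion out of range for {name}")
        if self.any_damage < max(self.per_feature.values(), default=0.0) - 1e-12:
            raise ValueError("any-damage proportion below a feature proportion")


@dataclass(frozen=True)
class ComparisonResult:
    """Observed-vs-expected enrichment for one feature (or any damage)."""

    feature: str
    observed_k: int
    n: int
    expected_p: float
    p_value: float
    significant: bool
    threshold: float

    @property
    def observed_fraction(self) -> float:
        return self.observed_k / self.n if self.n else float("nan")


def expected_spectrum(
    snv_reports: Sequence[tuple[SNVariant, DamageReport]],
    rates: ContextRateTable,
) -> ExpectedSpectrum:
    """Expected damage proportions over all candidate missense SNVs.

    Each SNV contributes its context-dependent rate; e_c for feature c is
    the rate mass of SNVs triggering c divided by the total rate mass.
    SNVs whose report lacks structural data must be filtered out upstream
    (they belong in neither numerator nor denominator).
    """
    total = 0.0
    mass = {f: 0.0 for f in FEATURES}
    mass_any = 0.0
    for snv, report in snv_reports:
        if not report.has_structural_data:
            raise ValueError(
                "SNV without structural data passed to expected_spectrum; "
                "filter these out of the cohort first"
            )
        r = rates.rate(snv)
        total += r
        if report.damaging:
            mass_any += r
        for f in report.triggered_features:
            mass[f] += r
    if total <= 0:
        raise ZeroDivisionError("total rate mass is zero; spectrum undefined")
    return ExpectedSpectrum(
        per_feature={f: m / total for f, m in mass.items()},
        any_damage=mass_any / total,
        denominator_rate_mass=total,
    )


def binomial_compare(
    observed_k: int,
    n: int,
    expected_p: float,
    sidedness: str = "greater",
    *,
    feature: str = ANY_DAMAGE,
    threshold: float = 0.05,
) -> ComparisonResult:
    """Exact binomial test of an observed count against a null proportion.

    No normal approximation: the p-value is computed from the binomial
    distribution itself (two-sided by the minimum-likelihood method).
    """
    if not 0 <= observed_k <= n:
        raise ValueError("observed count outside [0, n]")
    if not 0.0 < expected_p < 1.0:
        raise ValueError("degenerate null proportion (0 or 1)")
    if sidedness not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = stats.binomtest(observed_k, n, expected_p, alternative=sidedness).pvalue
    return ComparisonResult(
        feature=feature,
        observed_k=observed_k,
        n=n,
        expected_p=expected_p,
        p_value=float(p),
        significant=bool(p < threshold),
        threshold=threshold,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def observed_counts(reports: Iterable[DamageReport]) -> tuple[dict[str, int], int, int]:
    """Tally cohort damage reports: per-feature counts, any-damage, n.

    Reports without structural data are dropped from numerator and
    denominator alike.
    """
    counts = {f: 0 for f in FEATURES}
    k_any = 0
    n = 0
    for r in reports:
        if not r.has_structural_data:
            continue
        n += 1
        if r.damaging:
            k_any += 1
        for f in r.triggered_features:
            counts[f] += 1
    return counts, k_any, n


def compare_cohort(
    cohort_reports: Iterable[DamageReport],
    spectrum: ExpectedSpectrum,
    *,
    alpha: float = 0.05,
    m_tests: int = 15,
    sidedness: str = "greater",
    skip_degenerate: bool = True,
) -> list[ComparisonResult]:
    """Observed-vs-expected comparison for any-damage plus each feature.

    Any-damage is tested at ``alpha``; feature-level tests use the
    Bonferroni threshold ``alpha / m_tests`` with ``m_tests`` fixed at
    the catalogue size regardless of how many features have counts.
    Features with a degenerate expected proportion (0 under the
    spectrum) are skipped unless ``skip_degenerate`` is False.
    """
    counts, k_any, n = observed_counts(cohort_reports)
    if n == 0:
        raise ValueError("empty cohort (or no reports with structural data)")
    results = [
        binomial_compare(
            k_any, n, spectrum.any_damage, sidedness,
            feature=ANY_DAMAGE, threshold=alpha,
        )
    ]
    thr = bonferroni_threshold(alpha, m_tests)
    for f in FEATURES:
        e = spectrum.per_feature[f]
        if not 0.0 < e < 1.0:
            if skip_degenerate:
                continue
            raise ValueError(f"degenerate expected proportion for {f}")
        results.append(
            binomial_compare(counts[f], n, e, sidedness, feature=f, threshold=thr)
        )
    return results


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "feature": r.feature,
            "observed_k": r.observed_k,
            "n": r.n,
            "observed_pct": 100.0 * r.observed_fraction,
            "expected_pct": 100.0 * r.expected_p,
            "p_value": r.p_value,
            "significant": r.significant,
            "threshold": r.threshold,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
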