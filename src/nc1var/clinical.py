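"""Genotype-phenotype survival analysis of kidney failure.

X-linked Alport syndrome males with NC1-domain missense variants reach
kidney failure at variable ages.  Clinical records are aggregated to one
time-to-event observation per family (the family, not the individual, is
the unit of analysis): the mean of the affected males' kidney-failure
ages (a reported age range contributes its midpoint; a pre-aggregated
family median takes precedence when individual ages are unavailable), or
a right-censored observation at the latest review age when no male has
reached kidney failure.  Families with only affected females, males with
additional COL4A3-COL4A5 pathogenic variants, and mosaic individuals are
excluded.  Kaplan-Meier curves, medians and log-rank comparisons are
computed with lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass(frozen=True)
class IndividualRecord:
    """One affected individual as extracted from clinical records."""

    family_id: str
    sex: str  # "M" | "F" | "U"
    kidney_failure: bool
    age_at_kf: float | None = None
    age_range: tuple[float, float] | None = None
    age_last_review: float | None = None
    family_median_kf_age: float | None = None  # pre-aggregated fallback
    mosaic: bool = False
    extra_pathogenic_variants: bool = False
    hearing_loss: bool | None = None
    ocular: bool | None = None

    def __post_init__(self) -> None:
        if self.kidney_failure and (
            self.age_at_kf is None
            and self.age_range is None
            and self.family_median_kf_age is None
        ):
            raise ValueError(
                f"{self.family_id}: kidney failure without any age information"
            )

    @property
    def kf_age(self) -> float | None:
        """Age at kidney failure, a range contributing its midpoint."""
        if self.age_at_kf is not None:
            return self.age_at_kf
        if self.age_range is not None:
            lo, hi = self.age_range
            return (lo + hi) / 2.0
        return None


@dataclass(frozen=True)
class FamilyRecord:
    """One family, reduced to a single (time, event) observation."""

    family_id: str
    event_time: float
    event: bool
    aggregation_note: str = ""

    def __post_init__(self) -> None:
        if self.event_time <= 0:
            raise ValueError("event time must be positive")


@dataclass(frozen=True)
class ExcludedFamily:
    family_id: str
    reason: str


@dataclass
class SurvivalResult:
    median: float  # nan when not reached
    iqr: tuple[float, float]
    n: int
    n_events: int
    curve: pd.DataFrame  # columns: time, survival

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def aggregate_family(
    members: Sequence[IndividualRecord],
) -> FamilyRecord | ExcludedFamily:
    """Reduce a family's affected members to one survival observation.

    Only males enter the analysis; mosaic males and males carrying
    additional COL4A3-COL4A5 pathogenic variants are dropped first.  If
    any remaining male has kidney failure the family contributes an event
    at the mean of the available ages (per-individual ranges are taken at
    their midpoint; a pre-aggregated family median is used when it is the
    only age information).  Otherwise the family is censored at the
    latest review age.
    """
    if not members:
        raise ValueError("empty family")
    fam = members[0].family_id
    if any(m.family_id != fam for m in members):
        raise ValueError("members belong to different families")

    males = [m for m in members if m.sex == "M"]
    if not males:
        return ExcludedFamily(fam, "only affected females (or unknown sex)")
    males = [m for m in males if not m.mosaic]
    if not males:
        return ExcludedFamily(fam, "mosaic expression")
    males = [m for m in males if not m.extra_pathogenic_variants]
    if not males:
        return ExcludedFamily(fam, "additional COL4A3-COL4A5 pathogenic variants")

    with_kf = [m for m in males if m.kidney_failure]
    if with_kf:
        ages = [m.kf_age for m in with_kf if m.kf_age is not None]
        if ages:
            time = float(np.mean(ages))
            note = f"mean of {len(ages)} kidney-failure age(s)"
        else:
            medians = [
                m.family_median_kf_age
                for m in with_kf
                if m.family_median_kf_age is not None
            ]
            if not medians:
                return ExcludedFamily(fam, "no usable kidney-failure ages")
            time = float(medians[0])
            note = "pre-aggregated family median age"
        return FamilyRecord(fam, time, event=True, aggregation_note=note)

    reviews = [m.age_last_review for m in males if m.age_last_review is not None]
    if not reviews:
        return ExcludedFamily(fam, "no kidney failure and no review age")
    return FamilyRecord(
        fam, float(max(reviews)), event=False,
        aggregation_note="censored at latest review",
    )


def aggregate_cohort(
    individuals: Iterable[IndividualRecord],
) -> tuple[list[FamilyRecord], list[ExcludedFamily]]:
    by_family: dict[str, list[IndividualRecord]] = {}
    for ind in individuals:
        by_family.setdefault(ind.family_id, []).append(ind)
    families, excluded = [], []
    for fam in sorted(by_family):
        rec = aggregate_family(by_family[fam])
        (families if isinstance(rec, FamilyRecord) else excluded).append(rec)
    return families, excluded


def km_fit(families: Sequence[FamilyRecord]) -> SurvivalResult:
    """Kaplan-Meier product-limit estimate of the kidney-failure curve.

    The median is the earliest time at which survival drops to 0.5 or
    below (NaN when never reached).  The IQR is computed from the event
    times of families that reached kidney failure; with heavy censoring
    curve-based quartiles are frequently undefined, so this convention is
    used throughout and documented.
    """
    if not families:
        raise ValueError("no families to fit")
    times = np.array([f.event_time for f in families], dtype=float)
    events = np.array([f.event for f in families], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    event_times = times[events]
    if event_times.size:
        q1, q3 = np.percentile(event_times, [25, 75])
    else:
        q1 = q3 = float("nan")
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return SurvivalResult(
        median=median,
        iqr=(float(q1), float(q3)),
        n=len(families),
        n_events=int(events.sum()),
        curve=curve,
    )


def logrank(
    group_a: Sequence[FamilyRecord], group_b: Sequence[FamilyRecord]
) -> tuple[float, float]:
    """Log-rank test between two family cohorts: (statistic, p-value)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta = [f.event_time for f in group_a]
    ea = [f.event for f in group_a]
    tb = [f.event_time for f in group_b]
    eb = [f.event for f in group_b]
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Classifier evaluation against curated pathogenicity labels

PATHOGENIC_LABELS = {"P", "LP", "P/LP", "Pathogenic", "Likely Pathogenic"}
BENIGN_LABELS = {"B", "LB", "B/LB", "Benign", "Likely Benign"}
EXCLUDED_LABELS = {"VUS", "Conflicting"}


@dataclass(frozen=True)
class ClassifierEvaluation:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / n

    @property
    def n_included(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def evaluate_classifier(
    predictions: Mapping[str, bool],
    labels: Mapping[str, str],
) -> ClassifierEvaluation:
    """Sensitivity/specificity of damage predictions against P/LP vs B/LB.

    ``predictions`` maps variant name -> predicted damaging;``labels``
    maps variant name -> curated label.  VUS and conflicting labels are
    excluded; sensitivity is computed over pathogenic variants and
    specificity over benign ones.
    """
    tp = fn = tn = fp = 0
    for var, label in labels.items():
        if label in EXCLUDED_LABELS:
            continue
        if var not in predictions:
            continue
        pred = predictions[var]
        if label in PATHOGENIC_LABELS:
            tp += pred
            fn += not pred
        elif label in BENIGN_LABELS:
            fp += pred
            tn += not pred
        else:
            raise ValueError(f"unrecognised pathogenicity label {label!r}")
    if tp + fn + tn + fp == 0:
        raise ValueError("no variants with usable labels")
    return ClassifierEvaluation(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# Clinical TSV IO


def read_clinical_table(path: str | Path) -> list[IndividualRecord]:
    """Read the clinical TSV schema into individual records.

    Columns: family_id, individual_id, sex, kf_flag, kf_age,
    kf_age_range (``lo-hi``), last_review_age, family_median_kf_age,
    mosaic_flag, extra_variant_flag (missing optional columns default
    to empty/false).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"family_id": str})
    records = []
    for row in df.itertuples():
        rng = None
        raw_range = getattr(row, "kf_age_range", None)
        if isinstance(raw_range, str) and raw_range.strip():
            lo, hi = (float(x) for x in raw_range.split("-"))
            rng = (lo, hi)
        age = getattr(row, "kf_age", None)
        age = float(age) if age is not None and pd.notna(age) else None
        review = getattr(row, "last_review_age", None)
        review = float(review) if review is not None and pd.notna(review) else None
        fam_med = getattr(row, "family_median_kf_age", None)
        fam_med = float(fam_med) if fam_med is not None and pd.notna(fam_med) else None
        records.append(
            IndividualRecord(
                family_id=str(row.family_id),
                sex=str(row.sex),
                kidney_failure=bool(row.kf_flag),
                age_at_kf=age,
                age_range=rng,
                age_last_review=review,
                family_median_kf_age=fam_med,
                mosaic=bool(getattr(row, "mosaic_flag", False)),
                extra_pathogenic_variants=bool(getattr(row, "extra_variant_flag", False)),
            )
        )
    return records


def survival_summary(result: SurvivalResult, p_values: Mapping[str, float] | None = None) -> dict:
    return {
        "median": result.median,
        "iqr": list(result.iqr),
        "n": result.n,
        "n_events": result.n_events,
        "p_values": dict(p_values or {}),
    }
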