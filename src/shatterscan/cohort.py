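"""Cohort-level bookkeeping: event tallies, burden comparisons,
incidences, the positive-case table tallies, common deleted regions,
gene annotation, and a fold-change/FDR threshold filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    EventRecord,
    GenomicInterval,
    ValidationError,
)
from .io import Table1Fixture

__all__ = [
    "CohortSummary",
    "IncidenceResult",
    "tally_events",
    "group_compare",
    "exact_ranksum",
    "incidence",
    "table1_tallies",
    "common_deleted_region",
    "annotate_genes",
    "fdr_filter",
]


@dataclass
class IncidenceResult:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator if self.denominator else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_truncated(self) -> float:
        """One-decimal truncation, the rendering the study prints
        (12/103 -> 11.6, 12/39 -> 30.7)."""
        return math.floor(self.percent * 10) / 10

    @property
    def percent_rounded(self) -> float:
        return round(self.percent, 1)


@dataclass
class CohortSummary:
    n_cases: int = 0
    n_events_total: int = 0
    n_loss: int = 0
    n_gain: int = 0
    n_cnloh: int = 0
    per_case_burden: dict[str, int] = field(default_factory=dict)
    incidence_by_stratum: dict[str, IncidenceResult] = field(default_factory=dict)
    comparisons: list[tuple[str, str, str, float, float]] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_events_total": self.n_events_total,
            "n_loss": self.n_loss,
            "n_gain": self.n_gain,
            "n_cnloh": self.n_cnloh,
            "per_case_burden": dict(self.per_case_burden),
            "incidence_by_stratum": {
                k: {
                    "numerator": v.numerator,
                    "denominator": v.denominator,
                    "percent": v.percent,
                    "percent_truncated": v.percent_truncated,
                    "percent_rounded": v.percent_rounded,
                }
                for k, v in self.incidence_by_stratum.items()
            },
            "comparisons": [list(c) for c in self.comparisons],
        }


def tally_events(events: list[EventRecord]) -> CohortSummary:
    """Class counts and per-case burdens; additive over any case
    partition, with n_events_total = n_loss + n_gain + n_cnloh."""
    summary = CohortSummary()
    for ev in events:
        if ev.event_class == "loss":
            summary.n_loss += 1
        elif ev.event_class == "gain":
            summary.n_gain += 1
        elif ev.event_class == "cnLOH":
            summary.n_cnloh += 1
        else:  # EventRecord validates, but guard mutated inputs
            raise ValidationError(f"unknown event class {ev.event_class!r}")
        summary.per_case_burden[ev.case_id] = summary.per_case_burden.get(ev.case_id, 0) + 1
    summary.n_events_total = summary.n_loss + summary.n_gain + summary.n_cnloh
    summary.n_cases = len(summary.per_case_burden)
    return summary


_EXACT_RANKSUM_LIMIT = 200_000  # max C(n, n1) enumerated


def exact_ranksum(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum (Mann-Whitney U with midranks for
    ties): enumerate all assignments of the pooled midranks to group A
    and count those at least as extreme (|U - n1*n2/2|) as observed."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_mean = n1 * n2 / 2
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2
    dev_obs = abs(u_obs - u_mean)
    total = math.comb(n1 + n2, n1)
    n_extreme = 0
    base = n1 * (n1 + 1) / 2
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - base
        if abs(u - u_mean) >= dev_obs - 1e-9:
            n_extreme += 1
    return float(u_obs), n_extreme / total


def group_compare(a, b, method: str = "t_welch") -> tuple[float, float]:
    """Two-sample burden comparison.

    ``t_welch`` (default) and ``t_student`` are unpaired t tests;
    ``ranksum`` is the two-sided rank-sum test, exact (midranks, full
    enumeration) when feasible and asymptotic otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if method in ("t_welch", "t_student"):
        if a.std() == 0 and b.std() == 0:
            raise ValidationError("zero variance in both groups: t test is degenerate")
        res = stats.ttest_ind(a, b, equal_var=(method == "t_student"))
        return float(res.statistic), float(res.pvalue)
    if method == "ranksum":
        if math.comb(len(a) + len(b), len(a)) <= _EXACT_RANKSUM_LIMIT:
            return exact_ranksum(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown method {method!r}")


def incidence(
    verdicts: dict[str, bool],
    metas,
    stratify=None,
) -> dict[str, IncidenceResult]:
    """Positive-case incidence per stratum.

    ``stratify`` is an attribute name of the case metadata (e.g.
    ``"phenotype"``), a callable meta -> stratum name, or None for a
    single 'all' stratum.  Every verdict must have a matching meta.
    """
    meta_by_id = {m.case_id: m for m in metas}
    missing = set(verdicts) - set(meta_by_id)
    if missing:
        raise ValidationError(f"verdicts without metadata: {sorted(missing)}")
    if stratify is None:
        key = lambda m: "all"  # noqa: E731
    elif callable(stratify):
        key = stratify
    else:
        key = lambda m, attr=stratify: str(getattr(m, attr))  # noqa: E731
    out: dict[str, IncidenceResult] = {}
    for cid, verdict in verdicts.items():
        stratum = key(meta_by_id[cid])
        res = out.setdefault(stratum, IncidenceResult(0, 0))
        res.denominator += 1
        if verdict:
            res.numerator += 1
    return out


# recurrently deleted drivers tallied from the positive-case table
RECURRENT_DELETION_GENES = ("TP53", "RB1", "TCF7", "CDKN1B")
# genes inside the 6q14-q15 region (interstitial del(6q) marker)
_6Q_GENES = {"CASP8AP2", "GRIK2", "SEC63", "FYN"}


def table1_tallies(fixture: Table1Fixture) -> dict:
    """Named counts over the 12 positive cases: chromothriptic-
    chromosome histogram, recurrent deletions, NOTCH1/FBXW7 mutation
    count, and NUP214-rearranged primary events."""
    histogram: dict[int, int] = {}
    for chroms in fixture.cth_chromosomes.values():
        k = len(chroms)
        histogram[k] = histogram.get(k, 0) + 1
    deletions = {}
    for gene in RECURRENT_DELETION_GENES:
        deletions[gene] = sum(
            1 for m in fixture.metas if gene in fixture.deleted_genes(m.case_id)
        )
    deletions["6q14-q15"] = sum(
        1
        for m in fixture.metas
        if fixture.deleted_genes(m.case_id) & _6Q_GENES
    )
    n_notch = sum(1 for m in fixture.metas if m.notch_fbxw7 == "mutated")
    n_nup214 = sum(
        1 for m in fixture.metas if m.primary_event and "NUP214" in m.primary_event
    )
    return {
        "n_cases": len(fixture.metas),
        "cth_chromosome_histogram": dict(sorted(histogram.items())),
        "recurrent_deletions": deletions,
        "notch_fbxw7_mutated": n_notch,
        "nup214_rearranged": n_nup214,
        "nup214_percent": IncidenceResult(n_nup214, len(fixture.metas)),
    }


def common_deleted_region(
    intervals: list[GenomicInterval],
) -> GenomicInterval | None:
    """Intersection of deletion intervals across cases (the CDR);
    None when disjoint.  All intervals must share one chromosome."""
    if len(intervals) < 2:
        raise ValidationError("need >= 2 intervals for a common deleted region")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValidationError(f"mixed chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)


def annotate_genes(
    events: list[EventRecord],
    genes: list[tuple[str, GenomicInterval]],
) -> pd.DataFrame:
    """Per-gene hit table: a gene is hit by an event iff their
    half-open intervals overlap by >= 1 bp.  Rows are (gene,
    event_class) pairs with the number of distinct cases hit."""
    hits: dict[tuple[str, str], set[str]] = {}
    for name, locus in genes:
        for ev in events:
            if locus.overlaps(ev.interval):
                hits.setdefault((name, ev.event_class), set()).add(ev.case_id)
    rows = [
        (gene, cls, len(cases)) for (gene, cls), cases in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "event_class", "case_count"])


def fdr_filter(
    fold_changes,
    p_values,
    fc_min: float = 2.0,
    q_max: float = 0.05,
) -> list[int]:
    """Differential-expression style gate: Benjamini-Hochberg over the
    full p-value vector, keep indices with |fold change| >= fc_min and
    adjusted q < q_max."""
    fc = np.asarray(fold_changes, float)
    p = np.asarray(p_values, float)
    if fc.shape != p.shape:
        raise ValidationError("fold_changes and p_values must have equal length")
    if len(p) == 0:
        return []
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    keep = (np.abs(fc) >= fc_min) & (q < q_max)
    return [int(i) for i in np.nonzero(keep)[0]]
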