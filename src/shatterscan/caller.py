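"""Criteria-based chromothripsis calling on segmented profiles and SV joins.

Two modes:

* ``snpa_only`` — the SNP-array definition: a chromosome is positive
  when its copy-number profile shows at least ``min_switches`` adjacent
  switches oscillating between at most ``max_states`` total-copy-number
  states.  This is the cohort-wide default, applicable wherever only
  array data exist.
* ``full`` — the six sequencing-era criteria: (C1) pronounced
  breakpoint clustering, (C2) oscillating copy-number profile, (C3)
  interspersed loss and retention of heterozygosity, (C4) prevalence of
  rearrangements on a single allele, (C5) randomness of fragment joins
  and order, (C6) ability to walk the derivative chromosome by joining
  breakpoints.  A chromosome is positive when at least ``min_criteria``
  of the six hold.

C1 is a Monte-Carlo Kolmogorov-Smirnov goodness-of-fit of breakpoint
positions against uniform placement over the chromosome; chromothripsis
predicts clustering, so passing means *rejecting* uniformity.  C5 is an
exact (or Monte-Carlo, for many joins) multinomial goodness-of-fit of
the HH/HT/TH/TT join-type counts against the uniform multinomial;
chromothripsis predicts randomness, so passing means *failing to
reject* uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    ConfigurationError,
    CriteriaConfig,
    GenomicInterval,
    SegmentProfile,
    SVJoin,
    ValidationError,
)

__all__ = [
    "CthCall",
    "CohortCalls",
    "count_state_changes",
    "profile_breakpoints",
    "snpa_criterion",
    "test_breakpoint_clustering",
    "null_ks_distribution",
    "test_oscillation",
    "test_loh_interspersion",
    "test_single_allele",
    "test_join_randomness",
    "exact_multinomial_gof",
    "walk_derivative",
    "infer_fragments",
    "score_chromosome",
    "call_cohort",
]

CRITERIA = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass
class CthCall:
    """Per-chromosome chromothripsis verdict."""

    case_id: str
    chrom: str
    is_cth: bool
    n_switches: int
    n_states: int
    span: GenomicInterval | None
    mode: str
    criteria: dict[str, bool] = field(default_factory=dict)
    details: dict[str, object] = field(default_factory=dict)

    @property
    def n_criteria_met(self) -> int:
        return sum(bool(v) for v in self.criteria.values())

    @property
    def span_bp(self) -> int:
        return self.span.width if self.span else 0


def _span_segments(profile: SegmentProfile, chrom: str, pad: int = 1):
    """Segments of the maximal window containing all non-diploid
    (cn != 2) segments of the chromosome, extended by ``pad`` flanking
    segments on each side so the switches into and out of the affected
    region are counted; empty if all segments are diploid."""
    segs = profile.segments.get(chrom, [])
    idx = [i for i, s in enumerate(segs) if s.cn != 2]
    if not idx:
        return []
    return segs[max(idx[0] - pad, 0): idx[-1] + 1 + pad]


def count_state_changes(
    profile: SegmentProfile, chrom: str
) -> tuple[int, int, GenomicInterval | None]:
    """Count copy-number switches in the affected window.

    Returns ``(n_switches, n_states, span)``: the number of adjacent
    segment pairs with different total copy number inside the maximal
    window containing all non-diploid segments (extended one flanking
    segment each side, so the switches into and out of the affected
    region count — a lone deletion in a diploid background scores 2),
    the number of distinct copy-number states in that window, and the
    affected span (first to last non-diploid segment).  cnLOH
    transitions (copy number unchanged) are not switches.  An all-
    diploid or absent chromosome yields ``(0, 1, None)``.
    """
    window = _span_segments(profile, chrom)
    if not window:
        return 0, 1, None
    n_switches = sum(1 for a, b in zip(window, window[1:]) if a.cn != b.cn)
    n_states = len({s.cn for s in window})
    core = [s for s in window if s.cn != 2]
    span = GenomicInterval(chrom, core[0].interval.start, core[-1].interval.end)
    return n_switches, n_states, span


def profile_breakpoints(profile: SegmentProfile, chrom: str) -> list[int]:
    """Internal boundaries where adjacent segments change state."""
    segs = profile.segments.get(chrom, [])
    return [
        a.interval.end
        for a, b in zip(segs, segs[1:])
        if a.state != b.state and a.interval.end == b.interval.start
    ]


def snpa_criterion(
    profile: SegmentProfile, chrom: str, config: CriteriaConfig | None = None
) -> CthCall:
    """The SNP-array definition: >= min_switches oscillating between at
    most max_states copy-number states."""
    config = config or CriteriaConfig()
    n_switches, n_states, span = count_state_changes(profile, chrom)
    is_cth = n_switches >= config.min_switches and n_states <= config.max_states
    return CthCall(
        case_id=profile.case_id,
        chrom=chrom,
        is_cth=is_cth,
        n_switches=n_switches,
        n_states=n_states,
        span=span,
        mode="snpa_only",
    )


def _ks_uniform_distance(x: np.ndarray) -> float:
    """KS distance of points in [0, 1] against the uniform CDF."""
    x = np.sort(x)
    n = len(x)
    grid = np.arange(1, n + 1) / n
    return float(max((grid - x).max(), (x - (grid - 1 / n)).max()))


def null_ks_distribution(
    n: int, n_replicates: int = 10_000, rng: np.random.Generator | None = None
) -> np.ndarray:
    """KS distances of ``n_replicates`` uniform samples of size ``n``."""
    rng = rng or np.random.default_rng(0)
    u = np.sort(rng.random((n_replicates, n)), axis=1)
    grid = np.arange(1, n + 1) / n
    d_plus = (grid - u).max(axis=1)
    d_minus = (u - (grid - 1 / n)).max(axis=1)
    return np.maximum(d_plus, d_minus)


def test_breakpoint_clustering(
    breakpoints,
    chrom_length: int,
    config: CriteriaConfig | None = None,
    rng: np.random.Generator | None = None,
    null_dist: np.ndarray | None = None,
) -> tuple[float, bool]:
    """C1: Monte-Carlo KS test of breakpoints against uniform placement.

    Passing requires *rejecting* uniformity (p < alpha_cluster): the
    breaks are more clustered than chance.  Fewer than
    ``min_cluster_breakpoints`` breakpoints fail automatically at p=1.
    """
    config = config or CriteriaConfig()
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    bp = np.asarray(list(breakpoints), dtype=float)
    if len(bp) < config.min_cluster_breakpoints:
        return 1.0, False
    if bp.min() < 0 or bp.max() > chrom_length:
        raise ValidationError("breakpoints must lie within [0, chrom_length]")
    d_obs = _ks_uniform_distance(bp / chrom_length)
    if null_dist is None:
        null_dist = null_ks_distribution(
            len(bp), config.n_mc_replicates, rng or np.random.default_rng(0)
        )
    p = (1 + int((null_dist >= d_obs - 1e-12).sum())) / (len(null_dist) + 1)
    return p, p < config.alpha_cluster


def test_oscillation(
    profile: SegmentProfile, chrom: str, config: CriteriaConfig | None = None
) -> bool:
    """C2: the profile oscillates between at most max_states states,
    with the two most frequent states covering >= 50% of the window's
    segments, and at least min_switches switches."""
    config = config or CriteriaConfig()
    window = _span_segments(profile, chrom)
    if not window:
        return False
    n_switches, n_states, _ = count_state_changes(profile, chrom)
    counts = {}
    for s in window:
        counts[s.cn] = counts.get(s.cn, 0) + 1
    top2 = sum(sorted(counts.values(), reverse=True)[:2])
    return (
        n_states <= config.max_states
        and top2 >= 0.5 * len(window)
        and n_switches >= config.min_switches
    )


def test_loh_interspersion(
    profile: SegmentProfile, chrom: str, config: CriteriaConfig | None = None
) -> bool:
    """C3: interspersed loss and retention of heterozygosity — count
    alternations of the LOH flag along the affected window."""
    config = config or CriteriaConfig()
    window = _span_segments(profile, chrom)
    alternations = sum(1 for a, b in zip(window, window[1:]) if a.loh != b.loh)
    return alternations >= config.min_loh_alternations


def test_single_allele(
    joins: list[SVJoin],
    haplotypes: list[str | None] | None = None,
    config: CriteriaConfig | None = None,
) -> tuple[bool, str]:
    """C4: prevalence of rearrangements on a single allele.

    Haplotype labels come from the joins themselves (or from
    ``haplotypes``, overriding).  With no labels the criterion abstains
    (fails, flagged 'no data').
    """
    config = config or CriteriaConfig()
    if haplotypes is None:
        haplotypes = [j.haplotype for j in joins]
    labels = [h for h in haplotypes if h is not None]
    if not labels:
        return False, "no data"
    counts: dict[str, int] = {}
    for h in labels:
        counts[h] = counts.get(h, 0) + 1
    frac = max(counts.values()) / len(labels)
    return frac >= config.single_allele_frac, "ok"


def exact_multinomial_gof(counts, probs=None) -> float:
    """Exact p-value of the chi-square statistic for a multinomial
    goodness-of-fit, by enumeration of all outcome vectors."""
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    k = len(counts)
    probs = np.full(k, 1 / k) if probs is None else np.asarray(probs, float)
    expected = n * probs
    chi2_obs = float(((counts - expected) ** 2 / expected).sum())

    comps = _compositions(n, k)
    chi2_all = ((comps - expected) ** 2 / expected).sum(axis=1)
    pmf = np.exp(stats.multinomial.logpmf(comps, n, probs))
    return float(pmf[chi2_all >= chi2_obs - 1e-9].sum())


def _compositions(n: int, k: int) -> np.ndarray:
    if k == 1:
        return np.array([[n]])
    rows = []
    for first in range(n + 1):
        rest = _compositions(n - first, k - 1)
        rows.append(np.column_stack([np.full(len(rest), first), rest]))
    return np.vstack(rows)


JOIN_TYPES = ("HH", "HT", "TH", "TT")
_EXACT_JOIN_LIMIT = 60


def test_join_randomness(
    joins: list[SVJoin] | dict[str, int],
    config: CriteriaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool, str]:
    """C5: join-type counts consistent with the uniform multinomial.

    Chromothripsis predicts random joins, so passing means *not*
    rejecting uniformity (p >= alpha_join).  Fewer than ``min_joins``
    joins abstain (fail, flagged 'insufficient joins').
    """
    config = config or CriteriaConfig()
    if isinstance(joins, dict):
        counts = np.array([joins.get(t, 0) for t in JOIN_TYPES], dtype=int)
    else:
        counts = np.zeros(4, dtype=int)
        for j in joins:
            counts[JOIN_TYPES.index(j.join_type)] += 1
    n = int(counts.sum())
    if n < config.min_joins:
        return 1.0, False, "insufficient joins"
    if n <= _EXACT_JOIN_LIMIT:
        p = exact_multinomial_gof(counts)
    else:
        rng = rng or np.random.default_rng(0)
        expected = n / 4
        chi2_obs = float(((counts - expected) ** 2 / expected).sum())
        reps = rng.multinomial(n, [0.25] * 4, size=config.n_mc_replicates)
        chi2_rep = ((reps - expected) ** 2 / expected).sum(axis=1)
        p = (1 + int((chi2_rep >= chi2_obs - 1e-9).sum())) / (config.n_mc_replicates + 1)
    return p, p >= config.alpha_join, "ok"


def walk_derivative(
    joins: list[SVJoin],
    fragments: list[GenomicInterval],
    config: CriteriaConfig | None = None,
) -> tuple[float, bool]:
    """C6: walk the derivative chromosome through the breakpoint graph.

    Fragment ends are nodes; each fragment contributes a mandatory edge
    between its head and tail, each join an edge between the two ends it
    fuses.  Every end may appear in at most one join, so node degree is
    at most 2 and connected components are simple paths or cycles, each
    fully traversable by a walk alternating fragment and join edges
    (a cycle is a circular derivative, e.g. a ring chromosome).
    Coverage is the largest fraction of joins traversed by one walk.
    """
    config = config or CriteriaConfig()
    if not joins:
        return 0.0, False
    # map (pos, side) -> fragment end node id
    end_lookup: dict[tuple[str, int, str], int] = {}
    for i, frag in enumerate(fragments):
        end_lookup[(frag.chrom, frag.start, "head")] = 2 * i
        end_lookup[(frag.chrom, frag.end, "tail")] = 2 * i + 1

    parent = list(range(2 * len(fragments)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for i in range(len(fragments)):
        union(2 * i, 2 * i + 1)

    used_ends: set[int] = set()
    join_component: list[int | None] = []
    for j in joins:
        nodes = []
        for e in (j.end1, j.end2):
            node = end_lookup.get((e.chrom, e.pos, e.side))
            nodes.append(node)
        if any(n is None for n in nodes):
            join_component.append(None)  # dangling join: counted, untraversable
            continue
        for n in nodes:
            if n in used_ends:
                frag_i, side = divmod(n, 2)
                raise ValidationError(
                    f"fragment end used twice: fragment {frag_i} "
                    f"{'tail' if side else 'head'}"
                )
            used_ends.add(n)
        union(nodes[0], nodes[1])
        join_component.append(nodes[0])

    comp_counts: dict[int, int] = {}
    for node in join_component:
        if node is None:
            continue
        root = find(node)
        comp_counts[root] = comp_counts.get(root, 0) + 1
    best = max(comp_counts.values(), default=0)
    coverage = best / len(joins)
    return coverage, coverage >= config.walk_coverage


def infer_fragments(
    profile: SegmentProfile, chrom: str, joins: list[SVJoin]
) -> list[GenomicInterval]:
    """Retained-fragment intervals for the derivative walk: segments
    with cn >= 2 on the chromosome, split at join breakends falling
    strictly inside them (fragments merged into the diploid arms or
    into same-state neighbours are re-cut)."""
    window = profile.segments.get(chrom, [])
    cutpoints = sorted(
        {
            e.pos
            for j in joins
            for e in (j.end1, j.end2)
            if e.chrom == chrom
        }
    )
    frags: list[GenomicInterval] = []
    for seg in window:
        if seg.cn < 2:
            continue
        bounds = [seg.interval.start]
        bounds += [p for p in cutpoints if seg.interval.start < p < seg.interval.end]
        bounds.append(seg.interval.end)
        for a, b in zip(bounds, bounds[1:]):
            frags.append(GenomicInterval(chrom, a, b))
    return frags


def score_chromosome(
    profile: SegmentProfile,
    joins: list[SVJoin] | None,
    chrom: str,
    config: CriteriaConfig | None = None,
    mode: str = "snpa_only",
    chrom_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> CthCall:
    """Evaluate one chromosome of one case.

    ``snpa_only`` delegates to :func:`snpa_criterion`; ``full``
    evaluates C1-C6 (requires joins) and flags the chromosome when at
    least ``min_criteria`` criteria hold.  Inter-chromosomal joins
    contribute to C4/C5/C6 of both partner chromosomes.
    """
    config = config or CriteriaConfig()
    if mode == "snpa_only":
        return snpa_criterion(profile, chrom, config)
    if mode != "full":
        raise ConfigurationError(f"unknown mode {mode!r}")
    if joins is None:
        raise ConfigurationError("full mode requires joins")

    n_switches, n_states, span = count_state_changes(profile, chrom)
    chrom_joins = [
        j for j in joins if j.end1.chrom == chrom or j.end2.chrom == chrom
    ]
    if chrom_length is None:
        segs = profile.segments.get(chrom, [])
        chrom_length = segs[-1].interval.end if segs else 1

    bp = profile_breakpoints(profile, chrom)
    p_cluster, c1 = test_breakpoint_clustering(bp, chrom_length, config, rng=rng)
    c2 = test_oscillation(profile, chrom, config)
    c3 = test_loh_interspersion(profile, chrom, config)
    c4, c4_status = test_single_allele(chrom_joins, config=config)
    p_join, c5, c5_status = test_join_randomness(chrom_joins, config, rng=rng)
    fragments = infer_fragments(profile, chrom, chrom_joins)
    coverage, c6 = walk_derivative(chrom_joins, fragments, config)

    criteria = {"C1": c1, "C2": c2, "C3": c3, "C4": c4, "C5": c5, "C6": c6}
    call = CthCall(
        case_id=profile.case_id,
        chrom=chrom,
        is_cth=sum(criteria.values()) >= config.min_criteria,
        n_switches=n_switches,
        n_states=n_states,
        span=span,
        mode="full",
        criteria=criteria,
        details={
            "p_cluster": p_cluster,
            "p_join": p_join,
            "walk_coverage": coverage,
            "c4_status": c4_status,
            "c5_status": c5_status,
        },
    )
    return call


@dataclass
class CohortCalls:
    calls: list[CthCall]
    case_verdicts: dict[str, bool]
    flagged_chromosomes: dict[str, list[str]]


def call_cohort(
    profiles: list[SegmentProfile],
    joins: dict[str, list[SVJoin]] | None = None,
    metas=None,
    config: CriteriaConfig | None = None,
    mode: str = "snpa_only",
    chrom_lengths: dict[str, int] | None = None,
) -> CohortCalls:
    """Score every chromosome of every case; a case is positive iff at
    least one of its chromosomes is flagged."""
    config = config or CriteriaConfig()
    seen = set()
    for p in profiles:
        if p.case_id in seen:
            raise ValidationError(f"duplicate case id {p.case_id!r}")
        seen.add(p.case_id)
    if metas is not None:
        meta_ids = {m.case_id for m in metas}
        missing = seen - meta_ids
        if missing:
            raise ValidationError(f"cases without metadata: {sorted(missing)}")
    calls: list[CthCall] = []
    verdicts: dict[str, bool] = {}
    flagged: dict[str, list[str]] = {}
    for prof in profiles:
        case_joins = (joins or {}).get(prof.case_id)
        if mode == "full" and case_joins is None:
            raise ConfigurationError(f"full mode requires joins for {prof.case_id}")
        flagged[prof.case_id] = []
        for chrom in prof.chromosomes():
            clen = (chrom_lengths or {}).get(chrom)
            call = score_chromosome(
                prof, case_joins, chrom, config, mode, chrom_length=clen
            )
            calls.append(call)
            if call.is_cth:
                flagged[prof.case_id].append(chrom)
        verdicts[prof.case_id] = bool(flagged[prof.case_id])
    return CohortCalls(calls, verdicts, flagged)
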