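"""Simulation of chromothriptic and progressively rearranged genomes.

Two generative mechanisms with recorded ground truth:

* :func:`shatter_chromosome` — a one-off catastrophe: clustered double
  strand breaks inside a contiguous region, random fragment loss,
  uniform permutation and random flipping of the retained fragments.
  The resulting copy-number profile oscillates between the diploid
  baseline and the lost state, and the junctions connect consecutive
  retained fragment ends in the derivative order.
* :func:`simulate_progressive` — independent, scattered CNA/cnLOH
  events accumulated over time, the contrast class the caller must not
  flag.

:func:`simulate_cohort` combines them into a study-like cohort: by
default 103 cases (39 ETP/near-ETP, 59 non-ETP, 5 unknown), 12 of the
immature cases positive, positives carrying 10-23 oscillating segments
over a 50-218 Mb region on 1-4 chromosomes on top of the background
burden every case draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import (
    BreakEnd,
    CaseMeta,
    ConfigurationError,
    GenomicInterval,
    Segment,
    SegmentProfile,
    SVJoin,
    ValidationError,
)
from . import io as ssio

__all__ = [
    "CHROM_LENGTHS",
    "AUTOSOMES",
    "ShatterConfig",
    "ProgressiveConfig",
    "GroundTruth",
    "SimulatedCohort",
    "shatter_chromosome",
    "simulate_progressive",
    "simulate_cohort",
    "study_cohort",
    "sample_burden_cth_negative",
    "sample_burden_etp_stratum",
    "sample_burden_non_etp_stratum",
]

# GRCh37 chromosome lengths, rounded to the nearest 0.1 Mb.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_300_000, "2": 243_200_000, "3": 198_000_000, "4": 191_200_000,
    "5": 180_900_000, "6": 171_100_000, "7": 159_100_000, "8": 146_400_000,
    "9": 141_200_000, "10": 135_500_000, "11": 135_000_000, "12": 133_900_000,
    "13": 115_200_000, "14": 107_300_000, "15": 102_500_000, "16": 90_400_000,
    "17": 81_200_000, "18": 78_100_000, "19": 59_100_000, "20": 63_000_000,
    "21": 48_100_000, "22": 51_300_000, "X": 155_300_000, "Y": 59_400_000,
}
AUTOSOMES = tuple(str(i) for i in range(1, 23))

# Default CNA class mix: the loss/gain/cnLOH proportions of the study's
# 830-event tally (536/225/69).
DEFAULT_CLASS_WEIGHTS = (536 / 830, 225 / 830, 69 / 830)

# Background burden of chromothripsis-negative cases: median 5 events,
# observed range 0-14 in both immaturity strata.
_CTH_NEG_POISSON_MEAN = 5.0
_CTH_NEG_MAX = 14

# Stratum-level burden laws (positives included): ETP/near-ETP mean 13,
# median 11, range 0-79; non-ETP mean 5, median 5, range 0-14.
_ETP_NB_R = 2.5
_ETP_NB_MEAN = 13.0
_ETP_MAX = 79


def _truncated_draw(draw, maximum, rng, max_tries=1000):
    for _ in range(max_tries):
        x = int(draw(rng))
        if x <= maximum:
            return x
    return maximum


def sample_burden_cth_negative(rng: np.random.Generator) -> int:
    """Background event count for a chromothripsis-negative case."""
    return _truncated_draw(lambda r: r.poisson(_CTH_NEG_POISSON_MEAN), _CTH_NEG_MAX, rng)


def sample_burden_non_etp_stratum(rng: np.random.Generator) -> int:
    """Total event count law of the non-ETP stratum (median 5, range 0-14)."""
    return sample_burden_cth_negative(rng)


def sample_burden_etp_stratum(rng: np.random.Generator) -> int:
    """Total event count law of the ETP/near-ETP stratum (median 11, range 0-79)."""
    p = _ETP_NB_R / (_ETP_NB_R + _ETP_NB_MEAN)
    return _truncated_draw(lambda r: r.negative_binomial(_ETP_NB_R, p), _ETP_MAX, rng)


@dataclass(frozen=True)
class ShatterConfig:
    """Parameters of one chromothriptic shattering event.

    ``cluster_concentration`` in (0, 1] shrinks the shattered window to
    that fraction of ``region_span_bp`` (1.0 = breaks uniform over the
    whole region).  ``loss_mask`` / ``permutation`` / ``flips`` allow
    deterministic injection for testing and for the cohort generator's
    alternating retained/lost layout.
    """

    chrom: str = "7"
    n_fragments: int = 21
    loss_prob: float = 0.4
    region_span_bp: int = 100_000_000
    chrom_length_bp: int | None = None
    cluster_concentration: float = 1.0
    loh_fraction: float = 0.5
    dup_prob: float = 0.0
    seed: int = 0
    loss_mask: tuple[bool, ...] | None = None
    permutation: tuple[int, ...] | None = None
    flips: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_fragments < 2:
            raise ValidationError("n_fragments must be >= 2")
        if not (0 <= self.loss_prob < 1):
            raise ValidationError("loss_prob must be in [0, 1)")
        length = self.chrom_length_bp or CHROM_LENGTHS.get(self.chrom)
        if length is None:
            raise ValidationError(f"unknown chromosome {self.chrom!r}: give chrom_length_bp")
        if self.region_span_bp > length:
            raise ValidationError("region_span_bp exceeds chromosome length")
        if not (0 < self.cluster_concentration <= 1):
            raise ValidationError("cluster_concentration must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.chrom_length_bp or CHROM_LENGTHS[self.chrom]


@dataclass(frozen=True)
class ProgressiveConfig:
    """Parameters of a progressively rearranged (non-chromothriptic) case."""

    n_events: int = 5
    size_log_bounds: tuple[float, float] = (1e5, 1e7)  # bp, log-uniform
    class_weights: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValidationError("n_events must be >= 0")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValidationError("class_weights must sum to 1")
        lo, hi = self.size_log_bounds
        if not (0 < lo <= hi):
            raise ValidationError("size_log_bounds must satisfy 0 < lo <= hi")


@dataclass
class GroundTruth:
    """What the simulator actually did, for verdict scoring."""

    case_id: str
    cth_chromosomes: set[str] = field(default_factory=set)
    n_segmental_cna: dict[str, int] = field(default_factory=dict)
    lost_fragments: list[GenomicInterval] = field(default_factory=list)
    join_order: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    fragments: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    n_background_events: int = 0

    @property
    def is_positive(self) -> bool:
        return bool(self.cth_chromosomes)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cth_chromosomes"] = sorted(self.cth_chromosomes)
        d["lost_fragments"] = [(i.chrom, i.start, i.end) for i in self.lost_fragments]
        d["fragments"] = {
            c: [(i.chrom, i.start, i.end) for i in v] for c, v in self.fragments.items()
        }
        return d


class SimulationError(RuntimeError):
    pass


def _distinct_ints(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct integers from [0, n) without materializing arange(n)."""
    if k > n:
        raise ValidationError(f"cannot draw {k} distinct values from {n}")
    seen: set[int] = set()
    while len(seen) < k:
        for v in rng.integers(0, n, size=k - len(seen)):
            seen.add(int(v))
    return np.fromiter(seen, dtype=np.int64, count=k)


def _shatter_segments(
    config: ShatterConfig, rng: np.random.Generator
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Draw fragment boundaries and the loss mask (>=2 fragments kept)."""
    length = config.length
    span = int(config.region_span_bp * config.cluster_concentration)
    span = max(span, config.n_fragments * 2)
    region_start = int(rng.integers(0, length - span + 1))
    cuts = region_start + 1 + np.sort(
        _distinct_ints(rng, span - 1, config.n_fragments - 1)
    )
    bounds = np.concatenate(([region_start], cuts, [region_start + span]))
    frags = [
        GenomicInterval(config.chrom, int(a), int(b))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    if config.loss_mask is not None:
        if len(config.loss_mask) != config.n_fragments:
            raise ValidationError("loss_mask length must equal n_fragments")
        lost = np.asarray(config.loss_mask, dtype=bool)
        if (~lost).sum() < 2:
            raise SimulationError("loss_mask retains fewer than 2 fragments")
        return frags, lost
    for _ in range(100):
        lost = rng.random(config.n_fragments) < config.loss_prob
        if (~lost).sum() >= 2:
            return frags, lost
    raise SimulationError("could not retain >= 2 fragments after 100 resamples")


def shatter_chromosome(
    config: ShatterConfig,
) -> tuple[SegmentProfile, list[SVJoin], GroundTruth]:
    """Simulate one chromothriptic chromosome.

    Returns the merged copy-number profile of the whole chromosome
    (diploid outside the shattered region, cn 1 on lost fragments,
    cn 3 on duplicated ones, optional cnLOH on retained ones), the
    derivative-order junctions, and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    frags, lost = _shatter_segments(config, rng)
    n = config.n_fragments
    length = config.length
    region = GenomicInterval(config.chrom, frags[0].start, frags[-1].end)

    retained_idx = [i for i in range(n) if not lost[i]]
    dup = np.zeros(n, dtype=bool)
    if config.dup_prob > 0:
        dup_draw = rng.random(n) < config.dup_prob
        dup = dup_draw & ~lost
    loh = np.zeros(n, dtype=bool)
    if config.loh_fraction > 0:
        loh_draw = rng.random(n) < config.loh_fraction
        loh = loh_draw & ~lost

    # derivative chromosome: permute and flip retained fragments
    if config.permutation is not None:
        perm = list(config.permutation)
        if sorted(perm) != list(range(len(retained_idx))):
            raise ValidationError("permutation must permute the retained fragments")
    else:
        perm = list(rng.permutation(len(retained_idx)))
    if config.flips is not None:
        flips = list(config.flips)
        if len(flips) != len(retained_idx):
            raise ValidationError("flips length must equal number of retained fragments")
    else:
        flips = list(rng.random(len(retained_idx)) < 0.5)

    ordered = [(retained_idx[p], "-" if flips[k] else "+") for k, p in enumerate(perm)]
    joins: list[SVJoin] = []
    for (i, ori_i), (j, ori_j) in zip(ordered, ordered[1:]):
        exit_end = BreakEnd(
            config.chrom,
            frags[i].end if ori_i == "+" else frags[i].start,
            "tail" if ori_i == "+" else "head",
        )
        entry_end = BreakEnd(
            config.chrom,
            frags[j].start if ori_j == "+" else frags[j].end,
            "head" if ori_j == "+" else "tail",
        )
        joins.append(SVJoin(exit_end, entry_end, haplotype="A"))

    segments: list[Segment] = []
    if region.start > 0:
        segments.append(Segment(GenomicInterval(config.chrom, 0, region.start), 2, False))
    for i, frag in enumerate(frags):
        cn = 1 if lost[i] else (3 if dup[i] else 2)
        # a single-copy segment has by definition lost heterozygosity
        segments.append(Segment(frag, cn, bool(lost[i] or loh[i])))
    if region.end < length:
        segments.append(Segment(GenomicInterval(config.chrom, region.end, length), 2, False))
    profile = SegmentProfile.from_segments(f"sim-{config.seed}", segments)

    n_cna = sum(
        1 for seg in profile.segments[config.chrom] if seg.cn != 2
    )
    truth = GroundTruth(
        case_id=profile.case_id,
        cth_chromosomes={config.chrom},
        n_segmental_cna={config.chrom: n_cna},
        lost_fragments=[frags[i] for i in range(n) if lost[i]],
        join_order={config.chrom: ordered},
        fragments={config.chrom: [frags[i] for i in retained_idx]},
    )
    return profile, joins, truth


def _place_events(
    n_events: int,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    size_log_bounds: tuple[float, float],
    exclude_chroms: set[str] = frozenset(),
    max_tries: int = 2000,
) -> list[GenomicInterval]:
    """Place events uniformly (chromosome weighted by length) without overlap."""
    chroms = [c for c in chrom_lengths if c not in exclude_chroms]
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = size_log_bounds
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomicInterval] = []
    for _ in range(n_events):
        for _try in range(max_tries):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            clen = chrom_lengths[chrom]
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if size >= clen:
                size = clen // 2  # resize events larger than the chromosome
            start = int(rng.integers(0, clen - size))
            end = start + size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise SimulationError("could not place a non-overlapping event")
    return out


def simulate_progressive(
    config: ProgressiveConfig,
    chrom_lengths: dict[str, int] | None = None,
    case_id: str | None = None,
    exclude_chroms: set[str] = frozenset(),
    rng: np.random.Generator | None = None,
) -> tuple[SegmentProfile, list[SVJoin], GroundTruth]:
    """Simulate a case with scattered, independent CNA/cnLOH events.

    Deletions emit one junction (left-flank tail to right-flank head),
    tandem gains one (head to tail); cnLOH emits none.  Chromosome-level
    clustering arises only by chance.
    """
    chrom_lengths = dict(chrom_lengths or {c: CHROM_LENGTHS[c] for c in AUTOSOMES})
    rng = rng or np.random.default_rng(config.seed)
    case_id = case_id or f"sim-{config.seed}"
    intervals = _place_events(
        config.n_events, chrom_lengths, rng, config.size_log_bounds, exclude_chroms
    )
    classes = [
        ("loss", "gain", "cnLOH")[int(k)]
        for k in rng.choice(3, size=config.n_events, p=list(config.class_weights))
    ]
    segments: list[Segment] = []
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, cls in zip(intervals, classes):
        by_chrom.setdefault(iv.chrom, []).append((iv, cls))
    joins: list[SVJoin] = []
    for chrom, clen in chrom_lengths.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda t: t[0].start)
        cursor = 0
        for iv, cls in evs:
            if iv.start > cursor:
                segments.append(Segment(GenomicInterval(chrom, cursor, iv.start), 2, False))
            cn = {"loss": 1, "gain": 3, "cnLOH": 2}[cls]
            segments.append(Segment(iv, cn, cls in ("cnLOH", "loss")))
            if cls == "loss":
                joins.append(
                    SVJoin(
                        BreakEnd(chrom, iv.start, "tail"),
                        BreakEnd(chrom, iv.end, "head"),
                    )
                )
            elif cls == "gain":
                joins.append(
                    SVJoin(
                        BreakEnd(chrom, iv.start, "head"),
                        BreakEnd(chrom, iv.end, "tail"),
                    )
                )
            cursor = iv.end
        if cursor < clen:
            segments.append(Segment(GenomicInterval(chrom, cursor, clen), 2, False))
    profile = SegmentProfile.from_segments(case_id, segments)
    truth = GroundTruth(case_id=case_id, n_background_events=config.n_events)
    return profile, joins, truth


@dataclass
class SimulatedCohort:
    profiles: list[SegmentProfile]
    joins: dict[str, list[SVJoin]]
    metas: list[CaseMeta]
    truths: dict[str, GroundTruth]
    params: dict = field(default_factory=dict)

    def to_files(self, outdir) -> dict[str, str]:
        """Write the datamodel TSV dialects plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "segments": ssio.write_segments(self.profiles, outdir / "segments.tsv"),
            "cohort": ssio.write_cohort_meta(self.metas, outdir / "cohort.tsv"),
        }
        all_joins = []
        join_case = []
        for cid in sorted(self.joins):
            for j in self.joins[cid]:
                all_joins.append(j)
                join_case.append(cid)
        paths["joins"] = ssio.write_joins(all_joins, outdir / "joins.tsv")
        truth = {
            "params": self.params,
            "cases": {cid: t.to_jsonable() for cid, t in self.truths.items()},
        }
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
        paths["truth"] = str(truth_path)
        return paths


# chromothriptic chromosome multiplicities of the 12 positives:
# one chromosome in 7 cases, two in 3, three in 1, four in 1.
STUDY_CTH_CHROM_PATTERN = (1,) * 7 + (2,) * 3 + (3,) + (4,)

# chromosomes long enough to host a >= 50 Mb shattered region
_CTH_ELIGIBLE = tuple(c for c in AUTOSOMES if CHROM_LENGTHS[c] * 0.9 >= 50_000_000)

CNA_RANGE = (10, 23)        # segmental CNA per chromothriptic chromosome
SPAN_RANGE_MB = (50, 218)   # shattered region span


def _simulate_positive(
    case_id: str,
    n_cth_chroms: int,
    rng: np.random.Generator,
    background_events: int,
    chrom_lengths: dict[str, int],
) -> tuple[SegmentProfile, list[SVJoin], GroundTruth]:
    cth_chroms = list(rng.choice(_CTH_ELIGIBLE, size=n_cth_chroms, replace=False))
    prof_bg, joins, truth_bg = simulate_progressive(
        ProgressiveConfig(n_events=background_events),
        chrom_lengths,
        case_id=case_id,
        exclude_chroms=set(cth_chroms),
        rng=rng,
    )
    truth = GroundTruth(case_id=case_id, n_background_events=background_events)
    segments = [s for ch in prof_bg.segments for s in prof_bg.segments[ch]
                if ch not in cth_chroms]
    for chrom in cth_chroms:
        m = int(rng.integers(CNA_RANGE[0], CNA_RANGE[1] + 1))
        clen = chrom_lengths.get(chrom, CHROM_LENGTHS[chrom])
        hi = min(SPAN_RANGE_MB[1] * 1_000_000, int(clen * 0.9))
        span = int(rng.integers(SPAN_RANGE_MB[0] * 1_000_000, hi + 1))
        # alternating retained/lost layout: m lost runs, 2m+1 fragments
        mask = tuple(i % 2 == 1 for i in range(2 * m + 1))
        cfg = ShatterConfig(
            chrom=chrom,
            n_fragments=2 * m + 1,
            region_span_bp=span,
            chrom_length_bp=clen,
            loh_fraction=0.5,
            seed=int(rng.integers(0, 2**31 - 1)),
            loss_mask=mask,
        )
        prof_c, joins_c, truth_c = shatter_chromosome(cfg)
        segments.extend(prof_c.segments[chrom])
        joins.extend(joins_c)
        truth.cth_chromosomes.add(chrom)
        truth.n_segmental_cna[chrom] = truth_c.n_segmental_cna[chrom]
        truth.lost_fragments.extend(truth_c.lost_fragments)
        truth.join_order[chrom] = truth_c.join_order[chrom]
        truth.fragments[chrom] = truth_c.fragments[chrom]
    profile = SegmentProfile.from_segments(case_id, segments)
    return profile, joins, truth


def simulate_cohort(
    n_cases: int,
    positive_ids: list[str] | None = None,
    *,
    n_positives: int | None = None,
    phenotypes: dict[str, str] | None = None,
    cth_chrom_counts: tuple[int, ...] | None = None,
    master_seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> SimulatedCohort:
    """Simulate a cohort with known chromothripsis truth.

    Positives carry 10-23 segmental CNA per chromothriptic chromosome
    over 50-218 Mb on top of the shared background burden (median 5
    events); negatives carry background only.  Per-case seeds derive
    deterministically from ``master_seed``.
    """
    case_ids = [f"case_{i + 1:03d}" for i in range(n_cases)]
    if positive_ids is None:
        k = n_positives or 0
        if k > n_cases:
            raise ConfigurationError("n_cases smaller than the number of positives")
        positive_ids = case_ids[:k]
    if not set(positive_ids) <= set(case_ids):
        raise ConfigurationError("positive_ids must be a subset of the case ids")
    if n_cases < len(positive_ids):
        raise ConfigurationError("n_cases smaller than the number of positives")
    chrom_lengths = dict(chrom_lengths or {c: CHROM_LENGTHS[c] for c in AUTOSOMES})
    counts = cth_chrom_counts
    if counts is None:
        pat = STUDY_CTH_CHROM_PATTERN
        counts = tuple(pat[i % len(pat)] for i in range(len(positive_ids)))
    elif len(counts) != len(positive_ids):
        raise ConfigurationError("cth_chrom_counts length must match positives")

    profiles, joins, metas, truths = [], {}, [], {}
    pos_rank = {cid: i for i, cid in enumerate(positive_ids)}
    for idx, cid in enumerate(case_ids):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, idx)))
        background = sample_burden_cth_negative(rng)
        if cid in pos_rank:
            prof, js, truth = _simulate_positive(
                cid, counts[pos_rank[cid]], rng, background, chrom_lengths
            )
        else:
            prof, js, truth = simulate_progressive(
                ProgressiveConfig(n_events=background),
                chrom_lengths,
                case_id=cid,
                rng=rng,
            )
        phenotype = (phenotypes or {}).get(cid, "unknown")
        metas.append(CaseMeta(case_id=cid, age_group="adult", phenotype=phenotype))
        profiles.append(prof)
        joins[cid] = js
        truths[cid] = truth
    params = {
        "n_cases": n_cases,
        "positive_ids": list(positive_ids),
        "cth_chrom_counts": list(counts),
        "master_seed": master_seed,
        "cna_range": list(CNA_RANGE),
        "span_range_mb": list(SPAN_RANGE_MB),
    }
    return SimulatedCohort(profiles, joins, metas, truths, params)


def study_cohort(master_seed: int = 0) -> SimulatedCohort:
    """The study-design preset: 103 cases, 12 positives, all positives
    in the immature (ETP/near-ETP) adult stratum of 39, 59 non-ETP,
    5 of unknown phenotype."""
    n_cases = 103
    case_ids = [f"case_{i + 1:03d}" for i in range(n_cases)]
    positives = case_ids[:12]
    phenotypes: dict[str, str] = {}
    for i, cid in enumerate(case_ids):
        if i < 10:
            phenotypes[cid] = "ETP"
        elif i < 12:
            phenotypes[cid] = "near-ETP"
        elif i < 39:
            phenotypes[cid] = "ETP" if i % 2 else "near-ETP"
        elif i < 98:
            phenotypes[cid] = "non-ETP"
        else:
            phenotypes[cid] = "unknown"
    cohort = simulate_cohort(
        n_cases,
        positives,
        phenotypes=phenotypes,
        master_seed=master_seed,
    )
    cohort.params["preset"] = "study"
    return cohort
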