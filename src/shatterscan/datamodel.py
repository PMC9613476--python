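"""Core domain types for segmented copy-number profiles and SV joins.

Coordinates are 0-based, half-open throughout: an interval covers
``start <= x < end``.  Total copy number is an integer with diploid
baseline 2; ``loh`` marks loss of heterozygosity, so a segment with
``cn == 2`` and ``loh`` is a copy-neutral LOH (cnLOH) segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "GenomicInterval",
    "Segment",
    "SegmentProfile",
    "BreakEnd",
    "SVJoin",
    "EventRecord",
    "CaseMeta",
    "CriteriaConfig",
    "merge_segments",
    "segments_to_events",
]

PHENOTYPES = ("ETP", "near-ETP", "non-ETP", "unknown")
AGE_GROUPS = ("pediatric", "adult")
EVENT_CLASSES = ("loss", "gain", "cnLOH")
SIDES = ("head", "tail")


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete run configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class Segment:
    interval: GenomicInterval
    cn: int
    loh: bool = False

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValidationError(f"cn must be >= 0, got {self.cn}")

    @property
    def state(self) -> tuple[int, bool]:
        return (self.cn, self.loh)

    @property
    def is_diploid(self) -> bool:
        return self.cn == 2 and not self.loh


def merge_segments(segments: list[Segment]) -> list[Segment]:
    """Merge adjacent same-state segments into maximal runs.

    Segments must be on one chromosome, sorted and non-overlapping.
    Only abutting segments (no gap) with identical (cn, loh) merge.
    """
    merged: list[Segment] = []
    for seg in segments:
        if (
            merged
            and merged[-1].interval.end == seg.interval.start
            and merged[-1].state == seg.state
        ):
            prev = merged[-1]
            merged[-1] = Segment(
                GenomicInterval(prev.interval.chrom, prev.interval.start, seg.interval.end),
                prev.cn,
                prev.loh,
            )
        else:
            merged.append(seg)
    return merged


@dataclass
class SegmentProfile:
    """One case's segmented copy-number profile, per chromosome.

    Within a chromosome segments are sorted, non-overlapping, and
    maximal (adjacent segments never share the same (cn, loh) state).
    """

    case_id: str
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            for a, b in zip(segs, segs[1:]):
                if a.interval.end > b.interval.start:
                    raise ValidationError(
                        f"{self.case_id}/{chrom}: segments overlap or are unsorted "
                        f"at [{a.interval.start},{a.interval.end}) vs "
                        f"[{b.interval.start},{b.interval.end})"
                    )
                if a.interval.end == b.interval.start and a.state == b.state:
                    raise ValidationError(
                        f"{self.case_id}/{chrom}: adjacent segments share state "
                        f"{a.state}; profile is not maximally segmented"
                    )

    def chromosomes(self) -> list[str]:
        return list(self.segments)

    @classmethod
    def from_segments(cls, case_id: str, segments: list[Segment]) -> "SegmentProfile":
        """Build a profile, sorting and merging per chromosome."""
        by_chrom: dict[str, list[Segment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.interval.chrom, []).append(seg)
        out: dict[str, list[Segment]] = {}
        for chrom in by_chrom:
            segs = sorted(by_chrom[chrom], key=lambda s: s.interval.start)
            out[chrom] = merge_segments(segs)
        prof = cls(case_id, out)
        prof.validate()
        return prof


@dataclass(frozen=True)
class BreakEnd:
    chrom: str
    pos: int
    side: str  # "head" = lower-coordinate fragment end, "tail" = higher

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"pos must be >= 0, got {self.pos}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.side)


@dataclass(frozen=True)
class SVJoin:
    """A junction fusing two fragment ends.

    Stored in canonical order (lexicographic by (chrom, pos, side)) so
    equality is well defined; ``join_type`` concatenates the side
    initials (H for head, T for tail) of the canonically ordered ends.
    A deletion-like junction (tail of the left flank to head of the
    right flank) therefore reads TH, a tandem-gain junction HT.
    """

    end1: BreakEnd
    end2: BreakEnd
    haplotype: str | None = None

    def __post_init__(self) -> None:
        e1, e2 = self.end1, self.end2
        if e2.sort_key < e1.sort_key:
            object.__setattr__(self, "end1", e2)
            object.__setattr__(self, "end2", e1)

    @property
    def join_type(self) -> str:
        return self.end1.side[0].upper() + self.end2.side[0].upper()


@dataclass(frozen=True)
class EventRecord:
    """One CNA or cnLOH call: a maximal non-diploid segment of a case."""

    case_id: str
    interval: GenomicInterval
    event_class: str

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValidationError(
                f"event_class must be one of {EVENT_CLASSES}, got {self.event_class!r}"
            )


@dataclass(frozen=True)
class CaseMeta:
    case_id: str
    age_group: str = "unknown"
    phenotype: str = "unknown"
    primary_event: str | None = None
    notch_fbxw7: str = "unknown"

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS + ("unknown",):
            raise ValidationError(f"invalid age_group {self.age_group!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"invalid phenotype {self.phenotype!r}")
        if self.notch_fbxw7 not in ("mutated", "wild-type", "unknown"):
            raise ValidationError(f"invalid notch_fbxw7 {self.notch_fbxw7!r}")


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds for the chromothripsis criteria.

    ``min_switches`` and ``max_states`` encode the SNP-array definition
    (at least ten copy-number switches oscillating between at most
    two/three states); ``min_criteria`` is the number of the six
    sequencing-era criteria required for a positive call in full mode.
    The per-criterion thresholds (alpha levels, fractions, counts) are
    configurable because the criteria are qualitative in the source
    definitions.
    """

    min_switches: int = 10
    max_states: int = 3
    min_criteria: int = 3
    alpha_cluster: float = 0.01
    alpha_join: float = 0.05
    single_allele_frac: float = 0.8
    min_loh_alternations: int = 3
    walk_coverage: float = 0.9
    min_segment_bp: int = 100_000
    # machinery knobs, not criteria themselves
    n_mc_replicates: int = 10_000
    min_cluster_breakpoints: int = 3
    min_joins: int = 8

    def __post_init__(self) -> None:
        if self.min_switches < 1:
            raise ValidationError("min_switches must be >= 1")
        if self.max_states < 2:
            raise ValidationError("max_states must be >= 2")
        if not (1 <= self.min_criteria <= 6):
            raise ValidationError("min_criteria must be in 1..6")
        for name in ("alpha_cluster", "alpha_join", "single_allele_frac", "walk_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")

    def with_overrides(self, **kwargs) -> "CriteriaConfig":
        return replace(self, **kwargs)


def segments_to_events(profile: SegmentProfile) -> list[EventRecord]:
    """Emit one event per maximal non-diploid (or cnLOH) segment.

    cn < 2 -> loss, cn > 2 -> gain, cn == 2 with LOH -> cnLOH; plain
    diploid segments emit nothing.  Because profiles are maximally
    segmented, runs are never double counted.
    """
    profile.validate()
    events: list[EventRecord] = []
    for chrom in profile.segments:
        for seg in profile.segments[chrom]:
            if seg.cn < 2:
                cls = "loss"
            elif seg.cn > 2:
                cls = "gain"
            elif seg.loh:
                cls = "cnLOH"
            else:
                continue
            events.append(EventRecord(profile.case_id, seg.interval, cls))
    return events
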