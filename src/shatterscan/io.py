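"""Readers and writers for segment, join, gene, and cohort tables.

All tables are header-bearing TSV.  Default dialects:

* segments: ``case_id  chrom  start  end  cn  loh`` (loh as 0/1)
* joins:    ``chrom1  pos1  side1  chrom2  pos2  side2  [haplotype]``
* genes:    standard 4-column BED (no header)
* cohort:   ``case_id  age_group  phenotype  primary_event  notch_fbxw7``

Coordinates are 0-based half-open; a dialect can declare 1-based input
and it is converted on read.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (
    BreakEnd,
    CaseMeta,
    EventRecord,
    FormatError,
    GenomicInterval,
    Segment,
    SegmentProfile,
    SVJoin,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ("case_id", "chrom", "start", "end", "cn", "loh")
JOIN_COLUMNS = ("chrom1", "pos1", "side1", "chrom2", "pos2", "side2")
COHORT_COLUMNS = ("case_id", "age_group", "phenotype", "primary_event", "notch_fbxw7")


@dataclass(frozen=True)
class SegmentDialect:
    """Column-name map and coordinate convention for segment tables."""

    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in SEGMENT_COLUMNS}
    )
    one_based: bool = False


def _read_tsv(path, required, label):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{label} file {path} is empty (expected a header)")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{label} file {path} is missing column {col!r}")
    return df


def read_segments(
    path,
    dialect: SegmentDialect | None = None,
    min_segment_bp: int = 0,
) -> list[SegmentProfile]:
    """Read segment profiles from TSV.

    Adjacent same-state segments are merged (maximal segmentation) and
    segments shorter than ``min_segment_bp`` are dropped; the dropped
    count is logged.
    """
    dialect = dialect or SegmentDialect()
    cols = dialect.columns
    df = _read_tsv(path, [cols[c] for c in SEGMENT_COLUMNS], "segment")
    rows_by_case: dict[str, list[Segment]] = {}
    n_dropped = 0
    offset = 1 if dialect.one_based else 0
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        rec = {c: getattr(row, cols[c]) for c in SEGMENT_COLUMNS}
        try:
            # 1-based inclusive [start, end] -> 0-based half-open [start-1, end)
            start = int(rec["start"]) - offset
            end = int(rec["end"])
            cn = int(rec["cn"])
            loh = bool(int(rec["loh"]))
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-numeric field ({exc})")
        if start >= end:
            raise ValidationError(f"line {line_no}: start >= end ({start} >= {end})")
        if end - start < min_segment_bp:
            n_dropped += 1
            continue
        seg = Segment(GenomicInterval(str(rec["chrom"]), start, end), cn, loh)
        rows_by_case.setdefault(str(rec["case_id"]), []).append(seg)
    if n_dropped:
        logger.info("read_segments: dropped %d segments < %d bp", n_dropped, min_segment_bp)
    return [
        SegmentProfile.from_segments(case_id, segs)
        for case_id, segs in rows_by_case.items()
    ]


def write_segments(profiles: list[SegmentProfile], path) -> str:
    rows = []
    for prof in profiles:
        prof.validate()
        for chrom in prof.segments:
            for seg in prof.segments[chrom]:
                rows.append(
                    (prof.case_id, chrom, seg.interval.start, seg.interval.end,
                     seg.cn, int(seg.loh))
                )
    df = pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def read_joins(path) -> list[SVJoin]:
    df = _read_tsv(path, JOIN_COLUMNS, "join")
    joins = []
    has_hap = "haplotype" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        try:
            e1 = BreakEnd(str(row.chrom1), int(row.pos1), str(row.side1))
            e2 = BreakEnd(str(row.chrom2), int(row.pos2), str(row.side2))
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}")
        hap = getattr(row, "haplotype", None) if has_hap else None
        joins.append(SVJoin(e1, e2, haplotype=hap or None))
    return joins


def write_joins(joins: list[SVJoin], path) -> str:
    rows = [
        (j.end1.chrom, j.end1.pos, j.end1.side,
         j.end2.chrom, j.end2.pos, j.end2.side, j.haplotype or "")
        for j in joins
    ]
    df = pd.DataFrame(rows, columns=list(JOIN_COLUMNS) + ["haplotype"])
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def read_gene_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read a 4-column BED file into (name, interval) pairs."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"BED line {line_no}: expected 4 columns, got {len(parts)}"
                )
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"BED line {line_no}: {exc}")
            genes.append((parts[3], iv))
    return genes


def read_cohort_meta(path) -> list[CaseMeta]:
    df = _read_tsv(path, COHORT_COLUMNS, "cohort")
    return [
        CaseMeta(
            case_id=str(r.case_id),
            age_group=str(r.age_group),
            phenotype=str(r.phenotype),
            primary_event=str(r.primary_event) or None,
            notch_fbxw7=str(r.notch_fbxw7),
        )
        for r in df.itertuples(index=False)
    ]


def write_cohort_meta(metas: list[CaseMeta], path) -> str:
    df = pd.DataFrame(
        [
            (m.case_id, m.age_group, m.phenotype, m.primary_event or "", m.notch_fbxw7)
            for m in metas
        ],
        columns=list(COHORT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def write_events(events: list[EventRecord], path) -> str:
    df = pd.DataFrame(
        [
            (e.case_id, e.interval.chrom, e.interval.start, e.interval.end, e.event_class)
            for e in events
        ],
        columns=["case_id", "chrom", "start", "end", "event_class"],
    )
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def read_events(path) -> list[EventRecord]:
    df = _read_tsv(path, ("case_id", "chrom", "start", "end", "event_class"), "event")
    return [
        EventRecord(
            str(r.case_id),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            str(r.event_class),
        )
        for r in df.itertuples(index=False)
    ]


_ARR_RE = re.compile(r"arr\(([^)]*)\)cth")


def parse_cth_chromosomes(arr_string: str) -> set[str]:
    """Parse chromothriptic chromosome sets from ``arr(...)cth`` strings.

    Arm suffixes (p/q) are stripped: ``arr(1p)cth`` -> {"1"},
    ``arr(6,7,9)cth`` -> {"6", "7", "9"}.
    """
    m = _ARR_RE.search(arr_string)
    if not m:
        raise FormatError(f"cannot parse chromothripsis string {arr_string!r}")
    chroms = set()
    for tok in m.group(1).split(","):
        tok = tok.strip().rstrip("pq")
        if not tok:
            raise FormatError(f"empty chromosome token in {arr_string!r}")
        chroms.add(tok)
    return chroms


@dataclass(frozen=True)
class Table1Fixture:
    """The 12 chromothripsis-positive cases of the study cohort."""

    metas: list[CaseMeta]
    cth_chromosomes: dict[str, set[str]]
    additional_events: dict[str, list[str]]
    epigenetic_alterations: dict[str, list[str]]

    def deleted_genes(self, case_id: str) -> set[str]:
        """Genes lost in a case's 'del' tokens (compound names split on '-')."""
        genes = set()
        for tok in self.additional_events[case_id]:
            if tok.endswith(" del"):
                for part in tok[:-4].split("-"):
                    genes.add(part.strip())
        return genes


def load_table1_fixture() -> Table1Fixture:
    ref = importlib.resources.files("shatterscan").joinpath("data/table1.tsv")
    try:
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FormatError("packaged table1 fixture is missing")
    required = {"case_id", "age_group", "phenotype", "notch_fbxw7",
                "primary_event", "cth_event", "additional_events"}
    if not required <= set(df.columns):
        raise FormatError("packaged table1 fixture is corrupt (missing columns)")
    if len(df) != 12:
        raise FormatError(f"table1 fixture must have 12 cases, found {len(df)}")
    metas, cth, extra, epi = [], {}, {}, {}
    for r in df.itertuples(index=False):
        cid = str(r.case_id)
        metas.append(
            CaseMeta(
                case_id=cid,
                age_group=str(r.age_group),
                phenotype=str(r.phenotype),
                primary_event=str(r.primary_event),
                notch_fbxw7=str(r.notch_fbxw7),
            )
        )
        cth[cid] = parse_cth_chromosomes(str(r.cth_event))
        extra[cid] = [t for t in str(r.additional_events).split(";") if t]
        epi_field = getattr(r, "epigenetic_alterations", "")
        epi[cid] = [t for t in str(epi_field).split(";") if t]
    return Table1Fixture(metas, cth, extra, epi)
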