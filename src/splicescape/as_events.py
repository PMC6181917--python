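"""Alternative-splicing event detection from isoform comparison.

Detects the five local AS event types — skipped exon (SE), retained intron
(RI), alternative 5'/3' splice site (A5SS/A3SS) and mutually exclusive
exons (MXE) — by comparing isoform pairs within a gene, in the style of
transcript-model-driven event generators. Each event carries the junction
sets of its exon-inclusion (EII) and exon-exclusion (EEI) isoform forms and
a canonical key that is invariant to the order of the isoform pair that
produced it.

Strand conventions: a variable boundary on the genomic left of an intron is
the donor on '+' (hence A5SS) and the acceptor on '-' (hence A3SS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .annotation_model import (
    GeneModel,
    RegionPartition,
    TranscriptModel,
    longest_isoform,
    partition_regions,
)

__all__ = [
    "EVENT_TYPES",
    "ASEvent",
    "detect_events",
    "assign_region",
    "event_catalog",
    "events_table",
    "type_counts",
    "region_type_matrix",
]

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")

Interval = tuple[int, int]


@dataclass(frozen=True)
class ASEvent:
    """A typed local AS event with inclusion/exclusion junction structures."""

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    anchors: tuple[int, ...]
    inclusion_junctions: frozenset[Interval]
    exclusion_junctions: frozenset[Interval]
    region: str = "unpartitioned"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.inclusion_junctions & self.exclusion_junctions:
            raise ValueError("inclusion and exclusion junction sets overlap")

    @property
    def key(self) -> str:
        """Canonical event identifier (pair-order invariant)."""
        if self.event_type == "RI":
            # Outer exon bounds may differ between isoform pairs yielding the
            # same retained intron; identity is the intron itself.
            coords = self.anchors[1:3]
        else:
            coords = self.anchors
        return (
            f"{self.event_type}@{self.chrom}:{self.strand}:"
            + "-".join(str(c) for c in coords)
        )

    @property
    def defining_span(self) -> Interval:
        """The genomic span that characterizes the event (for region calls)."""
        a = self.anchors
        if self.event_type == "SE":
            return (a[1], a[2])  # skipped exon
        if self.event_type == "RI":
            return (a[1], a[2])  # retained intron
        if self.event_type in ("A5SS", "A3SS"):
            lo, hi = sorted(a[1:3])
            return (lo, hi)  # between the two alternative boundaries
        return (a[1], a[4])  # MXE: hull of the two exons


def _junction_set(t: TranscriptModel) -> set[Interval]:
    return set(t.junctions())


def _exon_ending_at(t: TranscriptModel, pos: int) -> Interval | None:
    for s, e in t.exons:
        if e == pos:
            return (s, e)
    return None


def _exon_starting_at(t: TranscriptModel, pos: int) -> Interval | None:
    for s, e in t.exons:
        if s == pos:
            return (s, e)
    return None


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _se_events(t_inc: TranscriptModel, t_exc: TranscriptModel) -> list[ASEvent]:
    """Skipped exons: t_inc has one intervening exon, t_exc splices past it."""
    out = []
    exc_junctions = _junction_set(t_exc)
    for i in range(1, len(t_inc.exons) - 1):
        up_end = t_inc.exons[i - 1][1]
        skip_s, skip_e = t_inc.exons[i]
        down_start = t_inc.exons[i + 1][0]
        if (up_end, down_start) in exc_junctions:
            out.append(
                ASEvent(
                    "SE",
                    t_inc.gene_id,
                    t_inc.chrom,
                    t_inc.strand,
                    (up_end, skip_s, skip_e, down_start),
                    frozenset({(up_end, skip_s), (skip_e, down_start)}),
                    frozenset({(up_end, down_start)}),
                )
            )
    return out


def _ri_events(t_ret: TranscriptModel, t_spl: TranscriptModel) -> list[ASEvent]:
    """Retained introns: a single exon of t_ret spans two exons of t_spl."""
    out = []
    ret_exons = set(t_ret.exons)
    for i in range(len(t_spl.exons) - 1):
        a, x = t_spl.exons[i]
        y, b = t_spl.exons[i + 1]
        if (a, b) in ret_exons:
            out.append(
                ASEvent(
                    "RI",
                    t_ret.gene_id,
                    t_ret.chrom,
                    t_ret.strand,
                    (a, x, y, b),
                    frozenset(),  # retention evidence is not a junction
                    frozenset({(x, y)}),
                )
            )
    return out


def _alt_ss_events(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """Alternative 5'/3' splice sites from junction pairs sharing one site.

    The two variable boundaries must sit on overlapping exons, which
    distinguishes a genuine alternative site from the junction pattern an SE
    or MXE pair also produces.
    """
    out = []
    strand = t1.strand
    for j1 in t1.junctions():
        for j2 in t2.junctions():
            if j1 == j2:
                continue
            if j1[1] == j2[1] and j1[0] != j2[0]:
                # variable genomic-left boundary
                e1 = _exon_ending_at(t1, j1[0])
                e2 = _exon_ending_at(t2, j2[0])
                if e1 and e2 and _overlap(e1, e2) > 0:
                    lo, hi = sorted((j1[0], j2[0]))
                    etype = "A5SS" if strand == "+" else "A3SS"
                    shared = j1[1]
                    # shorter intron (hi, shared) is the inclusion form
                    out.append(
                        ASEvent(
                            etype,
                            t1.gene_id,
                            t1.chrom,
                            strand,
                            (shared, lo, hi),
                            frozenset({(hi, shared)}),
                            frozenset({(lo, shared)}),
                        )
                    )
            elif j1[0] == j2[0] and j1[1] != j2[1]:
                # variable genomic-right boundary
                e1 = _exon_starting_at(t1, j1[1])
                e2 = _exon_starting_at(t2, j2[1])
                if e1 and e2 and _overlap(e1, e2) > 0:
                    lo, hi = sorted((j1[1], j2[1]))
                    etype = "A3SS" if strand == "+" else "A5SS"
                    shared = j1[0]
                    # shorter intron (shared, lo) is the inclusion form
                    out.append(
                        ASEvent(
                            etype,
                            t1.gene_id,
                            t1.chrom,
                            strand,
                            (shared, lo, hi),
                            frozenset({(shared, lo)}),
                            frozenset({(shared, hi)}),
                        )
                    )
    return out


def _mxe_events(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """Mutually exclusive exons between shared flanking donor/acceptor."""
    out = []
    for i in range(1, len(t1.exons) - 1):
        u1_end = t1.exons[i - 1][1]
        m1 = t1.exons[i]
        d1_start = t1.exons[i + 1][0]
        for j in range(1, len(t2.exons) - 1):
            if t2.exons[j - 1][1] != u1_end or t2.exons[j + 1][0] != d1_start:
                continue
            m2 = t2.exons[j]
            if m1 == m2 or _overlap(m1, m2) > 0:
                continue
            first, second = sorted((m1, m2))
            out.append(
                ASEvent(
                    "MXE",
                    t1.gene_id,
                    t1.chrom,
                    t1.strand,
                    (u1_end, *first, *second, d1_start),
                    frozenset({(u1_end, first[0]), (first[1], d1_start)}),
                    frozenset({(u1_end, second[0]), (second[1], d1_start)}),
                )
            )
    return out


def detect_events(g: GeneModel) -> list[ASEvent]:
    """All simple pairwise AS events of a gene, deduplicated by canonical key.

    Complex isoform nests emit the maximal set of simple pairwise events; no
    compound event types are produced. Genes with fewer than two isoforms
    yield no events. The result is deterministic and independent of isoform
    ordering.
    """
    by_key: dict[str, ASEvent] = {}
    transcripts = sorted(g.transcripts, key=lambda t: t.transcript_id)
    for t1, t2 in combinations(transcripts, 2):
        found: list[ASEvent] = []
        found += _se_events(t1, t2) + _se_events(t2, t1)
        found += _ri_events(t1, t2) + _ri_events(t2, t1)
        found += _alt_ss_events(t1, t2)
        found += _mxe_events(t1, t2)
        for ev in found:
            by_key.setdefault(ev.key, ev)
    return sorted(by_key.values(), key=lambda e: (e.defining_span, e.key))


def assign_region(e: ASEvent, rep: RegionPartition | None) -> ASEvent:
    """Assign the event to the gene region its defining span overlaps most.

    Ties go to the more 5' region (strand-aware). Without a partition, or
    when the span misses every region, the event is "unpartitioned".
    """
    if rep is None or not rep.is_partitioned:
        return replace(e, region="unpartitioned")
    span = e.defining_span
    best_label, best_ov = "unpartitioned", 0
    for label, iv in rep.regions_5to3():
        ov = _overlap(span, iv)
        if ov > best_ov:  # strict: ties keep the earlier (more 5') region
            best_label, best_ov = label, ov
    return replace(e, region=best_label)


def events_table(events: Iterable[ASEvent]) -> pd.DataFrame:
    """Long-format event table (one row per event)."""
    rows = []
    for e in events:
        rows.append(
            {
                "event_key": e.key,
                "event_type": e.event_type,
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "anchors": ",".join(str(a) for a in e.anchors),
                "defining_start": e.defining_span[0],
                "defining_end": e.defining_span[1],
                "region": e.region,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_key",
            "event_type",
            "gene_id",
            "chrom",
            "strand",
            "anchors",
            "defining_start",
            "defining_end",
            "region",
        ],
    )


def type_counts(events: Iterable[ASEvent]) -> pd.DataFrame:
    """Per-type event counts and percentages of the total."""
    events = list(events)
    total = len(events)
    rows = []
    for etype in EVENT_TYPES:
        n = sum(1 for e in events if e.event_type == etype)
        rows.append(
            {
                "event_type": etype,
                "count": n,
                "percent": round(100.0 * n / total, 2) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def region_type_matrix(events: Iterable[ASEvent]) -> pd.DataFrame:
    """Region x event-type count matrix (regions as rows)."""
    df = events_table(events)
    if df.empty:
        return pd.DataFrame(columns=list(EVENT_TYPES))
    mat = df.pivot_table(
        index="region", columns="event_type", values="event_key", aggfunc="count"
    ).fillna(0)
    return mat.reindex(columns=EVENT_TYPES, fill_value=0).astype(int)


def event_catalog(
    genes: Sequence[GeneModel], assign_regions: bool = True
) -> tuple[list[ASEvent], pd.DataFrame]:
    """Detect, region-assign and tabulate events across genes.

    Returns the event list and its long-format table; per-type counts and
    the region matrix are derived views (:func:`type_counts`,
    :func:`region_type_matrix`).
    """
    all_events: list[ASEvent] = []
    for g in genes:
        events = detect_events(g)
        if not events:
            continue
        if assign_regions:
            rep = partition_regions(longest_isoform(g))
            events = [assign_region(e, rep) for e in events]
        all_events.extend(events)
    return all_events, events_table(all_events)
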