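"""Splice-junction evidence and filtering.

A :class:`SpliceJunction` is a donor-acceptor genomic interval with
PCR-deduplicated read support split into perfectly matched and mismatched
reads. The filter removes, in order:

R1  junctions supported by fewer than 2 deduplicated reads;
R2  junctions supported only by mismatched reads;
R3  junctions with any mismatched support whose donor or acceptor lies
    within 10 nt of the corresponding site of a different junction that has
    perfect-read support (alignment wobble around a real junction).

R2/R3 behaviour is switchable (``mismatch_rule``) because the filtering
prose these rules derive from admits either a blanket mismatch rule or a
proximity-conditioned one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .annotation_model import GeneModel

__all__ = [
    "SpliceJunction",
    "dedup_support",
    "filter_junctions",
    "classify_novelty",
    "read_sj_table",
    "write_sj_table",
    "read_star_sj",
    "read_bed12_junctions",
    "write_removed_table",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class SpliceJunction:
    """A splice junction (intron interval) with deduplicated read support."""

    chrom: str
    strand: str  # '+', '-', or '.' when unknown
    start: int
    end: int
    reads_total: int = 0
    reads_dedup: int = 0
    reads_perfect: int = 0
    reads_mismatch: int = 0
    novelty: str = "unassigned"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"junction end {self.end} <= start {self.start}")
        if self.reads_dedup > self.reads_total:
            raise ValueError("reads_dedup > reads_total")
        if self.reads_perfect + self.reads_mismatch != self.reads_dedup:
            raise ValueError("reads_perfect + reads_mismatch != reads_dedup")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


def dedup_support(
    read_records: Sequence[tuple[int, int, int]],
    chrom: str,
    strand: str,
    span: Interval,
) -> SpliceJunction:
    """Collapse per-read records for one junction into support counts.

    ``read_records`` are ``(alignment_start, alignment_end, n_mismatches)``
    tuples. Records sharing identical alignment endpoints are PCR duplicates
    and collapse to one; the collapsed record keeps the best (minimum)
    mismatch count. Perfect/mismatch tallies are computed on the collapsed
    set.
    """
    groups: dict[tuple[int, int], int] = {}
    for aln_start, aln_end, mismatches in read_records:
        key = (aln_start, aln_end)
        if key not in groups or mismatches < groups[key]:
            groups[key] = mismatches
    perfect = sum(1 for m in groups.values() if m == 0)
    return SpliceJunction(
        chrom=chrom,
        strand=strand,
        start=span[0],
        end=span[1],
        reads_total=len(read_records),
        reads_dedup=len(groups),
        reads_perfect=perfect,
        reads_mismatch=len(groups) - perfect,
    )


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def filter_junctions(
    sjs: Iterable[SpliceJunction],
    min_reads: int = 2,
    proximity_nt: int = 10,
    mismatch_rule: str = "r2+r3",
) -> tuple[list[SpliceJunction], list[tuple[SpliceJunction, str]]]:
    """Apply the junction filtering rules; return ``(kept, removed)``.

    ``removed`` entries carry the tag of the first rule that fired (``R1``,
    ``R2`` or ``R3``). ``mismatch_rule`` selects which mismatch rules apply:
    ``"r2+r3"`` (default), ``"r2_only"``, or ``"r3_only"``.
    """
    if mismatch_rule not in ("r2+r3", "r2_only", "r3_only"):
        raise ValueError(f"unknown mismatch_rule {mismatch_rule!r}")
    sjs = list(sjs)

    kept: list[SpliceJunction] = []
    removed: list[tuple[SpliceJunction, str]] = []

    # R1: minimum deduplicated read support
    survivors = []
    for sj in sjs:
        if sj.reads_dedup < min_reads:
            removed.append((sj, "R1"))
        else:
            survivors.append(sj)

    # R2: supported only by mismatched reads
    if mismatch_rule in ("r2+r3", "r2_only"):
        nxt = []
        for sj in survivors:
            if sj.reads_perfect == 0:
                removed.append((sj, "R2"))
            else:
                nxt.append(sj)
        survivors = nxt

    # R3: mismatch-supported junction near a perfect-supported one
    if mismatch_rule in ("r2+r3", "r3_only"):
        refs = [sj for sj in survivors if sj.reads_perfect >= 1]
        nxt = []
        for sj in survivors:
            if sj.reads_mismatch >= 1 and _near_perfect(sj, refs, proximity_nt):
                removed.append((sj, "R3"))
            else:
                nxt.append(sj)
        survivors = nxt

    kept = survivors
    return kept, removed


def _near_perfect(
    sj: SpliceJunction, refs: Sequence[SpliceJunction], proximity_nt: int
) -> bool:
    # Per-site proximity: donor-to-donor / acceptor-to-acceptor, which for
    # same-strand junctions is start-to-start and end-to-end.
    for ref in refs:
        if ref.chrom != sj.chrom or ref.span == sj.span:
            continue
        if not _strands_compatible(ref.strand, sj.strand):
            continue
        if (
            abs(ref.start - sj.start) <= proximity_nt
            or abs(ref.end - sj.end) <= proximity_nt
        ):
            return True
    return False


def classify_novelty(
    sjs: Iterable[SpliceJunction], annotation: Sequence[GeneModel]
) -> list[SpliceJunction]:
    """Set junction novelty against annotated introns (exact-span match)."""
    known: dict[tuple[str, int, int], set[str]] = {}
    for g in annotation:
        for t in g.transcripts:
            for s, e in t.junctions():
                known.setdefault((g.chrom, s, e), set()).add(g.strand)
    out = []
    for sj in sjs:
        strands = known.get((sj.chrom, sj.start, sj.end))
        is_known = strands is not None and (
            sj.strand == "." or sj.strand in strands
        )
        out.append(replace(sj, novelty="known" if is_known else "novel"))
    return out


# ---------------------------------------------------------------------------
# I/O dialects
# ---------------------------------------------------------------------------

SJ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "reads_total",
    "reads_dedup",
    "reads_perfect",
    "reads_mismatch",
]


def write_sj_table(sjs: Iterable[SpliceJunction], path: str) -> None:
    """Write junctions as a TSV with full read-support metadata."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SJ_COLUMNS)
        for sj in sjs:
            w.writerow(
                [
                    sj.chrom,
                    sj.start,
                    sj.end,
                    sj.strand,
                    sj.reads_total,
                    sj.reads_dedup,
                    sj.reads_perfect,
                    sj.reads_mismatch,
                ]
            )


def read_sj_table(path: str) -> list[SpliceJunction]:
    """Read the metadata-rich TSV dialect written by :func:`write_sj_table`."""
    df = pd.read_csv(path, sep="\t")
    return [
        SpliceJunction(
            chrom=str(r.chrom),
            strand=str(r.strand),
            start=int(r.start),
            end=int(r.end),
            reads_total=int(r.reads_total),
            reads_dedup=int(r.reads_dedup),
            reads_perfect=int(r.reads_perfect),
            reads_mismatch=int(r.reads_mismatch),
        )
        for r in df.itertuples()
    ]


_STAR_STRAND = {0: ".", 1: "+", 2: "-"}


def read_star_sj(path: str) -> list[SpliceJunction]:
    """Read a STAR ``SJ.out.tab`` file.

    STAR reports 1-based inclusive intron coordinates and unique/multi read
    counts but no mismatch metadata; uniquely mapping reads are taken as
    deduplicated perfect support.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            chrom, start1, end1, strand_code = f[0], int(f[1]), int(f[2]), int(f[3])
            unique = int(f[6])
            out.append(
                SpliceJunction(
                    chrom=chrom,
                    strand=_STAR_STRAND.get(strand_code, "."),
                    start=start1 - 1,
                    end=end1,
                    reads_total=unique + int(f[7]),
                    reads_dedup=unique,
                    reads_perfect=unique,
                    reads_mismatch=0,
                )
            )
    return out


def read_bed12_junctions(path: str) -> list[SpliceJunction]:
    """Read TopHat-style ``junctions.bed`` (BED12, blocks are anchors).

    The intron span is derived from the two blocks: it runs from the end of
    block 1 to the start of block 2. The BED score column is the read count
    (treated as deduplicated perfect support).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start = f[0], int(f[1])
            score, strand = int(float(f[4])), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) < 2:
                continue
            start = chrom_start + starts[0] + sizes[0]
            end = chrom_start + starts[1]
            out.append(
                SpliceJunction(
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    reads_total=score,
                    reads_dedup=score,
                    reads_perfect=score,
                    reads_mismatch=0,
                )
            )
    return out


def write_removed_table(
    removed: Iterable[tuple[SpliceJunction, str]], path: str
) -> None:
    """Write removed junctions with the rule that removed each."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SJ_COLUMNS + ["removal_rule"])
        for sj, reason in removed:
            w.writerow(
                [
                    sj.chrom,
                    sj.start,
                    sj.end,
                    sj.strand,
                    sj.reads_total,
                    sj.reads_dedup,
                    sj.reads_perfect,
                    sj.reads_mismatch,
                    reason,
                ]
            )
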