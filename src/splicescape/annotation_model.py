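"""Transcript annotation models.

Parses and emits GTF, extracts introns from exon chains, classifies introns
as constitutive or alternatively spliced, selects representative isoforms,
and partitions a gene's representative isoform into 5'UTR / CDS / 3'UTR.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``(start, end)``. GTF I/O
converts to/from the standard 1-based inclusive GTF coordinates. On the
minus strand the 5' end of a transcript is the interval with the *largest*
genomic coordinate; all strand-aware logic (region labels, splice-site
orientation) lives in the functions, not in the stored coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ENORMOUS_INTRON_NT",
    "TranscriptModel",
    "GeneModel",
    "Intron",
    "RegionPartition",
    "GTFParseError",
    "AnnotationError",
    "read_gtf",
    "write_gtf",
    "extract_introns",
    "classify_intron_status",
    "gene_introns",
    "longest_isoform",
    "partition_regions",
]

#: Introns longer than this are flagged "enormous" (>50 kb).
ENORMOUS_INTRON_NT = 50_000

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Invalid annotation structure (bad exon chain, CDS outside span, ...)."""


class GTFParseError(AnnotationError):
    """Malformed GTF input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class TranscriptModel:
    """One isoform: an ordered, disjoint exon chain on a single strand.

    ``exons`` are 0-based half-open genomic intervals sorted by start;
    ``cds_span`` (if any) is the genomic hull of the coding sequence.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_span: Interval | None = None
    novelty: str = "known"

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise AnnotationError(
                    f"{self.transcript_id}: empty exon ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at ({s}, {e})"
                )
            prev_end = e
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (self.span[0] <= cs < ce <= self.span[1]):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS {self.cds_span} outside span {self.span}"
                )

    @property
    def span(self) -> Interval:
        """Genomic span: first exon start to last exon end."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        """Mature transcript length (sum of exon lengths)."""
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> tuple[Interval, ...]:
        """Intron spans between consecutive exons (= splice junctions)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class GeneModel:
    """A gene: a non-empty set of isoforms sharing chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise AnnotationError(
                    f"{self.gene_id}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand}"
                )

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


@dataclass
class Intron:
    """An intron between two consecutive exons of at least one isoform."""

    chrom: str
    strand: str
    start: int
    end: int
    status: str | None = None  # constitutive | alternative
    novelty: str = "known"

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_enormous(self) -> bool:
        return self.length > ENORMOUS_INTRON_NT


@dataclass(frozen=True)
class RegionPartition:
    """Strand-aware 5'UTR / CDS / 3'UTR partition of a genomic span.

    The three intervals (any of which may be ``None`` when empty) tile the
    representative isoform's genomic span without overlap. When the isoform
    carries no CDS the partition is "unpartitioned" and all regions are
    ``None``.
    """

    span: Interval
    strand: str
    five_prime_utr: Interval | None
    cds: Interval | None
    three_prime_utr: Interval | None

    @property
    def is_partitioned(self) -> bool:
        return self.cds is not None

    def regions_5to3(self) -> list[tuple[str, Interval]]:
        """Non-empty (label, interval) pairs in 5'->3' order."""
        out = []
        for label, iv in (
            ("5UTR", self.five_prime_utr),
            ("CDS", self.cds),
            ("3UTR", self.three_prime_utr),
        ):
            if iv is not None:
                out.append((label, iv))
        return out


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str, genome=None) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Only ``exon`` and ``CDS`` features are used; each must carry ``gene_id``
    and ``transcript_id`` attributes. 1-based inclusive GTF coordinates are
    converted to internal 0-based half-open intervals. When ``genome`` (a
    :class:`~splicescape.genome.GenomeAccess`) is given, exon coordinates are
    validated against chromosome bounds.
    """
    tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(lineno, f"non-integer coordinates {start_s},{end_s}")
            if end1 < start1:
                raise GTFParseError(lineno, f"end {end1} < start {start1}")
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise GTFParseError(lineno, "missing gene_id/transcript_id attribute")
            start, end = start1 - 1, end1  # to 0-based half-open
            if genome is not None:
                if chrom not in genome or end > genome.chrom_length(chrom):
                    raise AnnotationError(
                        f"GTF line {lineno}: feature [{start}, {end}) outside "
                        f"chromosome {chrom}"
                    )
            tid = attr["transcript_id"]
            rec = tx.get(tid)
            if rec is None:
                rec = tx[tid] = {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "novelty": attr.get("novelty", "known"),
                }
                order.append(tid)
            if feature == "exon":
                rec["exons"].append((start, end))
            else:
                rec["cds"].append((start, end))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = tx[tid]
        cds_span = None
        if rec["cds"]:
            cds_span = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
            cds_span=cds_span,
            novelty=rec["novelty"],
        )
        gid = t.gene_id
        if gid not in genes:
            genes[gid] = GeneModel(gid, t.chrom, t.strand, [t])
            gene_order.append(gid)
        else:
            g = genes[gid]
            g.transcripts.append(t)
            if t.chrom != g.chrom or t.strand != g.strand:
                raise AnnotationError(
                    f"{gid}: transcripts on different chromosomes/strands"
                )
    return [genes[gid] for gid in gene_order]


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "splicescape") -> None:
    """Write gene models as GTF (exon + optional CDS features, 1-based)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'novelty "{t.novelty}";'
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
                if t.cds_span is not None:
                    cs, ce = t.cds_span
                    fh.write(
                        f"{t.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Introns
# ---------------------------------------------------------------------------


def extract_introns(t: TranscriptModel) -> list[Intron]:
    """Introns between consecutive exons of ``t`` (empty for single-exon).

    Raises :class:`AnnotationError` on abutting exons (length-0 intron).
    """
    out = []
    for s, e in t.junctions():
        if e - s < 1:
            raise AnnotationError(
                f"{t.transcript_id}: zero-length intron at position {s}"
            )
        out.append(Intron(t.chrom, t.strand, s, e, novelty=t.novelty))
    return out


def classify_intron_status(g: GeneModel) -> dict[Interval, str]:
    """Classify each distinct intron span of ``g`` as constitutive/alternative.

    An intron is *constitutive* iff it appears (identical span) in every
    isoform whose genomic span contains the intron; otherwise *alternative*.
    Isoforms that end before the intron begins cannot vote against it.
    """
    per_tx = [(t.span, set(t.junctions())) for t in g.transcripts]
    status: dict[Interval, str] = {}
    all_spans = {iv for _, jset in per_tx for iv in jset}
    for iv in all_spans:
        covering = [jset for span, jset in per_tx if span[0] <= iv[0] and iv[1] <= span[1]]
        status[iv] = (
            "constitutive" if all(iv in jset for jset in covering) else "alternative"
        )
    return status


def gene_introns(g: GeneModel) -> list[Intron]:
    """Distinct introns of a gene with status and novelty resolved.

    An intron is "known" if at least one known isoform contains it.
    """
    status = classify_intron_status(g)
    novelty: dict[Interval, str] = {}
    for t in g.transcripts:
        for iv in t.junctions():
            if t.novelty == "known":
                novelty[iv] = "known"
            else:
                novelty.setdefault(iv, "novel")
    return [
        Intron(g.chrom, g.strand, s, e, status=status[(s, e)], novelty=novelty[(s, e)])
        for s, e in sorted(status)
    ]


# ---------------------------------------------------------------------------
# Representative isoform and gene regions
# ---------------------------------------------------------------------------


def longest_isoform(g: GeneModel) -> TranscriptModel:
    """Representative isoform: maximal summed exon length.

    Ties broken by smaller genomic start, then lexicographic transcript id.
    """
    return min(
        g.transcripts,
        key=lambda t: (-t.exonic_length, t.span[0], t.transcript_id),
    )


def partition_regions(t: TranscriptModel) -> RegionPartition:
    """Partition the genomic span of ``t`` into 5'UTR / CDS / 3'UTR.

    Strand-aware: on '-' the 5'UTR is genomically *downstream* of the CDS.
    With no CDS annotation the partition is returned unpartitioned.
    """
    span = t.span
    if t.cds_span is None:
        return RegionPartition(span, t.strand, None, None, None)
    cs, ce = t.cds_span
    left = (span[0], cs) if cs > span[0] else None
    right = (ce, span[1]) if span[1] > ce else None
    if t.strand == "+":
        return RegionPartition(span, t.strand, left, (cs, ce), right)
    return RegionPartition(span, t.strand, right, (cs, ce), left)


def intron_table(genes: Sequence[GeneModel]) -> list[Intron]:
    """All distinct introns across genes (convenience for feature computation)."""
    out: list[Intron] = []
    for g in genes:
        out.extend(gene_introns(g))
    return out
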