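"""Event quantification: junction-support counts, PSI, AS-score, FPKM.

For one event in one sample, ``counts_EII`` sums deduplicated junction
reads over the event's inclusion junctions and ``counts_EEI`` over its
exclusion junctions (the form with the larger intron). Percent spliced in
is

    PSI = counts_EII / (counts_EII + counts_EEI)

and the AS-score rescales PSI to [-1, 1]:

    AS = (PSI - 0.5) / 0.5

so -1 means only the exclusion form is expressed, +1 only the inclusion
form, and 0 equal expression of both.

Retained introns have no inclusion junction; their inclusion evidence is a
per-intron retention count (reads falling inside the intron window),
supplied alongside the junction tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .as_events import ASEvent
from .junction_filter import SpliceJunction

__all__ = [
    "EventQuant",
    "TranscriptAbundance",
    "psi",
    "as_score",
    "fpkm",
    "count_event_support",
    "quantify_events",
    "junction_count_map",
    "filter_transcripts",
]

log = logging.getLogger(__name__)

JunctionCounts = Mapping[tuple[str, int, int], int]


@dataclass(frozen=True)
class EventQuant:
    """Per-sample quantification of one AS event."""

    event_key: str
    sample_id: str
    counts_eii: int
    counts_eei: int

    @property
    def psi(self) -> float:
        return psi(self.counts_eii, self.counts_eei)

    @property
    def as_score(self) -> float:
        return as_score(self.psi)


@dataclass(frozen=True)
class TranscriptAbundance:
    """Expression summary of one transcript."""

    transcript_id: str
    fragments: int
    fpkm: float
    intronic_read_fraction: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError("FPKM must be non-negative")
        if not 0.0 <= self.intronic_read_fraction <= 1.0:
            raise ValueError("intronic_read_fraction must be in [0, 1]")


def psi(counts_eii: int, counts_eei: int) -> float:
    """Percent spliced in; NaN when the event has no supporting reads."""
    if counts_eii < 0 or counts_eei < 0:
        raise ValueError("counts must be non-negative")
    total = counts_eii + counts_eei
    if total == 0:
        return math.nan
    return counts_eii / total


def as_score(psi_value: float) -> float:
    """Linear rescaling of PSI to [-1, 1]; NaN passes through."""
    if math.isnan(psi_value):
        return math.nan
    if not 0.0 <= psi_value <= 1.0:
        raise ValueError(f"PSI out of range: {psi_value}")
    return (psi_value - 0.5) / 0.5


def fpkm(fragments: int, transcript_length_nt: int, library_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length_nt <= 0 or library_fragments <= 0:
        raise ValueError("transcript length and library size must be positive")
    return 1e9 * fragments / (transcript_length_nt * library_fragments)


def count_event_support(
    e: ASEvent,
    junctions: JunctionCounts,
    retention_counts: Mapping[tuple[str, int, int], int] | None = None,
) -> tuple[int, int]:
    """Sum deduplicated junction support for the inclusion/exclusion forms.

    ``junctions`` maps ``(chrom, start, end)`` to a deduplicated read count.
    For RI events the inclusion evidence is looked up in
    ``retention_counts`` keyed by the retained intron interval.
    """
    eei = sum(junctions.get((e.chrom, s, en), 0) for s, en in e.exclusion_junctions)
    if e.event_type == "RI":
        span = e.defining_span
        eii = (retention_counts or {}).get((e.chrom, span[0], span[1]), 0)
    else:
        eii = sum(
            junctions.get((e.chrom, s, en), 0) for s, en in e.inclusion_junctions
        )
    return eii, eei


def junction_count_map(sjs: Iterable[SpliceJunction]) -> dict[tuple[str, int, int], int]:
    """Deduplicated read counts keyed by (chrom, start, end)."""
    out: dict[tuple[str, int, int], int] = {}
    for sj in sjs:
        key = (sj.chrom, sj.start, sj.end)
        out[key] = out.get(key, 0) + sj.reads_dedup
    return out


def quantify_events(
    events: Sequence[ASEvent],
    sample_junctions: Mapping[str, JunctionCounts],
    sample_retention: Mapping[str, Mapping[tuple[str, int, int], int]] | None = None,
) -> pd.DataFrame:
    """Long-format per-event per-sample quantification table."""
    sample_retention = sample_retention or {}
    rows = []
    for sample_id, counts in sample_junctions.items():
        if counts is None:
            log.warning("sample %s has no junction counts; using zeros", sample_id)
            counts = {}
        retention = sample_retention.get(sample_id, {})
        for e in events:
            eii, eei = count_event_support(e, counts, retention)
            p = psi(eii, eei)
            rows.append(
                {
                    "event_key": e.key,
                    "event_type": e.event_type,
                    "gene_id": e.gene_id,
                    "sample_id": sample_id,
                    "counts_eii": eii,
                    "counts_eei": eei,
                    "psi": p,
                    "as_score": as_score(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_key",
            "event_type",
            "gene_id",
            "sample_id",
            "counts_eii",
            "counts_eei",
            "psi",
            "as_score",
        ],
    )


def filter_transcripts(
    abundances: Sequence[TranscriptAbundance],
    gene_of: Mapping[str, str],
    intronic_max: float = 0.15,
    relative_min: float = 0.10,
    combine: str = "or",
) -> tuple[list[TranscriptAbundance], list[tuple[TranscriptAbundance, str]]]:
    """Discard weakly supported isoforms per gene.

    A transcript is discarded if its intronic read fraction exceeds
    ``intronic_max`` or (default; ``combine="and"`` requires both) its FPKM
    is below ``relative_min`` times the gene's major (highest-FPKM) isoform.
    The major isoform is never discarded by the relative-expression rule,
    and at least one isoform of every expressed gene is always retained.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    by_gene: dict[str, list[TranscriptAbundance]] = {}
    for ab in abundances:
        by_gene.setdefault(gene_of[ab.transcript_id], []).append(ab)

    kept: list[TranscriptAbundance] = []
    discarded: list[tuple[TranscriptAbundance, str]] = []
    for gene_id, abs_ in by_gene.items():
        major = max(abs_, key=lambda a: (a.fpkm, a.transcript_id))
        gene_kept, gene_disc = [], []
        for ab in abs_:
            intronic_bad = ab.intronic_read_fraction > intronic_max
            relative_bad = (
                ab.transcript_id != major.transcript_id
                and ab.fpkm < relative_min * major.fpkm
            )
            if combine == "or":
                bad = intronic_bad or relative_bad
            else:
                bad = intronic_bad and relative_bad
            if bad:
                reason = (
                    "intronic>max" if intronic_bad and not relative_bad
                    else "fpkm<rel_min" if relative_bad and not intronic_bad
                    else "intronic>max;fpkm<rel_min"
                )
                gene_disc.append((ab, reason))
            else:
                gene_kept.append(ab)
        if not gene_kept and any(a.fpkm > 0 for a in abs_):
            # Never discard every isoform of an expressed gene.
            gene_disc = [(ab, r) for ab, r in gene_disc if ab is not major]
            gene_kept = [major]
            log.warning(
                "gene %s: all isoforms failed filters; retaining major isoform %s",
                gene_id,
                major.transcript_id,
            )
        kept.extend(gene_kept)
        discarded.extend(gene_disc)
    return kept, discarded
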