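"""Summary-report generation and the ratio statistics it is built from.

The ratio helpers are deliberately tiny, pure functions: the same code that
turns the pipeline's own catalogs into headline statistics (share of each
event type, mean events per AS gene, per-region type shares, annotated
AS-gene fraction) is also unit-testable against fixed count pairs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .annotation_model import GeneModel
from .as_events import ASEvent, EVENT_TYPES, region_type_matrix, type_counts

__all__ = [
    "percent",
    "events_per_gene",
    "catalog_summary",
    "annotated_as_gene_fraction",
    "render_text_report",
]


def percent(part: float, total: float, digits: int = 2) -> float:
    """``100 * part / total`` rounded to ``digits`` (the printed convention)."""
    if total == 0:
        raise ZeroDivisionError("percent of an empty total")
    return round(100.0 * part / total, digits)


def events_per_gene(n_events: int, n_genes: int, digits: int = 2) -> float:
    """Mean AS events per AS gene."""
    if n_genes == 0:
        raise ZeroDivisionError("no AS genes")
    return round(n_events / n_genes, digits)


def annotated_as_gene_fraction(n_as_genes: int, n_intron_genes: int) -> float:
    """Percentage of intron-containing genes that undergo AS."""
    return percent(n_as_genes, n_intron_genes)


def catalog_summary(
    events: Sequence[ASEvent], genes: Iterable[GeneModel] | None = None
) -> dict:
    """Headline statistics of an event catalog, all recomputed from it.

    Includes the internal-consistency surfaces: per-type counts summing to
    the total, per-type percentages, mean events per AS gene, the region x
    type matrix and each type's share within each region.
    """
    events = list(events)
    total = len(events)
    as_genes = sorted({e.gene_id for e in events})
    tc = type_counts(events)
    summary: dict = {
        "total_events": total,
        "n_as_genes": len(as_genes),
        "events_per_as_gene": (
            events_per_gene(total, len(as_genes)) if as_genes else None
        ),
        "type_counts": dict(zip(tc["event_type"], tc["count"].astype(int))),
        "type_percent": dict(zip(tc["event_type"], tc["percent"])),
    }
    mat = region_type_matrix(events)
    summary["region_type_counts"] = {
        region: {t: int(mat.loc[region, t]) for t in EVENT_TYPES}
        for region in mat.index
    }
    region_shares: dict = {}
    for region in mat.index:
        region_total = int(mat.loc[region].sum())
        if region_total:
            region_shares[region] = {
                t: percent(int(mat.loc[region, t]), region_total)
                for t in EVENT_TYPES
            }
    summary["region_type_percent"] = region_shares
    if genes is not None:
        genes = list(genes)
        intron_genes = [
            g for g in genes if any(len(t.exons) > 1 for t in g.transcripts)
        ]
        summary["n_genes"] = len(genes)
        summary["n_intron_genes"] = len(intron_genes)
        if intron_genes:
            summary["as_gene_fraction_pct"] = annotated_as_gene_fraction(
                len(as_genes), len(intron_genes)
            )
    return summary


def render_text_report(summary: dict) -> str:
    """Human-readable rendering of :func:`catalog_summary` output."""
    lines = ["AS event catalog summary", "========================"]
    lines.append(f"Total events:        {summary['total_events']}")
    lines.append(f"AS genes:            {summary['n_as_genes']}")
    if summary.get("events_per_as_gene") is not None:
        lines.append(f"Events per AS gene:  {summary['events_per_as_gene']}")
    if "as_gene_fraction_pct" in summary:
        lines.append(
            f"AS gene fraction:    {summary['as_gene_fraction_pct']}% "
            f"({summary['n_as_genes']}/{summary['n_intron_genes']} intron-containing)"
        )
    lines.append("")
    lines.append("Type       count   percent")
    for t in EVENT_TYPES:
        lines.append(
            f"{t:<8} {summary['type_counts'].get(t, 0):>7}"
            f"   {summary['type_percent'].get(t, 0.0):>6}%"
        )
    if summary.get("region_type_counts"):
        lines.append("")
        lines.append("Events by gene region:")
        for region, counts in summary["region_type_counts"].items():
            total = sum(counts.values())
            lines.append(f"  {region:<14} {total:>6}  " + "  ".join(
                f"{t}={counts[t]}" for t in EVENT_TYPES if counts[t]
            ))
    return "\n".join(lines) + "\n"
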