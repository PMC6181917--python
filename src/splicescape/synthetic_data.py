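"""Synthetic genomes, annotations and junction counts with planted truth.

The generator emulates the structures the analysis operates on: multi-exon
gene models with planted AS events in configurable type proportions (the
goat-like default: RI 37.04%, SE 32.90%, A3SS 15.98%, A5SS 12.74%, MXE
1.34%), log-normal intron lengths (median 1,472 nt), AU-rich intron bodies,
GT-AG borders at a configurable canonical fraction, and per-sample
replicate junction counts drawn around planted per-tissue PSI values, with
optional tissue-specific events and planted artifact junctions
(mismatch-only support near a true junction) for filter testing.

Every stage of the pipeline therefore has an oracle: the ground-truth
manifest records each planted event's type, anchors and junction structure
exactly as the detector reports them, and each event's true PSI per tissue.

What this does *not* model: repeat content, sequencing errors, reads (counts
are junction-level), or stage-dependent PSI (PSI is constant across
developmental stages within a tissue).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import GeneModel, TranscriptModel, write_gtf
from .as_events import ASEvent
from .genome import DictGenome, write_fasta
from .junction_filter import SpliceJunction, write_sj_table

__all__ = [
    "TISSUES",
    "STAGES",
    "SimulationConfig",
    "SimulatedAnnotation",
    "SimulatedCounts",
    "simulate_annotation",
    "simulate_junction_counts",
    "simulate_to_dir",
]

TISSUES = ("heart", "kidney", "muscle", "liver", "spleen")
STAGES = ("fetus", "m2", "y1", "adult")

Interval = tuple[int, int]

#: Goat-like AS type proportions (sum to 1).
DEFAULT_AS_PROPORTIONS = {
    "SE": 0.3290,
    "A3SS": 0.1598,
    "A5SS": 0.1274,
    "RI": 0.3704,
    "MXE": 0.0134,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the characteristics of the goat transcriptome data the
    pipeline targets: 5 tissues x 4 developmental stages x 3 replicates,
    goat-like AS type proportions, a 1,472-nt median intron length, 98%
    canonical GT-AG borders and 53% intron AU content. ``enormous_tail``
    widens the log-normal intron-length sigma to 1.687, which reproduces
    both the empirical mean/median ratio and a ~2% tail of introns >50 kb,
    at the cost of a much larger synthetic genome.
    """

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    as_gene_fraction: float = 0.8553
    as_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AS_PROPORTIONS)
    )
    intron_length_median: float = 1472.0
    intron_length_sigma: float = 0.75
    enormous_tail: bool = False
    min_intron_length: int = 80
    canonical_border_fraction: float = 0.98
    intron_au_target: float = 0.53
    novel_isoform_fraction: float = 0.33
    n_tissues: int = 5
    n_stages: int = 4
    replicates: int = 3
    coverage_mean: float = 50.0
    fraction_specific_events: float = 0.1
    fraction_differential_events: float = 0.2
    overdispersion_rho: float = 0.0
    artifact_fraction: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.as_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"as_type_proportions sum to {total}, not 1")
        for name in (
            "as_gene_fraction",
            "canonical_border_fraction",
            "intron_au_target",
            "novel_isoform_fraction",
            "fraction_specific_events",
            "fraction_differential_events",
            "artifact_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.n_tissues > len(TISSUES) or self.n_stages > len(STAGES):
            raise ValueError("at most 5 tissues / 4 stages supported")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]

    @property
    def stages(self) -> tuple[str, ...]:
        return STAGES[: self.n_stages]

    @property
    def sigma(self) -> float:
        return 1.687 if self.enormous_tail else self.intron_length_sigma


@dataclass
class PlantedEvent:
    """Ground-truth record of one planted AS event."""

    event: ASEvent
    psi: dict[str, float]  # per-tissue true PSI (constant across stages)
    specific_tissue: str | None = None
    differential: bool = False


@dataclass
class SimulatedAnnotation:
    genes: list[GeneModel]
    genome: DictGenome
    planted: list[PlantedEvent]
    config: SimulationConfig

    def manifest(self) -> dict:
        """JSON-serializable ground-truth manifest."""
        cfg = asdict(self.config)
        cfg["as_type_proportions"] = dict(self.config.as_type_proportions)
        return {
            "config": cfg,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "transcripts": {
                        t.transcript_id: [list(iv) for iv in t.exons]
                        for t in g.transcripts
                    },
                }
                for g in self.genes
            ],
            "events": [
                {
                    "event_key": p.event.key,
                    "event_type": p.event.event_type,
                    "gene_id": p.event.gene_id,
                    "chrom": p.event.chrom,
                    "strand": p.event.strand,
                    "anchors": list(p.event.anchors),
                    "inclusion_junctions": sorted(
                        list(iv) for iv in p.event.inclusion_junctions
                    ),
                    "exclusion_junctions": sorted(
                        list(iv) for iv in p.event.exclusion_junctions
                    ),
                    "psi": p.psi,
                    "specific_tissue": p.specific_tissue,
                    "differential": p.differential,
                }
                for p in self.planted
            ],
        }


@dataclass
class SimulatedCounts:
    sample_sheet: pd.DataFrame
    junctions: dict[str, list[SpliceJunction]]
    retention: dict[str, dict[tuple[str, int, int], int]]
    artifacts: dict[str, list[Interval]]
    library_sizes: dict[str, int]


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------


def _intron_lengths(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    mu = np.log(cfg.intron_length_median)
    lengths = np.exp(rng.normal(mu, cfg.sigma, size=n)).astype(int)
    return np.maximum(lengths, cfg.min_intron_length)


def _choose_type(rng: np.random.Generator, proportions: Mapping[str, float]) -> str:
    types = sorted(proportions)
    probs = np.array([proportions[t] for t in types])
    return types[int(rng.choice(len(types), p=probs / probs.sum()))]


def _plant_alt_isoform(
    rng: np.random.Generator,
    ev_type: str,
    exons: list[Interval],
    strand: str,
) -> tuple[list[Interval], tuple]:
    """Derive the alternate exon chain and event anchors for one event.

    Returns (alt_exons, (anchors, inclusion, exclusion)). MXE geometry is
    handled upstream (the host intron is pre-widened and the second exon
    position passed via the anchors here is recomputed from it).
    """
    n = len(exons)
    if ev_type == "SE":
        idx = int(rng.integers(1, n - 1))
        up_end = exons[idx - 1][1]
        skip_s, skip_e = exons[idx]
        down_s = exons[idx + 1][0]
        alt = exons[:idx] + exons[idx + 1 :]
        anchors = (up_end, skip_s, skip_e, down_s)
        incl = frozenset({(up_end, skip_s), (skip_e, down_s)})
        excl = frozenset({(up_end, down_s)})
        return alt, (anchors, incl, excl)
    if ev_type == "RI":
        idx = int(rng.integers(0, n - 1))
        a, x = exons[idx]
        y, b = exons[idx + 1]
        alt = exons[:idx] + [(a, b)] + exons[idx + 2 :]
        anchors = (a, x, y, b)
        return alt, (anchors, frozenset(), frozenset({(x, y)}))
    if ev_type in ("A5SS", "A3SS"):
        # Genomic side of the variable boundary depends on strand so the
        # event label matches the requested type.
        left_variable = (ev_type == "A5SS") == (strand == "+")
        if left_variable:
            idx = int(rng.integers(0, n - 1))  # exon whose end (donor side) moves
            s, e = exons[idx]
            delta = int(rng.integers(15, 50))
            alt = exons[:idx] + [(s, e - delta)] + exons[idx + 1 :]
            shared = exons[idx + 1][0]
            anchors = (shared, e - delta, e)
            incl = frozenset({(e, shared)})
            excl = frozenset({(e - delta, shared)})
        else:
            idx = int(rng.integers(1, n))  # exon whose start (right side) moves
            s, e = exons[idx]
            delta = int(rng.integers(15, 50))
            alt = exons[:idx] + [(s + delta, e)] + exons[idx + 1 :]
            shared = exons[idx - 1][1]
            anchors = (shared, s, s + delta)
            incl = frozenset({(shared, s)})
            excl = frozenset({(shared, s + delta)})
        return alt, (anchors, incl, excl)
    raise AssertionError(ev_type)


def simulate_annotation(
    cfg: SimulationConfig, seed: int | None = None
) -> SimulatedAnnotation:
    """Generate a genome, gene models with planted AS events, and the truth.

    Each gene lives on its own chromosome; AS genes carry a primary isoform
    plus one alternate isoform realizing the planted event. Output is
    deterministic for a given seed (default ``cfg.rng_seed``).
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    flank = 200
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    au = cfg.intron_au_target
    intron_probs = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])

    genes: list[GeneModel] = []
    chroms: dict[str, str] = {}
    planted: list[PlantedEvent] = []

    for gi in range(cfg.n_genes):
        gene_id = f"G{gi + 1:05d}"
        chrom = f"chr{gi + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(
            cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex
        ).astype(int)
        in_lens = _intron_lengths(rng, cfg, n_ex - 1)

        ev_type = None
        if rng.random() < cfg.as_gene_fraction:
            ev_type = _choose_type(rng, cfg.as_type_proportions)

        mxe_idx = mxe_exon2 = None
        if ev_type == "MXE":
            # Widen the intron after the chosen middle exon to host exon 2.
            mxe_idx = int(rng.integers(1, n_ex - 1))
            m2_len = int(
                rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)
            )
            extra = int(_intron_lengths(rng, cfg, 1)[0])
            mxe_exon2 = (int(in_lens[mxe_idx]), m2_len)  # (offset in intron, length)
            in_lens[mxe_idx] = in_lens[mxe_idx] + m2_len + extra

        # Lay out primary exon coordinates.
        exons: list[Interval] = []
        pos = flank
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_lens[i])))
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        chrom_len = pos + flank

        transcripts = [
            TranscriptModel(
                transcript_id=f"{gene_id}.1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_span=(
                    exons[0][0] + int(ex_lens[0]) // 2,
                    exons[-1][1] - int(ex_lens[-1]) // 2,
                ),
                novelty="known",
            )
        ]

        event: ASEvent | None = None
        if ev_type == "MXE":
            assert mxe_idx is not None and mxe_exon2 is not None
            u_end = exons[mxe_idx - 1][1]
            m1 = exons[mxe_idx]
            offset, m2_len = mxe_exon2
            m2 = (m1[1] + offset, m1[1] + offset + m2_len)
            down_s = exons[mxe_idx + 1][0]
            alt = exons[:mxe_idx] + [m2] + exons[mxe_idx + 1 :]
            event = ASEvent(
                "MXE",
                gene_id,
                chrom,
                strand,
                (u_end, *m1, *m2, down_s),
                frozenset({(u_end, m1[0]), (m1[1], down_s)}),
                frozenset({(u_end, m2[0]), (m2[1], down_s)}),
            )
        elif ev_type is not None:
            alt, (anchors, incl, excl) = _plant_alt_isoform(
                rng, ev_type, exons, strand
            )
            event = ASEvent(ev_type, gene_id, chrom, strand, anchors, incl, excl)
        else:
            alt = None

        if alt is not None:
            novelty = (
                "novel" if rng.random() < cfg.novel_isoform_fraction else "known"
            )
            # Isoforms share the gene's CDS hull; every event type preserves
            # the first-exon start and last-exon end, so containment holds.
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.2",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(alt),
                    cds_span=transcripts[0].cds_span,
                    novelty=novelty,
                )
            )

        # Sequence: uniform background, AU-tuned intron bodies, then borders.
        seq = letters[rng.integers(0, 4, size=chrom_len)].copy()
        for s, e in transcripts[0].junctions():
            body = letters[
                rng.choice(4, size=max(0, e - s - 4), p=intron_probs)
            ]
            seq[s + 2 : e - 2] = body
        all_introns = sorted(
            {iv for t in transcripts for iv in t.junctions()}
        )
        for s, e in all_introns:
            donor, acceptor = _draw_border(rng, cfg.canonical_border_fraction)
            if strand == "+":
                d2, a2 = donor, acceptor
            else:  # genomic-forward dinucleotides are the reverse complements
                d2 = _revcomp2(acceptor)
                a2 = _revcomp2(donor)
            seq[s : s + 2] = np.frombuffer(d2.encode(), dtype=np.uint8)
            seq[e - 2 : e] = np.frombuffer(a2.encode(), dtype=np.uint8)

        chroms[chrom] = seq.tobytes().decode("ascii")
        genes.append(GeneModel(gene_id, chrom, strand, transcripts))
        if event is not None:
            planted.append(PlantedEvent(event=event, psi={}))

    _assign_psi(rng, cfg, planted)
    return SimulatedAnnotation(genes, DictGenome(chroms), planted, cfg)


def _draw_border(rng: np.random.Generator, canonical: float) -> tuple[str, str]:
    if rng.random() < canonical:
        return "GT", "AG"
    r = rng.random()
    if r < 0.6:
        return "GC", "AG"
    if r < 0.9:
        return "AT", "AC"
    bases = "ACGT"
    pick = lambda: bases[int(rng.integers(0, 4))]  # noqa: E731
    return pick() + pick(), pick() + pick()


def _revcomp2(dinuc: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return comp[dinuc[1]] + comp[dinuc[0]]


def _assign_psi(
    rng: np.random.Generator, cfg: SimulationConfig, planted: list[PlantedEvent]
) -> None:
    n = len(planted)
    if n == 0:
        return
    n_specific = int(round(cfg.fraction_specific_events * n))
    specific_idx = set(
        rng.choice(n, size=n_specific, replace=False).tolist() if n_specific else []
    )
    remaining = [i for i in range(n) if i not in specific_idx]
    n_diff = int(round(cfg.fraction_differential_events * len(remaining)))
    diff_idx = set(
        rng.choice(len(remaining), size=n_diff, replace=False).tolist()
        if n_diff
        else []
    )
    diff_set = {remaining[i] for i in diff_idx}
    tissues = cfg.tissues
    for i, p in enumerate(planted):
        base = float(rng.uniform(0.2, 0.8))
        if i in specific_idx:
            tissue = tissues[int(rng.integers(0, len(tissues)))]
            p.specific_tissue = tissue
            p.psi = {t: (base if t == tissue else 0.0) for t in tissues}
        elif i in diff_set:
            p.differential = True
            p.psi = {t: float(rng.uniform(0.2, 0.8)) for t in tissues}
        else:
            p.psi = {t: base for t in tissues}


# ---------------------------------------------------------------------------
# Junction-count simulation
# ---------------------------------------------------------------------------


def _beta_binomial(
    rng: np.random.Generator, n: int, p: float, rho: float
) -> int:
    if n == 0:
        return 0
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    if rho <= 0.0:
        return int(rng.binomial(n, p))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def simulate_junction_counts(
    ann: SimulatedAnnotation, cfg: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedCounts:
    """Draw per-sample junction tables around the planted PSI values.

    Per sample and event, total coverage n ~ Poisson(coverage_mean) is split
    into inclusion/exclusion by Binomial(n, PSI) (Beta-Binomial under
    ``overdispersion_rho``); inclusion reads are spread across the event's
    inclusion junctions, RI inclusion goes to a retention-count record.
    Junctions not involved in any event receive independent Poisson counts.
    Artifact junctions (mismatch-only support 1-10 nt from a true junction)
    are planted at ``artifact_fraction`` per true junction per sample.
    """
    cfg = cfg or ann.config
    rng = np.random.default_rng(
        (cfg.rng_seed + 1_000_003) % (2**31) if seed is None else seed
    )
    samples = [
        (f"{t}_{s}_r{r + 1}", t, s, r + 1)
        for t in cfg.tissues
        for s in cfg.stages
        for r in range(cfg.replicates)
    ]
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "tissue", "stage", "replicate"]
    )

    # Junction universe: constitutive (non-event) junctions vs event junctions.
    chrom_strand = {g.chrom: g.strand for g in ann.genes}
    all_spans: set[tuple[str, int, int]] = set()
    for g in ann.genes:
        for t in g.transcripts:
            for s, e in t.junctions():
                all_spans.add((g.chrom, s, e))
    event_spans: set[tuple[str, int, int]] = set()
    for p in ann.planted:
        for s, e in p.event.inclusion_junctions | p.event.exclusion_junctions:
            event_spans.add((p.event.chrom, s, e))
    const_spans = sorted(all_spans - event_spans)

    junctions: dict[str, list[SpliceJunction]] = {}
    retention: dict[str, dict[tuple[str, int, int], int]] = {}
    artifacts: dict[str, list[Interval]] = {}
    library_sizes: dict[str, int] = {}

    for sample_id, tissue, _stage, _rep in samples:
        counts: dict[tuple[str, int, int], int] = {}
        ret: dict[tuple[str, int, int], int] = {}

        const_counts = rng.poisson(cfg.coverage_mean, size=len(const_spans))
        for key, c in zip(const_spans, const_counts):
            if c > 0:
                counts[key] = int(c)

        for p in ann.planted:
            e = p.event
            n = int(rng.poisson(cfg.coverage_mean))
            psi_true = p.psi.get(tissue, 0.0)
            inc = _beta_binomial(rng, n, psi_true, cfg.overdispersion_rho)
            exc = n - inc
            incl = sorted(e.inclusion_junctions)
            excl = sorted(e.exclusion_junctions)
            if e.event_type == "RI":
                span = e.defining_span
                ret[(e.chrom, span[0], span[1])] = inc
            elif len(incl) == 1:
                counts[(e.chrom, *incl[0])] = counts.get((e.chrom, *incl[0]), 0) + inc
            elif len(incl) == 2:
                first = int(rng.binomial(inc, 0.5))
                for iv, c in zip(incl, (first, inc - first)):
                    counts[(e.chrom, *iv)] = counts.get((e.chrom, *iv), 0) + c
            if len(excl) == 1:
                counts[(e.chrom, *excl[0])] = counts.get((e.chrom, *excl[0]), 0) + exc
            elif len(excl) == 2:
                first = int(rng.binomial(exc, 0.5))
                for iv, c in zip(excl, (first, exc - first)):
                    counts[(e.chrom, *iv)] = counts.get((e.chrom, *iv), 0) + c

        sjs = [
            SpliceJunction(
                chrom=chrom,
                strand=chrom_strand[chrom],
                start=s,
                end=e,
                reads_total=c,
                reads_dedup=c,
                reads_perfect=c,
                reads_mismatch=0,
            )
            for (chrom, s, e), c in sorted(counts.items())
            if c > 0
        ]

        sample_artifacts: list[Interval] = []
        if cfg.artifact_fraction > 0:
            occupied = set(counts)
            for (chrom, s, e) in sorted(counts):
                if rng.random() >= cfg.artifact_fraction:
                    continue
                shift = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
                if rng.random() < 0.5:
                    a_span = (s + shift, e)
                else:
                    a_span = (s, e + shift)
                if a_span[1] - a_span[0] < 4 or a_span[0] < 0:
                    continue
                if (chrom, *a_span) in occupied:
                    continue
                occupied.add((chrom, *a_span))
                dedup = int(rng.integers(2, 5))
                sjs.append(
                    SpliceJunction(
                        chrom=chrom,
                        strand=chrom_strand[chrom],
                        start=a_span[0],
                        end=a_span[1],
                        reads_total=dedup,
                        reads_dedup=dedup,
                        reads_perfect=0,
                        reads_mismatch=dedup,
                    )
                )
                sample_artifacts.append(a_span)

        junctions[sample_id] = sjs
        retention[sample_id] = ret
        artifacts[sample_id] = sample_artifacts
        library_sizes[sample_id] = int(sum(sj.reads_dedup for sj in sjs))

    return SimulatedCounts(sheet, junctions, retention, artifacts, library_sizes)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def simulate_to_dir(cfg: SimulationConfig, outdir: str) -> SimulatedAnnotation:
    """Run both simulation stages and write all artifacts under ``outdir``.

    Emits ``genome.fa``, ``annotation.gtf``, ``manifest.json``,
    ``samples.csv``, per-sample ``sj_<sample>.tsv`` junction tables and
    ``retention_<sample>.tsv`` retention counts.
    """
    os.makedirs(outdir, exist_ok=True)
    ann = simulate_annotation(cfg)
    counts = simulate_junction_counts(ann, cfg)

    write_fasta({c: ann.genome.fetch(c, 0, ann.genome.chrom_length(c)) for c in ann.genome}, os.path.join(outdir, "genome.fa"))
    write_gtf(ann.genes, os.path.join(outdir, "annotation.gtf"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(ann.manifest(), fh, indent=1)
    counts.sample_sheet.to_csv(os.path.join(outdir, "samples.csv"), index=False)
    for sample_id, sjs in counts.junctions.items():
        write_sj_table(sjs, os.path.join(outdir, f"sj_{sample_id}.tsv"))
        ret = counts.retention[sample_id]
        with open(os.path.join(outdir, f"retention_{sample_id}.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tcount\n")
            for (chrom, s, e), c in sorted(ret.items()):
                fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")
    with open(os.path.join(outdir, "library_sizes.json"), "w") as fh:
        json.dump(counts.library_sizes, fh, indent=1)
    return ann
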