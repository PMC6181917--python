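"""Intron sequence characteristics.

Length, AU-richness, border dinucleotides and position-weight-matrix
splice-site scores for intron sets, plus rank-sum group comparisons. The
splice-site score is a log-odds PWM over a 9-nt donor window (last 3 exonic
+ first 6 intronic bases) and a 23-nt acceptor window (last 20 intronic + 3
exonic bases), both read in the transcribed orientation; the score of a site
is sum over positions of log2(p_pos(base) / background(base)) in bits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import ENORMOUS_INTRON_NT, Intron
from .genome import GenomeAccess

__all__ = [
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "IntronFeatures",
    "SpliceSitePWM",
    "SiteScores",
    "au_richness",
    "gc_fraction",
    "border_dinucleotides",
    "donor_window",
    "acceptor_window",
    "train_pwm",
    "score_sequence",
    "splice_site_score",
    "compare_groups",
    "compute_intron_features",
    "summarize_introns",
]

log = logging.getLogger(__name__)

#: (exonic, intronic) base counts for the donor window (9 nt total).
DONOR_WINDOW = (3, 6)
#: (intronic, exonic) base counts for the acceptor window (23 nt total).
ACCEPTOR_WINDOW = (20, 3)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class IntronFeatures:
    """Per-intron feature vector."""

    chrom: str
    strand: str
    start: int
    end: int
    status: str | None
    novelty: str
    length: int
    au_fraction: float
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    donor_score: float
    acceptor_score: float
    site_score: float


@dataclass(frozen=True)
class SpliceSitePWM:
    """Position-specific nucleotide frequencies for donor/acceptor sites."""

    donor_matrix: np.ndarray  # shape (4, 9)
    acceptor_matrix: np.ndarray  # shape (4, 23)
    background: np.ndarray  # shape (4,)
    pseudocount: float
    n_training: int

    def __post_init__(self) -> None:
        for m in (self.donor_matrix, self.acceptor_matrix):
            if not np.allclose(m.sum(axis=0), 1.0):
                raise ValueError("PWM columns must each sum to 1")
            if (m <= 0).any():
                raise ValueError("PWM frequencies must be positive")


@dataclass(frozen=True)
class SiteScores:
    donor: float
    acceptor: float
    site: float
    skipped_positions: int


def au_richness(seq: str) -> float:
    """Fraction of A+U(T) bases; N excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    n = s.count("N")
    denom = len(s) - n
    if denom == 0:
        raise ValueError("sequence is all N")
    return (s.count("A") + s.count("T")) / denom


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; complements :func:`au_richness` for N-free input."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("sequence is all N")
    return (s.count("G") + s.count("C")) / denom


def border_dinucleotides(intron: Intron, genome: GenomeAccess) -> tuple[str, str]:
    """First and last two intronic nucleotides, strand-corrected.

    Minus-strand introns are reverse-complemented so canonical introns always
    read ``("GT", "AG")``.
    """
    if intron.length < 4:
        raise ValueError(f"intron shorter than 4 nt: {intron.span}")
    if intron.strand == "-":
        donor = genome.fetch(intron.chrom, intron.end - 2, intron.end, "-")
        acceptor = genome.fetch(intron.chrom, intron.start, intron.start + 2, "-")
    else:
        donor = genome.fetch(intron.chrom, intron.start, intron.start + 2)
        acceptor = genome.fetch(intron.chrom, intron.end - 2, intron.end)
    return donor, acceptor


def donor_window(intron: Intron, genome: GenomeAccess) -> str | None:
    """9-nt donor-site window in transcribed orientation; None if clipped."""
    ex, into = DONOR_WINDOW
    if intron.strand == "-":
        start, end = intron.end - into, intron.end + ex
        if start < 0 or end > genome.chrom_length(intron.chrom):
            return None
        return genome.fetch(intron.chrom, start, end, "-")
    start, end = intron.start - ex, intron.start + into
    if start < 0 or end > genome.chrom_length(intron.chrom):
        return None
    return genome.fetch(intron.chrom, start, end)


def acceptor_window(intron: Intron, genome: GenomeAccess) -> str | None:
    """23-nt acceptor-site window in transcribed orientation; None if clipped."""
    into, ex = ACCEPTOR_WINDOW
    if intron.strand == "-":
        start, end = intron.start - ex, intron.start + into
        if start < 0 or end > genome.chrom_length(intron.chrom):
            return None
        return genome.fetch(intron.chrom, start, end, "-")
    start, end = intron.end - into, intron.end + ex
    if start < 0 or end > genome.chrom_length(intron.chrom):
        return None
    return genome.fetch(intron.chrom, start, end)


def train_pwm(
    introns: Sequence[Intron],
    genome: GenomeAccess,
    pseudocount: float = 1.0,
) -> SpliceSitePWM:
    """Train donor/acceptor PWMs on a set of introns.

    Introns whose windows fall off the chromosome (or that are shorter than
    the intronic window parts) are excluded. The background distribution is
    estimated from all window positions pooled. Training sets below 50
    introns are accepted but flagged low-confidence in the log.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    d_counts = np.zeros((4, sum(DONOR_WINDOW)))
    a_counts = np.zeros((4, sum(ACCEPTOR_WINDOW)))
    n_used = 0
    for intron in introns:
        if intron.length < max(DONOR_WINDOW[1], ACCEPTOR_WINDOW[0]):
            continue
        dwin = donor_window(intron, genome)
        awin = acceptor_window(intron, genome)
        if dwin is None or awin is None:
            continue
        for counts, win in ((d_counts, dwin), (a_counts, awin)):
            for pos, base in enumerate(win):
                idx = _BASE_INDEX.get(base)
                if idx is not None:
                    counts[idx, pos] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable training introns")
    if n_used < 50:
        log.warning("PWM trained on only %d introns; low confidence", n_used)
    d_freq = (d_counts + pseudocount) / (d_counts + pseudocount).sum(axis=0)
    a_freq = (a_counts + pseudocount) / (a_counts + pseudocount).sum(axis=0)
    pooled = d_counts.sum(axis=1) + a_counts.sum(axis=1) + pseudocount
    background = pooled / pooled.sum()
    return SpliceSitePWM(d_freq, a_freq, background, pseudocount, n_used)


def score_sequence(
    seq: str, matrix: np.ndarray, background: np.ndarray
) -> tuple[float, int]:
    """Log-odds score (bits) of ``seq`` against a PWM column block.

    Positions with non-ACGT bases are skipped; returns (score, n_skipped).
    """
    if len(seq) != matrix.shape[1]:
        raise ValueError(f"sequence length {len(seq)} != PWM width {matrix.shape[1]}")
    score = 0.0
    skipped = 0
    for pos, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            skipped += 1
            continue
        score += float(np.log2(matrix[idx, pos] / background[idx]))
    return score, skipped


def splice_site_score(
    intron: Intron, pwm: SpliceSitePWM, genome: GenomeAccess
) -> SiteScores:
    """Donor, acceptor and mean site score for one intron."""
    dwin = donor_window(intron, genome)
    awin = acceptor_window(intron, genome)
    if dwin is None or awin is None:
        raise ValueError(f"score window clipped for intron {intron.span}")
    d, d_skip = score_sequence(dwin, pwm.donor_matrix, pwm.background)
    a, a_skip = score_sequence(awin, pwm.acceptor_matrix, pwm.background)
    return SiteScores(d, a, (d + a) / 2.0, d_skip + a_skip)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test: (W statistic, p).

    Exact null enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy). Constant pooled input
    is degenerate: p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled input; rank-sum test degenerate, p = 1")
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compute_intron_features(
    introns: Sequence[Intron],
    genome: GenomeAccess,
    pwm: SpliceSitePWM | None = None,
) -> pd.DataFrame:
    """Feature table (one row per intron): length, AU, borders, site scores.

    When ``pwm`` is None, a PWM is trained on the constitutive introns of
    the input (falling back to all introns if none are labelled).
    """
    introns = list(introns)
    if pwm is None:
        training = [i for i in introns if i.status == "constitutive"] or introns
        pwm = train_pwm(training, genome)
    rows = []
    for intron in introns:
        seq = genome.fetch(intron.chrom, intron.start, intron.end, intron.strand)
        donor_d, acceptor_d = border_dinucleotides(intron, genome)
        try:
            scores = splice_site_score(intron, pwm, genome)
            d_sc, a_sc, s_sc = scores.donor, scores.acceptor, scores.site
        except ValueError:  # clipped window near a contig edge
            d_sc = a_sc = s_sc = float("nan")
        rows.append(
            {
                "chrom": intron.chrom,
                "strand": intron.strand,
                "start": intron.start,
                "end": intron.end,
                "status": intron.status,
                "novelty": intron.novelty,
                "length": intron.length,
                "au_fraction": au_richness(seq),
                "donor_dinucleotide": donor_d,
                "acceptor_dinucleotide": acceptor_d,
                "donor_score": d_sc,
                "acceptor_score": a_sc,
                "site_score": s_sc,
                "enormous": intron.is_enormous,
            }
        )
    return pd.DataFrame(rows)


def summarize_introns(features: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Per-group summary of an intron feature table.

    ``by`` names a grouping column (e.g. ``status`` or ``novelty``); None
    summarizes the whole table as a single group. Empty groups are omitted
    with a warning by construction of pandas groupby.
    """
    if features.empty:
        warnings.warn("empty feature table; returning empty summary")
        return pd.DataFrame()
    df = features.copy()
    df["_group"] = "all" if by is None else df[by]
    out = []
    for group, sub in df.groupby("_group", dropna=False):
        borders = sub["donor_dinucleotide"] + "-" + sub["acceptor_dinucleotide"]
        out.append(
            {
                "group": group,
                "n": len(sub),
                "mean_length": sub["length"].mean(),
                "median_length": sub["length"].median(),
                "mean_au": sub["au_fraction"].mean(),
                "gt_ag_fraction": (borders == "GT-AG").mean(),
                "mean_site_score": sub["site_score"].mean(),
                "median_site_score": sub["site_score"].median(),
                "n_enormous": int((sub["length"] > ENORMOUS_INTRON_NT).sum()),
            }
        )
    return pd.DataFrame(out)
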