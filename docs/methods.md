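# Methods

This note documents the models, conventions and design decisions behind
splicescape, and what its synthetic-data tests do and do not demonstrate.

## Coordinate and annotation model

All internal intervals are 0-based half-open; GTF I/O converts to/from the
1-based inclusive GTF convention. A transcript is an ordered, disjoint exon
chain with an optional CDS hull; a gene is a non-empty set of isoforms on
one chromosome and strand. Introns are the gaps between consecutive exons;
abutting exons (a zero-length intron) are rejected as malformed rather than
silently merged. Introns longer than 50 kb are flagged "enormous".

**Constitutive vs alternative introns.** An intron is constitutive iff it
appears, with identical span, in every isoform of its gene whose genomic
span contains the intron. The containment restriction prevents isoforms
that simply end before an intron from voting against it. This is one of
several defensible definitions (an unrestricted all-isoform rule is a
one-line change); analyses comparing constitutive and alternative intron
features should state the rule used.

**Representative isoform and regions.** The representative isoform of a
gene is the one with maximal summed exon length (mature transcript length,
not genomic span), ties broken by smaller start coordinate then transcript
id. Its span is partitioned strand-awarely into 5′UTR / CDS / 3′UTR; an
event is assigned to the region its defining span (skipped exon, retained
intron, inter-boundary interval, or MXE hull) overlaps most, ties going to
the more 5′ region. Events on genes without CDS annotation are
"unpartitioned".

## Junction filtering

Junction evidence is PCR-deduplicated (identical alignment endpoints +
identical junction collapse to one record; no UMI support) and split into
perfectly matched and mismatched reads. Filtering applies, in order:

- **R1** — fewer than 2 deduplicated reads (threshold configurable).
- **R2** — zero perfect reads (mismatch-only support).
- **R3** — any mismatched support and a donor or acceptor within 10 nt of
  the corresponding site of a different junction that has perfect support.
  Proximity is measured per site (donor-to-donor, acceptor-to-acceptor,
  strand-compatible), because alignment wobble displaces one splice site,
  not the whole intron. A shared site (distance 0) counts as "within".

The filtering prose these rules derive from is ambiguous about whether the
mismatch rule is blanket (R2) or proximity-conditioned (R3); the default
applies both, and `mismatch_rule` selects `r2_only` / `r3_only`
alternatives. Filtering is idempotent, and kept/removed always partition
the input.

## Event detection

Events are extracted from unordered isoform pairs, SUPPA-style, rather
than from read alignments:

- **SE** — both isoforms share an upstream exon end and downstream exon
  start; one has exactly one intervening exon, the other splices directly.
- **RI** — one isoform's single exon exactly equals the other's two
  consecutive exons plus the intervening intron (outer bounds must match).
- **A5SS/A3SS** — two junctions share one boundary and differ at the
  other, and the variable boundaries sit on overlapping exons. The overlap
  requirement is what distinguishes a genuine alternative site from the
  junction pattern an SE or MXE pair also produces. Labels are
  strand-aware: a variable genomic-left boundary is a donor (A5SS) on '+'
  and an acceptor (A3SS) on '−'.
- **MXE** — shared flanking donor and acceptor with two disjoint,
  non-identical middle exons, one per isoform.

Events are deduplicated by a canonical key built from type, strand and
anchors (for RI, from the intron span only, since different isoform pairs
can present the same retained intron with different outer exon bounds).
Complex nests emit the maximal set of simple pairwise events; there are no
compound types. Detection is deterministic and invariant to isoform order.

Each event carries the junction sets of its exon-inclusion (EII) and
exon-exclusion (EEI) forms, the exclusion form being the one with the
larger intron. RI has no inclusion junction: its inclusion evidence is a
per-intron retention count (reads inside the intron window) supplied as a
separate table, which keeps the module alignment-free.

## Intron features and splice-site scores

AU-richness is computed on the full intron sequence as (A+T)/(length−N),
N excluded from numerator and denominator. Border dinucleotides are
strand-corrected so canonical introns always read GT–AG. Splice-site
scores are position-specific log-odds in bits: Σ log₂(p_pos(base)/bg(base))
over a 9-nt donor window (3 exonic + 6 intronic) and a 23-nt acceptor
window (20 intronic + 3 exonic), with a +1 pseudocount per cell, the
background pooled over all window positions, and non-ACGT positions
skipped (skips are counted and reported). The PWM is trained by default on
constitutive introns. No published tool defines these absolute score
values, so only ordinal comparisons between intron groups are meaningful;
the scorer is an interface behind which a different method (e.g. a
maximum-entropy model) could be substituted. Group comparisons use the
two-sided Wilcoxon rank-sum test (exact for small tie-free samples,
tie-corrected normal approximation otherwise; constant pooled input
degenerates to p = 1 with a warning).

## Quantification, specificity, differential splicing

PSI = EII/(EII+EEI), undefined (NaN) at zero coverage; the AS score is the
linear map of PSI onto [−1, 1]. FPKM is plain per-library
10⁹·fragments/(length·library); effective-length and cross-library
geometric normalization are out of scope. The transcript filter discards
isoforms with intronic read fraction > 0.15 **or** FPKM < 0.10 × the
gene's major isoform (the OR mirrors the two independent assembler
parameters these thresholds come from; AND is available), never discards
the major isoform by the relative rule, and never empties an expressed
gene.

**Tau.** Samples are pooled within groups (tissue mode pools stages and
replicates; stage mode pools replicates within one tissue) and normalized
to counts per million of the group's junction library. Each event
contributes two profiles (EII and EEI sides); a side is eligible if its
maximum per-group raw count is ≥ 3. τ = Σ(1 − x̂ᵢ)/(n−1) over group
abundances; at the default threshold 1.0 the call is exactly the rule
"expressed in exactly one group" (verified against a brute-force oracle),
and a relaxed threshold uses τ ≥ threshold with the argmax group. Tau runs
on counts by default because "normalized abundance" is underdetermined;
running it on PSI instead is a caller-side choice.

**LRT.** For two conditions with replicate (inclusion, exclusion) counts,
the null fits one common inclusion probability, the alternative one per
condition. The binomial MLEs are closed-form group proportions, so no
iterative fitting is needed; boundary MLEs (0 or 1) are handled by the
0·log 0 = 0 convention and flagged as separation. 2Δℓ ~ χ²(1); BH step-up
controls FDR at α = 0.05. The model deliberately omits overdispersion:
replicates are pooled within condition, which is exact under the binomial
assumption and anti-conservative under biological overdispersion — the
type-I error simulation in the tests checks the binomial regime only.

## Synthetic data

The generator defines the study conditions: 5 tissues × 4 stages × 3
replicates; AS type proportions SE 0.3290, A3SS 0.1598, A5SS 0.1274,
RI 0.3704, MXE 0.0134; 85.53% of genes AS; log-normal intron lengths with
median 1,472 nt; 98% canonical GT–AG borders (non-canonical split 60/30/10
between GC–AG, AT–AC and random); intron AU target 0.53; event coverage
Poisson with mean 50 per sample; 10% tissue-specific events; 20% of the
rest with tissue-varying PSI. Each gene sits on its own chromosome with
4–8 exons of 80–300 nt; one alternate isoform realizes one planted event,
sharing the primary's CDS hull (every event type preserves the terminal
exon boundaries, so containment always holds).

The default intron-length sigma is 0.75, which preserves the median but
not the long tail; `enormous_tail=True` switches sigma to 1.687, matching
a 6,100/1,472 mean/median ratio and a ~2% >50 kb tail, at the cost of a
much larger genome. PSI is constant across stages within a tissue;
specific events have inclusion support zeroed outside their tissue.
Inclusion counts are Binomial(n, PSI), or Beta-Binomial under
`overdispersion_rho`; inclusion reads are split evenly across an event's
two inclusion junctions when it has two. Artifact junctions (mismatch-only
support, one splice site shifted by 1–10 nt from a true junction) are
planted at 2% per true junction per sample for filter testing.

Because sequences are i.i.d. draws (no repeats, no real splice-site
consensus beyond the border dinucleotides, no error model, no reads),
passing tests demonstrate the correctness of the event algebra, the
counting, and the statistics under the stated sampling models — not
robustness to alignment artifacts, repeat-induced junction noise, or
assembler errors on real data.

## Numerical and degenerate-input conventions

Zero-coverage PSI and all-zero Tau profiles are NaN sentinels, never
exceptions. The p-value floor is the smallest positive double, so BH input
stays in (0, 1]. Event detection ties (identical keys from different
isoform pairs) keep the first occurrence in deterministic transcript-id
order. The pipeline aborts on the first failing stage with a stage-tagged
error, retaining tables already written.

## Problem sizes used in tests

The suite exercises detection recovery over 20 seeds at 200 genes,
type-proportion recovery at ~2,000 planted events, specificity recovery at
500 events (50 specific) noise-free and at ρ = 0.01, the LRT null at 2,000
simulated events, and PSI calibration at coverages 10/100/1,000 — sizes
chosen so the whole suite runs in well under a minute on one CPU while
keeping every Monte-Carlo tolerance at ≥3σ.

## Known limitations

- No read-coverage-based RI calling; retention evidence must be supplied.
- No overdispersed (paired/hierarchical) differential model; the
  beta-binomial appears only on the simulation side.
- Junction-count effective-length normalization between inclusion and
  skipping forms is not applied; PSI is a raw junction-count ratio.
- The Tau pipeline applies to whatever event catalog it is given; it does
  not reconcile catalogs produced by different upstream tools.
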