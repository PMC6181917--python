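# splicescape

Alternative-splicing (AS) landscape analysis for bulk RNA-seq studies that
work from assembled transcript models and splice-junction support tables —
the setting of genome-wide AS surveys in livestock transcriptomes (e.g.
multi-tissue, multi-stage goat RNA-seq designs). It is aimed at
bioinformaticians who have a genome FASTA, a transcript annotation GTF and
per-sample junction counts (STAR `SJ.out.tab`, TopHat `junctions.bed`, or
the package's richer TSV dialect) and want a tested, reproducible path from
those inputs to event catalogs, specificity calls and differential-splicing
tests — without re-running alignment or assembly.

## What it computes

- **Splice-junction filtering.** Junctions must carry ≥2 PCR-deduplicated
  reads (R1); junctions supported only by mismatched reads are removed
  (R2); junctions with any mismatched support whose donor or acceptor lies
  within 10 nt of the corresponding site of a perfectly supported junction
  are removed as alignment wobble (R3).
- **AS event classification.** The five local event types — skipped exon
  (SE), retained intron (RI), alternative 5′/3′ splice site (A5SS/A3SS) and
  mutually exclusive exons (MXE) — detected by pairwise isoform comparison
  within each gene, with strand-aware A5SS/A3SS labels, canonical
  pair-order-invariant event keys, and assignment of each event to the
  5′UTR / CDS / 3′UTR of the gene's representative (longest) isoform.
- **Intron characterization.** Length (with a >50 kb "enormous" flag),
  AU-richness, border dinucleotides (strand-corrected, canonical = GT–AG),
  and log-odds PWM splice-site scores over 9-nt donor / 23-nt acceptor
  windows; constitutive vs alternatively spliced intron status; Wilcoxon
  rank-sum group comparisons.
- **Quantification.** For an event with inclusion-form junction count
  Counts_EII and exclusion-form count Counts_EEI:

      PSI = Counts_EII / (Counts_EII + Counts_EEI)
      AS score = (PSI − 0.5) / 0.5  ∈ [−1, 1]

  plus FPKM plumbing and the transcript-level expression filters
  (intronic reads >15%, or <10% of the major isoform's FPKM).
- **Specificity.** Tissue/stage specificity of each event's isoform side
  via the Tau index over per-group CPM-normalized counts,
  τ = Σᵢ(1 − x̂ᵢ)/(n − 1), with a read-count <3 coverage filter and the
  strict single-group rule at the default threshold τ = 1.
- **Differential splicing.** A binomial logistic likelihood-ratio test of
  condition-specific inclusion odds across replicates, χ²(1), with
  Benjamini–Hochberg FDR (significant at q < 0.05).
- **Synthetic data.** A generator that plants all of the above — event
  types in configurable proportions, intron length/AU/border
  distributions, per-tissue PSI, tissue-specific events, artifact
  junctions — with a ground-truth manifest, so every stage is tested
  against a known answer.

## Worked example

Simulate a 50-gene dataset (5 tissues × 4 stages × 3 replicates) and run
the full pipeline:

```sh
splicescape simulate --n-genes 50 --seed 7 --out sim
splicescape run-all --gtf sim/annotation.gtf --fasta sim/genome.fa \
    --junctions 'sim/sj_*.tsv' --retention 'sim/retention_*.tsv' \
    --samples sim/samples.csv --library-sizes sim/library_sizes.json \
    --out out
```

which prints:

```
AS event catalog summary
========================
Total events:        44
AS genes:            44
Events per AS gene:  1.0
AS gene fraction:    88.0% (44/50 intron-containing)

Type       count   percent
SE            17    38.64%
RI             8    18.18%
A5SS          11     25.0%
A3SS           8    18.18%
MXE            0      0.0%

Events by gene region:
  CDS                44  SE=17  RI=8  A5SS=11  A3SS=8
```

44 of the 50 genes received a planted event (the default AS-gene fraction
is 85.53%), every planted event was recovered with its exact anchors, and
all events fall in the CDS because the simulated CDS hull covers the
internal exons. `out/` additionally contains the per-intron feature table
(here: 291 introns, mean length 2,234 nt, median 1,507 nt, mean AU 0.530,
GT–AG fraction 0.966), the per-sample PSI/AS-score table, the Tau
specificity table (4 tissue-specific events, matching the planted truth)
and the LRT differential table (73 significant tests across the 10 tissue
pairs at FDR < 0.05), plus `report.json`/`report.txt`.

The same stages are available as library functions
(`splicescape.as_events.detect_events`, `splicescape.quantification.psi`,
`splicescape.specificity_differential.tau`, …) and as individual
subcommands (`filter-junctions`, `classify-events`, `intron-features`,
`specificity`, `differential`).

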