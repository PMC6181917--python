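"""End-to-end pipeline orchestration.

Runs the stages in order — junction filtering, annotation parsing, AS event
detection, intron characterization, event quantification, specificity and
differential calls — from a :class:`PipelineConfig`, writing every table
with a schema header plus a JSON/text summary report. Reproducible given
the configured seed (the analysis itself is deterministic; the seed only
matters for simulation subcommands).
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from . import (
    annotation_model,
    as_events,
    intron_features,
    junction_filter,
    quantification,
    report,
    specificity_differential as spec_diff,
)
from .genome import FastaGenome

__all__ = ["PipelineConfig", "PipelineError", "run"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genome_fasta: str | None
    annotation_gtf: str
    junction_glob: str  # e.g. "dir/sj_*.tsv"; sample id from the file name
    sample_sheet: str
    out_dir: str
    retention_glob: str | None = None
    library_sizes_json: str | None = None
    min_sj_reads: int = 2
    proximity_nt: int = 10
    mismatch_rule: str = "r2+r3"
    intronic_fraction_max: float = 0.15
    relative_expression_min: float = 0.10
    min_isoform_count: int = 3
    tau_threshold: float = 1.0
    fdr_alpha: float = 0.05
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        for path, label in [
            (self.annotation_gtf, "annotation_gtf"),
            (self.sample_sheet, "sample_sheet"),
        ]:
            if not os.path.exists(path):
                raise PipelineError("config", f"{label} not found: {path}")
        if self.genome_fasta and not os.path.exists(self.genome_fasta):
            raise PipelineError("config", f"genome_fasta not found: {self.genome_fasta}")
        if not _glob.glob(self.junction_glob):
            raise PipelineError(
                "config", f"no junction tables match {self.junction_glob!r}"
            )
        if not (0 < self.fdr_alpha < 1):
            raise PipelineError("config", "fdr_alpha must be in (0, 1)")


def _sample_id_from_path(path: str, prefix: str) -> str:
    name = os.path.splitext(os.path.basename(path))[0]
    return name[len(prefix):] if name.startswith(prefix) else name


def _read_retention(path: str) -> dict[tuple[str, int, int], int]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.chrom), int(r.start), int(r.end)): int(r.count)
        for r in df.itertuples()
    }


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary report dictionary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    summary: dict = {"config": {"rng_seed": config.rng_seed}}

    # --- junction filtering -------------------------------------------------
    try:
        sample_sheet = pd.read_csv(config.sample_sheet)
        kept_by_sample: dict[str, list] = {}
        removed_rows = []
        for path in sorted(_glob.glob(config.junction_glob)):
            sample_id = _sample_id_from_path(path, "sj_")
            sjs = junction_filter.read_sj_table(path)
            kept, removed = junction_filter.filter_junctions(
                sjs,
                min_reads=config.min_sj_reads,
                proximity_nt=config.proximity_nt,
                mismatch_rule=config.mismatch_rule,
            )
            kept_by_sample[sample_id] = kept
            removed_rows.extend(
                {
                    "sample_id": sample_id,
                    "chrom": sj.chrom,
                    "start": sj.start,
                    "end": sj.end,
                    "strand": sj.strand,
                    "reads_dedup": sj.reads_dedup,
                    "removal_rule": rule,
                }
                for sj, rule in removed
            )
        pd.DataFrame(
            removed_rows,
            columns=[
                "sample_id", "chrom", "start", "end", "strand",
                "reads_dedup", "removal_rule",
            ],
        ).to_csv(out("junctions_removed.tsv"), sep="\t", index=False)
        summary["junctions"] = {
            "n_samples": len(kept_by_sample),
            "kept_total": int(sum(len(v) for v in kept_by_sample.values())),
            "removed_total": len(removed_rows),
        }
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("junction_filter", str(exc)) from exc

    # --- annotation ---------------------------------------------------------
    try:
        genome = FastaGenome(config.genome_fasta) if config.genome_fasta else None
        genes = annotation_model.read_gtf(config.annotation_gtf, genome=genome)
        all_kept = [sj for sjs in kept_by_sample.values() for sj in sjs]
        classified = junction_filter.classify_novelty(all_kept, genes)
        n_known = sum(1 for sj in classified if sj.novelty == "known")
        summary["annotation"] = {
            "n_genes": len(genes),
            "n_transcripts": int(sum(len(g.transcripts) for g in genes)),
            "kept_junctions_known": n_known,
            "kept_junctions_novel": len(classified) - n_known,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotation_model", str(exc)) from exc

    # --- AS events ----------------------------------------------------------
    try:
        events, events_df = as_events.event_catalog(genes)
        events_df.to_csv(out("events.tsv"), sep="\t", index=False)
        catalog = report.catalog_summary(events, genes)
        summary["catalog"] = catalog
    except Exception as exc:
        raise PipelineError("as_events", str(exc)) from exc

    # --- intron features ----------------------------------------------------
    if genome is not None:
        try:
            introns = annotation_model.intron_table(genes)
            features = intron_features.compute_intron_features(introns, genome)
            features.to_csv(out("introns.tsv"), sep="\t", index=False)
            stat_summary = intron_features.summarize_introns(features, by="status")
            stat_summary.to_csv(out("intron_summary.tsv"), sep="\t", index=False)
            overall = intron_features.summarize_introns(features)
            row = overall.iloc[0]
            summary["introns"] = {
                "n": int(row["n"]),
                "mean_length": float(row["mean_length"]),
                "median_length": float(row["median_length"]),
                "mean_au": float(row["mean_au"]),
                "gt_ag_fraction": float(row["gt_ag_fraction"]),
                "n_enormous": int(row["n_enormous"]),
            }
        except Exception as exc:
            raise PipelineError("intron_features", str(exc)) from exc

    # --- quantification -----------------------------------------------------
    try:
        sample_counts = {
            s: quantification.junction_count_map(sjs)
            for s, sjs in kept_by_sample.items()
        }
        sample_retention = {}
        if config.retention_glob:
            for path in sorted(_glob.glob(config.retention_glob)):
                sample_id = _sample_id_from_path(path, "retention_")
                sample_retention[sample_id] = _read_retention(path)
        quants = quantification.quantify_events(
            events, sample_counts, sample_retention
        )
        quants.to_csv(out("quant.tsv"), sep="\t", index=False)
        summary["quantification"] = {
            "n_rows": len(quants),
            "n_events_quantified": int(
                quants.loc[
                    quants["counts_eii"] + quants["counts_eei"] > 0, "event_key"
                ].nunique()
            ),
        }
    except Exception as exc:
        raise PipelineError("quantification", str(exc)) from exc

    # --- specificity & differential ----------------------------------------
    try:
        library_sizes = None
        if config.library_sizes_json:
            with open(config.library_sizes_json) as fh:
                library_sizes = json.load(fh)
        agg = spec_diff.aggregate_groups(
            quants, sample_sheet, mode="tissue", library_sizes=library_sizes
        )
        eligible = spec_diff.coverage_filter(agg, min_count=config.min_isoform_count)
        profiles = spec_diff.specificity_profiles(eligible)
        calls = spec_diff.call_specific(profiles, tau_threshold=config.tau_threshold)
        spec_table = eligible.merge(calls, on=["event_key", "side"], how="left")
        spec_table.to_csv(out("specificity.tsv"), sep="\t", index=False)
        specific_events = calls.loc[calls["specific"], "event_key"].nunique()
        summary["specificity"] = {
            "n_profiles": len(profiles),
            "n_specific_events": int(specific_events),
        }

        comparisons = config.comparisons or [
            tuple(c) for c in combinations(sorted(sample_sheet["tissue"].unique()), 2)
        ]
        diff_frames = []
        for a, b in comparisons:
            diff_frames.append(
                spec_diff.differential_table(
                    quants, sample_sheet, a, b, alpha=config.fdr_alpha
                )
            )
        diff = pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame()
        diff.to_csv(out("differential.tsv"), sep="\t", index=False)
        summary["differential"] = {
            "n_comparisons": len(comparisons),
            "n_tests": len(diff),
            "n_significant": int(diff["significant"].sum()) if len(diff) else 0,
        }
    except Exception as exc:
        raise PipelineError("specificity_differential", str(exc)) from exc

    # --- report -------------------------------------------------------------
    with open(out("report.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    with open(out("report.txt"), "w") as fh:
        fh.write(report.render_text_report(summary["catalog"]))
    log.info("pipeline complete; outputs in %s", config.out_dir)
    return summary
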