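"""Stage orchestration: run the full analysis from one RunConfig.

Stages (enrichment, dynamics, expression, motifs) have explicit input
requirements; a stage whose optional inputs are absent is skipped with a
notice, a stage that fails aborts its dependents but independent stages still
run. Every table is written as TSV; report.json carries the numbers plus a
provenance block (config hash, package version, timestamp).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dynamics import analyze_dynamics
from .expression import (
    classify_expression,
    compare_categories,
    fraction_pre_opened,
    tss_mean_coverage,
    ExpressionTable,
)
from .genome_io import (
    read_bed,
    read_chrom_sizes,
    read_fragments_bed,
    read_gene_table,
    read_narrowpeak,
    write_bed,
)
from .motifs import extract_sequences, motif_enrichment, read_fasta, read_jaspar
from .region_enrichment import (
    RegionCatalog,
    build_tss_windows,
    classify_peaks,
    fold_enrichment,
)

log = logging.getLogger("atacdyn")

__all__ = ["AnalysisReport", "run_all", "make_figures"]


@dataclass
class AnalysisReport:
    enrichment: pd.DataFrame | None = None
    classification_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    dynamics_summary: dict[str, float] | None = None
    category_counts: dict[str, int] | None = None
    comparisons: pd.DataFrame | None = None
    pre_opened_fraction: float | None = None
    motif_table: pd.DataFrame | None = None
    skipped_stages: list[str] = field(default_factory=list)
    failed_stages: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)


def _read_peaks(path: Path, genome, label: str):
    if str(path).endswith(("narrowPeak", "narrowpeak")):
        return read_narrowpeak(path, genome, label)
    return read_bed(path, genome, label)


def run_all(config: RunConfig) -> AnalysisReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport()
    report.provenance = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    genome = read_chrom_sizes(config.chrom_sizes)
    genes = read_gene_table(config.genes, genome)
    before = _read_peaks(config.peaks_before, genome, "before")
    after = _read_peaks(config.peaks_after, genome, "after")
    log.info("inputs: %d genes, %d before peaks, %d after peaks",
             len(genes), before.count(), after.count())

    # --- enrichment ---------------------------------------------------
    try:
        windows = build_tss_windows(genes, genome, config.tss_window_half)
        classes = {"tss": windows, "gene_body": [g.body for g in genes]}
        for label, bed_path in config.catalog.items():
            classes[label] = read_bed(bed_path, genome, label).intervals()
        catalog = RegionCatalog.from_intervals(genome, classes)
        rows = []
        for peaks in (before, after):
            for label in catalog.class_labels():
                res = fold_enrichment(
                    peaks, label, catalog,
                    per_region_intervals=windows if label == "tss" else None,
                )
                rows.append(asdict(res))
        report.enrichment = pd.DataFrame(rows)
        report.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        precedence = config.precedence or [c for c in ("tss", *config.catalog, "gene_body")]
        for peaks in (before, after):
            labels = classify_peaks(peaks, catalog, precedence)
            counts = labels.value_counts().to_dict()
            report.classification_counts[peaks.label] = {
                k: int(v) for k, v in counts.items()
            }
        pd.DataFrame(report.classification_counts).to_csv(
            outdir / "peak_classes.tsv", sep="\t"
        )
    except Exception as exc:  # pragma: no cover - defensive
        log.error("enrichment stage failed: %s", exc)
        report.failed_stages["enrichment"] = str(exc)

    # --- dynamics -----------------------------------------------------
    try:
        dyn = analyze_dynamics(
            before, after, genes,
            min_dist=config.min_new_dist, assoc_window=config.assoc_window,
        )
        for name, ps in (
            ("new", dyn.new_peaks),
            ("retained", dyn.retained_peaks),
            ("lost", dyn.lost_peaks),
            ("distal_new", dyn.distal_new_peaks),
        ):
            write_bed(ps, outdir / f"peaks_{name}.bed")
        report.dynamics_summary = {
            "n_before": before.count(),
            "n_after": after.count(),
            "n_new": dyn.new_peaks.count(),
            "n_retained": dyn.retained_peaks.count(),
            "n_lost": dyn.lost_peaks.count(),
            "n_distal_new": dyn.distal_new_peaks.count(),
            "n_genes_gaining_peak": len(dyn.genes_gaining_peak),
            "peak_count_ratio": after.count() / before.count(),
            "mean_tss_distance_new": dyn.mean_tss_distance_new.mean_bp,
            "mean_tss_distance_all_after": dyn.mean_tss_distance_all_after.mean_bp,
        }
        log.info("%d peaks appeared only after; mean TSS distance %d bp vs %d bp",
                 dyn.new_peaks.count(),
                 round(dyn.mean_tss_distance_new.mean_bp),
                 round(dyn.mean_tss_distance_all_after.mean_bp))
        pd.Series(report.dynamics_summary).to_csv(
            outdir / "dynamics_summary.tsv", sep="\t", header=False
        )
        with open(outdir / "genes_gaining_peak.txt", "w") as fh:
            fh.write("\n".join(dyn.genes_gaining_peak) + "\n")
        dynamics_ok = True
    except Exception as exc:
        log.error("dynamics stage failed: %s", exc)
        report.failed_stages["dynamics"] = str(exc)
        dynamics_ok = False

    # --- expression ---------------------------------------------------
    if config.expression is None or config.fragments_before is None:
        report.skipped_stages.append("expression")
        log.info("expression stage skipped (no expression table or fragments)")
    else:
        try:
            expr_df = pd.read_csv(config.expression, sep="\t")
            if {"expressed_before", "expressed_after"} <= set(expr_df.columns):
                table = ExpressionTable(expr_df)
            else:
                table = classify_expression(
                    dict(zip(expr_df["gene_id"], expr_df["abundance_before"])),
                    dict(zip(expr_df["gene_id"], expr_df["abundance_after"])),
                    config.expression_threshold,
                )
            fragments = read_fragments_bed(config.fragments_before, genome, "donor")
            profile = tss_mean_coverage(
                fragments, genes, genome.lengths, config.coverage_window
            )
            report.category_counts = table.category_counts()
            comps = compare_categories(profile, table)
            report.comparisons = pd.DataFrame([asdict(c) for c in comps])
            report.comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
            activated = table.genes_in("only_after")
            if activated:
                report.pre_opened_fraction = fraction_pre_opened(
                    activated, before, genes, config.coverage_window
                )
            per_gene = table.df.copy()
            per_gene["tss_coverage_donor"] = profile.coverage.loc[
                per_gene["gene_id"]
            ].to_numpy()
            per_gene.to_csv(outdir / "gene_categories.tsv", sep="\t", index=False)
        except Exception as exc:
            log.error("expression stage failed: %s", exc)
            report.failed_stages["expression"] = str(exc)

    # --- motifs -------------------------------------------------------
    if config.fasta is None or config.pwms is None:
        report.skipped_stages.append("motifs")
        log.info("motif stage skipped (no FASTA or PWM file)")
    elif not dynamics_ok:
        report.failed_stages["motifs"] = "dependent dynamics stage failed"
    else:
        try:
            sequences = read_fasta(config.fasta)
            pwms = read_jaspar(config.pwms)
            seqs_after = extract_sequences(sequences, dyn.new_peaks.intervals(), genome)
            seqs_before = extract_sequences(sequences, before.intervals(), genome)
            results = motif_enrichment(
                seqs_after, seqs_before, pwms, config.motif_threshold
            )
            report.motif_table = pd.DataFrame([asdict(r) for r in results])
            report.motif_table.to_csv(
                outdir / "motif_enrichment.tsv", sep="\t", index=False
            )
        except Exception as exc:
            log.error("motif stage failed: %s", exc)
            report.failed_stages["motifs"] = str(exc)

    payload = {
        "provenance": report.provenance,
        "skipped_stages": report.skipped_stages,
        "failed_stages": report.failed_stages,
        "dynamics_summary": report.dynamics_summary,
        "category_counts": report.category_counts,
        "pre_opened_fraction": report.pre_opened_fraction,
        "classification_counts": report.classification_counts,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    return report


def make_figures(report: AnalysisReport, outdir) -> list[Path]:
    """Presentation layer only: bar charts of the report's tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if report.enrichment is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        df = report.enrichment
        for i, (label, sub) in enumerate(df.groupby("peakset_label", sort=False)):
            x = np.arange(len(sub)) + i * 0.4
            ax.bar(x, sub["fold"], width=0.38, label=label)
            if i == 0:
                ax.set_xticks(np.arange(len(sub)) + 0.2)
                ax.set_xticklabels(sub["class_label"], rotation=30, ha="right")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("fold enrichment vs whole genome")
        ax.legend()
        fig.tight_layout()
        path = outdir / "enrichment.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if report.comparisons is not None and len(report.comparisons):
        fig, ax = plt.subplots(figsize=(6, 4))
        df = report.comparisons
        x = np.arange(len(df))
        ax.bar(x - 0.2, df["median_a"], width=0.38, label="group A median")
        ax.bar(x + 0.2, df["median_b"], width=0.38, label="group B median")
        ax.set_xticks(x)
        ax.set_xticklabels(
            [f"{a}\nvs {b}" for a, b in zip(df["label_a"], df["label_b"])], fontsize=8
        )
        ax.set_ylabel("median TSS coverage (fragments/bp)")
        ax.legend()
        fig.tight_layout()
        path = outdir / "category_comparisons.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if report.motif_table is not None and len(report.motif_table):
        fig, ax = plt.subplots(figsize=(6, 4))
        df = report.motif_table.sort_values("adjusted_p")
        ax.bar(np.arange(len(df)), -np.log10(df["adjusted_p"].clip(lower=1e-300)))
        ax.set_xticks(np.arange(len(df)))
        ax.set_xticklabels(df["motif_id"], rotation=30, ha="right", fontsize=8)
        ax.set_ylabel("-log10 adjusted p")
        fig.tight_layout()
        path = outdir / "motif_enrichment.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
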