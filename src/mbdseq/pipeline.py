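"""End-to-end orchestration of the synthetic study.

Runs the full design — simulate genome and four condition x passage
samples, deduplicate, call peaks against each sample's supernatant,
partition P1 peaks into DMRs, annotate genomic contexts, measure
cross-passage preservation with a chi-square comparison, and close the
loop with qPCR fold changes and a methylation-expression concordance
report.  Every stage logs its resolved parameters and writes plain-text
outputs (BED / refFlat / TSV / JSON); the run is summarized in a JSON
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, io
from .core import AnnotatedGenome, Peak
from .dmr_analysis import (
    chromosome_distribution,
    compare_preservation,
    global_methylated_fraction,
    partition_peaks,
    preservation,
)
from .expression_qpcr import analyze_folds, concordance_report
from .genomic_annotation import (
    build_feature_map,
    context_distribution,
    promoter_methylation_status,
)
from .peak_calling import PeakCallParams, call_peaks, compute_coverage, deduplicate_reads
from .synthetic_data import (
    SAMPLE_ORDER,
    GenomeSpec,
    LineageConfig,
    build_genome,
    build_truth_table,
    draw_landscapes,
    simulate_mbd_library,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    The default peak-calling bin (1 kb) is matched to the 2 kb planted
    regions and desk-scale depth of the default generator; the
    module-level 200 bp default remains appropriate for deep libraries.
    """

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    lineage: LineageConfig = field(default_factory=LineageConfig)
    peaks: PeakCallParams = field(
        default_factory=lambda: PeakCallParams(
            bin_size=1000, p_threshold=1e-5, min_width=1000, merge_gap=0
        )
    )
    promoter_def: tuple[int, int] = (2000, 500)
    qpcr_replicates: int = 6
    qpcr_noise_sd: float = 0.2
    qpcr_genes_per_class: int = 3
    seed: int = 0
    write_reads: bool = True

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            genome=dataclasses.replace(self.genome, seed=seed),
            lineage=dataclasses.replace(self.lineage, seed=seed),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = dict(data)
        if "genome" in kwargs:
            g = dict(kwargs["genome"])
            if "chromosomes" in g:
                g["chromosomes"] = tuple((str(c), int(s)) for c, s in g["chromosomes"])
            for key in ("gene_length_range", "exon_count_range", "cgi_length_range"):
                if key in g:
                    g[key] = tuple(g[key])
            kwargs["genome"] = GenomeSpec(**g)
        if "lineage" in kwargs:
            ln = dict(kwargs["lineage"])
            for key in ("level_range", "promoter_def"):
                if key in ln:
                    ln[key] = tuple(ln[key])
            kwargs["lineage"] = LineageConfig(**ln)
        if "peaks" in kwargs:
            kwargs["peaks"] = PeakCallParams(**kwargs["peaks"])
        if "promoter_def" in kwargs:
            kwargs["promoter_def"] = tuple(kwargs["promoter_def"])
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """What a run produced: config snapshot, file paths, and counts."""

    version: str
    seed: int
    config: dict[str, Any]
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    def validate_outputs(self) -> None:
        for stage, p in self.outputs.items():
            fp = Path(p)
            if not fp.exists() or fp.stat().st_size == 0:
                raise RuntimeError(f"stage '{stage}' output missing or empty: {p}")


def simulate_and_call(
    genome: AnnotatedGenome,
    cfg: LineageConfig,
    params: PeakCallParams,
) -> tuple[dict[str, Any], dict[str, list[Peak]]]:
    """Generate landscapes and libraries and call peaks for all four
    samples.  Returns (landscapes, peaks per sample).  This is the
    methylation arm of the study, reusable without file I/O."""
    landscapes = draw_landscapes(genome, cfg)
    sizes = genome.chrom_sizes
    peaks: dict[str, list[Peak]] = {}
    for name in SAMPLE_ORDER:
        reads = simulate_mbd_library(landscapes[name], genome, cfg)
        dedup = deduplicate_reads(reads)
        cap = compute_coverage(dedup[dedup["fraction"] == "captured"], sizes, params.bin_size)
        bg = compute_coverage(dedup[dedup["fraction"] == "supernatant"], sizes, params.bin_size)
        peaks[name] = call_peaks(cap, bg, params)
    return landscapes, peaks


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Execute the full study design and write all stage outputs."""
    if seed is not None:
        config = config.with_seed(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed, config=config.to_dict())
    save_config(config, out / "config.resolved.yaml")
    logger.info("resolved config written to %s", out / "config.resolved.yaml")

    def _stage(name: str):
        t0 = time.perf_counter()

        def _done() -> None:
            manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %-12s done in %.2fs", name, manifest.timings_s[name])

        return _done

    # --- simulate genome + annotation files
    done = _stage("genome")
    genome = build_genome(config.genome)
    io.write_refflat(genome.genes, out / "genes.refflat")
    io.write_bed3(genome.cgis, out / "cgis.bed")
    io.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    manifest.outputs.update(
        refflat=str(out / "genes.refflat"),
        cgis=str(out / "cgis.bed"),
        chrom_sizes=str(out / "chrom.sizes"),
    )
    done()

    # --- landscapes, libraries, peak calling
    done = _stage("methylation")
    landscapes = draw_landscapes(genome, config.lineage)
    truth = build_truth_table(landscapes)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest.outputs["truth_table"] = str(out / "truth.tsv")
    sizes = genome.chrom_sizes
    peaks: dict[str, list[Peak]] = {}
    for name in SAMPLE_ORDER:
        reads = simulate_mbd_library(landscapes[name], genome, config.lineage)
        if config.write_reads:
            io.write_reads_bed(reads, out / f"reads_{name}.bed")
            manifest.outputs[f"reads_{name}"] = str(out / f"reads_{name}.bed")
        dedup = deduplicate_reads(reads)
        cap = compute_coverage(
            dedup[dedup["fraction"] == "captured"], sizes, config.peaks.bin_size
        )
        bg = compute_coverage(
            dedup[dedup["fraction"] == "supernatant"], sizes, config.peaks.bin_size
        )
        peaks[name] = call_peaks(cap, bg, config.peaks)
        io.write_peaks_bed(peaks[name], out / f"peaks_{name}.bed")
        manifest.outputs[f"peaks_{name}"] = str(out / f"peaks_{name}.bed")
        manifest.summary[f"n_peaks_{name}"] = len(peaks[name])
        manifest.summary[f"n_reads_dedup_{name}"] = int(len(dedup))
    done()

    # --- P1 partition (DMRs) + chromosome distribution
    done = _stage("partition")
    part = partition_peaks(
        peaks["control_P1"], peaks["dex_P1"], labels=("control", "dex")
    )
    manifest.summary.update(
        n_unique_control=len(part.unique_a),
        n_unique_dex=len(part.unique_b),
        n_common=len(part.common),
    )
    io.write_peaks_bed(list(part.unique_a), out / "dmrs_control_unique.bed")
    io.write_peaks_bed(list(part.unique_b), out / "dmrs_dex_unique.bed")
    io.write_bed3(list(part.common), out / "peaks_common.bed")
    chrom_names = list(sizes)
    dist = pd.DataFrame(
        {
            "control": chromosome_distribution(peaks["control_P1"], chrom_names),
            "dex": chromosome_distribution(peaks["dex_P1"], chrom_names),
        }
    )
    dist.to_csv(out / "chromosome_distribution.tsv", sep="\t")
    manifest.outputs.update(
        dmrs_control_unique=str(out / "dmrs_control_unique.bed"),
        dmrs_dex_unique=str(out / "dmrs_dex_unique.bed"),
        peaks_common=str(out / "peaks_common.bed"),
        chromosome_distribution=str(out / "chromosome_distribution.tsv"),
    )
    manifest.summary["global_methylated_fraction"] = {
        name: global_methylated_fraction(
            [p.as_interval() for p in peaks[name]], sizes
        )
        for name in SAMPLE_ORDER
    }
    done()

    # --- genomic context annotation
    done = _stage("annotation")
    fmap = build_feature_map(genome, config.promoter_def)
    for label, pk in (
        ("dmrs_control_unique", list(part.unique_a)),
        ("dmrs_dex_unique", list(part.unique_b)),
    ):
        for cgi_only in (False, True):
            tag = f"{label}_context{'_cgi' if cgi_only else ''}"
            df = context_distribution(
                [p.as_interval() for p in pk], fmap, restrict_to_cgi=cgi_only
            )
            df.to_csv(out / f"{tag}.tsv", sep="\t")
            manifest.outputs[tag] = str(out / f"{tag}.tsv")
    done()

    # --- preservation across passages
    done = _stage("preservation")
    pres_dex = preservation(peaks["dex_P1"], peaks["dex_D3"])
    pres_ctrl = preservation(peaks["control_P1"], peaks["control_D3"])
    pres_dex = compare_preservation(pres_dex, pres_ctrl)
    manifest.summary.update(
        preservation_dex=pres_dex.fraction,
        preservation_control=pres_ctrl.fraction,
        preservation_chi_square=pres_dex.comparison[0],
        preservation_p_value=pres_dex.comparison[1],
    )
    with open(out / "preservation.json", "w") as fh:
        json.dump(
            {
                "dex": {"n_p1": pres_dex.n_p1, "n_preserved": pres_dex.n_preserved,
                        "fraction": pres_dex.fraction},
                "control": {"n_p1": pres_ctrl.n_p1, "n_preserved": pres_ctrl.n_preserved,
                            "fraction": pres_ctrl.fraction},
                "chi_square": pres_dex.comparison[0],
                "p_value": pres_dex.comparison[1],
            },
            fh,
            indent=2,
        )
    manifest.outputs["preservation"] = str(out / "preservation.json")
    done()

    # --- qPCR arm: pick genes by promoter status, simulate, analyze
    done = _stage("qpcr")
    statuses = {
        g.name: promoter_methylation_status(g, part, sizes, config.promoter_def)
        for g in genome.genes
    }
    k = config.qpcr_genes_per_class
    hypo = [g for g, s in statuses.items() if s == "hypomethylated_in_b"][:k]
    hyper = [g for g, s in statuses.items() if s == "hypermethylated_in_b"][:k]
    unchanged = [g for g, s in statuses.items() if s == "unchanged"][:k]
    design: dict[str, dict[str, float]] = {}
    # promoter hypomethylation in Dex -> upregulation, and vice versa
    design.update({g: {"control": 1.0, "dex": 2.0} for g in hypo})
    design.update({g: {"control": 1.0, "dex": 0.5} for g in hyper})
    design.update({g: {"control": 1.0, "dex": 1.0} for g in unchanged})
    ct = simulate_qpcr(
        design,
        replicates=config.qpcr_replicates,
        noise_sd=config.qpcr_noise_sd,
        seed=config.seed,
    )
    io.write_ct_table(ct, out / "qpcr_ct.tsv")
    folds = analyze_folds(ct, treated="dex", control="control")
    fold_rows = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "delta_delta_ct": r.delta_delta_ct,
                "fold": r.fold,
                "p_value": r.p_value,
            }
            for r in folds.values()
        ]
    )
    fold_rows.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
    report = concordance_report(folds, {g: statuses[g] for g in design})
    report.to_csv(out / "concordance.tsv", sep="\t", index=False)
    manifest.outputs.update(
        qpcr_ct=str(out / "qpcr_ct.tsv"),
        qpcr_folds=str(out / "qpcr_folds.tsv"),
        concordance=str(out / "concordance.tsv"),
    )
    manifest.summary["concordant_fraction"] = report.attrs["concordant_fraction"]
    manifest.summary["n_qpcr_genes"] = len(design)
    done()

    manifest.validate_outputs()
    manifest.save(out / "manifest.json")
    return manifest
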