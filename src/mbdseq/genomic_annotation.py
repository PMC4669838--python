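"""Genomic-context classification of peaks against refFlat gene models.

Each peak receives exactly one primary context — promoter, 5' UTR,
3' UTR, exon, intron, or intergenic — chosen by a configurable
precedence among the contexts it overlaps; CpG-island overlap is
tracked independently.  Context distributions report raw counts
alongside per-megabase-of-feature densities so the choice of
normalization is never hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import AnnotatedGenome, GeneModel, GenomicInterval
from .dmr_analysis import DmrPartition

logger = logging.getLogger(__name__)

#: Default precedence, highest first; "intergenic" is the fallback.
DEFAULT_PRECEDENCE = ("promoter", "5utr", "3utr", "exon", "intron")

CONTEXTS = DEFAULT_PRECEDENCE + ("intergenic",)


@dataclass(frozen=True)
class ContextAssignment:
    peak: GenomicInterval
    primary_context: str
    cgi_overlap: bool
    gene: str | None


@dataclass
class FeatureMap:
    """Per-context interval trees plus merged feature sizes in bp."""

    trees: dict[str, dict[str, IntervalTree]]
    cgi_trees: dict[str, IntervalTree]
    feature_bp: dict[str, int]
    genome_bp: int
    promoter_def: tuple[int, int]


def _promoter_interval(
    gene: GeneModel, promoter_def: tuple[int, int], chrom_len: int
) -> tuple[int, int] | None:
    """Strand-aware promoter window around the TSS, clipped to bounds."""
    up, down = promoter_def
    if gene.strand == "+":
        s, e = gene.tx_start - up, gene.tx_start + down
    else:
        s, e = gene.tx_end - down, gene.tx_end + up
    s, e = max(0, s), min(chrom_len, e)
    return (s, e) if s < e else None


def _gene_features(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Exon/intron/UTR blocks of one gene (UTRs are exonic, strand-aware)."""
    out: dict[str, list[tuple[int, int]]] = {
        "exon": [],
        "intron": [],
        "5utr": [],
        "3utr": [],
    }
    exons = list(zip(gene.exon_starts, gene.exon_ends))
    out["exon"] = exons
    for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
        if e1 < s2:
            out["intron"].append((e1, s2))
    if gene.is_coding:
        left, right = [], []  # exonic bp left of cds_start / right of cds_end
        for s, e in exons:
            if s < gene.cds_start:
                left.append((s, min(e, gene.cds_start)))
            if e > gene.cds_end:
                right.append((max(s, gene.cds_end), e))
        if gene.strand == "+":
            out["5utr"], out["3utr"] = left, right
        else:
            out["5utr"], out["3utr"] = right, left
    else:
        logger.debug("gene %s is non-coding: no UTRs emitted", gene.name)
    return out


def _merged_bp(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def build_feature_map(
    genome: AnnotatedGenome, promoter_def: tuple[int, int] = (2000, 500)
) -> FeatureMap:
    """Derive per-context interval sets from gene models and CGIs.

    The promoter is a strand-aware window around each TSS (default
    -2000/+500 bp); introns are transcript minus exons; UTRs come from
    cds vs transcript bounds and are empty for non-coding genes.
    """
    if promoter_def[0] < 0 or promoter_def[1] < 0:
        raise ValueError("promoter_def components must be non-negative")
    sizes = genome.chrom_sizes
    trees: dict[str, dict[str, IntervalTree]] = {
        ctx: {c: IntervalTree() for c in sizes} for ctx in DEFAULT_PRECEDENCE
    }
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        ctx: {c: [] for c in sizes} for ctx in DEFAULT_PRECEDENCE
    }
    for gene in genome.genes:
        prom = _promoter_interval(gene, promoter_def, sizes[gene.chrom])
        if prom is not None:
            trees["promoter"][gene.chrom][prom[0] : prom[1]] = gene.name
            raw["promoter"][gene.chrom].append(prom)
        for ctx, blocks in _gene_features(gene).items():
            for s, e in blocks:
                if s < e:
                    trees[ctx][gene.chrom][s:e] = gene.name
                    raw[ctx][gene.chrom].append((s, e))

    cgi_trees = {c: IntervalTree() for c in sizes}
    for cgi in genome.cgis:
        cgi_trees[cgi.chrom][cgi.start : cgi.end] = True

    feature_bp = {
        ctx: sum(_merged_bp(raw[ctx][c]) for c in sizes) for ctx in DEFAULT_PRECEDENCE
    }
    # intergenic: bp covered by no gene-derived feature at all
    all_by_chrom = {
        c: [iv for ctx in DEFAULT_PRECEDENCE for iv in raw[ctx][c]] for c in sizes
    }
    covered = sum(_merged_bp(v) for v in all_by_chrom.values())
    feature_bp["intergenic"] = genome.total_bp - covered
    return FeatureMap(
        trees=trees,
        cgi_trees=cgi_trees,
        feature_bp=feature_bp,
        genome_bp=genome.total_bp,
        promoter_def=promoter_def,
    )


def classify_context(
    peak: GenomicInterval,
    fmap: FeatureMap,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> ContextAssignment:
    """Assign the highest-precedence context the peak overlaps.

    Within the winning context, ties between genes are broken by larger
    overlap, then lexicographically smaller gene name.  CGI overlap is
    recorded independently of the primary context.
    """
    cgi = False
    tree = fmap.cgi_trees.get(peak.chrom)
    if tree is not None and tree.overlap(peak.start, peak.end):
        cgi = True
    for ctx in precedence:
        chrom_trees = fmap.trees.get(ctx, {})
        tree = chrom_trees.get(peak.chrom)
        if tree is None:
            continue
        hits = tree.overlap(peak.start, peak.end)
        if hits:
            best = min(
                hits,
                key=lambda iv: (
                    -(min(iv.end, peak.end) - max(iv.begin, peak.start)),
                    str(iv.data),  # smaller name wins on equal overlap
                ),
            )
            return ContextAssignment(peak, ctx, cgi, str(best.data))
    return ContextAssignment(peak, "intergenic", cgi, None)


def context_distribution(
    peaks: Sequence[GenomicInterval],
    fmap: FeatureMap,
    restrict_to_cgi: bool = False,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Tabulate peaks per context with per-Mb-of-feature densities.

    When ``restrict_to_cgi`` only CGI-overlapping peaks enter the
    counts.  A context with zero feature bp gets density NaN
    (undefined), never zero.
    """
    counts = {ctx: 0 for ctx in list(precedence) + ["intergenic"]}
    for peak in peaks:
        asg = classify_context(peak, fmap, precedence)
        if restrict_to_cgi and not asg.cgi_overlap:
            continue
        counts[asg.primary_context] += 1
    rows = []
    for ctx, n in counts.items():
        bp = fmap.feature_bp.get(ctx, 0)
        density = n / (bp / 1e6) if bp > 0 else float("nan")
        rows.append((ctx, n, bp, density))
    return pd.DataFrame(
        rows, columns=["context", "raw_count", "feature_bp", "density_per_mb"]
    ).set_index("context")


def promoter_methylation_status(
    gene: GeneModel,
    partition: DmrPartition,
    chrom_sizes: Mapping[str, int],
    promoter_def: tuple[int, int] = (2000, 500),
) -> str:
    """Methylation status of a gene's promoter across a two-condition
    partition (a = reference, b = treated).

    A promoter overlapped only by a reference-unique peak lost
    methylation in the treated condition (hypomethylated_in_b); only by
    a treated-unique peak, gained it (hypermethylated_in_b); by both,
    the call is "mixed"; by neither, "unchanged".
    """
    prom = _promoter_interval(gene, promoter_def, chrom_sizes[gene.chrom])
    if prom is None:
        return "unchanged"
    window = GenomicInterval(gene.chrom, prom[0], prom[1])
    in_a = any(window.overlap_bp(p) > 0 for p in partition.unique_a)
    in_b = any(window.overlap_bp(p) > 0 for p in partition.unique_b)
    if in_a and in_b:
        logger.warning("gene %s promoter overlaps both unique sets: mixed", gene.name)
        return "mixed"
    if in_a:
        return "hypomethylated_in_b"
    if in_b:
        return "hypermethylated_in_b"
    return "unchanged"
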