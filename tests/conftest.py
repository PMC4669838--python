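import networkx as nx
import numpy as np
import pytest

from mbdseq.core import GenomicInterval, Peak
from mbdseq.genomic_annotation import DEFAULT_PRECEDENCE
from mbdseq.synthetic_data import GenomeSpec, build_genome


def make_peaks(spans, chrom="chr1"):
    """Peaks from (start, end) or (chrom, start, end) tuples."""
    out = []
    for span in spans:
        if len(span) == 2:
            out.append(Peak(chrom, span[0], span[1]))
        else:
            out.append(Peak(span[0], span[1], span[2]))
    return out


def random_nonoverlapping_peaks(rng, chrom, length, n, wmin=200, wmax=2000, min_gap=1):
    """Up to n random non-overlapping peaks on one chromosome."""
    starts = np.sort(rng.integers(0, length - wmax, n * 3))
    peaks = []
    cursor = 0
    for s in starts:
        if len(peaks) >= n:
            break
        if s < cursor:
            continue
        w = int(rng.integers(wmin, wmax + 1))
        if s + w > length:
            continue
        peaks.append(Peak(chrom, int(s), int(s + w)))
        cursor = s + w + min_gap
    return peaks


def brute_force_partition(peaks_a, peaks_b):
    """Oracle for the peak partition: full pairwise overlap graph plus
    networkx connected components (independent of the sweep in the
    implementation)."""
    g = nx.Graph()
    g.add_nodes_from([("a", i) for i in range(len(peaks_a))])
    g.add_nodes_from([("b", i) for i in range(len(peaks_b))])
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.overlap_bp(pb) >= 1:
                g.add_edge(("a", i), ("b", j))
    unique_a, unique_b, common = [], [], []
    for comp in nx.connected_components(g):
        sides = {side for side, _ in comp}
        members = [(peaks_a if side == "a" else peaks_b)[i] for side, i in comp]
        if sides == {"a", "b"}:
            common.append(
                GenomicInterval(
                    members[0].chrom,
                    min(m.start for m in members),
                    max(m.end for m in members),
                )
            )
        elif sides == {"a"}:
            unique_a.extend(members)
        else:
            unique_b.extend(members)
    return sorted(unique_a), sorted(unique_b), sorted(common)


def oracle_features(gene, promoter_def, chrom_len):
    """Oracle: independent per-gene context intervals (positions for the
    derived features, so no interval arithmetic is shared with the
    implementation)."""
    up, down = promoter_def
    feats = {ctx: [] for ctx in DEFAULT_PRECEDENCE}
    if gene.strand == "+":
        prom = (gene.tx_start - up, gene.tx_start + down)
    else:
        prom = (gene.tx_end - down, gene.tx_end + up)
    prom = (max(0, prom[0]), min(chrom_len, prom[1]))
    if prom[0] < prom[1]:
        feats["promoter"].append(prom)
    exonic = set()
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        feats["exon"].append((s, e))
        exonic.update(range(s, e))
    for pos in range(gene.tx_start, gene.tx_end):
        if pos not in exonic:
            feats["intron"].append((pos, pos + 1))
    if gene.cds_start < gene.cds_end:
        before = [p for p in exonic if p < gene.cds_start]
        after = [p for p in exonic if p >= gene.cds_end]
        five, three = (before, after) if gene.strand == "+" else (after, before)
        feats["5utr"] = [(p, p + 1) for p in five]
        feats["3utr"] = [(p, p + 1) for p in three]
    return feats


def oracle_feature_cache(genome, promoter_def=(2000, 500)):
    sizes = genome.chrom_sizes
    return [
        (g.chrom, oracle_features(g, promoter_def, sizes[g.chrom]))
        for g in genome.genes
    ]


def oracle_classify(peak, cache):
    """Oracle: exhaustive overlap enumeration plus precedence."""
    for ctx in DEFAULT_PRECEDENCE:
        for chrom, feats in cache:
            if chrom != peak.chrom:
                continue
            for s, e in feats[ctx]:
                if min(e, peak.end) > max(s, peak.start):
                    return ctx
    return "intergenic"


@pytest.fixture(scope="session")
def small_genome():
    spec = GenomeSpec(
        chromosomes=(("chr1", 1_000_000), ("chr2", 600_000)),
        n_genes=40,
        n_cgis=25,
        seed=11,
    )
    return build_genome(spec)
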