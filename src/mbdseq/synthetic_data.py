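"""Synthetic study generator: genome, methylation landscapes, capture
libraries, and qPCR plates.

The generator emulates the design of a two-condition, two-passage MBD
capture experiment on neural stem cells: a control and a dexamethasone
(Dex) exposed culture are profiled right after exposure (parent, P1) and
again two passages later in never-exposed daughter cells (D3).  Dex
demethylates a fraction of the control methylation landscape in P1 (net
hypomethylation) and each P1 region survives into its lineage's D3
landscape with a lineage-specific retention probability — higher in the
Dex lineage than in control, which is the cross-passage stability signal
the downstream preservation analysis measures.

Randomness is consumed from named streams derived from one global seed
(genome = 0, landscapes = 1, libraries = 2 plus a per-sample index,
qPCR = 3), so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CAPTURED,
    SUPERNATANT,
    AnnotatedGenome,
    GeneModel,
    GenomicInterval,
    MethylationLandscape,
)

STREAM_GENOME = 0
STREAM_LANDSCAPES = 1
STREAM_LIBRARY = 2
STREAM_QPCR = 3

#: Canonical sample order; also fixes the per-sample library RNG stream.
SAMPLE_ORDER = ("control_P1", "dex_P1", "control_D3", "dex_D3")

MIN_EXON_BLOCK = 50
MIN_GENE_GAP = 200


class PackingError(ValueError):
    """Requested features do not fit into the genome."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the toy annotated genome.

    ``promoter_cgi_fraction`` controls how many CpG islands are anchored
    at a gene's transcription start site rather than placed uniformly;
    real CGIs cluster at promoters, and the annotation module's
    CGI-restricted distributions are only informative if some do here.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 12_000_000),
        ("chr2", 9_000_000),
        ("chr3", 6_000_000),
        ("chr4", 3_000_000),
    )
    n_genes: int = 300
    n_cgis: int = 200
    promoter_cgi_fraction: float = 0.5
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    exon_count_range: tuple[int, int] = (1, 8)
    noncoding_fraction: float = 0.2
    cgi_length_range: tuple[int, int] = (300, 2_000)
    seed: int = 0


@dataclass(frozen=True)
class LineageConfig:
    """Condition/lineage structure and sequencing parameters.

    The retention defaults (0.63 for the Dex lineage, 0.36 for control)
    are the cross-passage peak-preservation proportions of the emulated
    study; ``hypo_fraction`` and ``gain_fraction`` are derived from its
    peak partition (110000 control-unique and 37005 Dex-unique peaks out
    of 164801 control peaks: 110000/164801 ~= 0.667 demethylated,
    37005/164801 ~= 0.225 newly methylated in Dex).  Fragment length
    matches the ~200 bp sonicated DNA of the protocol.  Depth is a
    desk-scale library size for the default 30 Mb genome.
    """

    retention_dex: float = 0.63
    retention_control: float = 0.36
    hypo_fraction: float = 110_000 / 164_801
    gain_fraction: float = 37_005 / 164_801
    enrichment: float = 50.0
    base_capture_rate: float = 0.02
    depth: int = 800_000
    fragment_length: int = 200
    n_regions: int = 900
    region_width: int = 2_000
    region_min_gap: int = 2_000
    level_range: tuple[float, float] = (0.8, 1.0)
    hypo_promoter_bias: float = 4.0
    promoter_def: tuple[int, int] = (2_000, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("retention_dex", "retention_control", "hypo_fraction", "gain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if not 0.0 < self.base_capture_rate <= 1.0:
            raise ValueError("base_capture_rate must be in (0, 1]")


# ---------------------------------------------------------------------------
# genome construction


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: Sequence[tuple[str, int]],
    widths: np.ndarray,
    min_gap: int,
) -> pd.DataFrame:
    """Place intervals of the given widths without overlap.

    Intervals are allocated to chromosomes proportionally to length and
    positioned by distributing the leftover base pairs as random gaps,
    which is uniform over all feasible non-overlapping placements with
    the required spacing.  Raises :class:`PackingError` when they do not
    fit.
    """
    n = len(widths)
    lengths = np.array([length for _, length in chrom_sizes], dtype=float)
    counts = rng.multinomial(n, lengths / lengths.sum())
    # rebalance chromosomes that cannot hold their allocation
    order = np.argsort(widths)[::-1]
    rows: list[tuple[str, int, int]] = []
    cursor = 0
    for attempt in range(100):
        ok = True
        trial_rows: list[tuple[str, int, int]] = []
        cursor = 0
        for (chrom, clen), k in zip(chrom_sizes, counts):
            w = widths[order[cursor : cursor + k]]
            cursor += k
            if k == 0:
                continue
            free = clen - int(w.sum()) - (k - 1) * min_gap
            if free < 0:
                ok = False
                break
            gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
            pos = gaps[0]
            for i in range(k):
                trial_rows.append((chrom, int(pos), int(pos + w[i])))
                pos += w[i] + min_gap + gaps[i + 1]
        if ok:
            rows = trial_rows
            break
        # move one interval from the most to the least loaded chromosome
        load = counts * (widths.mean() if n else 0) / np.maximum(lengths, 1)
        src, dst = int(np.argmax(load)), int(np.argmin(load))
        if counts[src] == 0 or src == dst:
            raise PackingError(
                f"cannot place {n} intervals of total width {int(widths.sum())} bp"
            )
        counts[src] -= 1
        counts[dst] += 1
    else:
        raise PackingError(
            f"cannot place {n} intervals of total width {int(widths.sum())} bp"
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _make_gene(
    rng: np.random.Generator,
    name: str,
    chrom: str,
    start: int,
    end: int,
    spec: GenomeSpec,
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    length = end - start
    max_exons = max(1, min(spec.exon_count_range[1], (length // (2 * MIN_EXON_BLOCK) + 1) // 2))
    n_exons = int(rng.integers(spec.exon_count_range[0], max_exons + 1))
    n_blocks = 2 * n_exons - 1  # exon, intron, exon, ...
    extra = rng.multinomial(length - n_blocks * MIN_EXON_BLOCK, np.full(n_blocks, 1.0 / n_blocks))
    blocks = MIN_EXON_BLOCK + extra
    bounds = start + np.concatenate([[0], np.cumsum(blocks)])
    exon_starts = tuple(int(b) for b in bounds[0:-1:2])
    exon_ends = tuple(int(b) for b in bounds[1::2])
    if rng.random() < spec.noncoding_fraction:
        cds_start = cds_end = start
    else:
        cds_start = int(rng.integers(start + 1, start + max(2, length // 3)))
        cds_end = int(rng.integers(end - max(2, length // 3), end))
        if cds_start >= cds_end:
            cds_start, cds_end = sorted((cds_start, cds_end))
            if cds_start == cds_end:
                cds_end += 1
    return GeneModel(
        name=name,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        cds_start=cds_start,
        cds_end=cds_end,
        exon_starts=exon_starts,
        exon_ends=exon_ends,
    )


def build_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Build a deterministic annotated toy genome from the spec."""
    rng = np.random.default_rng([spec.seed, STREAM_GENOME])
    for name, length in spec.chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive size")

    widths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, spec.n_genes
    )
    placed = _place_nonoverlapping(rng, spec.chromosomes, widths, MIN_GENE_GAP)
    placed = placed.sort_values(["chrom", "start"]).reset_index(drop=True)
    genes = tuple(
        _make_gene(rng, f"gene_{i + 1:04d}", row.chrom, row.start, row.end, spec)
        for i, row in enumerate(placed.itertuples())
    )

    sizes = dict(spec.chromosomes)
    cgis: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    for i in range(spec.n_cgis):
        for _ in range(1000):
            w = int(rng.integers(spec.cgi_length_range[0], spec.cgi_length_range[1] + 1))
            if genes and rng.random() < spec.promoter_cgi_fraction:
                g = genes[int(rng.integers(len(genes)))]
                center = g.tss
                start = max(0, min(center - w // 2, sizes[g.chrom] - w))
                chrom = g.chrom
            else:
                ci = int(rng.integers(len(spec.chromosomes)))
                chrom, clen = spec.chromosomes[ci]
                if clen <= w:
                    continue
                start = int(rng.integers(0, clen - w))
            end = start + w
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                cgis.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise PackingError(f"cannot place CGI {i + 1} of {spec.n_cgis}")

    return AnnotatedGenome(
        chromosomes=tuple(spec.chromosomes),
        genes=genes,
        cgis=tuple(sorted(cgis)),
    )


# ---------------------------------------------------------------------------
# methylation landscapes


def _promoter_windows(genome: AnnotatedGenome, promoter_def: tuple[int, int]) -> dict[str, np.ndarray]:
    """Sorted promoter windows per chromosome as an (n, 2) array."""
    up, down = promoter_def
    sizes = genome.chrom_sizes
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    for g in genome.genes:
        if g.strand == "+":
            s, e = g.tx_start - up, g.tx_start + down
        else:
            s, e = g.tx_end - down, g.tx_end + up
        s, e = max(0, s), min(sizes[g.chrom], e)
        if s < e:
            per_chrom[g.chrom].append((s, e))
    return {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in per_chrom.items()}


def _overlaps_any(chrom: str, start: int, end: int, windows: Mapping[str, np.ndarray]) -> bool:
    w = windows.get(chrom)
    if w is None or len(w) == 0:
        return False
    i = np.searchsorted(w[:, 0], end)
    return bool((w[:i, 1] > start).any())


def _redraw_regions(
    rng: np.random.Generator,
    n: int,
    genome: AnnotatedGenome,
    width: int,
    forbidden: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, int, int]]:
    """Draw n uniform regions avoiding the forbidden intervals.

    Exclusion of the parental region set keeps the realized D3 overlap
    with P1 equal to the configured retention probability instead of
    being inflated by chance re-landings.
    """
    chroms = genome.chromosomes
    lengths = np.array([length for _, length in chroms], dtype=float)
    out: list[tuple[str, int, int]] = []
    for _ in range(n):
        for _ in range(10_000):
            ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom, clen = chroms[ci]
            if clen <= width:
                continue
            start = int(rng.integers(0, clen - width))
            end = start + width
            if all(end <= s or start >= e for s, e in forbidden[chrom]):
                forbidden[chrom].append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise PackingError("cannot redraw region without overlap")
    return out


def draw_landscapes(
    genome: AnnotatedGenome, cfg: LineageConfig
) -> dict[str, MethylationLandscape]:
    """Draw the four condition x passage methylation landscapes.

    control-P1 is the base landscape (all planted regions methylated).
    dex-P1 demethylates ``hypo_fraction`` of them — preferentially
    promoter-overlapping ones, weighted by ``hypo_promoter_bias`` — and
    gains ``gain_fraction`` new methylated regions at fresh positions.
    Each D3 landscape retains each parental methylated region
    independently with its lineage's retention probability and redraws
    the rest at random positions that avoid the parental set.
    """
    rng = np.random.default_rng([cfg.seed, STREAM_LANDSCAPES])
    widths = np.full(cfg.n_regions, cfg.region_width)
    base = _place_nonoverlapping(rng, genome.chromosomes, widths, cfg.region_min_gap)
    base = base.sort_values(["chrom", "start"]).reset_index(drop=True)
    base["region_id"] = [f"r{i + 1:05d}" for i in range(len(base))]
    base["level"] = rng.uniform(*cfg.level_range, len(base))
    base["methylated"] = True

    promoters = _promoter_windows(genome, cfg.promoter_def)
    at_promoter = np.array(
        [_overlaps_any(r.chrom, r.start, r.end, promoters) for r in base.itertuples()]
    )

    control_p1 = base.copy()

    # Dex demethylation, promoter-biased
    n_hypo = int(round(cfg.hypo_fraction * len(base)))
    weights = np.where(at_promoter, cfg.hypo_promoter_bias, 1.0)
    dex_p1 = base.copy()
    if n_hypo > 0:
        hypo_idx = rng.choice(len(base), size=n_hypo, replace=False, p=weights / weights.sum())
        dex_p1.loc[hypo_idx, "methylated"] = False
        dex_p1.loc[hypo_idx, "level"] = 0.0

    # Dex-specific gains at fresh positions
    n_gain = int(round(cfg.gain_fraction * len(base)))
    occupied = {c: [] for c, _ in genome.chromosomes}
    for r in base.itertuples():
        occupied[r.chrom].append((r.start, r.end))
    if n_gain > 0:
        gains = _redraw_regions(rng, n_gain, genome, cfg.region_width, occupied)
        gain_df = pd.DataFrame(gains, columns=["chrom", "start", "end"])
        gain_df["region_id"] = [f"g{i + 1:05d}" for i in range(len(gain_df))]
        gain_df["level"] = rng.uniform(*cfg.level_range, len(gain_df))
        gain_df["methylated"] = True
        dex_p1 = pd.concat([dex_p1, gain_df], ignore_index=True)

    def _daughter(parent: pd.DataFrame, retention: float, prefix: str) -> pd.DataFrame:
        meth = parent[parent["methylated"]].reset_index(drop=True)
        keep = rng.random(len(meth)) < retention
        retained = meth[keep].copy()
        retained["retained"] = True
        n_new = int((~keep).sum())
        forbidden = {c: [] for c, _ in genome.chromosomes}
        for r in meth.itertuples():
            forbidden[r.chrom].append((r.start, r.end))
        rows = _redraw_regions(rng, n_new, genome, cfg.region_width, forbidden)
        fresh = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        fresh["region_id"] = [f"{prefix}{i + 1:05d}" for i in range(len(fresh))]
        fresh["level"] = meth.loc[~keep, "level"].to_numpy()
        fresh["methylated"] = True
        fresh["retained"] = False
        return pd.concat([retained, fresh], ignore_index=True)

    control_d3 = _daughter(control_p1, cfg.retention_control, "nc")
    dex_d3 = _daughter(dex_p1, cfg.retention_dex, "nd")

    def _mk(df: pd.DataFrame, condition: str, stage: str) -> MethylationLandscape:
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        return MethylationLandscape(
            sample_id=f"{condition}_{stage}", condition=condition, stage=stage, regions=df
        )

    return {
        "control_P1": _mk(control_p1, "control", "P1"),
        "dex_P1": _mk(dex_p1, "dex", "P1"),
        "control_D3": _mk(control_d3, "control", "D3"),
        "dex_D3": _mk(dex_d3, "dex", "D3"),
    }


def build_truth_table(landscapes: Mapping[str, MethylationLandscape]) -> pd.DataFrame:
    """Flatten all planted regions into one table with sample flags."""
    frames = []
    for name in SAMPLE_ORDER:
        if name not in landscapes:
            continue
        ls = landscapes[name]
        df = ls.regions.copy()
        df.insert(0, "sample", ls.sample_id)
        df.insert(1, "condition", ls.condition)
        df.insert(2, "stage", ls.stage)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if "retained" in out.columns:
        out["retained"] = out["retained"].astype("boolean")
    return out


# ---------------------------------------------------------------------------
# sequencing libraries


def capture_probability(level: np.ndarray, cfg: LineageConfig) -> np.ndarray:
    """Per-fragment capture probability.

    Linear in the methylation level of the overlapped region, truncated
    at 1 (p = min(1, base_rate * enrichment * level)); fragments over
    unmethylated ground are captured at the base rate, modelling
    non-specific carry-over into the bound fraction.
    """
    return np.minimum(
        1.0, cfg.base_capture_rate * np.maximum(1.0, cfg.enrichment * np.asarray(level))
    )


def _sample_stream_index(sample_id: str) -> int:
    try:
        return SAMPLE_ORDER.index(sample_id)
    except ValueError:
        return 4 + zlib.crc32(sample_id.encode()) % 2**16


def simulate_mbd_library(
    landscape: MethylationLandscape,
    genome: AnnotatedGenome,
    cfg: LineageConfig,
) -> pd.DataFrame:
    """Simulate one sample's capture experiment.

    Fragment start positions are uniform over the genome; each fragment
    is assigned to the captured fraction with probability given by
    :func:`capture_probability` at its midpoint, otherwise to the
    supernatant, so captured + supernatant read counts always equal
    ``cfg.depth``.  Returns an aligned-read DataFrame (no sequence).
    """
    rng = np.random.default_rng(
        [cfg.seed, STREAM_LIBRARY, _sample_stream_index(landscape.sample_id)]
    )
    frag = cfg.fragment_length
    chroms = [(c, length) for c, length in genome.chromosomes]
    if any(length < frag for _, length in chroms):
        raise ValueError("fragment_length exceeds a chromosome length")
    lengths = np.array([length - frag + 1 for _, length in chroms], dtype=float)
    counts = rng.multinomial(cfg.depth, lengths / lengths.sum())

    meth = landscape.methylated_regions
    parts = []
    for (chrom, _clen), k in zip(chroms, counts):
        if k == 0:
            continue
        starts = rng.integers(0, int(lengths[chroms.index((chrom, _clen))]), k)
        mids = starts + frag // 2
        sub = meth[meth["chrom"] == chrom] if len(meth) else meth
        level = np.zeros(k)
        if len(sub):
            rs = sub["start"].to_numpy()
            re_ = sub["end"].to_numpy()
            lv = sub["level"].to_numpy()
            idx = np.searchsorted(rs, mids, side="right") - 1
            inside = (idx >= 0) & (mids < re_[np.clip(idx, 0, len(re_) - 1)])
            level[inside] = lv[idx[inside]]
        p = capture_probability(level, cfg)
        captured = rng.random(k) < p
        strand = pd.Categorical.from_codes(
            (rng.random(k) < 0.5).astype(np.int8), categories=["+", "-"]
        )
        fraction = pd.Categorical.from_codes(
            captured.astype(np.int8), categories=[SUPERNATANT, CAPTURED]
        )
        parts.append(
            (
                chrom,
                pd.DataFrame(
                    {
                        "start": starts,
                        "end": starts + frag,
                        "strand": strand,
                        "fraction": fraction,
                    }
                ),
            )
        )
    reads = pd.concat([df for _, df in parts], ignore_index=True)
    chrom_names = [c for c, _ in parts]
    codes = np.repeat(
        np.arange(len(parts), dtype=np.int8), [len(df) for _, df in parts]
    )
    reads.insert(
        0, "chrom", pd.Categorical.from_codes(codes, categories=chrom_names)
    )
    return reads


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr(
    design: Mapping[str, Mapping[str, float]],
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_gene: str = "Hprt",
    baseline_ct: float = 25.0,
    reference_baseline_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulate a Ct table for a fold-change design.

    ``design`` maps gene -> group -> expression fold relative to the
    unit-fold baseline.  Ct = baseline - log2(fold) + N(0, noise_sd); the
    housekeeping reference gene is measured for every sample with fold
    fixed at 1 (unaffected by group).
    """
    if replicates < 3:
        raise ValueError("at least 3 replicates are required")
    groups: list[str] = []
    for gene, per_group in design.items():
        for group, fold in per_group.items():
            if fold <= 0:
                raise ValueError(f"fold for {gene}/{group} must be positive")
            if group not in groups:
                groups.append(group)
    rng = np.random.default_rng([seed, STREAM_QPCR])
    rows = []
    for group in groups:
        for rep in range(1, replicates + 1):
            sample = f"{group}_r{rep}"
            rows.append(
                (
                    sample,
                    group,
                    reference_gene,
                    rep,
                    reference_baseline_ct + rng.normal(0.0, noise_sd),
                )
            )
            for gene, per_group in design.items():
                if gene == reference_gene:
                    continue
                fold = per_group.get(group, 1.0)
                rows.append(
                    (
                        sample,
                        group,
                        gene,
                        rep,
                        baseline_ct - np.log2(fold) + rng.normal(0.0, noise_sd),
                    )
                )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
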