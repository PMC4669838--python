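"""Core domain types shared by all analysis modules.

Coordinates are 0-based, half-open throughout (BED convention).  Bulk
read data travels as pandas DataFrames with the column schema of
:data:`READ_COLUMNS`; small structured objects (peaks, gene models,
genomes) are frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Column schema for aligned-read DataFrames (BED6-equivalent).
READ_COLUMNS = ("chrom", "start", "end", "strand", "fraction")

#: Library fractions of an MBD capture experiment.
CAPTURED = "captured"
SUPERNATANT = "supernatant"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class Peak(GenomicInterval):
    """Called methylation peak.

    ``score`` is the -log10 enrichment p-value of the captured fraction
    over the background expectation; ``fold_enrichment`` the ratio of
    observed to expected reads; ``n_reads`` the deduplicated captured
    reads supporting the peak.
    """

    score: float = 0.0
    fold_enrichment: float = 0.0
    n_reads: int = 0

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class OverlapRule:
    """Criterion deciding when two intervals count as overlapping.

    ``min_bp`` is the minimum absolute overlap (default: any overlap).
    ``min_frac``, if set, additionally requires reciprocal overlap of at
    least that fraction of *both* interval lengths.  Tightening either
    knob can only remove qualifying pairs.
    """

    min_bp: int = 1
    min_frac: float | None = None

    def __post_init__(self) -> None:
        if self.min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        if self.min_frac is not None and not 0.0 < self.min_frac <= 1.0:
            raise ValueError("min_frac must be in (0, 1]")

    def matches(self, a: GenomicInterval, b: GenomicInterval) -> bool:
        ov = a.overlap_bp(b)
        if ov < self.min_bp:
            return False
        if self.min_frac is not None:
            if ov < self.min_frac * a.length or ov < self.min_frac * b.length:
                return False
        return True


@dataclass(frozen=True)
class GeneModel:
    """refFlat-style transcript model (0-based, half-open blocks)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.name}: tx_start must be < tx_end")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.name}: cds bounds outside transcript")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.name}: need >= 1 exon block")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.name}: exon block outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: exon blocks unsorted/overlapping")
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


@dataclass(frozen=True)
class AnnotatedGenome:
    """Chromosomes plus gene models and CpG islands: the coordinate universe."""

    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneModel, ...]
    cgis: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        sizes = self.chrom_sizes
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for g in self.genes:
            if g.chrom not in sizes or g.tx_end > sizes[g.chrom]:
                raise ValueError(f"gene {g.name} outside chromosome bounds")
        for c in self.cgis:
            if c.chrom not in sizes or c.end > sizes[c.chrom]:
                raise ValueError(f"CGI {c.chrom}:{c.start}-{c.end} outside bounds")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass(frozen=True)
class MethylationLandscape:
    """Per-sample methylation ground truth at region granularity.

    ``regions`` is a DataFrame with columns ``chrom, start, end,
    methylated, level`` (level is the methylated fraction in [0, 1] and
    is 0 wherever ``methylated`` is False).  Regions are non-overlapping
    within a sample.
    """

    sample_id: str
    condition: str  # "control" | "dex"
    stage: str  # "P1" | "D3"
    regions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.condition not in ("control", "dex"):
            raise ValueError("condition must be 'control' or 'dex'")
        if self.stage not in ("P1", "D3"):
            raise ValueError("stage must be 'P1' or 'D3'")
        r = self.regions
        missing = {"chrom", "start", "end", "methylated", "level"} - set(r.columns)
        if missing:
            raise ValueError(f"landscape missing columns: {sorted(missing)}")
        if ((~r["methylated"]) & (r["level"] != 0)).any():
            raise ValueError("level must be 0 where methylated is False")
        for chrom, sub in r.sort_values(["chrom", "start"]).groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping regions on {chrom}")

    @property
    def methylated_regions(self) -> pd.DataFrame:
        return self.regions[self.regions["methylated"]].reset_index(drop=True)


@dataclass
class CoverageTrack:
    """Binned read counts over one chromosome."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Tabulate a peak list (BED6+2 column order)."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [f"peak_{i + 1}" for i in range(len(peaks))],
            "score": [p.score for p in peaks],
            "strand": ["." for _ in peaks],
            "fold_enrichment": [p.fold_enrichment for p in peaks],
            "n_reads": [p.n_reads for p in peaks],
        }
    )


def validate_nonoverlapping(intervals: Sequence[GenomicInterval], what: str = "peaks") -> None:
    """Raise if any two intervals in the set overlap (per chromosome)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda i: (i.start, i.end))
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"{what} overlap within one set on {chrom}: "
                    f"{prev.start}-{prev.end} vs {cur.start}-{cur.end}"
                )
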