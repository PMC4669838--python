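"""Read deduplication, coverage binning, and Poisson peak calling.

The caller tests each bin of the captured-fraction coverage against a
Poisson expectation derived from the matched supernatant background:
lambda_bin = max(scaled background count, genome-wide captured rate),
with the background scaled to the captured library size.  Significant
bins are merged (allowing small gaps) and short candidates discarded.
This is a deliberately simple, fully specified stand-in for a
model-based caller: the analyses downstream (DMR partition,
preservation) operate on peak sets and do not depend on caller
internals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .core import CoverageTrack, Peak

logger = logging.getLogger(__name__)

_MIN_P = 1e-300  # floor before taking -log10


@dataclass(frozen=True)
class PeakCallParams:
    """Caller parameters; defaults follow common MACS-era conventions
    for ~200 bp fragments."""

    bin_size: int = 200
    p_threshold: float = 1e-5
    min_width: int = 400
    merge_gap: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.min_width <= 0:
            raise ValueError("bin_size and min_width must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def deduplicate_reads(reads: pd.DataFrame, by_strand: bool = True) -> pd.DataFrame:
    """Collapse PCR duplicates: keep one read per chromosomal position.

    The key is (chrom, start) plus strand when ``by_strand`` (the
    stricter reading of one-read-per-position, and the default).  Reads
    are sorted by coordinate first, so retention is order-independent,
    and the operation is idempotent.
    """
    key = ["chrom", "start"] + (["strand"] if by_strand else [])
    out = reads.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    return out.drop_duplicates(subset=key, keep="first").reset_index(drop=True)


def compute_coverage(
    reads: pd.DataFrame, chrom_sizes: Mapping[str, int], bin_size: int
) -> dict[str, CoverageTrack]:
    """Bin reads by fragment midpoint into fixed-width bins.

    Every read lands in exactly one bin, so per-chromosome bin sums
    conserve read counts.  A read outside its chromosome bounds (or on
    an unknown chromosome) raises an error naming the read.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    tracks = {
        chrom: CoverageTrack(
            chrom, bin_size, np.zeros(math.ceil(size / bin_size), dtype=np.int64)
        )
        for chrom, size in chrom_sizes.items()
    }
    if len(reads) == 0:
        return tracks
    for chrom, sub in reads.groupby("chrom", sort=False, observed=True):
        if chrom not in chrom_sizes:
            row = sub.iloc[0]
            raise ValueError(
                f"read {chrom}:{row['start']}-{row['end']} on unknown chromosome"
            )
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = (starts < 0) | (ends > chrom_sizes[chrom])
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"read {chrom}:{starts[i]}-{ends[i]} outside chromosome "
                f"(length {chrom_sizes[chrom]})"
            )
        mids = (starts + ends) // 2
        binned = np.bincount(mids // bin_size, minlength=tracks[chrom].n_bins)
        tracks[chrom].counts += binned.astype(np.int64)
    return tracks


def _merge_significant_bins(
    sig_idx: np.ndarray, gap_bins: int
) -> list[tuple[int, int]]:
    """Group significant bin indices into runs separated by > gap_bins."""
    if len(sig_idx) == 0:
        return []
    runs = []
    run_start = prev = int(sig_idx[0])
    for i in sig_idx[1:]:
        i = int(i)
        if i - prev - 1 > gap_bins:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    return runs


def call_peaks(
    captured: Mapping[str, CoverageTrack],
    background: Mapping[str, CoverageTrack] | None,
    params: PeakCallParams = PeakCallParams(),
) -> list[Peak]:
    """Call enriched peaks in the captured fraction against background.

    When ``background`` is None the uniform genome-wide captured rate
    serves as the expectation everywhere (input-free calling).  Every
    emitted peak satisfies the peak-level Poisson test at
    ``params.p_threshold`` recomputed over its full span.
    """
    if background is not None:
        if set(background) != set(captured):
            raise ValueError("captured and background tracks cover different chromosomes")
        for chrom in captured:
            if captured[chrom].bin_size != background[chrom].bin_size:
                raise ValueError(f"bin size mismatch on {chrom}")
            if captured[chrom].n_bins != background[chrom].n_bins:
                raise ValueError(f"bin count mismatch on {chrom}")

    cap_total = sum(t.total for t in captured.values())
    bg_total = sum(t.total for t in background.values()) if background else 0
    n_bins = sum(t.n_bins for t in captured.values())
    if n_bins == 0:
        return []
    if cap_total == 0:
        logger.warning("no captured reads: returning empty peak list")
        return []
    genome_rate = cap_total / n_bins
    scale = cap_total / bg_total if bg_total > 0 else 0.0

    gap_bins = params.merge_gap // params.bin_size if params.bin_size else 0
    peaks: list[Peak] = []
    for chrom in sorted(captured):
        track = captured[chrom]
        k = track.counts
        if background is not None and bg_total > 0:
            lam = np.maximum(background[chrom].counts * scale, genome_rate)
        else:
            lam = np.full(track.n_bins, genome_rate)
        pvals = poisson.sf(k - 1, lam)
        sig_idx = np.flatnonzero(pvals <= params.p_threshold)
        for b0, b1 in _merge_significant_bins(sig_idx, gap_bins):
            start = b0 * params.bin_size
            end = (b1 + 1) * params.bin_size
            if end - start < params.min_width:
                continue
            k_sum = int(k[b0 : b1 + 1].sum())
            lam_sum = float(lam[b0 : b1 + 1].sum())
            p_peak = float(poisson.sf(k_sum - 1, lam_sum))
            if p_peak > params.p_threshold:
                continue
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    score=-math.log10(max(p_peak, _MIN_P)),
                    fold_enrichment=k_sum / lam_sum if lam_sum > 0 else float("inf"),
                    n_reads=k_sum,
                )
            )
    return peaks
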