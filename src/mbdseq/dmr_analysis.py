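"""DMR partition, chromosome summaries, cross-passage preservation, and
the chi-square test of proportions.

A DMR here is purely set-theoretic: a peak present in one condition's
peak set and absent (under the overlap rule) from the other's.  Peaks
shared between conditions are merged into common intervals and counted
once per overlapping cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import GenomicInterval, OverlapRule, Peak, validate_nonoverlapping


@dataclass(frozen=True)
class DmrPartition:
    """Two-condition peak partition: unique to each side plus merged
    common intervals.  Accounting invariant: every input peak is either
    unique or contributes to exactly one common interval."""

    unique_a: tuple[Peak, ...]
    unique_b: tuple[Peak, ...]
    common: tuple[GenomicInterval, ...]
    labels: tuple[str, str]
    n_a_in_common: int
    n_b_in_common: int

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"unique_{self.labels[0]}": len(self.unique_a),
            f"unique_{self.labels[1]}": len(self.unique_b),
            "common": len(self.common),
        }


@dataclass(frozen=True)
class PreservationResult:
    """Fraction of parental (P1) peaks overlapped by a daughter (D3) peak."""

    n_p1: int
    n_preserved: int
    comparison: tuple[float, float] | None = None  # (chi-square, p) vs another lineage

    @property
    def fraction(self) -> float:
        return self.n_preserved / self.n_p1


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def partition_peaks(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    rule: OverlapRule = OverlapRule(),
    labels: tuple[str, str] = ("a", "b"),
) -> DmrPartition:
    """Partition two peak sets into unique-to-a, unique-to-b, and common.

    Peaks are "shared" when they satisfy the overlap rule (default: any
    overlap of >= 1 bp).  Shared peaks are clustered by connectivity of
    the overlap graph and each cluster is reported as one merged common
    interval — the hull of its members.
    """
    validate_nonoverlapping(peaks_a, f"{labels[0]} peaks")
    validate_nonoverlapping(peaks_b, f"{labels[1]} peaks")

    tagged: list[tuple[Peak, int]] = [(p, 0) for p in peaks_a] + [(p, 1) for p in peaks_b]
    uf = _UnionFind(len(tagged))
    order = sorted(range(len(tagged)), key=lambda i: (tagged[i][0].chrom, tagged[i][0].start))
    # sweep: compare each peak to following peaks until starts pass its end
    for oi, i in enumerate(order):
        pi, _ = tagged[i]
        for j in order[oi + 1 :]:
            pj, _ = tagged[j]
            if pj.chrom != pi.chrom or pj.start >= pi.end:
                break
            if tagged[i][1] != tagged[j][1] and rule.matches(pi, pj):
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(tagged)):
        clusters.setdefault(uf.find(i), []).append(i)

    unique_a: list[Peak] = []
    unique_b: list[Peak] = []
    common: list[GenomicInterval] = []
    n_a_common = n_b_common = 0
    for members in clusters.values():
        sides = {tagged[i][1] for i in members}
        if sides == {0, 1}:
            ivs = [tagged[i][0] for i in members]
            common.append(
                GenomicInterval(
                    ivs[0].chrom, min(p.start for p in ivs), max(p.end for p in ivs)
                )
            )
            n_a_common += sum(1 for i in members if tagged[i][1] == 0)
            n_b_common += sum(1 for i in members if tagged[i][1] == 1)
        elif sides == {0}:
            unique_a.extend(tagged[i][0] for i in members)
        else:
            unique_b.extend(tagged[i][0] for i in members)

    assert len(unique_a) + n_a_common == len(peaks_a), "partition accounting failed (a)"
    assert len(unique_b) + n_b_common == len(peaks_b), "partition accounting failed (b)"
    return DmrPartition(
        unique_a=tuple(sorted(unique_a)),
        unique_b=tuple(sorted(unique_b)),
        common=tuple(sorted(common)),
        labels=labels,
        n_a_in_common=n_a_common,
        n_b_in_common=n_b_common,
    )


def chromosome_distribution(
    peaks: Sequence[GenomicInterval], chromosomes: Sequence[str] | None = None
) -> pd.Series:
    """Peak counts per chromosome (zero-count chromosomes included when
    the chromosome universe is given)."""
    counts: dict[str, int] = {c: 0 for c in (chromosomes or [])}
    for p in peaks:
        counts[p.chrom] = counts.get(p.chrom, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def preservation(
    peaks_p1: Sequence[Peak],
    peaks_d3: Sequence[Peak],
    rule: OverlapRule = OverlapRule(),
) -> PreservationResult:
    """Count parental peaks overlapped by at least one daughter peak."""
    validate_nonoverlapping(peaks_p1, "P1 peaks")
    validate_nonoverlapping(peaks_d3, "D3 peaks")
    if len(peaks_p1) == 0:
        raise ValueError("empty P1 peak set: preservation fraction undefined")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks_d3:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.start)
    n_preserved = 0
    for p in peaks_p1:
        cands = by_chrom.get(p.chrom, [])
        starts = [c.start for c in cands]
        lo = np.searchsorted(starts, p.start) if cands else 0
        # step back to catch a candidate starting before p but overlapping it
        i = max(0, int(lo) - 1)
        while i < len(cands) and cands[i].start < p.end:
            if rule.matches(p, cands[i]):
                n_preserved += 1
                break
            i += 1
    return PreservationResult(n_p1=len(peaks_p1), n_preserved=n_preserved)


def compare_preservation(
    a: PreservationResult, b: PreservationResult
) -> PreservationResult:
    """Attach a chi-square comparison of two lineages' preservation
    proportions to the first result."""
    stat, p = chi_square_proportions(a.n_preserved, a.n_p1, b.n_preserved, b.n_p1)
    return PreservationResult(a.n_p1, a.n_preserved, comparison=(stat, p))


def chi_square_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Pearson chi-square for two proportions (2x2 table, 1 df, no
    continuity correction).

    Equals n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the table
    [[k1, n1-k1], [k2, n2-k2]].  Any zero margin makes the statistic
    undefined and raises.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(chi2.sf(stat, df=1))


def global_methylated_fraction(
    peaks: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> float:
    """Fraction of the genome covered by (non-overlapping) peaks — a
    coarse proxy for global 5-mC level."""
    validate_nonoverlapping(peaks)
    total = sum(chrom_sizes.values())
    if total <= 0:
        raise ValueError("genome length must be positive")
    return sum(p.length for p in peaks) / total
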