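"""Replicate consensus, gained/lost/common classification and cross-assay
overlap.

Classification is set-based: intervals from the two conditions are
clustered by overlap (book-ended counts as overlapping) and each cluster
becomes one peak labeled common / gained (condition-2-only) / lost
(condition-1-only). The 100-bp proximity tolerance applies only to the
cross-assay pairing, not to classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from peakscape.core import (
    GenomicInterval,
    IntervalIndex,
    Peak,
    merge_overlapping,
)
from peakscape.motifs import bh_adjust


@dataclass
class ConsensusPeakSet:
    """Replicate-consensus peaks for one condition and assay."""

    condition: str
    assay: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sorted(set(self.peaks), key=lambda p: (p.chrom, p.start))


@dataclass
class CrossAssayMatrix:
    """Counts of query-class peaks by the class of their nearest subject
    peak within the gap tolerance ('none' when no subject qualifies)."""

    counts: dict[str, dict[str, int]]
    direction: str  # e.g. "ATAC->H3K27ac": query assay -> subject assay

    def row_fractions(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for qcls, row in self.counts.items():
            total = sum(row.values())
            out[qcls] = {
                k: (v / total if total else 0.0) for k, v in row.items()
            }
        return out


def consensus_replicates(
    rep1: Sequence[GenomicInterval],
    rep2: Sequence[GenomicInterval],
    condition: str = "",
    assay: str = "H3K27ac",
) -> ConsensusPeakSet:
    """Keep peaks supported by both replicates, merged to union intervals.

    A peak is retained iff it overlaps (distance 0, book-ended included) a
    peak in the other replicate; overlapping retained spans are coalesced.
    """
    index2 = IntervalIndex(rep2) if rep2 else None
    unions: list[GenomicInterval] = []
    if index2 is not None:
        for iv in rep1:
            hit = index2.nearest(iv, 0)
            if hit is not None:
                mate = hit[0]
                unions.append(
                    GenomicInterval(
                        iv.chrom, min(iv.start, mate.start), max(iv.end, mate.end)
                    )
                )
    # symmetric pass so rep2 peaks spanned by several rep1 peaks contribute
    index1 = IntervalIndex(rep1) if rep1 else None
    if index1 is not None:
        for iv in rep2:
            hit = index1.nearest(iv, 0)
            if hit is not None:
                mate = hit[0]
                unions.append(
                    GenomicInterval(
                        iv.chrom, min(iv.start, mate.start), max(iv.end, mate.end)
                    )
                )
    merged = merge_overlapping(unions) if unions else []
    return ConsensusPeakSet(condition, assay, merged)


def classify_peak_dynamics(
    set_a: ConsensusPeakSet, set_b: ConsensusPeakSet
) -> list[Peak]:
    """Classify peaks between condition 1 (set_a) and condition 2 (set_b).

    Overlap clusters spanning both conditions become 'common' (union
    interval); clusters only in set_b are 'gained'; only in set_a, 'lost'.
    The class counts sum to the merged union peak count.
    """
    if set_a.assay != set_b.assay:
        raise ValueError(
            f"assay mismatch: {set_a.assay!r} vs {set_b.assay!r}"
        )
    tagged: list[tuple[GenomicInterval, str]] = [
        (iv, "a") for iv in set_a.peaks
    ] + [(iv, "b") for iv in set_b.peaks]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))

    peaks: list[Peak] = []
    cluster: list[tuple[GenomicInterval, str]] = []

    def flush() -> None:
        if not cluster:
            return
        sources = {src for _, src in cluster}
        dynamics = (
            "common" if sources == {"a", "b"}
            else ("gained" if sources == {"b"} else "lost")
        )
        span = GenomicInterval(
            cluster[0][0].chrom,
            min(iv.start for iv, _ in cluster),
            max(iv.end for iv, _ in cluster),
        )
        peaks.append(Peak(span, assay=set_a.assay, dynamics=dynamics))

    cur_chrom, cur_end = None, -1
    for iv, src in tagged:
        if iv.chrom != cur_chrom or iv.start > cur_end:
            flush()
            cluster = []
            cur_chrom, cur_end = iv.chrom, iv.end
        cluster.append((iv, src))
        cur_end = max(cur_end, iv.end)
    flush()

    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    counters = {"gained": 0, "lost": 0, "common": 0}
    named: list[Peak] = []
    for p in peaks:
        counters[p.dynamics] += 1
        iv = replace(
            p.interval, name=f"{p.dynamics}_{counters[p.dynamics]:05d}"
        )
        named.append(Peak(iv, assay=p.assay, dynamics=p.dynamics))
    return named


def differential_occupancy_test(
    counts1: Sequence[int],
    counts2: Sequence[int],
    libsize1: int,
    libsize2: int,
) -> tuple[list[float], list[float]]:
    """Per-peak two-sided exact binomial test of condition-2 counts.

    For each peak, x2 successes in x1+x2 trials against
    p0 = libsize2/(libsize1+libsize2); zero-total peaks get p = 1.
    Returns (p-values, BH-adjusted FDRs) in input order.
    """
    if len(counts1) != len(counts2):
        raise ValueError("count vectors differ in length")
    if libsize1 <= 0 or libsize2 <= 0:
        raise ValueError("library sizes must be positive")
    p0 = libsize2 / (libsize1 + libsize2)
    pvals: list[float] = []
    for x1, x2 in zip(counts1, counts2):
        if x1 < 0 or x2 < 0:
            raise ValueError("counts must be non-negative")
        n = x1 + x2
        if n == 0:
            pvals.append(1.0)
        else:
            pvals.append(
                float(binomtest(x2, n, p0, alternative="two-sided").pvalue)
            )
    return pvals, bh_adjust(pvals)


def cross_assay_matrix(
    query_peaks: Sequence[Peak],
    subject_peaks: Sequence[Peak],
    max_gap: int = 100,
    direction: str = "ATAC->H3K27ac",
) -> CrossAssayMatrix:
    """Tabulate query peaks by the class of the nearest subject peak
    within ``max_gap`` bp (column 'none' when no subject qualifies)."""
    subject_class = [p.dynamics for p in subject_peaks]
    indexed = [
        replace(p.interval, name=str(i)) for i, p in enumerate(subject_peaks)
    ]
    index = IntervalIndex(indexed) if indexed else None
    classes = ("gained", "lost", "common")
    counts: dict[str, dict[str, int]] = {
        q: {s: 0 for s in (*classes, "none")} for q in classes
    }
    for peak in query_peaks:
        qcls = peak.dynamics
        if qcls not in counts:
            counts[qcls] = {s: 0 for s in (*classes, "none")}
        hit = index.nearest(peak.interval, max_gap) if index else None
        if hit is None:
            counts[qcls]["none"] += 1
        else:
            counts[qcls][subject_class[int(hit[0].name)]] += 1
    return CrossAssayMatrix(counts=counts, direction=direction)
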