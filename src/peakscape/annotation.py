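"""Peak-to-feature annotation (promoter / TTS / exon / intron / intergenic).

A peak is assigned by its midpoint with priority
promoter > TTS > exon > intron > intergenic; within a feature level, ties
between genes are resolved by absolute TSS distance, then gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from peakscape.core import Gene, GenomicInterval

FEATURES = ("promoter", "TTS", "exon", "intron", "intergenic")
_PRIORITY = {f: i for i, f in enumerate(FEATURES)}


@dataclass(frozen=True)
class AnnotationResult:
    peak_id: str
    feature: str
    gene_id: str | None
    distance_to_tss: int | None  # signed, strand-aware; negative = upstream

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if (self.gene_id is None) != (self.feature == "intergenic"):
            raise ValueError("gene_id must be present iff feature != intergenic")


def _signed_tss_distance(midpoint: int, gene: Gene) -> int:
    d = midpoint - gene.tss
    return d if gene.strand == "+" else -d


def _gene_feature(
    midpoint: int,
    gene: Gene,
    promoter_window: tuple[int, int],
    tts_window: int,
) -> str | None:
    """Best (highest-priority) feature this gene offers for the midpoint."""
    upstream, downstream = promoter_window
    d = _signed_tss_distance(midpoint, gene)
    if -upstream <= d < downstream:
        return "promoter"
    if gene.tx_end is not None:
        if gene.tx_end - tts_window <= midpoint < gene.tx_end + tts_window:
            return "TTS"
        body_lo = min(gene.tss, gene.tx_end)
        body_hi = max(gene.tss, gene.tx_end)
        if body_lo <= midpoint < body_hi:
            if gene.exons and any(
                e.start <= midpoint < e.end for e in gene.exons
            ):
                return "exon"
            return "intron"
    return None


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[Gene],
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: int = 1000,
) -> AnnotationResult:
    """Annotate one peak against the gene model by its midpoint."""
    mid = peak.midpoint
    pid = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
    candidates: list[tuple[int, int, str, Gene, str]] = []
    nearest: tuple[int, str, Gene] | None = None
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        d = _signed_tss_distance(mid, gene)
        key = (abs(d), gene.gene_id)
        if nearest is None or key < (nearest[0], nearest[1]):
            nearest = (abs(d), gene.gene_id, gene)
        feature = _gene_feature(mid, gene, promoter_window, tts_window)
        if feature is not None:
            candidates.append(
                (_PRIORITY[feature], abs(d), gene.gene_id, gene, feature)
            )
    if candidates:
        candidates.sort(key=lambda c: c[:3])
        _, _, _, gene, feature = candidates[0]
        return AnnotationResult(
            pid, feature, gene.gene_id, _signed_tss_distance(mid, gene)
        )
    distance = (
        _signed_tss_distance(mid, nearest[2]) if nearest is not None else None
    )
    return AnnotationResult(pid, "intergenic", None, distance)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[Gene],
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: int = 1000,
) -> list[AnnotationResult]:
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        annotate_peak(
            p, by_chrom.get(p.chrom, []), promoter_window, tts_window
        )
        for p in peaks
    ]


def annotation_summary(
    results: Sequence[AnnotationResult],
    classes: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Per-dynamics-class fractions over the five feature levels.

    Fractions per non-empty class sum to 1; classes present in ``classes``
    but with no annotated peaks get an all-zero row.
    """
    counts: dict[str, dict[str, int]] = {
        cls: {f: 0 for f in FEATURES} for cls in sorted(set(classes.values()))
    }
    for res in results:
        cls = classes.get(res.peak_id)
        if cls is None:
            raise ValueError(f"peak {res.peak_id!r} has no dynamics class")
        counts[cls][res.feature] += 1
    out: dict[str, dict[str, float]] = {}
    for cls, row in counts.items():
        total = sum(row.values())
        out[cls] = {
            f: (row[f] / total if total else 0.0) for f in FEATURES
        }
    return out
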