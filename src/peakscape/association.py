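"""Regulatory-domain construction and peak-gene association statistics.

Each gene gets a strand-oriented basal window around its TSS, extended
outward up to a maximum range or until a neighboring gene's basal region,
whichever comes first. Peaks associate with every gene whose domain
contains the peak midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import t as t_dist

from peakscape.core import Gene, GenomicInterval, Peak

DE_DIRECTIONS = ("up", "down", "ns")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    domain: GenomicInterval
    basal: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.domain.start <= self.basal.start
            and self.basal.end <= self.domain.end
        ):
            raise ValueError(f"{self.gene_id}: basal not contained in domain")


@dataclass(frozen=True)
class DERecord:
    """Differential-expression call for one gene."""

    gene_id: str
    log2fc: float
    fdr: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DE_DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr out of [0,1]: {self.fdr}")


def make_de_record(
    gene_id: str, log2fc: float, fdr: float, fdr_threshold: float = 0.05
) -> DERecord:
    if fdr < fdr_threshold and log2fc > 0:
        direction = "up"
    elif fdr < fdr_threshold and log2fc < 0:
        direction = "down"
    else:
        direction = "ns"
    return DERecord(gene_id, log2fc, fdr, direction)


def read_de_table(
    path: str | Path, fdr_threshold: float = 0.05
) -> list[DERecord]:
    """Read TSV with header gene_id, log2fc, fdr; directions derived."""
    records = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for name in ("gene_id", "log2fc", "fdr"):
            if name not in col:
                raise ValueError(f"{path}: missing column {name!r}")
        for raw in fh:
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            records.append(
                make_de_record(
                    fields[col["gene_id"]],
                    float(fields[col["log2fc"]]),
                    float(fields[col["fdr"]]),
                    fdr_threshold,
                )
            )
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tlog2fc\tfdr\tdirection\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.fdr:.6g}\t{r.direction}\n")


# ---------------------------------------------------------------------------
# regulatory domains
# ---------------------------------------------------------------------------

def basal_region(
    gene: Gene, basal_up: int, basal_down: int, chrom_length: int
) -> GenomicInterval:
    if gene.strand == "+":
        start, end = gene.tss - basal_up, gene.tss + basal_down
    else:
        start, end = gene.tss - basal_down, gene.tss + basal_up
    return GenomicInterval(
        gene.chrom, max(0, start), min(chrom_length, max(end, 1))
    )


def build_regulatory_domains(
    genes: Sequence[Gene],
    chrom_lengths: Mapping[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension domains, one per gene.

    The domain extends from the basal region outward until the nearest of:
    a neighboring gene's basal edge, TSS +/- max_ext, or the chromosome
    edge. A gene's own basal region is never truncated, even when neighbor
    basal regions overlap it.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        clen = chrom_lengths[g.chrom]
        if not (0 <= g.tss < clen):
            raise ValueError(f"{g.gene_id}: TSS outside chromosome")
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for chrom, chrom_genes in by_chrom.items():
        clen = chrom_lengths[chrom]
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.tss, g.gene_id))
        basals = [
            basal_region(g, basal_up, basal_down, clen) for g in chrom_genes
        ]
        for i, gene in enumerate(chrom_genes):
            own = basals[i]
            left_stops = [max(0, gene.tss - max_ext)]
            right_stops = [min(clen, gene.tss + max_ext)]
            for j, other in enumerate(chrom_genes):
                if j == i:
                    continue
                if basals[j].end <= gene.tss:
                    left_stops.append(basals[j].end)
                if basals[j].start >= gene.tss:
                    right_stops.append(basals[j].start)
            start = min(own.start, max(left_stops))
            end = max(own.end, min(right_stops))
            domains.append(
                RegulatoryDomain(
                    gene.gene_id,
                    chrom,
                    GenomicInterval(chrom, start, end, name=gene.gene_id),
                    own,
                )
            )
    domains.sort(key=lambda d: (d.chrom, d.domain.start, d.gene_id))
    return domains


def write_domains_bed(
    domains: Iterable[RegulatoryDomain], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for d in domains:
            fh.write(
                f"{d.chrom}\t{d.domain.start}\t{d.domain.end}\t{d.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """peak -> genes and gene -> per-dynamics-class peak counts."""

    peak_to_genes: dict[str, set[str]]
    gene_peak_counts: dict[str, dict[str, int]]

    def count(self, gene_id: str, peak_class: str) -> int:
        return self.gene_peak_counts.get(gene_id, {}).get(peak_class, 0)


def associate_peaks_to_genes(
    peaks: Sequence[Peak], domains: Sequence[RegulatoryDomain]
) -> AssociationTable:
    """Associate each peak (by midpoint) with every domain containing it."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)

    peak_to_genes: dict[str, set[str]] = {}
    gene_peak_counts: dict[str, dict[str, int]] = {
        d.gene_id: {} for d in domains
    }
    for idx, peak in enumerate(peaks):
        pid = peak.interval.name or f"peak{idx}"
        mid = peak.interval.midpoint
        genes = {
            d.gene_id
            for d in by_chrom.get(peak.interval.chrom, [])
            if d.domain.start <= mid < d.domain.end
        }
        peak_to_genes[pid] = genes
        for gid in genes:
            counts = gene_peak_counts[gid]
            counts[peak.dynamics] = counts.get(peak.dynamics, 0) + 1
    return AssociationTable(peak_to_genes, gene_peak_counts)


def association_summary(
    table: AssociationTable,
    de: Sequence[DERecord],
    peak_classes: Sequence[str] = ("gained", "lost", "common"),
) -> dict[str, dict[str, dict[str, float | None]]]:
    """Cross-tab of DE direction x peak class.

    Per cell: percent of direction-group genes with >=1 associated peak of
    that class, and mean associated peaks per gene. Empty direction groups
    yield None cells.
    """
    out: dict[str, dict[str, dict[str, float | None]]] = {}
    for direction in ("up", "down"):
        genes = [r.gene_id for r in de if r.direction == direction]
        row: dict[str, dict[str, float | None]] = {}
        for cls in peak_classes:
            if not genes:
                row[cls] = {"percent": None, "mean_peaks": None, "n_genes": 0}
                continue
            counts = [table.count(g, cls) for g in genes]
            row[cls] = {
                "percent": 100.0 * sum(c > 0 for c in counts) / len(genes),
                "mean_peaks": float(np.mean(counts)),
                "n_genes": len(genes),
            }
        out[direction] = row
    return out


def peakcount_expression_correlation(
    table: AssociationTable,
    de: Sequence[DERecord],
    peak_class: str,
    directions: Sequence[str] = ("up", "down", "ns"),
) -> tuple[float, float]:
    """Pearson correlation between per-gene peak count and log2 fold change.

    Returns (r, two-sided p). Raises ValueError on < 3 genes or zero
    variance in either variable.
    """
    recs = [r for r in de if r.direction in directions]
    if len(recs) < 3:
        raise ValueError("need >= 3 genes with defined log2fc")
    x = np.array([table.count(r.gene_id, peak_class) for r in recs], float)
    y = np.array([r.log2fc for r in recs], float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in peak counts or log2fc")
    r = float((xc * yc).sum() / denom)
    n = len(recs)
    if abs(r) >= 1.0:
        return r, 0.0
    t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * t_dist.sf(abs(t_stat), n - 2))
    return r, p


def gene_set_overlap(
    a: set[str],
    b: set[str],
    ortholog_map: Mapping[str, set[str]] | None = None,
) -> dict[str, float | int]:
    """Overlap statistics between two gene-id sets.

    With an ortholog map, each b gene is translated into a's namespace
    (many-to-many; a b gene counts as mapped if any ortholog exists).
    Reports both |A∩B|/|A∪B| and |A∩B|/|A| percentages.
    """
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    unmapped = 0
    if ortholog_map is not None:
        mapped: set[str] = set()
        for gid in b:
            targets = ortholog_map.get(gid, set())
            if targets:
                mapped |= set(targets)
            else:
                unmapped += 1
        b_in_a = mapped
    else:
        b_in_a = set(b)
    inter = a & b_in_a
    union = a | b_in_a
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "percent_of_union": 100.0 * len(inter) / len(union),
        "percent_of_a": 100.0 * len(inter) / len(a),
        "n_unmapped_b": unmapped,
    }
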