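"""Interval data model, distance engine and file I/O.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Book-ended intervals have distance 0; "within K bp" means distance <= K.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DYNAMICS_CLASSES = ("gained", "lost", "common", "unassigned")
ASSAYS = ("H3K27ac", "ATAC")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A called peak with assay and dynamics provenance."""

    interval: GenomicInterval
    assay: str = "H3K27ac"
    dynamics: str = "unassigned"
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.dynamics not in DYNAMICS_CLASSES:
            raise ValueError(f"unknown dynamics class {self.dynamics!r}")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr out of [0,1]: {self.fdr}")

    @property
    def name(self) -> str | None:
        return self.interval.name


@dataclass
class Gene:
    """TSS-anchored gene record.

    ``tss`` is the transcription start (0-based), ``tx_end`` the far end of
    the transcript regardless of strand (tx_end > tss on +, tx_end < tss
    on -). Exons, when present, are sorted non-overlapping intervals.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    tx_end: int | None = None
    exons: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.exons:
            exs = sorted(self.exons, key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping exons in {self.gene_id}")
                if a.chrom != self.chrom or b.chrom != self.chrom:
                    raise ValueError(f"exon off-chromosome in {self.gene_id}")
            self.exons = exs


# ---------------------------------------------------------------------------
# distance / nearest-neighbor engine
# ---------------------------------------------------------------------------

def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bases between two intervals; 0 if they overlap or are
    book-ended; None if on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.start:
        return max(0, b.start - a.end)
    return max(0, a.start - b.end)


class IntervalIndex:
    """Per-chromosome sorted index supporting nearest-neighbor queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end, iv.name or ""))
            self._starts[chrom] = [iv.start for iv in ivs]
            self._max_len[chrom] = max(len(iv) for iv in ivs)

    def nearest(
        self, query: GenomicInterval, max_distance: int
    ) -> tuple[GenomicInterval, int] | None:
        """Nearest subject within ``max_distance``; ties broken by smaller
        start, then lexicographic name."""
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return None
        starts = self._starts[query.chrom]
        # any subject within max_distance starts in this window
        lo = bisect_left(
            starts, query.start - max_distance - self._max_len[query.chrom]
        )
        hi = bisect_left(starts, query.end + max_distance + 1)
        best: tuple[int, int, str, GenomicInterval] | None = None
        for iv in ivs[lo:hi]:
            d = interval_distance(query, iv)
            assert d is not None
            if d > max_distance:
                continue
            key = (d, iv.start, iv.name or "")
            if best is None or key < best[:3]:
                best = (*key, iv)
        if best is None:
            return None
        return best[3], best[0]


def find_nearest(
    query: GenomicInterval,
    subjects: Sequence[GenomicInterval] | IntervalIndex,
    max_distance: int,
) -> tuple[GenomicInterval, int] | None:
    """Nearest subject to ``query`` within ``max_distance`` bp, or None."""
    index = (
        subjects
        if isinstance(subjects, IntervalIndex)
        else IntervalIndex(subjects)
    )
    return index.nearest(query, max_distance)


def intersect_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    max_gap: int,
) -> list[tuple[GenomicInterval, GenomicInterval | None, int | None]]:
    """For each interval in ``a``, the nearest ``b`` interval within
    ``max_gap`` (or None). Deterministic given inputs."""
    index = IntervalIndex(b)
    out: list[tuple[GenomicInterval, GenomicInterval | None, int | None]] = []
    for iv in a:
        hit = index.nearest(iv, max_gap)
        if hit is None:
            out.append((iv, None, None))
        else:
            out.append((iv, hit[0], hit[1]))
    return out


def merge_overlapping(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals into union spans."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, strict: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED5/BED6 into intervals (file order preserved).

    Malformed lines are skipped with a logged error, or raise ValueError in
    strict mode. Track/browser/comment lines are always skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 fields")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if start < 0 or start >= end:
                    raise ValueError(f"bad coordinates {start},{end}")
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score: float | None = None
                if len(fields) > 4 and fields[4] not in (".", ""):
                    score = float(fields[4])
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                msg = f"{path}:{lineno}: malformed BED line ({exc}): {line!r}"
                if strict:
                    raise ValueError(msg) from exc
                logger.error(msg)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                score = iv.score
                fields.append(str(int(score)) if score == int(score) else str(score))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene model I/O
# ---------------------------------------------------------------------------

GENE_MODEL_COLUMNS = (
    "gene_id",
    "chrom",
    "tss",
    "strand",
    "tx_end",
    "exon_starts",
    "exon_ends",
)


def read_gene_model(path: str | Path) -> list[Gene]:
    """Read the tab-delimited gene model (header required).

    Columns: gene_id, chrom, tss, strand[, tx_end, exon_starts, exon_ends];
    exon lists comma-delimited, BED-style coordinates.
    """
    path = Path(path)
    genes: list[Gene] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for name in ("gene_id", "chrom", "tss", "strand"):
            if name not in col:
                raise ValueError(f"{path}: missing required column {name!r}")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            tx_end: int | None = None
            if "tx_end" in col and fields[col["tx_end"]] not in ("", "."):
                tx_end = int(fields[col["tx_end"]])
            exons: list[GenomicInterval] | None = None
            chrom = fields[col["chrom"]]
            if (
                "exon_starts" in col
                and "exon_ends" in col
                and fields[col["exon_starts"]] not in ("", ".")
            ):
                starts = [int(x) for x in fields[col["exon_starts"]].split(",") if x]
                ends = [int(x) for x in fields[col["exon_ends"]].split(",") if x]
                if len(starts) != len(ends):
                    raise ValueError(f"{path}: exon list length mismatch")
                exons = [GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)]
            genes.append(
                Gene(
                    gene_id=fields[col["gene_id"]],
                    chrom=chrom,
                    tss=int(fields[col["tss"]]),
                    strand=fields[col["strand"]],
                    tx_end=tx_end,
                    exons=exons,
                )
            )
    return genes


def write_gene_model(genes: Iterable[Gene], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(GENE_MODEL_COLUMNS) + "\n")
        for g in genes:
            exon_starts = (
                ",".join(str(e.start) for e in g.exons) if g.exons else "."
            )
            exon_ends = ",".join(str(e.end) for e in g.exons) if g.exons else "."
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        str(g.tss),
                        g.strand,
                        str(g.tx_end) if g.tx_end is not None else ".",
                        exon_starts,
                        exon_ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}. Wrapped or unwrapped lines;
    N allowed."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    sequences: dict[str, str], path: str | Path, width: int = 70
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_chrom_sorted(
    intervals: Iterable[GenomicInterval],
) -> Iterator[GenomicInterval]:
    yield from sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
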