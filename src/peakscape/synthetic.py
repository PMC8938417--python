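"""Seeded in-silico dataset generator with planted structure.

Emits a genome, gene model, two-condition replicate peak sets per assay, a
differential-expression table, peak sequences with planted motifs, and a
ground-truth manifest for recovery tests. Fully deterministic given the
config seed; all randomness flows from one SeedSequence via named child
streams so stages are order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from peakscape.association import (
    AssociationTable,
    DERecord,
    build_regulatory_domains,
    make_de_record,
    write_de_table,
)
from peakscape.core import (
    Gene,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_gene_model,
)
from peakscape.motifs import PWM, builtin_motifs, reverse_complement

CONDITIONS = ("static", "flow")
ASSAYS = ("H3K27ac", "ATAC")
_MAX_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class SimConfig:
    n_chroms: int = 3
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_common: int = 150
    n_gained: int = 80
    n_lost: int = 60
    peak_length_range: tuple[int, int] = (200, 500)
    frac_up: float = 0.15
    frac_down: float = 0.10
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    assoc_prob: float = 0.7
    q_target: float = 0.6
    q_background: float = 0.05
    gc_content: float = 0.41
    jitter: int = 10
    seq_assay: str = "ATAC"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "assoc_prob", "q_target",
                     "q_background", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_common",
                     "n_gained", "n_lost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.peak_length_range
        if lo < 50 or hi < lo:
            raise ValueError("peak lengths must be >= 50 bp and ordered")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")


@dataclass
class PlantedMotif:
    motif: str
    offset: int
    strand: str
    instance: str


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the dataset bundle."""

    config: SimConfig
    gene_direction: dict[str, str]
    peak_class: dict[str, str]  # peak_id -> gained/lost/common
    peak_assay: dict[str, str]
    peak_interval: dict[str, tuple[str, int, int]]
    peak_target_gene: dict[str, str | None]  # domain-placed peaks only
    planted_motifs: dict[str, list[PlantedMotif]]

    def to_json(self) -> dict[str, Any]:
        return {
            "config": dataclasses.asdict(self.config),
            "gene_direction": self.gene_direction,
            "peak_class": self.peak_class,
            "peak_assay": self.peak_assay,
            "peak_interval": {
                k: list(v) for k, v in self.peak_interval.items()
            },
            "peak_target_gene": self.peak_target_gene,
            "planted_motifs": {
                k: [dataclasses.asdict(m) for m in v]
                for k, v in self.planted_motifs.items()
            },
        }


@dataclass
class DatasetBundle:
    config: SimConfig
    chrom_lengths: dict[str, int]
    genes: list[Gene]
    de_table: list[DERecord]
    replicate_peaks: dict[tuple[str, str, int], list[GenomicInterval]]
    sequences: dict[str, str]
    truth: SyntheticTruth


def _stream(seed: int, label: str) -> np.random.Generator:
    """Named child RNG so stage order never shifts another stage's draws."""
    digest = int.from_bytes(label.encode(), "big") % (2**32)
    return np.random.default_rng(np.random.SeedSequence((seed, digest)))


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def sample_motif_instance(pwm: PWM, rng: np.random.Generator) -> str:
    from peakscape.motifs import BASES

    return "".join(
        BASES[rng.choice(4, p=row / row.sum())] for row in pwm.matrix
    )


def plant_motif(
    sequence: str,
    motif: PWM | str,
    rng: np.random.Generator,
) -> tuple[str, PlantedMotif | None]:
    """Overwrite a uniform-random window of ``sequence`` with one motif
    instance on a uniform-random strand; returns (sequence, record).

    A PWM motif is sampled per-position from its base probabilities; a
    plain string is planted verbatim. Empty motifs leave the input
    unchanged.
    """
    if isinstance(motif, PWM):
        instance = sample_motif_instance(motif, rng)
        name = motif.name
    else:
        instance = motif.upper()
        name = motif.upper() or "(empty)"
    if not instance:
        return sequence, None
    if len(sequence) <= len(instance):
        raise ValueError("sequence too short to plant motif")
    offset = int(rng.integers(0, len(sequence) - len(instance) + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    embedded = instance if strand == "+" else reverse_complement(instance)
    new_seq = sequence[:offset] + embedded + sequence[offset + len(instance):]
    return new_seq, PlantedMotif(name, offset, strand, embedded)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _simulate_genes(config: SimConfig, rng: np.random.Generator) -> list[Gene]:
    genes: list[Gene] = []
    margin = 60_000  # keep transcripts inside the chromosome
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        tss = int(rng.integers(margin, config.chrom_length - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        tx_len = int(rng.integers(5_000, 50_000))
        tx_end = tss + tx_len if strand == "+" else tss - tx_len
        lo, hi = min(tss, tx_end), max(tss, tx_end)
        n_exons = int(rng.integers(2, 6))
        cuts = np.sort(rng.integers(lo, hi, size=2 * n_exons))
        exons = [
            GenomicInterval(chrom, int(s), int(e))
            for s, e in zip(cuts[::2], cuts[1::2])
            if e > s
        ]
        genes.append(
            Gene(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                tss=tss,
                strand=strand,
                tx_end=tx_end,
                exons=exons or None,
            )
        )
    return genes


def _simulate_de(
    config: SimConfig, genes: list[Gene], rng: np.random.Generator
) -> list[DERecord]:
    n = len(genes)
    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    order = rng.permutation(n)
    records: dict[str, DERecord] = {}
    for rank, gi in enumerate(order):
        gid = genes[gi].gene_id
        if rank < n_up:
            lfc = rng.normal(config.lfc_mean, config.lfc_sd)
            fdr = float(rng.uniform(1e-8, 0.049))
        elif rank < n_up + n_down:
            lfc = rng.normal(-config.lfc_mean, config.lfc_sd)
            fdr = float(rng.uniform(1e-8, 0.049))
        else:
            lfc = rng.normal(0.0, 0.1)
            fdr = float(rng.uniform(0.05, 1.0))
        records[gid] = make_de_record(gid, float(lfc), fdr)
    return [records[g.gene_id] for g in genes]


def _place_peak(
    config: SimConfig,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    domain: GenomicInterval | None,
) -> GenomicInterval:
    lo, hi = config.peak_length_range
    for _ in range(_MAX_PLACEMENT_RETRIES):
        length = int(rng.integers(lo, hi + 1))
        if domain is not None:
            if len(domain) <= length:
                continue  # infeasible for this length; resample
            start = int(rng.integers(domain.start, domain.end - length))
            return GenomicInterval(domain.chrom, start, start + length)
        chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        return GenomicInterval(chrom, start, start + length)
    raise RuntimeError("could not place peak after bounded retries")


def _jitter(
    iv: GenomicInterval, jitter: int, clen: int, rng: np.random.Generator
) -> GenomicInterval:
    shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    start = min(max(0, iv.start + shift), clen - len(iv))
    return GenomicInterval(iv.chrom, start, start + len(iv), iv.name)


def generate_dataset(config: SimConfig) -> DatasetBundle:
    """Generate the full synthetic bundle (deterministic given the seed)."""
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    genes = _simulate_genes(config, _stream(config.seed, "genes"))
    de_table = _simulate_de(config, genes, _stream(config.seed, "de"))
    direction = {r.gene_id: r.direction for r in de_table}
    domains = {
        d.gene_id: d.domain
        for d in build_regulatory_domains(genes, chrom_lengths)
    }
    up_genes = sorted(g for g, d in direction.items() if d == "up")
    down_genes = sorted(g for g, d in direction.items() if d == "down")

    truth = SyntheticTruth(
        config=config,
        gene_direction=direction,
        peak_class={},
        peak_assay={},
        peak_interval={},
        peak_target_gene={},
        planted_motifs={},
    )
    replicate_peaks: dict[tuple[str, str, int], list[GenomicInterval]] = {
        (assay, cond, rep): []
        for assay in ASSAYS
        for cond in CONDITIONS
        for rep in (1, 2)
    }

    for assay in ASSAYS:
        rng = _stream(config.seed, f"peaks:{assay}")
        specs = (
            [("common", None)] * config.n_common
            + [("gained", up_genes)] * config.n_gained
            + [("lost", down_genes)] * config.n_lost
        )
        for idx, (cls, pool) in enumerate(specs):
            pid = f"{assay}_pk{idx:05d}"
            target: str | None = None
            domain = None
            if pool and rng.random() < config.assoc_prob:
                target = pool[int(rng.integers(0, len(pool)))]
                domain = domains[target]
            iv = _place_peak(config, chrom_lengths, rng, domain)
            iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=pid)
            truth.peak_class[pid] = cls
            truth.peak_assay[pid] = assay
            truth.peak_interval[pid] = (iv.chrom, iv.start, iv.end)
            truth.peak_target_gene[pid] = target
            conditions = (
                CONDITIONS if cls == "common"
                else (("flow",) if cls == "gained" else ("static",))
            )
            clen = chrom_lengths[iv.chrom]
            for cond in conditions:
                for rep in (1, 2):
                    replicate_peaks[(assay, cond, rep)].append(
                        _jitter(iv, config.jitter, clen, rng)
                    )

    for key in replicate_peaks:
        replicate_peaks[key].sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    sequences, planted = _simulate_sequences(config, truth)
    truth.planted_motifs = planted
    return DatasetBundle(
        config=config,
        chrom_lengths=chrom_lengths,
        genes=genes,
        de_table=de_table,
        replicate_peaks=replicate_peaks,
        sequences=sequences,
        truth=truth,
    )


def _simulate_sequences(
    config: SimConfig, truth: SyntheticTruth
) -> tuple[dict[str, str], dict[str, list[PlantedMotif]]]:
    """Background-composition sequences for the configured assay's peaks,
    with the KLF-like motif planted preferentially in gained peaks and the
    ETS-like motif in lost peaks."""
    from peakscape.motifs import BASES

    rng = _stream(config.seed, "sequences")
    klf, ets = builtin_motifs()
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    planted: dict[str, list[PlantedMotif]] = {}
    for pid in sorted(truth.peak_class):
        if truth.peak_assay[pid] != config.seq_assay:
            continue
        chrom, start, end = truth.peak_interval[pid]
        length = end - start
        seq = "".join(BASES[i] for i in rng.choice(4, size=length, p=base_p))
        records: list[PlantedMotif] = []
        cls = truth.peak_class[pid]
        for pwm, target_cls in ((klf, "gained"), (ets, "lost")):
            rate = (
                config.q_target if cls == target_cls else config.q_background
            )
            if rng.random() < rate:
                seq, rec = plant_motif(seq, pwm, rng)
                if rec is not None:
                    records.append(rec)
        sequences[pid] = seq
        planted[pid] = records
    return sequences, planted


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to ``outdir``; returns {logical name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.tsv"
    write_gene_model(bundle.genes, paths["genes"])
    paths["de_table"] = outdir / "de_table.tsv"
    write_de_table(bundle.de_table, paths["de_table"])
    for (assay, cond, rep), peaks in sorted(bundle.replicate_peaks.items()):
        key = f"{assay}_{cond}_rep{rep}"
        paths[key] = outdir / f"{key}.bed"
        write_bed(peaks, paths[key])
    paths["sequences"] = outdir / "peaks.fasta"
    write_fasta(bundle.sequences, paths["sequences"])
    paths["truth"] = outdir / "truth.json"
    with paths["truth"].open("w") as fh:
        json.dump(bundle.truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    chrom_path = outdir / "chrom_lengths.tsv"
    with chrom_path.open("w") as fh:
        for chrom, clen in sorted(bundle.chrom_lengths.items()):
            fh.write(f"{chrom}\t{clen}\n")
    paths["chrom_lengths"] = chrom_path
    return paths


# ---------------------------------------------------------------------------
# controlled count-expression relation (for correlation recovery tests)
# ---------------------------------------------------------------------------

def linear_count_expression(
    n_genes: int,
    slope: float,
    noise_sd: float,
    mean_count: float,
    rng: np.random.Generator,
    peak_class: str = "gained",
) -> tuple[AssociationTable, list[DERecord], float]:
    """Plant log2fc = slope * count + Normal(0, noise_sd) over Poisson
    counts; returns (table, DE records, closed-form expected Pearson r).

    With Var(count) = mean_count, the expected correlation is
    slope * sqrt(mean_count) / sqrt(slope^2 * mean_count + noise_sd^2).
    """
    counts = rng.poisson(mean_count, size=n_genes)
    lfc = slope * counts + rng.normal(0.0, noise_sd, size=n_genes)
    table = AssociationTable(
        peak_to_genes={},
        gene_peak_counts={
            f"g{i:05d}": {peak_class: int(c)} for i, c in enumerate(counts)
        },
    )
    de = [
        DERecord(f"g{i:05d}", float(lfc[i]), 0.01, "up")
        for i in range(n_genes)
    ]
    expected_r = (
        slope
        * np.sqrt(mean_count)
        / np.sqrt(slope**2 * mean_count + noise_sd**2)
    )
    return table, de, float(expected_r)
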