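"""Pipeline orchestration: simulate -> classify -> crossassay -> annotate ->
associate -> motifs, with a consolidated report and run manifest.

All outputs are plain text under a config-named directory with no
timestamps, so identical config + seed gives byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from peakscape import annotation as ann
from peakscape import association as assoc
from peakscape import dynamics as dyn
from peakscape import motifs as mot
from peakscape import synthetic as syn
from peakscape.core import (
    GenomicInterval,
    Peak,
    read_bed,
    read_fasta,
    read_gene_model,
    write_bed,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "crossassay", "annotate", "associate", "motifs")
ASSAYS = ("H3K27ac", "ATAC")
CONDITIONS = ("static", "flow")


@dataclass
class RunConfig:
    """All pipeline thresholds and paths; echoed into the run manifest."""

    outdir: str = "peakscape_run"
    data_dir: str | None = None  # defaults to <outdir>/data
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    max_gap: int = 100
    de_fdr: float = 0.05
    peak_fdr: float = 0.05
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000
    threshold_frac: float = 0.8
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_window: int = 1000
    motif_file: str | None = None  # default: built-in fixture motifs
    sim: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("max_gap", "basal_up", "basal_down", "max_ext",
                     "tts_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


class StageError(RuntimeError):
    """A stage failed or its upstream outputs are missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing input {path}; run the '{producer}' stage first"
        )
    return path


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[Any]]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_chrom_lengths(path: Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with path.open() as fh:
        for line in fh:
            if line.strip():
                chrom, clen = line.split("\t")
                out[chrom] = int(clen)
    return out


def _read_classified(path: Path, assay: str) -> list[Peak]:
    peaks = []
    for iv in read_bed(path):
        cls = (iv.name or "unassigned").rsplit("_", 1)[0]
        peaks.append(Peak(iv, assay=assay, dynamics=cls))
    return peaks


class Pipeline:
    """Executes enabled stages in dependency order under ``config.outdir``."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.outdir = Path(config.outdir)
        self.data_dir = (
            Path(config.data_dir) if config.data_dir else self.outdir / "data"
        )
        self.report: dict[str, Any] = {}
        self.log_lines: list[str] = []

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        sim_config = syn.SimConfig(seed=self.config.seed, **self.config.sim)
        bundle = syn.generate_dataset(sim_config)
        syn.write_bundle(bundle, self.data_dir)
        n_peaks = sum(len(v) for v in bundle.replicate_peaks.values())
        self._log(
            f"simulate: {len(bundle.genes)} genes, "
            f"{n_peaks} replicate peak records, "
            f"{len(bundle.sequences)} sequences -> {self.data_dir}"
        )

    def classify(self) -> None:
        stage_dir = self._stage_dir("classify")
        counts_rows = []
        for assay in ASSAYS:
            consensus = {}
            for cond in CONDITIONS:
                reps = [
                    read_bed(
                        _require(
                            self.data_dir / f"{assay}_{cond}_rep{r}.bed",
                            "simulate",
                        )
                    )
                    for r in (1, 2)
                ]
                consensus[cond] = dyn.consensus_replicates(
                    reps[0], reps[1], condition=cond, assay=assay
                )
            classified = dyn.classify_peak_dynamics(
                consensus["static"], consensus["flow"]
            )
            write_bed(
                [p.interval for p in classified],
                stage_dir / f"{assay}_classified.bed",
            )
            by_class: dict[str, list[GenomicInterval]] = {}
            for p in classified:
                by_class.setdefault(p.dynamics, []).append(p.interval)
            for cls in ("gained", "lost", "common"):
                write_bed(
                    by_class.get(cls, []), stage_dir / f"{assay}_{cls}.bed"
                )
                counts_rows.append((assay, cls, len(by_class.get(cls, []))))
            self._log(
                f"classify[{assay}]: "
                + ", ".join(
                    f"{cls}={len(by_class.get(cls, []))}"
                    for cls in ("gained", "lost", "common")
                )
            )
        _write_tsv(
            stage_dir / "class_counts.tsv",
            ("assay", "dynamics", "count"),
            counts_rows,
        )
        self.report["class_counts"] = {
            f"{assay}:{cls}": n for assay, cls, n in counts_rows
        }

    def crossassay(self) -> None:
        stage_dir = self._stage_dir("crossassay")
        classify_dir = self.outdir / "classify"
        peaks = {
            assay: _read_classified(
                _require(classify_dir / f"{assay}_classified.bed", "classify"),
                assay,
            )
            for assay in ASSAYS
        }
        matrices = {}
        for query, subject in (("ATAC", "H3K27ac"), ("H3K27ac", "ATAC")):
            matrix = dyn.cross_assay_matrix(
                peaks[query],
                peaks[subject],
                max_gap=self.config.max_gap,
                direction=f"{query}->{subject}",
            )
            cols = ("gained", "lost", "common", "none")
            _write_tsv(
                stage_dir / f"matrix_{query}_vs_{subject}.tsv",
                ("query_class", *cols),
                [
                    (qcls, *(matrix.counts[qcls][c] for c in cols))
                    for qcls in ("gained", "lost", "common")
                ],
            )
            matrices[matrix.direction] = matrix.counts
            self._log(
                f"crossassay[{matrix.direction}]: "
                f"{sum(sum(r.values()) for r in matrix.counts.values())} "
                "query peaks tabulated"
            )
        self.report["cross_assay"] = matrices

    def annotate(self) -> None:
        stage_dir = self._stage_dir("annotate")
        genes = read_gene_model(
            _require(self.data_dir / "genes.tsv", "simulate")
        )
        for assay in ASSAYS:
            peaks = _read_classified(
                _require(
                    self.outdir / "classify" / f"{assay}_classified.bed",
                    "classify",
                ),
                assay,
            )
            results = ann.annotate_peaks(
                [p.interval for p in peaks],
                genes,
                promoter_window=(
                    self.config.promoter_upstream,
                    self.config.promoter_downstream,
                ),
                tts_window=self.config.tts_window,
            )
            _write_tsv(
                stage_dir / f"{assay}_annotation.tsv",
                ("peak_id", "feature", "gene_id", "distance_to_tss"),
                [
                    (
                        r.peak_id,
                        r.feature,
                        r.gene_id or ".",
                        r.distance_to_tss if r.distance_to_tss is not None else ".",
                    )
                    for r in results
                ],
            )
            classes = {p.interval.name: p.dynamics for p in peaks}
            summary = ann.annotation_summary(results, classes)
            _write_tsv(
                stage_dir / f"{assay}_summary.tsv",
                ("dynamics", *ann.FEATURES),
                [
                    (cls, *(f"{summary[cls][f]:.6f}" for f in ann.FEATURES))
                    for cls in sorted(summary)
                ],
            )
            self.report[f"annotation_fractions:{assay}"] = summary
            self._log(f"annotate[{assay}]: {len(results)} peaks annotated")

    def associate(self) -> None:
        stage_dir = self._stage_dir("associate")
        genes = read_gene_model(
            _require(self.data_dir / "genes.tsv", "simulate")
        )
        chrom_lengths = _read_chrom_lengths(
            _require(self.data_dir / "chrom_lengths.tsv", "simulate")
        )
        de = assoc.read_de_table(
            _require(self.data_dir / "de_table.tsv", "simulate"),
            fdr_threshold=self.config.de_fdr,
        )
        domains = assoc.build_regulatory_domains(
            genes,
            chrom_lengths,
            basal_up=self.config.basal_up,
            basal_down=self.config.basal_down,
            max_ext=self.config.max_ext,
        )
        assoc.write_domains_bed(domains, stage_dir / "domains.bed")
        for assay in ASSAYS:
            peaks = _read_classified(
                _require(
                    self.outdir / "classify" / f"{assay}_classified.bed",
                    "classify",
                ),
                assay,
            )
            table = assoc.associate_peaks_to_genes(peaks, domains)
            crosstab = assoc.association_summary(table, de)
            rows = []
            for direction in ("up", "down"):
                for cls in ("gained", "lost", "common"):
                    cell = crosstab[direction][cls]
                    rows.append(
                        (
                            direction,
                            cls,
                            cell["n_genes"],
                            "." if cell["percent"] is None
                            else f"{cell['percent']:.4f}",
                            "." if cell["mean_peaks"] is None
                            else f"{cell['mean_peaks']:.4f}",
                        )
                    )
            _write_tsv(
                stage_dir / f"{assay}_crosstab.tsv",
                ("direction", "peak_class", "n_genes", "percent", "mean_peaks"),
                rows,
            )
            correlations: dict[str, Any] = {}
            for cls in ("gained", "lost", "common"):
                try:
                    r, p = assoc.peakcount_expression_correlation(
                        table, de, cls
                    )
                    correlations[cls] = {"r": r, "p": p}
                except ValueError as exc:
                    correlations[cls] = {"error": str(exc)}
            with (stage_dir / f"{assay}_correlation.json").open("w") as fh:
                json.dump(correlations, fh, indent=1, sort_keys=True)
                fh.write("\n")
            self.report[f"association_crosstab:{assay}"] = crosstab
            self.report[f"correlation:{assay}"] = correlations
            self._log(
                f"associate[{assay}]: {len(table.peak_to_genes)} peaks vs "
                f"{len(domains)} domains"
            )

    def motifs(self) -> None:
        stage_dir = self._stage_dir("motifs")
        sequences = read_fasta(
            _require(self.data_dir / "peaks.fasta", "simulate")
        )
        seq_assay = syn.SimConfig(
            seed=self.config.seed, **self.config.sim
        ).seq_assay
        classified = _read_classified(
            _require(
                self.outdir / "classify" / f"{seq_assay}_classified.bed",
                "classify",
            ),
            seq_assay,
        )
        # locate each sequence's source interval via the replicate BEDs,
        # then take the class of the classified peak containing its midpoint
        id_to_iv: dict[str, GenomicInterval] = {}
        for cond in CONDITIONS:
            for iv in read_bed(
                _require(
                    self.data_dir / f"{seq_assay}_{cond}_rep1.bed", "simulate"
                )
            ):
                if iv.name and iv.name not in id_to_iv:
                    id_to_iv[iv.name] = iv
        by_class: dict[str, dict[str, str]] = {
            "gained": {}, "lost": {}, "common": {}
        }
        index = {}
        for p in classified:
            index.setdefault(p.interval.chrom, []).append(p)
        for sid, seq in sequences.items():
            iv = id_to_iv.get(sid)
            if iv is None:
                continue
            mid = iv.midpoint
            for p in index.get(iv.chrom, []):
                if p.interval.start <= mid < p.interval.end:
                    if p.dynamics in by_class:
                        by_class[p.dynamics][sid] = seq
                    break
        if self.config.motif_file:
            pwms = mot.read_motifs(self.config.motif_file)
        else:
            pwms = mot.builtin_motifs()
        motif_report: dict[str, Any] = {}
        for target_cls in ("gained", "lost"):
            targets = by_class[target_cls]
            background = by_class["common"]
            if not targets or not background:
                self._log(
                    f"motifs[{target_cls}]: skipped (empty target or background)"
                )
                continue
            results = mot.enrich_motifs(
                targets,
                background,
                pwms,
                threshold_frac=self.config.threshold_frac,
            )
            _write_tsv(
                stage_dir / f"{target_cls}_enrichment.tsv",
                ("motif", "target_hits", "n_target", "background_hits",
                 "n_background", "fold", "p", "fdr"),
                [
                    (r.motif, r.target_hits, r.n_target, r.background_hits,
                     r.n_background, f"{r.fold:.4g}", f"{r.p:.6g}",
                     f"{r.fdr:.6g}")
                    for r in results
                ],
            )
            motif_report[target_cls] = [
                {"motif": r.motif, "p": r.p, "fdr": r.fdr, "fold": r.fold}
                for r in results
            ]
            self._log(
                f"motifs[{target_cls}]: {len(targets)} targets vs "
                f"{len(background)} background, top motif "
                f"{results[0].motif} (p={results[0].p:.3g})"
            )
        self.report["motif_enrichment"] = motif_report

    # -- orchestration -----------------------------------------------------

    def run(self) -> Path:
        """Run enabled stages in order; returns the report path."""
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in self.config.stages:
            try:
                getattr(self, stage)()
            except StageError:
                self._finalize()  # retain partial results
                raise
        return self._finalize()

    def _finalize(self) -> Path:
        report_path = self.outdir / "report.json"
        with report_path.open("w") as fh:
            json.dump(self.report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log_path = self.outdir / "pipeline.log"
        log_path.write_text("".join(line + "\n" for line in self.log_lines))
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "files": {},
        }
        for path in sorted(self.outdir.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                rel = str(path.relative_to(self.outdir))
                manifest["files"][rel] = {
                    "size": path.stat().st_size,
                    "sha256": _sha256(path),
                }
        with (self.outdir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report_path

    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _log(self, message: str) -> None:
        logger.info(message)
        self.log_lines.append(message)


def run_pipeline(config: RunConfig) -> Path:
    return Pipeline(config).run()
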