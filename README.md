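# peakscape

Toolkit for integrative analysis of two-condition regulatory-element peak
data: it classifies peaks as gained / lost / common between conditions,
cross-tabulates two chromatin assays by proximity, annotates peaks to
genomic features, associates peaks with genes over basal-plus-extension
regulatory domains (up to 1 Mb), scores the association against
differential expression, and ranks transcription-factor motifs by
hypergeometric enrichment in target vs background peak sequences. A seeded
synthetic-data generator with planted structure (gained/lost/common peak
fractions, direction-biased peak placement near DE genes, planted KLF-like
and ETS-like motifs) makes the whole pipeline testable end to end without
any external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(interval-engine and regulatory-domain oracles, classification
conservation/recovery, association and correlation recovery, motif
enrichment calibration, BH correctness, end-to-end determinism).

## CLI

```sh
# full pipeline on a synthetic bundle
peakscape --outdir out --seed 1 run

# stage by stage
peakscape --outdir out --seed 1 simulate
peakscape --outdir out classify
peakscape --outdir out crossassay
peakscape --outdir out annotate
peakscape --outdir out associate
peakscape --outdir out motifs
peakscape --outdir out report
```

Thresholds (overlap gap, FDR cutoffs, domain extents, motif score
threshold) and simulation parameters live in a YAML config passed with
`--config`; CLI flags override it. Every run writes per-stage TSV/BED/JSON
outputs, a consolidated `report.json`, a `pipeline.log` with one summary
line per stage, and a `manifest.json` with the config echo and a checksum
for every output file. Identical config + seed reproduce the output
directory byte for byte.

## Library layout

| module                   | contents |
|--------------------------|----------|
| `peakscape.core`         | `GenomicInterval`/`Peak`/`Gene`, interval distance + nearest-neighbor index, BED / gene-model / FASTA I/O |
| `peakscape.synthetic`    | `SimConfig`, seeded dataset generator, motif planting, truth manifest |
| `peakscape.dynamics`     | replicate consensus, gained/lost/common classification, exact binomial occupancy test, cross-assay matrix |
| `peakscape.annotation`   | promoter/TTS/exon/intron/intergenic assignment and per-class summaries |
| `peakscape.association`  | regulatory domains, peak-gene association, DE cross-tabs, count-expression correlation, gene-set overlap |
| `peakscape.motifs`       | PWM parsing (JASPAR/HOMER), log-odds scanning, hypergeometric enrichment, BH adjustment, GC-matched subsampling |
| `peakscape.pipeline`     | `RunConfig` + stage orchestration |
| `peakscape.cli`          | `peakscape` command |

## Conventions

- Coordinates are 0-based half-open (BED) everywhere internally.
- Book-ended intervals have distance 0; "within K bp" means distance <= K.
- Peak-to-domain and peak-to-feature assignment use the peak midpoint.
- Nearest-neighbor ties break by smaller start, then name.
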