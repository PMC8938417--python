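"""PWM motif scanning and target-vs-background enrichment.

Scoring is log2 odds against a background base composition; a window is a
hit when its score reaches ``threshold_frac`` of the motif's maximum
achievable score. Enrichment counts sequences with >=1 hit and tests them
with a hypergeometric upper tail, BH-corrected across motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3, anything else (incl. N) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities over ACGT."""

    name: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 4:
            raise ValueError(f"{self.name}: matrix must be (L>=4, 4)")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: matrix rows must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6) or np.any(bg <= 0):
            raise ValueError(f"{self.name}: invalid background composition")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def with_background(self, background: np.ndarray) -> "PWM":
        return replace(self, background=np.asarray(background, dtype=float))

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[::-1, ::-1])


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based on the + strand
    strand: str  # '+' or '-'
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    target_hits: int
    n_target: int
    background_hits: int
    n_background: int
    fold: float
    p: float
    fdr: float


# ---------------------------------------------------------------------------
# motif file parsing (JASPAR PFM and HOMER motif text)
# ---------------------------------------------------------------------------

def _pfm_to_pwm(
    name: str, counts: np.ndarray, pseudocount: float
) -> PWM:
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError(f"{name}: motif column does not sum to a positive total")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    return PWM(name=name, matrix=probs, pseudocount=pseudocount)


def _parse_jaspar(blocks: list[tuple[str, list[str]]], pseudocount: float) -> list[PWM]:
    pwms = []
    for name, lines in blocks:
        rows: dict[str, list[float]] = {}
        for line in lines:
            base = line.split()[0].upper()
            nums = line.replace("[", " ").replace("]", " ").split()[1:]
            rows[base] = [float(x) for x in nums]
        counts = np.array([rows[b] for b in BASES]).T  # (L, 4)
        pwms.append(_pfm_to_pwm(name, counts, pseudocount))
    return pwms


def _parse_homer(blocks: list[tuple[str, list[str]]], pseudocount: float) -> list[PWM]:
    pwms = []
    for header, lines in blocks:
        # header: CONSENSUS<tab>NAME[<tab>threshold...]
        parts = header.split("\t")
        name = parts[1] if len(parts) > 1 else parts[0]
        probs = np.array([[float(x) for x in ln.split()] for ln in lines])
        if probs.shape[1] != 4:
            raise ValueError(f"{name}: expected 4 probabilities per row")
        # renormalize with a small floor so log-odds stay finite
        eps = 1e-3
        probs = (probs + eps) / (probs.sum(axis=1, keepdims=True) + 4 * eps)
        pwms.append(PWM(name=name, matrix=probs, pseudocount=pseudocount))
    return pwms


def read_motifs(path: str | Path, pseudocount: float = 0.25) -> list[PWM]:
    """Read a JASPAR-style PFM or HOMER-style motif file (auto-detected)."""
    path = Path(path)
    blocks: list[tuple[str, list[str]]] = []
    with path.open() as fh:
        current: list[str] | None = None
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = []
                blocks.append((line[1:].strip(), current))
            elif current is not None:
                current.append(line)
    if not blocks or not any(lines for _, lines in blocks):
        raise ValueError(f"{path}: no motifs found")
    first = blocks[0][1][0]
    if first.split()[0].upper() in ("A", "C", "G", "T"):
        return _parse_jaspar(blocks, pseudocount)
    return _parse_homer(blocks, pseudocount)


def write_jaspar(pwms: Iterable[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR-style integer count matrices."""
    with Path(path).open("w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for bi, base in enumerate(BASES):
                nums = " ".join(str(c) for c in counts[:, bi])
                fh.write(f"{base} [ {nums} ]\n")


def builtin_motifs() -> list[PWM]:
    """The KLF-like and ETS-like fixture motifs shipped with the package."""
    pwms: list[PWM] = []
    for fname in ("klf_like.jaspar", "ets_like.jaspar"):
        ref = resources.files("peakscape.data").joinpath(fname)
        with resources.as_file(ref) as p:
            pwms.extend(read_motifs(p))
    return pwms


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _strand_scores(
    lodds: np.ndarray, codes: np.ndarray
) -> np.ndarray:
    """Window scores for one strand; NaN where the window contains N."""
    L = lodds.shape[0]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(windows == 4).any(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        w = windows[valid]
        scores[valid] = lodds[np.arange(L), w].sum(axis=1)
    return scores


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold_frac: float = 0.8,
    seq_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold_frac * max score.

    The minus strand is scored on the reverse complement; reported offsets
    are always plus-strand window starts. Windows containing N are skipped.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    threshold = threshold_frac * pwm.max_score
    lodds = pwm.log_odds
    codes = encode(seq)
    hits: list[MotifHit] = []
    fwd = _strand_scores(lodds, codes)
    rc_lodds = pwm.reverse_complement().log_odds
    rev = _strand_scores(rc_lodds, codes)
    for offset in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(seq_id, int(offset), "+", float(fwd[offset])))
    for offset in np.flatnonzero(rev >= threshold):
        hits.append(MotifHit(seq_id, int(offset), "-", float(rev[offset])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _has_hit(pwm: PWM, codes: np.ndarray, threshold_frac: float) -> bool:
    L = len(pwm)
    if codes.size < L:
        return False
    threshold = threshold_frac * pwm.max_score
    fwd = _strand_scores(pwm.log_odds, codes)
    if fwd.size and np.nanmax(fwd, initial=-np.inf) >= threshold:
        return True
    rev = _strand_scores(pwm.reverse_complement().log_odds, codes)
    return bool(rev.size and np.nanmax(rev, initial=-np.inf) >= threshold)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def empirical_background(sequences: Iterable[str]) -> np.ndarray:
    """Base composition of the given sequences (ACGT; N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # floor avoids zero-probability bases in log-odds
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


def _as_items(sequences: Mapping[str, str] | Sequence[str]) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return [(k, sequences[k]) for k in sorted(sequences)]
    return [(f"seq{i}", s) for i, s in enumerate(sequences)]


def enrich_motifs(
    targets: Mapping[str, str] | Sequence[str],
    background: Mapping[str, str] | Sequence[str],
    pwms: Sequence[PWM],
    threshold_frac: float = 0.8,
    use_empirical_background: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each motif in targets vs background.

    k = target sequences with >=1 hit; the population is the pooled
    sequence sets and successes are all sequences with a hit. Results are
    sorted by ascending p, ties broken by motif name.
    """
    tgt = _as_items(targets)
    bg = _as_items(background)
    if not tgt or not bg:
        raise ValueError("target and background sets must be non-empty")
    if use_empirical_background:
        comp = empirical_background([s for _, s in tgt] + [s for _, s in bg])
        pwms = [pwm.with_background(comp) for pwm in pwms]
    tgt_codes = [encode(s) for _, s in tgt]
    bg_codes = [encode(s) for _, s in bg]
    n_t, n_b = len(tgt), len(bg)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for pwm in pwms:
        k = sum(_has_hit(pwm, c, threshold_frac) for c in tgt_codes)
        kb = sum(_has_hit(pwm, c, threshold_frac) for c in bg_codes)
        p = float(hypergeom.sf(k - 1, n_t + n_b, k + kb, n_t))
        target_rate = k / n_t
        bg_rate = kb / n_b
        fold = float("inf") if bg_rate == 0 and k > 0 else (
            1.0 if k == 0 and kb == 0 else target_rate / bg_rate
        )
        results.append(
            EnrichmentResult(pwm.name, k, n_t, kb, n_b, fold, p, fdr=1.0)
        )
        pvals.append(p)
    fdrs = bh_adjust(pvals)
    results = [replace(r, fdr=f) for r, f in zip(results, fdrs)]
    results.sort(key=lambda r: (r.p, r.motif))
    return results


def gc_content(seq: str) -> float:
    codes = encode(seq)
    acgt = codes[codes < 4]
    if acgt.size == 0:
        return 0.0
    return float(np.isin(acgt, (1, 2)).mean())


def gc_matched_subsample(
    background: Mapping[str, str] | Sequence[str],
    targets: Mapping[str, str] | Sequence[str],
    bins: int = 10,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Resample the background so its GC histogram matches the targets'.

    Bins are equal-width over [0, 1]. Bins where the background is short are
    sampled with replacement (logged); target bins with no background
    counterpart are skipped with a warning.
    """
    rng = rng or np.random.default_rng()
    tgt = _as_items(targets)
    bg = _as_items(background)
    edges = np.linspace(0, 1, bins + 1)
    tgt_bins = np.clip(
        np.digitize([gc_content(s) for _, s in tgt], edges) - 1, 0, bins - 1
    )
    bg_bins = np.clip(
        np.digitize([gc_content(s) for _, s in bg], edges) - 1, 0, bins - 1
    )
    out: list[tuple[str, str]] = []
    for b in range(bins):
        need = int((tgt_bins == b).sum())
        if need == 0:
            continue
        pool = [bg[i] for i in np.flatnonzero(bg_bins == b)]
        if not pool:
            logger.warning("GC bin %d has targets but no background; skipped", b)
            continue
        if len(pool) < need:
            logger.info(
                "GC bin %d short (%d < %d); sampling with replacement",
                b, len(pool), need,
            )
            idx = rng.integers(0, len(pool), size=need)
        else:
            idx = rng.permutation(len(pool))[:need]
        out.extend(pool[i] for i in idx)
    return out
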