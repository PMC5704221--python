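"""PWM scanning of peak sequences with exact background p-values.

A PWM is turned into a log2-odds score matrix against a 0-order background
model; every window of a peak sequence is scored on both strands, and a
window is reported as a motif hit when the exact p-value of its score under
the background distribution is at or below a threshold (default 1e-4).

The null distribution of the score is computed exactly by dynamic
programming: scores are discretized onto an integer grid of step
``granularity`` bits and convolved position by position. The scanner
scores windows with the *same* integer matrix used by the DP, so the
p-value attached to a hit is the exact tail probability of its discretized
score — reported p-values are never below the true continuous-score tail
for windows whose discretization rounds down, and for any external score
lookup the score is floored onto the grid first (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import ALPHABET, PWM, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "MotifHit",
    "ScoreDistribution",
    "regularize",
    "log_odds",
    "score_distribution",
    "scan_peak",
    "scan_all",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 0..3, N -> 4 (sentinel for skipped windows)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning parameters.

    alpha: hit threshold on the exact p-value (inclusive: p ≤ alpha).
    pseudocount: additive regularization ε; p' = (p + ε·b) / (1 + ε).
    background: 0-order base frequencies (A, C, G, T), used both in the
        log-odds numerator's denominator and as the null model.
    granularity: score-grid step in bits for the exact-p-value DP.
    max_grid_cells: cap on DP table size; exceeding it is an error that
        advises a coarser granularity.
    """

    alpha: float = 1e-4
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    granularity: float = 0.001
    max_grid_cells: int = 10**7

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be ≥ 0")
        b = np.asarray(self.background, dtype=float)
        if b.shape != (4,) or np.any(b <= 0) or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive values summing to 1")
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")


@dataclass(frozen=True, order=True)
class MotifHit:
    """One significant occurrence of a motif in a peak sequence.

    ``offset`` is 0-based within the peak; on strand '-', the motif matches
    the reverse complement of the window starting at ``offset``. ``score``
    is the log2-odds in bits; ``pvalue`` is the exact tail probability of
    the discretized score under the background.
    """

    motif_id: str
    peak_id: str
    offset: int
    strand: str
    score: float
    pvalue: float


def regularize(pwm: PWM, config: ScanConfig) -> PWM:
    """Pseudocount-regularize: p'[i][x] = (p[i][x] + ε·b[x]) / (1 + ε)."""
    b = np.asarray(config.background, dtype=float)
    eps = config.pseudocount
    p = (pwm.probabilities + eps * b[None, :]) / (1.0 + eps)
    return PWM(pwm.motif_id, pwm.tf_names, p)


def log_odds(pwm_reg: PWM, config: ScanConfig) -> np.ndarray:
    """Log2-odds score matrix s[i][x] = log2(p'[i][x] / b[x]) in bits."""
    b = np.asarray(config.background, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log2(pwm_reg.probabilities / b[None, :])


@dataclass
class ScoreDistribution:
    """Exact distribution of the window score on an integer grid.

    ``probs[q - min_score]`` is P(discretized score = q); ``tail`` holds
    the upper-tail P(score ≥ q) at the same offsets. ``int_matrix`` is the
    per-position integer score matrix (entries rounded to the nearest grid
    cell) that both the DP and the scanner use.
    """

    granularity: float
    int_matrix: np.ndarray  # (w, 4) int64
    min_score: int
    probs: np.ndarray
    tail: np.ndarray

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.probs) - 1

    def pvalue_int(self, q: int) -> float:
        """Exact P(score ≥ q) for an integer grid score."""
        if q <= self.min_score:
            return 1.0
        if q > self.max_score:
            return 0.0
        return float(self.tail[q - self.min_score])

    def pvalue(self, score_bits: float) -> float:
        """P(score ≥ t) for a real-valued score; t is floored onto the
        grid, so the returned p-value is never an underestimate."""
        return self.pvalue_int(int(np.floor(score_bits / self.granularity)))


def score_distribution(
    score_matrix: np.ndarray,
    background: Sequence[float],
    granularity: float = 0.001,
    max_grid_cells: int = 10**7,
) -> ScoreDistribution:
    """Exact null distribution of the total log-odds score.

    The total score of a window is the sum over positions of s[i][X_i]
    with X_i i.i.d. from ``background``. Each matrix entry is rounded to
    the nearest multiple of ``granularity`` and the distribution of the
    integer sum is built by position-wise convolution. Probabilities sum
    to 1 within 1e-9.
    """
    s = np.asarray(score_matrix, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError(
            "score matrix has non-finite entries; regularize the PWM "
            "(pseudocount > 0) before computing the distribution"
        )
    b = np.asarray(background, dtype=float)
    e = np.rint(s / granularity).astype(np.int64)  # (w, 4)
    lo = int(e.min(axis=1).sum())
    hi = int(e.max(axis=1).sum())
    n_cells = hi - lo + 1
    if n_cells > max_grid_cells:
        raise ValueError(
            f"score grid needs {n_cells} cells (> cap {max_grid_cells}); "
            f"increase granularity"
        )
    # convolve position by position; run_min tracks the current grid origin
    run_min = 0
    dist = np.array([1.0])
    for i in range(e.shape[0]):
        row = e[i]
        new_min = run_min + int(row.min())
        new_max = run_min + len(dist) - 1 + int(row.max())
        new = np.zeros(new_max - new_min + 1)
        for x in range(4):
            shift = run_min + int(row[x]) - new_min
            new[shift : shift + len(dist)] += b[x] * dist
        dist, run_min = new, new_min
    assert run_min == lo and len(dist) == n_cells
    total = dist.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"probability mass {total} deviates from 1")
    tail = np.cumsum(dist[::-1])[::-1]
    # clip accumulated float error; tail must be a valid probability
    np.clip(tail, 0.0, 1.0, out=tail)
    return ScoreDistribution(granularity, e, lo, dist, tail)


def _prepare(pwm: PWM, config: ScanConfig) -> tuple[np.ndarray, ScoreDistribution]:
    reg = regularize(pwm, config)
    s = log_odds(reg, config)
    dist = score_distribution(
        s, config.background, config.granularity, config.max_grid_cells
    )
    return s, dist


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Sum matrix[i, codes[o+i]] over i for every offset o (vectorized).

    ``codes`` may contain the sentinel 4 for N; callers mask those windows.
    A 5th all-zero column absorbs the sentinel so indexing stays in range.
    """
    w = matrix.shape[0]
    padded = np.concatenate([matrix, np.zeros((w, 1), dtype=matrix.dtype)], axis=1)
    n_win = len(codes) - w + 1
    total = np.zeros(n_win, dtype=padded.dtype)
    for i in range(w):
        total = total + padded[i, codes[i : i + n_win]]
    return total


def scan_peak(
    sequence: str,
    pwm: PWM,
    config: ScanConfig,
    peak_id: str = "",
    _prepared: tuple[np.ndarray, ScoreDistribution] | None = None,
) -> list[MotifHit]:
    """Score every window of ``sequence`` on both strands; keep p ≤ alpha.

    Windows containing N are skipped. A '-'-strand hit at offset o means
    the reverse complement of ``sequence[o:o+w]`` matches the motif. Hits
    are sorted by (offset, strand).
    """
    s, dist = _prepared if _prepared is not None else _prepare(pwm, config)
    w = pwm.width
    if len(sequence) < w:
        return []
    codes = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)].astype(
        np.int64
    )
    n_win = len(codes) - w + 1
    has_n = np.zeros(n_win, dtype=bool)
    n_pos = codes == 4
    if n_pos.any():
        # window o contains an N iff any of codes[o:o+w] is 4
        csum = np.concatenate([[0], np.cumsum(n_pos)])
        has_n = (csum[w:] - csum[:-w]) > 0

    e = dist.int_matrix
    # '-' strand: score the reverse complement of the forward window, which
    # equals scoring the forward window with the reversed-complemented matrix
    e_rc = e[::-1, ::-1]
    s_rc = s[::-1, ::-1]

    hits: list[MotifHit] = []
    for strand, e_mat, s_mat in (("+", e, s), ("-", e_rc, s_rc)):
        q = _window_scores(codes, e_mat)
        rel = q - dist.min_score
        pvals = np.ones(n_win)
        in_range = (rel >= 0) & (rel < len(dist.tail))
        pvals[in_range] = dist.tail[rel[in_range]]
        pvals[rel >= len(dist.tail)] = 0.0
        keep = np.nonzero(~has_n & (pvals <= config.alpha))[0]
        if len(keep):
            real = _window_scores(codes, s_mat)
            for o in keep:
                hits.append(
                    MotifHit(pwm.motif_id, peak_id, int(o), strand,
                             float(real[o]), float(pvals[o]))
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_all(
    peaks: Sequence[Peak],
    genome: str | Path,
    motifs: Sequence[PWM],
    config: ScanConfig | None = None,
) -> list[MotifHit]:
    """Scan every peak sequence against every motif.

    ``genome`` is a FASTA path (indexed on first use via pyfaidx). Output
    order is deterministic: peak file order, then motif order.
    """
    from pyfaidx import Fasta

    config = config or ScanConfig()
    fasta = Fasta(str(genome), sequence_always_upper=True)
    prepared = [(m, _prepare(m, config)) for m in motifs]
    hits: list[MotifHit] = []
    for peak in peaks:
        if peak.chrom not in fasta:
            raise ValueError(f"peak {peak.peak_id!r}: chromosome {peak.chrom!r} "
                             f"not in genome FASTA")
        seq = str(fasta[peak.chrom][peak.start : peak.end])
        for m, prep in prepared:
            hits.extend(scan_peak(seq, m, config, peak_id=peak.peak_id, _prepared=prep))
    return hits


def write_hits(hits, motif_to_tfs, path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf_names\tpeak_id\toffset\tstrand\tscore_bits\tpvalue\n")
        for h in hits:
            tfs = ",".join(motif_to_tfs.get(h.motif_id, ()))
            fh.write(
                f"{h.motif_id}\t{tfs}\t{h.peak_id}\t{h.offset}\t{h.strand}"
                f"\t{h.score:.4f}\t{h.pvalue!r}\n"
            )


def read_hits(path) -> list[MotifHit]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("motif_id\t"):
            raise ValueError(f"{path}: bad hits header")
        for line in fh:
            motif_id, _tfs, peak_id, offset, strand, score, pvalue = (
                line.rstrip("\n").split("\t")
            )
            out.append(
                MotifHit(motif_id, peak_id, int(offset), strand, float(score),
                         float(pvalue))
            )
    return out
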