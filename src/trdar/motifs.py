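"""PWM motif scanning with an exact score-distribution threshold.

Motifs are read from the Homer ``.motif`` dialect and converted to log-odds
(bits) against background base frequencies.  The per-motif hit threshold is
derived from the *exact* distribution of the log-odds score of a random
background window, computed by positionwise convolution over a discretized
score lattice, at a configurable tail probability (default 1e-4).  Scanning
covers both strands; a region's hit status is binary for enrichment, which
is a two-sided Fisher test of hit regions in targets vs background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .enrichment import EnrichmentRecord, _finalize, fisher_two_sided
from .intervals import RegionSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """A position probability matrix with derived log-odds scores.

    ``matrix`` is L x 4 (A, C, G, T) probabilities; rows are renormalized
    with a pseudocount at construction.  ``log_odds`` is in bits against the
    supplied background frequencies.
    """

    name: str
    matrix: np.ndarray
    consensus: str = ""
    pseudocount: float = 1e-3
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        if (m < 0).any():
            raise ValueError("probabilities must be >= 0")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=0.02):
            warnings.warn(
                f"motif {self.name!r}: rows do not sum to 1; renormalizing"
            )
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        if not self.consensus:
            self.consensus = "".join(BASES[i] for i in self.matrix.argmax(axis=1))
        bg = np.asarray(self.background, dtype=float)
        self.background = bg / bg.sum()
        self.log_odds = np.log2(self.matrix / self.background)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=0.0,
            background=self.background[::-1].copy(),
        )


# ---------------------------------------------------------------------------
# Homer .motif I/O
# ---------------------------------------------------------------------------


def read_homer_motifs(path, pseudocount: float = 1e-3) -> List[PWM]:
    """Parse a Homer-format motif file.

    Headers are ``>consensus<TAB>name<TAB>...``; each following line holds
    the four base probabilities of one position.  Rows not summing to ~1 are
    renormalized with a warning; malformed headers raise with the line
    number.
    """
    motifs: List[PWM] = []
    header: Optional[Tuple[str, str]] = None
    rows: List[List[float]] = []

    def _flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) < 1:
            raise ValueError(f"motif {header[1]!r} has no probability rows")
        motifs.append(
            PWM(
                name=header[1],
                consensus=header[0],
                matrix=np.array(rows),
                pseudocount=pseudocount,
            )
        )
        header, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush(lineno)
                fields = line[1:].split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: malformed Homer header (need >= 2 "
                        f"tab-separated fields): {line!r}"
                    )
                header = (fields[0], fields[1])
            else:
                vals = line.split()
                if header is None or len(vals) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 probability columns"
                    )
                rows.append([float(v) for v in vals])
    _flush(-1)
    return motifs


def write_homer_motifs(motifs: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.consensus}\t{m.name}\t0\n")
            for row in m.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# exact score distribution / threshold
# ---------------------------------------------------------------------------


def _discretized_log_odds(pwm: PWM, grid: float) -> np.ndarray:
    """Integer log-odds scores on the ``grid``-bit lattice (L x 4)."""
    return np.round(pwm.log_odds / grid).astype(np.int64)


def exact_score_distribution(
    pwm: PWM, background: Optional[np.ndarray] = None, grid: float = 1e-3
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the discretized window score under background.

    Returns (scores, probabilities), scores in bits on the grid lattice.
    Computed by dynamic programming: positionwise convolution of the
    per-position score distributions of a random background base.
    """
    bg = pwm.background if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    q = _discretized_log_odds(pwm, grid)
    qmin = q.min(axis=1)
    qmax = q.max(axis=1)
    dist = np.array([1.0])
    base = 0
    for i in range(len(pwm)):
        width = dist.size + int(qmax[i] - qmin[i])
        new = np.zeros(width)
        for b in range(4):
            s = int(q[i, b] - qmin[i])
            new[s : s + dist.size] += bg[b] * dist
        dist = new
        base += int(qmin[i])
    scores = (base + np.arange(dist.size)) * grid
    return scores, dist


def exact_score_threshold(
    pwm: PWM,
    background: Optional[np.ndarray] = None,
    alpha: float = 1e-4,
    grid: float = 1e-3,
) -> float:
    """Smallest grid score whose background tail probability is <= alpha.

    If alpha is below the minimum attainable tail (the probability of the
    maximal score), the maximal score is returned with a warning.
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    scores, probs = exact_score_distribution(pwm, background, grid)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = np.flatnonzero(tail <= alpha + 1e-15)
    if ok.size == 0:
        warnings.warn(
            f"motif {pwm.name!r}: alpha={alpha} below the minimum attainable "
            "tail; returning the maximum score"
        )
        return float(scores[-1])
    return float(scores[ok[0]])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)  # 4 = N / other
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(code: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Scores of all windows; windows containing N are -inf."""
    L = q.shape[0]
    if code.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = (win != 4).all(axis=1)
    qa = np.vstack([q.T, np.full(q.shape[0], np.nan)]).T  # row 4 -> NaN
    sc = qa[np.arange(L)[None, :], win].sum(axis=1)
    sc[~valid] = -np.inf
    return sc


def scan_sequence(
    seq: str, pwm: PWM, threshold: float, grid: float = 1e-3
) -> List[Tuple[int, str, float]]:
    """(offset, strand, score) hits at score >= threshold, both strands.

    Scores are computed on the same discretized lattice as the threshold so
    the comparison is exact.  Sequences shorter than the motif yield no
    hits; windows containing N are skipped.
    """
    code = _encode(seq)
    out: List[Tuple[int, str, float]] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        q = _discretized_log_odds(mat, grid).astype(float) * grid
        sc = _window_scores(code, q)
        for off in np.flatnonzero(sc >= threshold - 1e-12):
            out.append((int(off), strand, float(sc[off])))
    return sorted(out)


class MotifScanner(BaseEstimator):
    """Threshold calibration and region scanning for one PWM.

    ``fit`` estimates background base frequencies from the supplied
    sequences (pooled, pseudocounted) unless explicit frequencies are given,
    then computes the exact-distribution threshold at tail probability
    ``alpha``.  ``transform`` returns the MotifHit table for a named
    sequence set.

    Attributes
    ----------
    background_ : ndarray of 4 base frequencies
    threshold_ : float, bits
    """

    def __init__(self, pwm: PWM, alpha: float = 1e-4, grid: float = 1e-3):
        self.pwm = pwm
        self.alpha = alpha
        self.grid = grid

    def fit(
        self,
        background_sequences: Optional[Mapping[str, str]] = None,
        background_freqs: Optional[np.ndarray] = None,
    ) -> "MotifScanner":
        if background_freqs is not None:
            bg = np.asarray(background_freqs, dtype=float)
        elif background_sequences:
            counts = np.ones(4)  # pseudocount guards zero frequencies
            for seq in background_sequences.values():
                code = _encode(seq)
                counts += np.bincount(code[code < 4], minlength=4)
            bg = counts
        else:
            bg = UNIFORM_BG.copy()
        self.background_ = bg / bg.sum()
        self._pwm = PWM(
            name=self.pwm.name,
            matrix=self.pwm.matrix,
            consensus=self.pwm.consensus,
            pseudocount=0.0,
            background=self.background_,
        )
        self.threshold_ = exact_score_threshold(
            self._pwm, alpha=self.alpha, grid=self.grid
        )
        return self

    def transform(self, sequences: Mapping[str, str]) -> pd.DataFrame:
        rows = []
        for rid, seq in sequences.items():
            for off, strand, score in scan_sequence(
                seq, self._pwm, self.threshold_, self.grid
            ):
                rows.append(
                    {"region_id": rid, "offset": off, "strand": strand, "score": score}
                )
        return pd.DataFrame(rows, columns=["region_id", "offset", "strand", "score"])

    def hit_regions(self, sequences: Mapping[str, str]) -> set:
        """Region ids with >= 1 hit (vectorized across the sequence set).

        Sequences of equal length are scored as one batched window tensor;
        mixed lengths fall back to per-sequence scoring.
        """
        by_len: Dict[int, List[str]] = {}
        for rid, s in sequences.items():
            by_len.setdefault(len(s), []).append(rid)
        L = len(self._pwm)
        hits: set = set()
        mats = (self._pwm, self._pwm.reverse_complement())
        qs = [
            _discretized_log_odds(m, self.grid).astype(float) * self.grid
            for m in mats
        ]
        for seq_len, group in by_len.items():
            if seq_len < L:
                continue
            codes = np.stack([_encode(sequences[rid]) for rid in group])
            best = np.full(len(group), -np.inf)
            win = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)
            valid = (win != 4).all(axis=2)
            for q in qs:
                qa = np.vstack([q.T, np.full(L, np.nan)]).T  # row 4 -> NaN
                sc = qa[np.arange(L)[None, None, :], win].sum(axis=2)
                sc[~valid] = -np.inf
                if sc.shape[1]:
                    best = np.maximum(best, sc.max(axis=1))
            for rid, b in zip(group, best):
                if b >= self.threshold_ - 1e-12:
                    hits.add(rid)
        return hits


def scan_regions(
    sequences: Mapping[str, str], pwm: PWM, threshold: float, grid: float = 1e-3
) -> pd.DataFrame:
    """MotifHit table for a named sequence set at a fixed threshold."""
    rows = []
    for rid, seq in sequences.items():
        for off, strand, score in scan_sequence(seq, pwm, threshold, grid):
            rows.append(
                {"region_id": rid, "offset": off, "strand": strand, "score": score}
            )
    return pd.DataFrame(rows, columns=["region_id", "offset", "strand", "score"])


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def motif_enrichment(
    target_sequences: Mapping[str, str],
    background_sequences: Mapping[str, str],
    motifs: Sequence[PWM],
    alpha: float = 1e-4,
    grid: float = 1e-3,
    set_label: str = "targets",
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of hit regions in targets vs background.

    Background base frequencies (and hence thresholds) are estimated from
    the pooled background sequences.  BH is applied across motifs.
    """
    if not background_sequences:
        raise ValueError("background sequences must be non-empty")
    records = []
    n_t, n_b = len(target_sequences), len(background_sequences)
    # pooled background base frequencies, shared by every motif
    freq_counts = np.ones(4)
    for seq in background_sequences.values():
        code = _encode(seq)
        freq_counts += np.bincount(code[code < 4], minlength=4)
    bg_freqs = freq_counts / freq_counts.sum()
    for pwm in motifs:
        scanner = MotifScanner(pwm, alpha=alpha, grid=grid).fit(
            background_freqs=bg_freqs
        )
        ht = len(scanner.hit_regions(target_sequences))
        hb = len(scanner.hit_regions(background_sequences))
        odds, p = fisher_two_sided(ht, n_t - ht, hb, n_b - hb)
        records.append(
            EnrichmentRecord(set_label, pwm.name, ht, hb, ht + hb, n_t, n_b, odds, p)
        )
    return _finalize(records)


def chip_enrichment(
    targets: RegionSet,
    background: RegionSet,
    chip_peaks: Mapping[str, RegionSet],
    set_label: str = "targets",
) -> pd.DataFrame:
    """ChIP mode: hit status is >= 1 bp overlap with a TF's peak set."""
    records = []
    n_t, n_b = len(targets), len(background)
    for name in sorted(chip_peaks):
        peaks = chip_peaks[name]
        ht = sum(1 for r in targets if peaks.overlapping(r.chrom, r.start, r.end))
        hb = sum(1 for r in background if peaks.overlapping(r.chrom, r.start, r.end))
        odds, p = fisher_two_sided(ht, n_t - ht, hb, n_b - hb)
        records.append(
            EnrichmentRecord(set_label, name, ht, hb, len(peaks), n_t, n_b, odds, p)
        )
    return _finalize(records)
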