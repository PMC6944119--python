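"""Tandem-repeat array detection, copy-number estimation, and unit consensus.

Arrays are found by k-mer self-distance voting: every pair of nearby identical
k-mers votes for a candidate period at its separation; dense runs of votes at
a stable period become candidate arrays, which are then refined by cutting the
region into unit-length frames, training a column-majority consensus, and
extending frame-by-frame (then base-by-base for partial edge units) while the
per-unit identity stays above the floor.

Copy number is reported real-valued as span/unit_length; the integer "unit
content" used in per-genome histograms is its floor.  When both a period p and
its doubling 2p explain a locus, the smaller period wins if its mean unit
identity is within two percentage points of the larger (canonical minimal
period).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeAssembly, GenomicInterval
from .homology_search import encode, kmer_codes


@dataclass
class TandemArray:
    """A detected tandem-repeat array."""

    interval: GenomicInterval
    unit_length: int
    copy_number: float
    unit_consensus: str
    mean_unit_identity: float

    @property
    def unit_content(self) -> int:
        """Integer unit count (floor of the real-valued copy number)."""
        return int(self.copy_number)


def _period_votes(seq_arr: np.ndarray, k: int, min_unit: int,
                  max_unit: int) -> tuple[np.ndarray, np.ndarray]:
    """(position, lag) pairs of identical k-mers separated by a plausible period."""
    codes = kmer_codes(seq_arr, k)
    if codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    pos_list, lag_list = [], []
    # consecutive occurrences of each k-mer, vectorised over the sorted array
    same = sorted_codes[1:] == sorted_codes[:-1]
    valid = sorted_codes[1:] >= 0
    # within a code group, argsort(stable) keeps positions ascending
    p0, p1 = order[:-1], order[1:]
    lag = p1 - p0
    keep = same & valid & (lag >= min_unit) & (lag <= max_unit)
    return p0[keep], lag[keep]


def _majority_consensus(frames: list[str]) -> str:
    cols = np.array([encode(f) for f in frames])
    consensus = []
    for j in range(cols.shape[1]):
        vals, counts = np.unique(cols[:, j], return_counts=True)
        best = vals[np.argmax(counts)]
        consensus.append("ACGTN"[best])
    return "".join(consensus)


def _frame_identity(frame: str, consensus: str) -> float:
    a = np.frombuffer(frame.encode(), np.uint8)
    b = np.frombuffer(consensus.encode(), np.uint8)
    n = min(a.size, b.size)
    if n == 0:
        return 0.0
    return float(np.count_nonzero(a[:n] == b[:n])) / n


def _refine_candidate(seq: str, region_start: int, region_end: int, period: int,
                      min_copies: float, min_unit_identity: float):
    """Fit an array of the given period inside a candidate region.

    Returns (start, end, consensus, mean_identity, copy_number) or None.
    """
    n = len(seq)
    region_start = max(0, region_start)
    region_end = min(n, region_end)
    # votes only start inside the first unit copy, so a 2-copy array yields a
    # vote span of barely one period: one full frame is enough to seed the
    # consensus, extension recovers the rest
    if region_end - region_start < period:
        return None
    frames = [seq[s : s + period]
              for s in range(region_start, region_end - period + 1, period)]
    full = [f for f in frames if len(f) == period]
    if not full:
        return None
    consensus = _majority_consensus(full)

    # phase search: best placement of the consensus near the region start
    best_s, best_id = region_start, -1.0
    for s in range(max(0, region_start - period), min(region_start + period, n - period) + 1):
        ident = _frame_identity(seq[s : s + period], consensus)
        if ident > best_id:
            best_id, best_s = ident, s

    # frame-by-frame extension in both directions while identity holds
    start = best_s
    while start - period >= 0 and _frame_identity(
            seq[start - period : start], consensus) >= min_unit_identity:
        start -= period
    end = best_s + period
    while end + period <= n and _frame_identity(
            seq[end : end + period], consensus) >= min_unit_identity:
        end += period
    if (end - start) // period < 2:
        return None

    # retrain consensus on the fitted frames
    full = [seq[s : s + period] for s in range(start, end - period + 1, period)]
    consensus = _majority_consensus(full)

    # edge refinement: score each possible boundary within one unit of the
    # frame edges (+1 match / -1 mismatch against the phased consensus) and
    # take the maximum -- tolerates scattered mutations near the edge while
    # trimming any background spill inside the outermost frames
    anchor = start
    right_lo = max(anchor + period, end - period)
    right_hi = min(n, end + period)
    best_score, best_e, score = 0.0, right_lo, 0.0
    for i in range(right_lo, right_hi):
        score += 1.0 if seq[i] == consensus[(i - anchor) % period] else -1.0
        if score > best_score:
            best_score, best_e = score, i + 1
    end = best_e
    left_hi = min(end - period, anchor + period)
    left_lo = max(0, start - period)
    best_score, best_s, score = 0.0, left_hi, 0.0
    for i in range(left_hi - 1, left_lo - 1, -1):
        score += 1.0 if seq[i] == consensus[(i - anchor) % period] else -1.0
        if score > best_score:
            best_score, best_s = score, i
    start = best_s

    idents = [_frame_identity(seq[s : s + period], consensus)
              for s in range(anchor, end - period + 1, period)]
    mean_ident = float(np.mean(idents)) if idents else 0.0
    copy_number = (end - start) / period
    # a mutated terminal base can trim the span a hair below an integer copy
    # count; allow a tenth of a unit of slack on the floor
    if copy_number < min_copies - 0.1 or mean_ident < min_unit_identity:
        return None
    return start, end, consensus, mean_ident, copy_number


def detect_arrays(seq: str, min_unit: int = 10, max_unit: int = 2000,
                  min_copies: float = 2.0, min_unit_identity: float = 0.80,
                  chrom: str = "seq", k: int | None = None) -> list[TandemArray]:
    """Detect maximal non-overlapping tandem arrays in ``seq``.

    ``min_unit`` must be >= 10 (microsatellites are out of scope).  Returns an
    empty list when nothing qualifies.
    """
    if min_unit < 10:
        raise ValueError("min_unit must be >= 10 (microsatellite periods excluded)")
    if max_unit < min_unit:
        raise ValueError("max_unit must be >= min_unit")
    seq = seq.upper()
    if k is None:
        k = min(12, min_unit)
    arr = encode(seq)
    if arr.size < 2 * min_unit:
        return []
    pos, lag = _period_votes(arr, k, min_unit, max_unit)
    if pos.size == 0:
        return []
    order = np.argsort(pos, kind="stable")
    pos, lag = pos[order], lag[order]

    # split votes into regions wherever the positional gap exceeds max_unit
    split = np.nonzero(np.diff(pos) > max_unit)[0] + 1
    candidates = []
    for p_seg, l_seg in zip(np.split(pos, split), np.split(lag, split)):
        if p_seg.size < 2:
            continue
        # bin lags (+-2) and try the well-supported periods, smallest first
        counts = Counter(int(x) for x in l_seg)
        binned: Counter[int] = Counter()
        for val, c in counts.items():
            rep = max((v for v in counts if abs(v - val) <= 2),
                      key=lambda v: counts[v])
            binned[rep] += c
        top = max(binned.values())
        periods = sorted(p for p, c in binned.items() if c >= max(2, 0.3 * top))
        region = (int(p_seg.min()), int(p_seg.max()) + int(l_seg.max()) + k)
        fits = []
        for period in periods[:5]:
            fit = _refine_candidate(seq, region[0], region[1], period,
                                    min_copies, min_unit_identity)
            if fit is not None:
                fits.append(fit)
        if not fits:
            continue
        # minimal-period preference: smallest period within 2 identity points
        best_ident = max(f[3] for f in fits)
        fits.sort(key=lambda f: len(f[2]))
        chosen = next(f for f in fits if f[3] >= best_ident - 0.02)
        candidates.append(chosen)

    # greedy non-overlap selection, longest spans first
    candidates.sort(key=lambda f: -(f[1] - f[0]))
    kept: list[tuple] = []
    for c in candidates:
        if all(c[1] <= g[0] or c[0] >= g[1] for g in kept):
            kept.append(c)
    kept.sort(key=lambda f: f[0])
    return [
        TandemArray(
            interval=GenomicInterval(chrom, s, e, "+"),
            unit_length=len(cons),
            copy_number=cn,
            unit_consensus=cons,
            mean_unit_identity=ident,
        )
        for s, e, cons, ident, cn in kept
    ]


def detect_arrays_genome(assembly: GenomeAssembly, **kwargs) -> list[TandemArray]:
    """Run :func:`detect_arrays` over every chromosome of an assembly."""
    arrays: list[TandemArray] = []
    for chrom in assembly.chromosomes:
        arrays.extend(detect_arrays(chrom.sequence, chrom=chrom.id, **kwargs))
    return arrays


def train_unit_consensus(array: TandemArray, seq: str,
                         max_shift: int = 2) -> str:
    """Column-majority unit consensus, refined by one realignment pass.

    Frames are cut at unit-length boundaries, each frame is re-anchored to the
    current consensus by the small shift (<= ``max_shift``) maximising matches,
    and the column majority is recomputed once if the consensus changed.
    """
    p = array.unit_length
    start, end = array.interval.start, array.interval.end
    consensus = array.unit_consensus or ""
    frames = [seq[s : s + p] for s in range(start, end - p + 1, p)]
    frames = [f for f in frames if len(f) == p]
    if not frames:
        return consensus
    if not consensus:
        consensus = _majority_consensus(frames)
    for _ in range(2):
        aligned = []
        for i, f in enumerate(frames):
            best_f, best_id = f, _frame_identity(f, consensus)
            for shift in range(-max_shift, max_shift + 1):
                s = start + i * p + shift
                if shift == 0 or s < 0 or s + p > len(seq):
                    continue
                cand = seq[s : s + p]
                ident = _frame_identity(cand, consensus)
                if ident > best_id:
                    best_id, best_f = ident, cand
            aligned.append(best_f)
        new = _majority_consensus(aligned)
        if new == consensus:
            break
        consensus = new
    return consensus


def self_similarity_matrix(seq: str, k: int = 8) -> np.ndarray:
    """Binary dot-plot of exact k-word matches (symmetric; tandem arrays show
    as off-diagonal stripes at lags that are multiples of the unit length)."""
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence shorter than word size k={k}")
    codes = kmer_codes(encode(seq), k)
    valid = codes >= 0
    m = (codes[:, None] == codes[None, :]) & valid[:, None] & valid[None, :]
    return m
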