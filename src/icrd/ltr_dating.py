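"""Paired-LTR detection, K2P divergence, insertion dating, and LTR families.

An LTR retrotransposon's two terminal repeats are identical at insertion and
diverge afterwards, so the Kimura two-parameter distance d between the paired
LTRs converts to an insertion age T = d/(2r) at substitution rate r per site
per year (each LTR accumulates r*T).  Elements whose LTR pair cannot be
recovered (degraded ends, saturated divergence) are reported unpaired and
excluded from dating but kept in all other outputs.

P (transition proportion) and Q (transversion proportion) are computed over
ungapped aligned columns only, excluding columns containing N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .genome_io import GenomeAssembly, GenomicInterval, extract_interval
from .homology_search import SearchParams, _make_aligner, encode, kmer_codes


class SaturatedDivergenceError(ValueError):
    """The observed P/Q proportions are outside the K2P domain."""


@dataclass
class DatingConfig:
    rate: float = 1.3e-8           # substitutions / site / year
    min_ltr: int = 100
    max_ltr: int = 3_000
    min_element: int = 1_000
    max_element: int = 15_000
    ltr_similarity_floor: float = 0.70

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if not self.min_ltr < self.max_ltr:
            raise ValueError("min_ltr must be < max_ltr")


@dataclass
class LTRPair:
    """A dated (or undatable) element with its paired terminal repeats."""

    element_id: str
    element: GenomicInterval
    left_ltr: GenomicInterval | None
    right_ltr: GenomicInterval | None
    P: float | None = None
    Q: float | None = None
    d: float | None = None
    age_years: float | None = None
    ltr_identity: float | None = None

    @property
    def paired(self) -> bool:
        return self.left_ltr is not None and self.right_ltr is not None

    @property
    def dated(self) -> bool:
        return self.age_years is not None


@dataclass
class TEFamily:
    members: list[str]
    representative: str


# ---------------------------------------------------------------------------
# K2P distance and dating formulas
# ---------------------------------------------------------------------------

def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance d = -1/2 * ln[(1-2P-Q) * sqrt(1-2Q)].

    Raises :class:`SaturatedDivergenceError` when the proportions leave the
    model's domain (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative proportions")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(
            f"saturated divergence: P={P:.4f}, Q={Q:.4f} outside the K2P domain"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(d: float, r: float = 1.3e-8) -> float:
    """Insertion age T = d / (2 r) in years."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if d < 0:
        raise ValueError("distance d must be non-negative")
    return d / (2.0 * r)


# ---------------------------------------------------------------------------
# P/Q counting from alignments
# ---------------------------------------------------------------------------

def _pq_from_alignment(alignment, seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """(P, Q, identity) over ungapped, N-free aligned columns."""
    blocks_a, blocks_b = alignment.aligned
    ts = tv = same = total = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        a = encode(seq_a[as_:ae])
        b = encode(seq_b[bs:be])
        valid = (a < 4) & (b < 4)
        a, b = a[valid], b[valid]
        diff = a ^ b
        ts += int(np.count_nonzero(diff == 2))
        same += int(np.count_nonzero(diff == 0))
        total += a.size
    tv = total - ts - same
    if total == 0:
        return 0.0, 0.0, 0.0
    return ts / total, tv / total, same / total


def _dating_aligner() -> Align.PairwiseAligner:
    # Stiff gap costs: paired LTRs diverge almost exclusively by substitution,
    # and cheap gaps would buy spurious matches at high divergence, biasing
    # P/Q (hence d and T) downward.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -2
    return aligner


def substitution_proportions(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Globally align two homologous sequences and return (P, Q, identity)."""
    aligner = _dating_aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return _pq_from_alignment(alignment, seq_a.upper(), seq_b.upper())


def date_ltr_sequences(left: str, right: str, rate: float = 1.3e-8) -> tuple[float, float, float, float]:
    """Estimate (P, Q, d, T) from a pair of LTR copies.

    Raises :class:`SaturatedDivergenceError` when the divergence exceeds the
    K2P domain; callers should then report the element as undatable.
    """
    P, Q, _ident = substitution_proportions(left, right)
    d = k2p_distance(P, Q)
    return P, Q, d, insertion_time(d, rate)


# ---------------------------------------------------------------------------
# Paired-repeat detection inside candidate elements
# ---------------------------------------------------------------------------

def _direct_repeat_pair(seq: str, cfg: DatingConfig, k: int = 12,
                        anchor: tuple[int, int] | None = None):
    """Best pair of similar, disjoint direct repeats in ``seq``.

    Returns ((a_start, a_end), (b_start, b_end), P, Q, identity) or None.
    Seeds at long lags are clustered by diagonal; each cluster is scored by a
    local alignment of the two implied windows.  When ``anchor`` is given the
    two repeats must bracket it (one wholly left, one wholly right) -- the
    terminal repeats of a host element flank its internal anchor, and this
    keeps internal tandem-unit copies from masquerading as the pair.
    """
    arr = encode(seq)
    codes = kmer_codes(arr, k)
    if codes.size == 0:
        return None
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    # all pairs of equal k-mers: for each group take consecutive-pair lags
    # plus first-to-each lags; groups are tiny for non-repetitive candidates
    groups: list[np.ndarray] = []
    start = 0
    for i in range(1, sc.size + 1):
        if i == sc.size or sc[i] != sc[i - 1]:
            if i - start >= 2 and sc[start] >= 0:
                groups.append(np.sort(order[start:i]))
            start = i
    min_lag = max(cfg.min_ltr, 300)
    pairs = []
    for g in groups:
        if g.size > 50:       # low-complexity k-mer; skip
            continue
        for ai in range(g.size):
            for bi in range(ai + 1, g.size):
                lag = int(g[bi] - g[ai])
                if not (min_lag <= lag <= cfg.max_element):
                    continue
                if anchor is not None and not (g[ai] + k <= anchor[0]
                                               and g[bi] >= anchor[1]):
                    continue
                pairs.append((int(g[ai]), lag))
    if not pairs:
        return None
    pairs.sort(key=lambda t: (t[1], t[0]))
    # cluster by lag (diagonal), then by position
    clusters: list[list[tuple[int, int]]] = []
    for pos, lag in pairs:
        if (clusters and abs(lag - clusters[-1][-1][1]) <= 30
                and pos - clusters[-1][-1][0] <= cfg.max_ltr):
            clusters[-1].append((pos, lag))
        else:
            clusters.append([(pos, lag)])

    p = SearchParams()
    aligner = _make_aligner(p)
    best = None
    pad = 100
    for cl in clusters:
        a_lo = max(0, min(pos for pos, _ in cl) - pad)
        a_hi = min(len(seq), max(pos for pos, _ in cl) + k + pad)
        lag = int(np.median([lag for _, lag in cl]))
        b_lo = max(0, a_lo + lag - pad)
        b_hi = min(len(seq), a_hi + lag + pad)
        if b_lo >= b_hi or a_lo >= a_hi:
            continue
        win_a, win_b = seq[a_lo:a_hi], seq[b_lo:b_hi]
        alignment = aligner.align(win_a, win_b)[0]
        blocks_a, blocks_b = alignment.aligned
        if len(blocks_a) == 0:
            continue
        a_start = a_lo + int(blocks_a[0][0])
        a_end = a_lo + int(blocks_a[-1][1])
        b_start = b_lo + int(blocks_b[0][0])
        b_end = b_lo + int(blocks_b[-1][1])
        rep_len = max(a_end - a_start, b_end - b_start)
        if not (cfg.min_ltr <= rep_len <= cfg.max_ltr):
            continue
        if a_end > b_start:   # repeats must be disjoint (excludes tandem arrays)
            continue
        if anchor is not None and not (a_end <= anchor[0] and b_start >= anchor[1]):
            continue
        span = b_end - a_start
        if not (cfg.min_element <= span <= cfg.max_element):
            continue
        P, Q, ident = _pq_from_alignment(alignment, win_a, win_b)
        if ident < cfg.ltr_similarity_floor:
            continue
        score = float(alignment.score)
        if best is None or score > best[0]:
            best = (score, (a_start, a_end), (b_start, b_end), P, Q, ident)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4], best[5]


def detect_ltr_pairs(genome: GenomeAssembly,
                     candidates: Sequence[GenomicInterval],
                     cfg: DatingConfig | None = None,
                     flank: int = 4_000,
                     ids: Sequence[str] | None = None) -> list[LTRPair]:
    """Find the paired flanking LTRs of each candidate element and date them.

    Each candidate interval is expanded by ``flank`` bases on both sides and
    scanned for its highest-scoring pair of similar direct repeats within the
    configured length/spacing bounds.  Elements without a qualifying pair are
    returned unpaired; pairs whose divergence saturates the K2P model are
    returned paired but undated.
    """
    cfg = cfg or DatingConfig()
    out: list[LTRPair] = []
    for i, iv in enumerate(candidates):
        eid = ids[i] if ids is not None else f"element_{i + 1:03d}"
        chrom = genome[iv.chrom]
        lo = max(0, iv.start - flank)
        hi = min(chrom.length, iv.end + flank)
        seq = chrom.sequence[lo:hi]
        found = _direct_repeat_pair(seq, cfg, anchor=(iv.start - lo, iv.end - lo))
        if found is None:
            out.append(LTRPair(element_id=eid, element=iv,
                               left_ltr=None, right_ltr=None))
            continue
        (a_s, a_e), (b_s, b_e), P, Q, ident = found
        left = GenomicInterval(iv.chrom, lo + a_s, lo + a_e, "+")
        right = GenomicInterval(iv.chrom, lo + b_s, lo + b_e, "+")
        element = GenomicInterval(iv.chrom, left.start, right.end, iv.strand)
        try:
            d = k2p_distance(P, Q)
            age = insertion_time(d, cfg.rate)
        except SaturatedDivergenceError:
            d = age = None
        out.append(LTRPair(element_id=eid, element=element, left_ltr=left,
                           right_ltr=right, P=P, Q=Q, d=d, age_years=age,
                           ltr_identity=ident))
    return out


# ---------------------------------------------------------------------------
# LTR family clustering (80-80 single linkage)
# ---------------------------------------------------------------------------

def cluster_families(ltr_seqs: Sequence[str], ids: Sequence[str] | None = None,
                     min_identity: float = 0.80,
                     min_coverage: float = 0.80) -> list[TEFamily]:
    """Single-linkage clustering: two LTRs link iff one local alignment covers
    >=80% of *both* sequences at >=80% identity.  Returns a partition."""
    n = len(ltr_seqs)
    if n == 0:
        raise ValueError("cluster_families requires at least one sequence")
    ids = list(ids) if ids is not None else [f"LTR_{i + 1:03d}" for i in range(n)]
    aligner = _make_aligner(SearchParams())
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ltr_seqs[i].upper(), ltr_seqs[j].upper()
            alignment = aligner.align(a, b)[0]
            blocks_a, blocks_b = alignment.aligned
            if len(blocks_a) == 0:
                continue
            span_a = int(blocks_a[-1][1] - blocks_a[0][0])
            span_b = int(blocks_b[-1][1] - blocks_b[0][0])
            matches = 0
            ungapped = 0
            for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
                av = encode(a[as_:ae])
                bv = encode(b[bs:be])
                matches += int(np.count_nonzero((av == bv) & (av < 4)))
                ungapped += ae - as_
            gap_cols = (span_a - ungapped) + (span_b
                        - sum(int(e - s) for s, e in blocks_b))
            cols = ungapped + gap_cols
            identity = matches / cols if cols else 0.0
            if (identity >= min_identity
                    and span_a / len(a) >= min_coverage
                    and span_b / len(b) >= min_coverage):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    families = [TEFamily(members=[ids[i] for i in sorted(g)],
                         representative=ids[min(g)])
                for g in groups.values()]
    families.sort(key=lambda f: f.representative)
    return families


# ---------------------------------------------------------------------------
# Activity histogram
# ---------------------------------------------------------------------------

def activity_histogram(pairs: Sequence[LTRPair], bin_width_years: float = 5.0e6,
                       max_age_years: float | None = None) -> dict:
    """Histogram of insertion ages over uniform bins; undated pairs counted
    separately."""
    if bin_width_years <= 0:
        raise ValueError("bin width must be positive")
    ages = np.array([p.age_years for p in pairs if p.age_years is not None])
    n_undated = sum(1 for p in pairs if p.age_years is None)
    if max_age_years is None:
        max_age_years = float(ages.max()) if ages.size else 0.0
    # bins are half-open [lo, hi); extend one bin past the oldest age so the
    # maximum never lands on a closed upper edge
    n_bins = int(math.floor(max_age_years / bin_width_years)) + 1
    edges = np.arange(n_bins + 1) * bin_width_years
    counts, _ = np.histogram(ages, bins=edges)
    return {"bin_edges_years": edges.tolist(),
            "counts": counts.tolist(),
            "n_dated": int(ages.size),
            "n_undated": n_undated}


def pairs_to_table(pairs: Sequence[LTRPair]) -> str:
    """TSV: element id, coordinates, P, Q, d, T (1-based inclusive coords)."""
    header = "element_id\telement\tleft_ltr\tright_ltr\tP\tQ\td\tT_years\tltr_identity\n"
    rows = []
    for p in pairs:
        fmt = lambda x, spec="{:.5f}": "." if x is None else spec.format(x)
        rows.append("\t".join([
            p.element_id, p.element.render_1based(),
            p.left_ltr.render_1based() if p.left_ltr else ".",
            p.right_ltr.render_1based() if p.right_ltr else ".",
            fmt(p.P), fmt(p.Q), fmt(p.d),
            fmt(p.age_years, "{:.0f}"), fmt(p.ltr_identity, "{:.3f}"),
        ]))
    return header + "\n".join(rows) + ("\n" if rows else "")
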