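"""Seed-and-extend local homology search and the 80-80 presence/absence screen.

The search finds local alignments of a query against every chromosome of an
assembly, on both strands: exact k-mer seeds are clustered by diagonal, each
cluster is extended by a local dynamic-programming alignment over a bounded
target window (Bio.Align.PairwiseAligner, affine gap costs), and overlapping
hits at one locus are merged.  Hits carry identity and query coverage so that
the 80-80 family rule (aligned over >=80% of the query at >=80% identity,
boundaries inclusive) can classify a repeat as present, absent, or shared
between two genomes.

N bases never seed and never count as matches, so they behave as mismatches
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .genome_io import GenomeAssembly, Chromosome, GenomicInterval, reverse_complement

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing N get code -1."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = arr[j : j + n]
        codes = codes * 4 + col
        valid &= col < 4
    codes[~valid] = -1
    return codes


@dataclass(frozen=True)
class SearchParams:
    """Tuning knobs of the bespoke search (BLASTN-like desk-scale defaults)."""

    k: int = 12                  # seed word size
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2           # charged on the first gapped column
    gap_extend: int = -1
    xdrop: int = 20              # extension slack; sizes the DP window padding
    min_score: int = 25
    max_kmer_hits: int = 2000    # skip seeds from k-mers more frequent than this
    diag_merge: int = 50         # seeds within this diagonal offset cluster together
    seed_gap: int | None = None  # max target gap between clustered seeds (default: query length)
    max_single_seed_extensions: int = 20000
    # skip gapped extension for clusters whose best ungapped diagonal segment
    # scores below min(min_score, ungapped_trigger); None disables the filter
    # (exhaustive extension of every seed cluster)
    ungapped_trigger: int | None = 25


@dataclass
class AlignmentHit:
    """One gapped local alignment of a query against a target locus."""

    query_interval: GenomicInterval
    target_interval: GenomicInterval
    strand: str
    score: float
    matches: int
    mismatches: int
    gap_columns: int
    query_length: int

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.matches / cols if cols else 0.0

    @property
    def query_coverage(self) -> float:
        return self.query_interval.length / self.query_length


def _make_aligner(p: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    # PairwiseAligner's open score is charged instead of (not on top of) the
    # extend score for the first gap column: open = gap_open + gap_extend.
    aligner.open_gap_score = p.gap_open + p.gap_extend
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _seed_matches(q_codes: np.ndarray, t_codes: np.ndarray,
                  max_kmer_hits: int) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, target_pos) pairs whose k-mers are identical."""
    order = np.argsort(t_codes, kind="stable")
    t_sorted = t_codes[order]
    lo = np.searchsorted(t_sorted, q_codes, side="left")
    hi = np.searchsorted(t_sorted, q_codes, side="right")
    counts = hi - lo
    keep = (q_codes >= 0) & (counts > 0) & (counts <= max_kmer_hits)
    qpos_list, tpos_list = [], []
    for q in np.nonzero(keep)[0]:
        tpos_list.append(order[lo[q] : hi[q]])
        qpos_list.append(np.full(hi[q] - lo[q], q, dtype=np.int64))
    if not qpos_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(qpos_list), np.concatenate(tpos_list)


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, qlen: int,
                   p: SearchParams) -> list[tuple[int, int, int, int]]:
    """Group seeds into diagonal clusters.

    Returns (t_lo, t_hi, n_seeds, modal_diagonal) windows in target
    coordinates; windows covering one locus are merged across diagonals.
    """
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag, tpos_s, qpos_s = diag[order], tpos[order], qpos[order]
    seed_gap = p.seed_gap if p.seed_gap is not None else max(qlen, 200)
    clusters: list[tuple[int, int, int, int]] = []
    start = 0
    n = diag.size
    for i in range(1, n + 1):
        if (i == n or diag[i] - diag[i - 1] > p.diag_merge
                or (diag[i] == diag[i - 1] and tpos_s[i] - tpos_s[i - 1] > seed_gap)):
            t_lo = int(tpos_s[start:i].min() - qpos_s[start:i].max())
            t_hi = int(tpos_s[start:i].max() + (qlen - qpos_s[start:i].min()))
            vals, cnts = np.unique(diag[start:i], return_counts=True)
            clusters.append((t_lo, t_hi, i - start, int(vals[np.argmax(cnts)])))
            start = i
    # merge clusters whose target windows overlap (nearby diagonals, one locus)
    clusters.sort()
    merged: list[list[int]] = []
    for t_lo, t_hi, ns, d0 in clusters:
        if merged and t_lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t_hi)
            if ns > merged[-1][2]:
                merged[-1][3] = d0
            merged[-1][2] += ns
        else:
            merged.append([t_lo, t_hi, ns, d0])
    return [tuple(m) for m in merged]


def _ungapped_diagonal_score(q_arr: np.ndarray, t_arr: np.ndarray, diag: int,
                             p: SearchParams) -> float:
    """Best ungapped segment score along one diagonal (match/mismatch only).

    A lower bound on the best gapped alignment score through that diagonal;
    used to skip the expensive DP for seed clusters that cannot reach
    ``min_score`` without gapped joins across distant diagonals.
    """
    qlen, tlen = q_arr.size, t_arr.size
    j_lo = max(0, -diag)
    j_hi = min(qlen, tlen - diag)
    if j_hi <= j_lo:
        return 0.0
    q = q_arr[j_lo:j_hi]
    t = t_arr[j_lo + diag : j_hi + diag]
    contrib = np.where((q == t) & (q < 4), float(p.match), float(p.mismatch))
    s = np.cumsum(contrib)
    run_min = np.minimum.accumulate(np.concatenate(([0.0], s[:-1])))
    return float(np.max(s - run_min))


def _hit_from_alignment(alignment, window_start: int, chrom_id: str, strand: str,
                        window_seq: str, qseq: str, qlen: int) -> AlignmentHit | None:
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return None
    matches = mismatches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        a = np.frombuffer(window_seq[ts:te].encode(), dtype=np.uint8)
        b = np.frombuffer(qseq[qs:qe].encode(), dtype=np.uint8)
        eq = int(np.count_nonzero(a == b))
        matches += eq
        mismatches += (te - ts) - eq
    gap_columns = 0
    for j in range(1, len(t_blocks)):
        gap_columns += int(t_blocks[j][0] - t_blocks[j - 1][1])
        gap_columns += int(q_blocks[j][0] - q_blocks[j - 1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    if strand == "-":
        q_start, q_end = qlen - q_end, qlen - q_start
    return AlignmentHit(
        query_interval=GenomicInterval("query", q_start, q_end, "+"),
        target_interval=GenomicInterval(
            chrom_id, window_start + t_start, window_start + t_end, strand
        ),
        strand=strand,
        score=float(alignment.score),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gap_columns,
        query_length=qlen,
    )


def _search_chromosome(qseq_fwd: str, chrom: Chromosome,
                       p: SearchParams, aligner) -> list[AlignmentHit]:
    qlen = len(qseq_fwd)
    t_arr = encode(chrom.sequence)
    t_codes = kmer_codes(t_arr, p.k)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        qseq = qseq_fwd if strand == "+" else reverse_complement(qseq_fwd)
        q_codes = kmer_codes(encode(qseq), p.k)
        qpos, tpos = _seed_matches(q_codes, t_codes, p.max_kmer_hits)
        if qpos.size == 0:
            continue
        q_arr = encode(qseq)
        clusters = _cluster_seeds(qpos, tpos, qlen, p)
        if len(clusters) > p.max_single_seed_extensions:
            clusters = [c for c in clusters if c[2] >= 2]
        if p.ungapped_trigger is not None:
            trigger = min(p.ungapped_trigger, p.min_score)
            clusters = [c for c in clusters
                        if _ungapped_diagonal_score(q_arr, t_arr, c[3], p)
                        >= trigger]
        pad = qlen // 4 + p.xdrop
        for t_lo, t_hi, _ns, _d0 in clusters:
            w_lo = max(0, t_lo - pad)
            w_hi = min(chrom.length, t_hi + pad)
            window_seq = chrom.sequence[w_lo:w_hi]
            alignments = aligner.align(window_seq, qseq)
            if alignments.score < p.min_score:
                continue
            hit = _hit_from_alignment(alignments[0], w_lo, chrom.id, strand,
                                      window_seq, qseq, qlen)
            if hit is not None:
                hits.append(hit)
    return _dedupe(hits)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best hit per locus: drop hits mostly covered by a better one."""
    hits.sort(key=lambda h: -h.score)
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.strand != h.strand or g.target_interval.chrom != h.target_interval.chrom:
                continue
            ov = (min(g.target_interval.end, h.target_interval.end)
                  - max(g.target_interval.start, h.target_interval.start))
            if ov > 0.5 * h.target_interval.length:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (-h.score, h.target_interval.chrom,
                             h.target_interval.start))
    return kept


def search(query: str, target: GenomeAssembly,
           params: SearchParams | None = None) -> list[AlignmentHit]:
    """Find local alignments of ``query`` in ``target`` on both strands.

    Returns hits sorted by score (descending).  Raises ``ValueError`` when the
    query is shorter than the seed size.
    """
    p = params or SearchParams()
    query = query.upper()
    if len(query) < p.k:
        raise ValueError(f"query length {len(query)} is shorter than seed size k={p.k}")
    aligner = _make_aligner(p)
    hits: list[AlignmentHit] = []
    for chrom in target.chromosomes:
        if chrom.length >= p.k:
            hits.extend(_search_chromosome(query, chrom, p, aligner))
    hits.sort(key=lambda h: (-h.score, h.target_interval.chrom,
                             h.target_interval.start))
    return hits


def search_sequence(query: str, target_seq: str, target_id: str = "target",
                    params: SearchParams | None = None) -> list[AlignmentHit]:
    """Convenience wrapper: search against a single bare sequence."""
    asm = GenomeAssembly(name=target_id,
                         chromosomes=[Chromosome(target_id, target_seq.upper())])
    return search(query, asm, params)


# ---------------------------------------------------------------------------
# 80-80 rule and the genome-specificity screen
# ---------------------------------------------------------------------------

def passes_80_80(hit: AlignmentHit, min_identity: float = 0.80,
                 min_coverage: float = 0.80) -> bool:
    """True iff identity >= 80% and query coverage >= 80% (inclusive)."""
    return hit.identity >= min_identity and hit.query_coverage >= min_coverage


@dataclass
class ScreenResult:
    """Per-query outcome of the two-genome presence/absence screen."""

    query_name: str
    classification: str          # "specific" | "shared" | "absent"
    hits_present: int            # 80-80-passing hit count in the first genome
    hits_absent: int             # ... in the second genome
    per_chromosome_present: dict[str, int] = field(default_factory=dict)
    per_chromosome_absent: dict[str, int] = field(default_factory=dict)


def screen_genome_specific(queries: dict[str, str] | Sequence[str],
                           present_in: GenomeAssembly,
                           absent_from: GenomeAssembly,
                           params: SearchParams | None = None,
                           min_identity: float = 0.80,
                           min_coverage: float = 0.80) -> list[ScreenResult]:
    """Classify each query as genome-specific, shared, or absent.

    ``specific``: >=1 passing hit in ``present_in`` and none in ``absent_from``;
    ``shared``: passing hits in both; ``absent``: passing hits in neither.
    """
    if not queries:
        raise ValueError("screen requires at least one query")
    if not isinstance(queries, dict):
        queries = {f"query_{i + 1}": q for i, q in enumerate(queries)}
    results = []
    for name, seq in queries.items():
        counts = {}
        for label, asm in (("present", present_in), ("absent", absent_from)):
            hits = [h for h in search(seq, asm, params)
                    if passes_80_80(h, min_identity, min_coverage)]
            per_chrom: dict[str, int] = {c: 0 for c in asm.ids()}
            for h in hits:
                per_chrom[h.target_interval.chrom] += 1
            counts[label] = (len(hits), per_chrom)
        n_p, n_a = counts["present"][0], counts["absent"][0]
        if n_p and not n_a:
            cls = "specific"
        elif n_p and n_a:
            cls = "shared"
        else:
            cls = "absent"
        results.append(ScreenResult(
            query_name=name, classification=cls,
            hits_present=n_p, hits_absent=n_a,
            per_chromosome_present=counts["present"][1],
            per_chromosome_absent=counts["absent"][1],
        ))
    return results


def hits_to_table(hits: Sequence[AlignmentHit], query_name: str = "query") -> str:
    """BLAST outfmt-6-like TSV (1-based inclusive coordinates)."""
    lines = []
    for h in hits:
        qi, ti = h.query_interval, h.target_interval
        lines.append("\t".join(str(x) for x in (
            query_name, ti.chrom, f"{100 * h.identity:.2f}", h.aligned_columns,
            h.mismatches, h.gap_columns, qi.start + 1, qi.end,
            ti.start + 1 if h.strand == "+" else ti.end,
            ti.end if h.strand == "+" else ti.start + 1,
            f"{h.query_coverage:.3f}", f"{h.score:g}",
        )))
    return "\n".join(lines) + ("\n" if lines else "")
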