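"""The composite motif: definition, genome-wide constituent calling, pairing,
and the consensus-accumulation histogram.

A motif instance is a tandem-repeat (TR) array whose unit matches the family
unit consensus, adjacent (within ``max_gap``) to a hit of the family's
conserved sequence (CS) on the same chromosome and strand.  Constituents are
called independently -- TR arrays by tandem detection plus an 80-80 unit-
consensus membership check (rotation- and strand-aware), CS copies by
homology search plus the 80-80 rule -- and then paired greedily by smallest
gap.  Unpaired constituents are reported as lone insertions, mirroring the
observation that solitary TR and CS copies far outnumber complete motifs.

The consensus-accumulation histogram stacks many host-element sequences
against one reference by star alignment and counts, per reference column, how
many instances agree with the column majority: a conserved core inside
otherwise degraded elements shows up as a contiguous high-agreement plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .genome_io import Feature, GenomeAssembly, GenomicInterval, reverse_complement
from .homology_search import (
    AlignmentHit,
    SearchParams,
    _make_aligner,
    encode,
    passes_80_80,
    search,
)
from .tandem_repeats import TandemArray, detect_arrays_genome


@dataclass
class MotifDefinition:
    """Family consensus sequences plus the pairing geometry."""

    unit_consensus: str
    cs_consensus: str
    max_gap: int = 200
    min_units: int = 2

    def __post_init__(self) -> None:
        if not self.unit_consensus or not self.cs_consensus:
            raise ValueError("both consensus sequences must be non-empty")


@dataclass
class TRHit:
    """A tandem array assigned to the motif family."""

    array: TandemArray
    strand: str               # '+', '-' or '.' when orientation is ambiguous
    unit_identity_to_family: float

    @property
    def interval(self) -> GenomicInterval:
        return self.array.interval


@dataclass
class MotifInstance:
    """A paired TR array + CS copy forming one full motif."""

    tr: TRHit
    cs: AlignmentHit
    orientation: str
    unit_count: int
    full_interval: GenomicInterval
    gap: int


@dataclass
class PairingResult:
    instances: list[MotifInstance]
    lone_tr: list[TRHit]
    lone_cs: list[AlignmentHit]


@dataclass
class ConsensusHistogram:
    """Per-reference-column agreement counts from a star alignment."""

    columns: np.ndarray          # agreement count per reference position
    n_instances: int
    consensus: str = ""


# ---------------------------------------------------------------------------
# Constituent scanning
# ---------------------------------------------------------------------------

def _unit_family_membership(unit: str, family_unit: str,
                            min_identity: float, min_coverage: float
                            ) -> tuple[bool, str, float]:
    """Does a detected unit consensus belong to the family?

    The detected unit's phase is arbitrary, so it is aligned against the
    doubled family unit (any rotation is then a contiguous substring), on both
    strands.  Returns (member, strand, identity); strand is '.' when forward
    and reverse scores are indistinguishable.
    """
    aligner = _make_aligner(SearchParams())
    doubled = family_unit * 2
    results = {}
    for strand, query in (("+", unit), ("-", reverse_complement(unit))):
        alignment = aligner.align(doubled, query)[0]
        blocks_t, blocks_q = alignment.aligned
        if len(blocks_q) == 0:
            results[strand] = (0.0, 0.0, 0.0)
            continue
        matches = 0
        ungapped = 0
        for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
            a = encode(doubled[ts:te])
            b = encode(query[qs:qe])
            matches += int(np.count_nonzero((a == b) & (a < 4)))
            ungapped += te - ts
        span_q = int(blocks_q[-1][1] - blocks_q[0][0])
        span_t = int(blocks_t[-1][1] - blocks_t[0][0])
        cols = ungapped + (span_q - sum(int(e - s) for s, e in blocks_q)) \
            + (span_t - ungapped)
        identity = matches / cols if cols else 0.0
        coverage = span_q / len(unit)
        results[strand] = (float(alignment.score), identity, coverage)
    best = max(results, key=lambda s: results[s][0])
    other = "-" if best == "+" else "+"
    score, identity, coverage = results[best]
    member = identity >= min_identity and coverage >= min_coverage
    if score > 0 and results[other][0] >= 0.9 * score:
        strand = "."
    else:
        strand = best
    return member, strand, identity


def scan_constituents(genome: GenomeAssembly, definition: MotifDefinition,
                      params: SearchParams | None = None,
                      min_identity: float = 0.80, min_coverage: float = 0.80,
                      min_unit_identity: float = 0.80
                      ) -> tuple[list[TRHit], list[AlignmentHit]]:
    """Genome-wide TR-array and CS calls belonging to the motif family."""
    unit_len = len(definition.unit_consensus)
    arrays = detect_arrays_genome(
        genome,
        min_unit=max(10, int(unit_len * 0.5)),
        max_unit=int(unit_len * 2.5),
        min_copies=definition.min_units,
        min_unit_identity=min_unit_identity,
    )
    tr_hits = []
    for arr in arrays:
        member, strand, ident = _unit_family_membership(
            arr.unit_consensus, definition.unit_consensus,
            min_identity, min_coverage)
        if member:
            tr_hits.append(TRHit(array=arr, strand=strand,
                                 unit_identity_to_family=ident))
    cs_hits = [h for h in search(definition.cs_consensus, genome, params)
               if passes_80_80(h, min_identity, min_coverage)]
    return tr_hits, cs_hits


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def _gap_between(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.overlaps(b):
        return 0
    return max(b.start - a.end, a.start - b.end)


def pair_constituents(tr_hits: Sequence[TRHit], cs_hits: Sequence[AlignmentHit],
                      max_gap: int = 200) -> PairingResult:
    """Greedy nearest-neighbour pairing of TR and CS calls into motif instances.

    Candidate pairs must share chromosome and strand (an orientation-ambiguous
    TR matches either strand) and lie within ``max_gap``.  Smallest gap wins;
    ties break leftmost.  Each constituent is used at most once.
    """
    candidates = []
    for ti, tr in enumerate(tr_hits):
        for ci, cs in enumerate(cs_hits):
            a, b = tr.interval, cs.target_interval
            if a.chrom != b.chrom:
                continue
            if tr.strand != "." and tr.strand != cs.strand:
                continue
            gap = _gap_between(a, b)
            if gap <= max_gap:
                candidates.append((gap, min(a.start, b.start), ti, ci))
    candidates.sort()
    used_tr: set[int] = set()
    used_cs: set[int] = set()
    instances = []
    for gap, _left, ti, ci in candidates:
        if ti in used_tr or ci in used_cs:
            continue
        used_tr.add(ti)
        used_cs.add(ci)
        tr, cs = tr_hits[ti], cs_hits[ci]
        a, b = tr.interval, cs.target_interval
        orientation = cs.strand
        instances.append(MotifInstance(
            tr=tr, cs=cs, orientation=orientation,
            unit_count=tr.array.unit_content,
            full_interval=GenomicInterval(a.chrom, min(a.start, b.start),
                                          max(a.end, b.end), orientation),
            gap=gap,
        ))
    instances.sort(key=lambda m: (m.full_interval.chrom, m.full_interval.start))
    lone_tr = [t for i, t in enumerate(tr_hits) if i not in used_tr]
    lone_cs = [c for i, c in enumerate(cs_hits) if i not in used_cs]
    return PairingResult(instances=instances, lone_tr=lone_tr, lone_cs=lone_cs)


# ---------------------------------------------------------------------------
# Consensus accumulation (star alignment)
# ---------------------------------------------------------------------------

def _project_onto_reference(instance: str, reference: str) -> np.ndarray:
    """Instance bases projected onto reference columns (255 where unaligned),
    via a global edlib alignment."""
    res = edlib.align(instance, reference, mode="NW", task="path")
    cigar = res["cigar"]
    proj = np.full(len(reference), 255, dtype=np.uint8)
    inst = encode(instance)
    qi = ri = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            proj[ri : ri + n] = inst[qi : qi + n]
            qi += n
            ri += n
        elif ch == "I":          # present in instance, absent from reference
            qi += n
        elif ch == "D":          # gap in instance against reference columns
            ri += n
    return proj


def consensus_accumulation(instances: Sequence[str],
                           reference: str) -> ConsensusHistogram:
    """Stack instances on a reference and count per-column agreement.

    Each instance is pairwise-aligned to the reference (star alignment); for
    every reference column the majority base among aligned instance bases is
    the column consensus, and the histogram value is the number of instances
    carrying it.
    """
    if not instances:
        raise ValueError("need at least one instance sequence")
    reference = reference.upper()
    mat = np.stack([_project_onto_reference(s.upper(), reference)
                    for s in instances])
    n, m = mat.shape
    counts = np.zeros(m, dtype=np.int64)
    consensus = []
    for j in range(m):
        col = mat[:, j]
        col = col[col < 4]                 # aligned, non-N bases only
        if col.size == 0:
            consensus.append("N")
            continue
        vals, cnts = np.unique(col, return_counts=True)
        best = int(np.argmax(cnts))
        counts[j] = int(cnts[best])
        consensus.append("ACGT"[vals[best]])
    return ConsensusHistogram(columns=counts, n_instances=n,
                              consensus="".join(consensus))


def high_agreement_block(hist: ConsensusHistogram, smooth_window: int = 51,
                         level: float = 0.9) -> tuple[int, int]:
    """Longest contiguous run of top-agreement columns.

    The agreement track is smoothed by a centred moving average, then
    thresholded at ``min + level * (max - min)`` of the smoothed track; the
    longest run above threshold is returned as a half-open column interval.
    """
    x = hist.columns.astype(float)
    w = min(smooth_window, x.size) or 1
    kernel = np.ones(w) / w
    sm = np.convolve(x, kernel, mode="same")
    lo, hi = float(sm.min()), float(sm.max())
    thr = lo + level * (hi - lo)
    above = sm >= thr
    best = (0, 0)
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def instances_to_features(result: PairingResult) -> list[Feature]:
    """GFF3-ready features: ICRd_motif spans plus TR/CS children and lone calls."""
    feats = []
    for i, m in enumerate(result.instances, 1):
        mid = f"motif_{i:03d}"
        feats.append(Feature(interval=m.full_interval, name=mid,
                             type="ICRd_motif",
                             attributes={"ID": mid,
                                         "unit_count": str(m.unit_count)}))
        feats.append(Feature(interval=m.tr.interval, name=f"{mid}_TR",
                             type="ICRd_TR",
                             attributes={"ID": f"{mid}_TR", "Parent": mid,
                                         "copy_number": f"{m.tr.array.copy_number:.2f}"}))
        feats.append(Feature(interval=m.cs.target_interval, name=f"{mid}_CS",
                             type="ICRd_CS",
                             attributes={"ID": f"{mid}_CS", "Parent": mid}))
    for i, t in enumerate(result.lone_tr, 1):
        feats.append(Feature(interval=t.interval, name=f"loneTR_{i:03d}",
                             type="ICRd_TR",
                             attributes={"ID": f"loneTR_{i:03d}", "lone": "true"}))
    for i, c in enumerate(result.lone_cs, 1):
        feats.append(Feature(interval=c.target_interval, name=f"loneCS_{i:03d}",
                             type="ICRd_CS",
                             attributes={"ID": f"loneCS_{i:03d}", "lone": "true"}))
    return feats


def summary_table(result: PairingResult, genome: GenomeAssembly) -> str:
    """TSV summary: per-chromosome instance/lone counts + unit-content histogram."""
    per_chrom = {c: [0, 0, 0] for c in genome.ids()}
    for m in result.instances:
        per_chrom[m.full_interval.chrom][0] += 1
    for t in result.lone_tr:
        per_chrom[t.interval.chrom][1] += 1
    for c in result.lone_cs:
        per_chrom[c.target_interval.chrom][2] += 1
    lines = ["chrom\tmotif_instances\tlone_TR\tlone_CS"]
    for chrom, (a, b, c) in per_chrom.items():
        lines.append(f"{chrom}\t{a}\t{b}\t{c}")
    content = sorted(m.unit_count for m in result.instances)
    lines.append("")
    lines.append("unit_content\tn_motifs")
    for u in sorted(set(content)):
        lines.append(f"{u}\t{content.count(u)}")
    return "\n".join(lines) + "\n"
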