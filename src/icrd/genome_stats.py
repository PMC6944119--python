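"""Chromosomal distribution statistics, synteny-block chaining, and the
per-chromosome presence report.

The uniformity question -- are insertions spread over the chromosomes in
proportion to chromosome size? -- is answered by a chi-square goodness-of-fit
test with expectations E_i = N * L_i / sum(L).  Density tracks use tiling
(non-overlapping) windows, 500 kb by default.  Synteny blocks chain 80-80
local-alignment anchors between two homologous segments by a weighted longest
increasing subsequence; a locus deleted from one segment appears as a gap
between consecutive blocks.  The presence report restates the subgenome
contrast per chromosome and doubles as a misassembly detector: a motif
relocated into the wrong subgenome flips that chromosome's presence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import GenomeAssembly, GenomicInterval
from .homology_search import AlignmentHit, SearchParams, passes_80_80, search_sequence
from .motif_model import MotifDefinition, PairingResult, pair_constituents, scan_constituents


@dataclass
class ChromosomeCounts:
    """Observed insertion counts and chromosome lengths, aligned by id."""

    counts: dict[str, int]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(self.lengths):
            raise ValueError("counts and lengths must cover the same chromosomes")
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("all chromosome lengths must be positive")

    @property
    def N(self) -> int:
        return sum(self.counts.values())


@dataclass
class UniformityTest:
    chi2: float
    df: int
    p_value: float
    expected: dict[str, float]
    observed: dict[str, int]
    low_expected_warning: bool

    def band(self) -> str:
        """Report-style band for the p-value (e.g. 'P > 0.9')."""
        for t in (0.9, 0.5, 0.1, 0.05, 0.01):
            if self.p_value > t:
                return f"P > {t:g}"
        return "P <= 0.01"


def chi_square_uniformity(counts: ChromosomeCounts) -> UniformityTest:
    """Chi-square test of insertion counts against length-proportional
    expectations: chi2 = sum (O_i - E_i)^2 / E_i, df = k - 1."""
    N = counts.N
    if N == 0:
        raise ValueError("no observations: chi-square test undefined for N=0")
    total_len = sum(counts.lengths.values())
    expected = {c: N * L / total_len for c, L in counts.lengths.items()}
    chi2 = sum((counts.counts[c] - e) ** 2 / e for c, e in expected.items())
    df = len(expected) - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return UniformityTest(
        chi2=float(chi2), df=df, p_value=p, expected=expected,
        observed=dict(counts.counts),
        low_expected_warning=any(e < 5 for e in expected.values()),
    )


def window_density(features: Sequence[GenomicInterval], assembly: GenomeAssembly,
                   window: int = 500_000) -> pd.DataFrame:
    """Counts per tiling window (a feature belongs to the window containing
    its start) plus per-chromosome per-megabase densities."""
    if window <= 0:
        raise ValueError("window size must be positive")
    rows = []
    starts: dict[str, list[int]] = {c: [] for c in assembly.ids()}
    for f in features:
        starts[f.chrom].append(f.start)
    for chrom in assembly.chromosomes:
        n_win = max(1, -(-chrom.length // window))
        counts = np.zeros(n_win, dtype=int)
        for s in starts[chrom.id]:
            counts[min(s // window, n_win - 1)] += 1
        dens = len(starts[chrom.id]) / (chrom.length / 1e6)
        for w in range(n_win):
            rows.append({
                "chrom": chrom.id,
                "window_start": w * window,
                "window_end": min((w + 1) * window, chrom.length),
                "count": int(counts[w]),
                "chrom_density_per_mb": dens,
            })
    return pd.DataFrame(rows)


def plot_density(df: pd.DataFrame, path: str) -> None:
    """Basic per-chromosome density track plot (one panel per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = df["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, sharex=True,
                             figsize=(8, 1.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = df[df["chrom"] == chrom]
        ax.bar(sub["window_start"] / 1e6, sub["count"],
               width=(sub["window_end"] - sub["window_start"]) / 1e6,
               align="edge")
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_to_bedgraph(df: pd.DataFrame) -> str:
    lines = [f"{r.chrom}\t{r.window_start}\t{r.window_end}\t{r.count}"
             for r in df.itertuples()]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    a_interval: GenomicInterval
    b_interval: GenomicInterval
    orientation: str
    anchor_count: int


@dataclass
class SyntenyResult:
    blocks: list[SyntenyBlock]
    gaps_a: list[GenomicInterval] = field(default_factory=list)
    gaps_b: list[GenomicInterval] = field(default_factory=list)


def find_synteny_blocks(seg_a: str, seg_b: str,
                        anchor_size: int = 500,
                        params: SearchParams | None = None,
                        min_identity: float = 0.80,
                        min_coverage: float = 0.80,
                        max_block_gap: int = 2_000) -> SyntenyResult:
    """Chain 80-80 anchors between two segments into co-linear blocks.

    ``seg_a`` is tiled into ``anchor_size`` chunks; each chunk's best passing
    hit in ``seg_b`` is an anchor.  The heaviest order- and orientation-
    consistent anchor chain (weighted LIS on scores) is split into blocks
    wherever the chain jumps by more than ``max_block_gap`` on either segment;
    inter-block gaps are reported on both segments.
    """
    if not seg_a or not seg_b:
        raise ValueError("both segments must be non-empty")
    p = params or SearchParams()
    anchors = []      # (a_start, a_end, b_start, b_end, strand, score)
    for a_start in range(0, max(1, len(seg_a) - anchor_size + 1), anchor_size):
        chunk = seg_a[a_start : a_start + anchor_size]
        if len(chunk) < p.k:
            continue
        hits = [h for h in search_sequence(chunk, seg_b, "b", p)
                if passes_80_80(h, min_identity, min_coverage)]
        if not hits:
            continue
        h = hits[0]      # best scoring
        anchors.append((a_start + h.query_interval.start,
                        a_start + h.query_interval.end,
                        h.target_interval.start, h.target_interval.end,
                        h.strand, h.score))
    if not anchors:
        return SyntenyResult(blocks=[])
    anchors.sort()

    best_chain: list[tuple] = []
    best_weight = -1.0
    for orientation in ("+", "-"):
        cand = [a for a in anchors if a[4] == orientation]
        n = len(cand)
        if n == 0:
            continue
        weight = [a[5] for a in cand]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                consistent = (cand[j][3] <= cand[i][2] if orientation == "+"
                              else cand[i][3] <= cand[j][2])
                if consistent and weight[j] + cand[i][5] > weight[i]:
                    weight[i] = weight[j] + cand[i][5]
                    prev[i] = j
        end = int(np.argmax(weight))
        if weight[end] > best_weight:
            best_weight = weight[end]
            chain = []
            while end != -1:
                chain.append(cand[end])
                end = prev[end]
            best_chain = chain[::-1]

    blocks: list[SyntenyBlock] = []
    run = [best_chain[0]]
    orientation = best_chain[0][4]
    for a in best_chain[1:]:
        gap_a = a[0] - run[-1][1]
        gap_b = (a[2] - run[-1][3] if orientation == "+" else run[-1][2] - a[3])
        if gap_a > max_block_gap or gap_b > max_block_gap:
            blocks.append(_make_block(run, orientation))
            run = [a]
        else:
            run.append(a)
    blocks.append(_make_block(run, orientation))

    gaps_a, gaps_b = [], []
    for prev_b, nxt in zip(blocks, blocks[1:]):
        if nxt.a_interval.start > prev_b.a_interval.end:
            gaps_a.append(GenomicInterval("a", prev_b.a_interval.end,
                                          nxt.a_interval.start))
        b_lo = min(prev_b.b_interval.end, nxt.b_interval.end)
        b_hi = max(prev_b.b_interval.start, nxt.b_interval.start)
        if b_hi > b_lo:
            gaps_b.append(GenomicInterval("b", b_lo, b_hi))
    return SyntenyResult(blocks=blocks, gaps_a=gaps_a, gaps_b=gaps_b)


def _make_block(run: list[tuple], orientation: str) -> SyntenyBlock:
    a_lo = run[0][0]
    a_hi = run[-1][1]
    b_lo = min(r[2] for r in run)
    b_hi = max(r[3] for r in run)
    return SyntenyBlock(
        a_interval=GenomicInterval("a", a_lo, a_hi, "+"),
        b_interval=GenomicInterval("b", b_lo, b_hi, orientation),
        orientation=orientation,
        anchor_count=len(run),
    )


# ---------------------------------------------------------------------------
# Presence report
# ---------------------------------------------------------------------------

@dataclass
class PresenceReport:
    rows: pd.DataFrame            # chrom, motif_instances, lone_tr, lone_cs, present
    summary: str                  # Table-style one-liner
    pairing: PairingResult


def subgenome_presence_report(assembly: GenomeAssembly,
                              definition: MotifDefinition,
                              params: SearchParams | None = None,
                              max_gap: int | None = None) -> PresenceReport:
    """Per-chromosome motif presence for an assembly (or concatenated
    tetraploid).  Chromosomes with lone constituents but no paired instance
    are flagged via the lone_* columns."""
    if not assembly.chromosomes:
        return PresenceReport(
            rows=pd.DataFrame(columns=["chrom", "motif_instances", "lone_tr",
                                       "lone_cs", "present"]),
            summary="(empty assembly)",
            pairing=PairingResult([], [], []))
    tr_hits, cs_hits = scan_constituents(assembly, definition, params)
    pairing = pair_constituents(tr_hits, cs_hits,
                                max_gap if max_gap is not None else definition.max_gap)
    counts = {c: [0, 0, 0] for c in assembly.ids()}
    for m in pairing.instances:
        counts[m.full_interval.chrom][0] += 1
    for t in pairing.lone_tr:
        counts[t.interval.chrom][1] += 1
    for c in pairing.lone_cs:
        counts[c.target_interval.chrom][2] += 1
    rows = pd.DataFrame([
        {"chrom": c, "motif_instances": v[0], "lone_tr": v[1],
         "lone_cs": v[2], "present": v[0] > 0}
        for c, v in counts.items()
    ])
    present = [c for c, v in counts.items() if v[0] > 0]
    absent = [c for c, v in counts.items() if v[0] == 0]
    summary = f"{_compress(present) or 'None'}; absent: {_compress(absent) or 'none'}"
    return PresenceReport(rows=rows, summary=summary, pairing=pairing)


def _compress(chroms: list[str]) -> str:
    """Compress e.g. D01,D02,D03,D07 -> 'D01-D03, D07' (Table-style ranges)."""
    import re

    parsed = []
    for c in chroms:
        m = re.match(r"^(.*?)(\d+)$", c)
        if m:
            parsed.append((m.group(1), int(m.group(2)), len(m.group(2)), c))
        else:
            parsed.append((c, None, 0, c))
    parsed.sort(key=lambda t: (t[0], t[1] if t[1] is not None else -1))
    out = []
    i = 0
    while i < len(parsed):
        prefix, num, width, label = parsed[i]
        if num is None:
            out.append(label)
            i += 1
            continue
        j = i
        while (j + 1 < len(parsed) and parsed[j + 1][0] == prefix
               and parsed[j + 1][1] == parsed[j][1] + 1):
            j += 1
        if j > i:
            out.append(f"{label}-{parsed[j][3]}")
        else:
            out.append(label)
        i = j + 1
    return ", ".join(out)
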