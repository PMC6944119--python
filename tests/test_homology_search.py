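"""Seed-and-extend search against a brute-force Smith-Waterman oracle,
plus the 80-80 rule and the genome-specificity screen."""

import numpy as np
import pytest

from icrd.genome_io import Chromosome, GenomeAssembly, reverse_complement
from icrd.homology_search import (
    AlignmentHit,
    SearchParams,
    passes_80_80,
    screen_genome_specific,
    search,
    search_sequence,
)
from icrd.synthetic_data import random_sequence

# exhaustive search params: extend every seed cluster, accept tiny scores
EXHAUSTIVE = SearchParams(min_score=5, ungapped_trigger=None)


def smith_waterman_score(a: str, b: str, match=1, mismatch=-1,
                         gap_open=2, gap_extend=1) -> float:
    """Plain-Python affine-gap local alignment score (independent oracle).

    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_x = [neg] * (m + 1)   # gap in b (consuming a)
    prev_y = [neg] * (m + 1)   # gap in a (consuming b)
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_x = [neg] * (m + 1)
        cur_y = [neg] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1], 0.0)
            cur_m[j] = diag + s
            cur_x[j] = max(prev_m[j] - gap_open - gap_extend,
                           prev_x[j] - gap_extend)
            cur_y[j] = max(cur_m[j - 1] - gap_open - gap_extend,
                           cur_y[j - 1] - gap_extend)
            best = max(best, cur_m[j], cur_x[j], cur_y[j])
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def _mutate_subs(seq: str, n_subs: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(out)


class TestSearchBasics:
    def test_exact_substring_full_identity(self, rng):
        target = random_sequence(2000, 0.4, rng)
        query = target[700:900]
        (hit, *_) = search_sequence(query, target)
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0
        assert hit.strand == "+"
        assert (hit.target_interval.start, hit.target_interval.end) == (700, 900)

    def test_reverse_complement_query_hits_minus_strand(self, rng):
        target = random_sequence(2000, 0.4, rng)
        query = reverse_complement(target[700:900])
        (hit, *_) = search_sequence(query, target)
        assert hit.strand == "-"
        assert hit.identity == 1.0
        assert (hit.target_interval.start, hit.target_interval.end) == (700, 900)

    def test_query_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="seed size"):
            search_sequence("ACGT", "ACGTACGTACGTACGT")

    def test_strand_symmetry(self, rng):
        """Searching the reverse-complemented query yields the same loci with
        flipped strand."""
        target = random_sequence(3000, 0.4, rng)
        core = target[1000:1150]
        query = _mutate_subs(core, 5, rng)
        fwd = search_sequence(query, target, params=EXHAUSTIVE)
        rev = search_sequence(reverse_complement(query), target, params=EXHAUSTIVE)
        assert len(fwd) == len(rev)
        loci_f = {(h.target_interval.start, h.target_interval.end, h.strand)
                  for h in fwd}
        loci_r = {(h.target_interval.start, h.target_interval.end,
                   "+" if h.strand == "-" else "-") for h in rev}
        assert loci_f == loci_r

    def test_hit_counts_internally_consistent(self, rng):
        target = random_sequence(5000, 0.4, rng)
        query = _mutate_subs(target[2000:2400], 30, rng)
        hits = search_sequence(query, target, params=EXHAUSTIVE)
        assert hits
        for h in hits:
            assert h.aligned_columns == h.matches + h.mismatches + h.gap_columns
            assert 0.0 <= h.identity <= 1.0
            assert 0.0 <= h.query_coverage <= 1.0


class TestOracleEquivalence:
    def test_best_hit_score_matches_smith_waterman(self):
        """Seed-and-extend best-hit score equals exhaustive local DP on pairs
        of short sequences sharing a mutated homologous core."""
        rng = np.random.default_rng(424242)
        for _ in range(50):
            core_len = int(rng.integers(100, 140))
            core = random_sequence(core_len, 0.45, rng)
            query = (random_sequence(int(rng.integers(0, 30)), 0.45, rng)
                     + core
                     + random_sequence(int(rng.integers(0, 30)), 0.45, rng))
            mutated = _mutate_subs(core, int(rng.integers(0, core_len // 25)), rng)
            target = (random_sequence(int(rng.integers(0, 30)), 0.45, rng)
                      + mutated
                      + random_sequence(int(rng.integers(0, 30)), 0.45, rng))
            query, target = query[:200], target[:200]
            hits = search_sequence(query, target, params=EXHAUSTIVE)
            assert hits, "homologous core must be found"
            oracle = smith_waterman_score(query, target)
            assert hits[0].score == pytest.approx(oracle)


class TestRule8080:
    def _hit(self, identity, coverage, qlen=100):
        cols = 100
        matches = round(identity * cols)
        from icrd.genome_io import GenomicInterval

        span = round(coverage * qlen)
        return AlignmentHit(
            query_interval=GenomicInterval("query", 0, span),
            target_interval=GenomicInterval("t", 0, span or 1),
            strand="+", score=matches, matches=matches,
            mismatches=cols - matches, gap_columns=0, query_length=qlen,
        )

    @pytest.mark.parametrize("identity,coverage,expected", [
        (0.85, 0.90, True),
        (0.80, 0.80, True),     # thresholds are inclusive
        (0.79, 0.95, False),
        (0.95, 0.79, False),
    ])
    def test_threshold_boundaries(self, identity, coverage, expected):
        assert passes_80_80(self._hit(identity, coverage)) is expected

    def test_raising_thresholds_never_adds_hits(self, rng):
        target = random_sequence(4000, 0.4, rng)
        query = _mutate_subs(target[1500:1800], 40, rng)
        hits = search_sequence(query, target, params=EXHAUSTIVE)
        for lo_i, lo_c in [(0.5, 0.5), (0.7, 0.7), (0.8, 0.8), (0.9, 0.9)]:
            n_lo = sum(passes_80_80(h, lo_i, lo_c) for h in hits)
            n_hi = sum(passes_80_80(h, lo_i + 0.05, lo_c + 0.05) for h in hits)
            assert n_hi <= n_lo


class TestScreen:
    def test_specific_shared_absent(self, rng):
        shared = random_sequence(300, 0.4, rng)
        d_only = random_sequence(300, 0.4, rng)
        bg_d = random_sequence(5000, 0.4, rng)
        bg_a = random_sequence(5000, 0.4, rng)
        d = GenomeAssembly("d", [Chromosome(
            "c1", bg_d[:2000] + d_only + bg_d[2000:3000] + shared + bg_d[3000:])])
        a = GenomeAssembly("a", [Chromosome("c1", bg_a[:2500] + shared + bg_a[2500:])])
        results = screen_genome_specific(
            {"d_only": d_only, "shared": shared,
             "nowhere": random_sequence(300, 0.4, rng)}, d, a)
        by_name = {r.query_name: r.classification for r in results}
        assert by_name == {"d_only": "specific", "shared": "shared",
                           "nowhere": "absent"}

    def test_planted_motif_is_genome_specific(self, small_sim, small_definition):
        _cfg, d_like, a_like, _truth = small_sim
        (res,) = screen_genome_specific({"cs": small_definition.cs_consensus},
                                        d_like, a_like)
        assert res.classification == "specific"
        assert res.hits_present >= 1
        assert res.hits_absent == 0
        assert all(v == 0 for v in res.per_chromosome_absent.values())

    def test_empty_queries_rejected(self, small_sim):
        _cfg, d_like, a_like, _ = small_sim
        with pytest.raises(ValueError):
            screen_genome_specific({}, d_like, a_like)
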