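"""K2P distance, T = d/2r dating, paired-LTR detection, and LTR families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icrd.genome_io import Chromosome, GenomeAssembly, GenomicInterval
from icrd.ltr_dating import (
    DatingConfig,
    SaturatedDivergenceError,
    activity_histogram,
    cluster_families,
    detect_ltr_pairs,
    insertion_time,
    k2p_distance,
    substitution_proportions,
)
from icrd.synthetic_data import mutate_k2p, random_sequence


class TestK2PDistance:
    def test_zero_proportions_zero_distance(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # independent evaluation: -1/2 * ln(0.5 * sqrt(0.8))
        expected = -0.5 * math.log(0.5 * math.sqrt(0.8))
        assert k2p_distance(0.2, 0.1) == pytest.approx(expected, abs=1e-12)
        assert k2p_distance(0.2, 0.1) == pytest.approx(0.40236, abs=1e-5)

    def test_saturation_is_an_error_not_a_number(self):
        with pytest.raises(SaturatedDivergenceError):
            k2p_distance(0.45, 0.1)        # 1-2P-Q = 0
        with pytest.raises(SaturatedDivergenceError):
            k2p_distance(0.1, 0.5)         # 1-2Q = 0

    def test_negative_proportions_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance(-0.01, 0.0)

    @given(st.floats(0.0, 0.30), st.floats(0.0, 0.30))
    @settings(max_examples=200, deadline=None)
    def test_dominates_p_distance(self, P, Q):
        """d >= P + Q everywhere on the domain (multiple-hit correction only
        inflates the raw difference proportion)."""
        if 1 - 2 * P - Q <= 1e-9 or 1 - 2 * Q <= 1e-9:
            return
        assert k2p_distance(P, Q) >= P + Q - 1e-12

    @given(st.floats(0.0, 0.25), st.floats(0.0, 0.25), st.floats(1e-4, 0.05))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_each_argument(self, P, Q, eps):
        if 1 - 2 * (P + eps) - Q <= 1e-9 or 1 - 2 * (Q + eps) <= 1e-9 \
                or 1 - 2 * P - (Q + eps) <= 1e-9:
            return
        d0 = k2p_distance(P, Q)
        assert k2p_distance(P + eps, Q) > d0
        assert k2p_distance(P, Q + eps) > d0


class TestInsertionTime:
    def test_zero_distance_zero_age(self):
        assert insertion_time(0.0) == 0.0

    def test_headline_scales(self):
        assert insertion_time(0.78, 1.3e-8) == pytest.approx(3.0e7)
        assert insertion_time(0.26, 1.3e-8) == pytest.approx(1.0e7)

    def test_rate_scaling_invariance(self):
        d = k2p_distance(0.1, 0.05)
        assert insertion_time(d, 2.6e-8) == pytest.approx(
            insertion_time(d, 1.3e-8) / 2)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(0.1, 0.0)


def _element_genome(rng, d_side=0.0, ltr_len=300, body_len=2_000):
    """One chromosome holding leftLTR + body + rightLTR, with flanks."""
    ltr = random_sequence(ltr_len, 0.4, rng)
    left = mutate_k2p(ltr, d_side, 2.0, rng)
    right = mutate_k2p(ltr, d_side, 2.0, rng)
    body = random_sequence(body_len, 0.4, rng)
    flank5 = random_sequence(1_000, 0.4, rng)
    flank3 = random_sequence(1_000, 0.4, rng)
    seq = flank5 + left + body + right + flank3
    genome = GenomeAssembly("g", [Chromosome("c1", seq)])
    anchor = GenomicInterval("c1", 1_000 + ltr_len + 200,
                             1_000 + ltr_len + body_len - 200)
    return genome, anchor, (1_000, 1_000 + ltr_len), \
        (1_000 + ltr_len + body_len, 1_000 + 2 * ltr_len + body_len)


class TestDetectPairs:
    def test_identical_ltrs_give_zero_divergence(self, rng):
        genome, anchor, left, right = _element_genome(rng)
        (pair,) = detect_ltr_pairs(genome, [anchor], flank=2_000)
        assert pair.paired
        assert pair.P == 0.0 and pair.Q == 0.0 and pair.d == 0.0
        assert abs(pair.left_ltr.start - left[0]) <= 5
        assert abs(pair.right_ltr.end - right[1]) <= 5

    def test_divergence_recovered_within_3se(self, rng):
        d_side = 0.05
        genome, anchor, _l, _r = _element_genome(rng, d_side=d_side,
                                                 ltr_len=1_000)
        (pair,) = detect_ltr_pairs(genome, [anchor], flank=2_500)
        assert pair.dated
        d_expected = 2 * d_side
        se = math.sqrt(d_expected * (1 - d_expected) / 1_000)
        assert abs(pair.d - d_expected) < 3 * se

    def test_random_candidate_reported_unpaired(self, rng):
        seq = random_sequence(8_000, 0.4, rng)
        genome = GenomeAssembly("g", [Chromosome("c1", seq)])
        (pair,) = detect_ltr_pairs(genome,
                                   [GenomicInterval("c1", 3_000, 5_000)],
                                   flank=2_000)
        assert not pair.paired
        assert pair.age_years is None


class TestClusterFamilies:
    def test_identical_sequences_one_family(self, rng):
        ltr = random_sequence(300, 0.4, rng)
        (fam,) = cluster_families([ltr, ltr, ltr])
        assert len(fam.members) == 3

    def test_one_similar_pair_among_25(self, rng):
        """25 LTRs of which exactly one pair is similar: 24 families, one of
        size 2 and 23 singletons."""
        seqs = [random_sequence(300, 0.4, rng) for _ in range(24)]
        seqs.append(mutate_k2p(seqs[0], 0.05, 2.0, rng))
        fams = cluster_families(seqs)
        sizes = sorted(len(f.members) for f in fams)
        assert len(fams) == 24
        assert sizes == [1] * 23 + [2]

    def test_partition_invariant_to_input_order(self, rng):
        seqs = [random_sequence(200, 0.4, rng) for _ in range(6)]
        seqs.append(mutate_k2p(seqs[2], 0.03, 2.0, rng))
        ids = [f"L{i}" for i in range(len(seqs))]
        fams_fwd = cluster_families(seqs, ids)
        order = list(reversed(range(len(seqs))))
        fams_rev = cluster_families([seqs[i] for i in order],
                                    [ids[i] for i in order])
        as_sets = lambda fams: {frozenset(f.members) for f in fams}
        assert as_sets(fams_fwd) == as_sets(fams_rev)


class TestActivityHistogram:
    def _pair(self, age):
        iv = GenomicInterval("c", 0, 100)
        from icrd.ltr_dating import LTRPair

        return LTRPair(element_id="e", element=iv, left_ltr=iv, right_ltr=iv,
                       age_years=age)

    def test_point_mass_single_bin(self):
        pairs = [self._pair(30e6) for _ in range(5)]
        h = activity_histogram(pairs, bin_width_years=5e6)
        assert sum(h["counts"]) == 5
        nonzero = [i for i, c in enumerate(h["counts"]) if c]
        assert nonzero == [6]           # the [30, 35) MYA bin

    def test_normal_ages_mode_contains_mean(self):
        rng = np.random.default_rng(8)
        ages = rng.normal(30e6, 5e6, size=100)
        pairs = [self._pair(max(a, 0.0)) for a in ages]
        h = activity_histogram(pairs, bin_width_years=5e6)
        mode = int(np.argmax(h["counts"]))
        lo = h["bin_edges_years"][mode]
        hi = h["bin_edges_years"][mode + 1]
        assert lo <= 30e6 <= hi or abs(lo - 30e6) <= 5e6

    def test_empty_and_undated(self):
        h = activity_histogram([], bin_width_years=5e6)
        assert sum(h["counts"]) == 0
        undated = self._pair(None)
        h2 = activity_histogram([undated], bin_width_years=5e6)
        assert h2["n_undated"] == 1 and h2["n_dated"] == 0


def test_substitution_proportions_on_known_pair():
    a = "ACGTACGTACGTACGTACGT"
    b = "ACGTACGTGCGTACGTACGA"   # one A->G transition, one T->A transversion
    P, Q, ident = substitution_proportions(a, b)
    assert P == pytest.approx(1 / 20)
    assert Q == pytest.approx(1 / 20)
    assert ident == pytest.approx(18 / 20)
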