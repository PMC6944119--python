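"""The generative model: K2P mutator, element builder, genome-pair simulator."""

import numpy as np
import pytest

from icrd.genome_io import extract_interval
from icrd.homology_search import encode
from icrd.ltr_dating import insertion_time, k2p_distance, substitution_proportions


def pq_positionwise(a: str, b: str) -> tuple[float, float]:
    """Transition/transversion proportions by direct site comparison
    (valid oracle here: the mutator never introduces indels)."""
    ca, cb = encode(a), encode(b)
    diff = ca ^ cb
    P = float(np.count_nonzero(diff == 2)) / ca.size
    Q = float(np.count_nonzero((diff != 0) & (diff != 2))) / ca.size
    return P, Q
from icrd.synthetic_data import (
    SimulationConfig,
    TruthRecord,
    build_motif_element,
    make_tetraploid,
    mutate_k2p,
    random_sequence,
    simulate_genome_pair,
)


class TestMutateK2P:
    def test_zero_divergence_is_identity(self, rng):
        seq = random_sequence(500, 0.4, rng)
        assert mutate_k2p(seq, 0.0, 2.0, rng) == seq

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            mutate_k2p("ACGT" * 10, -0.1)

    def test_deterministic_given_seed(self):
        seq = "ACGTACGTACGT" * 20
        assert mutate_k2p(seq, 0.3, 2.0, 99) == mutate_k2p(seq, 0.3, 2.0, 99)

    def test_n_bases_untouched(self, rng):
        seq = "N" * 50
        assert mutate_k2p(seq, 0.5, 2.0, rng) == seq

    def test_expected_distance_recovered(self):
        """Monte-Carlo oracle: the K2P estimator applied to (input, mutant)
        pairs recovers the requested branch length within 3 standard errors."""
        rng = np.random.default_rng(11)
        L, d_true, reps = 10_000, 0.2, 50
        seq = random_sequence(L, 0.5, rng)
        est = []
        for _ in range(reps):
            mut = mutate_k2p(seq, d_true, 2.0, rng)
            P, Q = pq_positionwise(seq, mut)
            est.append(k2p_distance(P, Q))
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - d_true) < 3 * se

    def test_kappa_controls_transition_share(self):
        """Higher transition/transversion rate ratio yields a higher observed
        P/Q ratio."""
        rng = np.random.default_rng(5)
        seq = random_sequence(30_000, 0.5, rng)
        ratios = []
        for kappa in (1.0, 8.0):
            mut = mutate_k2p(seq, 0.1, kappa, rng)
            P, Q = pq_positionwise(seq, mut)
            ratios.append(P / Q)
        assert ratios[1] > 2 * ratios[0]


class TestBuildElement:
    CFG = SimulationConfig(seed=1, gap_range=(0, 0))

    def test_layout_arithmetic_u5(self, rng):
        _seq, layout = build_motif_element(self.CFG, 5, 1e6, rng)
        assert layout.tr[1] - layout.tr[0] == 5 * 133 == 665
        assert layout.motif[1] - layout.motif[0] == 5 * 133 + 860 == 1525

    def test_extreme_61_unit_array(self, rng):
        _seq, layout = build_motif_element(self.CFG, 61, 1e6, rng)
        assert layout.tr[1] - layout.tr[0] == 61 * 133 == 8113

    def test_zero_age_gives_identical_ltrs(self, rng):
        seq, layout = build_motif_element(self.CFG, 3, 0.0, rng)
        left = seq[layout.left_ltr[0] : layout.left_ltr[1]]
        right = seq[layout.right_ltr[0] : layout.right_ltr[1]]
        assert left == right

    def test_unit_count_below_minimum_rejected(self, rng):
        with pytest.raises(ValueError):
            build_motif_element(self.CFG, 1, 1e6, rng)

    def test_degraded_element_lacks_one_ltr(self):
        rng = np.random.default_rng(3)
        _seq, layout = build_motif_element(self.CFG, 3, 1e6, rng, degraded=True)
        assert (layout.left_ltr is None) != (layout.right_ltr is None)


class TestSimulatePair:
    def test_truth_counts_by_construction(self, small_sim):
        cfg, _d, _a, truth = small_sim
        kinds = {}
        for t in truth:
            kinds[t.kind] = kinds.get(t.kind, 0) + 1
        assert kinds["full_motif"] == cfg.n_motifs
        assert kinds["LTR_TE"] == cfg.n_motifs
        assert kinds["lone_TR"] == cfg.n_lone_tr
        assert kinds["lone_CS"] == cfg.n_lone_cs

    def test_constituent_level_counts(self):
        cfg = SimulationConfig(seed=2, n_chromosomes=2,
                               chromosome_length=400_000,
                               n_motifs=10, n_lone_tr=5, n_lone_cs=5)
        _d, _a, truth = simulate_genome_pair(cfg)
        n_tr = sum(t.kind in ("full_motif", "lone_TR") for t in truth)
        n_cs = sum(t.kind in ("full_motif", "lone_CS") for t in truth)
        n_paired = sum(t.kind == "full_motif" for t in truth)
        assert (n_tr, n_cs, n_paired) == (15, 15, 10)

    def test_same_seed_bit_identical(self, small_sim):
        cfg, d1, a1, t1 = small_sim
        d2, a2, t2 = simulate_genome_pair(cfg)
        assert [c.sequence for c in d1.chromosomes] == \
            [c.sequence for c in d2.chromosomes]
        assert [c.sequence for c in a1.chromosomes] == \
            [c.sequence for c in a2.chromosomes]
        assert t1 == t2

    def test_collinearity_after_deleting_planted_loci(self, small_sim):
        """Excising every planted element footprint from the D-like genome
        reconstructs the A-like genome exactly (collinear flanks)."""
        _cfg, d_like, a_like, truth = small_sim
        top = {}          # chromosome -> top-level planted intervals
        for t in truth:
            if t.kind in ("LTR_TE", "lone_TR", "lone_CS"):
                top.setdefault(t.interval.chrom, []).append(t.interval)
        for chrom in d_like.chromosomes:
            seq = chrom.sequence
            for iv in sorted(top.get(chrom.id, []), key=lambda v: -v.start):
                seq = seq[: iv.start] + seq[iv.end :]
            assert seq == a_like[chrom.id].sequence

    def test_planted_ages_recoverable(self):
        """Re-estimating LTR divergence from the planted pairs recovers true
        ages with small mean relative error and ~no bias."""
        cfg = SimulationConfig(seed=31, n_chromosomes=4,
                               chromosome_length=600_000, n_motifs=12,
                               n_lone_tr=0, n_lone_cs=0,
                               fraction_degraded=0.0, ltr_length=1_000)
        d_like, _a, truth = simulate_genome_pair(cfg)
        rel = []
        for t in truth:
            if t.kind != "LTR_TE":
                continue
            left = extract_interval(d_like, t.left_ltr)
            right = extract_interval(d_like, t.right_ltr)
            P, Q, _ = substitution_proportions(left, right)
            T = insertion_time(k2p_distance(P, Q), cfg.rate)
            rel.append((T - t.true_age) / t.true_age)
        rel = np.asarray(rel)
        assert np.abs(rel).mean() < 0.10

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1,
                               chromosome_length=20_000, n_motifs=10)
        with pytest.raises(ValueError, match="packing"):
            simulate_genome_pair(cfg)

    def test_truth_record_invariants(self):
        with pytest.raises(ValueError, match="sub-intervals"):
            TruthRecord(element_id="x", kind="full_motif",
                        interval=None)  # type: ignore[arg-type]


class TestTetraploid:
    def test_concatenation_renames_chromosomes(self, small_sim):
        _cfg, d_like, a_like, _t = small_sim
        tet = make_tetraploid(d_like, a_like)
        assert tet.ids() == ["A_t_01", "A_t_02", "A_t_03",
                             "D_t_01", "D_t_02", "D_t_03"]
        assert tet.total_length == d_like.total_length + a_like.total_length

    def test_relocation_moves_sequence_between_halves(self, small_sim):
        _cfg, d_like, a_like, truth = small_sim
        te = next(t for t in truth if t.kind == "LTR_TE")
        moved = extract_interval(
            d_like, type(te.interval)(te.interval.chrom, te.interval.start,
                                      te.interval.end, "+"))
        tet = make_tetraploid(d_like, a_like, relocate=(te.interval, 0), seed=4)
        d_idx = tet.ids().index("D_t_" + te.interval.chrom[-2:])
        assert moved not in tet.chromosomes[d_idx].sequence
        assert moved in tet["A_t_01"].sequence
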