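"""Synthetic genome pair with planted composite repeats and full ground truth.

The simulator emulates the presence/absence contrast between two sister
diploid cotton genomes: a "D-like" genome carrying a family of composite
repetitive elements -- a tandem-repeat (TR) array of ~133 bp units next to an
~860 bp conserved sequence (CS), embedded inside degraded LTR
retrotransposons -- and an "A-like" genome in which every such locus is
absent while the flanking sequence remains collinear.  An optional
"tetraploid" concatenates both chromosome sets, with a hook for relocating
one element into the A-like half to model a subgenome misassembly.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configurations are bit-reproducible.

The family has one TR unit sequence and one CS sequence genome-wide; each
planted instance receives independent low-level mutation (so consensus
training is non-trivial), while each host TE body is heavily diverged and
each element draws its own unrelated LTR template (so LTR clustering yields
singleton families, as in ancient, independently inserted elements).  Paired
LTRs are copied from one template and mutated independently to r*age
substitutions/site per side under a Kimura two-parameter process, so the
expected LTR-LTR divergence is d = 2*r*age and the insertion age is
recoverable as T = d/(2r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (
    Chromosome,
    Feature,
    GenomeAssembly,
    GenomicInterval,
    reverse_complement,
    write_fasta,
    write_features,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome pair.

    Defaults mirror the motif family being emulated: 133 bp TR units repeated
    2-21 times, an 860 bp conserved sequence, host elements aged ~1-30 million
    years under a substitution rate of 1.3e-8 per site per year.
    """

    seed: int = 0
    n_chromosomes: int = 13
    chromosome_length: int = 1_000_000
    n_motifs: int = 20
    n_lone_tr: int = 5
    n_lone_cs: int = 5
    unit_length: int = 133
    unit_copy_range: tuple[int, int] = (2, 21)
    cs_length: int = 860
    ltr_length: int = 500
    te_internal_length: int = 3_000
    age_range_years: tuple[float, float] = (1.0e6, 30.0e6)
    rate: float = 1.3e-8           # substitutions / site / year
    tstv_kappa: float = 2.0        # transition/transversion rate ratio
    background_gc: float = 0.35
    unit_mutation: float = 0.02    # per-unit divergence within one TR array
    cs_divergence: float = 0.02
    te_flank_divergence: float = 0.40
    gap_range: tuple[int, int] = (0, 50)
    fraction_degraded: float = 0.65  # host TEs losing one LTR (unpaired for dating)
    min_separation: int = 2_000
    decoy_microsatellites: int = 0   # planted (unit<10) decoys for stress tests

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.unit_copy_range[0] < 2:
            raise ValueError("minimum TR copy number is 2")
        for name in ("chromosome_length", "unit_length", "cs_length",
                     "ltr_length", "te_internal_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ElementLayout:
    """Sub-intervals of one built element, relative to its own sequence."""

    left_ltr: tuple[int, int] | None
    right_ltr: tuple[int, int] | None
    tr: tuple[int, int]
    cs: tuple[int, int]
    motif: tuple[int, int]          # TR..CS span
    unit_count: int
    age_years: float


@dataclass
class TruthRecord:
    """Ground truth for one planted feature, in D-like coordinates."""

    element_id: str
    kind: str                       # full_motif | lone_TR | lone_CS | LTR_TE
    interval: GenomicInterval
    orientation: str = "+"
    tr_interval: GenomicInterval | None = None
    cs_interval: GenomicInterval | None = None
    left_ltr: GenomicInterval | None = None
    right_ltr: GenomicInterval | None = None
    true_unit_count: int | None = None
    true_age: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "full_motif" and (self.tr_interval is None
                                          or self.cs_interval is None):
            raise ValueError("full_motif truth requires TR and CS sub-intervals")
        if self.true_age is not None and self.kind != "LTR_TE":
            raise ValueError("ages belong to LTR_TE records only")


# ---------------------------------------------------------------------------
# K2P generative mutation
# ---------------------------------------------------------------------------

def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, gc: float, rng) -> str:
    rng = _rng(rng)
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate_k2p(seq: str, d: float, kappa: float = 2.0, seed=0) -> str:
    """Mutate ``seq`` under a Kimura two-parameter process.

    ``d`` is the expected number of substitutions per site (branch length);
    multiple hits are modelled exactly through the K2P transition
    probabilities, so re-estimating the K2P distance between input and output
    is unbiased for ``d``.  ``kappa`` is the transition/transversion *rate*
    ratio (alpha/beta).  N sites are left untouched.
    """
    if d < 0:
        raise ValueError(f"expected distance d must be >= 0, got {d}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    if d == 0:
        return seq
    rng = _rng(seed)
    b = d / (kappa + 2.0)          # beta*t per transversion partner
    a = kappa * b                  # alpha*t
    e1 = np.exp(-4.0 * b)
    e2 = np.exp(-2.0 * (a + b))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    from .homology_search import encode  # local import avoids cycle at import time

    codes = encode(seq)
    valid = codes < 4
    u = rng.random(arr.size)
    out = codes.copy()
    ts_mask = valid & (u < p_ts)
    tv1_mask = valid & (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2_mask = valid & (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    out[ts_mask] ^= 2              # A<->G, C<->T
    out[tv1_mask] ^= 1
    out[tv2_mask] ^= 3
    arr[valid] = _BASES[out[valid]]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Element construction
# ---------------------------------------------------------------------------

@dataclass
class FamilyTemplates:
    """The genome-wide family sequences shared by all planted instances."""

    unit: str
    cs: str
    te_body: str


def family_templates(cfg: SimulationConfig) -> FamilyTemplates:
    """The family sequences a given config will plant (deterministic in the
    seed; they are drawn first from the simulation's generator)."""
    return make_family_templates(cfg, np.random.default_rng(cfg.seed))


def make_family_templates(cfg: SimulationConfig, rng) -> FamilyTemplates:
    rng = _rng(rng)
    return FamilyTemplates(
        unit=random_sequence(cfg.unit_length, cfg.background_gc, rng),
        cs=random_sequence(cfg.cs_length, cfg.background_gc, rng),
        te_body=random_sequence(cfg.te_internal_length, cfg.background_gc, rng),
    )


def build_tr_array(templates: FamilyTemplates, cfg: SimulationConfig,
                   unit_count: int, rng) -> str:
    rng = _rng(rng)
    lo, hi = cfg.unit_copy_range
    if not (lo <= unit_count):
        raise ValueError(f"unit count {unit_count} below minimum {lo}")
    units = [mutate_k2p(templates.unit, cfg.unit_mutation, cfg.tstv_kappa, rng)
             for _ in range(unit_count)]
    return "".join(units)


def build_motif_element(cfg: SimulationConfig, unit_count: int, age_years: float,
                        rng, templates: FamilyTemplates | None = None,
                        degraded: bool = False) -> tuple[str, ElementLayout]:
    """Build one host LTR-TE carrying the composite motif.

    Structure: leftLTR + body5' + [TR array + gap + CS] + body3' + rightLTR.
    Both LTRs derive from one fresh template and are independently mutated to
    an expected rate*age substitutions/site each, so the pair diverges by
    2*rate*age.  The TE body is heavily diverged from the family body; the
    motif core is only lightly mutated.  ``degraded`` drops one LTR (the
    element then has no datable pair).
    """
    rng = _rng(rng)
    lo, _hi = cfg.unit_copy_range
    # the minimum is a hard floor; larger-than-typical arrays (e.g. a 61-unit
    # outlier) are legal, the configured range only drives random draws
    if unit_count < lo:
        raise ValueError(f"unit count {unit_count} below minimum {lo}")
    if templates is None:
        templates = make_family_templates(cfg, rng)
    d_side = cfg.rate * age_years
    ltr_template = random_sequence(cfg.ltr_length, cfg.background_gc, rng)
    left_ltr = mutate_k2p(ltr_template, d_side, cfg.tstv_kappa, rng)
    right_ltr = mutate_k2p(ltr_template, d_side, cfg.tstv_kappa, rng)
    tr = build_tr_array(templates, cfg, unit_count, rng)
    gap_len = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
    gap = random_sequence(gap_len, cfg.background_gc, rng)
    cs = mutate_k2p(templates.cs, cfg.cs_divergence, cfg.tstv_kappa, rng)
    split = cfg.te_internal_length // 2
    body5 = mutate_k2p(templates.te_body[:split], cfg.te_flank_divergence,
                       cfg.tstv_kappa, rng)
    body3 = mutate_k2p(templates.te_body[split:], cfg.te_flank_divergence,
                       cfg.tstv_kappa, rng)
    drop_left = degraded and bool(rng.integers(0, 2))
    parts = []
    pos = 0

    def _add(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        span = (pos, pos + len(s))
        pos += len(s)
        return span

    lspan = None if (degraded and drop_left) else _add(left_ltr)
    _add(body5)
    tr_span = _add(tr)
    _add(gap)
    cs_span = _add(cs)
    _add(body3)
    rspan = None if (degraded and not drop_left) else _add(right_ltr)
    layout = ElementLayout(
        left_ltr=lspan, right_ltr=rspan, tr=tr_span, cs=cs_span,
        motif=(tr_span[0], cs_span[1]), unit_count=unit_count,
        age_years=age_years,
    )
    return "".join(parts), layout


def build_lone_tr(cfg: SimulationConfig, templates: FamilyTemplates,
                  unit_count: int, rng) -> str:
    return build_tr_array(templates, cfg, unit_count, rng)


def build_lone_cs(cfg: SimulationConfig, templates: FamilyTemplates, rng) -> str:
    return mutate_k2p(templates.cs, cfg.cs_divergence, cfg.tstv_kappa, _rng(rng))


# ---------------------------------------------------------------------------
# Genome pair simulation
# ---------------------------------------------------------------------------

def _place_insertions(cfg: SimulationConfig, n_items: int, rng) -> list[tuple[int, int]]:
    """(chromosome index, background position) per item; uniform by length."""
    rng = _rng(rng)
    placements: list[tuple[int, int]] = []
    occupied: dict[int, list[int]] = {i: [] for i in range(cfg.n_chromosomes)}
    lengths = np.full(cfg.n_chromosomes, cfg.chromosome_length, dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_items):
        for _attempt in range(1000):
            ci = int(rng.choice(cfg.n_chromosomes, p=probs))
            pos = int(rng.integers(cfg.min_separation,
                                   cfg.chromosome_length - cfg.min_separation))
            if all(abs(pos - q) >= cfg.min_separation for q in occupied[ci]):
                occupied[ci].append(pos)
                placements.append((ci, pos))
                break
        else:
            raise ValueError("infeasible packing: cannot place insertions "
                             "with the requested separation")
    return placements


def simulate_genome_pair(cfg: SimulationConfig) -> tuple[GenomeAssembly,
                                                         GenomeAssembly,
                                                         list[TruthRecord]]:
    """Generate the (D-like, A-like) pair plus the truth table.

    The A-like genome is the shared background; the D-like genome is that
    background with every element spliced in at its recorded position, so
    deleting all truth intervals from D-like recovers A-like exactly (the
    collinear-flanks property).
    """
    rng = np.random.default_rng(cfg.seed)
    templates = make_family_templates(cfg, rng)
    background = [random_sequence(cfg.chromosome_length, cfg.background_gc, rng)
                  for _ in range(cfg.n_chromosomes)]

    lo, hi = cfg.unit_copy_range
    n_items = cfg.n_motifs + cfg.n_lone_tr + cfg.n_lone_cs + cfg.decoy_microsatellites
    builds: list[tuple[str, str, ElementLayout | None, int | None, float | None]] = []
    for i in range(cfg.n_motifs):
        u = int(rng.integers(lo, hi + 1))
        age = float(rng.uniform(*cfg.age_range_years))
        degraded = bool(rng.random() < cfg.fraction_degraded)
        seq, layout = build_motif_element(cfg, u, age, rng, templates, degraded)
        builds.append((f"motif_{i + 1:03d}", "full_motif", layout, u, age, seq))
    for i in range(cfg.n_lone_tr):
        u = int(rng.integers(lo, hi + 1))
        seq = build_lone_tr(cfg, templates, u, rng)
        builds.append((f"loneTR_{i + 1:03d}", "lone_TR", None, u, None, seq))
    for i in range(cfg.n_lone_cs):
        seq = build_lone_cs(cfg, templates, rng)
        builds.append((f"loneCS_{i + 1:03d}", "lone_CS", None, None, None, seq))
    for i in range(cfg.decoy_microsatellites):
        motif = random_sequence(int(rng.integers(2, 7)), cfg.background_gc, rng)
        seq = motif * int(rng.integers(30, 120))
        builds.append((f"decoy_{i + 1:03d}", "decoy", None, None, None, seq))

    total_planted = sum(len(b[5]) for b in builds)
    if total_planted >= cfg.chromosome_length:
        raise ValueError("infeasible packing: planted length exceeds chromosome length")

    placements = _place_insertions(cfg, n_items, rng)
    per_chrom: dict[int, list[tuple[int, tuple]]] = {i: [] for i in range(cfg.n_chromosomes)}
    for (ci, pos), build in zip(placements, builds):
        per_chrom[ci].append((pos, build))

    d_chroms, a_chroms = [], []
    truth: list[TruthRecord] = []
    for ci in range(cfg.n_chromosomes):
        bg = background[ci]
        name = f"Chr{ci + 1:02d}"
        pieces, cursor, offset = [], 0, 0
        for pos, (eid, kind, layout, u, age, seq) in sorted(per_chrom[ci],
                                                            key=lambda t: t[0]):
            orientation = "+" if rng.random() < 0.5 else "-"
            planted = seq if orientation == "+" else reverse_complement(seq)
            pieces.append(bg[cursor:pos])
            pieces.append(planted)
            start = pos + offset
            end = start + len(planted)
            if kind == "full_motif" and layout is not None:
                def _map(span: tuple[int, int] | None) -> GenomicInterval | None:
                    if span is None:
                        return None
                    if orientation == "+":
                        return GenomicInterval(name, start + span[0], start + span[1], "+")
                    return GenomicInterval(name, end - span[1], end - span[0], "-")

                truth.append(TruthRecord(
                    element_id=eid, kind="full_motif",
                    interval=_map(layout.motif), orientation=orientation,
                    tr_interval=_map(layout.tr), cs_interval=_map(layout.cs),
                    true_unit_count=u,
                ))
                left, right = _map(layout.left_ltr), _map(layout.right_ltr)
                if orientation == "-":
                    left, right = right, left
                truth.append(TruthRecord(
                    element_id=eid + "_TE", kind="LTR_TE",
                    interval=GenomicInterval(name, start, end, orientation),
                    orientation=orientation, left_ltr=left, right_ltr=right,
                    true_age=age,
                ))
            elif kind in ("lone_TR", "lone_CS"):
                truth.append(TruthRecord(
                    element_id=eid, kind=kind,
                    interval=GenomicInterval(name, start, end, orientation),
                    orientation=orientation, true_unit_count=u,
                ))
            # decoys are intentionally absent from the truth table
            cursor = pos
            offset += len(planted)
        pieces.append(bg[cursor:])
        d_chroms.append(Chromosome(name, "".join(pieces)))
        a_chroms.append(Chromosome(name, bg))
    d_like = GenomeAssembly("D_like", d_chroms)
    a_like = GenomeAssembly("A_like", a_chroms)
    return d_like, a_like, truth


def make_tetraploid(d_like: GenomeAssembly, a_like: GenomeAssembly,
                    relocate: tuple[GenomicInterval, int] | None = None,
                    seed: int = 0) -> GenomeAssembly:
    """Concatenate both chromosome sets into an AADD-style assembly.

    Chromosomes are renamed ``A_t_NN`` / ``D_t_NN``.  ``relocate`` moves the
    sequence of one D-genome interval into the A-half chromosome of the given
    index (a synthetic subgenome misassembly): the locus is excised from its
    D chromosome and inserted at a seed-determined position of the A
    chromosome.
    """
    rng = np.random.default_rng(seed)
    a_seqs = {i: c.sequence for i, c in enumerate(a_like.chromosomes)}
    d_seqs = {i: c.sequence for i, c in enumerate(d_like.chromosomes)}
    if relocate is not None:
        iv, a_index = relocate
        d_index = next(i for i, c in enumerate(d_like.chromosomes) if c.id == iv.chrom)
        seq = d_seqs[d_index]
        moved = seq[iv.start:iv.end]
        d_seqs[d_index] = seq[:iv.start] + seq[iv.end:]
        a_seq = a_seqs[a_index]
        pos = int(rng.integers(1000, len(a_seq) - 1000))
        a_seqs[a_index] = a_seq[:pos] + moved + a_seq[pos:]
    chroms = [Chromosome(f"A_t_{i + 1:02d}", a_seqs[i]) for i in sorted(a_seqs)]
    chroms += [Chromosome(f"D_t_{i + 1:02d}", d_seqs[i]) for i in sorted(d_seqs)]
    return GenomeAssembly("tetraploid", chroms)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def truth_to_features(truth: list[TruthRecord]) -> list[Feature]:
    feats = []
    for t in truth:
        attrs = {"ID": t.element_id, "kind": t.kind}
        if t.true_unit_count is not None:
            attrs["unit_count"] = str(t.true_unit_count)
        if t.true_age is not None:
            attrs["age_years"] = f"{t.true_age:.0f}"
        feats.append(Feature(interval=t.interval, name=t.element_id,
                             type=t.kind, source="icrd_sim", attributes=attrs))
        for sub, label in ((t.tr_interval, "TR"), (t.cs_interval, "CS"),
                           (t.left_ltr, "left_LTR"), (t.right_ltr, "right_LTR")):
            if sub is not None:
                feats.append(Feature(
                    interval=sub, name=f"{t.element_id}_{label}", type=label,
                    source="icrd_sim",
                    attributes={"ID": f"{t.element_id}_{label}",
                                "Parent": t.element_id}))
    return feats


def write_simulation(outdir: str | Path, cfg: SimulationConfig,
                     d_like: GenomeAssembly, a_like: GenomeAssembly,
                     truth: list[TruthRecord],
                     tetraploid: GenomeAssembly | None = None) -> dict[str, str]:
    """Write FASTA pair (+ optional tetraploid), truth GFF3, and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for asm, fname in ((d_like, "D_like.fasta"), (a_like, "A_like.fasta")):
        write_fasta(asm, outdir / fname)
        manifest[fname] = str(outdir / fname)
    if tetraploid is not None:
        write_fasta(tetraploid, outdir / "tetraploid.fasta")
        manifest["tetraploid.fasta"] = str(outdir / "tetraploid.fasta")
    write_features(truth_to_features(truth), outdir / "truth.gff3")
    manifest["truth.gff3"] = str(outdir / "truth.gff3")
    fam = family_templates(cfg)
    fam_asm = GenomeAssembly("family", [Chromosome("TR_unit", fam.unit),
                                        Chromosome("CS", fam.cs)])
    write_fasta(fam_asm, outdir / "family.fasta")
    manifest["family.fasta"] = str(outdir / "family.fasta")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
    manifest["config.json"] = str(outdir / "config.json")
    return manifest
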