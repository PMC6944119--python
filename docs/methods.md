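# Methods

## The element and the analysis it requires

The pipeline targets a composite repetitive element with two constituents: a
length-variable tandem-repeat array (unit ≈ 133 bp, 2–21 copies, ending
mid-unit) and a stable conserved sequence (≈ 860 bp), sitting inside degraded
LTR retrotransposons that are present in one genome of a sister pair and
absent from the other. Characterizing such an element needs five
capabilities — genome-specificity screening, tandem-array calling, composite
pairing, host-element dating, and distribution statistics — each of which is
a module here. A generative simulator supplies genomes in which every one of
those capabilities can be scored against known truth.

## Coordinates and alphabets

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted exactly at the file boundary, and human-readable
reports render 1-based inclusive. Sequences are uppercase over {A,C,G,T,N}.
N never seeds, never matches, and is excluded from substitution counts —
the conservative reading of ambiguity.

## Homology search

Seed-and-extend local alignment: exact k-mer seeds (k = 12) on both strands
are grouped into diagonal clusters; each cluster is extended by an
affine-gap local DP (match +1, mismatch −1, gap open −2, gap extend −1,
via Bio.Align.PairwiseAligner) over a target window sized from the cluster
span plus slack; overlapping hits at a locus keep the best scorer. Two
filters keep genome scans fast without changing small-scale behaviour:
k-mers occurring more than `max_kmer_hits` times in the target never seed,
and a cluster is extended only if the best ungapped segment score along its
modal diagonal reaches `min(min_score, ungapped_trigger)` (a lower bound on
its gapped score; a hit whose every single-diagonal segment scores below the
trigger and that reaches `min_score` only by chaining gaps across distant
diagonals can be missed — irrelevant at the divergences the 80–80 rule
admits). Setting `ungapped_trigger=None` makes extension exhaustive; the
test suite verifies in that mode that best-hit scores equal an independent
plain-Python Smith–Waterman on short homologous pairs.

The 80–80 rule is applied with "matching ratio" read as query coverage
(aligned query span / query length) and "similarity" as alignment identity
(matches / aligned columns, gap columns included); both thresholds are
inclusive at 0.80. A query is *specific* to genome 1 if it has ≥ 1 passing
hit there and none in genome 2, *shared* if both, *absent* if neither.

## Tandem arrays

Candidate periods come from k-mer self-distance voting: every pair of equal
k-mers separated by a lag in [min_unit, max_unit] votes (position, lag);
runs of votes split at positional gaps > max_unit become candidate regions.
For each well-supported period the region is refined: frames of one period
are cut, a column-majority consensus trained, the best consensus placement
(phase) found, frames extended in both directions while per-frame identity
≥ the floor (0.80), and finally each boundary is placed at the maximum of a
+1/−1 match score against the phased consensus within one unit of the frame
edge — tolerating scattered mutations at the edges while trimming background
spill. Copy number is span/period (real-valued; the integer "unit content"
is its floor, with 0.1 units of slack on the ≥ 2-copy floor because a
mutated terminal base can trim the span just below an integer). When periods
p and 2p both fit, p wins if its mean unit identity is within 2 points of
2p's. Periods below 10 bp are out of scope (microsatellites).

## Motif calling and the consensus plateau

TR calls are detected arrays whose unit consensus matches the family unit
under 80–80; because a detected unit's phase is arbitrary, membership is
tested against the doubled family unit (any rotation is then a contiguous
substring) on both strands, with strand marked ambiguous when forward and
reverse scores are within 10 %. CS calls are 80–80-passing search hits of
the family CS. Pairing is greedy nearest-gap on same-chromosome,
same-strand (ambiguous TR matches either) constituent pairs with gap
≤ 200 bp — the constituents abut in the real element and the default is
deliberately permissive; ties break leftmost. Unpaired calls are reported
as lone insertions, which in both the real system and the simulator far
outnumber complete motifs.

The consensus-accumulation histogram star-aligns each extracted host
element to a reference element (edlib global alignment, cigar-projected
onto reference columns) and counts per-column agreement with the column
majority. A conserved core inside degraded elements appears as a plateau;
`high_agreement_block` extracts it by smoothing the track with a 51-column
moving average and thresholding at 90 % of the smoothed range, returning
the longest contiguous run. Star alignment to one reference replaces a full
multiple alignment: O(n) pairwise alignments reproduce the plateau, which
is the only quantity consumed downstream.

## LTR detection and dating

Within a candidate element (± 4 kb flank), the highest-scoring pair of
similar direct repeats is sought among long-lag k-mer seed clusters, with
constraints: repeat length in [100, 3000] bp, element span in [1, 15] kb,
the two copies disjoint, identity ≥ 0.70, and — because the motif is a
known internal anchor — the two repeats must bracket it (one wholly left,
one wholly right), which prevents tandem-unit copies inside the element
from masquerading as the terminal pair. Elements without a qualifying pair
are reported unpaired and excluded from dating only; with the default
similarity floor this truncates detection at roughly d ≈ 0.4 (≈ 15 MYA at
the default rate), so old elements are expected to be unpaired — matching
the empirical pattern that most such host elements are too degraded to date.

P and Q are counted over ungapped, N-free columns of a global LTR–LTR
alignment with stiff gap costs (open −8, extend −2): paired LTRs diverge
almost entirely by substitution, and cheap gaps would buy spurious matches
at high divergence, biasing d and therefore T downward (measured bias with
stiff gaps: ≈ −1 % over ages 1–30 MYA; with default search costs it was
≈ −5 %). d follows the Kimura two-parameter closed form and fails loudly
(`SaturatedDivergenceError`) outside its domain rather than returning NaN.
T = d/2r with r = 1.3 × 10⁻⁸ subs/site/year by default. Age-recovery
accuracy is measured from known LTR pairs (the simulator's layout), which
isolates estimator error from detection truncation; detected pairs at
identities near the floor have slightly shortened intervals and mildly
underestimated ages.

Families: single-linkage clustering where two LTRs link iff one local
alignment covers ≥ 80 % of both sequences at ≥ 80 % identity. Because each
simulated element draws its own LTR template, simulated families are
singletons unless similarity is planted.

## Distribution statistics

The χ² uniformity test uses expectations proportional to assembled
chromosome length, df = k − 1, upper-tail p from scipy's χ² survival
function, and a warning flag when any E_i < 5. Density tracks use tiling
(non-overlapping) 500 kb windows with stride = window — counts are
identical to a stride-1 track sampled at window boundaries — and features
are assigned by start coordinate, which is unambiguous for boundary-
spanning features. Synteny blocks: the first segment is tiled into 500 bp
chunks, each chunk's best 80–80 hit in the second segment is an anchor, the
heaviest order- and orientation-consistent chain is found by weighted LIS,
and the chain splits into blocks wherever it jumps > 2 kb on either
segment; inter-block gaps are reported on both segments, so a clean element
loss appears as a gap on exactly one side. The presence report runs the
full scan/pair stage per assembly and flags chromosomes by paired-instance
count; chromosomes with lone constituents but no instance remain visible
through the lone_* columns.

## The simulator and what it does (not) emulate

One family is drawn per configuration (TR unit, CS, TE body); each planted
instance mutates the family sequences independently (2 % per TR unit, 2 %
per CS — enough to make consensus training non-trivial), while each host
element draws its own LTR template, mutated per side by r·age under an
exact K2P site process (closed-form transition probabilities, so the
expected re-estimated distance equals the requested branch length and
multiple hits are modelled). The TE body is diverged at 0.40 — the
"degraded ancient element" regime. A configurable fraction of hosts
(default 0.65) loses one LTR entirely, reproducing the observation that
most host elements cannot be dated. Orientation flips with probability 0.5;
the TR–CS gap is uniform in [0, 50] bp. Insertion sites are uniform by
chromosome length with 2 kb minimum separation, so the χ² analysis is
calibrated by construction. The A-like genome is exactly the shared
background: deleting every planted footprint from the D-like genome
reconstructs it byte-for-byte, which is the collinear-loss scenario the
synteny stage illustrates.

Default study conditions: 13 chromosomes × 1 Mb, 20 motifs + 5 lone TRs +
5 lone CSs, unit 133 bp with 2–21 copies, CS 860 bp, LTR 500 bp (1 kb in
dating experiments), ages uniform 1–30 MYA, GC 0.35, transition/
transversion rate ratio κ = 2.

Deliberately not emulated: indels within LTRs (substitution-only; real LTR
pairs also accumulate indels, which the stiff-gap alignment would handle
but the estimator's calibration here does not cover), background repeats
(a decoy-microsatellite flag exists for stress tests), insertion-site
preference, nested insertions, and recombination/gene conversion between
LTRs (which in real data biases ages young). Passing tests therefore
demonstrate correctness of the method's logic and calibration of its
estimators under the stated generative model, not robustness to every
artefact of real assemblies.

## Problem sizes and numerical choices

Tests and the acceptance script use 13 × 1 Mb genomes (five replicates for
recovery), 100 elements for age recovery, 1,000 analytic replicates for χ²
calibration, and 20 instances for the plateau — sizes at which every stage's
behaviour is already asymptotic while a full run stays within minutes on
one CPU. Determinism: every stage consumes a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces byte-
identical outputs, which the pipeline verifies via SHA-256 manifest
checksums in its run report.
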