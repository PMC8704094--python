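# Methods

This note documents the models behind `dualbarcode`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Distances and the barcoding gap

Pairwise divergence uses the Kimura two-parameter model. For an aligned
pair, sites with both residues in {A, C, G, T} are compared (pairwise
deletion; complete deletion is available via the partition's exclusion
count when matrices carry masked entries). With P = transitions/sites and
Q = transversions/sites,

    d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)].

Saturated pairs (either log factor ≤ 0) and empty overlaps yield NaN; a
`DistanceMatrix` carries these as masked entries and reports their count
rather than dropping them. K2P ≥ p-distance whenever defined, with
equality only at zero — this is property-tested.

Alignment is global Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (match 1, mismatch −1, gap open −2, gap extend −0.5).
Near-identical barcode pairs are insensitive to these scores, which are
echoed in every report for reproducibility. Among co-optimal alignments
the aligner's first is used; this is deterministic, which is the property
that matters downstream. Matrices can either align each pair independently
(default, matching two-sequence barcode comparisons) or consume a supplied
multiple alignment (`aligned=True`); on gap-free inputs the two agree
exactly (tested).

The barcoding gap is reported as the open interval
(max intraspecific, min interspecific), flagged when the distributions
overlap or when either side is empty. Histograms use right-closed,
left-open bins with the first bin closed at 0 — a deterministic edge rule,
since plotting-tool conventions vary. Default bin widths are 0.001 and
0.0005 (the finer grid for genera whose intraspecific variation would
otherwise collapse into one bin). Extreme species pairs are computed per
strain pair, then aggregated to species-pair minima/maxima; the report
carries both, because per-strain and per-centroid conventions differ in
the literature.

Distances are fractions internally; reports print percent rounded
half-even to one decimal.

## ITS2 substitution classes and the CBC species concept

Structure work is done in the RNA alphabet (T→U on entry). Base-pair
categories: canonical {G·C, C·G, A·U, U·A}; wobble {G·U, U·G, A·C, C·A}
(A⁺·C is protonated adenine–cytosine; both orientations are included by
default and the wobble set is a parameter, since tools differ on C·A);
anything else non-canonical; any gap/N makes the comparison indeterminate.

Classification of a change between two states of the same structural
pair, in order: indeterminate (gapped) → identical → non-CBC (either
endpoint non-canonical) → CBC (both bases differ, both states canonical)
→ hCBC (one base differs, canonical ↔ wobble) → combined (both bases
differ between paired categories without being canonical → canonical,
e.g. G·C → U·G). "Combined" exists as its own class because two-base
changes that mix hCBC and non-CBC character do occur between real
species and forcing them into either class would misstate both; reports
list their decomposition. The classification is total over all 16×16
ACGU pair transitions and symmetric for identical/CBC/non-CBC
(hCBC and combined are direction-annotated). The full table is frozen as
a hand-checked fixture (`tests/data/cbc_truth_table.tsv`) that the
implementation is tested against but never reads.

Event enumeration takes an aligned ITS2 set plus a structure on alignment
coordinates (`project_structure` maps an ungapped structure through one
gapped reference row, turning gap columns into unpaired positions).
Species with several haplotypes are collapsed by majority-rule consensus
first; disagreeing columns fall to N (hence indeterminate) and the species
is flagged, so multi-haplotype unions never silently manufacture events.
Both species-vs-species (default) and species-vs-reference modes exist and
the report names the mode, since published counts do not always say which
was used. Differences at unpaired columns are tallied separately as
loop/junction single mutations — they carry no structural signal but are
part of the molecule's description.

CBC species support = species with at least one CBC against every other
congener; this is the delimitation readout and requires pairwise mode.

## Spacer delimitation

`extract_spacers` delimits ITS1 (between the 18S 3′ anchor and the 5.8S
start) and ITS2 (between the 5.8S end and the 28S 5′ anchor) using short
conserved degenerate motifs with a per-motif mismatch tolerance of 1. The
default motifs approximate the conserved flanks that ITSx-style delimiters
use; they are configuration, not ground truth — real datasets delimited by
other tools may shift boundaries by a couple of bases, which is why
downstream matching tolerates 5′ truncation. A spacer with one missing
anchor is returned best-effort with an open-end flag; with both anchors
missing it is marked undelimited rather than silently returned.

## Environmental matching

The matching rule is deliberately strict string logic: a query matches a
reference haplotype iff it equals the haplotype, or equals it with its
first k ≤ trim_tol bases removed (5′ trim only; default tolerance 2 bp for
ITS2, 0 for ITS1). There is no 3′ slack: the trimming phenomenon in spacer
databases concerns the ITS2 5′ end, and "full length coverage" is read as
the query being wholly contained and identical. N never matches anything,
including another N — exact matching requires defined semantics. The
matched species set is the union over all allowed trims; the smallest
matching trim is reported.

Distinctiveness between species is the minimum difference count over
cross-species haplotype pairs under end-gap-free comparison (equal-length
pairs reduce to Hamming distance). Zero means a shared haplotype: that
spacer cannot separate the pair, and assignments through it are flagged
ambiguous rather than resolved.

Per-species summaries use unique assignments only, by default — the point
of the 100% rule is unequivocal linking — with an include-ambiguous mode
for sensitivity analysis. The distribution type is a configurable rule
over Köppen-Geiger zone proportions (first letter: A tropical, C
temperate, D continental): tropical if ≥ 80% tropical, temperate/
continental if ≥ 80% temperate+continental, else global. The 80%
threshold is a package choice — field descriptions of the three
distribution types state no cutoff — and is echoed in reports.

## Synthetic data: what it emulates, and what it does not

`evolve_k2p` draws per-site substitutions from the exact K2P transition
functions. With transition rate α and per-transversion rate β (κ = α/β,
default 2 — a typical nuclear-marker transition bias), branch length is
solved so the expected number of substitutions equals the target d:
b = βt = d/(κ+2), giving

    P_ts = 1/4 + 1/4·e^(−4b) − 1/2·e^(−2(κ+1)b),
    P_tv = 1/2 − 1/2·e^(−4b),

so the K2P estimator applied to (input, output) is unbiased for d. This is
the generator used for estimator-recovery measurements (d ∈ {0.01, 0.05,
0.13}, length 10,000, 200 replicates — sizes chosen so the Monte Carlo
standard error of the mean is ≈ 2–3 × 10⁻⁴, sharp enough to expose any
estimator bias while running in seconds).

`simulate_genus` is a star-within-star design: species ancestors around a
root, strains around each ancestor. Its `intra_d`/`inter_d` are target
*pairwise* divergences (defaults 0.002 and 0.02, an ITS-like
narrow-gap regime at ITS-like length 600). Per-branch substitution counts
are planted deterministically — round(p(d)/2·L) changes per branch at
distinct random sites, where p(·) inverts the K2P expectation — rather
than drawn stochastically. This is what makes the generator's truth exact:
conspecific pairs differ by a known count and heterospecific pairs sit at
the interspecific target by construction (up to the 1/L planting
resolution and rare site collisions, both recorded in the truth object),
so gap-recovery tests can assert bounds, not just tendencies. The
stochastic and planted generators share the same rate machinery.

`plant_structure_events` consumes one eligible canonical pair per planted
event and rewrites it (CBC: another canonical pair; hCBC: an adjacent
wobble pair; non-CBC: a non-canonical pair), so the variant differs from
the template by exactly the planted events. `build_synthetic_its2` mirrors
the real molecule's ring architecture — H1 of 5 bp with a 3 nt loop, H2 of
9 bp with a mid-duplex bulge, and a long H3 (20 bp, a scaled-down stand-in
for the real 66–68 nt duplex so toy datasets stay small) — which is enough
structure for every classifier path without pretending to be a predicted
fold.

`simulate_env_reads` samples reference haplotypes with a 5′ trim drawn
from {0, 1, 2} bp (default weights 0.2/0.4/0.4, mass on the 1–2 bp
truncations seen in spacer databases), decoys rejection-sampled until they
match nothing at any allowed trim, and per-species metadata from
categorical models (substrate dominated by bulk soil at 65%, biomes by
forest at 55%, matching environmental-survey proportions) and normal
MAT/MAP models (tropical species 25 °C / 2803 mm; temperate 9 °C /
700 mm — the former are published per-species averages, the latter
field-realistic values).

What the generators do **not** emulate: indels and alignment error (the
alignment is not the object under test), rate heterogeneity across sites,
coalescent tree shape within species, chimeras and sequencing error in
environmental reads, and real Köppen rasters (climate labels are consumed
as metadata). Passing tests therefore demonstrate correctness of the
statistics and the matching/classification logic under their stated
assumptions — not robustness to misalignment or to sequencing artefacts.

## Numerical conventions and degenerate inputs

Coordinates are 1-based closed intervals in all public reports.
Fractions internally, percent at one decimal (half-even) in reports.
NaN marks undefined distances; empty intra or inter sets make the gap
report "undefined", never an exception. Histogram values falling exactly
on an edge go left (right-closed bins). All randomness flows through
`numpy.random.default_rng(seed)`; set iteration is never used where order
reaches an RNG. Determinism under fixed seeds is tested for every
generator and for CLI report bundles (bit-identical JSON).

## Known limitations

* The spacer anchors are approximations; sequences delimited by other
  tools can disagree by ±2 bp at boundaries, which matching absorbs via
  the trim tolerance but the delimiter itself does not model.
* CBC counting on real data depends on the supplied structure; a wrong
  consensus fold misclassifies events, and the package deliberately does
  not predict structures.
* The matching workflow is exact by design: one sequencing error makes a
  read unassignable (status "none"), which is the intended trade-off of
  the 100% rule, not a bug.
* `distance_matrix` is O(n²) pairwise alignments in pairwise mode; for
  genus-scale sets pass a multiple alignment (`aligned=True`).
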