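# dualbarcode

Dual-barcode species delimitation for filamentous fungi (and other groups
with an ITS + protein-coding barcode pair): K2P barcoding-gap analysis,
secondary-structure-aware classification of ITS2 substitutions for the CBC
species concept, and exact-match assignment of environmental ITS spacer
reads with biogeographic summaries.

## Who this is for

Taxonomists delimiting closely related species from strain-level barcode
data (ITS, ITS1, ITS2, tef1-α), and anyone linking described species to
environmental metabarcoding records where only exact spacer identity is
trustworthy. Every stage also has a seeded synthetic-data generator, so the
full pipeline runs, and can be validated, without any sequence downloads.

## What it computes

**Barcoding gap.** Pairwise distances under the Kimura two-parameter model,

d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

with P and Q the observed transition and transversion proportions over
compared sites (pairwise deletion of gap/N columns). Off-diagonal entries
are split into intraspecific and interspecific sets; the barcoding gap is
the open interval (max intra, min inter), reported with dual histograms
(default bin widths 0.001 and 0.0005) and the extreme species pairs
(lowest/highest interspecific divergence).

**CBC analysis.** Against a helix-annotated ITS2 consensus structure
(supplied as dot-bracket + helix spans; the package does not predict
structures), every structural base-pair change between species is
classified: CBC (both partners change, canonical → canonical, e.g.
G·C → C·G), hCBC (one partner changes, canonical ↔ wobble G·U / A⁺·C),
non-CBC (a non-canonical pair appears), or combined (two-base changes
between paired categories that are not canonical → canonical). Differences
at unpaired columns are tallied separately as loop/junction single
mutations. A species with ≥ 1 CBC against every congener is reported as
CBC-supported.

**Environmental matching.** Reference ITS1/ITS2 haplotypes are collapsed
per species; per-spacer distinctiveness (minimum cross-species haplotype
differences, end-gap-free) flags pairs separable by only one spacer. Reads
are assigned under the 100%-identity, full-length-coverage rule, tolerating
a 1–2 bp 5′ truncation of ITS2 references (databases routinely store ITS2
spacers missing their first bases). Unique assignments are joined with
sample metadata and summarised per species: substrate/biome proportions,
mean MAT/MAP, Köppen-Geiger zone tallies and a distribution type
(tropical, temperate/continental, or global; 80% zone-proportion rule).

## Worked example

```python
from dualbarcode.synthetic_data import GenusSimConfig, simulate_genus
from dualbarcode.distances import distance_matrix
from dualbarcode.barcode_gap import partition_distances, gap_report, extreme_pairs

cfg = GenusSimConfig(n_species=4, strains_per_species=3, length=600,
                     intra_d=0.002, inter_d=0.02, seed=1)
genus, truth = simulate_genus(cfg)
m = distance_matrix(genus, method="k2p", aligned=True)
part = partition_distances(m, genus.species_map())
rep = gap_report(part)
ext = extreme_pairs(m, genus.species_map())
print(f"pairs: {len(part.intra)} intra, {len(part.inter)} inter")
print(f"barcoding gap: ({rep.gap_low:.4f}, {rep.gap_high:.4f})  overlap: {rep.overlap}")
```

prints

```
pairs: 12 intra, 54 inter
barcoding gap: (0.0033, 0.0203)  overlap: False
```

A genus of 4 species × 3 strains simulated at 0.2% intraspecific and 2%
interspecific K2P divergence yields 66 strain pairs whose intraspecific
distances top out at 0.33% while the closest heterospecific strains sit at
2.03% — a clean barcoding gap, with no observed distance inside the
reported interval. `extreme_pairs` then names the closest and most
divergent species pairs the way a barcode report would (here all species
were planted at the same divergence, so both extremes print 2.0%).

The same analyses are available from the shell:

```sh
dualbarcode simulate --what genus --seed 1 --out sim
dualbarcode gap --fasta sim/genus_ITS.fasta --species-map sim/genus_species.tsv \
    --aligned --out gap_run
dualbarcode structure --help   # ITS2 event enumeration
dualbarcode match --help       # environmental read assignment
```

Reports are JSON/TSV bundles embedding the tool version, a config hash and
all analysis parameters; identical inputs and seeds give bit-identical
bundles.

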