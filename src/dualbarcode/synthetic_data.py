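"""Synthetic data generators with recoverable planted truth.

Every analysis stage has a generator emulating the statistical structure it
assumes, so the whole pipeline runs and is testable without downloads:

* :func:`evolve_k2p` — stochastic K2P sequence evolution: per-site
  substitution probabilities from the exact K2P transition functions, with
  the branch length solved so the expected estimated distance equals the
  target d.
* :func:`simulate_genus` — a star-within-star genus: species ancestors
  around a root, strains around each ancestor, with per-branch substitution
  counts planted deterministically so intra- and interspecific pairwise
  divergences hit their targets by construction (the planted truth records
  every branch).
* :func:`plant_structure_events` — ITS2 variants differing from a template
  by an exact list of CBC/hCBC/non-CBC events in chosen helices.
* :func:`simulate_env_reads` — environmental spacer reads sampled from a
  haplotype table with 1-2 bp 5' truncations, guaranteed-nonmatching decoy
  reads, and per-species metadata drawn from stated categorical/normal
  models.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give identical output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .its2_structure import CANONICAL, WOBBLE_BOTH, EventClass, to_rna
from .metabarcode_match import HaplotypeTable, match_query
from .seq_io import SecondaryStructure, SequenceRecord, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}
#: transition partner of each base (A<->G, C<->T), as index map
_TRANSITION = np.array([2, 3, 0, 1])
#: the two transversion partners of each base, as index maps
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int64)
    for base, i in _IDX.items():
        out[arr == ord(base)] = i
    return out


def _idx_to_seq(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _idx_to_seq(rng.integers(0, 4, size=length))


def k2p_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """Exact K2P per-site probabilities (transition, total transversion)
    after expected distance d with transition/transversion rate ratio kappa.

    With per-site rates alpha (transition) and beta (each of the two
    transversions), d = (alpha + 2 beta) t; writing b = beta*t = d/(kappa+2):

        P_ts = 1/4 + 1/4 e^{-4b} - 1/2 e^{-2(kappa+1)b}
        P_tv = 1/2 - 1/2 e^{-4b}
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    b = d / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * b) \
        - 0.5 * math.exp(-2.0 * (kappa + 1.0) * b)
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * b)
    if 1.0 - 2.0 * p_ts - p_tv <= 0.0 or 1.0 - 2.0 * p_tv <= 0.0:
        raise ValueError(f"distance d={d} saturates the K2P expectation")
    return p_ts, p_tv


def expected_p_distance(d: float, kappa: float) -> float:
    """Expected proportion of differing sites after distance d."""
    p_ts, p_tv = k2p_probabilities(d, kappa)
    return p_ts + p_tv


def evolve_k2p(
    seq: str, d: float, kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a sequence under the K2P process to expected distance d.

    Each site independently transitions with probability P_ts and takes each
    transversion with probability P_tv/2, from the exact K2P transition
    functions, so the K2P estimator applied to (input, output) is unbiased
    for d. Deterministic under seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if d == 0:
        return seq
    p_ts, p_tv = k2p_probabilities(d, kappa)
    idx = _seq_to_idx(seq)
    u = rng.random(idx.size)
    out = idx.copy()
    ts = u < p_ts
    out[ts] = _TRANSITION[idx[ts]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv / 2.0)
    tv2 = (u >= p_ts + p_tv / 2.0) & (u < p_ts + p_tv)
    out[tv1] = _TRANSVERSIONS[idx[tv1], 0]
    out[tv2] = _TRANSVERSIONS[idx[tv2], 1]
    return _idx_to_seq(out)


def _mutate_exact(
    seq: str, n_sub: int, kappa: float, rng: np.random.Generator
) -> str:
    """Substitute exactly n_sub distinct sites; per substitution the
    transition is chosen with probability kappa/(kappa+2), each transversion
    with 1/(kappa+2) (the K2P conditional change distribution)."""
    idx = _seq_to_idx(seq)
    if n_sub > idx.size:
        raise ValueError("more substitutions than sites")
    sites = rng.choice(idx.size, size=n_sub, replace=False)
    u = rng.random(n_sub)
    p_ts = kappa / (kappa + 2.0)
    for site, x in zip(sites, u):
        b = idx[site]
        if x < p_ts:
            idx[site] = _TRANSITION[b]
        elif x < p_ts + (1.0 - p_ts) / 2.0:
            idx[site] = _TRANSVERSIONS[b, 0]
        else:
            idx[site] = _TRANSVERSIONS[b, 1]
    return _idx_to_seq(idx)


@dataclass(frozen=True)
class GenusSimConfig:
    """Study conditions for a synthetic genus.

    ``intra_d`` and ``inter_d`` are the target pairwise K2P divergences
    between conspecific strains and between strains of different species
    (fraction units; intra < inter required). Defaults mirror a
    narrow-barcoding-gap fungal genus: ITS-length sequences, a few species
    with a few strains each, intraspecific divergence well below 1% and
    interspecific divergence of a few percent.
    """

    n_species: int = 4
    strains_per_species: int = 3
    length: int = 600
    intra_d: float = 0.002
    inter_d: float = 0.02
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intra_d < self.inter_d):
            raise ValueError("need 0 <= intra_d < inter_d")
        if self.length <= 0 or self.n_species < 1 \
                or self.strains_per_species < 1:
            raise ValueError("invalid genus design")


@dataclass
class SyntheticTruth:
    """Planted parameters sufficient to recompute every expected output."""

    config: dict = field(default_factory=dict)
    ancestral_sequences: dict[str, str] = field(default_factory=dict)
    branch_substitutions: dict[str, int] = field(default_factory=dict)
    planted_events: list[dict] = field(default_factory=list)
    query_origins: dict[str, dict] = field(default_factory=dict)
    metadata_models: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "ancestral_sequences": self.ancestral_sequences,
            "branch_substitutions": self.branch_substitutions,
            "planted_events": self.planted_events,
            "query_origins": self.query_origins,
            "metadata_models": self.metadata_models,
        }


def simulate_genus(cfg: GenusSimConfig) -> tuple[SequenceSet, SyntheticTruth]:
    """Simulate a labeled genus in a star-within-star design.

    Per-branch substitution counts are planted deterministically from the
    targets: each strain branch carries round(p(intra_d)/2 * L) changes and
    each root-to-ancestor branch round((p(inter_d) - p(intra_d))/2 * L),
    where p(.) inverts the K2P correction, so conspecific pairs sit at
    intra_d and heterospecific pairs at inter_d by construction (up to the
    planting resolution of 1/L and rare site collisions, all recorded in
    the truth).
    """
    rng = np.random.default_rng(cfg.seed)
    p_intra = expected_p_distance(cfg.intra_d, cfg.kappa)
    p_inter = expected_p_distance(cfg.inter_d, cfg.kappa)
    n_strain = round(p_intra / 2.0 * cfg.length)
    n_anc = round((p_inter - p_intra) / 2.0 * cfg.length)

    root = random_sequence(cfg.length, rng)
    truth = SyntheticTruth(
        config={
            "n_species": cfg.n_species,
            "strains_per_species": cfg.strains_per_species,
            "length": cfg.length, "intra_d": cfg.intra_d,
            "inter_d": cfg.inter_d, "kappa": cfg.kappa, "seed": cfg.seed,
        },
        ancestral_sequences={"root": root},
    )
    records: list[SequenceRecord] = []
    for s in range(1, cfg.n_species + 1):
        species = f"Species {s}"
        ancestor = _mutate_exact(root, n_anc, cfg.kappa, rng)
        truth.ancestral_sequences[species] = ancestor
        truth.branch_substitutions[f"root->{species}"] = n_anc
        for k in range(1, cfg.strains_per_species + 1):
            strain_id = f"sp{s}_st{k}"
            seq = _mutate_exact(ancestor, n_strain, cfg.kappa, rng)
            truth.branch_substitutions[f"{species}->{strain_id}"] = n_strain
            records.append(SequenceRecord(
                id=strain_id, residues=seq, species=species, locus="ITS",
            ))
    return SequenceSet(records=records, locus="ITS"), truth


# ---------------------------------------------------------------------------
# ITS2 structure templates and planted events


def build_synthetic_its2(
    seed: int = 0, *, h3_pairs: int = 20
) -> tuple[str, SecondaryStructure]:
    """A toy ITS2-like molecule with the ring architecture of the real one:
    helix H1 of 5 base pairs with a 3 nt hairpin loop, H2 of 9 pairs with a
    one-position bulge mid-duplex and a 4 nt loop, and a longer H3 (default
    20 pairs, a scaled-down stand-in for the real 66-68 nt duplex), joined
    by short single-stranded junctions. Returned in DNA alphabet with a
    dot-bracket-derived structure (1-based coordinates)."""
    rng = np.random.default_rng(seed)

    def helix(n: int) -> tuple[str, str]:
        pool = sorted(CANONICAL)  # sorted: set order is not seed-stable
        picks = [pool[i] for i in rng.integers(0, len(pool), size=n)]
        five = "".join(p[0] for p in picks)
        three = "".join(p[1] for p in reversed(picks))
        return five, three

    def loop(n: int) -> str:
        return random_sequence(n, rng)

    parts: list[str] = []
    db: list[str] = []
    spans: list[tuple[str, int, int]] = []

    def emit(seq: str, struct: str) -> None:
        parts.append(seq)
        db.append(struct)

    def cursor() -> int:
        return sum(len(p) for p in parts)

    # H1: 5 bp stem, 3 nt loop
    f, t = helix(5)
    start = cursor() + 1
    emit(f, "(" * 5)
    emit(loop(3), "..." )
    emit(t, ")" * 5)
    spans.append(("H1", start, cursor()))
    emit(loop(4), "....")
    # H2: 9 bp with a bulge after the 5th pair on the 5' strand, 4 nt loop
    f1, t1 = helix(5)
    f2, t2 = helix(4)
    start = cursor() + 1
    emit(f1, "(" * 5)
    emit(loop(1), ".")  # bulge
    emit(f2, "(" * 4)
    emit(loop(4), "....")
    emit(t2, ")" * 4)
    emit(t1, ")" * 5)
    spans.append(("H2", start, cursor()))
    emit(loop(5), ".....")
    # H3: long duplex, 4 nt loop
    f, t = helix(h3_pairs)
    start = cursor() + 1
    emit(f, "(" * h3_pairs)
    emit(loop(4), "....")
    emit(t, ")" * h3_pairs)
    spans.append(("H3", start, cursor()))
    emit(loop(3), "...")

    from .seq_io import parse_dotbracket  # local import avoids cycle at load

    rna = "".join(parts)
    structure = parse_dotbracket("".join(db), spans)
    return rna.replace("U", "T"), structure


_WOBBLE_FROM_CANONICAL = {
    ("G", "C"): [("G", "U")],
    ("C", "G"): [("U", "G")],
    ("A", "U"): [("G", "U"), ("A", "C")],
    ("U", "A"): [("U", "G"), ("C", "A")],
}


def plant_structure_events(
    template: str,
    structure: SecondaryStructure,
    spec: Sequence[tuple[str, str, int]],
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Plant an exact list of structural events into an ITS2 template.

    ``spec`` lists (event class, helix, count) with class in
    {"CBC", "hCBC", "nonCBC"}. Each planted event consumes one distinct
    canonical pair of the requested helix: a CBC rewrites both partners to a
    different canonical pair, an hCBC moves one partner to a wobble pair,
    and a non-CBC creates a non-canonical pair. The variant differs from the
    template by exactly the planted events; an infeasible request (not
    enough canonical pairs in the helix) is rejected.
    """
    rng = np.random.default_rng(seed)
    rna = list(to_rna(template))
    if len(rna) != structure.length:
        raise ValueError("template length != structure length")

    available: dict[str, list[tuple[int, int]]] = {}
    for (i, j), label in structure.helix_of.items():
        if (rna[i - 1], rna[j - 1]) in CANONICAL:
            available.setdefault(label, []).append((i, j))
    for label in available:
        available[label].sort()

    truth = SyntheticTruth(config={"seed": seed, "spec": list(map(list, spec))})
    for event, helix, count in spec:
        ev = EventClass(event)
        if ev not in (EventClass.CBC, EventClass.HCBC, EventClass.NONCBC):
            raise ValueError(f"cannot plant event class {event!r}")
        pool = available.get(helix, [])
        if len(pool) < count:
            raise ValueError(
                f"not enough eligible canonical pairs in {helix}: "
                f"need {count}, have {len(pool)}"
            )
        chosen_idx = rng.choice(len(pool), size=count, replace=False)
        chosen = [pool[i] for i in sorted(chosen_idx)]
        for pair in chosen:
            pool.remove(pair)
        for i, j in chosen:
            old = (rna[i - 1], rna[j - 1])
            if ev is EventClass.CBC:
                options = [p for p in sorted(CANONICAL) if p != old]
            elif ev is EventClass.HCBC:
                options = _WOBBLE_FROM_CANONICAL[old]
            else:  # non-CBC: change one partner to a non-canonical pair
                options = []
                for new5 in "ACGU":
                    if new5 != old[0]:
                        cand = (new5, old[1])
                        if cand not in CANONICAL and cand not in WOBBLE_BOTH:
                            options.append(cand)
                for new3 in "ACGU":
                    if new3 != old[1]:
                        cand = (old[0], new3)
                        if cand not in CANONICAL and cand not in WOBBLE_BOTH:
                            options.append(cand)
            new = options[int(rng.integers(0, len(options)))]
            rna[i - 1], rna[j - 1] = new
            truth.planted_events.append({
                "event": ev.value, "helix": helix, "pos5": i, "pos3": j,
                "from": "".join(old), "to": "".join(new),
            })
    variant = "".join(rna).replace("U", "T")
    return variant, truth


# ---------------------------------------------------------------------------
# Environmental reads and metadata


@dataclass(frozen=True)
class MetadataModel:
    """Generative per-species sample metadata model.

    Categorical distributions for substrate, biome and Köppen-Geiger climate
    zone; normal distributions for MAT (°C) and MAP (mm). The defaults
    below (see :func:`default_metadata_models`) mirror environmental-survey
    proportions: samples dominated by bulk soil and forest biomes, with
    tropical species around MAT 25 °C / MAP 2800 mm and temperate ones
    around MAT 9 °C / MAP 700 mm.
    """

    substrate: tuple[tuple[str, float], ...]
    biome: tuple[tuple[str, float], ...]
    climate_zone: tuple[tuple[str, float], ...]
    mat_mean: float
    mat_sd: float
    map_mean: float
    map_sd: float

    def as_dict(self) -> dict:
        return {
            "substrate": dict(self.substrate), "biome": dict(self.biome),
            "climate_zone": dict(self.climate_zone),
            "MAT": {"mean": self.mat_mean, "sd": self.mat_sd},
            "MAP": {"mean": self.map_mean, "sd": self.map_sd},
        }


_SUBSTRATES = (("bulk soil", 0.65), ("roots", 0.16),
               ("rhizosphere soil", 0.11), ("shoots", 0.035),
               ("litter", 0.024), ("other", 0.021))
_BIOMES = (("forest", 0.55), ("cropland", 0.19), ("grassland", 0.17),
           ("other", 0.09))

TROPICAL_MODEL = MetadataModel(
    substrate=_SUBSTRATES, biome=_BIOMES,
    climate_zone=(("Af", 0.5), ("Am", 0.3), ("Aw", 0.2)),
    mat_mean=25.0, mat_sd=2.0, map_mean=2803.0, map_sd=500.0,
)
TEMPERATE_MODEL = MetadataModel(
    substrate=_SUBSTRATES, biome=_BIOMES,
    climate_zone=(("Cfb", 0.5), ("Dfb", 0.3), ("Cfa", 0.2)),
    mat_mean=9.0, mat_sd=3.0, map_mean=700.0, map_sd=200.0,
)


def default_metadata_models(species: Sequence[str]) -> dict[str, MetadataModel]:
    """Alternate tropical/temperate models across the species list."""
    return {
        sp: (TROPICAL_MODEL if i % 2 == 0 else TEMPERATE_MODEL)
        for i, sp in enumerate(sorted(species))
    }


def _draw_categorical(
    dist: tuple[tuple[str, float], ...], rng: np.random.Generator
) -> str:
    labels = [k for k, _ in dist]
    probs = np.array([p for _, p in dist], dtype=float)
    probs = probs / probs.sum()
    return labels[int(rng.choice(len(labels), p=probs))]


def simulate_env_reads(
    t: HaplotypeTable,
    n_per_species: int = 10,
    trim_distribution: Mapping[int, float] | None = None,
    n_decoys: int = 5,
    metadata_models: Mapping[str, MetadataModel] | None = None,
    seed: int = 0,
    *,
    spacer: str = "ITS2",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, SyntheticTruth]:
    """Simulate environmental spacer reads with metadata and planted truth.

    Planted reads are reference haplotypes with a sampled 5' truncation
    (default distribution over {0, 1, 2} bp weighted toward the 1-2 bp
    truncations seen in spacer databases; ITS1 reads are never truncated).
    Decoys are single-base variants rejection-sampled until they match no
    haplotype under the 100% rule at any allowed trim. Metadata are drawn
    from the per-species models and from the tropical model for decoys.
    """
    rng = np.random.default_rng(seed)
    if trim_distribution is None:
        trim_distribution = {0: 0.2, 1: 0.4, 2: 0.4} if spacer == "ITS2" \
            else {0: 1.0}
    trims = sorted(trim_distribution)
    tprobs = np.array([trim_distribution[k] for k in trims], dtype=float)
    tprobs = tprobs / tprobs.sum()
    if metadata_models is None:
        metadata_models = default_metadata_models(t.species)

    truth = SyntheticTruth(
        config={"n_per_species": n_per_species, "n_decoys": n_decoys,
                "spacer": spacer, "seed": seed,
                "trim_distribution": {str(k): float(v) for k, v in
                                      trim_distribution.items()}},
        metadata_models={sp: m.as_dict() for sp, m in metadata_models.items()},
    )
    queries: list[tuple[str, str, str]] = []
    meta_rows: list[dict] = []
    counter = 0

    def metadata_for(model: MetadataModel, qid: str) -> dict:
        return {
            "id": qid,
            "latitude": round(float(rng.uniform(-60, 70)), 4),
            "longitude": round(float(rng.uniform(-180, 180)), 4),
            "country": "synthetic",
            "substrate": _draw_categorical(model.substrate, rng),
            "biome": _draw_categorical(model.biome, rng),
            "climate_zone": _draw_categorical(model.climate_zone, rng),
            "MAT": round(float(rng.normal(model.mat_mean, model.mat_sd)), 2),
            "MAP": round(float(rng.normal(model.map_mean, model.map_sd)), 1),
            "pH": round(float(rng.normal(6.0, 1.0)), 2),
        }

    max_trim = max(trims)
    for sp in t.species:
        haps = sorted(t.haplotypes(sp, spacer))
        if not haps:
            continue
        model = metadata_models[sp]
        for _ in range(n_per_species):
            counter += 1
            qid = f"q{counter:04d}"
            hap = haps[int(rng.integers(0, len(haps)))]
            trim = trims[int(rng.choice(len(trims), p=tprobs))]
            queries.append((qid, spacer, hap[trim:]))
            meta_rows.append(metadata_for(model, qid))
            truth.query_origins[qid] = {
                "species": sp, "trim": trim, "decoy": False,
            }

    all_haps = [hap for sp in t.species for hap in t.haplotypes(sp, spacer)]
    for _ in range(n_decoys):
        counter += 1
        qid = f"q{counter:04d}"
        while True:
            hap = all_haps[int(rng.integers(0, len(all_haps)))]
            pos = int(rng.integers(0, len(hap)))
            base = hap[pos]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == base:
                continue
            cand = hap[:pos] + alt + hap[pos + 1:]
            trim = trims[int(rng.choice(len(trims), p=tprobs))]
            cand = cand[trim:]
            if match_query(cand, t, spacer, max_trim).status == "none":
                break
        queries.append((qid, spacer, cand))
        meta_rows.append(metadata_for(TROPICAL_MODEL, qid))
        truth.query_origins[qid] = {"species": None, "trim": trim,
                                    "decoy": True}

    metadata = pd.DataFrame(meta_rows)
    return queries, metadata, truth
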