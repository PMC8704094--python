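"""Exact-match assignment of environmental ITS spacer reads.

Implements a GlobalFungi-style workflow: reference ITS1/ITS2 haplotypes are
collapsed per species, per-spacer distinctiveness between species is
screened (some species are separable by only one of the two spacers), and
environmental queries are assigned under the 100%-identity,
full-length-coverage rule. Database-deposited ITS2 spacers usually lack
1-2 bp at the 5' end, so a bounded 5' truncation of the reference is
tolerated for ITS2 (default 2 bp; 0 for ITS1). N never matches anything,
including another N.

Assigned reads are joined with their sample metadata (substrate, biome,
Köppen-Geiger climate zone, MAT in °C, MAP in mm) and summarised per
species, including a distribution-type call (tropical, temperate/
continental, or global) from climate-zone proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import count_differences
from .seq_io import SequenceSet

SPACERS = ("ITS1", "ITS2")
#: default 5' trim tolerance per spacer (bp)
DEFAULT_TRIM_TOL = {"ITS1": 0, "ITS2": 2}
_ACGT = frozenset("ACGT")

#: Köppen-Geiger first letters grouped for the distribution-type rule
ZONE_GROUPS = {"A": "tropical", "B": "arid", "C": "temperate",
               "D": "continental", "E": "polar"}


@dataclass
class HaplotypeTable:
    """Distinct spacer haplotypes per (species, spacer) with provenance."""

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    provenance: dict[tuple[str, str, str], list[str]] = field(
        default_factory=dict
    )

    @property
    def species(self) -> list[str]:
        return sorted(self.entries)

    def haplotypes(self, species: str, spacer: str) -> set[str]:
        return self.entries.get(species, {}).get(spacer, set())

    def add(self, species: str, spacer: str, seq: str, source_id: str) -> None:
        if spacer not in SPACERS:
            raise ValueError(f"unknown spacer {spacer!r}")
        cell = self.entries.setdefault(species, {}).setdefault(spacer, set())
        cell.add(seq)
        self.provenance.setdefault((species, spacer, seq), []).append(source_id)

    def iter_haplotypes(self, spacer: str) -> Iterable[tuple[str, str]]:
        """Yield (species, haplotype) for one spacer."""
        for sp in self.species:
            for hap in sorted(self.haplotypes(sp, spacer)):
                yield sp, hap

    def shared_haplotypes(self, spacer: str) -> dict[str, list[str]]:
        """Haplotypes present in more than one species (recorded, allowed)."""
        seen: dict[str, list[str]] = {}
        for sp, hap in self.iter_haplotypes(spacer):
            seen.setdefault(hap, []).append(sp)
        return {h: sps for h, sps in seen.items() if len(sps) > 1}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            for spacer in SPACERS:
                for hap in sorted(self.haplotypes(sp, spacer)):
                    rows.append({
                        "species": sp, "spacer": spacer, "haplotype": hap,
                        "sources": ";".join(
                            self.provenance.get((sp, spacer, hap), [])
                        ),
                    })
        return pd.DataFrame(rows,
                            columns=["species", "spacer", "haplotype", "sources"])


def build_reference(
    refs: Mapping[str, SequenceSet],
    species_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse spacer-level reference sequences into a haplotype table.

    ``refs`` maps spacer name -> SequenceSet of that spacer. Species labels
    come from ``species_map`` or from the records. Identical sequences within
    a (species, spacer) cell collapse to one haplotype; identical haplotypes
    across species are kept in both cells (distinctiveness reports them).
    """
    table = HaplotypeTable()
    n = 0
    for spacer, sset in refs.items():
        if spacer not in SPACERS:
            raise ValueError(f"unknown spacer {spacer!r}")
        for rec in sset:
            species = None
            if species_map is not None:
                species = species_map.get(rec.id)
            if species is None:
                species = rec.species
            if not species:
                raise ValueError(f"record {rec.id} has no species label")
            table.add(species, spacer, rec.degapped(), rec.id)
            n += 1
    if n == 0:
        raise ValueError("empty reference input")
    return table


@dataclass(frozen=True)
class DistinctivenessMatrix:
    """Per spacer: minimum pairwise difference count between species'
    haplotypes (end-gap-free) and whether the pair is separable (>= 1)."""

    spacer: str
    min_diffs: dict[tuple[str, str], int]

    def separable(self, a: str, b: str) -> bool:
        return self.min_diffs[tuple(sorted((a, b)))] >= 1

    def get(self, a: str, b: str) -> int:
        return self.min_diffs[tuple(sorted((a, b)))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"speciesA": a, "speciesB": b, "spacer": self.spacer,
             "min_differences": d, "separable": d >= 1}
            for (a, b), d in sorted(self.min_diffs.items())
        ]
        return pd.DataFrame(rows)


def distinctiveness(
    t: HaplotypeTable, spacers: Sequence[str] = SPACERS
) -> dict[str, DistinctivenessMatrix]:
    """Minimum cross-species haplotype differences per spacer.

    Zero means some haplotype is shared between the two species and the
    spacer cannot separate them (only the other spacer, if distinctive,
    links environmental reads to one species unequivocally).
    """
    if len(t.species) < 2:
        raise ValueError("need at least 2 species")
    out: dict[str, DistinctivenessMatrix] = {}
    for spacer in spacers:
        mins: dict[tuple[str, str], int] = {}
        sp = t.species
        for i, a in enumerate(sp):
            for b in sp[i + 1:]:
                haps_a = t.haplotypes(a, spacer)
                haps_b = t.haplotypes(b, spacer)
                if not haps_a or not haps_b:
                    continue
                mins[(a, b)] = min(
                    count_differences(ha, hb)
                    for ha in haps_a for hb in haps_b
                )
        out[spacer] = DistinctivenessMatrix(spacer=spacer, min_diffs=mins)
    return out


def _exact_equal(q: str, h: str) -> bool:
    # 100% rule over the full compared length; N is always a mismatch
    return len(q) == len(h) and all(
        a == b and a in _ACGT for a, b in zip(q, h)
    )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query against the haplotype table."""

    query_id: str
    spacer: str
    status: str  # unique | ambiguous | none
    species: frozenset[str]
    haplotype: str | None
    trim: int  # 5' bases removed from the reference to obtain the match

    def __post_init__(self) -> None:
        if self.status == "unique" and len(self.species) != 1:
            raise ValueError("unique match must have exactly one species")
        if self.status == "ambiguous" and len(self.species) < 2:
            raise ValueError("ambiguous match needs >= 2 species")


def match_query(
    q: str,
    t: HaplotypeTable,
    spacer: str,
    trim_tol: int | None = None,
    *,
    query_id: str = "",
) -> MatchResult:
    """Match one spacer read under the 100%-identity full-coverage rule.

    The query matches haplotype h iff q == h, or q == h with its first
    k <= trim_tol bases removed (5' trim only, no 3' slack). The smallest
    trim achieving a match is reported.
    """
    if trim_tol is None:
        trim_tol = DEFAULT_TRIM_TOL.get(spacer, 0)
    if trim_tol < 0:
        raise ValueError("trim_tol must be >= 0")
    q = q.upper().replace("U", "T")
    matched: set[str] = set()
    best_hap: str | None = None
    best_trim = 0
    for k in range(trim_tol + 1):
        for sp, hap in t.iter_haplotypes(spacer):
            if len(hap) - k == len(q) and _exact_equal(q, hap[k:]):
                if best_hap is None:
                    best_hap, best_trim = hap, k  # smallest trim reported
                matched.add(sp)
    status = ("none" if not matched
              else "unique" if len(matched) == 1 else "ambiguous")
    return MatchResult(query_id=query_id, spacer=spacer, status=status,
                       species=frozenset(matched), haplotype=best_hap,
                       trim=best_trim if matched else 0)


METADATA_COLUMNS = ("id", "latitude", "longitude", "country", "substrate",
                    "biome", "climate_zone", "MAT", "MAP", "pH")


def assign_dataset(
    queries: Iterable[tuple[str, str, str]],
    metadata: pd.DataFrame,
    t: HaplotypeTable,
    trim_tol: Mapping[str, int] = DEFAULT_TRIM_TOL,
) -> pd.DataFrame:
    """Assign every query and join its sample metadata.

    ``queries`` yields (id, spacer, sequence). Metadata must carry an ``id``
    column; queries without metadata are kept and flagged as orphans.
    Ambiguous assignments are retained and flagged (summaries exclude them
    by default).
    """
    rows = []
    for qid, spacer, seq in queries:
        r = match_query(seq, t, spacer, trim_tol.get(spacer), query_id=qid)
        rows.append({
            "id": qid, "spacer": spacer, "status": r.status,
            "species": (next(iter(r.species)) if r.status == "unique"
                        else None),
            "species_set": ";".join(sorted(r.species)),
            "trim": r.trim,
        })
    out = pd.DataFrame(rows, columns=["id", "spacer", "status", "species",
                                      "species_set", "trim"])
    if not metadata.empty and "id" not in metadata.columns:
        raise ValueError("metadata must have an 'id' column")
    merged = out.merge(metadata, on="id", how="left",
                       indicator=True) if not out.empty else out.assign(
                           _merge=pd.Series(dtype=object))
    if "_merge" in merged.columns:
        merged["orphan"] = merged["_merge"] == "left_only"
        merged = merged.drop(columns="_merge")
    else:
        merged["orphan"] = True
    return merged


@dataclass(frozen=True)
class SpeciesBiogeoSummary:
    """Biogeographic profile of one species over its assigned samples."""

    species: str
    n_samples: int
    substrate_proportions: dict[str, float]
    biome_proportions: dict[str, float]
    mean_mat: float | None
    mean_map: float | None
    climate_zone_counts: dict[str, int]
    distribution_type: str | None

    def as_dict(self) -> dict:
        return {
            "species": self.species, "n_samples": self.n_samples,
            "substrate_proportions": self.substrate_proportions,
            "biome_proportions": self.biome_proportions,
            "mean_MAT_C": self.mean_mat, "mean_MAP_mm": self.mean_map,
            "climate_zone_counts": self.climate_zone_counts,
            "distribution_type": self.distribution_type,
        }


def zone_group(koppen_label: str) -> str:
    """Group a Köppen-Geiger label by its leading letter."""
    if not koppen_label:
        return "unknown"
    return ZONE_GROUPS.get(koppen_label[0].upper(), "unknown")


def classify_distribution(
    zone_counts: Mapping[str, int],
    *,
    tropical_threshold: float = 0.8,
    temperate_threshold: float = 0.8,
) -> str | None:
    """Distribution-type rule over climate-zone proportions.

    Tropical if >= 80% of samples fall in tropical zones; temperate/
    continental if >= 80% fall in temperate + continental zones; else
    global. Thresholds configurable and echoed in reports.
    """
    total = sum(zone_counts.values())
    if total == 0:
        return None
    groups: dict[str, int] = {}
    for label, n in zone_counts.items():
        groups[zone_group(label)] = groups.get(zone_group(label), 0) + n
    p_trop = groups.get("tropical", 0) / total
    p_temp = (groups.get("temperate", 0) + groups.get("continental", 0)) / total
    if p_trop >= tropical_threshold:
        return "tropical"
    if p_temp >= temperate_threshold:
        return "temperate/continental"
    return "global"


def _proportions(series: pd.Series) -> dict[str, float]:
    counts = series.dropna().value_counts()
    total = int(counts.sum())
    if total == 0:
        return {}
    return {str(k): round(int(v) / total, 4) for k, v in counts.items()}


def summarize_species(
    assignments: pd.DataFrame,
    *,
    include_ambiguous: bool = False,
    all_species: Sequence[str] | None = None,
    tropical_threshold: float = 0.8,
    temperate_threshold: float = 0.8,
) -> dict[str, SpeciesBiogeoSummary]:
    """Per-species biogeographic summaries over assigned samples.

    Ambiguous assignments are excluded by default (species are linked to
    reads unequivocally); ``include_ambiguous`` adds each ambiguous read to
    every species of its set for sensitivity analysis. Species listed in
    ``all_species`` but never assigned get an n=0 summary.
    """
    frames: list[pd.DataFrame] = []
    unique = assignments[assignments["status"] == "unique"]
    frames.append(unique)
    if include_ambiguous:
        amb = assignments[assignments["status"] == "ambiguous"].copy()
        if not amb.empty:
            amb = amb.assign(
                species=amb["species_set"].str.split(";")
            ).explode("species")
            frames.append(amb)
    data = pd.concat(frames) if len(frames) > 1 else frames[0]

    out: dict[str, SpeciesBiogeoSummary] = {}
    universe = set(all_species or []) | set(data["species"].dropna())
    for sp in sorted(universe):
        sub = data[data["species"] == sp]
        n = len(sub)
        zones = sub["climate_zone"].dropna() if "climate_zone" in sub else \
            pd.Series(dtype=object)
        zone_counts = {str(k): int(v) for k, v in zones.value_counts().items()}
        mat = (float(sub["MAT"].dropna().mean())
               if "MAT" in sub and sub["MAT"].notna().any() else None)
        map_ = (float(sub["MAP"].dropna().mean())
                if "MAP" in sub and sub["MAP"].notna().any() else None)
        out[sp] = SpeciesBiogeoSummary(
            species=sp, n_samples=n,
            substrate_proportions=_proportions(sub["substrate"])
            if "substrate" in sub else {},
            biome_proportions=_proportions(sub["biome"])
            if "biome" in sub else {},
            mean_mat=mat, mean_map=map_,
            climate_zone_counts=zone_counts,
            distribution_type=classify_distribution(
                zone_counts, tropical_threshold=tropical_threshold,
                temperate_threshold=temperate_threshold,
            ),
        )
    return out
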