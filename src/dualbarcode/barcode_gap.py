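"""Barcoding-gap analysis.

Splits the off-diagonal entries of a pairwise distance matrix into
intraspecific and interspecific sets, reports the barcoding gap as the open
interval (max intraspecific, min interspecific), builds dual histograms on a
common grid (default bin widths 0.001 and 0.0005 for fine-grained ITS data),
and locates the extreme species pairs (lowest and highest interspecific
divergence).

Histogram bins are right-closed, left-open, except the first bin which is
closed at 0 — a deterministic edge rule stated in all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

from .distances import DistanceMatrix


class IntraEntry(NamedTuple):
    idA: str
    idB: str
    species: str
    d: float


class InterEntry(NamedTuple):
    idA: str
    idB: str
    speciesA: str
    speciesB: str
    d: float


@dataclass(frozen=True)
class DistancePartition:
    """Exhaustive, non-overlapping split of off-diagonal distances.

    ``n_excluded`` counts undefined (NaN-masked) entries left out of both
    lists; singleton species contribute no intra entries.
    """

    intra: tuple[IntraEntry, ...]
    inter: tuple[InterEntry, ...]
    n_excluded: int = 0

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([e.d for e in self.intra])

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([e.d for e in self.inter])


@dataclass(frozen=True)
class GapReport:
    """The barcoding gap: the open interval (max intra, min inter).

    ``overlap`` is True when the distributions overlap (width <= 0);
    ``defined`` is False when either list was empty, in which case the
    missing bound is NaN and no gap statement is made.
    """

    max_intra: float
    min_inter: float
    overlap: bool
    defined: bool

    @property
    def gap_low(self) -> float:
        return self.max_intra

    @property
    def gap_high(self) -> float:
        return self.min_inter

    @property
    def width(self) -> float:
        return self.min_inter - self.max_intra

    def as_dict(self) -> dict:
        return {
            "max_intra": self.max_intra,
            "min_inter": self.min_inter,
            "gap_low_percent": round(self.max_intra * 100, 1)
            if self.defined else None,
            "gap_high_percent": round(self.min_inter * 100, 1)
            if self.defined else None,
            "overlap": self.overlap,
            "defined": self.defined,
            "width": self.width if self.defined else None,
        }


@dataclass(frozen=True)
class Histogram:
    """Intra/inter counts on shared uniform edges starting at 0."""

    bin_width: float
    edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray


class PairExtreme(NamedTuple):
    speciesA: str
    speciesB: str
    d: float


@dataclass(frozen=True)
class ExtremePairs:
    """Global extremes over species-pair-level minima and maxima."""

    min_inter_pair: PairExtreme
    max_inter_pair: PairExtreme
    per_species_pair: dict[tuple[str, str], tuple[float, float]]


def partition_distances(
    m: DistanceMatrix, species_map: Mapping[str, str]
) -> DistancePartition:
    """Partition off-diagonal entries by species labels.

    Every defined entry lands in exactly one list; NaN entries are counted
    in ``n_excluded``. Unlabeled ids are an error.
    """
    for label in m.labels:
        if label not in species_map:
            raise KeyError(f"id {label!r} has no species label")
    intra: list[IntraEntry] = []
    inter: list[InterEntry] = []
    excluded = 0
    labels = m.labels
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            d = float(m.values[i, j])
            if math.isnan(d):
                excluded += 1
                continue
            sa, sb = species_map[a], species_map[b]
            if sa == sb:
                intra.append(IntraEntry(a, b, sa, d))
            else:
                inter.append(InterEntry(a, b, sa, sb, d))
    return DistancePartition(intra=tuple(intra), inter=tuple(inter),
                             n_excluded=excluded)


def gap_report(p: DistancePartition) -> GapReport:
    """Report the gap bounds; flagged undefined if either list is empty."""
    has_intra = len(p.intra) > 0
    has_inter = len(p.inter) > 0
    max_intra = float(p.intra_values.max()) if has_intra else float("nan")
    min_inter = float(p.inter_values.min()) if has_inter else float("nan")
    defined = has_intra and has_inter
    overlap = bool(defined and max_intra >= min_inter)
    return GapReport(max_intra=max_intra, min_inter=min_inter,
                     overlap=overlap, defined=defined)


def _bin_index(values: np.ndarray, bin_width: float) -> np.ndarray:
    # right-closed, left-open bins; first bin closed at 0:
    # bin k covers (k*w, (k+1)*w], bin 0 covers [0, w]
    idx = np.ceil(values / bin_width).astype(int) - 1
    return np.clip(idx, 0, None)


def gap_histogram(p: DistancePartition, bin_width: float = 0.001) -> Histogram:
    """Dual histogram of intra and inter distances on common edges."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra, inter = p.intra_values, p.inter_values
    top = max(
        [v.max() for v in (intra, inter) if v.size > 0], default=0.0
    )
    n_bins = max(int(math.ceil(top / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts = np.zeros(n_bins, dtype=int)
    inter_counts = np.zeros(n_bins, dtype=int)
    if intra.size:
        np.add.at(intra_counts, _bin_index(intra, bin_width), 1)
    if inter.size:
        np.add.at(inter_counts, _bin_index(inter, bin_width), 1)
    return Histogram(bin_width=bin_width, edges=edges,
                     intra_counts=intra_counts, inter_counts=inter_counts)


def extreme_pairs(
    m: DistanceMatrix, species_map: Mapping[str, str]
) -> ExtremePairs:
    """Per species pair, the min and max strain-pair distance; globally,
    the minimum of the minima and the maximum of the maxima."""
    p = partition_distances(m, species_map)
    if not p.inter:
        raise ValueError("need at least 2 species with defined distances")
    per: dict[tuple[str, str], tuple[float, float]] = {}
    for e in p.inter:
        key = tuple(sorted((e.speciesA, e.speciesB)))
        lo, hi = per.get(key, (math.inf, -math.inf))
        per[key] = (min(lo, e.d), max(hi, e.d))
    min_key = min(per, key=lambda k: per[k][0])
    max_key = max(per, key=lambda k: per[k][1])
    return ExtremePairs(
        min_inter_pair=PairExtreme(*min_key, per[min_key][0]),
        max_inter_pair=PairExtreme(*max_key, per[max_key][1]),
        per_species_pair=per,
    )
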