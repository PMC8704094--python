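"""Pairwise alignment, substitution counting and K2P/identity distances.

The Kimura two-parameter (K2P) distance corrects the observed proportions of
transitions (P) and transversions (Q) for multiple hits:

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites with a gap or N on either row are excluded pairwise (pairwise
deletion); complete deletion is available as a flag. Saturated pairs (log
argument <= 0) and empty overlaps yield NaN, which distance matrices carry
as masked entries rather than dropping silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import Align

from .seq_io import SequenceRecord, SequenceSet

Method = Literal["k2p", "p", "identity"]

_A, _C, _G, _T = (ord(c) for c in "ACGT")


@dataclass(frozen=True)
class AlignmentParams:
    """Needleman-Wunsch scoring: defaults match 1 / mismatch -1 /
    gap open -2 / gap extend -0.5; recorded in every report."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    free_end_gaps: bool = False

    def as_dict(self) -> dict[str, float | bool]:
        return {
            "match": self.match, "mismatch": self.mismatch,
            "gap_open": self.gap_open, "gap_extend": self.gap_extend,
            "free_end_gaps": self.free_end_gaps,
        }


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows; degapping recovers the inputs."""

    idA: str
    idB: str
    rowA: str
    rowB: str
    params: AlignmentParams = AlignmentParams()
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.rowA) != len(self.rowB):
            raise ValueError("aligned rows must have equal length")


@dataclass(frozen=True)
class SubCounts:
    """Substitution counts under pairwise deletion.

    L counts columns with both residues in ACGT; s transitions (A<->G,
    C<->T); v transversions. P = s/L and Q = v/L are the K2P proportions.
    """

    L: int
    s: int
    v: int

    def __post_init__(self) -> None:
        if self.s + self.v > self.L:
            raise ValueError("s + v cannot exceed L")

    @property
    def P(self) -> float:
        return self.s / self.L if self.L else float("nan")

    @property
    def Q(self) -> float:
        return self.v / self.L if self.L else float("nan")


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    if params.free_end_gaps:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def global_align(a: SequenceRecord, b: SequenceRecord,
                 params: AlignmentParams = AlignmentParams()) -> AlignedPair:
    """Global (Needleman-Wunsch, affine-gap) alignment of two records.

    Deterministic: of co-optimal alignments the aligner's first is taken,
    so identical inputs always give identical output.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    if a.locus is not None and b.locus is not None and a.locus != b.locus:
        raise ValueError(f"locus mismatch: {a.locus} vs {b.locus}")
    sa, sb = a.degapped(), b.degapped()
    aln = _aligner(params).align(sa, sb)
    best = aln[0]
    return AlignedPair(idA=a.id, idB=b.id, rowA=str(best[0]),
                       rowB=str(best[1]), params=params, score=aln.score)


def _encode(row: str) -> np.ndarray:
    return np.frombuffer(row.encode("ascii"), dtype=np.uint8)


def substitution_counts(pair: AlignedPair) -> SubCounts:
    """Count compared sites, transitions and transversions (pairwise
    deletion: any column with gap or N on either row is excluded)."""
    return counts_from_rows(pair.rowA, pair.rowB)


def counts_from_rows(rowA: str, rowB: str) -> SubCounts:
    a, b = _encode(rowA), _encode(rowB)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    acgt_a = (a == _A) | (a == _C) | (a == _G) | (a == _T)
    acgt_b = (b == _A) | (b == _C) | (b == _G) | (b == _T)
    valid = acgt_a & acgt_b
    L = int(valid.sum())
    diff = valid & (a != b)
    transition = diff & (
        ((a == _A) & (b == _G)) | ((a == _G) & (b == _A))
        | ((a == _C) & (b == _T)) | ((a == _T) & (b == _C))
    )
    s = int(transition.sum())
    v = int(diff.sum()) - s
    return SubCounts(L=L, s=s, v=v)


def k2p(counts: SubCounts) -> float:
    """K2P distance from substitution counts; NaN when undefined.

    Undefined cases: L = 0 (no comparable sites) and saturation, i.e.
    (1 - 2P - Q) <= 0 or (1 - 2Q) <= 0.
    """
    if counts.L == 0:
        return float("nan")
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(counts: SubCounts) -> float:
    if counts.L == 0:
        return float("nan")
    return (counts.s + counts.v) / counts.L


def percent_identity(
    pair: AlignedPair,
    mode: Literal["compared_sites", "shorter_seq"] = "compared_sites",
) -> float:
    """Percent identity of an aligned pair.

    ``compared_sites`` (default): matches / columns with both residues in
    ACGT. ``shorter_seq``: matches / length of the shorter degapped input.
    """
    counts = substitution_counts(pair)
    matches = counts.L - counts.s - counts.v
    if mode == "compared_sites":
        denom = counts.L
    elif mode == "shorter_seq":
        denom = min(len(pair.rowA.replace("-", "")),
                    len(pair.rowB.replace("-", "")))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ValueError("zero denominator for percent identity")
    return 100.0 * matches / denom


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction-scale distance as percent, rounded half-even."""
    scaled = round(fraction * 100.0, decimals)
    return f"{scaled:.{decimals}f}"


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix (fraction units) with NaN-masked entries."""

    labels: list[str]
    values: np.ndarray
    method: Method = "k2p"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        mask = ~np.isnan(self.values)
        if not np.array_equal(mask, mask.T) or not np.allclose(
            self.values[mask & mask.T], self.values.T[mask & mask.T]
        ):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                d = self.values[i, j]
                rows.append({
                    "idA": a, "idB": self.labels[j], "method": self.method,
                    "distance": d,
                    "percent": None if math.isnan(d) else round(d * 100, 1),
                })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def _pair_value(counts: SubCounts, method: Method) -> float:
    if method == "k2p":
        return k2p(counts)
    if method == "p":
        return p_distance(counts)
    if method == "identity":
        if counts.L == 0:
            return float("nan")
        return 1.0 - (counts.L - counts.s - counts.v) / counts.L
    raise ValueError(f"unknown method {method!r}")


def distance_matrix(
    sset: SequenceSet,
    method: Method = "k2p",
    params: AlignmentParams = AlignmentParams(),
    *,
    aligned: bool = False,
) -> DistanceMatrix:
    """All-vs-all distances.

    With ``aligned=True`` rows are taken as a supplied multiple alignment
    (equal lengths required) and compared column-wise; otherwise each pair is
    globally aligned independently (the default, matching two-sequence
    barcode comparisons). Undefined entries are NaN-masked, never dropped.
    """
    recs = sset.records
    if len(recs) < 2:
        raise ValueError("need at least 2 records")
    n = len(recs)
    values = np.zeros((n, n))
    if aligned:
        lengths = {len(r.residues) for r in recs}
        if len(lengths) != 1:
            raise ValueError("aligned=True requires equal-length rows")
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                counts = counts_from_rows(recs[i].residues, recs[j].residues)
            else:
                counts = substitution_counts(
                    global_align(recs[i], recs[j], params)
                )
            values[i, j] = values[j, i] = _pair_value(counts, method)
    return DistanceMatrix(labels=[r.id for r in recs], values=values,
                          method=method)


def count_differences(a: str, b: str,
                      params: AlignmentParams | None = None) -> int:
    """Minimum difference count between two sequences under end-gap-free
    comparison (mismatches + internal indel columns; terminal overhangs are
    not penalised). Equal-length inputs take a Hamming fast path."""
    if len(a) == len(b):
        return int(sum(1 for x, y in zip(a, b) if x != y))
    p = params or AlignmentParams(free_end_gaps=True)
    if not p.free_end_gaps:
        p = AlignmentParams(p.match, p.mismatch, p.gap_open, p.gap_extend, True)
    best = _aligner(p).align(a, b)[0]
    rowA, rowB = str(best[0]), str(best[1])
    # trim terminal gap runs (end-gap-free semantics)
    start, end = 0, len(rowA)
    while start < end and (rowA[start] == "-" or rowB[start] == "-"):
        start += 1
    while end > start and (rowA[end - 1] == "-" or rowB[end - 1] == "-"):
        end -= 1
    return sum(1 for x, y in zip(rowA[start:end], rowB[start:end]) if x != y)
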