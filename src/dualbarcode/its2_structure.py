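"""Classification of ITS2 helix base-pair substitutions for the CBC
species concept.

Against a helix-annotated consensus secondary structure, each structural
base pair is compared between species and the change classified as:

* CBC (compensatory base change): both partners change and both states are
  canonical Watson-Crick pairs (G·C, C·G, A·U, U·A) — structure perfectly
  preserved; the signal used to delimit sexually incompatible species.
* hCBC (hemi-compensatory): one partner changes, converting a canonical
  pair to a near-isosteric wobble pair (G·U, A⁺·C, either orientation) or
  back — minor perturbation.
* non-CBC: the change produces (or starts from) a non-canonical pair —
  the largest perturbation.
* combined: both partners change between paired categories without being a
  canonical-to-canonical event (e.g. G·C → U·G), reported with its
  decomposition rather than forced into hCBC/non-CBC.

Structure work is done in the RNA alphabet (T converted to U on entry).
Differences at unpaired alignment columns are tallied separately as single
mutations in hairpin loops and junction areas.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_io import SecondaryStructure, SequenceSet

CANONICAL = frozenset({("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")})
#: wobble pairs: G·U and protonated A⁺·C, both orientations (configurable)
WOBBLE_BOTH = frozenset({("G", "U"), ("U", "G"), ("A", "C"), ("C", "A")})
_RNA = frozenset("ACGU")


class EventClass(str, Enum):
    IDENTICAL = "identical"
    CBC = "CBC"
    HCBC = "hCBC"
    NONCBC = "nonCBC"
    COMBINED = "combined"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class BasePairState:
    """The two bases observed at one structural pair (alignment columns
    pos5 < pos3), RNA alphabet."""

    pos5: int
    pos3: int
    bases: tuple[str, str]

    def category(self, wobble: frozenset = WOBBLE_BOTH) -> str:
        b = self.bases
        if b[0] not in _RNA or b[1] not in _RNA:
            return "gapped"
        if b in CANONICAL:
            return "canonical"
        if b in wobble:
            return "wobble"
        return "noncanonical"


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def classify_pair_change(
    x: BasePairState, y: BasePairState,
    wobble: frozenset = WOBBLE_BOTH,
) -> EventClass:
    """Classify the change between two states of the same structural pair.

    Total and deterministic over all inputs; symmetric for identical, CBC
    and non-CBC (hCBC/combined directionality is noted in reports).
    """
    cx, cy = x.category(wobble), y.category(wobble)
    if cx == "gapped" or cy == "gapped":
        return EventClass.INDETERMINATE
    if x.bases == y.bases:
        return EventClass.IDENTICAL
    if cx == "noncanonical" or cy == "noncanonical":
        return EventClass.NONCBC
    n_diff = sum(a != b for a, b in zip(x.bases, y.bases))
    if n_diff == 2:
        if cx == "canonical" and cy == "canonical":
            return EventClass.CBC
        return EventClass.COMBINED
    # single-base change between paired categories: canonical <-> wobble
    if cx != cy:
        return EventClass.HCBC
    # same category, one base changed: unreachable for canonical/wobble
    # alphabets, kept total for safety
    return EventClass.COMBINED


@dataclass
class EventTable:
    """Per-helix CBC/hCBC/non-CBC events between species.

    ``events`` holds one row per non-identical, determinate structural-pair
    comparison; ``loop_mutations`` the per-species-pair tally of single
    mutations at unpaired (loop/junction) columns; ``indeterminate`` the
    per-pair count of comparisons skipped for gaps/N.
    """

    events: pd.DataFrame
    loop_mutations: pd.DataFrame
    species: tuple[str, ...]
    mode: str
    n_structural_pairs: int
    indeterminate: dict[tuple[str, str], int]
    ambiguous_species: frozenset[str] = frozenset()

    EVENT_COLUMNS = ("speciesA", "speciesB", "helix", "pos5", "pos3",
                     "pairA", "pairB", "event")

    def helix_counts(self) -> pd.DataFrame:
        """Counts by (speciesA, speciesB, helix, event)."""
        if self.events.empty:
            return pd.DataFrame(
                columns=["speciesA", "speciesB", "helix", "event", "count"]
            )
        return (
            self.events.groupby(
                ["speciesA", "speciesB", "helix", "event"], as_index=False
            )
            .size()
            .rename(columns={"size": "count"})
        )

    def cbc_counts(self) -> dict[tuple[str, str], int]:
        """CBC count per (sorted) species pair, zero-filled."""
        out: dict[tuple[str, str], int] = {}
        for i, a in enumerate(self.species):
            for b in self.species[i + 1:]:
                out[(a, b)] = 0
        if not self.events.empty:
            cbc = self.events[self.events["event"] == EventClass.CBC.value]
            for _, row in cbc.iterrows():
                key = tuple(sorted((row["speciesA"], row["speciesB"])))
                out[key] = out.get(key, 0) + 1
        return out


def _consensus(rows: Sequence[str]) -> tuple[str, bool]:
    """Majority-rule consensus of equal-length rows; ties and non-majority
    columns become N (flagged ambiguous)."""
    if len(rows) == 1:
        return rows[0], False
    ambiguous = False
    cols = []
    for column in zip(*rows):
        counts = Counter(column).most_common()
        if len(counts) == 1:
            cols.append(counts[0][0])
        elif counts[0][1] > counts[1][1]:
            cols.append(counts[0][0])
            ambiguous = True
        else:
            cols.append("N")
            ambiguous = True
    return "".join(cols), ambiguous


def project_structure(
    structure: SecondaryStructure, ref_row: str
) -> SecondaryStructure:
    """Map an ungapped-coordinate structure onto alignment coordinates using
    one gapped reference row; gap columns become unpaired."""
    ungapped_to_col: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch != "-":
            k += 1
            ungapped_to_col[k] = col
    if k != structure.length:
        raise ValueError(
            f"reference row has {k} residues, structure length {structure.length}"
        )
    pairs = {}
    for (i, j), label in structure.helix_of.items():
        pairs[(ungapped_to_col[i], ungapped_to_col[j])] = label
    paired = {p for ij in pairs for p in ij}
    unpaired = frozenset(set(range(1, len(ref_row) + 1)) - paired)
    return SecondaryStructure(
        length=len(ref_row),
        pairs=frozenset(pairs),
        helix_of=pairs,
        unpaired=unpaired,
    )


def enumerate_events(
    aln: SequenceSet,
    structure: SecondaryStructure,
    *,
    reference_species: str | None = None,
    wobble: frozenset = WOBBLE_BOTH,
) -> EventTable:
    """Enumerate per-helix substitution events over a species alignment.

    The structure must be given on alignment coordinates (length equal to
    the alignment width; see :func:`project_structure`). Species with
    several rows are collapsed to a majority-rule consensus first (flagged).
    With ``reference_species`` set, every other species is compared to that
    reference only; otherwise all species pairs are compared.
    """
    width = {len(r.residues) for r in aln.records}
    if len(width) != 1:
        raise ValueError("alignment rows must have equal length")
    if width.pop() != structure.length:
        raise ValueError("alignment length != structure length")

    by_species: dict[str, list[str]] = {}
    for rec in aln.records:
        if not rec.species:
            raise ValueError(f"record {rec.id} has no species label")
        by_species.setdefault(rec.species, []).append(to_rna(rec.residues))

    consensus: dict[str, str] = {}
    ambiguous: set[str] = set()
    for sp, rows in by_species.items():
        cons, amb = _consensus(rows)
        consensus[sp] = cons
        if amb:
            ambiguous.add(sp)

    species = tuple(sorted(consensus))
    if reference_species is not None:
        if reference_species not in consensus:
            raise ValueError(f"unknown reference species {reference_species!r}")
        mode = "reference"
        compare = [(reference_species, sp) for sp in species
                   if sp != reference_species]
    else:
        mode = "pairwise"
        compare = [(a, b) for i, a in enumerate(species)
                   for b in species[i + 1:]]

    sorted_pairs = sorted(structure.pairs)
    event_rows: list[dict] = []
    loop_rows: list[dict] = []
    indeterminate: dict[tuple[str, str], int] = {}
    for sa, sb in compare:
        ra, rb = consensus[sa], consensus[sb]
        n_indet = 0
        for i, j in sorted_pairs:
            x = BasePairState(i, j, (ra[i - 1], ra[j - 1]))
            y = BasePairState(i, j, (rb[i - 1], rb[j - 1]))
            ev = classify_pair_change(x, y, wobble)
            if ev is EventClass.INDETERMINATE:
                n_indet += 1
                continue
            if ev is EventClass.IDENTICAL:
                continue
            event_rows.append({
                "speciesA": sa, "speciesB": sb,
                "helix": structure.helix_of[(i, j)],
                "pos5": i, "pos3": j,
                "pairA": "".join(x.bases), "pairB": "".join(y.bases),
                "event": ev.value,
            })
        n_loop = sum(
            1 for p in structure.unpaired
            if ra[p - 1] != rb[p - 1]
            and ra[p - 1] in _RNA and rb[p - 1] in _RNA
        )
        loop_rows.append({"speciesA": sa, "speciesB": sb, "count": n_loop})
        indeterminate[(sa, sb)] = n_indet

    events = pd.DataFrame(event_rows, columns=list(EventTable.EVENT_COLUMNS))
    loops = pd.DataFrame(loop_rows, columns=["speciesA", "speciesB", "count"])
    return EventTable(
        events=events, loop_mutations=loops, species=species, mode=mode,
        n_structural_pairs=len(sorted_pairs), indeterminate=indeterminate,
        ambiguous_species=frozenset(ambiguous),
    )


def cbc_species_support(t: EventTable) -> set[str]:
    """Species carrying at least one CBC against every other congener —
    the species the CBC concept corroborates. Requires pairwise mode."""
    if t.mode != "pairwise":
        raise ValueError("CBC support needs a pairwise-mode event table")
    counts = t.cbc_counts()
    supported: set[str] = set()
    for sp in t.species:
        others = [o for o in t.species if o != sp]
        if others and all(
            counts[tuple(sorted((sp, o)))] >= 1 for o in others
        ):
            supported.add(sp)
    return supported
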