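"""Sequence and secondary-structure I/O.

Reads and writes multi-FASTA barcode sequence sets (ITS, ITS1, ITS2, 28S,
tef1-α), parses dot-bracket RNA secondary-structure files with helix-span
annotations, and delimits the ITS1/ITS2 spacers of a full ITS amplicon from
conserved anchor motifs flanking the 5.8S gene.

Coordinates in all public reports are 1-based, closed intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

LOCI = frozenset({"ITS", "ITS1", "ITS2", "28S", "tef1a"})

#: residues accepted after normalization (DNA convention: U -> T)
_ALLOWED = frozenset("ACGTN-")
#: IUPAC ambiguity codes mapped to N in lenient mode
_IUPAC_AMBIG = frozenset("RYSWKMBDHV")

_IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class SequenceError(ValueError):
    """Malformed sequence input (bad residues, duplicate ids, empty files)."""


def normalize_residues(raw: str, *, strict: bool = True) -> str:
    """Uppercase, convert U->T (DNA convention) and validate residues.

    In strict mode (default) any character outside ``ACGTN-`` raises
    :class:`SequenceError` with its 1-based position; in lenient mode IUPAC
    ambiguity codes are mapped to N instead.
    """
    if not raw:
        raise SequenceError("empty sequence")
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        if ch == "U":
            ch = "T"
        if ch not in _ALLOWED:
            if not strict and ch in _IUPAC_AMBIG:
                ch = "N"
            else:
                raise SequenceError(
                    f"illegal residue {ch!r} at position {pos}"
                )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """A single labeled barcode sequence.

    ``id`` is the strain or accession identifier, ``species`` the (optional)
    species label and ``locus`` one of ``ITS, ITS1, ITS2, 28S, tef1a``.
    Residues are stored uppercased with U normalized to T.
    """

    id: str
    residues: str
    species: str | None = None
    locus: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"{self.id}: empty residues")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise SequenceError(
                f"{self.id}: non-normalized residues {sorted(bad)}; "
                "use normalize_residues() on ingest"
            )
        if self.locus is not None and self.locus not in LOCI:
            raise SequenceError(f"{self.id}: unknown locus {self.locus!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class SequenceSet:
    """Ordered collection of records sharing a locus, with unique ids."""

    records: list[SequenceRecord]
    locus: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            if self.locus is not None and rec.locus not in (None, self.locus):
                raise SequenceError(
                    f"{rec.id}: locus {rec.locus!r} != set locus {self.locus!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, int):
            return self.records[key]
        for rec in self.records:
            if rec.id == key:
                return rec
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_map(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records if r.species}


# ---------------------------------------------------------------------------
# FASTA + species map I/O


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, species) into a dict."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise SequenceError(f"species map row too short: {row!r}")
            out[row[0]] = row[1]
    return out


def write_species_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for k, v in mapping.items():
            w.writerow([k, v])


def read_fasta(
    path: str | Path,
    locus: str | None = None,
    species_map: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> SequenceSet:
    """Read a multi-FASTA into a :class:`SequenceSet`.

    Species labels come from ``species_map`` when given; otherwise headers of
    the form ``id|species`` are honoured (the map takes precedence).
    """
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        header = bio.id
        rec_id, _, header_species = header.partition("|")
        species = None
        if species_map is not None and rec_id in species_map:
            species = species_map[rec_id]
        elif header_species:
            species = header_species.replace("_", " ")
        try:
            residues = normalize_residues(str(bio.seq), strict=strict)
        except SequenceError as exc:
            raise SequenceError(f"{rec_id}: {exc}") from exc
        records.append(
            SequenceRecord(id=rec_id, residues=residues,
                           species=species, locus=locus)
        )
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return SequenceSet(records=records, locus=locus)


def write_fasta(sset: SequenceSet | Iterable[SequenceRecord],
                path: str | Path) -> None:
    """Write records as FASTA with ``id|species`` headers (round-trippable)."""
    bio_records = []
    for rec in sset:
        header = rec.id
        if rec.species:
            header = f"{rec.id}|{rec.species.replace(' ', '_')}"
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=header, description="")
        )
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Dot-bracket secondary structure


class StructureError(ValueError):
    """Malformed dot-bracket input or helix annotation."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Helix-annotated base-pair map of an RNA secondary structure.

    Positions are 1-based. ``pairs`` holds (i, j) with i < j; ``helix_of``
    assigns each pair a label in {H1, H2, H3, other}; ``unpaired`` holds all
    positions in no pair. ``pairs`` and ``unpaired`` partition 1..length.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    helix_of: Mapping[tuple[int, int], str]
    unpaired: frozenset[int]

    def __post_init__(self) -> None:
        used: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair {(i, j)} out of range")
            if i in used or j in used:
                raise StructureError(f"position in more than one pair: {(i, j)}")
            used.update((i, j))
        if used & set(self.unpaired):
            raise StructureError("paired position listed as unpaired")
        if used | set(self.unpaired) != set(range(1, self.length + 1)):
            raise StructureError("pairs and unpaired do not partition 1..length")
        if set(self.helix_of) != set(self.pairs):
            raise StructureError("helix labels do not cover all pairs")

    @property
    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def pairs_in_helix(self, label: str) -> list[tuple[int, int]]:
        return sorted(p for p, h in self.helix_of.items() if h == label)

    @property
    def helices(self) -> list[str]:
        return sorted(set(self.helix_of.values()))


def parse_dotbracket(
    structure_text: str,
    helix_spans: Sequence[tuple[str, int, int]] = (),
) -> SecondaryStructure:
    """Build a pair map from a dot-bracket string by bracket matching.

    Each pair is assigned the label of the helix span containing its 5'
    position (1-based, closed spans); pairs outside every span get "other".
    Unbalanced brackets and overlapping spans are rejected.
    """
    structure_text = structure_text.strip()
    n = len(structure_text)
    spans = sorted(helix_spans, key=lambda s: s[1])
    prev_end = 0
    for label, start, end in spans:
        if not (1 <= start <= end <= n):
            raise StructureError(f"helix span {label} ({start},{end}) out of range")
        if start <= prev_end:
            raise StructureError(f"overlapping helix spans at {label}")
        prev_end = end

    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure_text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")

    def label_for(i: int) -> str:
        for label, start, end in spans:
            if start <= i <= end:
                return label
        return "other"

    helix_of = {(i, j): label_for(i) for i, j in pairs}
    paired = {p for ij in pairs for p in ij}
    unpaired = frozenset(set(range(1, n + 1)) - paired)
    return SecondaryStructure(
        length=n, pairs=frozenset(pairs), helix_of=helix_of, unpaired=unpaired
    )


def read_structure_file(path: str | Path) -> tuple[str, SecondaryStructure]:
    """Read the structure file format: line 1 sequence, line 2 dot-bracket,
    lines 3+ helix spans as ``label<TAB>start<TAB>end`` (1-based, closed)."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if len(lines) < 2:
        raise StructureError(f"{path}: need sequence and structure lines")
    seq, db = lines[0].strip(), lines[1].strip()
    if len(seq) != len(db):
        raise StructureError(f"{path}: sequence/structure length mismatch")
    spans = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise StructureError(f"{path}: bad helix span line {ln!r}")
        spans.append((parts[0], int(parts[1]), int(parts[2])))
    return seq, parse_dotbracket(db, spans)


def write_structure_file(seq: str, structure: SecondaryStructure,
                         path: str | Path) -> None:
    db = ["."] * structure.length
    for i, j in structure.pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    span_rows = []
    for label in structure.helices:
        if label == "other":
            continue
        ps = structure.pairs_in_helix(label)
        cols = [c for p in ps for c in p]
        span_rows.append((label, min(cols), max(cols)))
    with open(path, "w") as fh:
        fh.write(seq + "\n")
        fh.write("".join(db) + "\n")
        for label, start, end in sorted(span_rows, key=lambda s: s[1]):
            fh.write(f"{label}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# ITS spacer delimitation


@dataclass(frozen=True)
class AnchorConfig:
    """Degenerate anchor motifs delimiting the ITS spacers.

    The defaults approximate the conserved 18S 3' end, the two 5.8S termini
    and the 28S 5' end used by ITSx-style delimiters; each motif tolerates
    ``mismatch_tol`` mismatches (IUPAC degeneracy honoured).
    """

    ssu_end: str = "GTAGGTGAACCTGCGG"
    r58s_start: str = "AACTTTCAACAACGGATCTC"
    r58s_end: str = "TTGAACGCACATTGCGCC"
    lsu_start: str = "TTGACCTCGGATCAGGTAGG"
    mismatch_tol: int = 1


@dataclass(frozen=True)
class Spacer:
    """One delimited ITS spacer; ``record`` is None when undelimited."""

    record: SequenceRecord | None
    open_start: bool = False
    open_end: bool = False

    @property
    def undelimited(self) -> bool:
        return self.record is None


def find_motif(seq: str, motif: str, *, mismatch_tol: int = 1,
               start: int = 0) -> tuple[int, int] | None:
    """First occurrence of a degenerate motif with <= mismatch_tol mismatches.

    Returns 0-based ``(begin, end)`` half-open coordinates, or None.
    """
    m = len(motif)
    sets = [_IUPAC_SETS.get(c, frozenset(c)) for c in motif.upper()]
    for off in range(start, len(seq) - m + 1):
        mm = 0
        for k in range(m):
            if seq[off + k] not in sets[k]:
                mm += 1
                if mm > mismatch_tol:
                    break
        else:
            return off, off + m
    return None


def extract_spacers(
    record: SequenceRecord,
    anchors: AnchorConfig = AnchorConfig(),
) -> dict[str, Spacer]:
    """Delimit ITS1 and ITS2 from a full ITS record.

    ITS1 spans from the 18S 3'-anchor to the 5.8S start anchor; ITS2 from the
    5.8S end anchor to the 28S 5'-anchor. A spacer with one missing anchor is
    returned best-effort with the corresponding open-end flag; a spacer with
    both anchors missing is undelimited (record None).
    """
    if record.locus != "ITS":
        raise SequenceError(f"{record.id}: extract_spacers needs locus ITS")
    seq = record.residues
    tol = anchors.mismatch_tol

    ssu = find_motif(seq, anchors.ssu_end, mismatch_tol=tol)
    r58a = find_motif(seq, anchors.r58s_start, mismatch_tol=tol,
                      start=ssu[1] if ssu else 0)
    r58b = find_motif(seq, anchors.r58s_end, mismatch_tol=tol,
                      start=r58a[1] if r58a else 0)
    lsu = find_motif(seq, anchors.lsu_start, mismatch_tol=tol,
                     start=r58b[1] if r58b else 0)

    def make(sub: str, tag: str) -> SequenceRecord | None:
        if not sub:
            return None
        return replace(record, residues=sub, locus=tag)

    out: dict[str, Spacer] = {}
    # ITS1: between 18S end and 5.8S start
    if ssu is None and r58a is None:
        out["ITS1"] = Spacer(record=None)
    else:
        begin = ssu[1] if ssu else 0
        end = r58a[0] if r58a else len(seq)
        rec = make(seq[begin:end], "ITS1") if begin < end else None
        out["ITS1"] = Spacer(record=rec, open_start=ssu is None,
                             open_end=r58a is None)
    # ITS2: between 5.8S end and 28S start
    if r58b is None and lsu is None:
        out["ITS2"] = Spacer(record=None)
    else:
        begin = r58b[1] if r58b else 0
        end = lsu[0] if lsu else len(seq)
        rec = make(seq[begin:end], "ITS2") if begin < end else None
        out["ITS2"] = Spacer(record=rec, open_start=r58b is None,
                             open_end=lsu is None)
    return out
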