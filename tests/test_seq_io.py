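"""seq_io: FASTA round trips, residue normalization, dot-bracket parsing
and ITS spacer delimitation."""

import pytest

from dualbarcode.seq_io import (
    AnchorConfig,
    SequenceError,
    SequenceRecord,
    SequenceSet,
    StructureError,
    extract_spacers,
    find_motif,
    normalize_residues,
    parse_dotbracket,
    read_fasta,
    read_species_map,
    read_structure_file,
    write_fasta,
    write_species_map,
    write_structure_file,
)

from conftest import random_balanced_dotbracket


class TestNormalization:
    def test_uppercase_and_u_to_t(self):
        assert normalize_residues("acgu") == "ACGT"

    def test_strict_rejects_ambiguity_with_position(self):
        with pytest.raises(SequenceError, match="position 3"):
            normalize_residues("ACRG")

    def test_lenient_maps_ambiguity_to_n(self):
        assert normalize_residues("ACRG", strict=False) == "ACNG"

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            normalize_residues("")


class TestFasta:
    def test_parse_two_entries(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1\nACGT\n>s2\nACGTTT\n")
        sset = read_fasta(p, locus="ITS")
        assert len(sset) == 2
        assert [len(r) for r in sset] == [4, 6]

    def test_lowercase_u_normalized(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1\nacgu\n")
        assert read_fasta(p, locus="ITS")[0].residues == "ACGT"

    def test_header_species_convention_and_map_precedence(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1|Fusarium_oxysporum\nACGT\n>s2\nACGT\n")
        sset = read_fasta(p, locus="ITS", species_map={"s2": "Fusarium oxysporum"})
        assert sset["s1"].species == "Fusarium oxysporum"
        assert sset["s2"].species == "Fusarium oxysporum"
        override = read_fasta(p, locus="ITS", species_map={"s1": "Other sp."})
        assert override["s1"].species == "Other sp."

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1\nACGT\n>s1\nACGT\n")
        with pytest.raises(SequenceError, match="duplicate"):
            read_fasta(p, locus="ITS")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text("")
        with pytest.raises(SequenceError, match="no FASTA records"):
            read_fasta(p, locus="ITS")

    def test_round_trip_exact(self, tmp_path, two_species_set):
        out = tmp_path / "rt.fasta"
        write_fasta(two_species_set, out)
        back = read_fasta(out, locus="ITS")
        for orig, new in zip(two_species_set, back):
            assert (orig.id, orig.species, orig.residues) == \
                (new.id, new.species, new.residues)

    def test_species_map_round_trip(self, tmp_path):
        mapping = {"s1": "Alpha one", "s2": "Beta two"}
        p = tmp_path / "map.tsv"
        write_species_map(mapping, p)
        assert read_species_map(p) == mapping


class TestDotBracket:
    def test_simple_nested(self):
        s = parse_dotbracket("((..))", [("H1", 1, 6)])
        assert s.pairs == frozenset({(1, 6), (2, 5)})
        assert s.unpaired == frozenset({3, 4})
        assert set(s.helix_of.values()) == {"H1"}

    def test_all_unpaired(self):
        s = parse_dotbracket("......")
        assert not s.pairs
        assert s.unpaired == frozenset(range(1, 7))

    def test_bulged_helix_pair_count(self):
        # 9-bp helix with an internal one-base bulge on the 5' strand
        db = "(((((.((((....)))).)))))"
        s = parse_dotbracket(db, [("H2", 1, len(db))])
        assert len(s.pairs) == 9
        assert 6 in s.unpaired  # the bulge
        assert all(lbl == "H2" for lbl in s.helix_of.values())

    def test_unbalanced_rejected(self):
        with pytest.raises(StructureError):
            parse_dotbracket("((.)")
        with pytest.raises(StructureError):
            parse_dotbracket(".))")

    def test_overlapping_spans_rejected(self):
        with pytest.raises(StructureError, match="overlap"):
            parse_dotbracket("((..))", [("H1", 1, 4), ("H2", 3, 6)])

    def test_agrees_with_stack_oracle_on_random_strings(self, rng):
        """Pair maps must equal an independent stack matcher on 1,000
        random balanced strings."""
        for _ in range(1000):
            db = random_balanced_dotbracket(rng)
            stack, expected = [], set()
            for pos, ch in enumerate(db, start=1):
                if ch == "(":
                    stack.append(pos)
                elif ch == ")":
                    expected.add((stack.pop(), pos))
            s = parse_dotbracket(db)
            assert s.pairs == frozenset(expected)
            assert s.unpaired == frozenset(
                set(range(1, len(db) + 1)) - {p for ij in expected for p in ij}
            )

    def test_structure_file_round_trip(self, tmp_path, toy_its2):
        seq, structure = toy_its2
        p = tmp_path / "s.txt"
        write_structure_file(seq, structure, p)
        seq2, structure2 = read_structure_file(p)
        assert seq2 == seq
        assert structure2.pairs == structure.pairs
        assert structure2.helix_of == structure.helix_of


ANCHORS = AnchorConfig(
    ssu_end="GTAGGTGAACCTGCGG",
    r58s_start="AACTTTCAACAACGGATCTC",
    r58s_end="TTGAACGCACATTGCGCC",
    lsu_start="TTGACCTCGGATCAGGTAGG",
    mismatch_tol=1,
)


class TestSpacerExtraction:
    def test_planted_spacers_recovered_exactly(self):
        its1, its2 = "ACCTGTTGCTTCGGCGGAC", "TGTCTGAGTACTATATAATAGT"
        full = ("AA" + ANCHORS.ssu_end + its1 + ANCHORS.r58s_start
                + "GCATCGATGAAGAACG" + ANCHORS.r58s_end + its2
                + ANCHORS.lsu_start + "GG")
        rec = SequenceRecord("x", full, species="Alpha", locus="ITS")
        spacers = extract_spacers(rec, ANCHORS)
        assert spacers["ITS1"].record.residues == its1
        assert spacers["ITS2"].record.residues == its2
        assert not spacers["ITS1"].open_start
        assert not spacers["ITS2"].open_end
        assert spacers["ITS1"].record.locus == "ITS1"
        assert spacers["ITS1"].record.species == "Alpha"

    def test_interior_reconstruction_invariant(self):
        """When all anchors are found, ITS1 + 5.8S + ITS2 reconstructs the
        interior between the flanking anchors."""
        its1, its2 = "ACCTGTTGCTTCGGCGGAC", "TGTCTGAGTACTATATAATAGT"
        r58s_interior = "GCATCGATGAAGAACG"
        full = (ANCHORS.ssu_end + its1 + ANCHORS.r58s_start
                + r58s_interior + ANCHORS.r58s_end + its2 + ANCHORS.lsu_start)
        rec = SequenceRecord("x", full, locus="ITS")
        spacers = extract_spacers(rec, ANCHORS)
        interior = (spacers["ITS1"].record.residues + ANCHORS.r58s_start
                    + r58s_interior + ANCHORS.r58s_end
                    + spacers["ITS2"].record.residues)
        assert full == ANCHORS.ssu_end + interior + ANCHORS.lsu_start

    def test_missing_28s_tail_flags_open_end(self):
        its2 = "TGTCTGAGTACTATATAATAGT"
        full = ("AA" + ANCHORS.ssu_end + "ACCTGTT" + ANCHORS.r58s_start
                + "GCATCGATGAAGAACG" + ANCHORS.r58s_end + its2)
        rec = SequenceRecord("x", full, locus="ITS")
        spacers = extract_spacers(rec, ANCHORS)
        assert spacers["ITS2"].open_end
        assert spacers["ITS2"].record.residues == its2

    def test_no_anchors_means_undelimited(self):
        rec = SequenceRecord("x", "ACGT" * 30, locus="ITS")
        spacers = extract_spacers(rec, ANCHORS)
        assert spacers["ITS1"].undelimited
        assert spacers["ITS2"].undelimited

    def test_one_mismatch_tolerated_in_anchor(self):
        its1 = "ACCTGTTGCTTCGGCGGAC"
        mutated = "A" + ANCHORS.ssu_end[1:]  # 1 mismatch
        full = (mutated + its1 + ANCHORS.r58s_start + "GCATCG"
                + ANCHORS.r58s_end + "TTTT" + ANCHORS.lsu_start)
        rec = SequenceRecord("x", full, locus="ITS")
        assert extract_spacers(rec, ANCHORS)["ITS1"].record.residues == its1

    def test_wrong_locus_rejected(self):
        rec = SequenceRecord("x", "ACGT", locus="ITS2")
        with pytest.raises(SequenceError):
            extract_spacers(rec)


class TestFindMotif:
    def test_degenerate_match(self):
        assert find_motif("AAGTCCAA", "GYC", mismatch_tol=0) == (2, 5)

    def test_not_found(self):
        assert find_motif("AAAA", "GGG", mismatch_tol=0) is None
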