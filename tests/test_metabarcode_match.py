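"""metabarcode_match: haplotype tables, distinctiveness, exact matching
under the 100% / full-coverage rule, assignment and biogeography summaries."""

import numpy as np
import pandas as pd
import pytest

from dualbarcode.metabarcode_match import (
    HaplotypeTable,
    assign_dataset,
    build_reference,
    classify_distribution,
    distinctiveness,
    match_query,
    summarize_species,
    zone_group,
)
from dualbarcode.seq_io import SequenceRecord, SequenceSet
from dualbarcode.synthetic_data import random_sequence


def sset(spacer, entries):
    return SequenceSet(
        [SequenceRecord(i, s, species=sp, locus=spacer)
         for i, sp, s in entries],
        locus=spacer,
    )


@pytest.fixture
def table():
    t = HaplotypeTable()
    t.add("Alpha", "ITS2", "ACGTACGTACGTACGT", "a1")
    t.add("Alpha", "ITS2", "ACGTACGTACGTACGA", "a2")
    t.add("Beta", "ITS2", "ACGTACGTACGTCCGT", "b1")
    t.add("Alpha", "ITS1", "TTTTACGTACGTAAAA", "a1")
    t.add("Beta", "ITS1", "TTTTACGTACGTAAAA", "b1")  # shared with Alpha
    return t


class TestBuildReference:
    def test_identical_sequences_collapse(self):
        refs = {"ITS1": sset("ITS1", [
            ("r1", "Alpha", "ACGTACGT"),
            ("r2", "Alpha", "ACGTACGT"),
            ("r3", "Alpha", "ACGTACGT"),
        ])}
        t = build_reference(refs)
        assert t.haplotypes("Alpha", "ITS1") == {"ACGTACGT"}
        assert sorted(t.provenance[("Alpha", "ITS1", "ACGTACGT")]) == \
            ["r1", "r2", "r3"]

    def test_cross_species_shared_haplotype_recorded(self):
        refs = {"ITS1": sset("ITS1", [
            ("r1", "Alpha", "ACGTACGT"),
            ("r2", "Beta", "ACGTACGT"),
        ])}
        t = build_reference(refs)
        assert t.shared_haplotypes("ITS1") == {"ACGTACGT": ["Alpha", "Beta"]}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_reference({})

    def test_species_map_overrides(self):
        refs = {"ITS1": sset("ITS1", [("r1", None, "ACGT")])}
        t = build_reference(refs, {"r1": "Gamma"})
        assert t.species == ["Gamma"]


class TestDistinctiveness:
    def test_shared_haplotype_not_separable(self, table):
        d = distinctiveness(table)
        assert d["ITS1"].get("Alpha", "Beta") == 0
        assert not d["ITS1"].separable("Alpha", "Beta")

    def test_minimum_over_haplotype_pairs(self, table):
        # closest Alpha/Beta ITS2 haplotypes differ at a single position
        assert distinctiveness(table)["ITS2"].get("Alpha", "Beta") == 1

    def test_planted_two_differences(self):
        refs = {"ITS2": sset("ITS2", [
            ("r1", "Alpha", "ACGTACGTACGTACGT"),
            ("r2", "Beta", "ACGTACTTACGTACTT"),
        ])}
        d = distinctiveness(build_reference(refs))
        assert d["ITS2"].get("Alpha", "Beta") == 2
        assert d["ITS2"].separable("Alpha", "Beta")

    def test_single_species_rejected(self):
        t = HaplotypeTable()
        t.add("Alpha", "ITS1", "ACGT", "r1")
        with pytest.raises(ValueError):
            distinctiveness(t)


class TestMatchQuery:
    def test_exact_unique_match(self, table):
        r = match_query("ACGTACGTACGTCCGT", table, "ITS2")
        assert r.status == "unique"
        assert r.species == frozenset({"Beta"})
        assert r.trim == 0

    def test_one_mismatch_everywhere_is_none(self, table):
        r = match_query("TCGTACGTACGTCCGT", table, "ITS2")
        assert r.status == "none"

    def test_five_prime_trimmed_query_matches_with_offset(self, table):
        r = match_query("GTACGTACGTCCGT", table, "ITS2", trim_tol=2)
        assert r.status == "unique"
        assert r.trim == 2

    def test_three_prime_truncation_never_matches(self, table):
        r = match_query("ACGTACGTACGTCC", table, "ITS2", trim_tol=2)
        assert r.status == "none"

    def test_n_is_always_a_mismatch(self, table):
        r = match_query("NCGTACGTACGTCCGT", table, "ITS2")
        assert r.status == "none"

    def test_shared_haplotype_ambiguous_with_all_species(self, table):
        r = match_query("TTTTACGTACGTAAAA", table, "ITS1", trim_tol=0)
        assert r.status == "ambiguous"
        assert r.species == frozenset({"Alpha", "Beta"})

    def test_agrees_with_brute_force_scan(self, rng):
        """Exact-string semantics: 1,000 random queries must agree with an
        independent scan over all haplotypes and all allowed trims."""
        t = HaplotypeTable()
        haps = []
        for sp in ("A sp.", "B sp.", "C sp."):
            for k in range(3):
                h = random_sequence(30, rng)
                t.add(sp, "ITS2", h, f"{sp}{k}")
                haps.append((sp, h))
        trim_tol = 2
        for _ in range(1000):
            choice = rng.random()
            if choice < 0.5:
                sp, h = haps[int(rng.integers(0, len(haps)))]
                q = h[int(rng.integers(0, 4)):]
            else:
                q = random_sequence(int(rng.integers(25, 32)), rng)
            expected = set()
            for sp, h in haps:
                for k in range(trim_tol + 1):
                    if h[k:] == q:
                        expected.add(sp)
            r = match_query(q, t, "ITS2", trim_tol)
            assert r.species == frozenset(expected)
            status = ("none" if not expected else
                      "unique" if len(expected) == 1 else "ambiguous")
            assert r.status == status


class TestAssignDataset:
    def make_meta(self, ids, zone="Af"):
        return pd.DataFrame([{
            "id": i, "substrate": "bulk soil", "biome": "forest",
            "climate_zone": zone, "MAT": 25.0, "MAP": 2800.0,
        } for i in ids])

    def test_planted_queries_all_unique(self, table):
        queries = [("q1", "ITS2", "ACGTACGTACGTACGT"),
                   ("q2", "ITS2", "ACGTACGTACGTCCGT")]
        out = assign_dataset(queries, self.make_meta(["q1", "q2"]), table)
        assert list(out["status"]) == ["unique", "unique"]
        assert list(out["species"]) == ["Alpha", "Beta"]
        assert not out["orphan"].any()

    def test_metadata_orphan_flagged(self, table):
        queries = [("q1", "ITS2", "ACGTACGTACGTACGT")]
        out = assign_dataset(queries, self.make_meta(["other"]), table)
        assert out["orphan"].all()

    def test_empty_query_set(self, table):
        out = assign_dataset([], self.make_meta([]), table)
        assert out.empty


class TestSummaries:
    def test_zone_grouping(self):
        assert zone_group("Af") == "tropical"
        assert zone_group("Cfb") == "temperate"
        assert zone_group("Dfc") == "continental"
        assert zone_group("ET") == "polar"

    def test_distribution_rule(self):
        assert classify_distribution({"Af": 8, "Cfb": 2}) == "tropical"
        assert classify_distribution({"Cfb": 5, "Dfb": 4, "Af": 1}) == \
            "temperate/continental"
        assert classify_distribution({"Af": 5, "Cfb": 5}) == "global"
        assert classify_distribution({}) is None

    def test_single_substrate_proportion_one(self, table):
        queries = [("q1", "ITS2", "ACGTACGTACGTACGT"),
                   ("q2", "ITS2", "ACGTACGTACGTACGT")]
        meta = pd.DataFrame([
            {"id": "q1", "substrate": "bulk soil", "biome": "forest",
             "climate_zone": "Af", "MAT": 24.0, "MAP": 2600.0},
            {"id": "q2", "substrate": "bulk soil", "biome": "cropland",
             "climate_zone": "Am", "MAT": 26.0, "MAP": 3000.0},
        ])
        out = assign_dataset(queries, meta, table)
        s = summarize_species(out)["Alpha"]
        assert s.n_samples == 2
        assert s.substrate_proportions == {"bulk soil": 1.0}
        assert s.mean_mat == pytest.approx(25.0)
        assert s.mean_map == pytest.approx(2800.0)
        assert s.distribution_type == "tropical"

    def test_ambiguous_excluded_by_default(self, table):
        queries = [("q1", "ITS1", "TTTTACGTACGTAAAA")]
        meta = pd.DataFrame([
            {"id": "q1", "substrate": "roots", "biome": "forest",
             "climate_zone": "Cfb", "MAT": 9.0, "MAP": 700.0}])
        out = assign_dataset(queries, meta, table)
        assert summarize_species(out) == {}
        incl = summarize_species(out, include_ambiguous=True)
        assert incl["Alpha"].n_samples == 1
        assert incl["Beta"].n_samples == 1

    def test_species_without_assignments_gets_zero_summary(self, table):
        out = assign_dataset([], pd.DataFrame(columns=["id"]), table)
        s = summarize_species(out, all_species=["Alpha"])
        assert s["Alpha"].n_samples == 0
        assert s["Alpha"].distribution_type is None
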