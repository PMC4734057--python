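import logging
import random

import pytest

from alnkit.core import AlignmentError, DataType, Partition, validate_alignment
from alnkit import fixtures
from alnkit.io import write_alignment
from alnkit.core import FormatSpec
from alnkit.manipulate import (
    ReplicateSpec,
    concatenate,
    make_replicates,
    parse_partition_file,
    remove_taxa,
    split,
    write_partition_file,
)


def _aln(records, name):
    return validate_alignment(records, source_name=name)


class TestConcatenate:
    def test_two_locus_union_with_fill(self):
        sm = concatenate([
            _aln([("sp1", "AAA"), ("sp2", "CCC")], "locus1"),
            _aln([("sp2", "GG"), ("sp3", "TT")], "locus2"),
        ])
        assert sm.alignment.records == (
            ("sp1", "AAA??"), ("sp2", "CCCGG"), ("sp3", "???TT")
        )
        assert [(p.name, p.start, p.end) for p in sm.partitions] == [
            ("locus1", 1, 3), ("locus2", 4, 5)
        ]

    def test_single_alignment_identity(self):
        a = _aln([("t1", "ACGT"), ("t2", "ACGA")], "only")
        sm = concatenate([a])
        assert sm.alignment.records == a.records
        assert [(p.name, p.start, p.end) for p in sm.partitions] == [("only", 1, 4)]

    def test_identical_taxon_sets_join_without_fill(self):
        sm = concatenate([
            _aln([("t1", "AA"), ("t2", "CC")], "a"),
            _aln([("t1", "GG"), ("t2", "TT")], "b"),
        ])
        assert "?" not in "".join(sm.alignment.sequences)
        assert sm.alignment.length == 4

    def test_duplicate_source_names_disambiguated(self, caplog):
        with caplog.at_level(logging.WARNING):
            sm = concatenate([
                _aln([("t1", "AA")], "x"), _aln([("t1", "CC")], "x"),
            ])
        assert [p.name for p in sm.partitions] == ["x", "x_2"]
        assert "disambiguated" in caplog.text

    def test_empty_list_rejected(self):
        with pytest.raises(AlignmentError, match="empty"):
            concatenate([])

    def test_partitions_tile_and_conserve_residues(self, rng):
        loci = fixtures.random_locus_set(rng, n_loci=8, occupancy=0.6)
        sm = concatenate(loci)
        assert sm.partitions[0].start == 1
        assert sm.partitions[-1].end == sm.alignment.length
        non_fill = sum(
            sum(1 for c in seq if c != "?") for seq in sm.alignment.sequences
        )
        # inputs carry their own '?' cells; fill adds the rest
        input_q = sum(seq.count("?") for a in loci for seq in a.sequences)
        assert non_fill + input_q + sum(
            (sm.alignment.n_taxa - a.n_taxa) * a.length for a in loci
        ) == sm.alignment.n_taxa * sm.alignment.length

    def test_associative_in_residue_content(self):
        a = _aln([("t1", "AA"), ("t2", "CC")], "a")
        b = _aln([("t2", "GG"), ("t3", "TT")], "b")
        c = _aln([("t1", "AC")], "c")
        left = concatenate([a, b, c]).alignment
        ab = concatenate([a, b]).alignment.with_source("ab")
        nested = concatenate([ab, c]).alignment
        assert left.records == nested.records


class TestPartitionFiles:
    @pytest.mark.parametrize(
        "partitions, expected",
        [
            ([Partition("p1", (1, 2, 3)), Partition("p2", (4, 5))],
             "p1 = 1-3\np2 = 4-5\n"),
            ([], ""),
            ([Partition.from_range("x", 1, 10)], "x = 1-10\n"),
        ],
    )
    def test_write(self, partitions, expected):
        assert write_partition_file(partitions) == expected

    @pytest.mark.parametrize(
        "text, expected",
        [
            ("p1 = 1-3\np2 = 4-5", [("p1", (1, 2, 3)), ("p2", (4, 5))]),
            ("codon1 = 1-6\\3", [("codon1", (1, 4))]),
            ("DNA, gene1 = 1-10", [("gene1", tuple(range(1, 11)))]),
            ("WAG, g = 2-4;", [("g", (2, 3, 4))]),
            ("charset g1 = 1-2, 5, 8-10;", [("g1", (1, 2, 5, 8, 9, 10))]),
            ("\n# comment\np = 7\n", [("p", (7,))]),
        ],
    )
    def test_parse_dialects(self, text, expected):
        got = [(p.name, p.sites) for p in parse_partition_file(text)]
        assert got == expected

    @pytest.mark.parametrize("bad", ["p1 1-3", "p2 = 3-1", "p3 = x-4", " = 1-2"])
    def test_malformed_lines_raise_with_line_number(self, bad):
        with pytest.raises(AlignmentError, match="line 2"):
            parse_partition_file("ok = 1-2\n" + bad)

    def test_overlap_warns_but_parses(self, caplog):
        with caplog.at_level(logging.WARNING):
            parts = parse_partition_file("a = 1-5\nb = 4-8")
        assert len(parts) == 2
        assert "re-claims" in caplog.text

    def test_write_parse_roundtrip(self, rng):
        loci = fixtures.random_locus_set(rng, n_loci=5)
        parts = concatenate(loci).partitions
        parsed = parse_partition_file(write_partition_file(parts))
        assert [(p.name, p.sites) for p in parsed] == [
            (p.name, p.sites) for p in parts
        ]


class TestSplit:
    def test_direct_site_extraction(self):
        aln = _aln([("t1", "ACGT")], "m")
        out = split(aln, [Partition("p", (1, 4))])
        assert out[0].records == (("t1", "AT"),)
        assert out[0].source_name == "p"

    def test_full_range_partition_is_identity(self):
        aln = _aln([("t1", "ACGT"), ("t2", "AC-T")], "m")
        out = split(aln, [Partition.from_range("all", 1, 4)])
        assert out[0].records == aln.records

    def test_site_beyond_length_names_partition(self):
        aln = _aln([("t1", "ACGT")], "m")
        with pytest.raises(AlignmentError, match="'oops'.*site 9"):
            split(aln, [Partition.from_range("oops", 5, 9)])

    def test_inverse_of_concatenation(self, rng):
        loci = fixtures.random_locus_set(rng, n_loci=7, occupancy=0.6)
        sm = concatenate(loci)
        back = split(sm.alignment, sm.partitions, remove_empty=True)
        assert len(back) == len(loci)
        for original, recovered in zip(loci, back):
            expected = tuple(
                (n, s) for n, s in original.records
                if not all(c in "?-N" for c in s.upper())
            )
            assert recovered.records == expected
            assert recovered.source_name == original.source_name

    def test_without_remove_empty_keeps_padded_taxa(self):
        sm = concatenate([
            _aln([("sp1", "AAA")], "a"), _aln([("sp2", "TT")], "b"),
        ])
        padded = split(sm.alignment, sm.partitions, remove_empty=False)
        assert padded[0].n_taxa == 2
        lean = split(sm.alignment, sm.partitions, remove_empty=True)
        assert lean[0].records == (("sp1", "AAA"),)


class TestRemoveTaxa:
    def test_removes_named_taxa_preserving_order(self):
        aln = _aln([("t1", "AA"), ("t2", "CC"), ("t3", "GG")], "m")
        assert remove_taxa(aln, ["t2"]).taxon_names == ("t1", "t3")

    def test_empty_removal_list_is_identity(self):
        aln = _aln([("t1", "AA"), ("t2", "CC")], "m")
        assert remove_taxa(aln, []) == aln

    def test_absent_name_warns_but_succeeds(self, caplog):
        aln = _aln([("t1", "AA")], "m")
        with caplog.at_level(logging.WARNING):
            assert remove_taxa(aln, ["tX"]) == aln
        assert "tX" in caplog.text

    def test_removing_every_taxon_rejected(self):
        aln = _aln([("t1", "AA")], "m")
        with pytest.raises(AlignmentError, match="empty alignment"):
            remove_taxa(aln, ["t1"])


class TestReplicates:
    @pytest.fixture
    def loci(self, rng):
        return fixtures.random_locus_set(rng, n_loci=4, occupancy=1.0)

    def test_seeded_determinism(self, loci):
        spec = ReplicateSpec(2, 2, seed=7)
        first = make_replicates(loci, spec)
        second = make_replicates(loci, spec)
        for a, b in zip(first, second):
            assert write_alignment(a.alignment, FormatSpec.FASTA) == \
                write_alignment(b.alignment, FormatSpec.FASTA)

    def test_sampling_all_loci_is_a_permutation(self, loci):
        reps = make_replicates(loci, ReplicateSpec(3, len(loci), seed=1))
        names = sorted(a.source_name for a in loci)
        for sm in reps:
            assert sorted(p.name for p in sm.partitions) == names
            assert sm.alignment.length == sum(a.length for a in loci)

    def test_every_locus_eventually_drawn(self, loci):
        reps = make_replicates(loci, ReplicateSpec(200, 1, seed=3))
        drawn = {sm.partitions[0].name for sm in reps}
        assert drawn == {a.source_name for a in loci}

    def test_oversampling_rejected(self, loci):
        with pytest.raises(AlignmentError, match="without replacement"):
            make_replicates(loci, ReplicateSpec(1, 5, seed=0))
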