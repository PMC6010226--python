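"""Alignment I/O, flank pruning and haplotype collapsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specdelim.alignments import (
    AlignmentError,
    MarkerAlignment,
    PruningPolicy,
    clade_haplotype_report,
    collapse_identical,
    extract_clade,
    prune_to_full_coverage,
    read_alignment,
    split_by_clade,
    write_alignment,
)


def _aln(*rows, marker="COI"):
    return MarkerAlignment(marker, [(f"s{i}_1", r) for i, r in enumerate(rows)])


class TestReadWrite:
    def test_fasta_roundtrip(self, tmp_path):
        aln = _aln("ACGT", "ACGA", "TTTT")
        path = tmp_path / "a.fasta"
        write_alignment(aln, path)
        back = read_alignment(path)
        assert back.rows == aln.rows
        assert back.length == 4

    def test_ragged_fasta_rejected(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentError):
            read_alignment(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            MarkerAlignment("COI", [("a", "ACGT"), ("a", "ACGT")])

    def test_non_iupac_rejected(self):
        with pytest.raises(AlignmentError, match="non-IUPAC"):
            MarkerAlignment("COI", [("a", "ACGX")])

    def test_u_normalized_to_t(self, tmp_path):
        path = tmp_path / "u.fasta"
        path.write_text(">a\nacgu\n")
        assert read_alignment(path).rows[0][1] == "ACGT"

    def test_nexus_interleaved_matches_sequential(self, tmp_path):
        seqs = {"a_1": "ACGTACGT", "b_1": "ACGAACGA", "c_2": "TTGTACGT"}
        seq_path = tmp_path / "seq.nex"
        seq_path.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
            + "".join(f"{k} {v}\n" for k, v in seqs.items())
            + ";\nEND;\n"
        )
        inter_path = tmp_path / "inter.nex"
        inter_path.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=YES;\nMATRIX\n"
            + "".join(f"{k} {v[:4]}\n" for k, v in seqs.items())
            + "\n"
            + "".join(f"{k} {v[4:]}\n" for k, v in seqs.items())
            + ";\nEND;\n"
        )
        assert read_alignment(seq_path, "nexus").rows == read_alignment(
            inter_path, "nexus"
        ).rows


class TestExtractClade:
    def test_suffix_membership(self):
        aln = MarkerAlignment(
            "COI", [("a_1", "ACGT"), ("b_1", "ACGA"), ("c_2", "TTTT")]
        )
        assert extract_clade(aln, "1").ids == ["a_1", "b_1"]
        # membership equals a brute-force suffix filter
        for clade in ("1", "2"):
            expected = [s for s, _ in aln.rows if s.endswith(f"_{clade}")]
            assert extract_clade(aln, clade).ids == expected

    def test_unknown_clade_empty_with_warning(self):
        aln = MarkerAlignment("COI", [("a_1", "ACGT")])
        with pytest.warns(UserWarning):
            assert len(extract_clade(aln, "99")) == 0

    def test_split_by_clade_partitions_ids(self, small_dataset):
        coi = small_dataset.alignments["COI"]
        clades = split_by_clade(coi)
        all_ids = sorted(i for aln in clades.values() for i in aln.ids)
        assert all_ids == sorted(coi.ids)


def _oracle_window(rows):
    """Widest window anchored at both ends whose terminal columns are free
    of gap/?/N in every row, found by exhaustive scan."""
    length = len(rows[0])
    missing = set("-?N")
    start = 0
    while start < length and any(r[start] in missing for r in rows):
        start += 1
    stop = length
    while stop > start and any(r[stop - 1] in missing for r in rows):
        stop -= 1
    return start, stop


class TestPruning:
    def test_staggered_terminal_gaps_match_oracle(self):
        rows = [
            "--GTACGTAC",
            "ACGTACGT--",
            "NCGTACGTAN",
        ]
        aln = _aln(*rows)
        pruned = prune_to_full_coverage(aln)
        start, stop = _oracle_window(rows)
        assert pruned.length == stop - start
        assert [r for _, r in pruned.rows] == [r[start:stop] for r in rows]

    def test_clean_alignment_unchanged(self):
        aln = _aln("ACGT", "ACGA")
        assert prune_to_full_coverage(aln).rows == aln.rows

    def test_repruning_is_identity(self):
        aln = _aln("--GTAC", "ACGTAC", "ACGTA-")
        once = prune_to_full_coverage(aln)
        assert prune_to_full_coverage(once).rows == once.rows

    def test_interior_gaps_untouched(self):
        aln = _aln("AC-TAC", "ACGTAC")
        assert prune_to_full_coverage(aln).length == 6

    def test_all_missing_rejected(self):
        with pytest.raises(AlignmentError, match="zero columns"):
            prune_to_full_coverage(_aln("----", "NNNN"))

    def test_removed_ids_dropped_first(self):
        aln = MarkerAlignment(
            "COI", [("a_1", "--GT"), ("b_1", "ACGT"), ("c_1", "ACGA")]
        )
        pruned = prune_to_full_coverage(aln, PruningPolicy(removed_ids=("a_1",)))
        assert pruned.ids == ["b_1", "c_1"]
        assert pruned.length == 4

    def test_auto_mode_prefers_more_haplotypes(self):
        # one short ragged sequence forces pruning to a window in which two
        # haplotypes merge; dropping it keeps three
        aln = MarkerAlignment(
            "COI",
            [
                ("a_1", "ACGTACGT"),
                ("b_1", "ACGAACGT"),
                ("c_1", "NNNNACGT"),
            ],
        )
        literal = prune_to_full_coverage(aln, PruningPolicy())
        assert len(collapse_identical(literal)) == 1  # window merges a and b
        auto = prune_to_full_coverage(aln, PruningPolicy(mode="auto", max_removals=1))
        assert len(collapse_identical(auto)) == 2
        assert auto.length == 8  # the short sequence was dropped instead


class TestCollapse:
    def test_identical_rows_merge(self):
        haps = collapse_identical(_aln("ACGT", "ACGT"))
        assert len(haps) == 1
        assert len(haps.haplotypes[0][1]) == 2

    def test_missing_is_ordinary_symbol_by_default(self):
        assert len(collapse_identical(_aln("ACGT", "ACGN"))) == 2

    def test_wildcard_mode_merges_compatible(self):
        assert len(collapse_identical(_aln("ACGT", "ACGN"), True)) == 1

    @given(
        st.lists(
            st.text(alphabet="ACGT-N", min_size=4, max_size=4),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_collapse_partitions_and_is_idempotent(self, seqs):
        aln = MarkerAlignment("COI", [(f"s{i}", q) for i, q in enumerate(seqs)])
        haps = collapse_identical(aln)
        members = [m for _, mem in haps.haplotypes for m in mem]
        assert sorted(members) == sorted(aln.ids)  # partition of input ids
        again = collapse_identical(haps.representatives)
        assert len(again) == len(haps)  # idempotent
        # permutation invariance of the haplotype count
        rev = MarkerAlignment("COI", list(reversed(aln.rows)))
        assert len(collapse_identical(rev)) == len(haps)

    def test_members_sequences_equal_representative(self):
        aln = _aln("ACGT", "ACGA", "ACGT")
        for rep, members in collapse_identical(aln).haplotypes:
            for m in members:
                assert aln.sequence(m) == rep


class TestHaplotypeReport:
    def test_identical_clade_collapses_to_one(self):
        pruned = {"1": _aln("ACGT", "ACGT", "ACGT")}
        report = clade_haplotype_report(pruned)
        row = report.iloc[0]
        assert (row.n_specimens, row.n_haplotypes) == (3, 1)

    def test_pruned_count_matches_direct_recount(self, small_dataset):
        coi = small_dataset.alignments["COI"]
        clades = split_by_clade(coi)
        pruned = {c: prune_to_full_coverage(a) for c, a in clades.items()}
        report = clade_haplotype_report(pruned, clades)
        for _, row in report.iterrows():
            direct = len(collapse_identical(pruned[row.clade]))
            assert row.n_haplotypes == direct
            assert row.pruned_length <= row.original_length
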