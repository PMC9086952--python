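import pytest
from Bio.Align import substitution_matrices

from aggtol.aggregation import AggregationProfile, surrogate_scores
from aggtol.profiles import (
    call_hotspots,
    find_indels,
    global_align,
    map_profiles,
    profile_table_rows,
    read_aligned_fasta,
)
from oracles import gotoh_global

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = global_align("MKVLG", "MKVLG")
        assert aln.gapped_a == aln.gapped_b == "MKVLG"
        assert aln.gaps_pct == 0.0

    def test_score_matches_dp_oracle(self, rng):
        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(40):
            a = "".join(rng.choice(list("GAVLK"), rng.integers(1, 13)))
            b = "".join(rng.choice(list("GAVLK"), rng.integers(1, 13)))
            assert global_align(a, b).score == pytest.approx(
                gotoh_global(a, b, matrix, 14.0, 4.0)
            )

    def test_two_gap_example_scores_like_oracle(self):
        matrix = substitution_matrices.load("BLOSUM62")
        aln = global_align("MKVLG", "MKG")
        assert aln.score == pytest.approx(gotoh_global("MKVLG", "MKG", matrix, 14.0, 4.0))
        assert sum(c == "-" for c in aln.gapped_b) == 2

    def test_external_alignment_accepted_verbatim(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nMKV-LG\n>b\nMKVQLG\n")
        ga, gb = read_aligned_fasta(p)
        assert ga == "MKV-LG" and gb == "MKVQLG"


def zip_profile(seq_a="MKVLG", seq_b="MKVLG"):
    pa = surrogate_scores(seq_a, protein_id="a")
    pb = surrogate_scores(seq_b, protein_id="b")
    aln = global_align(seq_a, seq_b)
    return aln, pa, pb


class TestMapProfiles:
    def test_gap_free_alignment_zips_profiles(self):
        aln, pa, pb = zip_profile()
        ap = map_profiles(aln.gapped_a, aln.gapped_b, pa, pb, pair_id="p")
        assert len(ap.columns) == 5
        for i, col in enumerate(ap.columns):
            assert col.agg_a == pytest.approx(pa.scores[i])
            assert col.agg_b == pytest.approx(pb.scores[i])

    def test_insertion_columns_carry_missing_values(self):
        gapped_a, gapped_b = "MKVVVLG", "MK---LG"
        pa = surrogate_scores("MKVVVLG", protein_id="a")
        pb = surrogate_scores("MKLG", protein_id="b")
        ap = map_profiles(gapped_a, gapped_b, pa, pb)
        gap_cols = [c for c in ap.columns if c.res_b == "-"]
        assert len(gap_cols) == 3
        assert all(c.agg_b is None and c.agg_a is not None for c in gap_cols)

    def test_ungapping_recovers_inputs_exactly(self, rng):
        a = "M" + "".join(rng.choice(list(AA), 30))
        b = a[:12] + a[18:]
        aln, pa, pb = zip_profile(a, b)[0], surrogate_scores(a, protein_id="a"), None
        pb = surrogate_scores(b, protein_id="b")
        aln = global_align(a, b)
        ap = map_profiles(aln.gapped_a, aln.gapped_b, pa, pb)
        prot_a, scores_a = ap.ungapped("a")
        prot_b, scores_b = ap.ungapped("b")
        assert prot_a == a and scores_a == pytest.approx(pa.scores)
        assert prot_b == b and scores_b == pytest.approx(pb.scores)

    def test_column_conservation(self, rng):
        a = "M" + "".join(rng.choice(list(AA), 25))
        b = "M" + "".join(rng.choice(list(AA), 19))
        aln = global_align(a, b)
        pa, pb = surrogate_scores(a), surrogate_scores(b)
        ap = map_profiles(aln.gapped_a, aln.gapped_b, pa, pb)
        n_cols = len(ap.columns)
        assert n_cols == len(a) + aln.gapped_a.count("-")
        assert n_cols == len(b) + aln.gapped_b.count("-")

    def test_length_mismatch_rejected(self):
        pa = surrogate_scores("MKV")
        with pytest.raises(ValueError, match="profile"):
            map_profiles("MKVL", "MKVL", pa, pa)


class TestHotspots:
    def test_quiet_profile_has_no_annotations(self):
        aln, pa, pb = zip_profile()
        ap = map_profiles(
            aln.gapped_a, aln.gapped_b, pa, pb,
            muts_a={1: [("m", 0.5)]}, muts_b={2: [("m", -0.9)]},
        )
        assert call_hotspots(ap) == []

    def test_worked_example_detrimental_site(self):
        """The MI mutant of the two-residue worked example is a +48 change
        at residue 2 of that species."""
        from aggtol.io import CodingRecord
        from aggtol.mutagenesis import summarize_protein

        s = summarize_protein(CodingRecord.from_cds("x", "ATGAAATAA"))
        pa = surrogate_scores("MK", protein_id="a")
        ap = map_profiles("MK", "MK", pa, pa, muts_a=s.per_site)
        hits = call_hotspots(ap)
        assert (
            len(hits) == 1
            and hits[0].col_index == 2
            and hits[0].species == "a"
            and hits[0].kind == "detrimental"
            and hits[0].count == 1
        )

    def test_thresholds_are_strict(self):
        aln, pa, pb = zip_profile()
        ap = map_profiles(
            aln.gapped_a, aln.gapped_b, pa, pb,
            muts_a={1: [("m", 1.0)]}, muts_b={1: [("m", -1.0)]},
        )
        assert call_hotspots(ap) == []

    def test_hotspot_counts_sum_to_landscape_counts(self, rng):
        muts_a = {
            i + 1: [("m", float(v)) for v in rng.normal(0, 2, 5)] for i in range(5)
        }
        aln, pa, pb = zip_profile()
        ap = map_profiles(aln.gapped_a, aln.gapped_b, pa, pb, muts_a=muts_a)
        expected = sum(
            1 for vals in muts_a.values() for _, v in vals if abs(v) > 1
        )
        assert sum(h.count for h in call_hotspots(ap)) == expected


class TestIndels:
    def test_gap_free_alignment(self):
        assert find_indels("MKVL", "MKVL") == []

    def test_single_run_coordinates(self):
        gapped_a = "M" * 9 + "KVL" + "A" * 5
        gapped_b = "M" * 9 + "---" + "A" * 5
        assert find_indels(gapped_a, gapped_b) == [("b", 10, 12, 3)]

    def test_two_runs_do_not_overlap(self):
        out = find_indels("MK--VLGG-A", "MKQQ--GGQA")
        assert out == [("a", 3, 4, 2), ("b", 5, 6, 2), ("a", 9, 9, 1)]


def test_profile_table_gap_fields_export_empty():
    pa = surrogate_scores("MKV", protein_id="a")
    pb = surrogate_scores("MK", protein_id="b")
    ap = map_profiles("MKV", "MK-", pa, pb, pair_id="p")
    rows = profile_table_rows(ap)
    gap_row = [r for r in rows if r["species"] == "b" and r["residue"] == "-"][0]
    assert gap_row["agg"] == ""
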