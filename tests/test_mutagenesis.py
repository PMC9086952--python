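import numpy as np
import pytest

from aggtol.aggregation import SurrogatePredictor
from aggtol.io import CodingRecord
from aggtol.mutagenesis import (
    MutagenesisSummary,
    enumerate_mutants,
    mutational_agg,
    muttol_delta,
    summarize_protein,
)
from conftest import random_cds
from oracles import naive_mutant_sets


class TestEnumerateMutants:
    def test_worked_example_distinct_set(self):
        ms = enumerate_mutants(CodingRecord.from_cds("x", "ATGAAATAA"))
        assert ms.n_events == 27
        assert ms.distinct_mutants == frozenset({"MQ", "ME", "MT", "MR", "MI", "MN"})
        # 7 qualifying events collapse to 6 proteins (AAC/AAT both give MN)
        assert ms.n_qualifying_events == 7

    def test_every_length9_cds_has_27_events(self, rng):
        for _ in range(5):
            cds = random_cds(rng, 3)
            assert enumerate_mutants(CodingRecord.from_cds("x", cds)).n_events == 27

    def test_start_and_stop_codon_rules(self):
        """Codon-1 events are start-losses; stop->sense events are
        length-changes; stop->stop events are synonymous."""
        ms = enumerate_mutants(CodingRecord.from_cds("x", "ATGTAA"))
        assert ms.distinct_mutants == frozenset()
        assert ms.exclusion_counts["start_loss"] == 9
        assert ms.exclusion_counts["synonymous"] == 2  # TAA->TAG, TAA->TGA
        assert ms.exclusion_counts["length_change"] == 7

    def test_length_cap_enforced(self):
        rec = CodingRecord.from_cds("x", "ATGAAAAAATAA")
        with pytest.raises(ValueError, match="cap"):
            enumerate_mutants(rec, max_len=2)

    def test_event_conservation_and_scaling_guard(self, rng):
        """synonymous + start_loss + length_change + qualifying == 3L, and
        qualifying events never exceed 9n - 9 for n codons."""
        for _ in range(20):
            n = int(rng.integers(3, 30))
            ms = enumerate_mutants(CodingRecord.from_cds("x", random_cds(rng, n)))
            length = 3 * n
            assert ms.n_events == 3 * length
            assert sum(ms.exclusion_counts.values()) + ms.n_qualifying_events == 3 * length
            assert ms.n_qualifying_events <= 9 * n - 9

    def test_matches_naive_retranslation_oracle(self, rng):
        for _ in range(15):
            cds = random_cds(rng, int(rng.integers(3, 25)))
            ms = enumerate_mutants(CodingRecord.from_cds("x", cds))
            counts, distinct, events = naive_mutant_sets(cds)
            assert ms.exclusion_counts == counts
            assert set(ms.distinct_mutants) == distinct
            assert [(e.nt_position, e.ref_base, e.alt_base, e.outcome) for e in ms.events] == events


class TestMutationalAgg:
    def test_worked_example_tolerances(self):
        s = summarize_protein(CodingRecord.from_cds("x", "ATGAAATAA"))
        assert s.n_total == 6
        assert s.strict_tolerance == pytest.approx(5 / 6)
        assert s.lenient_tolerance == pytest.approx(5 / 6)
        assert s.beneficial_proportion == 0.0
        assert s.mutational_agg["MI"] == pytest.approx(48.0)
        assert {m for m, _ in s.per_site[2]} == {"MQ", "ME", "MT", "MR", "MI", "MN"}
        assert len(s.per_site[2]) == 7  # one entry per qualifying event

    def test_flat_landscape_gives_full_tolerance(self):
        """A protein none of whose single-residue mutants activates any
        window has strict = lenient = 1."""
        rec = CodingRecord.from_cds(
            "x", "ATG" + "GGA" * 30 + "TAA"
        )  # poly-Gly interior: window means stay far below theta
        s = summarize_protein(rec)
        assert s.strict_tolerance == 1.0 and s.lenient_tolerance == 1.0

    def test_category_inclusions(self, rng):
        for _ in range(8):
            rec = CodingRecord.from_cds("x", random_cds(rng, int(rng.integers(5, 30))))
            s = summarize_protein(rec)
            assert 0.0 <= s.strict_tolerance <= s.lenient_tolerance <= 1.0
            assert s.strict_tolerance + s.beneficial_proportion <= s.lenient_tolerance + 1e-12
            assert 0.0 <= s.beneficial_proportion <= 1.0

    def test_event_weighted_denominator(self):
        rec = CodingRecord.from_cds("x", "ATGAAATAA")
        pred = SurrogatePredictor()
        s = mutational_agg(enumerate_mutants(rec), pred, denominator="events")
        assert s.n_total == 7  # 7 qualifying events, 6 distinct proteins
        assert s.strict_tolerance == pytest.approx(6 / 7)

    def test_determinism(self, rng):
        cds = random_cds(rng, 20)
        rec = CodingRecord.from_cds("x", cds)
        s1, s2 = summarize_protein(rec), summarize_protein(rec)
        assert s1.mutational_agg == s2.mutational_agg
        assert s1.strict_tolerance == s2.strict_tolerance


def _summary(strict: float) -> MutagenesisSummary:
    return MutagenesisSummary(
        protein_id="p", wt_agg_p=0.0, mutational_agg={}, strict_tolerance=strict,
        lenient_tolerance=strict, beneficial_proportion=0.0,
        detrimental_proportion=0.0, n_total=1, per_site={},
    )


class TestMutTolDelta:
    def test_identical_pairs_give_zero_delta(self):
        with pytest.raises(ValueError):
            # all-zero deltas have zero sd
            muttol_delta(["p1", "p2", "p3"], [_summary(0.5)] * 3, [_summary(0.5)] * 3)

    def test_hand_computed_z(self):
        """deltas {0,0,0,0.5}: sample mean 0.125, sample sd 0.25 -> z=1.5."""
        a = [_summary(0.5)] * 3 + [_summary(1.0)]
        b = [_summary(0.5)] * 4
        out = muttol_delta(["p1", "p2", "p3", "p4"], a, b)
        assert out[3].delta == pytest.approx(0.5)
        assert out[3].z == pytest.approx(1.5)
        assert all(rec.cls == "similar" for rec in out)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            muttol_delta(["p1", "p2"], [_summary(0.1)] * 2, [_summary(0.9)] * 2)
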