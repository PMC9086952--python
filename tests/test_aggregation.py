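import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggtol.aggregation import (
    AggregationProfile,
    SurrogateParams,
    SurrogatePredictor,
    agg_d,
    agg_p,
    project_domains,
    surrogate_scores,
)
from aggtol.io import DomainAnnotation, ScoreFile

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSurrogate:
    def test_poly_ile_saturates(self):
        assert surrogate_scores("I" * 10).scores == tuple([100.0] * 10)

    def test_poly_gly_is_silent(self):
        assert surrogate_scores("G" * 10).scores == tuple([0.0] * 10)

    def test_hand_evaluated_two_residue_example(self):
        # Kyte-Doolittle M=1.9, K=-3.9, I=4.5; window means with truncation
        assert surrogate_scores("MK").scores == (0.0, 0.0)
        assert surrogate_scores("MI").scores == pytest.approx((48.0, 48.0))

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            surrogate_scores("MKXL")

    def test_window_truncation_matches_direct_mean(self, rng):
        params = SurrogateParams()
        pred = SurrogatePredictor(params)
        protein = "".join(rng.choice(list(AA), 23))
        vals = np.array([params.scale[c] for c in protein])
        half = params.window // 2
        for i in range(len(protein)):
            w = vals[max(0, i - half) : min(len(protein), i + half + 1)]
            raw = w.mean()
            expected = (
                0.0
                if raw <= params.theta
                else 100.0 * min(1.0, (raw - params.theta) / (params.smax - params.theta))
            )
            assert pred(protein)[i] == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=3, max_size=25), st.data())
    def test_monotone_in_scale_value(self, protein, data):
        """Replacing one residue by a strictly higher-scale one never
        decreases any per-residue score."""
        params = SurrogateParams()
        pred = SurrogatePredictor(params)
        pos = data.draw(st.integers(0, len(protein) - 1))
        current = params.scale[protein[pos]]
        higher = [a for a in AA if params.scale[a] > current]
        if not higher:
            return
        repl = data.draw(st.sampled_from(higher))
        mutant = protein[:pos] + repl + protein[pos + 1 :]
        assert (pred(mutant) >= pred(protein) - 1e-12).all()

    def test_scores_bounded(self, rng):
        protein = "".join(rng.choice(list(AA), 200))
        scores = surrogate_scores(protein).scores
        assert min(scores) >= 0.0 and max(scores) <= 100.0


class TestAggScores:
    def test_whole_protein_mean(self):
        prof = AggregationProfile("p", (0.0, 50.0, 50.0, 0.0))
        assert agg_p(prof) == 25.0

    def test_all_zero(self):
        assert agg_p(AggregationProfile("p", (0.0,) * 7)) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            agg_p(AggregationProfile("p", ()))

    def test_domain_slice(self):
        prof = AggregationProfile("p", (0.0, 50.0, 50.0, 0.0))
        assert agg_d(prof, DomainAnnotation("p", "PF1", 2, 3)) == 50.0

    def test_full_length_domain_equals_whole_protein(self, rng):
        prof = AggregationProfile("p", tuple(rng.uniform(0, 100, 31)))
        dom = DomainAnnotation("p", "PF1", 1, 31)
        assert agg_d(prof, dom) == agg_p(prof)

    def test_random_interval_matches_slice_mean(self, rng):
        scores = rng.uniform(0, 100, 60)
        prof = AggregationProfile("p", tuple(scores))
        for _ in range(20):
            s = int(rng.integers(1, 60))
            e = int(rng.integers(s, 61))
            dom = DomainAnnotation("p", "PF1", s, e)
            assert agg_d(prof, dom) == pytest.approx(
                round(float(scores[s - 1 : e].mean()), 6)
            )

    def test_out_of_bounds_domain_rejected(self):
        prof = AggregationProfile("p", (1.0, 2.0))
        with pytest.raises(ValueError):
            agg_d(prof, DomainAnnotation("p", "PF1", 1, 3))

    def test_predictor_source_is_irrelevant_downstream(self, rng):
        """File-parsed and surrogate profiles with identical vectors give
        identical aggregate scores."""
        protein = "".join(rng.choice(list(AA), 40))
        surr = surrogate_scores(protein, protein_id="p")
        from_file = AggregationProfile.from_score_file(
            ScoreFile("p", protein, tuple(surr.scores))
        )
        assert agg_p(surr) == agg_p(from_file)
        dom = DomainAnnotation("p", "PF1", 5, 20)
        assert agg_d(surr, dom) == agg_d(from_file, dom)


class TestProjectDomains:
    def test_identity_alignment(self):
        doms = [DomainAnnotation("p", "PF1", 3, 7)]
        projected, dropped = project_domains(doms, "MKVLGAAA", "MKVLGAAA")
        assert dropped == [] and (projected[0].start, projected[0].end) == (3, 7)

    def test_insertion_in_target_shifts_coordinates(self):
        # B carries 3 extra residues before A's position 5
        gapped_a = "MKVL---GAAAXY"
        gapped_b = "MKVLQQQGAAAXY"
        doms = [DomainAnnotation("p", "PF1", 5, 10)]
        projected, _ = project_domains(doms, gapped_a, gapped_b)
        assert (projected[0].start, projected[0].end) == (8, 13)

    def test_domain_deleted_in_target_is_dropped(self):
        gapped_a = "MKVLGAAA"
        gapped_b = "MK----AA"
        doms = [DomainAnnotation("p", "PF1", 3, 6)]
        projected, dropped = project_domains(doms, gapped_a, gapped_b)
        assert projected == [] and dropped[0][0].domain_acc == "PF1"

    def test_boundary_in_gap_snaps_inward(self):
        gapped_a = "MKVLGAAA"
        gapped_b = "MK-LGA-A"
        doms = [DomainAnnotation("p", "PF1", 3, 7)]
        projected, _ = project_domains(doms, gapped_a, gapped_b)
        assert (projected[0].start, projected[0].end) == (3, 5)

    def test_projection_preserves_order(self, rng):
        """Projections of disjoint domains never interleave."""
        a = "M" + "".join(rng.choice(list(AA), 39))
        from aggtol.profiles import global_align

        b = a[:10] + a[15:]  # deletion in B
        aln = global_align(a, b)
        doms = [
            DomainAnnotation("p", "PF1", 2, 8),
            DomainAnnotation("p", "PF2", 20, 30),
        ]
        projected, _ = project_domains(doms, aln.gapped_a, aln.gapped_b)
        assert all(d.start <= d.end for d in projected)
        if len(projected) == 2:
            assert projected[0].end < projected[1].start
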