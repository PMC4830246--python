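import numpy as np
import pytest

from markermine.synthetic_data import (
    CommunityMember,
    CommunityProfile,
    GenePayload,
    back_translate,
    evaluate_against_truth,
    make_reference_set,
    mutate_nt,
    mutate_protein,
    realize_community,
    simulate_reads,
)
from markermine.homology_search import translate_six_frames


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestReferenceSets:
    def test_zero_divergence_gives_identical_decoys(self):
        targets, decoys = make_reference_set("fam", 3, 3, 0.1, 0.0, seed=5)
        for i, dseq in enumerate(decoys.values()):
            assert dseq == list(targets.values())[i % 3]

    def test_same_seed_is_byte_identical(self):
        a = make_reference_set("fam", 4, 4, 0.1, 0.4, seed=11)
        b = make_reference_set("fam", 4, 4, 0.1, 0.4, seed=11)
        assert a == b

    def test_decoy_divergence_sets_mean_identity(self):
        # divergence 0.4 -> mean pairwise identity to source ~60% +/- 5
        targets, decoys = make_reference_set(
            "fam", 4, 8, 0.1, 0.4, seed=3, length=400
        )
        tlist = list(targets.values())
        idents = [
            _identity(d, tlist[i % 4]) for i, d in enumerate(decoys.values())
        ]
        assert abs(float(np.mean(idents)) - 0.60) < 0.05

    def test_divergence_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            make_reference_set("fam", 2, 2, 0.1, 1.2, seed=0)

    def test_back_translation_round_trips_through_frame_one(self, rng):
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
        nt = back_translate(protein, rng)
        assert translate_six_frames(nt)[0] == protein

    def test_mutate_nt_hits_requested_rate(self, rng):
        nt = back_translate("M" * 500, rng)
        mut = mutate_nt(nt, 0.1, rng)
        diff = sum(a != b for a, b in zip(nt, mut)) / len(nt)
        assert 0.06 < diff < 0.14


def _one_gene_profile(rng) -> CommunityProfile:
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
    member = CommunityMember(
        label="solo",
        lineage=("root",),
        abundance=1.0,
        genome_size=600,
        payload=(GenePayload(label="fam", protein=protein),),
    )
    return CommunityProfile(members=(member,))


class TestSimulateReads:
    def test_gene_covering_genome_labels_every_read(self, rng):
        profile = _one_gene_profile(rng)
        reads, truth = simulate_reads(
            profile, n_reads=200, length_mean=150, length_sd=10,
            error_rate=0.0, seed=2, min_length=100,
        )
        assert all(t.origin == "fam" for t in truth.values())
        assert all(r.truth == "fam" for r in reads)

    def test_conservation_and_determinism(self, rng):
        profile = _one_gene_profile(rng)
        r1, t1 = simulate_reads(profile, n_reads=500, seed=9, min_length=50,
                                length_mean=120, length_sd=10)
        r2, t2 = simulate_reads(profile, n_reads=500, seed=9, min_length=50,
                                length_mean=120, length_sd=10)
        assert len(r1) == 500 == len(t1)
        assert [(r.id, r.seq, r.quals) for r in r1] == [
            (r.id, r.seq, r.quals) for r in r2
        ]
        assert t1 == t2

    def test_family_read_count_tracks_genome_fraction(self, rng):
        # Binomial oracle: family occupies fraction f of sampled bp; the
        # count of family-labeled reads is Binomial(n, ~f) (the >=50%
        # overlap rule makes the effective window exactly the gene length).
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        member = CommunityMember(
            label="m", lineage=("root",), abundance=1.0, genome_size=9000,
            payload=(GenePayload(label="fam", protein=protein),),
        )
        profile = CommunityProfile(members=(member,))
        n = 10_000
        reads, truth = simulate_reads(
            profile, n_reads=n, length_mean=150, length_sd=10, seed=4,
            error_rate=0.0,
        )
        f = 900 / 9000
        count = sum(t.origin == "fam" for t in truth.values())
        sd = (n * f * (1 - f)) ** 0.5
        assert abs(count - n * f) < 3 * sd

    def test_empty_profile_is_rejected(self):
        with pytest.raises(ValueError):
            CommunityProfile(members=())

    def test_abundances_must_sum_to_one(self, rng):
        member = _one_gene_profile(rng).members[0]
        import dataclasses

        with pytest.raises(ValueError, match="sum"):
            CommunityProfile(members=(dataclasses.replace(member, abundance=0.7),))

    def test_genome_must_fit_payload(self):
        with pytest.raises(ValueError, match="smaller than payload"):
            CommunityMember(
                label="m", lineage=(), abundance=1.0, genome_size=100,
                payload=(GenePayload(label="f", protein="M" * 100),),
            )

    def test_realization_embeds_genes_at_recorded_coordinates(self, rng):
        profile = _one_gene_profile(rng)
        real = realize_community(profile, seed=3)
        (label, s, e) = real.features["solo"][0]
        assert label == "fam"
        gene_nt = real.genomes["solo"][s:e]
        assert translate_six_frames(gene_nt)[0] == profile.members[0].payload[0].protein


class TestEvaluateAgainstTruth:
    def _truth(self, rng, n=200):
        from markermine.synthetic_data import TruthRow

        truth = {}
        for i in range(n):
            origin = "famA" if i % 2 == 0 else "background"
            truth[f"r{i}"] = TruthRow("m", origin, 0, 100)
        return truth

    def test_perfect_decisions_score_one(self, rng):
        truth = self._truth(rng)
        decisions = {
            rid: "famA" for rid, t in truth.items() if t.origin == "famA"
        }
        res = evaluate_against_truth(decisions, truth)
        assert res["famA"].precision == 1.0
        assert res["famA"].recall == 1.0

    def test_empty_decisions_give_zero_recall(self, rng):
        truth = self._truth(rng)
        res = evaluate_against_truth({}, truth, families=["famA"])
        assert res["famA"].recall == 0.0
        assert res["famA"].precision is None  # nothing kept

    def test_zero_truth_family_reports_undefined_recall(self, rng):
        truth = self._truth(rng)
        res = evaluate_against_truth({}, truth, families=["famB"])
        assert res["famB"].recall is None

    def test_unknown_read_id_is_an_error(self, rng):
        truth = self._truth(rng)
        with pytest.raises(KeyError, match="unknown read ids"):
            evaluate_against_truth({"nope": "famA"}, truth)

    def test_random_half_kept_recovers_half_recall(self, rng):
        truth = self._truth(rng, n=2000)
        famA = [rid for rid, t in truth.items() if t.origin == "famA"]
        kept = rng.choice(famA, size=len(famA) // 2, replace=False)
        res = evaluate_against_truth({rid: "famA" for rid in kept}, truth)
        n = len(famA)
        assert abs(res["famA"].recall - 0.5) < 3 * (0.25 / n) ** 0.5
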