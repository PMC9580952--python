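"""Stage-by-stage tests of the taxonomy-informed clustering cascade on
sequences with constructed, oracle-verified identities."""

import random

import pytest

from conftest import FULL_LINEAGE, make_seq, random_dna, with_substitutions
from ticlust.metrics import count_mixed_clusters
from ticlust.seqsim import global_identity
from ticlust.simdata import make_adversarial_pair, make_benchmark
from ticlust.taxonomy import PruneSpec, TaxonomicPath
from ticlust.tic_core import (
    Cutoffs,
    TicError,
    TicResult,
    cluster_known_genera,
    place_family_level,
    place_order_level,
    place_unranked,
    run_tic,
    taxonomy_blind_baseline,
    validate_result,
)


def lineage(genus=None, **overrides):
    ranks = dict(FULL_LINEAGE, **overrides)
    if genus is not None:
        ranks["genus"] = genus
    return ranks


class TestCutoffs:
    def test_defaults(self):
        c = Cutoffs()
        assert (c.species, c.genus, c.family) == (0.97, 0.95, 0.90)

    def test_ordering_enforced(self):
        with pytest.raises(TicError):
            Cutoffs(species=0.90, genus=0.95, family=0.97)


class TestClusterKnownGenera:
    def test_two_tight_genera(self, rng):
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)  # far apart
        seqs = [
            make_seq("a1", a, **lineage("G1")),
            make_seq("a2", with_substitutions(a, 3, offset=200), **lineage("G1")),
            make_seq("b1", b, **lineage("G2")),
            make_seq("b2", with_substitutions(b, 3, offset=200), **lineage("G2")),
        ]
        sotus = cluster_known_genera(seqs)
        assert len(sotus) == 2
        for cluster in sotus:
            assert cluster.taxonomy.known("species")
            assert cluster.taxonomy.name("species").startswith("sOTU_")

    def test_split_below_species_cutoff(self, rng):
        a = random_dna(rng, 300)
        b = with_substitutions(a, 12)  # 0.96: same genus, two molecular species
        assert global_identity(a, b) == pytest.approx(0.96)
        sotus = cluster_known_genera(
            [make_seq("a", a, **lineage("G1")), make_seq("b", b, **lineage("G1"))]
        )
        assert len(sotus) == 2
        assert {c.taxonomy.name("genus") for c in sotus} == {"G1"}

    def test_cross_genus_never_merged(self, rng):
        a = random_dna(rng, 300)
        b = with_substitutions(a, 3)  # 0.99 identical but different genus
        sotus = cluster_known_genera(
            [make_seq("a", a, **lineage("G1")), make_seq("b", b, **lineage("G2"))]
        )
        assert len(sotus) == 2

    def test_unknown_genus_rejected(self, rng):
        seq = make_seq("x", random_dna(rng, 50), **FULL_LINEAGE)
        with pytest.raises(TicError):
            cluster_known_genera([seq])


def _state_from_gseqs(gseqs, cutoffs=Cutoffs()):
    return run_tic(gseqs, cutoffs)


class TestPlaceFamilyLevel:
    def test_join_and_adopt(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        fseq = make_seq("f1", with_substitutions(a, 6), **lineage())  # 0.98
        result = place_family_level([fseq], state)
        assert result.seq_to_sotu["f1"] == result.seq_to_sotu["g1"]
        assert result.updated_taxonomy["f1"].name("genus") == "G1"

    def test_novel_sotu_in_existing_genus(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        fseq = make_seq("f1", with_substitutions(a, 12), **lineage())  # 0.96
        result = place_family_level([fseq], state)
        assert result.seq_to_sotu["f1"] != result.seq_to_sotu["g1"]
        assert result.updated_taxonomy["f1"].name("genus") == "G1"
        assert len(result.gotus) == 1

    def test_deferred_pair_forms_novel_genus(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        x = random_dna(rng, 300)                   # far from the known genus
        y = with_substitutions(x, 12, offset=150)  # 0.96 to x
        result = place_family_level(
            [make_seq("f1", x, **lineage()), make_seq("f2", y, **lineage())], state
        )
        novel_sotus = [c for c in result.sotus if "f1" in c.member_ids or "f2" in c.member_ids]
        assert len(novel_sotus) == 2
        genera = {c.taxonomy.name("genus") for c in novel_sotus}
        assert len(genera) == 1
        assert genera.pop().startswith("gOTU_")
        assert result.updated_taxonomy["f1"].name("family") == "Family_001"

    def test_known_genus_rejected(self, rng):
        seq = make_seq("x", random_dna(rng, 50), **lineage("G1"))
        with pytest.raises(TicError):
            place_family_level([seq], None)


class TestPlaceOrderLevel:
    def test_genus_tier_match_joins_family(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        oseq = make_seq(
            "o1", with_substitutions(a, 21),  # 0.93: family tier
            **{k: v for k, v in lineage().items() if k != "family"},
        )
        result = place_order_level([oseq], state)
        tax = result.updated_taxonomy["o1"]
        assert tax.name("family") == "Family_001"
        assert tax.name("genus").startswith("gOTU_")
        assert len(result.fotus) == 1  # placed inside the existing family

    def test_below_family_cutoff_seeds_novel_fotu(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        oseq = make_seq(
            "o1", random_dna(rng, 300),
            **{k: v for k, v in lineage().items() if k != "family"},
        )
        result = place_order_level([oseq], state)
        tax = result.updated_taxonomy["o1"]
        assert tax.name("family").startswith("fOTU_")
        assert len(result.fotus) == 2

    def test_single_oseq_empty_state_full_chain(self, rng):
        oseq = make_seq(
            "o1", random_dna(rng, 300),
            **{k: v for k, v in lineage().items() if k != "family"},
        )
        result = place_order_level([oseq], TicResult.empty())
        assert len(result.sotus) == len(result.gotus) == len(result.fotus) == 1
        tax = result.updated_taxonomy["o1"]
        assert tax.name("species").startswith("sOTU_")
        assert tax.name("genus").startswith("gOTU_")
        assert tax.name("family").startswith("fOTU_")
        assert tax.name("order") == "Order_1"

    def test_known_family_rejected(self, rng):
        with pytest.raises(TicError):
            place_order_level([make_seq("x", "ACGT" * 20, **lineage())], None)


class TestPlaceUnranked:
    def test_fully_unclassified_gets_placeholders(self, rng):
        seq = make_seq("u1", random_dna(rng, 300))
        result = place_unranked([seq], TicResult.empty())
        tax = result.updated_taxonomy["u1"]
        assert tax.name("order") == "UNKORDER"
        assert tax.name("class") == "UNKCLASS"
        assert tax.name("phylum") == "UNKPHYLUM"
        assert tax.name("family").startswith("fOTU_")
        assert tax.is_prefix_contiguous()

    def test_class_known_match_adopts_full_path(self, rng):
        a = random_dna(rng, 300)
        state = _state_from_gseqs([make_seq("g1", a, size=5, **lineage("G1"))])
        useq = make_seq(
            "u1", with_substitutions(a, 6),
            domain="Bacteria", phylum="Phylum_1", **{"class": "Class_1"},
        )
        result = place_unranked([useq], state)
        assert result.seq_to_sotu["u1"] == result.seq_to_sotu["g1"]
        assert result.updated_taxonomy["u1"].name("genus") == "G1"

    def test_two_distant_unclassified_two_fotus(self, rng):
        a = random_dna(rng, 300)
        b = with_substitutions(a, 45)  # 0.85: below family cutoff
        result = place_unranked(
            [make_seq("u1", a), make_seq("u2", b)], TicResult.empty()
        )
        assert len(result.fotus) == 2
        for tax in result.updated_taxonomy.values():
            assert tax.name("phylum") == "UNKPHYLUM"

    def test_order_known_rejected(self, rng):
        seq = make_seq(
            "x", "ACGT" * 20, **{k: v for k, v in lineage().items() if k != "family"}
        )
        with pytest.raises(TicError):
            place_unranked([seq], None)


class TestRunTic:
    def test_fully_classified_mirrors_structure(self, mini_benchmark, mini_params):
        dataset, truth = mini_benchmark
        result = run_tic(dataset)
        validate_result(result, dataset)
        assert len(result.fotus) == mini_params.n_families
        assert len(result.gotus) == mini_params.n_genera
        assert len(result.sotus) == mini_params.n_species
        # known clusters are flagged non-novel, species always novel
        assert all(c.novel for c in result.sotus)
        assert not any(c.novel for c in result.gotus)
        assert not any(c.novel for c in result.fotus)

    def test_empty_taxonomy_equals_place_unranked(self, rng):
        seqs = [make_seq(f"s{i}", random_dna(rng, 300)) for i in range(3)]
        via_run = run_tic(seqs)
        via_stage = place_unranked(seqs, TicResult.empty())
        assert via_run.seq_to_sotu == via_stage.seq_to_sotu
        assert via_run.updated_taxonomy == via_stage.updated_taxonomy

    def test_duplicate_ids_rejected(self, rng):
        seq = make_seq("dup", random_dna(rng, 50))
        with pytest.raises(TicError, match="duplicate"):
            run_tic([seq, make_seq("dup", random_dna(rng, 50))])

    def test_noncontiguous_taxonomy_rejected(self, rng):
        seq = make_seq("x", random_dna(rng, 50), domain="Bacteria", genus="G")
        with pytest.raises(TicError, match="contiguous"):
            run_tic([seq])

    def test_reserved_names_rejected(self, rng):
        seq = make_seq("x", random_dna(rng, 50), **lineage("gOTU_7"))
        with pytest.raises(TicError, match="reserved"):
            run_tic([seq])

    def test_input_species_rank_ignored(self, rng):
        seq = make_seq("x", random_dna(rng, 300), **lineage("G1"), species="RealSpecies")
        result = run_tic([seq])
        assert result.updated_taxonomy["x"].name("species").startswith("sOTU_")

    def test_soft_pruned_zero_mixed_genera(self, mini_params):
        spec = PruneSpec(mode="soft", seed=31)
        dataset, truth = make_benchmark(mini_params, spec)
        result = run_tic(dataset)
        validate_result(result, dataset)
        assert (
            count_mixed_clusters(
                result.sequence_members("genus"), truth.paths, "genus"
            )
            == 0
        )

    def test_prune_rate_zero_is_idempotent(self, mini_params):
        unpruned, _ = make_benchmark(mini_params)
        spec = PruneSpec(rates={}, mode="soft", seed=1)
        pruned, _ = make_benchmark(mini_params, spec)
        res_a = run_tic(unpruned)
        res_b = run_tic(pruned)
        assert res_a.seq_to_sotu == res_b.seq_to_sotu
        assert res_a.sotu_to_gotu == res_b.sotu_to_gotu
        assert res_a.updated_taxonomy == res_b.updated_taxonomy

    def test_shuffle_invariance(self, mini_params):
        spec = PruneSpec(mode="soft", seed=13)
        dataset, _ = make_benchmark(mini_params, spec)
        shuffled = list(dataset)
        random.Random(99).shuffle(shuffled)
        res_a = run_tic(dataset)
        res_b = run_tic(shuffled)
        assert res_a.seq_to_sotu == res_b.seq_to_sotu
        assert res_a.sotu_to_gotu == res_b.sotu_to_gotu
        assert res_a.gotu_to_fotu == res_b.gotu_to_fotu
        assert res_a.updated_taxonomy == res_b.updated_taxonomy

    def test_membership_identity_at_species_cutoff(self, mini_params):
        spec = PruneSpec(mode="soft", seed=31)
        dataset, _ = make_benchmark(mini_params, spec)
        result = run_tic(dataset)
        by_id = {s.id: s for s in dataset}
        for cluster in result.sotus:
            for member in cluster.member_ids:
                assert (
                    global_identity(by_id[member].seq, cluster.centroid_seq) >= 0.97
                )

    def test_hierarchy_conservation(self, mini_benchmark):
        dataset, _ = mini_benchmark
        result = run_tic(dataset)
        seqs_via_family = sorted(
            sid
            for members in result.sequence_members("family").values()
            for sid in members
        )
        assert seqs_via_family == sorted(s.id for s in dataset)


class TestBaselineComparison:
    def test_tic_never_worse_than_blind(self, mini_params):
        spec = PruneSpec(mode="soft", seed=31)
        dataset, truth = make_benchmark(mini_params, spec)
        result = run_tic(dataset)
        tic_mixed = count_mixed_clusters(
            result.sequence_members("genus"), truth.paths, "genus"
        )
        blind = taxonomy_blind_baseline(dataset, 0.95)
        blind_mixed = count_mixed_clusters(blind, truth.paths, "genus")
        assert tic_mixed == 0
        assert blind_mixed >= tic_mixed

    def test_adversarial_fixture_strict_separation(self):
        dataset, truth = make_adversarial_pair(seed=1)
        result = run_tic(dataset)
        tic_mixed = count_mixed_clusters(
            result.sequence_members("genus"), truth.paths, "genus"
        )
        blind = taxonomy_blind_baseline(dataset, 0.95)
        blind_mixed = count_mixed_clusters(blind, truth.paths, "genus")
        assert tic_mixed == 0
        assert blind_mixed >= 1
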