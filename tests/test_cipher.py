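import numpy as np
import pytest

from herbnet.cipher import (
    DrugCipherCS,
    concordance_score,
    formula_profiles,
    rank_targets,
    read_profiles,
    top_k_profile,
    write_profiles,
)
from herbnet.compounds import Compound, SimilarityVector
from herbnet.ppi import ClosenessVector, network_from_edges
from herbnet.synthetic import generate_space, generate_query, precision_at_k

from _oracles import pearson_sums


def vecs(sim, clo, refs=None):
    refs = refs or tuple(f"d{i}" for i in range(len(sim)))
    return (
        SimilarityVector("q", refs, np.array(sim)),
        ClosenessVector("G", refs, np.array(clo)),
    )


class TestConcordance:
    def test_perfect_positive_affine_relation(self):
        sim, clo = vecs([0.1, 0.4, 0.9], [1.2, 1.8, 2.8])  # clo = 2*sim + 1
        assert concordance_score(sim, clo) == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        sim, clo = vecs([0.1, 0.4, 0.9], [-0.1, -0.4, -0.9])
        assert concordance_score(sim, clo) == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        x, y = [0.1, 0.5, 0.9, 0.3], [0.2, 0.4, 1.1, 0.2]
        sim, clo = vecs(x, y)
        assert concordance_score(sim, clo) == pytest.approx(
            pearson_sums(x, y), abs=1e-12
        )

    def test_degenerate_zero_variance_scores_zero(self):
        sim, clo = vecs([0.5, 0.5, 0.5], [0.1, 0.9, 0.3])
        assert concordance_score(sim, clo) == 0.0

    def test_misaligned_references_raise(self):
        sim, _ = vecs([0.1, 0.2, 0.3], [1, 2, 3])
        _, clo = vecs([0.1, 0.2, 0.3], [1, 2, 3], refs=("x", "y", "z"))
        with pytest.raises(ValueError):
            concordance_score(sim, clo)

    def test_too_short_raises(self):
        sim, clo = vecs([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            concordance_score(sim, clo)

    def test_affine_invariance_property(self, rng):
        for _ in range(20):
            x = rng.random(10)
            y = rng.random(10)
            sim, clo = vecs(x, y, refs=tuple(f"d{i}" for i in range(10)))
            base = concordance_score(sim, clo)
            sim2, clo2 = vecs(
                2.5 * x + 1.0, 0.3 * y + 7.0, refs=tuple(f"d{i}" for i in range(10))
            )
            assert concordance_score(sim2, clo2) == pytest.approx(base, abs=1e-10)


def _toy_space():
    """5 drugs, two disjoint target modules wired as two cliques."""
    module_a = [f"A{i}" for i in range(4)]
    module_b = [f"B{i}" for i in range(4)]
    edges = [(m[i], m[j]) for m in (module_a, module_b)
             for i in range(4) for j in range(i + 1, 4)]
    edges.append(("A0", "B0"))  # weak bridge
    net = network_from_edges(edges)

    def fp(*on):
        v = np.zeros(16, dtype=np.uint8)
        v[list(on)] = 1
        return v

    refs = [
        Compound("dA1", "reference", "", fp(0, 1, 2)),
        Compound("dA2", "reference", "", fp(0, 1, 3)),
        Compound("dA3", "reference", "", fp(0, 2, 3)),
        Compound("dB1", "reference", "", fp(8, 9, 10)),
        Compound("dB2", "reference", "", fp(8, 9, 11)),
    ]
    ref_targets = {
        "dA1": {"A0", "A1"},
        "dA2": {"A1", "A2"},
        "dA3": {"A2", "A3"},
        "dB1": {"B0", "B1"},
        "dB2": {"B2", "B3"},
    }
    query = Compound("q", "query", "", fp(0, 1, 2))  # identical to dA1
    return query, refs, ref_targets, net, module_a, module_b


class TestRanking:
    def test_query_matching_drug_family_ranks_its_module_first(self):
        query, refs, ref_targets, net, module_a, module_b = _toy_space()
        scores = rank_targets(query, refs, ref_targets, net)
        top4 = [t.gene for t in scores[:4]]
        assert set(top4) == set(module_a)

    def test_single_gene_universe(self):
        query, refs, ref_targets, net, *_ = _toy_space()
        scores = rank_targets(query, refs, ref_targets, net, gene_universe=["A0"])
        assert len(scores) == 1 and scores[0].gene == "A0"

    def test_universe_order_does_not_change_output(self):
        query, refs, ref_targets, net, module_a, module_b = _toy_space()
        a = rank_targets(
            query, refs, ref_targets, net, gene_universe=module_a + module_b
        )
        b = rank_targets(
            query, refs, ref_targets, net, gene_universe=module_b[::-1] + module_a
        )
        assert [t.gene for t in a] == [t.gene for t in b]

    def test_vectorized_scores_match_scalar_concordance(self):
        from herbnet.compounds import similarity_vector
        from herbnet.ppi import closeness_vector

        query, refs, ref_targets, net, *_ = _toy_space()
        scores = {t.gene: t for t in rank_targets(query, refs, ref_targets, net)}
        sim = similarity_vector(query, refs)
        for gene in net.nodes:
            clo = closeness_vector(gene, ref_targets, net)
            expected = concordance_score(sim, clo)
            assert scores[gene].score == pytest.approx(expected, abs=1e-10)

    def test_fewer_than_three_references_raise(self):
        query, refs, ref_targets, net, *_ = _toy_space()
        with pytest.raises(ValueError):
            rank_targets(query, refs[:2], ref_targets, net)

    def test_degenerate_genes_sort_last(self):
        query, refs, ref_targets, net, *_ = _toy_space()
        net2 = network_from_edges(
            [tuple(e) for e in net.edges] + [("LONER1", "LONER2")]
        )
        scores = rank_targets(query, refs, ref_targets, net2)
        assert {t.gene for t in scores[-2:]} == {"LONER1", "LONER2"}
        assert all(t.degenerate for t in scores[-2:])


class TestProfiles:
    def test_default_k_on_large_universe(self):
        scores = rank_targets(*_toy_space()[:4])
        prof = top_k_profile(scores, k=3)
        assert len(prof) == 3 and prof.k == 3

    def test_truncation_floor(self):
        scores = rank_targets(*_toy_space()[:4])
        prof = top_k_profile(scores, k=100)
        assert len(prof) == 8  # universe smaller than k

    def test_k_one(self):
        scores = rank_targets(*_toy_space()[:4])
        assert len(top_k_profile(scores, k=1)) == 1

    def test_nonpositive_k_raises(self):
        scores = rank_targets(*_toy_space()[:4])
        with pytest.raises(ValueError):
            top_k_profile(scores, k=0)

    def test_identical_structures_identical_profiles(self):
        query, refs, ref_targets, net, *_ = _toy_space()
        twin = Compound("q2", "query", "", query.fingerprint)
        model = DrugCipherCS(k=5).fit(refs, ref_targets, net)
        out = model.predict([query, twin])
        assert out["q"].entries == out["q2"].entries

    def test_empty_collection_warns_and_returns_empty(self):
        query, refs, ref_targets, net, *_ = _toy_space()
        model = DrugCipherCS().fit(refs, ref_targets, net)
        with pytest.warns(UserWarning):
            assert model.predict([]) == {}

    def test_roundtrip_through_tsv(self, tmp_path):
        query, refs, ref_targets, net, *_ = _toy_space()
        out = DrugCipherCS(k=4).fit(refs, ref_targets, net).predict([query])
        path = tmp_path / "profiles.tsv"
        write_profiles(out, path)
        back = read_profiles(path)
        assert back["q"].genes == out["q"].genes


class TestPlantedRecovery:
    def test_mean_recovery_beats_hypergeometric_baseline(self):
        space = generate_space(seed=42)
        n_genes = space.ppi.number_of_nodes()
        model = DrugCipherCS(k=100).fit(
            space.references, space.reference_targets, space.ppi
        )
        precisions = []
        for fam in range(len(space.modules)):
            query, planted = generate_query(space, fam)
            prof = model.predict([query])[query.id]
            baseline = len(planted) / n_genes  # hypergeometric k·m/N over k
            precisions.append((precision_at_k(prof.genes, planted), baseline))
        assert np.mean([p for p, _ in precisions]) > np.mean(
            [b for _, b in precisions]
        )

    def test_formula_profiles_one_per_ingredient(self):
        space = generate_space(
            n_families=3, drugs_per_family=4, genes_per_module=20,
            inter_module_edges=20, seed=5,
        )
        queries = [generate_query(space, f)[0] for f in range(3)]
        profs = formula_profiles(
            queries, space.references, space.reference_targets, space.ppi, k=10
        )
        assert set(profs) == {q.id for q in queries}
        assert all(len(p) == 10 for p in profs.values())
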