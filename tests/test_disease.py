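import pytest

from herbnet.cipher import TargetProfile
from herbnet.disease import (
    assemble_seeds,
    expand_to_disease_network,
    flag_off_targets,
    map_herb_targets,
)
from herbnet.ppi import network_from_edges

from _oracles import one_hop_union


def profile(iid, genes):
    return TargetProfile(iid, tuple((g, 1.0) for g in genes), k=len(genes))


class TestSeeds:
    def test_multilabel_merge(self):
        seeds = assemble_seeds(known=["TNF"], predicted=["TNF", "IL1B"])
        assert len(seeds) == 2
        assert seeds.genes["TNF"] == frozenset({"known", "predicted"})

    def test_disjoint_lists_union(self):
        seeds = assemble_seeds(
            known=["A", "B"], predicted=["C", "D", "E"],
            drug_targets=["F", "G", "H", "I"],
        )
        assert len(seeds) == 9

    def test_case_variants_merge(self):
        seeds = assemble_seeds(known=["Tnf"], predicted=["TNF"])
        assert seeds.symbols() == {"TNF"}

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            assemble_seeds()


class TestExpansion:
    def test_star_center_seed_pulls_whole_star(self):
        net = network_from_edges([("HUB", f"L{i}") for i in range(5)])
        dn = expand_to_disease_network(assemble_seeds(known=["HUB"]), net)
        assert dn.nodes == net.nodes
        assert dn.expansion_layer["HUB"] == 0
        assert all(dn.expansion_layer[f"L{i}"] == 1 for i in range(5))

    def test_absent_seed_kept_isolated(self, chain_net):
        dn = expand_to_disease_network(assemble_seeds(known=["ZZZ"]), chain_net)
        assert dn.nodes == {"ZZZ"}
        assert dn.network.graph.degree("ZZZ") == 0

    def test_matches_bruteforce_adjacency_union(self, rng):
        nodes = [f"N{i}" for i in range(12)]
        pairs = [
            (nodes[i], nodes[j])
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.25
        ]
        net = network_from_edges(pairs)
        seeds = assemble_seeds(known=["N0", "N5", "N11"])
        dn = expand_to_disease_network(seeds, net)
        edge_set = {frozenset(p) for p in pairs}
        assert dn.nodes == one_hop_union({"N0", "N5", "N11"} & net.nodes, edge_set) | {
            s for s in ("N0", "N5", "N11") if s not in net.nodes
        }
        # induced edges match exhaustive pair checking
        for a in dn.nodes:
            for b in dn.nodes:
                if a < b:
                    assert dn.network.graph.has_edge(a, b) == (
                        frozenset((a, b)) in edge_set
                    )

    def test_adding_a_seed_never_shrinks(self, chain_net):
        base = expand_to_disease_network(assemble_seeds(known=["A"]), chain_net)
        grown = expand_to_disease_network(
            assemble_seeds(known=["A"], predicted=["C"]), chain_net
        )
        assert base.nodes <= grown.nodes

    def test_depth_two_option(self, chain_net):
        dn = expand_to_disease_network(
            assemble_seeds(known=["A"]), chain_net, depth=2
        )
        assert dn.nodes == {"A", "B", "C"}
        assert dn.expansion_layer["C"] == 2


class TestHerbMapping:
    def test_profiles_outside_network_empty_herb_net(self, chain_net):
        dn = expand_to_disease_network(assemble_seeds(known=["A"]), chain_net)
        hn = map_herb_targets("H", {"i1": profile("i1", ["X", "Y"])}, dn)
        assert hn.mapped_targets == frozenset()
        assert hn.network is None

    def test_full_coverage_reproduces_disease_network(self, chain_net):
        dn = expand_to_disease_network(assemble_seeds(known=["B"]), chain_net)
        hn = map_herb_targets("H", {"i1": profile("i1", ["A", "B", "C"])}, dn)
        assert hn.mapped_targets == dn.nodes
        assert hn.network.edges == dn.network.edges

    def test_repeated_mapping_is_idempotent(self, chain_net):
        dn = expand_to_disease_network(assemble_seeds(known=["B"]), chain_net)
        profs = {"i1": profile("i1", ["A", "B"])}
        first = map_herb_targets("H", profs, dn)
        second = map_herb_targets("H", profs, dn)
        assert first.mapped_targets == second.mapped_targets
        assert first.network.edges == second.network.edges

    def test_qly_huang_bai_maps_kdr_and_ptgs1(self, qly):
        from herbnet.disease import read_seed_list
        from herbnet.ppi import load_network

        ppi = load_network(qly.data_dir / "ppi.tsv")
        seeds = assemble_seeds(
            known=read_seed_list(qly.data_dir / "seeds_known.txt"),
            predicted=read_seed_list(qly.data_dir / "seeds_predicted.txt"),
            drug_targets=read_seed_list(qly.data_dir / "seeds_drug_targets.txt"),
        )
        dn = expand_to_disease_network(seeds, ppi)
        herb_profiles = {
            ing: profile(ing, sorted(qly.ingredient_targets[ing]))
            for ing, herb in qly.herb_of_ingredient.items()
            if herb == "Huang-Bai"
        }
        hn = map_herb_targets("Huang-Bai", herb_profiles, dn)
        assert {"KDR", "PTGS1"} <= hn.mapped_targets


class TestOffTargets:
    def _kushen_and_huangbai(self, qly):
        from herbnet.disease import read_seed_list
        from herbnet.ppi import load_network

        ppi = load_network(qly.data_dir / "ppi.tsv")
        seeds = assemble_seeds(
            known=read_seed_list(qly.data_dir / "seeds_known.txt"),
            predicted=read_seed_list(qly.data_dir / "seeds_predicted.txt"),
            drug_targets=read_seed_list(qly.data_dir / "seeds_drug_targets.txt"),
        )
        dn = expand_to_disease_network(seeds, ppi)
        nets = {}
        for herb in ("Ku-Shen", "Huang-Bai"):
            profs = {
                ing: profile(ing, sorted(qly.ingredient_targets[ing]))
                for ing, h in qly.herb_of_ingredient.items()
                if h == herb
            }
            nets[herb] = map_herb_targets(herb, profs, dn)
        return nets

    def test_ptgs1_flagged_with_counteracting_herb(self, qly):
        nets = self._kushen_and_huangbai(qly)
        flagged = flag_off_targets(nets["Ku-Shen"], qly.adverse_genes, nets)
        assert flagged.off_target_flags == {"PTGS1"}
        assert flagged.counter_acting_herbs["PTGS1"] == {"Huang-Bai"}

    def test_empty_adverse_list_no_flags(self, qly):
        nets = self._kushen_and_huangbai(qly)
        assert not flag_off_targets(nets["Ku-Shen"], []).off_target_flags

    def test_adverse_gene_outside_network_not_flagged(self, qly):
        nets = self._kushen_and_huangbai(qly)
        flagged = flag_off_targets(nets["Huang-Bai"], ["NOTAGENE"])
        assert not flagged.off_target_flags
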