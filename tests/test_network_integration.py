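"""Network seeding, KO mapping, pathway-co-membership expansion and export."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kernelprot.network_integration import (
    Expansion,
    NetworkConfig,
    build_network,
    expand_interactions,
    filter_candidates,
    map_orthology,
    read_graphml,
    strip_protein_suffix,
    summarize,
    write_graphml,
    write_sif,
)
from kernelprot.quant_io import OrthologMap, PathwayLinkTable


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "ratio,kept", [(5.0, True), (0.2, True), (2.0, False), (0.25, False), (8.0, True)]
    )
    def test_two_sided_five_fold_cutoff(self, ratio, kept):
        out = filter_candidates({"P1": {10: ratio}}, NetworkConfig())
        assert ("P1" in out) == kept

    def test_any_stage_suffices(self):
        out = filter_candidates({"P1": {10: 1.0, 46: 6.0}}, NetworkConfig())
        assert out == {"P1"}

    def test_grid_matches_brute_force_predicate(self):
        cfg = NetworkConfig(min_fold=5.0)
        for ratio in np.logspace(-2, 2, 401):
            kept = filter_candidates({"P": {10: float(ratio)}}, cfg)
            expected = ratio >= 5.0 or ratio <= 0.2
            assert ("P" in kept) == expected

    def test_min_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            NetworkConfig(min_fold=1.0)


class TestMapOrthology:
    def test_suffix_stripping_reaches_gene_model(self):
        omap = OrthologMap(
            protein_to_gene={"GRMZM2G097226": "GRMZM2G097226"},
            gene_to_ko={"GRMZM2G097226": "K00001"},
        )
        mapped, unmapped = map_orthology(["GRMZM2G097226_P01"], omap)
        assert mapped == {"GRMZM2G097226_P01": "K00001"}
        assert unmapped == []

    def test_unmapped_seed_reported_not_dropped(self):
        mapped, unmapped = map_orthology(["NOPE_P01"], OrthologMap())
        assert mapped == {}
        assert unmapped == ["NOPE_P01"]

    def test_strip_suffix_only_on_isoform_pattern(self):
        assert strip_protein_suffix("GRMZM2G170017_P01") == "GRMZM2G170017"
        assert strip_protein_suffix("AC12345.3_P02") == "AC12345.3"
        assert strip_protein_suffix("NO_SUFFIX") == "NO_SUFFIX"

    @given(
        genes=st.dictionaries(
            st.text(alphabet="AB", min_size=1, max_size=3),
            st.sampled_from(["K00001", "K00002", None]),
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_two_step_dictionary_lookup(self, genes):
        omap = OrthologMap(
            protein_to_gene={f"{g}_P01": g for g in genes},
            gene_to_ko={g: ko for g, ko in genes.items() if ko},
        )
        seeds = [f"{g}_P01" for g in genes]
        mapped, unmapped = map_orthology(seeds, omap)
        for g, ko in genes.items():
            pid = f"{g}_P01"
            if ko is None:
                assert pid in unmapped
            else:
                assert mapped[pid] == ko


def links_from(pairs):
    return PathwayLinkTable(pairs=set(pairs))


class TestExpandInteractions:
    def test_single_pathway_one_hop(self):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KC", "p1")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        assert exp.first_degree == {"B", "C"}
        assert exp.second_degree == set()

    def test_chained_pathways_two_hops(self):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KB", "p2"), ("KC", "p2")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        assert exp.first_degree == {"B"}
        assert exp.second_degree == {"C"}

    def test_seed_without_pathways_contributes_nothing(self):
        links = links_from([("KB", "p1")])
        exp = expand_interactions({"A": "KA"}, links, {"A": "KA", "B": "KB"})
        assert exp.first_degree == set() and exp.second_degree == set()
        assert exp.isolated_seeds == ["A"]

    def test_max_degree_one_stops_after_first_hop(self):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KB", "p2"), ("KC", "p2")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome, max_degree=1)
        assert exp.first_degree == {"B"} and exp.second_degree == set()

    def test_witness_pathways_recorded(self):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KB", "p2"), ("KC", "p2")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        assert exp.witness["B"] == {"p1"}
        assert exp.witness["C"] == {"p2"}


def bfs_oracle(seed_kos, pairs, max_depth=2):
    """Depth-limited BFS on the KO co-membership graph."""
    g = nx.Graph()
    by_pathway = {}
    for ko, pw in pairs:
        g.add_node(ko)
        by_pathway.setdefault(pw, set()).add(ko)
    for members in by_pathway.values():
        for a, b in itertools.combinations(sorted(members), 2):
            g.add_edge(a, b)
    depth = {}
    frontier = set(seed_kos)
    for ko in frontier:
        depth[ko] = 0
    for d in range(1, max_depth + 1):
        nxt = set()
        for ko in frontier:
            for nb in g.neighbors(ko) if ko in g else ():
                if nb not in depth:
                    depth[nb] = d
                    nxt.add(nb)
        frontier = nxt
    first = {k for k, d in depth.items() if d == 1}
    second = {k for k, d in depth.items() if d == 2}
    return first, second


class TestBfsEquivalence:
    def test_random_bipartite_graphs_match_bfs_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n_kos = int(rng.integers(3, 50))
            n_pw = int(rng.integers(1, 10))
            density = float(rng.uniform(0.05, 0.5))
            kos = [f"K{i:05d}" for i in range(n_kos)]
            pairs = {
                (k, f"p{j}")
                for k in kos
                for j in range(n_pw)
                if rng.random() < density
            }
            n_seeds = int(rng.integers(1, max(2, n_kos // 4)))
            seed_kos = {f"S{i}": kos[i] for i in range(n_seeds)}
            proteome = {f"S{i}": kos[i] for i in range(n_seeds)}
            proteome.update({f"N{k}": k for k in kos[n_seeds:]})
            exp = expand_interactions(seed_kos, links_from(pairs), proteome)
            first_k, second_k = bfs_oracle(set(seed_kos.values()), pairs)
            # a non-seed protein sharing a pathway-member seed KO is one
            # co-membership hop from the seed, hence first-degree
            kos_in_pathways = {k for k, _ in pairs}
            first_level = first_k | (set(seed_kos.values()) & kos_in_pathways)
            expected_first = {
                p for p, k in proteome.items()
                if k in first_level and p not in seed_kos
            }
            expected_second = {
                p for p, k in proteome.items()
                if k in second_k and p not in seed_kos
            }
            assert exp.first_degree == expected_first
            assert exp.second_degree == expected_second

    def test_removing_pathway_never_grows_interactor_sets(self):
        rng = np.random.default_rng(5)
        kos = [f"K{i:05d}" for i in range(15)]
        pairs = {
            (k, f"p{j}") for k in kos for j in range(5) if rng.random() < 0.3
        }
        proteome = {f"N{k}": k for k in kos}
        seed_kos = {"Nseed": kos[0]}
        proteome["Nseed"] = kos[0]
        full = expand_interactions(seed_kos, links_from(pairs), proteome)
        for drop in {pw for _, pw in pairs}:
            reduced = {(k, p) for k, p in pairs if p != drop}
            exp = expand_interactions(seed_kos, links_from(reduced), proteome)
            assert exp.first_degree <= full.first_degree | full.second_degree
            assert len(exp.first_degree) <= len(full.first_degree)


class TestBuildNetwork:
    def fixture_graph(self):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KC", "p1")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        return build_network(
            {"A"}, exp, {"A": [46]}, proteome, links, stages=(46,)
        )

    def test_hand_counted_fixture(self):
        g = self.fixture_graph()
        roles = nx.get_node_attributes(g, "role")
        assert sum(1 for r in roles.values() if r == "stage") == 1
        assert sum(1 for r in roles.values() if r == "dep") == 1
        assert sum(1 for r in roles.values() if r == "first_degree") == 2
        assert g.number_of_edges() == 3  # stage-dep + 2 dep-interactor

    def test_empty_seed_set_gives_stage_nodes_only(self):
        links = links_from([("KA", "p1")])
        exp = Expansion(first_degree=set(), second_degree=set())
        g = build_network(set(), exp, {}, {}, links, stages=(10, 20, 33, 46))
        roles = set(nx.get_node_attributes(g, "role").values())
        assert roles == {"stage"}
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 0

    def test_role_multiset_invariant_under_input_order(self):
        from collections import Counter

        links = links_from([("KA", "p1"), ("KB", "p1"), ("KC", "p1"), ("KC", "p2"), ("KD", "p2")])
        proteome = {"A": "KA", "B": "KB", "C": "KC", "D": "KD"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        g1 = build_network({"A"}, exp, {"A": [10, 46]}, proteome, links)
        proteome2 = dict(reversed(list(proteome.items())))
        exp2 = expand_interactions({"A": "KA"}, links, proteome2)
        g2 = build_network({"A"}, exp2, {"A": [46, 10]}, proteome2, links)
        c1 = Counter(nx.get_node_attributes(g1, "role").values())
        c2 = Counter(nx.get_node_attributes(g2, "role").values())
        assert c1 == c2


class TestSummarizeAndExport:
    def test_endosperm_scale_counts_total(self):
        """97 first- plus 883 second-degree interactors total 980."""
        g = nx.Graph()
        g.add_node("d", role="dep")
        for i in range(97):
            g.add_node(f"f{i}", role="first_degree")
        for i in range(883):
            g.add_node(f"s{i}", role="second_degree")
        s = summarize(g)
        assert (s.n_first, s.n_second) == (97, 883)
        assert s.n_total_interactors == 980

    def test_empty_network_all_zero(self):
        s = summarize(nx.Graph())
        assert (s.n_dep, s.n_first, s.n_second, s.n_total_interactors) == (0, 0, 0, 0)

    def test_graphml_round_trip_preserves_roles_and_edges(self, tmp_path):
        links = links_from([("KA", "p1"), ("KB", "p1"), ("KB", "p2"), ("KC", "p2")])
        proteome = {"A": "KA", "B": "KB", "C": "KC"}
        exp = expand_interactions({"A": "KA"}, links, proteome)
        g = build_network({"A"}, exp, {"A": [10]}, proteome, links, stages=(10,))
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        back = read_graphml(path)
        assert nx.get_node_attributes(back, "role") == nx.get_node_attributes(g, "role")
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}

    def test_sif_lists_every_edge_once(self, tmp_path):
        g = self_graph = TestBuildNetwork().fixture_graph()
        path = tmp_path / "net.sif"
        write_sif(g, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == g.number_of_edges()
        assert all(len(line.split("\t")) == 3 for line in lines)
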