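import numpy as np
import pytest
import sympy

from strucbif.network_core import Reaction, ReactionNetwork, Species
from strucbif.symbolic_amatrix import SignClass, build_A, symbolic_determinant
from strucbif.decomposition import (
    StructuralSingularityError,
    all_buffering_structures,
    bifurcating_chemicals,
    block_triangularize,
    buffering_structures,
    inducing_parameters,
    influence_graph,
    is_output_complete,
    minimal_buffering_structure,
    six_step_report,
    subnetwork_index,
)
from strucbif.fixtures import RandomNetworkSpec, random_network

from oracles import bruteforce_buffering_structures


def _block_members(dec):
    return {frozenset(s.chemicals) | frozenset(s.reactions)
            for s in dec.structures if s.chemicals or s.reactions}


class TestBlockTriangularize:
    def test_socs3d_three_structures(self, macrophage_socs3d):
        fx = macrophage_socs3d
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        expected = {
            frozenset({"N", "Np", "R7", "R8"}),
            frozenset({"S1", "S1p", "S6", "S6p", "R1", "R2", "R5", "R6"}),
            frozenset({"S3", "S3p", "R3", "R4"}),
        }
        assert _block_members(dec) == expected

    def test_conserved_example_blocks(self, conserved_example):
        fx = conserved_example
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        expected = {
            frozenset({"A", "R2"}),
            frozenset({"C", "R4"}),
            frozenset({"B", "D", "E", "R3", "R5", "R6"}),
            frozenset({"R1"}),
        }
        assert _block_members(dec) == expected
        # the inflow-only block carries the through-flux loop column
        r1_block = next(s for s in dec.structures if s.reactions == ["R1"])
        assert len(r1_block.loop_cols) == 1

    def test_wild_type_single_block(self, macrophage_wt):
        fx = macrophage_wt
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        assert dec.n_blocks == 1

    def test_diagonal_network_fully_splits(self):
        net = ReactionNetwork(
            [Species(s) for s in ("A", "B")],
            [Reaction("R1", reactants={"A": 1}),
             Reaction("R2", reactants={"B": 1})])
        dec = block_triangularize(build_A(net))
        assert dec.n_blocks == 2
        assert all(len(s.row_idx) == 1 for s in dec.structures)

    def test_upper_triangular_and_permutations(self, all_fixtures):
        for fx in all_fixtures:
            dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
            assert dec.verify_upper_triangular()
            n = dec.A.sym.rows
            assert sorted(dec.row_perm) == list(range(n))
            assert sorted(dec.col_perm) == list(range(n))

    def test_degenerate_network_raises(self):
        net = ReactionNetwork([Species("A")],
                              [Reaction("R1", products={"A": 1})])
        with pytest.raises(StructuralSingularityError):
            block_triangularize(build_A(net))

    def test_det_A_is_product_of_blocks(self, conserved_example,
                                        macrophage_socs3d):
        for fx in (conserved_example, macrophage_socs3d):
            A = build_A(fx.network, C=fx.C, D=fx.D)
            dec = block_triangularize(A)
            product = sympy.Integer(dec.permutation_sign())
            for s in dec.structures:
                product *= s.determinant
            assert sympy.expand(symbolic_determinant(A.sym) - product) == 0

    def test_finestness_no_block_splits_further(self, all_fixtures):
        for fx in all_fixtures:
            dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
            for s in dec.structures:
                if len(s.row_idx) <= 1:
                    continue
                sub = build_A(fx.network, C=fx.C, D=fx.D).sym[s.row_idx,
                                                              s.col_idx]
                # re-decomposing the block alone must not split it
                from scipy.sparse import csr_matrix
                from scipy.sparse.csgraph import connected_components
                import networkx as nx
                pat = np.array([[sub[i, j] != 0 for j in range(sub.cols)]
                                for i in range(sub.rows)])
                from scipy.sparse.csgraph import maximum_bipartite_matching
                match = maximum_bipartite_matching(
                    csr_matrix(pat.astype(np.int8)), perm_type="column")
                row_of_col = np.empty(len(match), dtype=int)
                row_of_col[match] = np.arange(len(match))
                H = nx.DiGraph()
                H.add_nodes_from(range(len(match)))
                for c in range(len(match)):
                    for c2 in np.nonzero(pat[row_of_col[c]])[0]:
                        if c2 != c:
                            H.add_edge(c, int(c2))
                assert nx.number_strongly_connected_components(H) == 1


class TestInfluenceGraph:
    def test_conserved_example_edges(self, conserved_example):
        fx = conserved_example
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        label = {i: frozenset(s.chemicals) | frozenset(s.reactions)
                 for i, s in enumerate(dec.structures)}
        edges = {(label[u], label[v]) for u, v in graph.graph.edges()}
        g1 = frozenset({"A", "R2"})
        g2 = frozenset({"C", "R4"})
        g3 = frozenset({"B", "D", "E", "R3", "R5", "R6"})
        g4 = frozenset({"R1"})
        assert edges == {(g2, g1), (g4, g1), (g4, g2), (g4, g3)}

    def test_socs3d_influence(self, macrophage_socs3d):
        fx = macrophage_socs3d
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        by_chem = {}
        for i, s in enumerate(dec.structures):
            if "N" in s.chemicals:
                by_chem["g1"] = i
            elif "S1" in s.chemicals:
                by_chem["g2"] = i
            elif "S3" in s.chemicals:
                by_chem["g3"] = i
        edges = set(graph.graph.edges())
        assert (by_chem["g2"], by_chem["g1"]) in edges
        # STAT3 block is upstream of both others, nothing flows into it
        assert graph.graph.in_degree(by_chem["g3"]) == 0

    def test_single_block_no_edges(self, macrophage_wt):
        fx = macrophage_wt
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        assert graph.graph.number_of_edges() == 0

    def test_acyclic_on_random_networks(self):
        import networkx as nx
        for seed in range(30):
            net = random_network(RandomNetworkSpec(seed=seed))
            try:
                dec = block_triangularize(build_A(net))
            except StructuralSingularityError:
                continue
            graph = influence_graph(dec)
            assert nx.is_directed_acyclic_graph(graph.graph)

    def test_dot_and_graphml_exports(self, conserved_example):
        fx = conserved_example
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        dot = graph.to_dot()
        assert dot.startswith("digraph") and "->" in dot
        assert "<graphml" in graph.to_graphml()


class TestBufferingStructures:
    def test_example1_gamma(self, example1):
        rep = six_step_report(example1.network, C=example1.C, D=example1.D)
        members = {(b.chemicals, b.reactions) for b in rep.buffering}
        assert (frozenset({"B"}), frozenset({"R2", "R3"})) in members

    def test_conserved_example_named_structures(self, conserved_example):
        fx = conserved_example
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        members = {(b.chemicals, b.reactions) for b in rep.buffering}
        assert (frozenset({"A"}), frozenset({"R2"})) in members
        assert (frozenset({"A", "C"}), frozenset({"R2", "R4"})) in members
        assert (frozenset({"B", "D", "E"}),
                frozenset({"R3", "R5", "R6"})) in members

    def test_wild_type_only_trivial(self, macrophage_wt):
        fx = macrophage_wt
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        assert len(rep.buffering) == 1
        assert rep.buffering[0].is_trivial

    def test_trivial_reported_last(self, conserved_example):
        fx = conserved_example
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        assert rep.buffering[-1].is_trivial
        assert not any(b.is_trivial for b in rep.buffering[:-1])

    def test_structures_are_output_complete_and_index_zero(self,
                                                           all_fixtures):
        for fx in all_fixtures:
            rep = six_step_report(fx.network, C=fx.C, D=fx.D)
            for b in rep.buffering:
                assert is_output_complete(fx.network, b.chemicals,
                                          b.reactions)
                assert subnetwork_index(fx.network, b.chemicals,
                                        b.reactions) == 0

    def test_descendant_closed(self, conserved_example):
        fx = conserved_example
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        g = rep.graph
        for b in rep.buffering:
            for i in b.block_indices:
                assert g.descendants_closure(i) <= b.block_indices


class TestOracleEquivalence:
    N_NETWORKS = 60  # acceptance runs the full 200; keep the suite snappy

    def test_matches_bruteforce_on_random_networks(self):
        checked = 0
        for seed in range(self.N_NETWORKS):
            spec = RandomNetworkSpec(n_species=(2, 5), n_reactions=(2, 7),
                                     seed=seed)
            net = random_network(spec)
            try:
                ours = all_buffering_structures(net)
            except StructuralSingularityError:
                continue
            assert ours == bruteforce_buffering_structures(net), \
                f"buffering-structure mismatch at seed {seed}"
            checked += 1
        assert checked >= self.N_NETWORKS * 0.8

    def test_matches_bruteforce_on_fixtures(self, example1,
                                            conserved_example):
        for fx in (example1, conserved_example):
            assert all_buffering_structures(fx.network) == \
                bruteforce_buffering_structures(fx.network)


class TestBifurcationRules:
    def test_example1_inducing_includes_r2(self, example1):
        fx = example1
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        gamma = next(i for i, s in enumerate(dec.structures)
                     if "B" in s.chemicals)
        params = inducing_parameters(graph, gamma)
        assert "R2" in params["reactions"]

    def test_wt_inducing_includes_eta1(self, macrophage_wt):
        fx = macrophage_wt
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        params = inducing_parameters(graph, 0)
        assert "eta1" in params["conserved"]

    def test_conserved_example_gamma3_parameters(self, conserved_example):
        fx = conserved_example
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        g3 = next(i for i, s in enumerate(dec.structures)
                  if "B" in s.chemicals)
        params = inducing_parameters(graph, g3)
        assert set(params["reactions"]) == {"R1", "R3", "R5", "R6"}
        assert "R2" not in params["reactions"]
        assert "R4" not in params["reactions"]

    def test_inducing_equals_quoted_set_rule(self, conserved_example,
                                             macrophage_socs3d):
        # parameters NOT inside any buffering structure disjoint from the block
        for fx in (conserved_example, macrophage_socs3d):
            rep = six_step_report(fx.network, C=fx.C, D=fx.D)
            graph, dec = rep.graph, rep.decomposition
            for beta in range(dec.n_blocks):
                got = set(inducing_parameters(graph, beta)["reactions"])
                excluded = set()
                for b in rep.buffering:
                    if beta not in b.block_indices:
                        excluded |= b.reactions
                expected = {r for s in dec.structures
                            for r in s.reactions} - excluded
                assert got == expected

    def test_bifurcating_chemicals_example1(self, example1):
        fx = example1
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        gamma = next(i for i, s in enumerate(dec.structures)
                     if "B" in s.chemicals)
        assert bifurcating_chemicals(graph, gamma) == {"B"}

    def test_bifurcating_chemicals_socs3d(self, macrophage_socs3d):
        fx = macrophage_socs3d
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        g2 = next(i for i, s in enumerate(dec.structures)
                  if "S1" in s.chemicals)
        assert bifurcating_chemicals(graph, g2) == \
            {"N", "Np", "S1", "S1p", "S6", "S6p"}

    def test_bifurcating_chemicals_double_mutant(self,
                                                 macrophage_socs3d_klf4d):
        fx = macrophage_socs3d_klf4d
        dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
        graph = influence_graph(dec)
        g2 = next(i for i, s in enumerate(dec.structures)
                  if "S1" in s.chemicals)
        assert bifurcating_chemicals(graph, g2) == \
            {"S1", "S1p", "S6", "S6p"}

    def test_minimal_buffering_structure_is_buffering(self, all_fixtures):
        for fx in all_fixtures:
            dec = block_triangularize(build_A(fx.network, C=fx.C, D=fx.D))
            graph = influence_graph(dec)
            full = frozenset(range(dec.n_blocks))
            for i in range(dec.n_blocks):
                b = minimal_buffering_structure(graph, i)
                if b.block_indices != full:
                    assert is_output_complete(fx.network, b.chemicals,
                                              b.reactions)
                    assert subnetwork_index(fx.network, b.chemicals,
                                            b.reactions) == 0


class TestSixStepReport:
    def test_example1_report(self, example1):
        rep = six_step_report(example1.network, C=example1.C, D=example1.D)
        assert len(rep.conditions) == 1
        cond = rep.conditions[0]
        assert cond["bifurcating_chemicals"] == ["B"]
        det = sympy.sympify(cond["condition"])
        assert len(det.args) == 2  # r2B - r3B

    def test_socs3d_only_gamma2_responsible(self, macrophage_socs3d):
        fx = macrophage_socs3d
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        assert len(rep.conditions) == 1
        assert sorted(rep.conditions[0]["bifurcating_chemicals"]) == \
            ["N", "Np", "S1", "S1p", "S6", "S6p"]

    def test_wt_all_chemicals_bifurcate(self, macrophage_wt):
        fx = macrophage_wt
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        assert len(rep.conditions) == 1
        assert sorted(rep.conditions[0]["bifurcating_chemicals"]) == \
            sorted(fx.network.species_ids)

    def test_renderings(self, conserved_example):
        fx = conserved_example
        rep = six_step_report(fx.network, C=fx.C, D=fx.D)
        assert "determinant_structures" in rep.to_dict()
        assert rep.to_json().strip().startswith("{")
        assert rep.to_markdown().startswith("# Bifurcation report")

    def test_deletions_route(self, macrophage_wt):
        from strucbif.fixtures import SOCS3_DELETION
        rep = six_step_report(macrophage_wt.network, C=macrophage_wt.C,
                              D=macrophage_wt.D, deletions=SOCS3_DELETION)
        assert rep.decomposition.n_blocks == 3
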