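"""Finest block-triangularization of A and everything it implies.

The nonzero pattern of A is block-triangularized by the standard finest
construction: maximum bipartite matching, strongly connected components of
the matched directed graph, condensation topological order.  The diagonal
blocks are the *determinant structures*; the off-diagonal pattern yields the
(acyclic) influence graph; descendant-closed unions of blocks are the
*buffering structures*; and the per-block determinant sign classes drive the
six-step bifurcation report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
import sympy as sp
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from strucbif.network_core import ReactionNetwork, build_stoichiometric_matrix
from strucbif.linear_structure import (
    restricted_cokernel_dim,
    restricted_kernel_dim,
)
from strucbif.symbolic_amatrix import (
    AugmentedMatrixA,
    SignClass,
    apply_deletion,
    build_A,
    classify_sign,
    symbolic_determinant,
)


def _exact_rank_cached(arr: np.ndarray) -> int:
    import sympy as _sp
    return _sp.Matrix(arr.tolist()).rank() if arr.size else 0


class StructuralSingularityError(ValueError):
    """A has no perfect matching on its nonzero pattern: det A is identically 0."""


class DecompositionContractError(AssertionError):
    """A closed set failed output-completeness or the index check."""


@dataclass
class DeterminantStructure:
    """One diagonal block of the finest block-triangular form of A."""

    label: str
    chemicals: list[str]
    reactions: list[str]
    loop_cols: list[str]
    cons_rows: list[str]
    row_idx: list[int]            # original row indices in A, block order
    col_idx: list[int]
    A: AugmentedMatrixA

    @cached_property
    def block(self) -> sp.Matrix:
        return self.A.sym[self.row_idx, self.col_idx]

    @cached_property
    def determinant(self) -> sp.Expr:
        return symbolic_determinant(self.block)

    @cached_property
    def sign_class(self) -> SignClass:
        return classify_sign(self.determinant, self.A.sign_table())

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.chemicals) | frozenset(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"DeterminantStructure({self.label}: "
                f"chem={self.chemicals}, rxn={self.reactions})")


@dataclass
class BlockDecomposition:
    A: AugmentedMatrixA
    structures: list[DeterminantStructure]
    row_perm: list[int]           # P_r A P_c = A[row_perm][:, col_perm]
    col_perm: list[int]

    @property
    def n_blocks(self) -> int:
        return len(self.structures)

    def permuted_matrix(self) -> sp.Matrix:
        return self.A.sym[self.row_perm, self.col_perm]

    def permutation_sign(self) -> int:
        """det(P_r) * det(P_c); relates det A to the product of block dets."""
        return _perm_sign(self.row_perm) * _perm_sign(self.col_perm)

    def off_diagonal_nonzero(self) -> np.ndarray:
        """Y pattern: entry (i, j) True iff block Y_ij (i != j) is nonzero."""
        S = self.n_blocks
        Y = np.zeros((S, S), dtype=bool)
        for i, bi in enumerate(self.structures):
            for j, bj in enumerate(self.structures):
                if i == j:
                    continue
                sub = self.A.sym[bi.row_idx, bj.col_idx]
                Y[i, j] = any(sub[k, l] != 0 for k in range(sub.rows)
                              for l in range(sub.cols))
        return Y

    def verify_upper_triangular(self) -> bool:
        Y = self.off_diagonal_nonzero()
        return not np.any(np.tril(Y, k=-1))


@dataclass
class InfluenceGraph:
    """DAG over determinant structures; edge i -> j: i influences j."""

    decomposition: BlockDecomposition
    graph: nx.DiGraph

    @property
    def structures(self) -> list[DeterminantStructure]:
        return self.decomposition.structures

    def descendants_closure(self, index: int) -> frozenset[int]:
        """Block index set reachable from ``index`` (inclusive)."""
        return frozenset({index} | nx.descendants(self.graph, index))

    def ancestors_closure(self, index: int) -> frozenset[int]:
        return frozenset({index} | nx.ancestors(self.graph, index))

    def to_dot(self) -> str:
        lines = ["digraph influence {"]
        for i, s in enumerate(self.structures):
            members = ", ".join(s.chemicals + s.reactions)
            lines.append(f'  g{i} [label="{s.label}\\n{{{members}}}"];')
        for u, v in sorted(self.graph.edges()):
            lines.append(f"  g{u} -> g{v};")
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self) -> str:
        g = nx.DiGraph()
        for i, s in enumerate(self.structures):
            g.add_node(f"g{i}", label=s.label,
                       chemicals=",".join(s.chemicals),
                       reactions=",".join(s.reactions))
        for u, v in self.graph.edges():
            g.add_edge(f"g{u}", f"g{v}")
        return "\n".join(nx.generate_graphml(g)) + "\n"


@dataclass
class BufferingStructure:
    """Descendant-closed union of determinant structures.

    Output-complete and of zero index: perturbations inside it stay inside.
    """

    block_indices: frozenset[int]
    chemicals: frozenset[str]
    reactions: frozenset[str]
    is_trivial: bool
    join_irreducible: bool        # the closure of a single block

    @property
    def members(self) -> frozenset[str]:
        return self.chemicals | self.reactions


def block_triangularize(A: AugmentedMatrixA) -> BlockDecomposition:
    """Finest block-triangular form of A's nonzero pattern.

    Maximum bipartite matching + SCCs of the matched digraph + condensation
    topological order (ties broken by smallest original column index).
    Raises :class:`StructuralSingularityError` without a perfect matching.
    """
    pattern = A.pattern()
    n = pattern.shape[0]
    if pattern.shape[0] != pattern.shape[1]:
        raise AssertionError("A must be square")
    if n == 0:
        return BlockDecomposition(A, [], [], [])

    sparse = csr_matrix(pattern.astype(np.int8))
    # row i is matched with column match[i]
    match = maximum_bipartite_matching(sparse, perm_type="column")
    if np.any(match < 0):
        raise StructuralSingularityError(
            "structurally degenerate network: det A == 0 identically")
    row_of_col = np.empty(n, dtype=int)
    row_of_col[match] = np.arange(n)

    # digraph on columns: c -> c' iff the row matched to c has an entry at c'
    H = nx.DiGraph()
    H.add_nodes_from(range(n))
    for c in range(n):
        r = row_of_col[c]
        for c2 in np.nonzero(pattern[r])[0]:
            if c2 != c:
                H.add_edge(c, int(c2))

    cond = nx.condensation(H)  # nodes carry 'members'
    order = list(nx.lexicographical_topological_sort(
        cond, key=lambda b: min(cond.nodes[b]["members"])))

    net = A.net
    M, N = net.n_species, net.n_reactions
    structures: list[DeterminantStructure] = []
    row_perm: list[int] = []
    col_perm: list[int] = []
    for k, b in enumerate(order):
        cols = sorted(cond.nodes[b]["members"])
        rows = sorted(int(row_of_col[c]) for c in cols)
        structures.append(DeterminantStructure(
            label=f"G{k + 1}",
            chemicals=[A.col_labels[c] for c in cols if c < M],
            reactions=[A.row_labels[r] for r in rows if r < N],
            loop_cols=[A.col_labels[c] for c in cols if c >= M],
            cons_rows=[A.row_labels[r] for r in rows if r >= N],
            row_idx=rows, col_idx=cols, A=A,
        ))
        row_perm.extend(rows)
        col_perm.extend(cols)

    dec = BlockDecomposition(A, structures, row_perm, col_perm)
    if not dec.verify_upper_triangular():
        raise AssertionError("internal error: decomposition is not upper "
                             "block triangular")
    return dec


def influence_graph(dec: BlockDecomposition) -> InfluenceGraph:
    """Edge i -> j iff Y_ji is nonzero (block i's columns feed block j's rows)."""
    Y = dec.off_diagonal_nonzero()
    g = nx.DiGraph()
    g.add_nodes_from(range(dec.n_blocks))
    for i in range(dec.n_blocks):
        for j in range(dec.n_blocks):
            if i != j and Y[j, i]:
                g.add_edge(i, j)
    if not nx.is_directed_acyclic_graph(g):
        raise AssertionError("internal error: influence graph has a cycle; "
                             "the decomposition was not finest")
    return InfluenceGraph(dec, g)


def _closed_set_structure(graph: InfluenceGraph,
                          blocks: frozenset[int]) -> tuple[frozenset[str],
                                                           frozenset[str]]:
    chems: set[str] = set()
    rxns: set[str] = set()
    for i in blocks:
        s = graph.structures[i]
        chems.update(s.chemicals)
        rxns.update(s.reactions)
    return frozenset(chems), frozenset(rxns)


def is_output_complete(net: ReactionNetwork, chemicals: frozenset[str],
                       reactions: frozenset[str]) -> bool:
    """Every reaction whose rate depends on a member chemical is a member."""
    for rxn in net.reactions:
        if rxn.id in reactions:
            continue
        if any(sp_id in chemicals for sp_id in rxn.dependent_species()):
            return False
    return True


def subnetwork_index(net: ReactionNetwork, chemicals: frozenset[str],
                     reactions: frozenset[str]) -> int:
    """#chemicals - #reactions + #loops - #conserved, by restricted null spaces.

    Both counts are basis independent and fixed by the requirement that the
    subnetwork can sit as a square leading block of a triangular rearrangement
    of A: loops are kernel directions supported entirely on the subnetwork's
    reactions (their columns may join the block); conserved quantities are
    cokernel directions whose support *touches* the subnetwork's chemicals
    (their rows are forced into the block).  A buffering structure has index
    zero.
    """
    nu = build_stoichiometric_matrix(net)
    rxn_idx = [net.reaction_index(r) for r in reactions]
    comp_idx = [i for i, s in enumerate(net.species_ids) if s not in chemicals]
    loops = restricted_kernel_dim(nu.entries, rxn_idx)
    q_total = nu.shape[0] - _exact_rank_cached(nu.entries)
    conserved = q_total - restricted_cokernel_dim(nu.entries, comp_idx)
    return len(chemicals) - len(reactions) + loops - conserved


def _is_buffering(net: ReactionNetwork, chems: frozenset[str],
                  rxns: frozenset[str]) -> bool:
    return (is_output_complete(net, chems, rxns)
            and subnetwork_index(net, chems, rxns) == 0)


def _closed_sets(graph: InfluenceGraph,
                 max_structures: int) -> tuple[set[frozenset[int]],
                                               list[frozenset[int]], bool]:
    """Joins of the principal descendant closures, capped; plus the full set."""
    S = graph.decomposition.n_blocks
    closures = [graph.descendants_closure(i) for i in range(S)]
    found: set[frozenset[int]] = set(closures)
    frontier = list(found)
    truncated = False
    while frontier and len(found) < max_structures:
        nxt: list[frozenset[int]] = []
        for a in frontier:
            for b in closures:
                u = a | b
                if u not in found:
                    found.add(u)
                    nxt.append(u)
                    if len(found) >= max_structures:
                        truncated = True
                        break
            if len(found) >= max_structures:
                break
        frontier = nxt
    found.add(frozenset(range(S)))
    return found, closures, truncated


def buffering_structures(graph: InfluenceGraph,
                         dec: BlockDecomposition | None = None,
                         max_structures: int = 512) -> list[BufferingStructure]:
    """All buffering structures expressible as closed unions of blocks.

    Candidates are the descendant-closed unions of determinant structures
    (enumeration capped at ``max_structures``, with a ``truncated`` flag on
    the results); each candidate is kept only if it passes the definition:
    output-complete and zero index.  A closed set can genuinely fail the
    definition when a conserved-moiety vector straddles several blocks --
    its row sits in one block but the quantity is not conserved within the
    candidate subnetwork -- so filtering is correct behaviour, not an error.
    """
    dec = dec or graph.decomposition
    net = dec.A.net
    found, closures, truncated = _closed_sets(graph, max_structures)
    full = frozenset(range(dec.n_blocks))
    out: list[BufferingStructure] = []
    for blocks in found:
        chems, rxns = _closed_set_structure(graph, blocks)
        if not (chems or rxns):
            continue
        if blocks != full and not _is_buffering(net, chems, rxns):
            continue
        out.append(BufferingStructure(
            block_indices=blocks, chemicals=chems, reactions=rxns,
            is_trivial=(blocks == full),
            join_irreducible=(blocks in closures),
        ))
    out.sort(key=lambda b: (b.is_trivial, len(b.block_indices),
                            sorted(b.block_indices)))
    for b in out:
        b.truncated = truncated  # type: ignore[attr-defined]
    return out


def minimal_buffering_structure(graph: InfluenceGraph,
                                block_index: int) -> BufferingStructure:
    """Smallest buffering structure containing a determinant structure.

    Starts from the descendant closure and, while the candidate fails the
    buffering definition (a conserved row straddling out of it), pulls in the
    blocks of the straddling chemicals and re-closes.  Terminates at the
    trivial whole-network structure at the latest.
    """
    dec = graph.decomposition
    net = dec.A.net
    chem_block = {c: i for i, s in enumerate(dec.structures)
                  for c in s.chemicals}
    blocks = graph.descendants_closure(block_index)
    full = frozenset(range(dec.n_blocks))
    while True:
        chems, rxns = _closed_set_structure(graph, blocks)
        if blocks == full or _is_buffering(net, chems, rxns):
            break
        grown = set(blocks)
        for i in blocks:
            for lab in dec.structures[i].cons_rows:
                q = dec.A.D.labels.index(lab)
                support = {net.species_ids[m]
                           for m in np.nonzero(dec.A.D.D[:, q])[0]}
                grown.update(chem_block[c] for c in support)
        if grown == set(blocks):
            blocks = full      # no progress possible: fall back to trivial
        else:
            blocks = frozenset().union(
                *(graph.descendants_closure(i) for i in grown))
    chems, rxns = _closed_set_structure(graph, blocks)
    return BufferingStructure(blocks, chems, rxns,
                              is_trivial=(blocks == full),
                              join_irreducible=True)


def inducing_parameters(graph: InfluenceGraph,
                        block_index: int) -> dict[str, list[str]]:
    """Parameters whose change can drive the block's determinant through zero.

    These live in the blocks from which ``block_index`` is reachable
    (ancestors plus itself): their reaction rate constants and the conserved
    quantities whose rows sit in those blocks.  Equivalent to: parameters not
    inside any buffering structure disjoint from the block.
    """
    blocks = graph.ancestors_closure(block_index)
    reactions: list[str] = []
    conserved: list[str] = []
    for i in sorted(blocks):
        s = graph.structures[i]
        reactions.extend(s.reactions)
        conserved.extend(s.cons_rows)
    return {"reactions": sorted(reactions), "conserved": sorted(conserved)}


def bifurcating_chemicals(graph: InfluenceGraph,
                          block_index: int) -> frozenset[str]:
    """Chemicals of the minimal buffering structure containing the block."""
    return minimal_buffering_structure(graph, block_index).chemicals


def all_buffering_structures(net: ReactionNetwork,
                             max_structures: int = 4096,
                             max_bases: int = 4096
                             ) -> set[tuple[frozenset[str], frozenset[str]]]:
    """Every buffering structure, via influence-graph closures.

    A single block-triangularization sees only the buffering structures whose
    loops lie in *its* kernel basis; overlapping circuits (e.g. three 2-cycles
    spanning a 2-dimensional kernel) make a simultaneously adapted basis
    impossible.  This routine unions the descendant-closed sets over a family
    of circuit-adapted bases: for every independent set of kernel circuits
    (up to the kernel dimension, capped at ``max_bases`` distinct support
    patterns) a basis containing it.  Any subnetwork's loop space is spanned
    by circuits inside it, so some enumerated basis is adapted to each
    buffering structure.  Candidates still pass the basis-independent
    definition checks (with cached restricted ranks -- only the nonzero
    patterns matter here, so the inner loop is numpy-only).
    """
    import itertools as _it

    from strucbif.linear_structure import (_exact_rank,
                                           kernel_basis, kernel_circuits,
                                           minimal_support_cokernel_basis,
                                           minimal_support_kernel_basis)

    nu = build_stoichiometric_matrix(net).entries
    M, N = nu.shape
    D = minimal_support_cokernel_basis(nu)
    C0 = minimal_support_kernel_basis(nu)
    circuits = kernel_circuits(nu)
    P = kernel_basis(nu).P

    # dependency pattern of dr/dx (boolean, N x M)
    dep = np.zeros((N, M), dtype=bool)
    for i, rxn in enumerate(net.reactions):
        for sid in rxn.dependent_species():
            dep[i, net.species_ids.index(sid)] = True

    # cached exact restricted null-space dimensions
    loop_cache: dict[frozenset, int] = {}
    cons_cache: dict[frozenset, int] = {}
    Q_total = D.Q

    def loops_of(rxn_idx: frozenset) -> int:
        if rxn_idx not in loop_cache:
            from strucbif.linear_structure import restricted_kernel_dim
            loop_cache[rxn_idx] = restricted_kernel_dim(nu, sorted(rxn_idx))
        return loop_cache[rxn_idx]

    def cons_of(chem_idx: frozenset) -> int:
        if chem_idx not in cons_cache:
            from strucbif.linear_structure import restricted_cokernel_dim
            comp = sorted(set(range(M)) - chem_idx)
            cons_cache[chem_idx] = Q_total - restricted_cokernel_dim(nu, comp)
        return cons_cache[chem_idx]

    def closed_sets_for(C_cols: np.ndarray):
        """Closed block unions of the pattern-BTF for kernel matrix C_cols."""
        n = N + Q_total
        pattern = np.zeros((n, n), dtype=bool)
        pattern[:N, :M] = dep
        if C_cols.size:
            pattern[:N, M:] = C_cols != 0
        if D.Q:
            pattern[N:, :M] = D.D.T != 0
        sparse = csr_matrix(pattern.astype(np.int8))
        match = maximum_bipartite_matching(sparse, perm_type="column")
        if np.any(match < 0):
            raise StructuralSingularityError(
                "structurally degenerate network: det A == 0 identically")
        row_of_col = np.empty(n, dtype=int)
        row_of_col[match] = np.arange(n)
        H = nx.DiGraph()
        H.add_nodes_from(range(n))
        for c in range(n):
            for c2 in np.nonzero(pattern[row_of_col[c]])[0]:
                if c2 != c:
                    H.add_edge(c, int(c2))
        cond = nx.condensation(H)
        rev = cond.reverse()  # influence direction: descendants = downstream
        members = [frozenset(cond.nodes[b]["members"]) for b in cond.nodes]
        out = set()
        closures = [frozenset({b} | nx.descendants(rev, b))
                    for b in cond.nodes]
        frontier = set(closures)
        seen = set(frontier)
        while frontier:
            nxt = set()
            for a in frontier:
                for b in closures:
                    u = a | b
                    if u not in seen and len(seen) < max_structures:
                        seen.add(u)
                        nxt.add(u)
            frontier = nxt
        for blocks in seen:
            cols = frozenset().union(*(members[b] for b in blocks))
            chem_idx = frozenset(c for c in cols if c < M)
            rxn_idx = frozenset(int(row_of_col[c]) for c in cols
                                if int(row_of_col[c]) < N)
            out.add((chem_idx, rxn_idx))
        return out

    # basis family: independent circuit subsets, deduped by support pattern
    def complete(vs: list[np.ndarray]) -> np.ndarray | None:
        chosen = list(vs)
        for cand in circuits:
            if len(chosen) >= P:
                break
            stack = np.array(chosen + [cand]).T
            if np.linalg.matrix_rank(stack.astype(float)) == len(chosen) + 1:
                chosen.append(cand)
        for j in range(C0.C.shape[1]):
            if len(chosen) >= P:
                break
            cand = C0.C[:, j]
            stack = np.array(chosen + [cand]).T
            if np.linalg.matrix_rank(stack.astype(float)) == len(chosen) + 1:
                chosen.append(cand)
        if len(chosen) != P:
            return None
        arr = np.array(chosen, dtype=np.int64).T
        return arr if _exact_rank(arr) == P else None

    candidates: set[tuple[frozenset, frozenset]] = set()
    if P == 0:
        candidates |= closed_sets_for(np.zeros((N, 0), dtype=np.int64))
    seen_patterns: set = set()
    n_bases = 0
    for size in range(1 if P == 0 else 0, min(P, len(circuits)) + 1):
        if n_bases >= max_bases:
            break
        for combo in _it.combinations(range(len(circuits)), size):
            vs = [circuits[i] for i in combo]
            if vs and np.linalg.matrix_rank(
                    np.array(vs).T.astype(float)) != size:
                continue
            C_cols = complete(vs)
            if C_cols is None:
                continue
            key = frozenset(tuple(np.nonzero(C_cols[:, j])[0].tolist())
                            for j in range(P))
            if key in seen_patterns:
                continue
            seen_patterns.add(key)
            n_bases += 1
            candidates |= closed_sets_for(C_cols)
            if n_bases >= max_bases:
                break

    found: set[tuple[frozenset[str], frozenset[str]]] = set()
    for chem_idx, rxn_idx in candidates:
        if not (chem_idx or rxn_idx):
            continue
        # output-completeness on the boolean dependency pattern
        depends = dep[:, sorted(chem_idx)].any(axis=1) if chem_idx else \
            np.zeros(N, dtype=bool)
        if not set(np.nonzero(depends)[0]) <= rxn_idx:
            continue
        index = (len(chem_idx) - len(rxn_idx) + loops_of(rxn_idx)
                 - cons_of(chem_idx))
        if index != 0:
            continue
        found.add((frozenset(net.species_ids[i] for i in chem_idx),
                   frozenset(net.reaction_ids[i] for i in rxn_idx)))
    return found


# ---------------------------------------------------------------------------
# The six-step report
# ---------------------------------------------------------------------------

@dataclass
class BifurcationReport:
    net: ReactionNetwork
    A: AugmentedMatrixA
    decomposition: BlockDecomposition
    graph: InfluenceGraph
    buffering: list[BufferingStructure]
    conditions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_species": self.net.n_species,
            "n_reactions": self.net.n_reactions,
            "n_loops": self.A.C.P,
            "n_conserved": self.A.D.Q,
            "determinant_structures": [
                {
                    "label": s.label,
                    "chemicals": s.chemicals,
                    "reactions": s.reactions,
                    "loops": s.loop_cols,
                    "conserved": s.cons_rows,
                    "determinant": str(s.determinant),
                    "sign_class": s.sign_class.value,
                }
                for s in self.decomposition.structures
            ],
            "influence_edges": [
                [self.graph.structures[u].label, self.graph.structures[v].label]
                for u, v in sorted(self.graph.graph.edges())
            ],
            "buffering_structures": [
                {
                    "blocks": [self.graph.structures[i].label
                               for i in sorted(b.block_indices)],
                    "chemicals": sorted(b.chemicals),
                    "reactions": sorted(b.reactions),
                    "is_trivial": b.is_trivial,
                    "join_irreducible": b.join_irreducible,
                }
                for b in self.buffering
            ],
            "bifurcation_conditions": self.conditions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = ["# Bifurcation report", "",
                 f"Species: {d['n_species']}, reactions: {d['n_reactions']}, "
                 f"loops: {d['n_loops']}, conserved quantities: "
                 f"{d['n_conserved']}", "",
                 "## Determinant structures", ""]
        for s in d["determinant_structures"]:
            lines.append(f"- **{s['label']}**: chemicals {s['chemicals']}, "
                         f"reactions {s['reactions']}; det = `{s['determinant']}`"
                         f" [{s['sign_class']}]")
        lines += ["", "## Influence edges", ""]
        for u, v in d["influence_edges"]:
            lines.append(f"- {u} -> {v}")
        lines += ["", "## Buffering structures", ""]
        for b in d["buffering_structures"]:
            tag = " (trivial: whole network)" if b["is_trivial"] else ""
            lines.append(f"- {{{', '.join(b['blocks'])}}}: "
                         f"chemicals {b['chemicals']}{tag}")
        lines += ["", "## Bifurcation conditions", ""]
        if not d["bifurcation_conditions"]:
            lines.append("- none: every block determinant is sign-definite")
        for c in d["bifurcation_conditions"]:
            lines.append(
                f"- **{c['structure']}**: condition `{c['condition']} = 0`; "
                f"inducing reactions {c['inducing_parameters']['reactions']}, "
                f"conserved {c['inducing_parameters']['conserved']}; "
                f"bifurcating chemicals {c['bifurcating_chemicals']}")
        return "\n".join(lines) + "\n"


def six_step_report(net: ReactionNetwork,
                    C=None, D=None,
                    deletions: set[tuple[str, str]] | None = None,
                    max_structures: int = 512) -> BifurcationReport:
    """Run the full kinetics-free analysis.

    1. build A; 2. block-triangularize; 3. influence graph; 4. per-block
    symbolic determinants; 5. sign classes -> conditions + inducing
    parameters; 6. bifurcating chemicals per condition.
    """
    A = build_A(net, C=C, D=D)
    if deletions:
        A = apply_deletion(A, deletions)
    dec = block_triangularize(A)
    graph = influence_graph(dec)
    buff = buffering_structures(graph, dec, max_structures=max_structures)
    conditions = []
    for i, s in enumerate(dec.structures):
        if s.sign_class is SignClass.INDETERMINATE:
            conditions.append({
                "structure": s.label,
                "condition": str(s.determinant),
                "note": "determinant can change sign",
                "inducing_parameters": inducing_parameters(graph, i),
                "bifurcating_chemicals": sorted(bifurcating_chemicals(graph, i)),
            })
        elif s.sign_class is SignClass.IDENTICALLY_ZERO:
            conditions.append({
                "structure": s.label,
                "condition": "0",
                "note": "identically zero determinant: degenerate block",
                "inducing_parameters": inducing_parameters(graph, i),
                "bifurcating_chemicals": sorted(bifurcating_chemicals(graph, i)),
            })
    return BifurcationReport(net=net, A=A, decomposition=dec, graph=graph,
                             buffering=buff, conditions=conditions)


def _perm_sign(perm: list[int]) -> int:
    sign = 1
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, cycle = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            cycle += 1
        if cycle % 2 == 0:
            sign = -sign
    return sign
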