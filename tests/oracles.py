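"""Independent brute-force oracles used by the property tests.

These deliberately avoid the package's decomposition machinery: subnetwork
counts come from raw sympy ranks over bitmask-enumerated subsets.
"""

from __future__ import annotations

import sympy

from strucbif.network_core import ReactionNetwork, build_stoichiometric_matrix


def _nullity(mat: sympy.Matrix) -> int:
    return (mat.cols - mat.rank()) if mat.cols else 0


def bruteforce_buffering_structures(net: ReactionNetwork):
    """All output-complete, index-zero subnetworks by exhaustive enumeration.

    Index = #chemicals - #reactions + #loops - #conserved with
    loops = dim of kernel vectors supported on the subnetwork's reactions and
    conserved = number of independent cokernel directions touching the
    subnetwork's chemicals.
    """
    nu = build_stoichiometric_matrix(net).entries
    M, N = nu.shape
    Q = (M - sympy.Matrix(nu.tolist()).rank()) if nu.size else M
    out = set()
    for smask in range(2 ** M):
        chems = frozenset(net.species_ids[i] for i in range(M)
                          if smask >> i & 1)
        dep = {r.id for r in net.reactions
               if any(s in chems for s in r.dependent_species())}
        free = [r.id for r in net.reactions if r.id not in dep]
        comp = sorted(i for i in range(M) if net.species_ids[i] not in chems)
        outside = _nullity(sympy.Matrix(nu[comp, :].T.tolist())) if comp else 0
        conserved = Q - outside
        for emask in range(2 ** len(free)):
            rxns = frozenset(dep | {free[i] for i in range(len(free))
                                    if emask >> i & 1})
            if not chems and not rxns:
                continue
            ridx = sorted(net.reaction_index(r) for r in rxns)
            loops = _nullity(sympy.Matrix(nu[:, ridx].tolist())) if ridx else 0
            if len(chems) - len(rxns) + loops - conserved == 0:
                out.add((chems, rxns))
    return out


def numeric_determinant(matrix) -> float:
    """LU determinant of a numeric matrix; oracle for symbolic expansion."""
    import numpy as np
    return float(np.linalg.det(np.asarray(matrix, dtype=float)))
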