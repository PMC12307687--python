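"""The symbolic augmented matrix A and sign analysis of its determinants.

A is the square symbolic matrix

        [ dr/dx | C ]
        [ D^T   | 0 ]

with one row per reaction plus one per conserved quantity, and one column per
chemical plus one per loop.  Entries of dr/dx are abstract rate-derivative
symbols whose *signs* (but not magnitudes) are fixed by the network: positive
for reactants, the annotated sign for regulators, zero otherwise.  Everything
downstream -- determinants, their sign classes, block decompositions -- is a
function of this matrix and therefore of topology alone.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from strucbif.network_core import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    ReactionNetwork,
    build_stoichiometric_matrix,
)
from strucbif.linear_structure import (
    CokernelBasis,
    KernelBasis,
    minimal_support_cokernel_basis,
    minimal_support_kernel_basis,
    validate_cokernel_basis,
    validate_kernel_basis,
)


class SignClass(enum.Enum):
    ALWAYS_POSITIVE = "always_positive"
    ALWAYS_NEGATIVE = "always_negative"
    INDETERMINATE = "indeterminate"
    IDENTICALLY_ZERO = "identically_zero"


@dataclass(frozen=True)
class SignedRateSymbol:
    """One partial derivative d r_n / d x_m with its topology-fixed sign."""

    reaction_id: str
    species_id: str
    sign: str  # '+', '-' or '?'
    symbol: sp.Symbol

    @property
    def name(self) -> str:
        return self.symbol.name


@dataclass
class AugmentedMatrixA:
    """Symbolic (N+Q) x (M+P) matrix with its symbol table and provenance."""

    sym: sp.Matrix
    row_labels: list[str]          # reaction ids then conserved-quantity labels
    col_labels: list[str]          # species ids then loop labels
    net: ReactionNetwork
    C: KernelBasis
    D: CokernelBasis
    symbols: dict[tuple[str, str], SignedRateSymbol] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.sym.rows, self.sym.cols)

    @property
    def n_reaction_rows(self) -> int:
        return self.net.n_reactions

    @property
    def n_species_cols(self) -> int:
        return self.net.n_species

    def sign_table(self) -> dict[sp.Symbol, str]:
        return {s.symbol: s.sign for s in self.symbols.values()}

    def pattern(self) -> np.ndarray:
        """Boolean nonzero pattern, derivable from the network alone."""
        return np.array([[self.sym[i, j] != 0 for j in range(self.sym.cols)]
                         for i in range(self.sym.rows)], dtype=bool)

    def symbol(self, reaction_id: str, species_id: str) -> sp.Symbol:
        return self.symbols[(reaction_id, species_id)].symbol

    def instantiate(self, values: dict) -> np.ndarray:
        """Numeric matrix with rate-derivative symbols replaced by values.

        ``values`` maps (reaction_id, species_id) pairs -- or the symbols
        themselves -- to floats.  Every symbol must be covered.
        """
        subs: dict[sp.Symbol, float] = {}
        for key, val in values.items():
            symb = self.symbols[key].symbol if isinstance(key, tuple) else key
            subs[symb] = float(val)
        missing = [s.name for s in self.sym.free_symbols if s not in subs]
        if missing:
            raise ValueError(f"no value for symbols: {sorted(missing)}")
        out = np.zeros(self.shape, dtype=float)
        for i in range(self.sym.rows):
            for j in range(self.sym.cols):
                e = self.sym[i, j]
                out[i, j] = float(e.subs(subs)) if e.free_symbols else float(e)
        return out

    def render_text(self) -> str:
        """Aligned plain-text rendering for side-by-side pattern comparison."""
        cells = [["" ] + self.col_labels]
        for i, lab in enumerate(self.row_labels):
            cells.append([lab] + [str(self.sym[i, j]) if self.sym[i, j] != 0
                                  else "." for j in range((self.sym.cols))])
        widths = [max(len(row[j]) for row in cells) for j in range(len(cells[0]))]
        return "\n".join("  ".join(c.rjust(w) for c, w in zip(row, widths))
                         for row in cells) + "\n"

    def render_latex(self) -> str:
        return sp.latex(self.sym)


def _rate_symbol_name(reaction_id: str, species_id: str) -> str:
    # r_{n,m}; compact form mirrors the usual r_2B style when ids are R2, B
    rid = reaction_id[1:] if (reaction_id.startswith("R")
                              and reaction_id[1:].isdigit()) else reaction_id
    return f"r_{rid}{species_id}"


def build_A(net: ReactionNetwork, C: KernelBasis | None = None,
            D: CokernelBasis | None = None) -> AugmentedMatrixA:
    """Assemble A = [[dr/dx, C], [D^T, 0]] from the network topology.

    When bases are not supplied, support-minimal automatic bases are computed
    (they keep loop columns and conserved rows localized, which the finest
    block decomposition relies on).  Supplied bases are validated.
    """
    nu = build_stoichiometric_matrix(net)
    if C is None:
        C = minimal_support_kernel_basis(nu.entries)
    else:
        validate_kernel_basis(nu.entries, C)
    if D is None:
        D = minimal_support_cokernel_basis(nu.entries)
    else:
        validate_cokernel_basis(nu.entries, D)

    M, N = nu.shape
    P, Q = C.P, D.Q
    if N + Q != M + P:
        raise AssertionError("A is not square; bases are inconsistent with nu")

    mat = sp.zeros(N + Q, M + P)
    symbols: dict[tuple[str, str], SignedRateSymbol] = {}
    for i, rxn in enumerate(net.reactions):
        for sid in rxn.dependent_species():
            sign = rxn.rate_dependence_sign(sid)
            symb = sp.Symbol(_rate_symbol_name(rxn.id, sid), positive=None)
            symbols[(rxn.id, sid)] = SignedRateSymbol(rxn.id, sid, sign, symb)
            mat[i, net.species_index(sid)] = symb
        for p in range(P):
            mat[i, M + p] = int(C.C[i, p])
    for q in range(Q):
        for m in range(M):
            mat[N + q, m] = int(D.D[m, q])

    return AugmentedMatrixA(
        sym=mat,
        row_labels=list(net.reaction_ids) + list(D.labels),
        col_labels=list(net.species_ids) + list(C.labels),
        net=net, C=C, D=D, symbols=symbols,
    )


def apply_deletion(A: AugmentedMatrixA,
                   zeroed: set[tuple[str, str]]) -> AugmentedMatrixA:
    """Return a copy of A with the listed (reaction, species) entries zeroed.

    Models removal of regulations (e.g. knocking out a mediating gene).
    Zeroing an already-zero entry is a no-op; zeroing a reactant-derivative
    entry is allowed but warned about, as it is biologically unusual.
    """
    mat = A.sym.copy()
    symbols = dict(A.symbols)
    for rid, sid in zeroed:
        if rid not in A.net.reaction_ids:
            raise KeyError(f"unknown reaction id {rid!r}")
        if sid not in A.net.species_ids:
            raise KeyError(f"unknown species id {sid!r}")
        if (rid, sid) not in symbols:
            continue  # already structurally zero
        if sid in A.net.reaction(rid).reactants:
            warnings.warn(
                f"zeroing reactant-derivative entry ({rid}, {sid})",
                stacklevel=2,
            )
        i = A.net.reaction_index(rid)
        j = A.net.species_index(sid)
        mat[i, j] = 0
        del symbols[(rid, sid)]
    return replace(A, sym=mat, symbols=symbols)


def symbolic_determinant(block: sp.Matrix) -> sp.Expr:
    """Fully expanded determinant of a square symbolic block."""
    if block.rows != block.cols:
        raise ValueError("determinant of a non-square block")
    if block.rows == 0:
        return sp.Integer(1)
    return sp.expand(block.det(method="berkowitz"))


def classify_sign(poly: sp.Expr, signs: dict[sp.Symbol, str]) -> SignClass:
    """Monomial-sign test (sufficient condition only).

    ``always_positive`` iff every expanded monomial is positive given the
    symbol signs, and analogously for negative.  A single unknown-sign symbol
    at odd power, or monomials of mixed sign, yields ``indeterminate``:
    the determinant *can* change sign, which is all the procedure needs.
    """
    poly = sp.expand(poly)
    if poly == 0:
        return SignClass.IDENTICALLY_ZERO
    monomial_signs: set[int] = set()
    for term in poly.as_ordered_terms():
        coeff, factors = term.as_coeff_mul()
        sign = 1 if coeff > 0 else -1
        for f in factors:
            base, exp = f.as_base_exp()
            if not base.free_symbols:
                if base < 0 and int(exp) % 2:
                    sign = -sign
                continue
            s = signs.get(base, UNKNOWN)
            if int(exp) % 2 == 0:
                continue
            if s == POSITIVE:
                pass
            elif s == NEGATIVE:
                sign = -sign
            else:
                return SignClass.INDETERMINATE
        monomial_signs.add(sign)
        if len(monomial_signs) > 1:
            return SignClass.INDETERMINATE
    return (SignClass.ALWAYS_POSITIVE if monomial_signs == {1}
            else SignClass.ALWAYS_NEGATIVE)


@dataclass
class SensitivityResponse:
    """Linear steady-state response to a unit parameter perturbation."""

    source: str                      # row label of the perturbed reaction/eta
    col_labels: list[str]
    response: np.ndarray             # chemicals then loop-flux coefficients

    def chemical_response(self) -> dict[str, float]:
        n_chem = len(self.col_labels) - (len(self.response)
                                         - len(self.col_labels[:len(self.response)]))
        # col_labels = species then loops; chemical part is the species prefix
        return {lab: float(v) for lab, v in zip(self.col_labels, self.response)}


def sensitivity_solve(A: AugmentedMatrixA, source: str,
                      values: dict) -> SensitivityResponse:
    """Solve A . response = -e_source for a numeric instantiation of A.

    ``source`` is a reaction id or a conserved-quantity label (a row of A).
    Raises if A is singular at the given values (at a bifurcation point or
    structurally degenerate).
    """
    if source not in A.row_labels:
        raise KeyError(f"unknown source row {source!r}")
    num = A.instantiate(values)
    rhs = np.zeros(num.shape[0])
    rhs[A.row_labels.index(source)] = -1.0
    try:
        resp = np.linalg.solve(num, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "A is singular: at bifurcation or structurally degenerate"
        ) from exc
    return SensitivityResponse(source=source, col_labels=list(A.col_labels),
                               response=resp)
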