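"""Exact integer/rational linear algebra on the stoichiometric matrix.

Kernel (loop) and cokernel (conserved-moiety) bases, an image basis with its
pseudo-inverse, the square constant matrix Lambda = [[nu, D], [C^T, 0]], and
the change to/from reduced coordinates (xi, eta).

All bases are integer matrices with primitive columns (entry gcd 1, first
nonzero entry positive) so that printed determinant values are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from strucbif.network_core import StoichiometricMatrix

_EMPTY_INT = np.zeros((0, 0), dtype=np.int64)


def _as_int_array(nu) -> np.ndarray:
    if isinstance(nu, StoichiometricMatrix):
        return nu.entries
    arr = np.asarray(nu)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return arr.astype(np.int64)


def _primitive_int_columns(vectors: list[sp.Matrix]) -> np.ndarray:
    """Scale rational columns to primitive integer columns, sign-normalized."""
    cols = []
    for v in vectors:
        denoms = [sp.Rational(x).q for x in v]
        scaled = [int(sp.Rational(x) * math.lcm(*denoms)) for x in v]
        g = math.gcd(*scaled) if any(scaled) else 1
        scaled = [x // g for x in scaled] if g else scaled
        lead = next((x for x in scaled if x != 0), 1)
        if lead < 0:
            scaled = [-x for x in scaled]
        cols.append(scaled)
    if not cols:
        return _EMPTY_INT
    return np.array(cols, dtype=np.int64).T


@dataclass
class KernelBasis:
    """Integer basis C (N x P) of ker(nu); columns are steady-state flux loops."""

    C: np.ndarray
    provenance: str = "automatic"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        if not self.labels:
            self.labels = [f"c{p + 1}" for p in range(self.C.shape[1])]

    @property
    def P(self) -> int:
        return self.C.shape[1]


@dataclass
class CokernelBasis:
    """Integer basis D (M x Q) of ker(nu^T); eta := D^T x are conserved."""

    D: np.ndarray
    provenance: str = "automatic"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int64)
        if not self.labels:
            self.labels = [f"eta{q + 1}" for q in range(self.D.shape[1])]

    @property
    def Q(self) -> int:
        return self.D.shape[1]


@dataclass
class ImageBasis:
    """Integer V with <V> = im(nu), plus rational pseudo-inverses.

    V_pinv = (V^T V)^-1 V^T and D_pinv = (D^T D)^-1 D^T, kept exact (sympy
    Rational) with float views for numeric work.
    """

    V: np.ndarray
    V_pinv: sp.Matrix
    D_pinv: sp.Matrix

    @property
    def V_pinv_float(self) -> np.ndarray:
        return np.array(self.V_pinv, dtype=float)

    @property
    def D_pinv_float(self) -> np.ndarray:
        return np.array(self.D_pinv, dtype=float)


@dataclass
class LambdaMatrix:
    """The square integer block matrix [[nu, D], [C^T, 0]]."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int64)
        r, c = self.entries.shape
        if r != c:
            raise ValueError(f"Lambda must be square, got {r}x{c}; "
                             "check that C and D are valid bases")

    @property
    def det(self) -> int:
        return int(sp.Matrix(self.entries.tolist()).det(method="bareiss"))


def kernel_basis(nu) -> KernelBasis:
    """Primitive integer basis of ker(nu), by exact rational elimination."""
    arr = _as_int_array(nu)
    if arr.shape[1] == 0:
        return KernelBasis(np.zeros((0, 0), dtype=np.int64))
    vecs = sp.Matrix(arr.tolist()).nullspace()
    C = _primitive_int_columns(vecs)
    if C.size == 0:
        C = np.zeros((arr.shape[1], 0), dtype=np.int64)
    return KernelBasis(C)


def cokernel_basis(nu) -> CokernelBasis:
    """Primitive integer basis of ker(nu^T)."""
    arr = _as_int_array(nu)
    if arr.shape[0] == 0:
        return CokernelBasis(np.zeros((0, 0), dtype=np.int64))
    vecs = sp.Matrix(arr.T.tolist()).nullspace()
    D = _primitive_int_columns(vecs)
    if D.size == 0:
        D = np.zeros((arr.shape[0], 0), dtype=np.int64)
    return CokernelBasis(D)


def validate_kernel_basis(nu, basis: KernelBasis) -> None:
    arr = _as_int_array(nu)
    C = basis.C
    if C.shape[0] != arr.shape[1]:
        raise ValueError("kernel basis row count != number of reactions")
    if np.any(arr @ C):
        raise ValueError("kernel basis violates nu @ C = 0")
    if C.shape[1] != arr.shape[1] - _exact_rank(arr):
        raise ValueError("kernel basis has wrong dimension")
    if C.shape[1] and _exact_rank(C) != C.shape[1]:
        raise ValueError("kernel basis columns are dependent")


def validate_cokernel_basis(nu, basis: CokernelBasis) -> None:
    arr = _as_int_array(nu)
    D = basis.D
    if D.shape[0] != arr.shape[0]:
        raise ValueError("cokernel basis row count != number of species")
    if np.any(arr.T @ D):
        raise ValueError("cokernel basis violates nu^T @ D = 0")
    if D.shape[1] != arr.shape[0] - _exact_rank(arr):
        raise ValueError("cokernel basis has wrong dimension")
    if D.shape[1] and _exact_rank(D) != D.shape[1]:
        raise ValueError("cokernel basis columns are dependent")


def _exact_rank(arr: np.ndarray) -> int:
    if arr.size == 0:
        return 0
    return sp.Matrix(arr.tolist()).rank()


def image_basis(nu, D: CokernelBasis | None = None) -> ImageBasis:
    """V = pivot columns of nu under rational column reduction.

    Any V with the same column span gives the same det(J_g) (similarity), so
    the pivot-column choice is only a reproducibility convention.
    """
    arr = _as_int_array(nu)
    if D is None:
        D = cokernel_basis(arr)
    m = sp.Matrix(arr.tolist())
    pivots = m.rref()[1] if arr.size else ()
    V = arr[:, list(pivots)] if arr.size else np.zeros((arr.shape[0], 0),
                                                       dtype=np.int64)
    Vm = sp.Matrix(V.tolist()) if V.size else sp.zeros(arr.shape[0], 0)
    V_pinv = (Vm.T * Vm).inv() * Vm.T if V.shape[1] else sp.zeros(0, arr.shape[0])
    Dm = sp.Matrix(D.D.tolist()) if D.D.size else sp.zeros(arr.shape[0], 0)
    D_pinv = (Dm.T * Dm).inv() * Dm.T if D.Q else sp.zeros(0, arr.shape[0])
    return ImageBasis(V=V, V_pinv=V_pinv, D_pinv=D_pinv)


def build_lambda(nu, C: KernelBasis, D: CokernelBasis) -> LambdaMatrix:
    """Assemble Lambda = [[nu, D], [C^T, 0]]; square whenever C, D are bases."""
    arr = _as_int_array(nu)
    M, N = arr.shape
    if C.C.shape[0] != N:
        raise ValueError("kernel basis does not match nu's column count")
    if D.D.shape[0] != M:
        raise ValueError("cokernel basis does not match nu's row count")
    top = np.hstack([arr, D.D.reshape(M, -1)])
    bottom = np.hstack([C.C.T.reshape(-1, N),
                        np.zeros((C.P, D.Q), dtype=np.int64)])
    return LambdaMatrix(np.vstack([top, bottom]))


def reduce_coordinates(x: np.ndarray, image: ImageBasis,
                       D: CokernelBasis) -> tuple[np.ndarray, np.ndarray]:
    """Split a concentration vector into (xi, eta): xi = V^+ x, eta = D^T x."""
    x = np.asarray(x, dtype=float)
    xi = image.V_pinv_float @ x
    eta = D.D.T.astype(float) @ x
    return xi, eta


def lift_coordinates(xi: np.ndarray, eta: np.ndarray, image: ImageBasis,
                     D: CokernelBasis) -> np.ndarray:
    """x = V xi + (D^+)^T eta; exact inverse of :func:`reduce_coordinates`."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    x = image.V.astype(float) @ xi
    if D.Q:
        x = x + image.D_pinv_float.T @ eta
    return x


# ---------------------------------------------------------------------------
# Restricted null spaces and support-minimal bases
# ---------------------------------------------------------------------------

def restricted_kernel_dim(nu, columns: set[int] | list[int]) -> int:
    """dim { v in ker(nu) : supp(v) subset of ``columns`` } (exact)."""
    arr = _as_int_array(nu)
    cols = sorted(set(columns))
    if not cols:
        return 0
    sub = arr[:, cols]
    return len(cols) - _exact_rank(sub)


def restricted_cokernel_dim(nu, rows: set[int] | list[int]) -> int:
    """dim { w in ker(nu^T) : supp(w) subset of ``rows`` } (exact)."""
    arr = _as_int_array(nu)
    return restricted_kernel_dim(arr.T, rows)


def minimal_support_kernel_basis(nu, max_checks: int = 100_000) -> KernelBasis:
    """Greedy support-minimal kernel basis.

    Enumerates column subsets by increasing size and collects independent
    kernel vectors of smallest support first.  A support-sparse basis keeps
    the augmented matrix's loop columns localized, which is what the finest
    block-triangular decomposition needs.  Falls back to the elimination
    basis for dimensions the enumeration cannot reach within ``max_checks``.
    """
    arr = _as_int_array(nu)
    N = arr.shape[1]
    target = N - _exact_rank(arr)
    if target == 0:
        return KernelBasis(np.zeros((N, 0), dtype=np.int64))

    # columns that participate in at least one kernel vector
    full_dim = target
    cyclic = [j for j in range(N)
              if restricted_kernel_dim(arr, [k for k in range(N) if k != j])
              < full_dim]

    chosen: list[np.ndarray] = []
    checks = 0
    for size in range(1, len(cyclic) + 1):
        if len(chosen) >= target or checks > max_checks:
            break
        for combo in itertools.combinations(cyclic, size):
            checks += 1
            if checks > max_checks:
                break
            sub = arr[:, list(combo)]
            nullity = size - np.linalg.matrix_rank(sub.astype(float))
            if nullity <= 0:
                continue
            # how many chosen vectors already live inside this support?
            inside = [v for v in chosen if not np.any(np.delete(v, list(combo)))]
            if len(inside) >= nullity:
                continue
            for vec in sp.Matrix(sub.tolist()).nullspace():
                emb = sp.zeros(N, 1)
                for i, j in enumerate(combo):
                    emb[j] = vec[i]
                cand = _primitive_int_columns([emb])[:, 0]
                stack = np.array(chosen + [cand]).T if chosen else cand.reshape(-1, 1)
                if _exact_rank(stack) == (len(chosen) + 1):
                    chosen.append(cand)
                    if len(chosen) >= target:
                        break
            if len(chosen) >= target:
                break

    if len(chosen) < target:
        for vec in sp.Matrix(arr.tolist()).nullspace():
            cand = _primitive_int_columns([vec])[:, 0]
            stack = np.array(chosen + [cand]).T if chosen else cand.reshape(-1, 1)
            if _exact_rank(stack) == len(chosen) + 1:
                chosen.append(cand)
            if len(chosen) >= target:
                break
    C = np.array(chosen, dtype=np.int64).T
    return KernelBasis(C, provenance="automatic")


def kernel_circuits(nu, max_checks: int = 100_000,
                    max_circuits: int = 256) -> list[np.ndarray]:
    """All support-minimal kernel vectors (circuits), primitive and normalized.

    Enumerates column subsets by increasing size; a circuit is a dependent
    set all of whose proper subsets are independent (nullity exactly one on
    its own support).  Capped for safety; networks of interest are small.
    """
    arr = _as_int_array(nu)
    N = arr.shape[1]
    total = N - _exact_rank(arr)
    if total == 0:
        return []
    full_dim = total
    cyclic = [j for j in range(N)
              if restricted_kernel_dim(arr, [k for k in range(N) if k != j])
              < full_dim]
    circuits: list[np.ndarray] = []
    seen_supports: list[frozenset[int]] = []
    checks = 0
    for size in range(1, len(cyclic) + 1):
        for combo in itertools.combinations(cyclic, size):
            checks += 1
            if checks > max_checks or len(circuits) >= max_circuits:
                return circuits
            cs = frozenset(combo)
            if any(s <= cs for s in seen_supports):
                continue
            sub = arr[:, list(combo)]
            nullity = size - np.linalg.matrix_rank(sub.astype(float))
            if nullity <= 0:
                continue
            vec = sp.Matrix(sub.tolist()).nullspace()[0]
            if any(v == 0 for v in vec):
                continue  # support not minimal: a smaller circuit is inside
            emb = sp.zeros(N, 1)
            for i, j in enumerate(combo):
                emb[j] = vec[i]
            circuits.append(_primitive_int_columns([emb])[:, 0])
            seen_supports.append(cs)
    return circuits


def basis_containing(nu, vectors,
                     max_checks: int = 100_000) -> KernelBasis:
    """A support-sparse kernel basis whose first columns are ``vectors``."""
    arr = _as_int_array(nu)
    if isinstance(vectors, np.ndarray) and vectors.ndim == 1:
        vectors = [vectors]
    chosen = [np.asarray(v, dtype=np.int64) for v in vectors]
    for v in chosen:
        if np.any(arr @ v):
            raise ValueError("vector is not in the kernel")
    if len(chosen) > 1 and _exact_rank(np.array(chosen).T) != len(chosen):
        raise ValueError("seed vectors are dependent")
    for cand in kernel_circuits(arr, max_checks=max_checks):
        stack = np.array(chosen + [cand]).T
        if _exact_rank(stack) == len(chosen) + 1:
            chosen.append(cand)
    target = arr.shape[1] - _exact_rank(arr)
    if len(chosen) < target:
        for vec in sp.Matrix(arr.tolist()).nullspace():
            cand = _primitive_int_columns([vec])[:, 0]
            stack = np.array(chosen + [cand]).T
            if _exact_rank(stack) == len(chosen) + 1:
                chosen.append(cand)
            if len(chosen) >= target:
                break
    return KernelBasis(np.array(chosen, dtype=np.int64).T)


def minimal_support_cokernel_basis(nu, max_checks: int = 100_000) -> CokernelBasis:
    """Greedy support-minimal cokernel basis (see kernel counterpart)."""
    arr = _as_int_array(nu)
    kb = minimal_support_kernel_basis(arr.T, max_checks=max_checks)
    return CokernelBasis(kb.C, provenance="automatic")


def matrix_to_tsv(entries: np.ndarray, row_labels: list[str],
                  col_labels: list[str]) -> str:
    """Labeled TSV export used by the CLI for any of the structural matrices."""
    lines = ["\t".join(["", *col_labels])]
    for lab, row in zip(row_labels, np.asarray(entries)):
        lines.append("\t".join([lab, *[str(x) for x in row.tolist()]]))
    return "\n".join(lines) + "\n"
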