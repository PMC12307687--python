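"""Numeric instantiation: rate laws, Jacobians, and the determinant identity.

A :class:`KineticModel` attaches a differentiable rate law to every reaction
of a network.  From it we evaluate the standard Jacobian J_f = nu . dr/dx,
the modified Jacobian J_g = V^+ J_f V in reduced coordinates (free of the
zero eigenvalues forced by conserved quantities), the numeric augmented
matrix, the identity

    det A = det(D^T D) det(C^T C) / det(Lambda) . det(J_g),

and the sign-based instability criterion
sign(det Lambda . det A) != (-1)^(M-L)  =>  not a stable equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy as sp

from strucbif.network_core import (
    NEGATIVE,
    POSITIVE,
    ReactionNetwork,
    build_stoichiometric_matrix,
)
from strucbif.linear_structure import (
    CokernelBasis,
    ImageBasis,
    KernelBasis,
    build_lambda,
    cokernel_basis,
    image_basis,
    kernel_basis,
)
from strucbif.symbolic_amatrix import AugmentedMatrixA, build_A


class RateLawError(ValueError):
    """Bad rate-law specification."""


def _law_expression(rxn, law: dict, x: dict[str, sp.Symbol],
                    p: dict[str, sp.Symbol]) -> sp.Expr:
    """Symbolic rate for one reaction.

    Law kinds:

    * ``constant``: r = k  (zero-order inflow)
    * ``mass_action``: r = k * prod(x_reactant ** coeff)
    * ``sigmoid_activation``: r = k * prod(x_reactant ** coeff)
      / (1 + sum((x_i / K_i) ** h_i)) over the declared inhibitors
    * ``expression``: arbitrary sympy expression in species ids and
      parameter names (the escape hatch for bespoke models)
    """
    kind = law.get("law")
    if kind == "constant":
        return p["k"]
    if kind == "mass_action":
        expr = p["k"]
        for sid, coeff in rxn.reactants.items():
            expr = expr * x[sid] ** coeff
        return expr
    if kind == "sigmoid_activation":
        expr = p["k"]
        for sid, coeff in rxn.reactants.items():
            expr = expr * x[sid] ** coeff
        inhibition = sp.Integer(0)
        for sid, spec in law.get("inhibitors", {}).items():
            inhibition += (x[sid] / p[f"K_{sid}"]) ** p[f"h_{sid}"]
        return expr / (1 + inhibition)
    if kind == "expression":
        local = dict(x)
        local.update(p)
        expr = sp.sympify(law["expr"], locals=local)
        extra = expr.free_symbols - set(local.values())
        if extra:
            raise RateLawError(f"reaction {rxn.id!r}: unknown symbols {extra}")
        return expr
    raise RateLawError(f"reaction {rxn.id!r}: unknown law kind {kind!r}")


def _law_parameters(law: dict) -> dict[str, float]:
    kind = law.get("law")
    if kind in ("constant", "mass_action"):
        return {"k": float(law["k"])}
    if kind == "sigmoid_activation":
        params = {"k": float(law["k"])}
        for sid, spec in law.get("inhibitors", {}).items():
            params[f"K_{sid}"] = float(spec["K"])
            params[f"h_{sid}"] = float(spec.get("h", 2))
        return params
    if kind == "expression":
        return {k: float(v) for k, v in law.get("params", {}).items()}
    raise RateLawError(f"unknown law kind {kind!r}")


@dataclass
class KineticModel:
    """A network plus one rate law per reaction.

    ``laws`` maps reaction id -> law spec (see :func:`_law_expression`).
    ``C``/``D`` optionally pin the loop/conserved bases (and hence the meaning
    and order of the eta components); automatic bases are used otherwise.
    ``domain`` is the concentration box on which rate-derivative signs are
    validated against the network annotation.
    """

    net: ReactionNetwork
    laws: dict[str, dict]
    C: KernelBasis | None = None
    D: CokernelBasis | None = None
    domain: tuple[float, float] = (1e-3, 10.0)
    validate: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [r.id for r in self.net.reactions if r.id not in self.laws]
        if missing:
            raise RateLawError(f"no rate law for reactions {missing}")
        nu = build_stoichiometric_matrix(self.net)
        self.nu = nu.entries
        if self.C is None:
            self.C = kernel_basis(self.nu)
        if self.D is None:
            self.D = cokernel_basis(self.nu)
        self.image: ImageBasis = image_basis(self.nu, self.D)
        self.Lambda = build_lambda(self.nu, self.C, self.D)
        self._build()
        if self.validate:
            self.validate_signs()

    # -- construction -----------------------------------------------------
    def _build(self) -> None:
        xs = {s.id: sp.Symbol(f"x_{s.id}", positive=True)
              for s in self.net.species}
        self._x_syms = [xs[s.id] for s in self.net.species]
        self._param_names: list[tuple[str, str]] = []
        self._param_values: list[float] = []
        p_syms_flat: list[sp.Symbol] = []
        exprs = []
        for rxn in self.net.reactions:
            law = self.laws[rxn.id]
            values = _law_parameters(law)
            psyms = {}
            for name, val in values.items():
                symb = sp.Symbol(f"p_{rxn.id}_{name}", positive=True)
                psyms[name] = symb
                p_syms_flat.append(symb)
                self._param_names.append((rxn.id, name))
                self._param_values.append(val)
            exprs.append(_law_expression(rxn, law, xs, psyms))
        r_vec = sp.Matrix(exprs)
        jac = r_vec.jacobian(self._x_syms) if exprs else sp.zeros(0, len(xs))
        args = (self._x_syms, p_syms_flat)
        self._r_fn = sp.lambdify(args, r_vec, "numpy")
        self._drdx_fn = sp.lambdify(args, jac, "numpy")
        self._r_exprs = exprs

    # -- parameters -------------------------------------------------------
    def param(self, reaction_id: str, name: str) -> float:
        return self._param_values[self._param_names.index((reaction_id, name))]

    def set_param(self, reaction_id: str, name: str, value: float) -> None:
        self._param_values[self._param_names.index((reaction_id, name))] = float(value)

    @property
    def parameters(self) -> dict[tuple[str, str], float]:
        return dict(zip(self._param_names, self._param_values))

    # -- evaluation -------------------------------------------------------
    def rates(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(self._r_fn(np.asarray(x, dtype=float),
                                    self._param_values), dtype=float)
        return out.reshape(-1)

    def drdx(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(self._drdx_fn(np.asarray(x, dtype=float),
                                       self._param_values), dtype=float)
        return out.reshape(self.net.n_reactions, self.net.n_species)

    def f(self, x: np.ndarray) -> np.ndarray:
        """Right-hand side dx/dt = nu . r(x)."""
        return self.nu @ self.rates(x)

    def equilibrium_residual(self, x: np.ndarray) -> float:
        r = self.rates(x)
        return float(np.max(np.abs(self.nu @ r)))

    def is_equilibrium(self, x: np.ndarray, rtol: float = 1e-9) -> bool:
        r = self.rates(x)
        return np.max(np.abs(self.nu @ r)) < rtol * (1 + np.max(np.abs(r)))

    def validate_signs(self, n_samples: int = 32, seed: int = 0) -> list[str]:
        """Check dr/dx signs against the network annotation on sample states.

        Mismatches are reported (and warned about), not fatal: expression laws
        may be monotone only on the domain of interest.
        """
        rng = np.random.default_rng(seed)
        lo, hi = self.domain
        issues: list[str] = []
        for _ in range(n_samples):
            x = rng.uniform(lo, hi, size=self.net.n_species)
            J = self.drdx(x)
            for i, rxn in enumerate(self.net.reactions):
                for j, sp_ in enumerate(self.net.species):
                    sign = rxn.rate_dependence_sign(sp_.id)
                    v = J[i, j]
                    if sign is None and abs(v) > 1e-12:
                        issues.append(f"({rxn.id},{sp_.id}): nonzero but "
                                      "undeclared")
                    elif sign == POSITIVE and v < -1e-12:
                        issues.append(f"({rxn.id},{sp_.id}): negative, "
                                      "declared positive")
                    elif sign == NEGATIVE and v > 1e-12:
                        issues.append(f"({rxn.id},{sp_.id}): positive, "
                                      "declared negative")
        issues = sorted(set(issues))
        if issues:
            warnings.warn("rate-law sign mismatches: " + "; ".join(issues),
                          stacklevel=2)
        return issues


@dataclass
class JacobianPair:
    J_f: np.ndarray
    J_g: np.ndarray
    x: np.ndarray

    @property
    def det_J_f(self) -> float:
        return float(np.linalg.det(self.J_f))

    @property
    def det_J_g(self) -> float:
        if self.J_g.size == 0:
            return 1.0
        return float(np.linalg.det(self.J_g))


def evaluate_jacobians(model: KineticModel, x: np.ndarray) -> JacobianPair:
    """J_f = nu . dr/dx and J_g = V^+ J_f V at the state ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    J_f = model.nu @ model.drdx(x)
    Vp = model.image.V_pinv_float
    V = model.image.V.astype(float)
    J_g = Vp @ J_f @ V
    return JacobianPair(J_f=J_f, J_g=J_g, x=x)


def instantiate_A(model: KineticModel, x: np.ndarray,
                  A: AugmentedMatrixA | None = None) -> np.ndarray:
    """Numeric A at state ``x``: dr/dx entries from the model's derivatives."""
    if A is None:
        A = build_A(model.net, C=model.C, D=model.D)
    J = model.drdx(np.asarray(x, dtype=float))
    values = {}
    for (rid, sid), srs in A.symbols.items():
        values[srs.symbol] = J[model.net.reaction_index(rid),
                               model.net.species_index(sid)]
    return A.instantiate(values)


def theorem1_prefactor(model: KineticModel) -> Fraction:
    """det(D^T D) . det(C^T C) / det(Lambda), exactly."""
    C, D = model.C.C, model.D.D
    det_ctc = int(sp.Matrix((C.T @ C).tolist()).det()) if C.shape[1] else 1
    det_dtd = int(sp.Matrix((D.T @ D).tolist()).det()) if D.shape[1] else 1
    det_l = model.Lambda.det
    if det_l == 0:
        raise ZeroDivisionError("det Lambda = 0: C or D is not a basis")
    return Fraction(det_dtd * det_ctc, det_l)


def theorem1_residual(model: KineticModel, x: np.ndarray,
                      A: AugmentedMatrixA | None = None) -> float:
    """| det A - prefactor . det J_g | / max(1, |det A|) at ``x``."""
    num_A = instantiate_A(model, x, A=A)
    det_A = float(np.linalg.det(num_A))
    pair = evaluate_jacobians(model, x)
    lhs_rhs_gap = det_A - float(theorem1_prefactor(model)) * pair.det_J_g
    return abs(lhs_rhs_gap) / max(1.0, abs(det_A))


@dataclass
class StabilityVerdict:
    x: np.ndarray
    det_A: float
    det_Lambda: int
    M: int
    L: int
    verdict: str                   # 'not_stable' | 'possibly_stable'
    eigenvalues: np.ndarray        # of J_g

    @property
    def not_stable(self) -> bool:
        return self.verdict == "not_stable"


def stability_check(model: KineticModel, x: np.ndarray,
                    rtol: float = 1e-9,
                    A: AugmentedMatrixA | None = None) -> StabilityVerdict:
    """One-sided instability criterion from the sign of det Lambda . det A.

    Requires ``x`` to be an equilibrium.  The criterion only ever certifies
    instability; 'possibly_stable' is not a stability proof.
    """
    if not model.is_equilibrium(x, rtol=rtol):
        raise ValueError(
            f"x is not an equilibrium: residual {model.equilibrium_residual(x):.3e}")
    det_A = float(np.linalg.det(instantiate_A(model, x, A=A)))
    det_l = model.Lambda.det
    M = model.net.n_species
    L = model.D.Q
    expected = (-1) ** (M - L)
    s = np.sign(det_l * det_A)
    verdict = "not_stable" if s != expected else "possibly_stable"
    eig = np.linalg.eigvals(evaluate_jacobians(model, x).J_g)
    return StabilityVerdict(x=np.asarray(x, float), det_A=det_A,
                            det_Lambda=det_l, M=M, L=L, verdict=verdict,
                            eigenvalues=eig)
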