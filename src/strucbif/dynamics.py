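"""Equilibrium finding, parameter sweeps, branch tracking, and diagrams.

Equilibria are found in reduced coordinates xi (so conserved values eta are
held exactly), from multiple seeded random starts.  Sweeps walk a parameter
grid, connect equilibria across grid steps by nearest-neighbour continuation,
and bisect the parameter values where branches appear or disappear.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from strucbif.jacobian_bridge import KineticModel, evaluate_jacobians


@dataclass
class EquilibriumPoint:
    x: np.ndarray                # concentrations
    eta: np.ndarray              # conserved values D^T x
    mu: np.ndarray               # loop coefficients: r(x) = C mu
    stable: bool                 # leading Re(eig J_g) < 0
    eigenvalues: np.ndarray
    residual: float

    @property
    def leading_eig(self) -> float:
        if self.eigenvalues.size == 0:
            return -np.inf
        return float(np.max(self.eigenvalues.real))


def _make_point(model: KineticModel, x: np.ndarray,
                eig_tol: float = 1e-9) -> EquilibriumPoint:
    r = model.rates(x)
    C = model.C.C.astype(float)
    if C.shape[1]:
        mu, *_ = np.linalg.lstsq(C, r, rcond=None)
    else:
        mu = np.zeros(0)
    eig = np.linalg.eigvals(evaluate_jacobians(model, x).J_g)
    stable = bool(eig.size == 0 or np.max(eig.real) < -eig_tol)
    return EquilibriumPoint(
        x=np.asarray(x, float),
        eta=model.D.D.T.astype(float) @ x,
        mu=np.asarray(mu, float),
        stable=stable,
        eigenvalues=eig,
        residual=model.equilibrium_residual(x),
    )


def find_equilibria(model: KineticModel, eta: np.ndarray | list[float],
                    n_starts: int = 30, seed: int = 0,
                    rtol: float = 1e-9,
                    dedup_tol: float = 1e-5) -> list[EquilibriumPoint]:
    """Roots of the reduced equation at fixed conserved values ``eta``.

    Random positive starts are drawn inside the model's domain box; converged
    roots are kept when all concentrations are (numerically) nonnegative and
    the full equilibrium residual passes; duplicates are merged.  Results are
    deterministic for a fixed seed and sorted for reproducibility.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if eta.shape[0] != model.D.Q:
        raise ValueError(f"eta must have {model.D.Q} components")
    rng = np.random.default_rng(seed)
    lo, hi = model.domain
    V = model.image.V.astype(float)
    Vp = model.image.V_pinv_float
    offset = (model.image.D_pinv_float.T @ eta) if model.D.Q else \
        np.zeros(model.net.n_species)

    def g(xi: np.ndarray) -> np.ndarray:
        x = V @ xi + offset
        return Vp @ (model.nu @ model.rates(x))

    solutions: list[np.ndarray] = []
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi, size=model.net.n_species)
        xi0 = Vp @ x0
        try:
            sol = root(g, xi0, method="hybr", tol=1e-12)
        except (ValueError, FloatingPointError):
            continue
        if not sol.success:
            continue
        x = V @ sol.x + offset
        if np.any(x < -1e-8) or not np.all(np.isfinite(x)):
            continue
        x = np.clip(x, 0.0, None)
        r = model.rates(x)
        if not np.all(np.isfinite(r)):
            continue
        if np.max(np.abs(model.nu @ r)) >= rtol * (1 + np.max(np.abs(r))) * 1e3:
            continue
        scale = 1.0 + float(np.max(np.abs(x)))
        if any(np.max(np.abs(x - s)) < dedup_tol * scale for s in solutions):
            continue
        solutions.append(x)
    solutions.sort(key=lambda v: tuple(np.round(v, 8)))
    return [_make_point(model, x) for x in solutions]


def perturbation_stability(model: KineticModel, point: EquilibriumPoint,
                           eps: float = 1e-2, n_trials: int = 5,
                           seed: int = 0, t_max: float = 500.0,
                           recover_factor: float = 0.2) -> bool:
    """Integrate small conserved-quantity-preserving perturbations.

    Perturbations are sampled in im(nu) so eta is untouched; the point is
    stable iff every successful trial returns to within
    ``recover_factor * |delta x|`` of the equilibrium.
    """
    rng = np.random.default_rng(seed)
    x0 = point.x
    scale = eps * (1.0 + float(np.max(np.abs(x0))))
    verdicts: list[bool] = []
    for _ in range(n_trials):
        direction = model.nu @ rng.standard_normal(model.net.n_reactions)
        norm = np.linalg.norm(direction)
        if norm < 1e-14:
            continue
        dx = direction / norm * scale
        start = np.clip(x0 + dx, 1e-12, None)
        try:
            sol = solve_ivp(lambda t, y: model.f(y), (0.0, t_max), start,
                            method="LSODA", rtol=1e-9, atol=1e-11)
        except Exception:  # noqa: BLE001 - integrator failures are flagged
            sol = None
        if sol is None or not sol.success:
            warnings.warn("perturbation trial failed to integrate; excluded",
                          stacklevel=2)
            continue
        final = sol.y[:, -1]
        verdicts.append(bool(np.linalg.norm(final - x0)
                             < recover_factor * np.linalg.norm(dx)))
    if not verdicts:
        raise RuntimeError("all perturbation trials failed")
    return all(verdicts)


@dataclass
class Branch:
    id: int
    params: list[float] = field(default_factory=list)
    points: list[EquilibriumPoint] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        return all(p.stable for p in self.points)


@dataclass
class BifurcationDiagram:
    parameter: str
    grid: np.ndarray
    branches: list[Branch]
    thresholds: list[dict]
    seed: int

    def coexisting(self, value: float, atol: float = 1e-9) -> list[EquilibriumPoint]:
        pts = []
        for br in self.branches:
            for pv, pt in zip(br.params, br.points):
                if abs(pv - value) <= atol:
                    pts.append(pt)
        return pts

    def to_csv(self, species_ids: list[str]) -> str:
        header = ["parameter", "branch", "stable", *species_ids]
        lines = [",".join(header)]
        for br in self.branches:
            for pv, pt in zip(br.params, br.points):
                row = [f"{pv:.12g}", str(br.id), str(int(pt.stable)),
                       *[f"{v:.12g}" for v in pt.x]]
                lines.append(",".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self, species_ids: list[str]) -> str:
        return json.dumps({
            "parameter": self.parameter,
            "seed": self.seed,
            "grid": [float(v) for v in self.grid],
            "thresholds": self.thresholds,
            "branches": [
                {"id": br.id, "stable": br.stable,
                 "points": [{"parameter": float(pv),
                             "stable": pt.stable,
                             "x": {s: float(v) for s, v in zip(species_ids, pt.x)}}
                            for pv, pt in zip(br.params, br.points)]}
                for br in self.branches
            ],
        }, indent=2) + "\n"


def plot_diagram(diagram: BifurcationDiagram, species_ids: list[str],
                 path: str, species: list[str] | None = None) -> None:
    """Render one panel per chemical: branches solid (stable)/dotted, with
    vertical dashed lines at detected thresholds.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    species = species or species_ids
    cols = min(4, len(species))
    rows = -(-len(species) // cols)
    fig, axes = plt.subplots(rows, cols, figsize=(3 * cols, 2.2 * rows),
                             squeeze=False, sharex=True)
    for k, sid in enumerate(species):
        ax = axes[k // cols][k % cols]
        idx = species_ids.index(sid)
        for br in diagram.branches:
            style = "-" if br.stable else ":"
            ax.plot(br.params, [p.x[idx] for p in br.points], style,
                    marker=".", ms=3, lw=1)
        for t in diagram.thresholds:
            ax.axvline(t["parameter_value"], ls="--", lw=0.8, color="gray")
        ax.set_title(sid, fontsize=9)
    for k in range(len(species), rows * cols):
        axes[k // cols][k % cols].axis("off")
    fig.supxlabel(diagram.parameter)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _set_sweep_value(model: KineticModel, parameter: str,
                     eta: np.ndarray, value: float) -> np.ndarray:
    """Apply a sweep value: 'eta:<label>' tweaks eta, 'RID:name' a rate param."""
    kind, _, name = parameter.partition(":")
    if kind == "eta":
        eta = eta.copy()
        eta[model.D.labels.index(name)] = value
        return eta
    model.set_param(kind, name, value)
    return eta


def sweep_diagram(model: KineticModel, parameter: str,
                  sweep_range: tuple[float, float],
                  eta: np.ndarray | list[float] | None = None,
                  grid_size: int = 50, n_starts: int = 30, seed: int = 0,
                  threshold_precision: float = 1e-3) -> BifurcationDiagram:
    """Grid-plus-multistart continuation over one parameter.

    ``parameter`` is ``"eta:<label>"`` for a conserved value or
    ``"<reaction id>:<param name>"`` for a rate parameter.  Branches are
    matched across grid steps by nearest x-distance under a jump tolerance;
    branch births/deaths are bisected down to ``threshold_precision``.
    """
    eta = np.atleast_1d(np.asarray(eta if eta is not None else
                                   np.zeros(model.D.Q), dtype=float))
    lo, hi = sweep_range
    if hi < lo:
        lo, hi = hi, lo
    grid = np.linspace(lo, hi, max(1, grid_size))

    def equilibria_at(value: float, extra_starts: list[np.ndarray] = ()):
        eta_here = _set_sweep_value(model, parameter, eta, value)
        pts = find_equilibria(model, eta_here, n_starts=n_starts, seed=seed)
        # polish continuation guesses from neighbouring grid points too
        for guess in extra_starts:
            pts_g = _polish(model, parameter, eta_here, guess)
            for p in pts_g:
                scale = 1.0 + float(np.max(np.abs(p.x)))
                if not any(np.max(np.abs(p.x - q.x)) < 1e-5 * scale
                           for q in pts):
                    pts.append(p)
        return pts

    per_grid: list[list[EquilibriumPoint]] = []
    for i, value in enumerate(grid):
        extra = [p.x for p in per_grid[-1]] if per_grid else []
        per_grid.append(equilibria_at(float(value), extra))

    branches, thresholds = _assemble_branches(model, parameter, eta, grid,
                                              per_grid, n_starts, seed,
                                              threshold_precision)
    return BifurcationDiagram(parameter=parameter, grid=grid,
                              branches=branches, thresholds=thresholds,
                              seed=seed)


def _polish(model, parameter, eta_here, guess):
    V = model.image.V.astype(float)
    Vp = model.image.V_pinv_float
    offset = (model.image.D_pinv_float.T @ eta_here) if model.D.Q else 0.0
    try:
        sol = root(lambda xi: Vp @ (model.nu @ model.rates(V @ xi + offset)),
                   Vp @ guess, method="hybr", tol=1e-12)
    except (ValueError, FloatingPointError):
        return []
    if not sol.success:
        return []
    x = V @ sol.x + offset
    if np.any(x < -1e-8) or not np.all(np.isfinite(x)):
        return []
    x = np.clip(x, 0.0, None)
    r = model.rates(x)
    if np.max(np.abs(model.nu @ r)) >= 1e-6 * (1 + np.max(np.abs(r))):
        return []
    return [_make_point(model, x)]


def _assemble_branches(model, parameter, eta, grid, per_grid, n_starts, seed,
                       precision):
    branches: list[Branch] = []
    open_branches: dict[int, np.ndarray] = {}
    thresholds: list[dict] = []
    next_id = 0

    def jump_tol(pts: list[EquilibriumPoint]) -> float:
        if len(pts) < 2:
            return np.inf
        d = [np.linalg.norm(a.x - b.x) for i, a in enumerate(pts)
             for b in pts[i + 1:]]
        return max(0.5 * float(np.median(d)), 1e-6)

    for gi, (value, pts) in enumerate(zip(grid, per_grid)):
        tol = jump_tol(pts)
        assigned: dict[int, int] = {}
        # greedy nearest matching of open branches to new points
        pairs = sorted(
            ((float(np.linalg.norm(open_branches[bid] - p.x)), bid, pi)
             for bid in open_branches for pi, p in enumerate(pts)),
            key=lambda t: t[0])
        used_b, used_p = set(), set()
        for dist, bid, pi in pairs:
            if bid in used_b or pi in used_p or dist > tol:
                continue
            used_b.add(bid)
            used_p.add(pi)
            assigned[pi] = bid
        # closed branches: died between grid[gi-1] and grid[gi]
        for bid in list(open_branches):
            if bid not in used_b:
                thr = _bisect_threshold(model, parameter, eta, grid[gi - 1],
                                        value, branches[bid], precision)
                thresholds.append({"branch": bid, "kind": "disappears",
                                   "parameter_value": thr})
                del open_branches[bid]
        for pi, p in enumerate(pts):
            if pi in assigned:
                bid = assigned[pi]
            else:
                bid = next_id
                next_id += 1
                branches.append(Branch(id=bid))
                if gi > 0:
                    thresholds.append({"branch": bid, "kind": "appears",
                                       "parameter_value": _bisect_threshold(
                                           model, parameter, eta, value,
                                           grid[gi - 1], None, precision,
                                           seed_point=p.x)})
            branches[bid].params.append(float(value))
            branches[bid].points.append(p)
            open_branches[bid] = p.x
    return branches, thresholds


def _bisect_threshold(model, parameter, eta, v_alive, v_dead, branch,
                      precision, seed_point=None):
    """Bisect the parameter value where a branch stops existing.

    ``v_alive`` has the branch, ``v_dead`` does not; existence is probed by
    polishing the last known branch point at the midpoint.
    """
    x_ref = seed_point if seed_point is not None else branch.points[-1].x
    a, b = float(v_alive), float(v_dead)
    guard = 0
    while abs(b - a) > precision and guard < 60:
        mid = 0.5 * (a + b)
        eta_mid = _set_sweep_value(model, parameter, np.asarray(eta, float),
                                   mid)
        pts = _polish(model, parameter, eta_mid, x_ref)
        scale = 1.0 + float(np.max(np.abs(x_ref)))
        alive = bool(pts) and np.max(np.abs(pts[0].x - x_ref)) < 0.5 * scale
        if alive:
            a = mid
            x_ref = pts[0].x
        else:
            b = mid
        guard += 1
    return 0.5 * (a + b)


def predicted_vs_observed(diagram: BifurcationDiagram, report,
                          tolerance: float = 1e-3) -> dict:
    """Check that only predicted chemicals vary across coexisting branches.

    Returns a verdict with per-chemical evidence: the largest spread of each
    chemical's equilibrium value over branch points at a common parameter
    value, and whether the varying set is contained in the predicted
    bifurcating set.
    """
    species = report.net.species_ids
    predicted: set[str] = set()
    for cond in report.conditions:
        predicted.update(cond["bifurcating_chemicals"])
    if not report.conditions:
        predicted = set()

    spread = {s: 0.0 for s in species}
    for value in diagram.grid:
        pts = diagram.coexisting(float(value))
        if len(pts) < 2:
            continue
        xs = np.array([p.x for p in pts])
        rng_ = xs.max(axis=0) - xs.min(axis=0)
        for s, d in zip(species, rng_):
            spread[s] = max(spread[s], float(d))
    scale = 1.0 + max(spread.values(), default=0.0)
    varying = {s for s, d in spread.items() if d > tolerance * scale}
    return {
        "varying": sorted(varying),
        "predicted": sorted(predicted),
        "consistent": varying.issubset(predicted),
        "spread": spread,
    }
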