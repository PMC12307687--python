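"""Bundled example networks, kinetic presets, and a random-network generator.

Catalog entries:

* ``example1`` -- two species A, B; inflow, a B-activated conversion A -> B,
  back-conversion, and outflow.  No conserved quantities; {B, R2, R3} is a
  buffering structure.  Three kinetic presets exhibit pitchfork,
  transcritical and saddle-node diagrams while only B ever bifurcates.
* ``conserved_example`` -- five species A..E, six reactions, one conserved
  quantity (x_D - x_E) and two flux loops; decomposes into four blocks.
* ``macrophage_wt`` -- the eight-species phosphorylation-cycle signalling
  network (STAT1, STAT3, STAT6, NFkB and their active forms) with nine
  negative regulations and four conserved totals.
* ``macrophage_socs3d`` / ``macrophage_socs3d_klf4d`` -- the same network
  with the SOCS3-mediated (and additionally the KLF4-mediated) regulations
  removed; identical to wild type otherwise.

The macrophage kinetic preset is a qualitative reconstruction: mass-action
deactivation, sigmoid activation with inhibitors, parameters calibrated so
the wild-type diagram is bistable over part of eta1 in [6, 8.5] with the
M1-like branch terminating at low eta1.  It is not fitted to any published
parameter set; supplying exact parameters via config reproduces exact
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from strucbif.network_core import (
    Reaction,
    ReactionNetwork,
    Species,
    build_stoichiometric_matrix,
)
from strucbif.linear_structure import CokernelBasis, KernelBasis
from strucbif.jacobian_bridge import KineticModel


@dataclass
class Fixture:
    name: str
    network: ReactionNetwork
    C: KernelBasis | None = None
    D: CokernelBasis | None = None
    presets: dict[str, dict] = field(default_factory=dict)

    def model(self, preset: str, **overrides) -> KineticModel:
        spec = self.presets[preset]
        kwargs = dict(net=self.network, laws=spec["laws"], C=self.C, D=self.D,
                      domain=spec.get("domain", (1e-3, 10.0)))
        kwargs.update(overrides)
        return KineticModel(**kwargs)

    def default_eta(self, preset: str) -> np.ndarray:
        return np.asarray(self.presets[preset].get("eta", []), dtype=float)


def _example1() -> Fixture:
    net = ReactionNetwork(
        species=[Species("A"), Species("B")],
        reactions=[
            Reaction("R1", products={"A": 1}),
            Reaction("R2", reactants={"A": 1}, products={"B": 1},
                     regulators={"B": "+"}),
            Reaction("R3", reactants={"B": 1}, products={"A": 1}),
            Reaction("R4", reactants={"A": 1}),
        ],
        metadata={"name": "example1"},
    )
    C = KernelBasis(np.array([[1, 0], [1, 1], [1, 1], [1, 0]]),
                    provenance="user-supplied")
    D = CokernelBasis(np.zeros((2, 0), dtype=np.int64),
                      provenance="user-supplied")

    def preset(r2_bracket: str, lam_range, note):
        laws = {
            "R1": {"law": "constant", "k": 1.0},
            "R2": {"law": "expression",
                   "expr": f"(A/a0)*({r2_bracket})",
                   "params": {"a0": 1.0, "c0": 2.0, "k3": 4.0, "lam": 0.25}},
            "R3": {"law": "expression", "expr": "c0 + k3*B",
                   "params": {"c0": 2.0, "k3": 4.0}},
            "R4": {"law": "mass_action", "k": 1.0},
        }
        return {"laws": laws, "eta": [], "domain": (0.05, 2.0),
                "sweep": {"parameter": "R2:lam", "range": lam_range},
                "note": note}

    presets = {
        "pitchfork": preset("c0 + k3*B + lam*(B-1) - (B-1)**3", (-0.4, 0.4),
                            "supercritical pitchfork at lam = 0"),
        "transcritical": preset("c0 + k3*B + lam*(B-1) - (B-1)**2",
                                (-0.4, 0.4), "transcritical crossing at lam = 0"),
        "saddle_node": preset("c0 + k3*B + lam - (B-1)**2", (-0.3, 0.4),
                              "fold at lam = 0"),
    }
    return Fixture("example1", net, C, D, presets)


def _conserved_example() -> Fixture:
    net = ReactionNetwork(
        species=[Species(s) for s in "ABCDE"],
        reactions=[
            Reaction("R1", products={"A": 1}),
            Reaction("R2", reactants={"A": 1}, products={"B": 1},
                     regulators={"C": "?"}),
            Reaction("R3", reactants={"B": 1}, products={"C": 1},
                     regulators={"E": "-"}),
            Reaction("R4", reactants={"C": 1}),
            Reaction("R5", reactants={"D": 1, "E": 1}, products={"B": 1}),
            Reaction("R6", reactants={"B": 1}, products={"D": 1, "E": 1}),
        ],
        metadata={"name": "conserved_example"},
    )
    C = KernelBasis(np.array([
        [0, 1], [0, 1], [0, 1], [0, 1], [1, 0], [1, 0]]),
        provenance="user-supplied")
    D = CokernelBasis(np.array([[0], [0], [0], [1], [-1]]),
                      provenance="user-supplied")
    laws = {
        "R1": {"law": "constant", "k": 1.0},
        "R2": {"law": "expression", "expr": "k*A/(1 + C)", "params": {"k": 1.0}},
        "R3": {"law": "expression", "expr": "k*B/(1 + E)", "params": {"k": 2.0}},
        "R4": {"law": "mass_action", "k": 1.0},
        "R5": {"law": "mass_action", "k": 1.0},
        "R6": {"law": "mass_action", "k": 1.0},
    }
    presets = {"mass_action": {"laws": laws, "eta": [1.0],
                               "domain": (0.05, 4.0)}}
    return Fixture("conserved_example", net, C, D, presets)


_MACROPHAGE_SPECIES = ["S1", "S1p", "S3", "S3p", "S6", "S6p", "N", "Np"]

# regulator -> (K, h) per activation reaction; the mutual-antagonism edges
# (S6p on R1, S1p on R5) carry the strong inhibition, cross-talk is weaker
_MACROPHAGE_INHIBITION = {
    "R1": {"S3p": (8.0, 4.0), "S6p": (2.0, 4.0)},
    "R3": {"S1p": (2.0, 4.0), "S3p": (4.0, 4.0), "Np": (2.0, 4.0)},
    "R5": {"S1p": (3.0, 6.0)},
    "R7": {"S3p": (6.0, 4.0), "S6p": (2.5, 4.0), "Np": (4.0, 2.0)},
}

SOCS3_DELETION = {("R3", "S1p"), ("R3", "S3p"), ("R3", "Np")}
KLF4_DELETION = {("R7", "S6p")}


def _macrophage(name: str, deletions: set[tuple[str, str]]) -> Fixture:
    pairs = [("S1", "S1p", "R1", "R2"), ("S3", "S3p", "R3", "R4"),
             ("S6", "S6p", "R5", "R6"), ("N", "Np", "R7", "R8")]
    reactions = []
    for inactive, active, r_act, r_deact in pairs:
        regulators = {sid: "-" for sid in _MACROPHAGE_INHIBITION[r_act]
                      if (r_act, sid) not in deletions}
        reactions.append(Reaction(r_act, reactants={inactive: 1},
                                  products={active: 1}, regulators=regulators))
        reactions.append(Reaction(r_deact, reactants={active: 1},
                                  products={inactive: 1}))
    order = ["R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8"]
    reactions.sort(key=lambda r: order.index(r.id))
    net = ReactionNetwork([Species(s) for s in _MACROPHAGE_SPECIES], reactions,
                          metadata={"name": name})
    C = np.zeros((8, 4), dtype=np.int64)
    D = np.zeros((8, 4), dtype=np.int64)
    for p in range(4):
        C[2 * p, p] = C[2 * p + 1, p] = 1       # loop through Rodd/Reven pair
        D[2 * p, p] = D[2 * p + 1, p] = 1       # total of the species pair
    laws: dict[str, dict] = {}
    for inactive, active, r_act, r_deact in pairs:
        inhibitors = {sid: {"K": K, "h": h}
                      for sid, (K, h) in _MACROPHAGE_INHIBITION[r_act].items()
                      if (r_act, sid) not in deletions}
        laws[r_act] = {"law": "sigmoid_activation", "k": 4.0,
                       "inhibitors": inhibitors}
        laws[r_deact] = {"law": "mass_action", "k": 1.0}
    presets = {"sigmoid": {
        "laws": laws,
        "eta": [8.0, 8.0, 8.0, 8.0],
        "domain": (1e-3, 8.5),
        "sweep": {"parameter": "eta:eta1", "range": (6.0, 8.5)},
    }}
    return Fixture(name, net,
                   KernelBasis(C, provenance="user-supplied"),
                   CokernelBasis(D, provenance="user-supplied"),
                   presets)


_CATALOG_BUILDERS = {
    "example1": _example1,
    "conserved_example": _conserved_example,
    "macrophage_wt": lambda: _macrophage("macrophage_wt", set()),
    "macrophage_socs3d": lambda: _macrophage("macrophage_socs3d",
                                             SOCS3_DELETION),
    "macrophage_socs3d_klf4d": lambda: _macrophage(
        "macrophage_socs3d_klf4d", SOCS3_DELETION | KLF4_DELETION),
}

CATALOG = tuple(_CATALOG_BUILDERS)


def load_fixture(name: str) -> Fixture:
    """Load a catalog fixture by name; bases are validated on load."""
    try:
        fixture = _CATALOG_BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(CATALOG)}") from None
    nu = build_stoichiometric_matrix(fixture.network)
    if fixture.C is not None and fixture.C.P:
        assert not np.any(nu.entries @ fixture.C.C), f"{name}: bad kernel basis"
    if fixture.D is not None and fixture.D.Q:
        assert not np.any(nu.entries.T @ fixture.D.D), \
            f"{name}: bad cokernel basis"
    return fixture


# ---------------------------------------------------------------------------
# Random networks for property tests
# ---------------------------------------------------------------------------

@dataclass
class RandomNetworkSpec:
    n_species: tuple[int, int] = (2, 5)
    n_reactions: tuple[int, int] = (2, 7)
    regulation_density: float = 0.15
    reversible_fraction: float = 0.3
    allow_degenerate: bool = False
    seed: int = 0


class GenerationError(RuntimeError):
    pass


def random_network(spec: RandomNetworkSpec, max_retries: int = 50
                   ) -> ReactionNetwork:
    """Seeded random network; structurally nonsingular unless degenerate allowed.

    Reversible reaction pairs are included with the requested fraction to
    induce conserved quantities.
    """
    from strucbif.symbolic_amatrix import build_A
    from strucbif.decomposition import (StructuralSingularityError,
                                        block_triangularize)

    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        net = _draw_network(rng, spec)
        if spec.allow_degenerate:
            return net
        try:
            block_triangularize(build_A(net))
        except StructuralSingularityError:
            continue
        return net
    raise GenerationError(f"no structurally nonsingular network after "
                          f"{max_retries} draws (seed {spec.seed})")


def _draw_network(rng: np.random.Generator,
                  spec: RandomNetworkSpec) -> ReactionNetwork:
    M = int(rng.integers(spec.n_species[0], spec.n_species[1] + 1))
    N = int(rng.integers(spec.n_reactions[0], spec.n_reactions[1] + 1))
    species = [Species(f"X{i + 1}") for i in range(M)]
    ids = [s.id for s in species]
    reactions: list[Reaction] = []
    k = 0
    while len(reactions) < N:
        k += 1
        kind = rng.choice(["convert", "inflow", "outflow", "complex"],
                          p=[0.5, 0.15, 0.2, 0.15])
        if kind == "inflow":
            reactants, products = {}, {str(rng.choice(ids)): 1}
        elif kind == "outflow":
            reactants, products = {str(rng.choice(ids)): 1}, {}
        elif kind == "convert":
            a, b = rng.choice(M, size=2, replace=False) if M > 1 else (0, 0)
            reactants, products = {ids[int(a)]: 1}, {ids[int(b)]: 1}
            if a == b:
                products = {}
        else:
            chosen = rng.choice(M, size=min(M, 2), replace=False)
            reactants = {ids[int(c)]: int(rng.integers(1, 3)) for c in chosen}
            products = {str(rng.choice(ids)): 1}
            products = {k2: v for k2, v in products.items()
                        if k2 not in reactants}
            if not products:
                products = {}
        if not reactants and not products:
            continue
        rid = f"R{len(reactions) + 1}"
        reactions.append(Reaction(rid, reactants=reactants, products=products))
        if (reactants and products and len(reactions) < N
                and rng.random() < spec.reversible_fraction):
            reactions.append(Reaction(f"R{len(reactions) + 1}",
                                      reactants=dict(products),
                                      products=dict(reactants)))
    # sprinkle signed regulations
    for rxn in reactions:
        for sid in ids:
            if sid in rxn.reactants or sid in rxn.regulators:
                continue
            if rng.random() < spec.regulation_density:
                rxn.regulators[sid] = str(rng.choice(["+", "-"]))
    return ReactionNetwork(species, reactions,
                           metadata={"seed": spec.seed})
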