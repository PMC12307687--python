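"""Data model and I/O for reaction networks with signed regulations.

A network is a list of species and a list of reactions.  Each reaction has
integer reactant/product stoichiometries and, optionally, regulators: species
that modulate the reaction rate without being consumed or produced.  The
external reservoir is implicit -- a reaction with an empty reactant (product)
side takes from (releases to) the outside and needs no special node.

Species order and reaction order are significant: they define the row and
column order of the stoichiometric matrix and of every matrix derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

POSITIVE = "+"
NEGATIVE = "-"
UNKNOWN = "?"
_SIGNS = (POSITIVE, NEGATIVE, UNKNOWN)


class SchemaError(ValueError):
    """Raised when a network document violates the schema."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("species id must be nonempty")


@dataclass(frozen=True)
class Reaction:
    """One reaction: reactants -> products, modulated by regulators.

    ``reactants`` and ``products`` map species id -> positive integer
    coefficient; ``regulators`` maps species id -> sign ('+', '-' or '?').
    ``sign_overrides`` resolves the rate-derivative sign for a species that is
    simultaneously a reactant and a regulator (otherwise reported unknown).
    """

    id: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    regulators: dict[str, str] = field(default_factory=dict)
    sign_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("reaction id must be nonempty")
        for side in (self.reactants, self.products):
            for sp, coeff in side.items():
                if not isinstance(coeff, int) or isinstance(coeff, bool) or coeff <= 0:
                    raise SchemaError(
                        f"reaction {self.id!r}: stoichiometric coefficient of "
                        f"{sp!r} must be a positive integer, got {coeff!r}"
                    )
        for sp, sign in self.regulators.items():
            if sign not in _SIGNS:
                raise SchemaError(
                    f"reaction {self.id!r}: regulator sign for {sp!r} must be "
                    f"one of {_SIGNS}, got {sign!r}"
                )
        for sp, sign in self.sign_overrides.items():
            if sign not in _SIGNS:
                raise SchemaError(
                    f"reaction {self.id!r}: sign override for {sp!r} must be "
                    f"one of {_SIGNS}, got {sign!r}"
                )
        if not (self.reactants or self.products or self.regulators):
            raise SchemaError(f"reaction {self.id!r} is empty")

    def rate_dependence_sign(self, species_id: str) -> str | None:
        """Sign of d(rate)/d(concentration) for ``species_id``.

        Returns '+', '-', '?' or None (None = rate does not depend on it).
        A species that is both reactant and regulator gets '?' unless an
        explicit override is given: the two contributions may conflict.
        """
        is_reactant = species_id in self.reactants
        is_regulator = species_id in self.regulators
        if not is_reactant and not is_regulator:
            return None
        if species_id in self.sign_overrides:
            return self.sign_overrides[species_id]
        if is_reactant and is_regulator:
            return UNKNOWN
        if is_reactant:
            return POSITIVE
        return self.regulators[species_id]

    def dependent_species(self) -> list[str]:
        """Species ids the rate may depend on (reactants + regulators)."""
        seen: list[str] = []
        for sp in list(self.reactants) + list(self.regulators):
            if sp not in seen:
                seen.append(sp)
        return seen


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise SchemaError(f"duplicate species id {dup!r}")
        rids = [r.id for r in self.reactions]
        dup = _first_duplicate(rids)
        if dup is not None:
            raise SchemaError(f"duplicate reaction id {dup!r}")
        known = set(ids)
        for rxn in self.reactions:
            for sp in (*rxn.reactants, *rxn.products, *rxn.regulators,
                       *rxn.sign_overrides):
                if sp not in known:
                    raise SchemaError(
                        f"reaction {rxn.id!r} references unknown species {sp!r}"
                    )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def reaction_index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index(reaction_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (self.species == other.species
                and self.reactions == other.reactions
                and self.metadata == other.metadata)


@dataclass
class StoichiometricMatrix:
    """Integer M x N matrix of net production coefficients."""

    entries: np.ndarray
    species_ids: list[str]
    reaction_ids: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int64)
        if self.entries.shape != (len(self.species_ids), len(self.reaction_ids)):
            raise ValueError("stoichiometric matrix shape/label mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_tsv(self) -> str:
        lines = ["\t".join(["species", *self.reaction_ids])]
        for i, sp in enumerate(self.species_ids):
            lines.append("\t".join([sp, *map(str, self.entries[i].tolist())]))
        return "\n".join(lines) + "\n"


def build_stoichiometric_matrix(net: ReactionNetwork) -> StoichiometricMatrix:
    """Column n = products minus reactants of reaction n.

    Regulator annotations never enter the stoichiometric matrix.
    """
    mat = np.zeros((net.n_species, net.n_reactions), dtype=np.int64)
    for j, rxn in enumerate(net.reactions):
        for sp, coeff in rxn.reactants.items():
            mat[net.species_index(sp), j] -= coeff
        for sp, coeff in rxn.products.items():
            mat[net.species_index(sp), j] += coeff
    return StoichiometricMatrix(mat, net.species_ids, net.reaction_ids)


# ---------------------------------------------------------------------------
# JSON document format
# ---------------------------------------------------------------------------

def parse_network(document: str | dict) -> ReactionNetwork:
    """Parse the package JSON network format.

    Top-level keys: ``species`` (list of {id, name}), ``reactions`` (list of
    {id, reactants, products, regulators, sign_overrides}), ``metadata``.
    """
    if isinstance(document, str):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}") from exc
    else:
        doc = document
    if not isinstance(doc, dict):
        raise SchemaError("network document must be a JSON object")
    species = []
    for entry in doc.get("species", []):
        if not isinstance(entry, dict) or "id" not in entry:
            raise SchemaError(f"bad species entry: {entry!r}")
        species.append(Species(id=str(entry["id"]), name=str(entry.get("name", ""))))
    reactions = []
    for entry in doc.get("reactions", []):
        if not isinstance(entry, dict) or "id" not in entry:
            raise SchemaError(f"bad reaction entry: {entry!r}")
        reactions.append(Reaction(
            id=str(entry["id"]),
            reactants=_int_map(entry.get("reactants", {}), entry["id"]),
            products=_int_map(entry.get("products", {}), entry["id"]),
            regulators={str(k): str(v) for k, v in entry.get("regulators", {}).items()},
            sign_overrides={str(k): str(v)
                            for k, v in entry.get("sign_overrides", {}).items()},
        ))
    return ReactionNetwork(species, reactions, metadata=doc.get("metadata", {}))


def serialize_network(net: ReactionNetwork) -> str:
    """Inverse of :func:`parse_network`; orderings are preserved as written."""
    doc: dict = {
        "species": [{"id": s.id, "name": s.name} for s in net.species],
        "reactions": [],
        "metadata": net.metadata,
    }
    for rxn in net.reactions:
        entry: dict = {"id": rxn.id,
                       "reactants": dict(rxn.reactants),
                       "products": dict(rxn.products),
                       "regulators": dict(rxn.regulators)}
        if rxn.sign_overrides:
            entry["sign_overrides"] = dict(rxn.sign_overrides)
        doc["reactions"].append(entry)
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


def _int_map(raw: dict, rxn_id: str) -> dict[str, int]:
    out = {}
    for k, v in raw.items():
        if isinstance(v, bool) or not isinstance(v, int):
            raise SchemaError(
                f"reaction {rxn_id!r}: non-integer stoichiometry {v!r} for {k!r}"
            )
        out[str(k)] = v
    return out


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# TSV edge-list format (for hand-authoring)
# ---------------------------------------------------------------------------

def parse_network_tsv(text: str) -> ReactionNetwork:
    """Read a TSV edge list.

    Rows (tab-separated; '#' starts a comment):

    * ``species<TAB>ID[<TAB>NAME]`` declares a species,
    * ``reaction<TAB>ID`` declares a reaction (optional when edges imply it),
    * ``edge<TAB>REACTION<TAB>ROLE<TAB>SPECIES<TAB>VALUE`` with ROLE one of
      ``reactant``/``product`` (VALUE = integer coefficient) or ``regulator``
      (VALUE = '+', '-' or '?').

    Declaration order fixes species/reaction order.
    """
    species: list[Species] = []
    rxn_order: list[str] = []
    parts_by_rxn: dict[str, dict[str, dict]] = {}

    def ensure_reaction(rid: str) -> dict[str, dict]:
        if rid not in parts_by_rxn:
            rxn_order.append(rid)
            parts_by_rxn[rid] = {"reactants": {}, "products": {},
                                 "regulators": {}, "sign_overrides": {}}
        return parts_by_rxn[rid]

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        cells = line.split("\t")
        kind = cells[0].strip()
        if kind == "species":
            if len(cells) < 2:
                raise SchemaError(f"line {lineno}: species row needs an id")
            species.append(Species(cells[1].strip(),
                                   cells[2].strip() if len(cells) > 2 else ""))
        elif kind == "reaction":
            if len(cells) < 2:
                raise SchemaError(f"line {lineno}: reaction row needs an id")
            ensure_reaction(cells[1].strip())
        elif kind == "edge":
            if len(cells) < 5:
                raise SchemaError(f"line {lineno}: edge row needs 5 columns")
            _, rid, role, sp, value = (c.strip() for c in cells[:5])
            parts = ensure_reaction(rid)
            if role in ("reactant", "product"):
                try:
                    coeff = int(value)
                except ValueError:
                    raise SchemaError(
                        f"line {lineno}: non-integer stoichiometry {value!r}"
                    ) from None
                parts[role + "s"][sp] = coeff
            elif role == "regulator":
                parts["regulators"][sp] = value
            elif role == "override":
                parts["sign_overrides"][sp] = value
            else:
                raise SchemaError(f"line {lineno}: unknown role {role!r}")
        else:
            raise SchemaError(f"line {lineno}: unknown row kind {kind!r}")

    reactions = [Reaction(id=rid, **parts_by_rxn[rid]) for rid in rxn_order]
    return ReactionNetwork(species, reactions)


# ---------------------------------------------------------------------------
# Optional SBML import
# ---------------------------------------------------------------------------

def parse_sbml(path: str) -> ReactionNetwork:
    """Import an SBML file (requires ``python-libsbml``).

    speciesReferences map to stoichiometry; modifierSpeciesReferences become
    regulators with sign '?' (SBML carries no regulation sign).
    Non-integer stoichiometries are rejected.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SBML import requires the python-libsbml package") from exc
    doc = libsbml.readSBML(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SchemaError(f"libsbml failed to read {path!r}")
    model = doc.getModel()
    species = [Species(s.getId(), s.getName() or "") for s in model.getListOfSpecies()]
    reactions = []
    for rxn in model.getListOfReactions():
        def _side(refs):
            side = {}
            for ref in refs:
                st = ref.getStoichiometry()
                if st != int(st):
                    raise SchemaError(
                        f"reaction {rxn.getId()!r}: non-integer stoichiometry {st}"
                    )
                side[ref.getSpecies()] = side.get(ref.getSpecies(), 0) + int(st)
            return side
        reactions.append(Reaction(
            id=rxn.getId(),
            reactants=_side(rxn.getListOfReactants()),
            products=_side(rxn.getListOfProducts()),
            regulators={m.getSpecies(): UNKNOWN
                        for m in rxn.getListOfModifiers()},
        ))
    return ReactionNetwork(species, reactions)
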