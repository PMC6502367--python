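"""Network data model: metabolites, reactions, stoichiometry, file format.

A model holds an ordered list of metabolites and reactions.  Exactly one
metabolite is the fictitious ``External`` node standing in for the rest of
the cell; it carries no concentration and has no row in the stoichiometric
matrix, so exchange reactions appear as one-sided columns.  Cofactor
bookkeeping species (ATP, NADH, NADPH) are ordinary internal metabolites
with a carbon count of zero; only the reduced/charged member of each pair
is a state variable, the oxidized partner being folded into the rate
constants.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

EXTERNAL_ID = "External"

_ID_RE = re.compile(r"^[A-Za-z0-9_]+$")


class NetworkError(ValueError):
    """Raised for malformed networks or unresolvable species references."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.

    ``carbon_count`` is the number of carbon atoms the species carries; it
    weights the self-regulation cost (a metabolite with more carbon is more
    expensive to leave imbalanced) and enters carbon-balance validation.
    """

    id: str
    name: str = ""
    carbon_count: int = 0
    is_external: bool = False

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.id):
            raise NetworkError(f"invalid metabolite id {self.id!r}")
        if self.carbon_count < 0:
            raise NetworkError(f"negative carbon count for {self.id!r}")


@dataclass(frozen=True)
class ReactionKinetics:
    """Kinetic parameters of one reaction.

    ``v_forward``/``v_backward`` are the peak forward/backward rates,
    ``km_substrates``/``km_products`` the Michaelis constants aligned with
    the substrate/product species lists, and ``k_eq`` the equilibrium
    constant (dimensionless in reduced units) used by the thermodynamic
    (Haldane) constraint.  ``k_eq`` may be ``None`` for irreversible or
    exchange reactions.
    """

    v_forward: float
    v_backward: float
    km_substrates: tuple[float, ...]
    km_products: tuple[float, ...]
    k_eq: float | None = None

    def __post_init__(self) -> None:
        if self.v_forward < 0 or self.v_backward < 0:
            raise NetworkError("peak rates must be non-negative")
        if any(k <= 0 for k in self.km_substrates + self.km_products):
            raise NetworkError("Michaelis constants must be positive")
        if self.k_eq is not None and self.k_eq <= 0:
            raise NetworkError("equilibrium constant must be positive")

    @property
    def reversible(self) -> bool:
        return self.v_backward > 0.0


@dataclass(frozen=True)
class ReactionSpec:
    """One (possibly reversible) reaction with explicit multiplicities.

    A species consumed or produced more than once appears once in the
    ``substrates``/``products`` list with an integer multiplicity; the rate
    law expands the multiplicity as repeated saturation factors.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kinetics: ReactionKinetics
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.id):
            raise NetworkError(f"invalid reaction id {self.id!r}")
        if not self.substrates or not self.products:
            raise NetworkError(
                f"reaction {self.id!r}: substrates and products must be "
                "non-empty (exchange reactions use the External node)"
            )
        for side, kms in (
            (self.substrates, self.kinetics.km_substrates),
            (self.products, self.kinetics.km_products),
        ):
            if any(m < 1 for _, m in side):
                raise NetworkError(f"reaction {self.id!r}: multiplicity < 1")
            ids = [s for s, _ in side]
            if len(set(ids)) != len(ids):
                raise NetworkError(
                    f"reaction {self.id!r}: repeated species must be merged "
                    "into a single entry with a multiplicity"
                )
            if len(kms) != len(side):
                raise NetworkError(
                    f"reaction {self.id!r}: Michaelis constants misaligned "
                    "with species list"
                )

    @property
    def is_exchange(self) -> bool:
        return any(s == EXTERNAL_ID for s, _ in self.substrates + self.products)

    def species_ids(self) -> set[str]:
        return {s for s, _ in self.substrates + self.products}

    def net_stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for s, m in self.substrates:
            net[s] = net.get(s, 0) - m
        for s, m in self.products:
            net[s] = net.get(s, 0) + m
        return net


def build_stoichiometric_matrix(
    reactions: Sequence[ReactionSpec],
    metabolites: Sequence[Metabolite],
) -> np.ndarray:
    """Assemble the N x M signed stoichiometric matrix.

    Rows follow the order of internal metabolites, columns the order of
    reactions; the External metabolite has no row.
    """
    internal = [m for m in metabolites if not m.is_external]
    index = {m.id: i for i, m in enumerate(internal)}
    known = set(index) | {m.id for m in metabolites if m.is_external}
    S = np.zeros((len(internal), len(reactions)), dtype=int)
    for j, rxn in enumerate(reactions):
        for sp in rxn.species_ids():
            if sp not in known:
                raise NetworkError(
                    f"reaction {rxn.id!r} references unknown species {sp!r}"
                )
        for sp, coeff in rxn.net_stoichiometry().items():
            if sp == EXTERNAL_ID:
                continue
            S[index[sp], j] = coeff
    return S


@dataclass
class NetworkModel:
    """A metabolic network: metabolites, reactions and their stoichiometry."""

    metabolites: list[Metabolite]
    reactions: list[ReactionSpec]
    name: str = "network"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        n_ext = sum(m.is_external for m in self.metabolites)
        if n_ext != 1:
            raise NetworkError(
                f"exactly one External metabolite required, found {n_ext}"
            )
        self._met_index = {
            m.id: i
            for i, m in enumerate(m for m in self.metabolites if not m.is_external)
        }
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        self.stoich_matrix = build_stoichiometric_matrix(
            self.reactions, self.metabolites
        )

    # -- lookups ---------------------------------------------------------
    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    @property
    def n_internal(self) -> int:
        return len(self._met_index)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise NetworkError(f"unknown internal metabolite {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise NetworkError(f"unknown reaction {rxn_id!r}") from None

    def reaction(self, rxn_id: str) -> ReactionSpec:
        return self.reactions[self.reaction_index(rxn_id)]

    def carbon_vector(self) -> np.ndarray:
        """Carbon counts of the internal metabolites, in row order."""
        return np.array(
            [m.carbon_count for m in self.internal_metabolites], dtype=float
        )

    def carbon_imbalance(self, rxn: ReactionSpec) -> int:
        """Net carbon created by a reaction counting only internal species."""
        carbons = {m.id: m.carbon_count for m in self.metabolites}
        carbons[EXTERNAL_ID] = 0
        return sum(
            coeff * carbons[sp]
            for sp, coeff in rxn.net_stoichiometry().items()
            if sp != EXTERNAL_ID
        )

    def with_reactions(self, reactions: Iterable[ReactionSpec]) -> "NetworkModel":
        return NetworkModel(list(self.metabolites), list(reactions), name=self.name)

    def replace_kinetics(
        self, updates: Mapping[str, ReactionKinetics]
    ) -> "NetworkModel":
        new = [
            replace(r, kinetics=updates[r.id]) if r.id in updates else r
            for r in self.reactions
        ]
        return self.with_reactions(new)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return (
            self.name == other.name
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


@dataclass
class ValidationReport:
    """Structural problems found in a model; empty report <=> valid."""

    carbon_imbalanced: list[tuple[str, int]] = field(default_factory=list)
    orphan_metabolites: list[str] = field(default_factory=list)
    degenerate_kinetics: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.carbon_imbalanced
            or self.orphan_metabolites
            or self.degenerate_kinetics
        )

    def entries(self) -> list[str]:
        out = [
            f"carbon imbalance in {rid}: net {d:+d} C"
            for rid, d in self.carbon_imbalanced
        ]
        out += [f"orphan metabolite {mid}" for mid in self.orphan_metabolites]
        out += [f"degenerate kinetics in {rid}" for rid in self.degenerate_kinetics]
        return out


def validate_network(model: NetworkModel) -> ValidationReport:
    """Report carbon-imbalanced reactions, orphan metabolites and dead kinetics.

    Exchange reactions are exempt from the carbon balance (the External node
    carries the difference); everything else must conserve carbon exactly.
    """
    report = ValidationReport()
    for rxn in model.reactions:
        if not rxn.is_exchange:
            diff = model.carbon_imbalance(rxn)
            if diff != 0:
                report.carbon_imbalanced.append((rxn.id, diff))
        kin = rxn.kinetics
        if kin.v_forward == 0.0 and kin.v_backward == 0.0 and "knocked_out" not in rxn.tags:
            report.degenerate_kinetics.append(rxn.id)
    used = np.abs(model.stoich_matrix).sum(axis=1)
    for m, row in zip(model.internal_metabolites, used):
        if row == 0:
            report.orphan_metabolites.append(m.id)
    return report


def rank_of_stoichiometry(
    model: NetworkModel, columns: Sequence[int] | None = None, tol: float | None = None
) -> int:
    """Numerical rank of the stoichiometric matrix (singular values above tol).

    ``columns`` restricts the rank to a subset of reactions, which is what
    the relaxation-time bookkeeping needs when some exchange fluxes are held
    constant and therefore contribute no concentration dependence.
    """
    S = model.stoich_matrix.astype(float)
    if columns is not None:
        S = S[:, list(columns)]
    if S.size == 0:
        return 0
    return int(np.linalg.matrix_rank(S, tol=tol))


# -- file format ----------------------------------------------------------

def _kinetics_to_dict(k: ReactionKinetics) -> dict:
    d = {
        "v_forward": k.v_forward,
        "v_backward": k.v_backward,
        "km_substrates": list(k.km_substrates),
        "km_products": list(k.km_products),
    }
    if k.k_eq is not None:
        d["k_eq"] = k.k_eq
    return d


def save_network(model: NetworkModel, path) -> None:
    """Write the model to the package JSON network format."""
    doc = {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "carbon_count": m.carbon_count,
                "is_external": m.is_external,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": [[s, m] for s, m in r.substrates],
                "products": [[s, m] for s, m in r.products],
                "tags": sorted(r.tags),
                "kinetics": _kinetics_to_dict(r.kinetics),
            }
            for r in model.reactions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_network(path) -> NetworkModel:
    """Read a model from the package JSON network format."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"malformed network file {path}: {exc}") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                carbon_count=int(m["carbon_count"]),
                is_external=bool(m.get("is_external", False)),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            kin = r["kinetics"]
            rxns.append(
                ReactionSpec(
                    id=r["id"],
                    substrates=tuple((s, int(m)) for s, m in r["substrates"]),
                    products=tuple((s, int(m)) for s, m in r["products"]),
                    tags=frozenset(r.get("tags", [])),
                    kinetics=ReactionKinetics(
                        v_forward=float(kin["v_forward"]),
                        v_backward=float(kin["v_backward"]),
                        km_substrates=tuple(float(k) for k in kin["km_substrates"]),
                        km_products=tuple(float(k) for k in kin["km_products"]),
                        k_eq=float(kin["k_eq"]) if "k_eq" in kin else None,
                    ),
                )
            )
    except KeyError as exc:
        raise NetworkError(
            f"network file {path} missing required field {exc}"
        ) from exc
    return NetworkModel(mets, rxns, name=doc.get("name", "network"))
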