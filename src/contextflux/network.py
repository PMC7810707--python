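"""Compartmentalised constraint-based metabolic network data model.

A :class:`MetabolicNetwork` holds metabolites (each assigned to one of eight
fixed sub-cellular compartments), reactions with stoichiometry, flux bounds
and GPR rules, a gene universe, and a biomass pseudo-reaction serving as the
objective.  Reversibility is encoded purely through a negative lower bound;
there is no separate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DanglingMetaboliteError,
    MissingObjectiveError,
    UnknownCompartmentError,
)
from .gpr import Gpr

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "stoichiometric_matrix",
    "nullspace_dimension",
]

#: Fixed compartment codes: cytosol, extracellular, golgi, lysosome,
#: mitochondria, nucleus, endoplasmic reticulum, peroxisome.
COMPARTMENTS: dict[str, str] = {
    "c": "cytosol",
    "e": "extracellular",
    "g": "golgi",
    "l": "lysosome",
    "m": "mitochondria",
    "n": "nucleus",
    "r": "endoplasmic reticulum",
    "p": "peroxisome",
}


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise UnknownCompartmentError(
                f"metabolite {self.id!r}: unknown compartment code "
                f"{self.compartment!r} (allowed: {sorted(COMPARTMENTS)})"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry maps metabolite id to a nonzero
    coefficient (negative = consumed, positive = produced)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Gpr = field(default_factory=Gpr)
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.id!r}: zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicNetwork:
    """Ordered collection of metabolites and reactions with an objective.

    Metabolite and reaction order is meaningful (it fixes the rows/columns
    of the stoichiometric matrix and the LP column order, which context
    extraction deliberately permutes).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: frozenset[str]
    objective_id: str
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ValueError("duplicate reaction ids")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise DanglingMetaboliteError(
                    f"reaction {rxn.id!r} references undefined metabolites "
                    f"{sorted(missing)}"
                )
        if self.objective_id not in set(rxn_ids):
            raise MissingObjectiveError(
                f"objective reaction {self.objective_id!r} not in network"
            )
        gpr_genes = set().union(*(r.gpr.genes() for r in self.reactions)) if self.reactions else set()
        if not gpr_genes <= set(self.genes):
            raise ValueError(
                f"GPR genes outside the gene universe: {sorted(gpr_genes - set(self.genes))}"
            )

    # -- lookups ----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- derived networks -------------------------------------------------

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Copy with the given per-reaction (lower, upper) bound overrides."""
        new_rxns = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return MetabolicNetwork(
            list(self.metabolites), new_rxns, self.genes, self.objective_id, self.name
        )

    def subnetwork(self, reaction_ids: set[str] | frozenset[str]) -> "MetabolicNetwork":
        """Restriction to a reaction subset (metabolites pruned to those used).

        The objective reaction is always carried along so the sub-model can
        be re-verified by FBA.
        """
        keep = set(reaction_ids) | {self.objective_id}
        rxns = [r for r in self.reactions if r.id in keep]
        used = set().union(*(set(r.stoichiometry) for r in rxns)) if rxns else set()
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(mets, rxns, self.genes, self.objective_id, self.name)

    def permuted(self, order: list[str]) -> "MetabolicNetwork":
        """Copy with reactions re-ordered to the given id sequence."""
        if sorted(order) != sorted(self.reaction_ids):
            raise ValueError("permutation must cover exactly the reaction ids")
        by_id = {r.id: r for r in self.reactions}
        return MetabolicNetwork(
            list(self.metabolites),
            [by_id[i] for i in order],
            self.genes,
            self.objective_id,
            self.name,
        )


def stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense S of shape |metabolites| x |reactions| in network order."""
    n_m, n_r = len(network.metabolites), len(network.reactions)
    S = np.zeros((n_m, n_r))
    row = {m.id: i for i, m in enumerate(network.metabolites)}
    for j, rxn in enumerate(network.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[row[met_id], j] = coeff
    return S


def nullspace_dimension(network: MetabolicNetwork) -> int:
    """|reactions| - rank(S), the number of independent steady-state flux
    degrees of freedom.  Rank uses the standard SVD tolerance
    max(dim) * eps * sigma_max."""
    if not network.reactions:
        return 0
    S = stoichiometric_matrix(network)
    return int(S.shape[1] - np.linalg.matrix_rank(S))
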