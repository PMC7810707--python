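"""Organelle (compartment) enrichment profiles of DE-gene sub-networks.

Differentially expressed genes are mapped to reactions through GPR rules;
the metabolites those reactions touch are then counted per sub-cellular
compartment, giving a descriptive per-organelle size profile for each
direction of regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .network import COMPARTMENTS, MetabolicNetwork

__all__ = ["OrganelleProfile", "de_reaction_subnetwork", "organelle_profile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrganelleProfile:
    """Distinct-metabolite counts per compartment for one gene-set direction.

    ``fractions`` relate each compartment's count to that compartment's
    whole-network metabolite total (0 when the compartment is empty
    network-wide).
    """

    direction: str
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)


def de_reaction_subnetwork(
    network: MetabolicNetwork,
    de_genes: set[str],
    strict_gpr: bool = False,
) -> set[str]:
    """Reaction ids mapped by the DE gene set.

    Default is the any-occurrence rule: a reaction is selected iff any gene
    in its GPR is differentially expressed, ignoring the AND/OR structure.
    With ``strict_gpr`` the boolean rule must evaluate true when exactly
    the DE genes are present.  Genes outside the network's universe are
    logged and ignored.
    """
    unknown = de_genes - set(network.genes)
    if unknown:
        logger.info(
            "%d DE genes not in the network gene universe (e.g. %s); ignored",
            len(unknown),
            sorted(unknown)[:3],
        )
    known = de_genes - unknown
    selected: set[str] = set()
    for rxn in network.reactions:
        if rxn.gpr.is_empty:
            continue
        if strict_gpr:
            if rxn.gpr.evaluate(known):
                selected.add(rxn.id)
        elif rxn.gpr.genes() & known:
            selected.add(rxn.id)
    return selected


def organelle_profile(
    network: MetabolicNetwork,
    reaction_ids: set[str],
    direction: str,
    exclude_metabolites: set[str] | None = None,
) -> OrganelleProfile:
    """Count distinct metabolites per compartment over the given reactions.

    Each metabolite lives in exactly one compartment, so it contributes to
    exactly one count.  ``exclude_metabolites`` supports dropping currency
    metabolites (protons, water, cofactors); by default nothing is excluded.
    """
    missing = reaction_ids - set(network.reaction_ids)
    if missing:
        raise KeyError(f"reactions not in network: {sorted(missing)[:5]}")
    exclude = exclude_metabolites or set()
    compartment_of = {m.id: m.compartment for m in network.metabolites}

    touched: set[str] = set()
    for rxn in network.reactions:
        if rxn.id in reaction_ids:
            touched |= set(rxn.stoichiometry) - exclude

    counts = {code: 0 for code in COMPARTMENTS}
    for met in touched:
        counts[compartment_of[met]] += 1

    totals = {code: 0 for code in COMPARTMENTS}
    for met, code in compartment_of.items():
        if met not in exclude:
            totals[code] += 1
    fractions = {
        code: (counts[code] / totals[code] if totals[code] else 0.0)
        for code in COMPARTMENTS
    }
    return OrganelleProfile(direction=direction, counts=counts, fractions=fractions)
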