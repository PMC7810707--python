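"""GIMME context-specific model extraction.

Given presence/absence calls, GIMME finds the flux distribution that
minimises total flux through *absent* reactions (binary penalties: absent
= 1, present or non-gene-associated = 0) while forcing the biomass
objective to at least a required fraction (default 50%) of the parent
network's optimum.  Reactions retained in the context model are those whose
GPR evaluates present, those with no GPR, and those absent reactions the
optimum still routes flux through.

The published procedure runs the extraction several times on randomly
re-sorted reaction orders — alternate optima of the degenerate LP then
surface as different retained sets — and keeps only the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import FunctionalityFloorInfeasibleError
from .fba import fba
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = ["GimmeConfig", "ContextModel", "gimme_extract", "gimme_consensus"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GimmeConfig:
    """Extraction parameters.

    required_fraction: objective floor as a fraction of the parent optimum.
    activity_tolerance: |flux| above which an absent reaction counts as
    used at the optimum.  iterations/seed control the reaction-reordering
    consensus.
    """

    required_fraction: float = 0.5
    activity_tolerance: float = 1e-9
    iterations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.required_fraction <= 1):
            raise ValueError("required_fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ContextModel:
    """A GIMME-retained reaction subset for one condition/iteration."""

    parent: MetabolicNetwork
    retained: frozenset[str]
    inconsistency: float
    iteration: str  # "0", "1", ... or "consensus"
    seed: int | None = None
    floor_value: float = 0.0
    floor_verified: bool = True
    reaction_order: list[str] = field(default_factory=list)

    def submodel(self) -> MetabolicNetwork:
        return self.parent.subnetwork(set(self.retained))

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "seed": self.seed,
            "inconsistency": self.inconsistency,
            "floor_value": self.floor_value,
            "floor_verified": self.floor_verified,
            "retained": sorted(self.retained),
        }


def _absent_reactions(network: MetabolicNetwork, present_genes: set[str]) -> set[str]:
    """Reactions whose GPR evaluates absent (empty GPRs are never absent)."""
    return {
        r.id
        for r in network.reactions
        if not r.gpr.is_empty and not r.gpr.evaluate(present_genes)
    }


def gimme_extract(
    network: MetabolicNetwork,
    presence: dict[str, bool],
    config: GimmeConfig | None = None,
    iteration: str = "0",
    seed: int | None = None,
) -> ContextModel:
    """One GIMME extraction on the network's current reaction order.

    ``presence`` maps gene id to present flag; genes not covered are
    treated as absent.  Any demand reactions that must stay active are
    assumed to already carry their pre-extraction lower bounds.
    """
    config = config or GimmeConfig()
    parent_opt = fba(network)
    if not parent_opt.optimal:
        raise FunctionalityFloorInfeasibleError(
            f"parent network FBA is {parent_opt.status}; no objective floor exists"
        )
    floor = config.required_fraction * parent_opt.objective_value

    present_genes = {g for g, ok in presence.items() if ok}
    absent = _absent_reactions(network, present_genes)

    rxn_ids = network.reaction_ids
    n = len(rxn_ids)
    S = stoichiometric_matrix(network)

    # split v = v+ - v- for the absolute-value objective
    lbs = np.array([r.lower_bound for r in network.reactions])
    ubs = np.array([r.upper_bound for r in network.reactions])
    fwd_bounds = list(zip(np.maximum(lbs, 0.0), np.maximum(ubs, 0.0)))
    bwd_bounds = list(zip(np.maximum(-ubs, 0.0), np.maximum(-lbs, 0.0)))
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])

    penalty = np.array([1.0 if rid in absent else 0.0 for rid in rxn_ids])
    c = np.concatenate([penalty, penalty])

    j_obj = rxn_ids.index(network.objective_id)
    floor_row = np.zeros(2 * n)
    floor_row[j_obj] = -1.0
    floor_row[n + j_obj] = 1.0  # -(v+ - v-) <= -floor

    res = linprog(
        c,
        A_ub=floor_row[None, :],
        b_ub=np.array([-floor]),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=fwd_bounds + bwd_bounds,
        method="highs",
    )
    if res.status == 2:
        raise FunctionalityFloorInfeasibleError(
            f"objective floor {floor:g} is infeasible for the context"
        )
    if res.status != 0:
        raise RuntimeError(f"GIMME LP failed with status {res.status}")

    v = res.x[:n] - res.x[n:]
    inconsistency = float(res.fun)

    retained = {
        r.id
        for r in network.reactions
        if r.gpr.is_empty or r.gpr.evaluate(present_genes)
    }
    active_absent = {
        rxn_ids[j]
        for j in range(n)
        if rxn_ids[j] in absent and abs(v[j]) > config.activity_tolerance
    }
    retained |= active_absent

    model = ContextModel(
        parent=network,
        retained=frozenset(retained),
        inconsistency=inconsistency,
        iteration=iteration,
        seed=seed,
        floor_value=floor,
        reaction_order=list(rxn_ids),
    )
    model.floor_verified = _verify_floor(model)
    return model


def _verify_floor(model: ContextModel, tol: float = 1e-6) -> bool:
    sub = model.submodel()
    res = fba(sub)
    return bool(res.optimal and res.objective_value >= model.floor_value - tol)


def gimme_consensus(
    network: MetabolicNetwork,
    presence: dict[str, bool],
    config: GimmeConfig | None = None,
) -> tuple[ContextModel, list[ContextModel]]:
    """Run k extractions on column-permuted copies; intersect retained sets.

    Returns (consensus model, per-iteration models).  A consensus whose
    intersection can no longer attain the objective floor is flagged
    (``floor_verified = False``) and a warning logged, never silently used.
    """
    config = config or GimmeConfig()
    rng = np.random.default_rng(config.seed)
    iterations: list[ContextModel] = []
    for i in range(config.iterations):
        iter_seed = int(rng.integers(0, 2**31 - 1))
        order = list(np.random.default_rng(iter_seed).permutation(network.reaction_ids))
        permuted = network.permuted(order)
        model = gimme_extract(
            permuted, presence, config, iteration=str(i), seed=iter_seed
        )
        iterations.append(model)

    consensus_set = frozenset.intersection(*(m.retained for m in iterations))
    consensus = ContextModel(
        parent=network,
        retained=consensus_set,
        inconsistency=float(np.mean([m.inconsistency for m in iterations])),
        iteration="consensus",
        seed=config.seed,
        floor_value=iterations[0].floor_value,
        reaction_order=list(network.reaction_ids),
    )
    consensus.floor_verified = _verify_floor(consensus)
    if not consensus.floor_verified:
        logger.warning(
            "consensus context model no longer attains the objective floor "
            "%.6g; flagged for inspection",
            consensus.floor_value,
        )
    return consensus, iterations
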