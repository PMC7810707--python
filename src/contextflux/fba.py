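"""Flux balance analysis and demand-reaction construction.

FBA solves ``max c.v  s.t.  S.v = 0, lb <= v <= ub`` as a linear program
(HiGHS backend through scipy).  Demand reactions are artificial sinks used
to probe production capability: a maintenance-style ATP demand, a reduced
glutathione sink, or a protein demand whose stoichiometry is the amino-acid
composition of a sequence (here: the neurotrophin BDNF).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.optimize import linprog

from .errors import MissingMetaboliteError, UnknownResidueError
from .gpr import Gpr
from .network import MetabolicNetwork, Reaction, stoichiometric_matrix

__all__ = [
    "LPResult",
    "DemandSpec",
    "fba",
    "flux_variability",
    "apply_rich_media",
    "protein_demand_from_sequence",
    "read_fasta_sequence",
    "add_demand",
    "set_reaction_bounds",
    "relative_mean_flux",
    "AMINO_ACID_METABOLITES",
]

#: Default mapping of one-letter residue codes to cytosolic metabolite ids
#: (BiGG-style; glycine is achiral hence no L suffix).
AMINO_ACID_METABOLITES: dict[str, str] = {
    "A": "ala__L_c", "R": "arg__L_c", "N": "asn__L_c", "D": "asp__L_c",
    "C": "cys__L_c", "Q": "gln__L_c", "E": "glu__L_c", "G": "gly_c",
    "H": "his__L_c", "I": "ile__L_c", "L": "leu__L_c", "K": "lys__L_c",
    "M": "met__L_c", "F": "phe__L_c", "P": "pro__L_c", "S": "ser__L_c",
    "T": "thr__L_c", "W": "trp__L_c", "Y": "tyr__L_c", "V": "val__L_c",
}


@dataclass(frozen=True)
class LPResult:
    """Outcome of one linear program: status, optimum and flux vector."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class DemandSpec:
    """An artificial sink: consumed metabolite id -> positive coefficient."""

    name: str
    consumed: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def __post_init__(self) -> None:
        if not self.consumed:
            raise ValueError("demand must consume at least one metabolite")
        if any(c <= 0 for c in self.consumed.values()):
            raise ValueError("demand coefficients must be positive")


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba(
    network: MetabolicNetwork,
    objective_id: str | None = None,
    sense: str = "max",
) -> LPResult:
    """Optimise flux through ``objective_id`` (default: the biomass reaction).

    Infeasibility/unboundedness are reported through the status field, not
    raised.
    """
    obj = objective_id or network.objective_id
    rxn_ids = network.reaction_ids
    if obj not in rxn_ids:
        raise KeyError(f"objective reaction {obj!r} not in network")
    S = stoichiometric_matrix(network)
    n = len(rxn_ids)
    c = np.zeros(n)
    sign = -1.0 if sense == "max" else 1.0
    c[rxn_ids.index(obj)] = sign
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return LPResult(status=status)
    fluxes = pd.Series(res.x, index=rxn_ids, name=network.name or "fluxes")
    value = float(-res.fun) if sense == "max" else float(res.fun)
    return LPResult(status="optimal", objective_value=value, fluxes=fluxes)


def flux_variability(network: MetabolicNetwork) -> pd.DataFrame:
    """Per-reaction (min, max) achievable flux with rows of flux vectors.

    Returns a DataFrame indexed by reaction id with columns ``min``/``max``;
    the attaining flux vectors are kept in ``.attrs["vectors"]`` as a
    points x reactions array (2 rows per reaction, min then max).
    """
    S = stoichiometric_matrix(network)
    rxn_ids = network.reaction_ids
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    n = len(rxn_ids)
    vectors = []
    mins, maxs = [], []
    for j in range(n):
        for sign, store in ((1.0, mins), (-1.0, maxs)):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(
                c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
            )
            if res.status != 0:
                raise RuntimeError(
                    f"FVA LP not optimal for {rxn_ids[j]} (status {res.status})"
                )
            store.append(float(sign * res.fun))
            vectors.append(res.x)
    df = pd.DataFrame({"min": mins, "max": maxs}, index=rxn_ids)
    df.attrs["vectors"] = np.array(vectors)
    return df


def apply_rich_media(network: MetabolicNetwork, uptake_magnitude: float = 1000.0,
                     overrides: dict[str, float] | None = None) -> MetabolicNetwork:
    """Open every exchange reaction's uptake to ``-uptake_magnitude``.

    Identical bounds are applied for every condition; ``overrides`` maps
    exchange reaction id to a per-reaction uptake magnitude.
    """
    if uptake_magnitude < 0:
        raise ValueError("uptake magnitude must be non-negative")
    overrides = overrides or {}
    new_bounds = {}
    for r in network.reactions:
        if r.is_exchange:
            mag = overrides.get(r.id, uptake_magnitude)
            new_bounds[r.id] = (-float(mag), r.upper_bound)
    return network.with_bounds(new_bounds)


def read_fasta_sequence(path: str | Path) -> str:
    """First record's sequence from a FASTA file."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def protein_demand_from_sequence(
    sequence: str,
    name: str,
    metabolite_map: dict[str, str] | None = None,
    lower_bound: float = 0.0,
    upper_bound: float = 1000.0,
) -> DemandSpec:
    """Demand consuming free amino acids with residue-count stoichiometry.

    The coefficient of each amino-acid metabolite equals the residue's count
    in the sequence, so coefficients sum to the sequence length.  No
    polymerisation (ATP/GTP) cost is included.
    """
    metabolite_map = metabolite_map or AMINO_ACID_METABOLITES
    seq = sequence.strip().upper()
    unknown = set(seq) - set(AMINO_ACID_METABOLITES)
    if unknown:
        raise UnknownResidueError(
            f"sequence contains non-standard residues {sorted(unknown)}"
        )
    counts = Counter(seq)
    consumed = {metabolite_map[res]: float(cnt) for res, cnt in sorted(counts.items())}
    return DemandSpec(name=name, consumed=consumed,
                      lower_bound=lower_bound, upper_bound=upper_bound)


def add_demand(
    network: MetabolicNetwork, spec: DemandSpec, lower_bound: float | None = None
) -> MetabolicNetwork:
    """Append ``DM_<name>`` consuming the spec's metabolites; original
    reactions are untouched."""
    missing = set(spec.consumed) - set(network.metabolite_ids)
    if missing:
        raise MissingMetaboliteError(
            f"demand {spec.name!r}: metabolites missing from network: {sorted(missing)}"
        )
    lb = spec.lower_bound if lower_bound is None else lower_bound
    demand = Reaction(
        id=f"DM_{spec.name}",
        stoichiometry={m: -c for m, c in spec.consumed.items()},
        lower_bound=lb,
        upper_bound=spec.upper_bound,
        gpr=Gpr(None),
        subsystem="demand",
    )
    return MetabolicNetwork(
        list(network.metabolites),
        list(network.reactions) + [demand],
        network.genes,
        network.objective_id,
        network.name,
    )


def set_reaction_bounds(
    network: MetabolicNetwork, reaction_id: str, lower: float, upper: float
) -> MetabolicNetwork:
    """Copy with one reaction's bounds replaced (e.g. resetting a demand
    floor to 0 after context extraction)."""
    if reaction_id not in set(network.reaction_ids):
        raise KeyError(reaction_id)
    return network.with_bounds({reaction_id: (lower, upper)})


def relative_mean_flux(
    treated: pd.DataFrame, control: pd.DataFrame, reaction_ids: list[str]
) -> pd.DataFrame:
    """mean(treated) / mean(control) per reaction over sampled points.

    Reactions missing from either matrix are flagged ``absent``; a zero
    control mean is flagged ``undefined``.  Columns: ratio, mean_treated,
    mean_control, status.
    """
    rows = []
    for rid in reaction_ids:
        if rid not in treated.columns or rid not in control.columns:
            rows.append((rid, np.nan, np.nan, np.nan, "absent"))
            continue
        mt = float(treated[rid].mean())
        mc = float(control[rid].mean())
        if mc == 0.0:
            rows.append((rid, np.nan, mt, mc, "undefined"))
        else:
            rows.append((rid, mt / mc, mt, mc, "ok"))
    return pd.DataFrame(
        rows, columns=["reaction", "ratio", "mean_treated", "mean_control", "status"]
    ).set_index("reaction")
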