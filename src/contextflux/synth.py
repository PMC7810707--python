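"""Synthetic study generators with planted ground truth.

Three generators emulate the inputs of a multi-toxin transcriptome /
metabolic-model comparison so every pipeline stage can be exercised against
known answers:

* :func:`make_toy_network` — compartmentalised toy networks made of linear
  reaction chains (optionally with parallel-path bypasses).  Each chain is a
  planted fully-coupled reaction set and contributes one steady-state degree
  of freedom; each bypass adds one more.
* :func:`make_expression` — per-condition intensity profiles in which each
  toxin silences a configured gene set (intensities strictly below the
  presence cutoff) while everything else stays callable as present.
* :func:`make_de_tables` — per-toxin differential-expression tables whose
  up/down membership follows configured Venn occupancy strata exactly, with
  per-toxin fold-change location shifts so rank tests have known power.

All generators are pure functions of their spec (seed included); no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import DEGeneRecord, ExpressionProfile, PRESENCE_CUTOFF
from .gpr import Gpr, parse_gpr
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "ToyNetworkSpec",
    "SyntheticStudySpec",
    "NetworkGroundTruth",
    "make_toy_network",
    "make_expression",
    "make_de_tables",
    "toy3",
    "toy_bypass",
]


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyNetworkSpec:
    """Blueprint for a chain-structured toy network.

    chain_lengths: number of internal metabolite-to-metabolite steps per
    chain (>= 2 metabolites each).  compartment_cycle: compartments
    assigned to successive internal metabolites (the chain entry is always
    extracellular).  bypasses: (chain index, step index) pairs that get a
    parallel duplicate reaction with its own gene.  uptake_bound: |lower
    bound| of the first chain's exchange (the biomass bottleneck).
    """

    chain_lengths: tuple[int, ...] = (4,)
    compartment_cycle: tuple[str, ...] = ("c", "c", "m", "m", "r", "g")
    bypasses: tuple[tuple[int, int], ...] = ()
    gpr_style: str = "single"  # "single" | "composite"
    uptake_bound: float = 10.0
    internal_bound: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.chain_lengths):
            raise ValueError("chain lengths must be >= 2")
        for chain, step in self.bypasses:
            if chain >= len(self.chain_lengths):
                raise ValueError(f"bypass on nonexistent chain {chain}")
            if step >= self.chain_lengths[chain] - 1:
                raise ValueError(f"bypass on nonexistent step {step} of chain {chain}")


@dataclass(frozen=True)
class NetworkGroundTruth:
    """What the generator planted: fully-coupled reaction sets, the
    null-space dimension, per-compartment metabolite totals, the biomass
    optimum, and which gene gates each reaction."""

    coupled_sets: tuple[frozenset[str], ...]
    nullspace_dim: int
    compartment_totals: dict[str, int]
    max_biomass: float
    reaction_genes: dict[str, frozenset[str]]


def make_toy_network(spec: ToyNetworkSpec) -> tuple[MetabolicNetwork, NetworkGroundTruth]:
    """Build the network and its planted ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    genes: set[str] = set()
    coupled: list[frozenset[str]] = []
    reaction_genes: dict[str, frozenset[str]] = {}
    bypass_of: dict[int, list[int]] = {}
    for chain, step in spec.bypasses:
        bypass_of.setdefault(chain, []).append(step)

    def gpr_for(rid: str) -> Gpr:
        if spec.gpr_style == "composite" and rng.random() < 0.5:
            g1, g2 = f"g_{rid}_a", f"g_{rid}_b"
            genes.update((g1, g2))
            op = "or" if rng.random() < 0.5 else "and"
            gpr = parse_gpr(f"{g1} {op} {g2}")
        else:
            g = f"g_{rid}"
            genes.add(g)
            gpr = parse_gpr(g)
        reaction_genes[rid] = gpr.genes()
        return gpr

    for ci, length in enumerate(spec.chain_lengths):
        comps = ["e"] + [
            spec.compartment_cycle[j % len(spec.compartment_cycle)]
            for j in range(length - 1)
        ]
        met_ids = [f"m{ci}_{j}_{comps[j]}" for j in range(length)]
        for mid, comp in zip(met_ids, comps):
            metabolites.append(Metabolite(id=mid, compartment=comp))

        ex_id = f"EX_chain{ci}"
        uptake = spec.uptake_bound if ci == 0 else spec.internal_bound
        reactions.append(
            Reaction(
                id=ex_id,
                stoichiometry={met_ids[0]: -1.0},
                lower_bound=-uptake,
                upper_bound=spec.internal_bound,
                is_exchange=True,
            )
        )
        chain_rxns = [ex_id]
        uncoupled_steps = set(bypass_of.get(ci, []))
        for j in range(length - 1):
            rid = f"R{ci}_{j}"
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry={met_ids[j]: -1.0, met_ids[j + 1]: 1.0},
                    lower_bound=0.0,
                    upper_bound=spec.internal_bound,
                    gpr=gpr_for(rid),
                )
            )
            if j not in uncoupled_steps:
                chain_rxns.append(rid)
            else:
                bid = f"R{ci}_{j}b"
                reactions.append(
                    Reaction(
                        id=bid,
                        stoichiometry={met_ids[j]: -1.0, met_ids[j + 1]: 1.0},
                        lower_bound=0.0,
                        upper_bound=spec.internal_bound,
                        gpr=gpr_for(bid),
                    )
                )
        if ci == 0:
            sink_id = "BIOMASS"
            reactions.append(
                Reaction(
                    id=sink_id,
                    stoichiometry={met_ids[-1]: -1.0},
                    lower_bound=0.0,
                    upper_bound=spec.internal_bound,
                )
            )
        else:
            sink_id = f"SINK_chain{ci}"
            reactions.append(
                Reaction(
                    id=sink_id,
                    stoichiometry={met_ids[-1]: -1.0},
                    lower_bound=0.0,
                    upper_bound=spec.internal_bound,
                    is_exchange=True,
                )
            )
        chain_rxns.append(sink_id)
        if len(chain_rxns) >= 2:
            coupled.append(frozenset(chain_rxns))

    network = MetabolicNetwork(
        metabolites,
        reactions,
        frozenset(genes),
        "BIOMASS",
        name=f"toy_seed{spec.seed}",
    )
    totals: dict[str, int] = {}
    for m in metabolites:
        totals[m.compartment] = totals.get(m.compartment, 0) + 1
    truth = NetworkGroundTruth(
        coupled_sets=tuple(coupled),
        nullspace_dim=len(spec.chain_lengths) + len(spec.bypasses),
        compartment_totals=totals,
        max_biomass=min(spec.uptake_bound, spec.internal_bound),
        reaction_genes=reaction_genes,
    )
    return network, truth


def toy3() -> MetabolicNetwork:
    """The 5-metabolite / 6-reaction linear chain used throughout the docs:
    A is taken up, converted to B in the cytosol, shuttled into the
    mitochondrion and converted to C, which feeds the biomass sink."""
    mets = [
        Metabolite("A_e", "e"),
        Metabolite("A_c", "c"),
        Metabolite("B_c", "c"),
        Metabolite("B_m", "m"),
        Metabolite("C_m", "m"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g1")),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g2")),
        Reaction("T_B", {"B_c": -1.0, "B_m": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g3")),
        Reaction("R2", {"B_m": -1.0, "C_m": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g4")),
        Reaction("BIOMASS", {"C_m": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns, frozenset({"g1", "g2", "g3", "g4"}), "BIOMASS", name="TOY3")


def toy_bypass() -> MetabolicNetwork:
    """TOY3 plus a parallel cytosolic A->B path (gene g2b), giving the
    network a second steady-state degree of freedom."""
    base = toy3()
    rxns = list(base.reactions)
    rxns.insert(3, Reaction("R1b", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g2b")))
    return MetabolicNetwork(
        list(base.metabolites),
        rxns,
        frozenset(base.genes | {"g2b"}),
        "BIOMASS",
        name="TOY-BYPASS",
    )


# ---------------------------------------------------------------------------
# Expression profiles and DE tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStudySpec:
    """Conditions, silenced genes and DE-table structure for one study.

    silenced: per-toxin gene sets driven below the presence cutoff.
    up_strata / down_strata: target Venn occupancy counts keyed by the
    tuple of toxin indices sharing the genes (e.g. ``(0,)`` exclusive to
    the first toxin, ``(0, 1, 2)`` common to all three).
    fold_shift: per-toxin location shift of log fold-change magnitudes
    beyond the DE thresholds; unequal shifts give rank tests known power.
    """

    toxins: tuple[str, ...] = ("toxinA", "toxinB", "toxinC")
    control: str = "control"
    silenced: dict[str, frozenset[str]] = field(default_factory=dict)
    n_genes: int = 500
    up_strata: dict[tuple[int, ...], int] = field(
        default_factory=lambda: {(0,): 100, (1,): 40, (2,): 40, (0, 1, 2): 20}
    )
    down_strata: dict[tuple[int, ...], int] = field(
        default_factory=lambda: {(0,): 50, (1,): 20, (2,): 20, (0, 1, 2): 10}
    )
    fold_shift: tuple[float, ...] = (0.6, 0.15, 0.15)
    fold_sigma: float = 0.4
    presence_cutoff: float = PRESENCE_CUTOFF
    present_median: float = 100.0
    silenced_median: float = 3.0
    intensity_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fold_shift) != len(self.toxins):
            raise ValueError("need one fold_shift per toxin")
        n_de = sum(self.up_strata.values()) + sum(self.down_strata.values())
        if n_de > self.n_genes:
            raise ValueError(
                f"stratum counts ({n_de}) exceed the gene universe ({self.n_genes})"
            )
        for strata in (self.up_strata, self.down_strata):
            for key, count in strata.items():
                if count < 0:
                    raise ValueError("stratum counts must be non-negative")
                if any(i >= len(self.toxins) for i in key):
                    raise ValueError(f"stratum {key} references unknown toxin index")


def make_expression(
    spec: SyntheticStudySpec, network: MetabolicNetwork
) -> dict[str, ExpressionProfile]:
    """One intensity profile per condition over the network's gene universe.

    Silenced genes get intensities strictly below the presence cutoff; all
    other genes land at or above it, so presence calls are deterministic
    even though the intensities themselves vary with the seed.
    """
    for toxin, silenced in spec.silenced.items():
        unknown = set(silenced) - set(network.genes)
        if unknown:
            raise ValueError(f"{toxin}: silenced genes not in network: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    genes = sorted(network.genes)
    profiles: dict[str, ExpressionProfile] = {}
    for condition in (spec.control, *spec.toxins):
        silenced = set(spec.silenced.get(condition, frozenset()))
        intensities: dict[str, float] = {}
        for g in genes:
            if g in silenced:
                raw = spec.silenced_median * rng.lognormal(0.0, spec.intensity_sigma)
                intensities[g] = float(min(raw, spec.presence_cutoff * 0.95))
            else:
                raw = spec.present_median * rng.lognormal(0.0, spec.intensity_sigma)
                intensities[g] = float(max(raw, spec.presence_cutoff))
        profiles[condition] = ExpressionProfile(condition=condition, intensities=intensities)
    return profiles


def _assign_strata(
    gene_pool: list[str],
    strata: dict[tuple[int, ...], int],
    start: int,
) -> tuple[dict[str, tuple[int, ...]], int]:
    membership: dict[str, tuple[int, ...]] = {}
    pos = start
    for key in sorted(strata, key=lambda k: (len(k), k)):
        for _ in range(strata[key]):
            membership[gene_pool[pos]] = key
            pos += 1
    return membership, pos


def make_de_tables(spec: SyntheticStudySpec) -> dict[str, list[DEGeneRecord]]:
    """Per-toxin DE tables over a shared synthetic gene universe.

    Thresholding each table (fold > 1.75 / < 0.55, p <= 0.05, q < 0.1) and
    Venn-partitioning the resulting up (resp. down) sets recovers the
    configured strata exactly; fold-change magnitudes carry the per-toxin
    location shifts.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    up_members, pos = _assign_strata(genes, spec.up_strata, 0)
    down_members, _ = _assign_strata(genes, spec.down_strata, pos)
    max_shift = max(spec.fold_shift)

    tables: dict[str, list[DEGeneRecord]] = {}
    for ti, toxin in enumerate(spec.toxins):
        shift = spec.fold_shift[ti]
        # a larger shift moves the toxin's whole fold distribution up in
        # rank: up-folds further above the threshold, down-folds closer to
        # it (less extreme), so rank effects add instead of cancelling
        down_location = max_shift - shift
        records: list[DEGeneRecord] = []
        for g in genes:
            up_key = up_members.get(g)
            down_key = down_members.get(g)
            if up_key is not None and ti in up_key:
                magnitude = abs(rng.normal(shift, spec.fold_sigma))
                fold = 1.75 * float(np.exp(magnitude)) * 1.001
                p = float(rng.uniform(1e-4, 0.05))
                q = float(rng.uniform(1e-3, 0.099))
            elif down_key is not None and ti in down_key:
                magnitude = abs(rng.normal(down_location, spec.fold_sigma))
                fold = 0.55 / (float(np.exp(magnitude)) * 1.001)
                p = float(rng.uniform(1e-4, 0.05))
                q = float(rng.uniform(1e-3, 0.099))
            else:
                # inside the fold window: fails the DE filter regardless of p
                fold = float(rng.uniform(0.6, 1.6))
                p = float(rng.uniform(0.0, 1.0))
                q = float(rng.uniform(0.0, 1.0))
            records.append(DEGeneRecord(gene=g, fold_change=fold, p_value=p, fdr_q=q))
        tables[toxin] = records
    return tables
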