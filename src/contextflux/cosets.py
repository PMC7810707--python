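"""Correlated reaction sets (co-sets) from sampled fluxes.

Two reactions belong to the same co-set when their sampled fluxes are
(near-)perfectly correlated — they behave as one functional pathway unit.
Grouping is by single-linkage connected components of the graph whose
edges are reaction pairs with |r| >= threshold (default 0.975).  Per-
condition co-set activity is summarised by the representative reaction's
mean |flux| expressed as a percentage of its sum across conditions, and
those percentage profiles are hierarchically clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .sampling import FluxSampleMatrix

__all__ = [
    "CoSet",
    "CoSetProfile",
    "flux_correlation_matrix",
    "build_cosets",
    "large_cosets",
    "coset_relative_profile",
    "cluster_profiles",
]

#: Sampled-flux standard deviation below which a reaction is treated as
#: constant and excluded from correlation.
_VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class CoSet:
    """A correlated reaction set (>= 2 members)."""

    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a co-set needs at least 2 members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def id(self) -> str:
        return min(self.members)


@dataclass
class CoSetProfile:
    """Per-co-set, per-condition representative flux and percentage share."""

    values: pd.DataFrame  # co-set id x condition, representative mean |flux|
    percentages: pd.DataFrame  # same shape, rows summing to 100 where defined
    flagged: dict[str, str] = field(default_factory=dict)


def flux_correlation_matrix(
    matrix: FluxSampleMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlations over sampled points plus the excluded list.

    Zero-variance (constant) reactions cannot be correlated; they are
    dropped from the matrix and returned separately.
    """
    if matrix.n_points < 2:
        raise ValueError("need at least 2 sampled points")
    values = matrix.values
    stds = values.std(axis=0, ddof=0)
    excluded = [str(c) for c in values.columns[stds <= _VARIANCE_TOL]]
    kept = [c for c in values.columns if c not in set(excluded)]
    if not kept:
        return pd.DataFrame(index=[], columns=[]), excluded
    corr = np.corrcoef(values[kept].to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=kept, columns=kept), excluded


def build_cosets(
    correlation: pd.DataFrame,
    threshold: float = 0.975,
    signed: bool = False,
) -> tuple[list[frozenset[str]], list[str]]:
    """Single-linkage components of the |r| >= threshold graph.

    Returns (co-sets of size >= 2 sorted by id, singleton reaction ids).
    With ``signed`` only positive correlations r >= threshold link
    reactions (anticorrelated pairs are then kept apart).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ids = list(correlation.index)
    if not ids:
        return [], []
    r = correlation.to_numpy()
    adj = (r >= threshold) if signed else (np.abs(r) >= threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    groups: dict[int, set[str]] = {}
    for rid, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(rid)
    cosets = sorted(
        (frozenset(g) for g in groups.values() if len(g) >= 2), key=min
    )
    singletons = sorted(rid for g in groups.values() if len(g) == 1 for rid in g)
    return cosets, singletons


def large_cosets(cosets: list[CoSet] | list[frozenset[str]], min_size: int = 6):
    """Co-sets with at least ``min_size`` members, order preserved."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    return [c for c in cosets if len(getattr(c, "members", c)) >= min_size]


def assign_representatives(
    cosets: list[frozenset[str]],
    control: FluxSampleMatrix,
    others: list[FluxSampleMatrix] | None = None,
) -> list[CoSet]:
    """Pick each co-set's representative: the member with the largest mean
    |flux| in the control condition that exists in every condition."""
    others = others or []
    shared = set(control.reaction_ids)
    for m in others:
        shared &= set(m.reaction_ids)
    means = control.values.abs().mean(axis=0)
    out = []
    for members in cosets:
        candidates = sorted(members & shared) or sorted(members)
        rep = max(candidates, key=lambda rid: (means.get(rid, -np.inf), rid))
        out.append(CoSet(members=members, representative=rep))
    return out


def coset_relative_profile(
    cosets: list[CoSet],
    matrices: dict[str, FluxSampleMatrix],
) -> CoSetProfile:
    """Representative mean |flux| per condition, as percentages of the
    cross-condition sum.

    A co-set whose representative is missing from a condition contributes 0
    there and is flagged; an all-zero row has undefined percentages (NaN)
    and is flagged.
    """
    conditions = list(matrices)
    rows, flagged = {}, {}
    for cs in cosets:
        vals = []
        for cond in conditions:
            m = matrices[cond]
            if cs.representative in m.values.columns:
                vals.append(float(m.values[cs.representative].abs().mean()))
            else:
                vals.append(0.0)
                flagged[cs.id] = f"representative absent in {cond}"
        rows[cs.id] = vals
    values = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
    sums = values.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        percentages = values.div(sums, axis=0) * 100.0
    for cs_id in values.index[sums == 0]:
        flagged[cs_id] = "all-zero flux across conditions"
        percentages.loc[cs_id] = np.nan
    return CoSetProfile(values=values, percentages=percentages, flagged=flagged)


def cluster_profiles(profile: CoSetProfile) -> dict:
    """Average-linkage agglomerative clustering of percentage profiles
    (Euclidean distance).  Rows are pre-sorted by co-set id so the result
    is deterministic; all-NaN rows are left out.

    Returns {"ids": leaf-ordered co-set ids, "linkage": scipy linkage
    matrix as nested lists}.
    """
    data = profile.percentages.dropna().sort_index()
    if len(data) == 0:
        raise ValueError("no defined profiles to cluster")
    if len(data) == 1:
        return {"ids": list(data.index), "linkage": []}
    Z = linkage(data.to_numpy(), method="average", metric="euclidean")
    order = leaves_list(Z)
    return {
        "ids": [data.index[i] for i in order],
        "linkage": [[float(x) for x in row] for row in Z],
    }
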