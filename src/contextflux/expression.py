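"""Expression presence calls, differential-expression thresholding and
cross-condition comparison statistics.

Presence/absence is a hard intensity cutoff (default 11, boundary
inclusive).  DE calling applies linear fold-change thresholds (> 1.75 up,
< 0.55 down, both strict) together with p <= 0.05 and FDR q < 0.1 filters.
Fold-change distributions across toxins are compared with a tie-corrected
Kruskal-Wallis H test and Dunn's post-hoc pairwise z tests with Bonferroni
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionProfile",
    "DEGeneRecord",
    "call_presence",
    "call_de",
    "venn_partition",
    "kruskal_wallis",
    "dunn_posthoc",
    "read_expression_tsv",
    "read_de_tsv",
    "write_venn_tsv",
]

#: Default microarray-intensity presence cutoff.
PRESENCE_CUTOFF = 11.0


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-condition gene intensities (non-negative, arbitrary units)."""

    condition: str
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.intensities.items() if v < 0]
        if bad:
            raise ValueError(f"negative intensities for genes {bad[:5]}")


@dataclass(frozen=True)
class DEGeneRecord:
    """One gene's differential-expression evidence (linear fold change
    treated/control, raw p, FDR q)."""

    gene: str
    fold_change: float
    p_value: float
    fdr_q: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.gene}: fold change must be positive")


def call_presence(profile: ExpressionProfile, cutoff: float = PRESENCE_CUTOFF) -> dict[str, bool]:
    """Gene -> present flag; a gene is present iff intensity >= cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return {g: v >= cutoff for g, v in profile.intensities.items()}


def call_de(
    records: Iterable[DEGeneRecord],
    up_threshold: float = 1.75,
    down_threshold: float = 0.55,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> tuple[set[str], set[str]]:
    """Partition genes into (up-regulated, down-regulated) sets.

    Up: fold > up_threshold (strict); down: fold < down_threshold (strict);
    both additionally require p <= p_max and q < q_max.  The two sets are
    disjoint by construction since up_threshold > down_threshold.
    """
    if up_threshold <= 0 or down_threshold <= 0 or up_threshold <= down_threshold:
        raise ValueError("need up_threshold > down_threshold > 0")
    up: set[str] = set()
    down: set[str] = set()
    for rec in records:
        if rec.p_value > p_max or rec.fdr_q >= q_max:
            continue
        if rec.fold_change > up_threshold:
            up.add(rec.gene)
        elif rec.fold_change < down_threshold:
            down.add(rec.gene)
    return up, down


def venn_partition(sets: Sequence[set]) -> dict[frozenset[int], int]:
    """Occupancy-stratum counts for k >= 2 sets.

    Returns a map from the frozenset of member set indices (e.g.
    ``frozenset({0, 2})``) to the number of elements belonging to exactly
    those sets.  The 2^k - 1 strata are disjoint and cover the union;
    strata with zero elements are included with count 0.
    """
    k = len(sets)
    if k < 2:
        raise ValueError("venn_partition needs at least 2 sets")
    counts: dict[frozenset[int], int] = {}
    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            counts[frozenset(combo)] = 0
    for element in set().union(*sets):
        stratum = frozenset(i for i in range(k) if element in sets[i])
        counts[stratum] += 1
    return counts


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and chi-square p value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # every observation identical: H = 0, no evidence of difference
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons with Bonferroni adjustment.

    For groups i, j with mean mid-ranks Rbar_i, Rbar_j over the pooled
    sample of size N::

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for ties.  Adjusted
    p = min(1, raw two-sided p x number of pairs).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    variance_base = n * (n + 1) / 12.0 - tie_term

    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, p_raw * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, condition: str) -> ExpressionProfile:
    """Read a two-column TSV (gene, intensity) with header."""
    df = pd.read_csv(path, sep="\t")
    gene_col, value_col = df.columns[0], df.columns[1]
    return ExpressionProfile(
        condition=condition,
        intensities=dict(zip(df[gene_col].astype(str), df[value_col].astype(float))),
    )


def read_de_tsv(path: str | Path) -> list[DEGeneRecord]:
    """Read a DE table TSV with columns gene, fold_change, p_value, fdr_q."""
    df = pd.read_csv(path, sep="\t")
    return [
        DEGeneRecord(
            gene=str(row["gene"]),
            fold_change=float(row["fold_change"]),
            p_value=float(row["p_value"]),
            fdr_q=float(row["fdr_q"]),
        )
        for _, row in df.iterrows()
    ]


def write_venn_tsv(
    counts: dict[frozenset[int], int], labels: Sequence[str], path: str | Path
) -> None:
    lines = ["stratum\tcount"]
    order = sorted(counts, key=lambda s: (len(s), sorted(s)))
    for stratum in order:
        name = "&".join(labels[i] for i in sorted(stratum))
        lines.append(f"{name}\t{counts[stratum]}")
    Path(path).write_text("\n".join(lines) + "\n")
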