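"""Differential reaction-flux calling between conditions.

Each reaction shared by a treated and an untreated flux-sample matrix is
tested (Welch or index-paired t-test); significance requires the Bonferroni-
adjusted p below alpha, at least a ``min_fold`` difference between the
absolute mean fluxes, and both |means| below a magnitude ceiling that
screens out numerically extreme, near-unbounded fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import venn_partition
from .sampling import FluxSampleMatrix

__all__ = ["DiffFluxConfig", "DiffFluxRecord", "differential_reactions", "significant_set_venn"]


@dataclass(frozen=True)
class DiffFluxConfig:
    alpha: float = 0.05
    min_fold: float = 2.0
    magnitude_ceiling: float = 1000.0
    pairing: str = "unpaired-welch"  # or "paired-by-index"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")
        if self.pairing not in ("unpaired-welch", "paired-by-index"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")


@dataclass(frozen=True)
class DiffFluxRecord:
    reaction: str
    mean_treated: float
    mean_untreated: float
    fold: float  # ratio of larger to smaller |mean|; inf when one mean is 0
    p_raw: float | None
    tested: bool
    significant: bool
    reasons: tuple[str, ...] = ()

    def recompute_flag(self, config: DiffFluxConfig, n_tested: int) -> bool:
        """Re-derive the significance flag from the record's own fields."""
        if not self.tested or self.p_raw is None:
            return False
        return (
            self.p_raw < config.alpha / n_tested
            and self.fold >= config.min_fold
            and abs(self.mean_treated) < config.magnitude_ceiling
            and abs(self.mean_untreated) < config.magnitude_ceiling
        )


def _fold_ratio(m1: float, m2: float, zero_tol: float) -> float:
    a, b = abs(m1), abs(m2)
    lo, hi = min(a, b), max(a, b)
    if hi <= zero_tol:
        return 1.0  # both effectively zero: no fold difference
    if lo <= zero_tol:
        return np.inf
    return hi / lo


def differential_reactions(
    treated: FluxSampleMatrix,
    untreated: FluxSampleMatrix,
    config: DiffFluxConfig | None = None,
    zero_tol: float = 1e-7,
) -> tuple[list[DiffFluxRecord], int]:
    """Per-shared-reaction comparison; returns (records, n_tested).

    The Bonferroni denominator is the number of reactions actually tested
    (shared with nonzero variance in at least one group).
    """
    config = config or DiffFluxConfig()
    shared = [c for c in treated.reaction_ids if c in set(untreated.reaction_ids)]
    if not shared:
        raise ValueError("no shared reactions between the two matrices")
    if config.pairing == "paired-by-index" and treated.n_points != untreated.n_points:
        raise ValueError("paired mode requires equal point counts")

    prelim = []
    for rid in shared:
        x = treated.values[rid].to_numpy()
        y = untreated.values[rid].to_numpy()
        mt, mu = float(x.mean()), float(y.mean())
        if x.std() == 0 and y.std() == 0:
            if mt == mu:
                prelim.append((rid, mt, mu, None, False, ("constant and equal",)))
            else:
                # identical within group but offset between groups: the
                # t statistic is degenerate, treat as p = 0
                prelim.append((rid, mt, mu, 0.0, True, ()))
            continue
        if config.pairing == "paired-by-index":
            stat = stats.ttest_rel(x, y)
        else:
            stat = stats.ttest_ind(x, y, equal_var=False)
        p = float(stat.pvalue)
        if np.isnan(p):
            prelim.append((rid, mt, mu, None, False, ("undefined p",)))
        else:
            prelim.append((rid, mt, mu, p, True, ()))

    n_tested = sum(1 for item in prelim if item[4])
    records = []
    for rid, mt, mu, p, tested, reasons in prelim:
        fold = _fold_ratio(mt, mu, zero_tol)
        sig = False
        why = list(reasons)
        if tested and n_tested > 0:
            if p >= config.alpha / n_tested:
                why.append("not significant after Bonferroni")
            if fold < config.min_fold:
                why.append("fold below threshold")
            if abs(mt) >= config.magnitude_ceiling or abs(mu) >= config.magnitude_ceiling:
                why.append("mean flux above magnitude ceiling")
            sig = not why
        records.append(
            DiffFluxRecord(
                reaction=rid,
                mean_treated=mt,
                mean_untreated=mu,
                fold=fold,
                p_raw=p,
                tested=tested,
                significant=sig,
                reasons=tuple(why),
            )
        )
    return records, n_tested


def significant_set_venn(per_toxin_sets: dict[str, set[str]]) -> dict[frozenset[int], int]:
    """Occupancy strata of the per-toxin significant reaction sets
    (delegates to :func:`contextflux.expression.venn_partition`; indices
    follow the sorted toxin labels)."""
    labels = sorted(per_toxin_sets)
    return venn_partition([per_toxin_sets[lab] for lab in labels])


def records_to_frame(records: list[DiffFluxRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction": r.reaction,
                "mean_treated": r.mean_treated,
                "mean_untreated": r.mean_untreated,
                "fold": r.fold,
                "p_raw": r.p_raw,
                "tested": r.tested,
                "significant": r.significant,
                "reasons": ";".join(r.reasons),
            }
            for r in records
        ]
    ).set_index("reaction")
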