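"""Artificially-centred hit-and-run (ACHR) sampling of the steady-state
flux polytope.

The polytope is {v : S.v = 0, lb <= v <= ub}.  Points are parametrised in
an orthonormal basis N of null(S) as v = N.alpha, so every emitted sample
satisfies the steady-state constraint to machine precision by construction;
only the box bounds constrain the chord search.  Warm-up points are the
flux-variability (per-reaction min/max) vertices.  Each step picks a random
warm-up-or-accepted point, takes the direction from the running centre
through it, and moves a uniform distance along the feasible chord — the
"artificial centring" that adapts directions to the polytope's shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .errors import SamplingError
from .fba import flux_variability
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "SamplerConfig",
    "FluxSampleMatrix",
    "warmup_points",
    "achr_sample",
    "merge_samples",
    "apply_cutoff",
]


@dataclass(frozen=True)
class SamplerConfig:
    """points: samples to emit; burn-in steps are discarded; thinning keeps
    every t-th accepted point; cutoff zeroes |flux| below it afterwards."""

    points: int = 5000
    burn_in: int = 0
    thinning: int = 1
    seed: int = 0
    cutoff: float = 1e-7

    def __post_init__(self) -> None:
        if self.points < 1:
            raise ValueError("points must be >= 1")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class FluxSampleMatrix:
    """points x reactions sampled fluxes for one condition."""

    condition: str
    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_points(self) -> int:
        return len(self.values)


def warmup_points(model: MetabolicNetwork) -> np.ndarray:
    """FVA min/max flux vectors, deduplicated: shape (n_points, n_reactions).

    Raises :class:`SamplingError` for an infeasible model.
    """
    try:
        fva = flux_variability(model)
    except RuntimeError as exc:
        raise SamplingError(f"warmup failed: {exc}") from exc
    vectors = fva.attrs["vectors"]
    _, idx = np.unique(np.round(vectors, 9), axis=0, return_index=True)
    return vectors[np.sort(idx)]


def achr_sample(
    model: MetabolicNetwork, config: SamplerConfig | None = None
) -> FluxSampleMatrix:
    """Sample the model's flux polytope; deterministic given the seed.

    The numerical cutoff is *not* applied here (see :func:`apply_cutoff`),
    so feasibility of the raw points can be asserted downstream.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    rxn_ids = model.reaction_ids
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    S = stoichiometric_matrix(model)
    N = null_space(S)  # orthonormal, possibly 0 columns
    warm_v = warmup_points(model)

    if N.shape[1] == 0:
        # fully determined fluxes: the polytope is a single point
        point = warm_v[0]
        values = np.tile(point, (config.points, 1))
        return _package(model.name, rxn_ids, values, config, warm_v.shape[0])

    # project warmup onto the null-space coordinates; this also scrubs the
    # LP solver's tiny steady-state residuals
    alphas = warm_v @ N  # (n_warm, k)
    centre = alphas.mean(axis=0)
    pool = [a for a in alphas]
    n_pool_fixed = len(pool)

    samples = np.empty((config.points, len(rxn_ids)))
    current = alphas[0].copy()
    emitted = 0
    step = 0
    total_steps = config.burn_in + config.points * config.thinning
    n_accepted = 0
    while emitted < config.points:
        direction = None
        for _ in range(64):
            pick = pool[int(rng.integers(0, len(pool)))]
            d = pick - centre
            norm = np.linalg.norm(d)
            if norm > 1e-12:
                direction = d / norm
                break
        if direction is None:
            # degenerate polytope (single point in alpha space)
            new = current
        else:
            v = N @ current
            dv = N @ direction
            t_lo, t_hi = -np.inf, np.inf
            mask = np.abs(dv) > 1e-11
            with np.errstate(divide="ignore"):
                lo = (lb[mask] - v[mask]) / dv[mask]
                hi = (ub[mask] - v[mask]) / dv[mask]
            lows = np.minimum(lo, hi)
            highs = np.maximum(lo, hi)
            if lows.size:
                t_lo = float(lows.max())
                t_hi = float(highs.min())
            # the current point is feasible, so 0 lies in [t_lo, t_hi] up to
            # round-off; clamp to protect against drift and degenerate chords
            t_lo, t_hi = min(t_lo, 0.0), max(t_hi, 0.0)
            if not (np.isfinite(t_lo) and np.isfinite(t_hi)) or not t_hi - t_lo > 0:
                new = current
            else:
                t = float(rng.uniform(t_lo, t_hi))
                new = current + t * direction
        current = new
        pool.append(current.copy())
        n_accepted += 1
        centre = centre + (current - centre) / (n_pool_fixed + n_accepted)
        step += 1
        if step > config.burn_in and (step - config.burn_in) % config.thinning == 0:
            samples[emitted] = N @ current
            emitted += 1
        if step > total_steps + config.points:  # safety, unreachable normally
            raise SamplingError("sampler failed to emit the requested points")

    return _package(model.name, rxn_ids, samples, config, warm_v.shape[0])


def _package(
    name: str,
    rxn_ids: list[str],
    values: np.ndarray,
    config: SamplerConfig,
    n_warmup: int,
) -> FluxSampleMatrix:
    df = pd.DataFrame(values, columns=rxn_ids)
    return FluxSampleMatrix(
        condition=name,
        values=df,
        provenance={
            "seed": config.seed,
            "points": config.points,
            "burn_in": config.burn_in,
            "thinning": config.thinning,
            "n_warmup": int(n_warmup),
        },
    )


def merge_samples(matrices: list[FluxSampleMatrix], condition: str | None = None) -> FluxSampleMatrix:
    """Concatenate sample rows over the intersection of reaction columns.

    Values are not rescaled: identical uptake conditions across the source
    models make the raw points directly comparable.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    conditions = {m.condition for m in matrices}
    if condition is None:
        if len(conditions) > 1:
            raise ValueError(f"mixed condition labels {sorted(conditions)}")
        condition = matrices[0].condition
    shared = set(matrices[0].reaction_ids)
    for m in matrices[1:]:
        shared &= set(m.reaction_ids)
    if not shared:
        raise ValueError("empty reaction intersection across iteration models")
    # keep the first matrix's column order restricted to the intersection
    columns = [c for c in matrices[0].reaction_ids if c in shared]
    values = pd.concat(
        [m.values[columns] for m in matrices], axis=0, ignore_index=True
    )
    return FluxSampleMatrix(
        condition=condition,
        values=values,
        provenance={"sources": [m.provenance for m in matrices]},
    )


def apply_cutoff(matrix: FluxSampleMatrix, cutoff: float = 1e-7) -> FluxSampleMatrix:
    """Zero all entries with |value| strictly below the cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    values = matrix.values.where(matrix.values.abs() >= cutoff, 0.0)
    return FluxSampleMatrix(
        condition=matrix.condition,
        values=values,
        provenance={**matrix.provenance, "cutoff": cutoff},
    )
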