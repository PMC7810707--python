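"""End-to-end pipeline orchestration.

Stage order: presence calls -> GIMME consensus per condition -> demand
handling -> ACHR sampling of every iteration model -> merge -> numerical
cutoff -> co-sets and profile clustering -> differential flux -> organelle
profiles -> DE comparison.  One master seed deterministically derives every
stage seed, so a config file plus one integer reproduces the whole run
byte-for-byte; the manifest echoes every parameter actually used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosets import (
    assign_representatives,
    build_cosets,
    cluster_profiles,
    coset_relative_profile,
    flux_correlation_matrix,
    large_cosets,
)
from .diffflux import DiffFluxConfig, differential_reactions, records_to_frame, significant_set_venn
from .errors import ConfigurationError
from .expression import (
    call_de,
    call_presence,
    dunn_posthoc,
    kruskal_wallis,
    read_de_tsv,
    read_expression_tsv,
    venn_partition,
    write_venn_tsv,
)
from .fba import (
    add_demand,
    apply_rich_media,
    protein_demand_from_sequence,
    read_fasta_sequence,
    relative_mean_flux,
    set_reaction_bounds,
)
from .gimme import GimmeConfig, gimme_consensus
from .io import read_network
from .organelle import de_reaction_subnetwork, organelle_profile
from .sampling import SamplerConfig, achr_sample, apply_cutoff, merge_samples

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    network_path: str
    network_format: str = "json"
    expression_paths: dict[str, str] = field(default_factory=dict)  # condition -> TSV
    de_table_paths: dict[str, str] = field(default_factory=dict)  # toxin -> TSV
    demand_sequence_path: str | None = None
    control: str = "control"

    presence_cutoff: float = 11.0
    up_threshold: float = 1.75
    down_threshold: float = 0.55
    p_max: float = 0.05
    q_max: float = 0.1
    gimme_fraction: float = 0.5
    gimme_iterations: int = 3
    sampler_points: int = 5000
    numerical_cutoff: float = 1e-7
    coset_threshold: float = 0.975
    coset_min_size: int = 6
    diff_alpha: float = 0.05
    diff_min_fold: float = 2.0
    diff_magnitude_ceiling: float = 1000.0
    diff_pairing: str = "unpaired-welch"
    rich_media_uptake: float = 1000.0
    demand_lower_bound: float = 1e-6
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        paths = [self.network_path, *self.expression_paths.values(), *self.de_table_paths.values()]
        if self.demand_sequence_path:
            paths.append(self.demand_sequence_path)
        for p in paths:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        if self.control not in self.expression_paths:
            raise ConfigurationError(
                f"control condition {self.control!r} missing from expression_paths"
            )

    @property
    def toxins(self) -> list[str]:
        return sorted(c for c in self.expression_paths if c != self.control)


def _stage_seeds(master_seed: int, conditions: list[str]) -> dict[str, int]:
    """Derive one 31-bit seed per named stage from the master seed."""
    names = ["de"] + [f"gimme:{c}" for c in conditions] + [f"sample:{c}" for c in conditions]
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage, writing per-stage artefacts plus a manifest.

    Returns the manifest dict.  Stage failures raise with the failing stage
    named; artefacts written before the failure are retained for debugging.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = [config.control] + config.toxins
    seeds = _stage_seeds(config.master_seed, conditions)
    manifest: dict = {
        "contextflux_version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "stages": {},
    }

    stage = "load-network"
    try:
        network = read_network(config.network_path, config.network_format)
        manifest["stages"][stage] = {
            "metabolites": len(network.metabolites),
            "reactions": len(network.reactions),
        }

        # -- DE comparison -------------------------------------------------
        stage = "de-compare"
        de_up: dict[str, set[str]] = {}
        de_down: dict[str, set[str]] = {}
        pooled_folds: dict[str, list[float]] = {}
        for toxin in sorted(config.de_table_paths):
            records = read_de_tsv(config.de_table_paths[toxin])
            up, down = call_de(
                records,
                config.up_threshold,
                config.down_threshold,
                config.p_max,
                config.q_max,
            )
            de_up[toxin], de_down[toxin] = up, down
            de_genes = up | down
            pooled_folds[toxin] = [r.fold_change for r in records if r.gene in de_genes]
        de_summary: dict = {}
        if len(de_up) >= 2:
            labels = sorted(de_up)
            up_counts = venn_partition([de_up[t] for t in labels])
            down_counts = venn_partition([de_down[t] for t in labels])
            write_venn_tsv(up_counts, labels, out / "de_venn_up.tsv")
            write_venn_tsv(down_counts, labels, out / "de_venn_down.tsv")
            groups = [pooled_folds[t] for t in labels if pooled_folds[t]]
            if len(groups) >= 2:
                h, p = kruskal_wallis(groups)
                de_summary = {"labels": labels, "kw_h": h, "kw_p": p}
                if len(groups) >= 3:
                    dunn = dunn_posthoc(groups)
                    de_summary["dunn"] = dunn.to_dict(orient="records")
                (out / "kw_dunn.json").write_text(json.dumps(de_summary, indent=2) + "\n")
        manifest["stages"][stage] = {
            t: {"up": len(de_up[t]), "down": len(de_down[t])} for t in sorted(de_up)
        }

        # -- organelle profiles --------------------------------------------
        stage = "organelle"
        organelle_rows = []
        for toxin in sorted(de_up):
            for direction, genes in (
                ("up", de_up[toxin]),
                ("down", de_down[toxin]),
                ("combined", de_up[toxin] | de_down[toxin]),
            ):
                rxns = de_reaction_subnetwork(network, genes)
                prof = organelle_profile(network, rxns, direction)
                for code in sorted(prof.counts):
                    organelle_rows.append(
                        {
                            "toxin": toxin,
                            "direction": direction,
                            "compartment": code,
                            "metabolite_count": prof.counts[code],
                            "network_fraction": prof.fractions[code],
                        }
                    )
        if organelle_rows:
            df = pd.DataFrame(organelle_rows).set_index(["toxin", "direction", "compartment"])
            _write_tsv(df.sort_index(), out / "organelle_profiles.tsv")
        manifest["stages"][stage] = {"rows": len(organelle_rows)}

        # -- presence calls -------------------------------------------------
        stage = "presence"
        presence: dict[str, dict[str, bool]] = {}
        for cond in conditions:
            profile = read_expression_tsv(config.expression_paths[cond], cond)
            presence[cond] = call_presence(profile, config.presence_cutoff)
        manifest["stages"][stage] = {
            cond: sum(presence[cond].values()) for cond in conditions
        }

        # -- media and demands ----------------------------------------------
        stage = "demands"
        prepared = apply_rich_media(network, config.rich_media_uptake)
        demand_id = None
        if config.demand_sequence_path:
            seq = read_fasta_sequence(config.demand_sequence_path)
            spec = protein_demand_from_sequence(seq, "protein")
            prepared = add_demand(prepared, spec, lower_bound=config.demand_lower_bound)
            demand_id = "DM_protein"
        manifest["stages"][stage] = {"demand": demand_id}

        # -- GIMME consensus -------------------------------------------------
        stage = "extract"
        contexts = {}
        iteration_models = {}
        for cond in conditions:
            gconf = GimmeConfig(
                required_fraction=config.gimme_fraction,
                iterations=config.gimme_iterations,
                seed=seeds[f"gimme:{cond}"],
            )
            consensus, iters = gimme_consensus(prepared, presence[cond], gconf)
            contexts[cond] = consensus
            iteration_models[cond] = iters
        (out / "context_models.json").write_text(
            json.dumps(
                {
                    cond: {
                        "consensus": contexts[cond].to_dict(),
                        "iterations": [m.to_dict() for m in iteration_models[cond]],
                    }
                    for cond in conditions
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        manifest["stages"][stage] = {
            cond: {
                "retained": len(contexts[cond].retained),
                "floor_verified": contexts[cond].floor_verified,
            }
            for cond in conditions
        }

        # -- sampling --------------------------------------------------------
        stage = "sample"
        merged = {}
        for cond in conditions:
            base_seed = seeds[f"sample:{cond}"]
            matrices = []
            for i, itmodel in enumerate(iteration_models[cond]):
                sub = itmodel.submodel()
                if demand_id is not None and demand_id in set(sub.reaction_ids):
                    # demand floor applies only during extraction
                    sub = set_reaction_bounds(sub, demand_id, 0.0, sub.reaction(demand_id).upper_bound)
                sconf = SamplerConfig(
                    points=config.sampler_points,
                    seed=(base_seed + i) % (2**31 - 1),
                    cutoff=config.numerical_cutoff,
                )
                m = achr_sample(sub, sconf)
                m.condition = cond
                matrices.append(m)
            merged[cond] = apply_cutoff(merge_samples(matrices), config.numerical_cutoff)
            _write_tsv(
                merged[cond].values.round(8),
                out / f"samples_{cond}.tsv",
            )
        manifest["stages"][stage] = {
            cond: {"points": merged[cond].n_points, "reactions": len(merged[cond].reaction_ids)}
            for cond in conditions
        }

        # -- co-sets ----------------------------------------------------------
        stage = "cosets"
        coset_rows = []
        per_condition_cosets = {}
        for cond in conditions:
            corr, excluded = flux_correlation_matrix(merged[cond])
            groups, singletons = build_cosets(corr, config.coset_threshold)
            per_condition_cosets[cond] = groups
            for members in groups:
                cid = min(members)
                for rid in sorted(members):
                    coset_rows.append(
                        {"condition": cond, "coset": cid, "reaction": rid, "size": len(members)}
                    )
            manifest["stages"].setdefault(stage, {})[cond] = {
                "cosets": len(groups),
                "singletons": len(singletons),
                "excluded_constant": len(excluded),
                "large_cosets": len(large_cosets(groups, config.coset_min_size)),
            }
        if coset_rows:
            df = pd.DataFrame(coset_rows).set_index(["condition", "coset", "reaction"])
            _write_tsv(df.sort_index(), out / "cosets.tsv")

        control_groups = per_condition_cosets[config.control]
        clustering = None
        if control_groups:
            reps = assign_representatives(
                control_groups,
                merged[config.control],
                [merged[c] for c in config.toxins],
            )
            profile = coset_relative_profile(reps, merged)
            _write_tsv(profile.percentages.sort_index(), out / "coset_profile.tsv")
            defined = profile.percentages.dropna()
            if len(defined) >= 1:
                clustering = cluster_profiles(profile)
                (out / "coset_clustering.json").write_text(
                    json.dumps(clustering, indent=2) + "\n"
                )

        # -- differential flux -------------------------------------------------
        stage = "diff-flux"
        dconf = DiffFluxConfig(
            alpha=config.diff_alpha,
            min_fold=config.diff_min_fold,
            magnitude_ceiling=config.diff_magnitude_ceiling,
            pairing=config.diff_pairing,
        )
        significant_sets: dict[str, set[str]] = {}
        for toxin in config.toxins:
            records, n_tested = differential_reactions(
                merged[toxin], merged[config.control], dconf
            )
            frame = records_to_frame(records).sort_index()
            _write_tsv(frame, out / f"diffflux_{toxin}.tsv")
            significant_sets[toxin] = {r.reaction for r in records if r.significant}
            manifest["stages"].setdefault(stage, {})[toxin] = {
                "tested": n_tested,
                "significant": len(significant_sets[toxin]),
            }
            rel = relative_mean_flux(
                merged[toxin].values,
                merged[config.control].values,
                sorted(set(merged[toxin].reaction_ids) | set(merged[config.control].reaction_ids)),
            )
            _write_tsv(rel.sort_index(), out / f"relative_flux_{toxin}.tsv")
        if len(significant_sets) >= 2:
            counts = significant_set_venn(significant_sets)
            write_venn_tsv(counts, sorted(significant_sets), out / "diffflux_venn.tsv")

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
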