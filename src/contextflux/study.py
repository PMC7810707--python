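"""Write a complete synthetic study to disk in the pipeline's input formats.

The default study is a two-chain toy network with a bypass on the first
chain, four conditions, and three planted perturbations:

* ``toxinA`` silences the first step of the second chain, killing that
  chain's flux — its remaining reactions become planted differential
  reactions (zero flux vs a broad control distribution);
* ``toxinB`` silences the bypassed main step of chain 0, so the context
  model must reroute biomass flux through the parallel path;
* ``toxinC`` silences nothing and should behave like the control.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .expression import DEGeneRecord
from .io import write_json
from .pipeline import PipelineConfig
from .synth import (
    SyntheticStudySpec,
    ToyNetworkSpec,
    make_de_tables,
    make_expression,
    make_toy_network,
)

__all__ = ["write_synthetic_study"]


def write_synthetic_study(
    outdir: str | Path,
    seed: int = 0,
    sampler_points: int = 5000,
    gimme_iterations: int = 3,
) -> tuple[PipelineConfig, dict]:
    """Generate and write network, expression and DE tables plus a ready
    pipeline config; returns (config, planted ground truth)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    net_spec = ToyNetworkSpec(chain_lengths=(5, 4), bypasses=((0, 1),), seed=seed)
    network, truth = make_toy_network(net_spec)

    study = SyntheticStudySpec(
        silenced={
            "toxinA": frozenset({"g_R1_0"}),
            "toxinB": frozenset({"g_R0_1"}),
        },
        seed=seed,
    )
    profiles = make_expression(study, network)
    tables = make_de_tables(study)
    # tie the transcriptome to the model: each toxin's silenced network
    # genes appear as clearly down-regulated records in its DE table, so the
    # organelle-mapping stage sees a non-empty reaction sub-network
    for toxin, records in tables.items():
        silenced = study.silenced.get(toxin, frozenset())
        for gene in sorted(network.genes):
            if gene in silenced:
                records.append(DEGeneRecord(gene=gene, fold_change=0.3,
                                            p_value=0.001, fdr_q=0.01))
            else:
                records.append(DEGeneRecord(gene=gene, fold_change=1.0,
                                            p_value=0.5, fdr_q=0.5))

    write_json(network, out / "network.json")
    expression_paths = {}
    for cond, profile in profiles.items():
        path = out / f"expression_{cond}.tsv"
        pd.DataFrame(
            sorted(profile.intensities.items()), columns=["gene", "intensity"]
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")
        expression_paths[cond] = str(path)
    de_paths = {}
    for toxin, records in tables.items():
        path = out / f"de_{toxin}.tsv"
        pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "fdr_q": r.fdr_q,
                }
                for r in records
            ]
        ).to_csv(path, sep="\t", index=False, float_format="%.8g")
        de_paths[toxin] = str(path)

    config = PipelineConfig(
        network_path=str(out / "network.json"),
        expression_paths=expression_paths,
        de_table_paths=de_paths,
        sampler_points=sampler_points,
        gimme_iterations=gimme_iterations,
        master_seed=seed,
    )
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    # chain 1 downstream of the silenced step: planted differential reactions
    chain1 = next(s for s in truth.coupled_sets if "EX_chain1" in s)
    ground_truth = {
        "coupled_sets": [sorted(s) for s in truth.coupled_sets],
        "nullspace_dim": truth.nullspace_dim,
        "max_biomass": truth.max_biomass,
        "planted_differential": {"toxinA": sorted(chain1 - {"R1_0"})},
        "rerouted_bypass": {"toxinB": {"dropped": "R0_1", "kept": "R0_1b"}},
        "up_strata": {"|".join(map(str, k)): v for k, v in study.up_strata.items()},
        "down_strata": {"|".join(map(str, k)): v for k, v in study.down_strata.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2) + "\n")
    return config, ground_truth
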