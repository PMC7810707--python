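"""Synthetic-data generators: determinism, planted structure, schema
conformance with the pipeline's readers."""

import numpy as np
import pytest

import contextflux as cf
from contextflux.expression import call_de, call_presence, kruskal_wallis, venn_partition
from contextflux.gimme import gimme_extract
from contextflux.synth import (
    SyntheticStudySpec,
    ToyNetworkSpec,
    make_de_tables,
    make_expression,
    make_toy_network,
)


class TestToyNetwork:
    def test_single_chain_ground_truth(self):
        net, truth = make_toy_network(ToyNetworkSpec(chain_lengths=(6,), seed=0))
        assert truth.nullspace_dim == 1
        assert cf.nullspace_dimension(net) == 1
        assert len(truth.coupled_sets) == 1
        # the coupled set spans exchange, every internal step and the sink
        assert {"EX_chain0", "BIOMASS"} <= truth.coupled_sets[0]

    def test_two_chains_two_coupled_sets(self):
        net, truth = make_toy_network(ToyNetworkSpec(chain_lengths=(4, 4), seed=1))
        assert truth.nullspace_dim == 2
        assert cf.nullspace_dimension(net) == 2
        assert len(truth.coupled_sets) == 2

    def test_bypass_adds_degree_of_freedom_and_uncouples_step(self):
        net, truth = make_toy_network(
            ToyNetworkSpec(chain_lengths=(5,), bypasses=((0, 1),), seed=2)
        )
        assert truth.nullspace_dim == 2
        assert cf.nullspace_dimension(net) == 2
        (chain,) = truth.coupled_sets
        assert "R0_1" not in chain and "R0_1b" not in chain

    def test_same_seed_identical_network(self):
        a, _ = make_toy_network(ToyNetworkSpec(seed=5, gpr_style="composite"))
        b, _ = make_toy_network(ToyNetworkSpec(seed=5, gpr_style="composite"))
        assert a.reaction_ids == b.reaction_ids
        assert [r.gpr.to_string() for r in a.reactions] == [
            r.gpr.to_string() for r in b.reactions
        ]

    def test_invalid_bypass_rejected(self):
        with pytest.raises(ValueError):
            ToyNetworkSpec(chain_lengths=(3,), bypasses=((1, 0),))

    def test_compartment_totals_match_network(self):
        net, truth = make_toy_network(ToyNetworkSpec(chain_lengths=(5, 3), seed=3))
        counted = {}
        for m in net.metabolites:
            counted[m.compartment] = counted.get(m.compartment, 0) + 1
        assert counted == truth.compartment_totals

    def test_fba_matches_planted_bottleneck(self):
        net, truth = make_toy_network(ToyNetworkSpec(chain_lengths=(4,), uptake_bound=7.5, seed=4))
        res = cf.fba(net)
        assert res.objective_value == pytest.approx(truth.max_biomass, abs=1e-8)


class TestExpression:
    def _setup(self, seed=0):
        net, _ = make_toy_network(ToyNetworkSpec(chain_lengths=(4, 3), seed=0))
        silenced = frozenset({"g_R1_0"})
        spec = SyntheticStudySpec(silenced={"toxinA": silenced}, seed=seed)
        return net, spec, make_expression(spec, net)

    def test_silenced_genes_called_absent_only_in_their_toxin(self):
        net, spec, profiles = self._setup()
        calls_a = call_presence(profiles["toxinA"])
        calls_ctrl = call_presence(profiles["control"])
        assert not calls_a["g_R1_0"]
        assert calls_ctrl["g_R1_0"]
        assert all(calls_ctrl.values())

    def test_intensity_values_straddle_cutoff_strictly(self):
        _, spec, profiles = self._setup()
        for g, v in profiles["toxinA"].intensities.items():
            if g in spec.silenced["toxinA"]:
                assert v < spec.presence_cutoff
            else:
                assert v >= spec.presence_cutoff

    def test_different_seeds_same_presence_calls(self):
        _, _, p1 = self._setup(seed=1)
        _, _, p2 = self._setup(seed=2)
        assert p1["toxinA"].intensities != p2["toxinA"].intensities
        assert call_presence(p1["toxinA"]) == call_presence(p2["toxinA"])

    def test_unknown_silenced_gene_rejected(self):
        net, _ = make_toy_network(ToyNetworkSpec(seed=0))
        spec = SyntheticStudySpec(silenced={"toxinA": frozenset({"ghost"})})
        with pytest.raises(ValueError):
            make_expression(spec, net)

    def test_silencing_sole_path_forces_inconsistency(self):
        """A silenced gene on an unbypassed chain step leaves GIMME either
        keeping the reaction with positive inconsistency or dropping the
        chain's capability."""
        net, _ = make_toy_network(ToyNetworkSpec(chain_lengths=(4,), seed=0))
        spec = SyntheticStudySpec(silenced={"toxinA": frozenset({"g_R0_1"})})
        profiles = make_expression(spec, net)
        model = gimme_extract(net, call_presence(profiles["toxinA"]))
        assert model.inconsistency > 0
        assert "R0_1" in model.retained  # needed for the biomass floor


class TestDeTables:
    def test_replay_recovers_configured_strata_exactly(self):
        spec = SyntheticStudySpec(
            up_strata={(0,): 50, (1,): 20, (2,): 20, (0, 1, 2): 10},
            down_strata={(0,): 15, (1,): 5, (2,): 5, (0, 1, 2): 3},
            seed=3,
        )
        tables = make_de_tables(spec)
        ups, downs = [], []
        for toxin in spec.toxins:
            up, down = call_de(tables[toxin])
            ups.append(up)
            downs.append(down)
        up_counts = venn_partition(ups)
        assert up_counts[frozenset({0})] == 50
        assert up_counts[frozenset({1})] == 20
        assert up_counts[frozenset({2})] == 20
        assert up_counts[frozenset({0, 1, 2})] == 10
        assert up_counts[frozenset({0, 1})] == 0
        down_counts = venn_partition(downs)
        assert down_counts[frozenset({0})] == 15
        assert down_counts[frozenset({0, 1, 2})] == 3

    def test_kw_power_at_configured_shift(self):
        """Unequal fold-change location shifts: the rank test should reject
        in >= 90% of replicates."""
        rejections = 0
        reps = 40
        for seed in range(reps):
            spec = SyntheticStudySpec(seed=seed)
            tables = make_de_tables(spec)
            groups = []
            for toxin in spec.toxins:
                up, down = call_de(tables[toxin])
                groups.append(
                    [r.fold_change for r in tables[toxin] if r.gene in up | down]
                )
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert rejections / reps >= 0.9

    def test_zero_shift_null_rejection_near_alpha(self):
        """Equal shifts, single-direction tables: group values are iid from
        one distribution, so KW should reject at ~alpha."""
        rejections = 0
        reps = 500
        for seed in range(reps):
            spec = SyntheticStudySpec(
                fold_shift=(0.3, 0.3, 0.3),
                down_strata={},
                seed=seed,
            )
            tables = make_de_tables(spec)
            groups = []
            for toxin in spec.toxins:
                up, down = call_de(tables[toxin])
                groups.append(
                    [r.fold_change for r in tables[toxin] if r.gene in up | down]
                )
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_zero_shift_mixed_directions_never_anticonservative(self):
        """With both directions the per-group up:down ratio is fixed by
        construction (stratified, not iid), which makes KW conservative —
        rejections must stay at or below alpha."""
        rejections = 0
        reps = 100
        for seed in range(reps):
            spec = SyntheticStudySpec(fold_shift=(0.3, 0.3, 0.3), seed=seed)
            tables = make_de_tables(spec)
            groups = []
            for toxin in spec.toxins:
                up, down = call_de(tables[toxin])
                groups.append(
                    [r.fold_change for r in tables[toxin] if r.gene in up | down]
                )
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert rejections / reps <= 0.05

    def test_same_seed_identical_tables(self):
        a = make_de_tables(SyntheticStudySpec(seed=9))
        b = make_de_tables(SyntheticStudySpec(seed=9))
        assert a == b

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudySpec(n_genes=10, up_strata={(0,): 50})
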