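"""Co-set detection against a brute-force union-find oracle, plus profiles
and clustering."""

import numpy as np
import pandas as pd
import pytest

import contextflux as cf
from contextflux.cosets import (
    assign_representatives,
    build_cosets,
    cluster_profiles,
    coset_relative_profile,
    flux_correlation_matrix,
    large_cosets,
)
from contextflux.sampling import FluxSampleMatrix, SamplerConfig


def union_find_oracle(corr: pd.DataFrame, threshold: float):
    """Independent O(n^2) grouping: enumerate every pair, union-find merge."""
    ids = list(corr.index)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in ids:
            if i < j and abs(corr.loc[i, j]) >= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    cosets = sorted((frozenset(g) for g in groups.values() if len(g) >= 2), key=min)
    singles = sorted(i for g in groups.values() if len(g) == 1 for i in g)
    return cosets, singles


def matrix_from(df: pd.DataFrame) -> FluxSampleMatrix:
    return FluxSampleMatrix(condition="test", values=df)


class TestCorrelation:
    def test_coupled_chain_all_correlated(self, toy3_samples):
        corr, excluded = flux_correlation_matrix(toy3_samples)
        assert excluded == []
        assert (np.abs(corr.to_numpy()) > 0.999999).all()

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(15000, 6)), columns=[f"R{i}" for i in range(6)])
        corr, _ = flux_correlation_matrix(matrix_from(df))
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        corr, excluded = flux_correlation_matrix(matrix_from(df))
        assert excluded == ["B"]
        assert list(corr.index) == ["A"]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            flux_correlation_matrix(matrix_from(pd.DataFrame({"A": [1.0]})))


class TestBuildCosets:
    def test_matches_union_find_oracle_on_sampled_networks(self):
        for seed in (0, 1, 2):
            spec = cf.ToyNetworkSpec(chain_lengths=(4, 3), bypasses=((0, 1),), seed=seed)
            net, _ = cf.make_toy_network(spec)
            m = cf.achr_sample(net, SamplerConfig(points=1500, seed=seed))
            corr, _ = flux_correlation_matrix(m)
            assert len(corr) <= 30
            ours = build_cosets(corr, 0.975)
            oracle = union_find_oracle(corr, 0.975)
            assert ours == oracle

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 12
            raw = rng.uniform(-1, 1, size=(n, n))
            corr = (raw + raw.T) / 2
            np.fill_diagonal(corr, 1.0)
            df = pd.DataFrame(corr, index=[f"R{i}" for i in range(n)],
                              columns=[f"R{i}" for i in range(n)])
            assert build_cosets(df, 0.9) == union_find_oracle(df, 0.9)

    def test_single_linkage_transitivity(self):
        ids = ["A", "B", "C"]
        corr = pd.DataFrame(
            [[1.0, 0.98, 0.90], [0.98, 1.0, 0.98], [0.90, 0.98, 1.0]],
            index=ids, columns=ids,
        )
        cosets, singles = build_cosets(corr, 0.975)
        assert cosets == [frozenset({"A", "B", "C"})]
        assert singles == []

    def test_no_pairs_above_threshold(self):
        ids = ["A", "B"]
        corr = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=ids, columns=ids)
        cosets, singles = build_cosets(corr, 0.975)
        assert cosets == [] and singles == ["A", "B"]

    def test_partition_property(self, toy3_samples):
        corr, excluded = flux_correlation_matrix(toy3_samples)
        cosets, singles = build_cosets(corr, 0.975)
        covered = set(singles)
        for cs in cosets:
            assert not (covered & cs)
            covered |= cs
        assert covered == set(corr.index)

    def test_raising_threshold_refines(self):
        rng = np.random.default_rng(3)
        n = 10
        raw = rng.uniform(0, 1, size=(n, n))
        corr = (raw + raw.T) / 2
        np.fill_diagonal(corr, 1.0)
        ids = [f"R{i}" for i in range(n)]
        df = pd.DataFrame(corr, index=ids, columns=ids)
        lo, _ = build_cosets(df, 0.5)
        hi, _ = build_cosets(df, 0.8)
        for fine in hi:
            assert any(fine <= coarse for coarse in lo)

    def test_signed_mode_ignores_anticorrelation(self):
        ids = ["A", "B"]
        corr = pd.DataFrame([[1.0, -0.99], [-0.99, 1.0]], index=ids, columns=ids)
        unsigned, _ = build_cosets(corr, 0.975)
        signed, _ = build_cosets(corr, 0.975, signed=True)
        assert unsigned == [frozenset({"A", "B"})]
        assert signed == []


class TestLargeCosets:
    def test_size_filter_boundary(self):
        sets = [frozenset(f"r{i}{j}" for j in range(n)) for i, n in enumerate([2, 6, 7, 5])]
        kept = large_cosets(sets, 6)
        assert [len(s) for s in kept] == [6, 7]
        assert large_cosets([], 6) == []

    def test_min_size_validated(self):
        with pytest.raises(ValueError):
            large_cosets([], 1)


class TestProfiles:
    def _cosets(self):
        return [cf.CoSet(members=frozenset({"R1", "R2"}), representative="R1")]

    def _mat(self, value, points=4):
        df = pd.DataFrame({"R1": [value] * points, "R2": [value] * points})
        return FluxSampleMatrix(condition="x", values=df)

    def test_equal_values_equal_percentages(self):
        mats = {c: self._mat(2.0) for c in ("control", "a", "b", "d")}
        prof = coset_relative_profile(self._cosets(), mats)
        assert (prof.percentages.loc["R1"] == 25.0).all()

    def test_single_active_condition(self):
        mats = {"control": self._mat(0.0), "a": self._mat(0.0),
                "b": self._mat(0.0), "d": self._mat(6.0)}
        prof = coset_relative_profile(self._cosets(), mats)
        row = prof.percentages.loc["R1"]
        assert row["d"] == 100.0 and row["control"] == 0.0

    def test_all_zero_row_flagged_undefined(self):
        mats = {"control": self._mat(0.0), "a": self._mat(0.0)}
        prof = coset_relative_profile(self._cosets(), mats)
        assert prof.percentages.loc["R1"].isna().all()
        assert "all-zero" in prof.flagged["R1"]

    def test_missing_representative_contributes_zero_and_flagged(self):
        absent = FluxSampleMatrix("a", pd.DataFrame({"other": [1.0, 2.0]}))
        mats = {"control": self._mat(3.0), "a": absent}
        prof = coset_relative_profile(self._cosets(), mats)
        assert prof.values.loc["R1", "a"] == 0.0
        assert "absent" in prof.flagged["R1"]

    def test_representative_choice_largest_control_flux(self, toy3_samples):
        cosets, _ = build_cosets(flux_correlation_matrix(toy3_samples)[0], 0.975)
        reps = assign_representatives(cosets, toy3_samples)
        means = toy3_samples.values.abs().mean()
        for cs in reps:
            assert means[cs.representative] == pytest.approx(
                max(means[m] for m in cs.members)
            )


class TestClustering:
    def _profile(self, rows):
        values = pd.DataFrame.from_dict(rows, orient="index", columns=["c1", "c2", "c3", "c4"])
        perc = values.div(values.sum(axis=1), axis=0) * 100
        return cf.CoSetProfile(values=values, percentages=perc)

    def test_identical_profiles_merge_at_zero(self):
        prof = self._profile({"a": [1, 1, 1, 1], "b": [2, 2, 2, 2]})
        out = cluster_profiles(prof)
        assert out["linkage"][0][2] == pytest.approx(0.0)

    def test_opposite_profiles_separate_last(self):
        prof = self._profile(
            {
                "x": [100, 0, 0, 0],
                "y": [0, 0, 0, 100],
                "u": [25, 25, 25, 25],
                "v": [25, 25, 25, 25],
            }
        )
        out = cluster_profiles(prof)
        # final merge distance corresponds to the extreme pair separation
        distances = [row[2] for row in out["linkage"]]
        assert distances == sorted(distances)
        assert distances[0] == pytest.approx(0.0)  # u/v merge first
        assert distances[-1] > 80

    def test_single_profile_single_leaf(self):
        prof = self._profile({"only": [1, 2, 3, 4]})
        out = cluster_profiles(prof)
        assert out["ids"] == ["only"] and out["linkage"] == []


def test_planted_chains_recovered_for_shipped_seeds():
    """Full sample -> correlate -> group path recovers the planted
    fully-coupled chains for every shipped generator seed."""
    for seed in (0, 1, 2):
        spec = cf.ToyNetworkSpec(chain_lengths=(5, 4), seed=seed)
        net, truth = cf.make_toy_network(spec)
        m = cf.achr_sample(net, SamplerConfig(points=5000, seed=seed + 100))
        corr, _ = flux_correlation_matrix(m)
        cosets, _ = build_cosets(corr, 0.975)
        assert set(cosets) == set(truth.coupled_sets)
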