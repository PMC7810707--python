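"""Presence calling, DE thresholding, Venn partitioning and rank statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from contextflux.expression import (
    DEGeneRecord,
    ExpressionProfile,
    call_de,
    call_presence,
    dunn_posthoc,
    kruskal_wallis,
    read_de_tsv,
    read_expression_tsv,
    venn_partition,
)


def rec(gene, fold, p=0.01, q=0.05):
    return DEGeneRecord(gene=gene, fold_change=fold, p_value=p, fdr_q=q)


class TestPresence:
    def test_cutoff_boundary_inclusive(self):
        profile = ExpressionProfile("c", {"gA": 12.0, "gB": 10.0, "gC": 11.0})
        calls = call_presence(profile, cutoff=11.0)
        assert calls == {"gA": True, "gB": False, "gC": True}

    def test_zero_cutoff_everything_present(self):
        profile = ExpressionProfile("c", {"gA": 0.0, "gB": 5.0})
        assert all(call_presence(profile, cutoff=0.0).values())

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfile("c", {"gA": -1.0})


class TestCallDe:
    def test_threshold_examples(self):
        up, down = call_de(
            [
                rec("u", 2.0),                      # clear up
                rec("b", 1.75),                     # on the boundary: excluded
                rec("pf", 0.5, p=0.2),              # p filter fails
                rec("d", 0.4),                      # clear down
                rec("qf", 3.0, q=0.15),             # FDR filter fails
                rec("db", 0.55),                    # down boundary: excluded
            ]
        )
        assert up == {"u"}
        assert down == {"d"}

    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 20.0),
                st.floats(0.0, 1.0),
                st.floats(0.0, 1.0),
            ),
            max_size=40,
        )
    )
    def test_up_and_down_always_disjoint(self, rows):
        records = [rec(f"g{i}", f, p, q) for i, (f, p, q) in enumerate(rows)]
        up, down = call_de(records)
        assert up & down == set()

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            rec("g", 0.0)


class TestVenn:
    def test_worked_three_set_example(self):
        counts = venn_partition([{"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}])
        assert counts[frozenset({0, 1, 2})] == 1  # {c}
        assert counts[frozenset({0})] == 1  # {a}
        assert counts[frozenset({1})] == 1  # {d}
        assert counts[frozenset({2})] == 1  # {e}
        assert counts[frozenset({0, 1})] == 1  # {b}

    def test_identical_and_disjoint_sets(self):
        same = venn_partition([{1, 2}, {1, 2}, {1, 2}])
        assert same[frozenset({0, 1, 2})] == 2
        assert all(v == 0 for k, v in same.items() if k != frozenset({0, 1, 2}))
        disjoint = venn_partition([{1}, {2, 3}, {4}])
        assert disjoint[frozenset({0, 1, 2})] == 0
        assert disjoint[frozenset({0})] == 1
        assert disjoint[frozenset({1})] == 2

    @given(st.lists(st.sets(st.integers(0, 30)), min_size=2, max_size=4))
    def test_strata_cover_the_union(self, sets):
        counts = venn_partition(sets)
        assert sum(counts.values()) == len(set().union(*sets))

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_permuting_sets_permutes_exclusives(self, a, b, c):
        fwd = venn_partition([a, b, c])
        rev = venn_partition([c, b, a])
        assert fwd[frozenset({0})] == rev[frozenset({2})]
        assert fwd[frozenset({0, 1, 2})] == rev[frozenset({0, 1, 2})]


class TestKruskalWallis:
    def test_worked_example(self):
        # rank-sum formula by hand: 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(1 - stats.chi2.cdf(7.2, df=2))

    def test_identical_groups_have_zero_h(self):
        h, _ = kruskal_wallis([[1, 2, 3]] * 3)
        assert h == 0.0
        h, p = kruskal_wallis([[5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    @given(
        st.lists(st.integers(-50, 50), min_size=3, max_size=10, unique=True),
        st.lists(st.integers(-50, 50), min_size=3, max_size=10, unique=True),
    )
    def test_invariant_under_monotone_transform(self, g1, g2):
        # integer observations: a strictly monotone transform cannot merge
        # distinct values through floating-point underflow
        h1, _ = kruskal_wallis([g1, g2])
        transform = lambda xs: [np.exp(x / 25.0) for x in xs]
        h2, _ = kruskal_wallis([transform(g1), transform(g2)])
        assert h1 == pytest.approx(h2, abs=1e-9)
        assert h1 >= 0


class TestDunn:
    def test_identical_groups_all_adjusted_one(self):
        table = dunn_posthoc([[1, 2, 3]] * 3)
        assert (table["p_adjusted"] == 1.0).all()

    def test_bonferroni_multiplier_three_groups(self):
        table = dunn_posthoc([[1, 2, 3], [4, 5, 6], [2, 3, 4]])
        for _, row in table.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * 3))

    def test_matches_textbook_formula_on_worked_groups(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        table = dunn_posthoc(groups)
        # hand oracle: no ties, N=9; mean ranks 2, 5, 8; var base N(N+1)/12
        n = 9
        base = n * (n + 1) / 12.0
        se = np.sqrt(base * (1 / 3 + 1 / 3))
        expected_z01 = (2 - 5) / se
        row01 = table[(table.group_i == 0) & (table.group_j == 1)].iloc[0]
        assert row01["z"] == pytest.approx(expected_z01)
        expected_p = 2 * stats.norm.sf(abs(expected_z01))
        assert row01["p_raw"] == pytest.approx(expected_p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


def test_tsv_readers(tmp_path):
    ep = tmp_path / "expr.tsv"
    ep.write_text("gene\tintensity\ngA\t12.5\ngB\t3.0\n")
    profile = read_expression_tsv(ep, "control")
    assert profile.intensities == {"gA": 12.5, "gB": 3.0}

    dp = tmp_path / "de.tsv"
    dp.write_text(
        "gene\tfold_change\tp_value\tfdr_q\ngA\t2.5\t0.01\t0.02\ngB\t0.4\t0.3\t0.5\n"
    )
    records = read_de_tsv(dp)
    assert records[0].gene == "gA" and records[0].fold_change == 2.5
    assert records[1].p_value == 0.3
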