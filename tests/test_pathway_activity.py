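import itertools

import numpy as np
import pandas as pd
import pytest

from ithimmune import pathway_activity as pa
from ithimmune.heterogeneity import HIGH_HET, LOW_HET, NORMAL
from ithimmune.io_formats import ExpressionMatrix, GeneSetCollection, Units
from oracles import ssgsea_oracle


def _expr(data, genes, samples, units=Units.LOG2TPM):
    return ExpressionMatrix(
        values=pd.DataFrame(np.asarray(data, dtype=float), index=genes,
                            columns=samples),
        unit_state=units,
    )


class TestGroupMeans:
    def test_arithmetic_mean_and_degenerate_group(self):
        m = _expr([[1, 3, 7], [2, 2, 2]], ["G1", "G2"], ["a", "b", "c"])
        groups = {"a": NORMAL, "b": NORMAL, "c": LOW_HET}
        E = pa.group_mean_expression(m, groups, group_order=(NORMAL, LOW_HET))
        assert E.loc["G1", NORMAL] == 2.0
        assert E.loc["G1", LOW_HET] == 7.0  # single-sample group
        assert (E.loc["G2"] == 2.0).all()

    def test_empty_group_errors(self):
        m = _expr([[1, 2]], ["G1"], ["a", "b"])
        with pytest.raises(ValueError, match="HIGH_HET"):
            pa.group_mean_expression(m, {"a": NORMAL, "b": LOW_HET})


class TestRelativeExpression:
    def test_flat_gene(self):
        E = pd.DataFrame({"n": [2.0], "l": [2.0], "h": [2.0]}, index=["G1"])
        assert (pa.relative_expression(E).loc["G1"] == 1.0).all()

    def test_hand_ratio(self):
        E = pd.DataFrame({"n": [3.0], "l": [2.0], "h": [1.0]}, index=["G1"])
        r = pa.relative_expression(E)
        assert r.loc["G1"].tolist() == [1.5, 1.0, 0.5]

    def test_normalization_identity_and_zero_drop(self):
        rng = np.random.default_rng(2)
        E = pd.DataFrame(rng.random((40, 3)) + 0.1, columns=["n", "l", "h"])
        E.loc[5] = 0.0
        r = pa.relative_expression(E)
        assert 5 not in r.index
        np.testing.assert_allclose(r.mean(axis=1), 1.0, atol=1e-12)


class TestWeightedActivity:
    def test_reciprocal_multiplicity_weight(self):
        sets = GeneSetCollection(
            sets={f"P{i}": (["SHARED"] if i < 4 else ["ONLY"]) + [f"G{i}"]
                  for i in range(20)}
        )
        w = pa.pathway_weights(sets)
        assert w["SHARED"] == pytest.approx(0.25)
        assert w["ONLY"] == pytest.approx(1.0 / 16)
        assert w["G7"] == 1.0

    def test_weighted_mean_hand_example(self):
        # two genes with weights (1, 0.5) and r = (1.2, 0.9):
        # p = (1*1.2 + 0.5*0.9) / 1.5 = 1.1
        sets = GeneSetCollection(sets={"P1": ["A", "B"], "P2": ["B", "C"]})
        r = pd.DataFrame({"j": [1.2, 0.9, 5.0]}, index=["A", "B", "C"])
        p = pa.weighted_pathway_activity(r, sets)
        assert p.loc["P1", "j"] == pytest.approx(1.1)

    def test_flat_expression_gives_unit_scores(self):
        sets = GeneSetCollection(sets={"P1": ["A", "B"], "P2": ["B"]})
        r = pd.DataFrame(1.0, index=["A", "B"], columns=["n", "l", "h"])
        p = pa.weighted_pathway_activity(r, sets)
        assert (p.to_numpy() == 1.0).all()

    def test_weighted_average_bound(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(30)]
        sets = GeneSetCollection(
            sets={f"P{t}": list(rng.choice(genes, size=8, replace=False))
                  for t in range(6)}
        )
        r = pd.DataFrame(rng.random((30, 3)) + 0.2, index=genes,
                         columns=["n", "l", "h"])
        p = pa.weighted_pathway_activity(r, sets)
        for t in p.index:
            sub = r.loc[[g for g in sets[t]]]
            assert (p.loc[t] >= sub.min(axis=0) - 1e-12).all()
            assert (p.loc[t] <= sub.max(axis=0) + 1e-12).all()

    def test_absent_genes_skipped_and_empty_pathway_excluded(self):
        sets = GeneSetCollection(sets={"P1": ["A", "MISSING"], "P2": ["GONE"]})
        r = pd.DataFrame({"j": [2.0]}, index=["A"])
        p = pa.weighted_pathway_activity(r, sets)
        assert p.loc["P1", "j"] == pytest.approx(2.0)
        assert "P2" not in p.index


class TestSsgsea:
    def test_top_gene_singleton(self):
        m = _expr([[3.0], [2.0], [1.0]], ["A", "B", "C"], ["s"])
        sets = GeneSetCollection(sets={"S": ["A"]})
        es = pa.ssgsea(m, sets, alpha=0.0)
        assert es.loc["S", "s"] == pytest.approx(1.5)

    def test_bottom_gene_singleton(self):
        m = _expr([[3.0], [2.0], [1.0]], ["A", "B", "C"], ["s"])
        sets = GeneSetCollection(sets={"S": ["C"]})
        es = pa.ssgsea(m, sets, alpha=0.0)
        assert es.loc["S", "s"] == pytest.approx(-1.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(20)]
        for _ in range(25):
            x = rng.normal(size=20)
            size = int(rng.integers(2, 10))
            members = list(rng.choice(genes, size=size, replace=False))
            m = _expr(x[:, None], genes, ["s"])
            sets = GeneSetCollection(sets={"S": members})
            got = pa.ssgsea(m, sets, alpha=0.25).loc["S", "s"]
            want = ssgsea_oracle(list(x), genes, members, alpha=0.25)
            assert got == pytest.approx(want, abs=1e-9)

    def test_rank_invariance(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=40)
        genes = [f"G{i}" for i in range(40)]
        sets = GeneSetCollection(sets={"S": genes[3:12]})
        m1 = _expr(x[:, None], genes, ["s"])
        m2 = _expr(np.exp(x)[:, None], genes, ["s"])  # strictly increasing
        assert pa.ssgsea(m1, sets).loc["S", "s"] == pytest.approx(
            pa.ssgsea(m2, sets).loc["S", "s"], abs=1e-12
        )

    def test_degenerate_sets_are_nan(self):
        m = _expr([[1.0], [2.0]], ["A", "B"], ["s"])
        sets = GeneSetCollection(sets={"ALL": ["A", "B"], "NONE": ["ZZZ"]})
        es = pa.ssgsea(m, sets)
        assert es.isna().all().all()

    def test_complementary_sets_anticorrelated(self):
        rng = np.random.default_rng(31)
        genes = [f"G{i}" for i in range(30)]
        sets = GeneSetCollection(sets={"TOP": genes[:15], "REST": genes[15:]})
        m = _expr(rng.normal(size=(30, 25)), genes,
                  [f"s{j}" for j in range(25)])
        es = pa.ssgsea(m, sets, alpha=0.0)
        r = np.corrcoef(es.loc["TOP"], es.loc["REST"])[0, 1]
        assert r < -0.95


class TestTrendClassifier:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((3, 2, 1), pa.TrendClass.DEC),
            ((1, 2, 3), pa.TrendClass.INC),
            ((3, 1, 2), pa.TrendClass.DOWN_UP),
            ((2, 1, 3), pa.TrendClass.DOWN_UP),
            ((1, 3, 2), pa.TrendClass.UP_DOWN),
            ((2, 3, 1), pa.TrendClass.UP_DOWN),
        ],
    )
    def test_all_strict_orderings(self, triple, expected):
        assert pa.classify_trend(*triple) is expected

    def test_partition_of_orderings(self):
        counts = {}
        for perm in itertools.permutations([1.0, 2.0, 3.0]):
            cls = pa.classify_trend(*perm)
            counts[cls] = counts.get(cls, 0) + 1
        assert counts == {
            pa.TrendClass.DEC: 1,
            pa.TrendClass.INC: 1,
            pa.TrendClass.DOWN_UP: 2,
            pa.TrendClass.UP_DOWN: 2,
        }

    def test_tie_within_eps_is_undetermined(self):
        assert pa.classify_trend(3, 2, 2) is pa.TrendClass.UNDETERMINED
        assert pa.classify_trend(3.0, 2.0, 1.95, eps=0.1) is (
            pa.TrendClass.UNDETERMINED
        )


class TestGroupDifferences:
    def _scores_and_groups(self, shift, n=30, seed=13):
        rng = np.random.default_rng(seed)
        samples = [f"s{j}" for j in range(3 * n)]
        groups = {s: g for s, g in zip(samples, [NORMAL] * n + [LOW_HET] * n
                                       + [HIGH_HET] * n)}
        base = rng.normal(size=3 * n)
        base[n: 2 * n] += shift
        base[2 * n:] += 2 * shift
        scores = pd.DataFrame([base], index=["P"], columns=samples)
        return scores, groups

    def test_strong_shift_detected(self):
        scores, groups = self._scores_and_groups(shift=3.0)
        res = pa.test_group_differences(scores, groups)
        assert res.loc["P", "kw_p"] < 1e-3
        assert (res.loc["P"].filter(like="wilcoxon") < 0.05).all()

    def test_constant_scores_give_p_one(self):
        samples = [f"s{j}" for j in range(9)]
        groups = dict(zip(samples, [NORMAL] * 3 + [LOW_HET] * 3 + [HIGH_HET] * 3))
        scores = pd.DataFrame([[1.0] * 9], index=["P"], columns=samples)
        res = pa.test_group_differences(scores, groups)
        assert res.loc["P", "kw_p"] == 1.0

    def test_small_group_errors(self):
        scores = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P"],
                              columns=["a", "b", "c"])
        groups = {"a": NORMAL, "b": LOW_HET, "c": HIGH_HET}
        with pytest.raises(ValueError, match="fewer than 2"):
            pa.test_group_differences(scores, groups)


class TestKeyPathwaySelection:
    def test_alpha_zero_selects_nothing(self, cohort, pipeline_result):
        res = pa.select_key_pathways(
            pipeline_result.activity, pipeline_result.pathway_ssgsea,
            pipeline_result.groups, alpha=0.0,
        )
        assert res.selected == []

    def test_k_larger_than_candidates_returns_all(self, pipeline_result):
        res = pa.select_key_pathways(
            pipeline_result.activity, pipeline_result.pathway_ssgsea,
            pipeline_result.groups, k=100,
        )
        assert len(res.selected) == int(res.report["candidate"].sum())

    def test_selection_is_subset_of_decreasing(self, pipeline_result):
        rep = pipeline_result.key_pathways.report
        sel = rep[rep["selected"]]
        assert (sel["trend_activity"] == "DEC").all()
        assert (sel["trend_ssgsea"] == "DEC").all()

    def test_planted_pathways_recovered(self, cohort, pipeline_result):
        assert set(pipeline_result.key_pathways.selected) == (
            cohort.truth.decreasing_pathways
        )
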