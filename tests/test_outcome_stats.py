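import numpy as np
import pandas as pd
import pytest

from ithimmune import outcome_stats as oc
from ithimmune.io_formats import ClinicalTable
from oracles import km_oracle


def _clin(times, events, prefix="s"):
    return ClinicalTable(
        records=pd.DataFrame(
            {
                "sample": [f"{prefix}{i}" for i in range(len(times))],
                "time": times,
                "event": events,
            }
        )
    )


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        clin = _clin(times, events)
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = oc.km_logrank(clin, labels)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_km_matches_product_limit_oracle(self):
        times = [2.0, 5.0, 1.0, 8.0, 3.0]
        events = [1, 1, 1, 1, 1]
        clin = _clin(times, events)
        res = oc.km_logrank(clin, {f"s{i}": "G" for i in range(5)})
        curve = res.curves["G"].set_index("time")["survival"]
        for t, s in km_oracle(times, events):
            assert curve.loc[t] == pytest.approx(s)

    def test_km_with_censoring_matches_oracle(self):
        times = [1.0, 2.0, 2.5, 4.0, 6.0, 7.0]
        events = [1, 0, 1, 1, 0, 1]
        clin = _clin(times, events)
        res = oc.km_logrank(clin, {f"s{i}": "G" for i in range(6)})
        curve = res.curves["G"].set_index("time")["survival"]
        for t, s in km_oracle(times, events):
            assert curve.loc[t] == pytest.approx(s)

    def test_no_events_errors(self):
        clin = _clin([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            oc.km_logrank(clin, {"s0": "A", "s1": "B"})

    def test_missing_clinical_record_errors(self):
        clin = _clin([1.0], [1])
        with pytest.raises(ValueError, match="without clinical"):
            oc.km_logrank(clin, {"s0": "A", "ghost": "B"})


class TestTmbCompare:
    def _tmb(self, values, prefix="s"):
        return pd.DataFrame(
            {"tmb": values}, index=[f"{prefix}{i}" for i in range(len(values))]
        )

    def test_shift_detected(self):
        rng = np.random.default_rng(21)
        a = rng.normal(5, 1, 50)
        b = a + 1.5
        tmb = self._tmb(np.concatenate([a, b]))
        labels = {f"s{i}": (1 if i < 50 else 2) for i in range(100)}
        medians, p, direction = oc.tmb_compare(tmb, labels)
        assert p < 0.05
        assert direction == "2"
        assert medians[2] > medians[1]

    def test_identical_groups_tie(self):
        tmb = self._tmb([3.0, 3.0, 3.0, 3.0])
        labels = {"s0": 1, "s1": 1, "s2": 2, "s3": 2}
        medians, p, direction = oc.tmb_compare(tmb, labels)
        assert p == 1.0
        assert direction == "none"

    def test_more_than_two_subtypes_errors(self):
        tmb = self._tmb([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            oc.tmb_compare(tmb, {"s0": 1, "s1": 2, "s2": 3})


class TestUnivariateCox:
    def _survival_with_effect(self, n, log_hr, seed=0, censor=0.2):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        h = 0.05 * np.exp(log_hr * x)
        t = rng.exponential(1.0 / h)
        cens = rng.random(n) < censor
        obs = np.where(cens, t * rng.random(n), t)
        clin = _clin(obs, (~cens).astype(int))
        scores = pd.DataFrame(
            [x], index=["F"], columns=[f"s{i}" for i in range(n)]
        )
        return clin, scores

    def test_planted_effect_recovered_per_sd(self):
        clin, scores = self._survival_with_effect(800, np.log(2), seed=6)
        res = oc.univariate_cox(clin, scores)
        assert res.loc["F", "log_hr"] == pytest.approx(np.log(2), abs=0.15)
        assert res.loc["F", "risk_class"] == oc.RISK
        assert res.loc["F", "significant"]
        assert res.loc["F", "ci95_low"] < res.loc["F", "hr"] < res.loc["F", "ci95_high"]

    def test_protective_classification(self):
        clin, scores = self._survival_with_effect(800, -np.log(2), seed=7)
        res = oc.univariate_cox(clin, scores)
        assert res.loc["F", "risk_class"] == oc.PROTECTIVE

    def test_constant_feature_reported_na(self):
        clin, scores = self._survival_with_effect(60, 0.0, seed=8)
        scores.loc["F"] = 1.0
        res = oc.univariate_cox(clin, scores)
        assert np.isnan(res.loc["F", "log_hr"])
        assert res.loc["F", "risk_class"] == "NA"

    def test_too_few_events_errors(self):
        clin = _clin([1.0, 2.0, 3.0], [1, 0, 0])
        scores = pd.DataFrame([[1.0, 2.0, 3.0]], index=["F"],
                              columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="events"):
            oc.univariate_cox(clin, scores)


class TestPathwayCellCorrelation:
    def _inputs(self, n=40, seed=9):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        metab = pd.DataFrame(rng.normal(size=(3, n)), index=["M1", "M2", "M3"],
                             columns=samples)
        inf = pd.DataFrame(rng.normal(size=(2, n)), index=["C1", "C2"],
                           columns=samples)
        labels = {s: 1 for s in samples}
        return metab, inf, labels

    def test_duplicated_vector_r_one(self):
        metab, inf, labels = self._inputs()
        inf.loc["C1"] = metab.loc["M1"]
        out = oc.pathway_cell_correlation(metab, inf, labels, 1)
        row = out[(out.pathway == "M1") & (out.cell == "C1")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)

    def test_negation_flips_sign(self):
        metab, inf, labels = self._inputs()
        out1 = oc.pathway_cell_correlation(metab, inf, labels, 1)
        out2 = oc.pathway_cell_correlation(-metab, inf, labels, 1)
        np.testing.assert_allclose(
            out1["pearson_r"], -out2["pearson_r"], atol=1e-12
        )

    def test_constant_vector_is_nan(self):
        metab, inf, labels = self._inputs()
        inf.loc["C1"] = 2.0
        out = oc.pathway_cell_correlation(metab, inf, labels, 1)
        assert out[out.cell == "C1"]["pearson_r"].isna().all()

    def test_independent_normals_mostly_small(self):
        rng = np.random.default_rng(33)
        samples = [f"s{i}" for i in range(100)]
        metab = pd.DataFrame(rng.normal(size=(10, 100)), columns=samples)
        inf = pd.DataFrame(rng.normal(size=(9, 100)), columns=samples)
        out = oc.pathway_cell_correlation(metab, inf, {s: 1 for s in samples}, 1)
        assert (out["pearson_r"].abs() < 0.3).mean() >= 0.99

    def test_fdr_flag_option(self):
        metab, inf, labels = self._inputs()
        out = oc.pathway_cell_correlation(metab, inf, labels, 1, fdr=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"].dropna() >= out["p"].dropna() - 1e-15).all()
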