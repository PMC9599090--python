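import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plfcs.connectivity import StrengthVector
from plfcs.proportional_loss import BaselineSigma, PLFCSVector
from plfcs.stats import (
    clinical_correlation,
    crossmodal_correlation,
    global_group_comparison,
    hub_vulnerability,
    region_permutation_test,
    region_ttest,
)


def _df(values, labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.arange(1, values.shape[1] + 1)
    return pd.DataFrame(values, columns=labels,
                        index=[f"s{i}" for i in range(values.shape[0])])


class TestRegionTTest:
    def test_identical_groups_give_null_result(self):
        a = _df([[1, 5], [2, 6], [3, 7]])
        res = region_ttest(a, a.copy())
        assert np.all(res["t"] == 0)
        assert np.all(res["p"] == 1)
        assert not res["significant"].any()

    def test_matches_pooled_variance_formula_oracle(self):
        rng = np.random.default_rng(21)
        a = _df(rng.standard_normal((6, 4)))
        b = _df(rng.standard_normal((5, 4)) + 0.5)
        res = region_ttest(a, b)
        for k, col in enumerate(a.columns):
            x, y = a[col].to_numpy(), b[col].to_numpy()
            na, nb = len(x), len(y)
            sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * sps.t.sf(abs(t), na + nb - 2)
            assert res["t"].iloc[k] == pytest.approx(t, abs=1e-10)
            assert res["p"].iloc[k] == pytest.approx(p, abs=1e-10)

    def test_group_label_swap_flips_t_and_keeps_p(self):
        rng = np.random.default_rng(22)
        a = _df(rng.standard_normal((5, 3)))
        b = _df(rng.standard_normal((7, 3)) + 1)
        r1 = region_ttest(a, b)
        r2 = region_ttest(b, a)
        np.testing.assert_allclose(r1["t"], -r2["t"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_zero_variance_regions_never_silent_nan(self):
        a = _df([[1.0, 1.0], [1.0, 1.0]])
        b = _df([[1.0, 2.0], [1.0, 2.0]])
        res = region_ttest(a, b)
        # equal means, zero variance -> t=0, p=1
        assert res["t"].iloc[0] == 0 and res["p"].iloc[0] == 1
        assert not res["degenerate"].iloc[0]
        # different means, zero variance -> flagged degenerate
        assert res["degenerate"].iloc[1]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            region_ttest(_df([[1.0]]), _df([[1.0], [2.0]]))


class TestRegionPermutationTest:
    def test_identical_multisets_give_p_one_exhaustively(self):
        a = _df([[3.0], [1.0], [2.0]])
        b = _df([[2.0], [3.0], [1.0]])
        res = region_permutation_test(a, b, n_permutations=100)
        assert res["exhaustive"].iloc[0]
        assert res["permutation_p"].iloc[0] == 1.0

    def test_two_vs_two_exhaustive_enumeration(self):
        # splits of {10,11} vs {0,1}: only the observed split and its mirror
        # reach |mean difference| >= 10, so p = 2/6
        a = _df([[10.0], [11.0]])
        b = _df([[0.0], [1.0]])
        res = region_permutation_test(a, b, n_permutations=100)
        assert res["exhaustive"].iloc[0]
        assert res["permutation_p"].iloc[0] == pytest.approx(2 / 6, abs=1e-15)

    def test_monte_carlo_agrees_with_exhaustive(self):
        # 7 vs 7 -> C(14,7) = 3432 relabelings: enumerable exactly, yet large
        # enough that a 3000-draw Monte-Carlo run stays in sampling mode
        rng = np.random.default_rng(23)
        a = _df(rng.standard_normal((7, 3)))
        b = _df(rng.standard_normal((7, 3)) + 1.0)
        exact = region_permutation_test(a, b, n_permutations=4000)
        assert exact["exhaustive"].iloc[0]
        mc = region_permutation_test(a, b, n_permutations=3000, seed=1)
        assert not mc["exhaustive"].iloc[0]
        np.testing.assert_allclose(
            mc["permutation_p"], exact["permutation_p"], atol=0.02
        )

    def test_add_one_estimator_never_returns_zero(self):
        rng = np.random.default_rng(24)
        a = _df(rng.standard_normal((6, 2)))
        b = _df(rng.standard_normal((6, 2)) + 50.0)
        res = region_permutation_test(a, b, n_permutations=200, seed=2)
        assert (res["permutation_p"] > 0).all()
        assert res["permutation_p"].iloc[0] == pytest.approx(1 / 201)

    def test_too_few_permutations_or_subjects_rejected(self):
        a = _df([[1.0], [2.0]])
        with pytest.raises(ValueError, match="100 permutations"):
            region_permutation_test(a, a, n_permutations=50)
        with pytest.raises(ValueError, match="2 subjects"):
            region_permutation_test(_df([[1.0]]), a)


class TestCrossmodalCorrelation:
    def test_perfect_linear_relations(self):
        rng = np.random.default_rng(25)
        metric = _df(rng.standard_normal((6, 2)))
        suvr = metric.copy()
        suvr[1] = 2 * metric[1] + 1
        suvr[2] = -metric[2] + 5
        res = crossmodal_correlation(metric, suvr, group="AD")
        assert res.loc[1, "r"] == pytest.approx(1.0)
        assert res.loc[2, "r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(26)
        metric = _df(rng.standard_normal((5, 1)))
        suvr = _df(rng.standard_normal((5, 1)))
        res = crossmodal_correlation(metric, suvr)
        x, y = metric[1].to_numpy(), suvr[1].to_numpy()
        r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert res.loc[1, "r"] == pytest.approx(r, abs=1e-12)

    def test_subject_mismatch_and_zero_variance(self):
        metric = _df([[1.0], [2.0], [3.0]])
        suvr = _df([[1.0], [1.0], [1.0]])
        res = crossmodal_correlation(metric, suvr)
        assert res["degenerate"].iloc[0]
        with pytest.raises(ValueError, match="identical subjects"):
            crossmodal_correlation(metric, suvr.iloc[::-1])


class TestHubVulnerability:
    def _strength(self, values):
        return StrengthVector(values, "group_mean", "pearson_r",
                              np.arange(1, len(values) + 1))

    def _loss(self, values):
        n = len(values)
        base = BaselineSigma(
            sigma=1.0, variant="global_scalar", source_group="NC",
            scale="fisher_z", region_labels=np.arange(1, n + 1),
        )
        return PLFCSVector(values=values, baseline=base,
                           region_labels=np.arange(1, n + 1), level="group_mean")

    def test_constructed_anticorrelation(self):
        mu = np.linspace(1, 10, 12)
        r, p = hub_vulnerability(self._strength(mu), self._loss(-0.05 * mu + 0.2))
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_independent_loss_shows_no_association(self):
        rng = np.random.default_rng(27)
        mu = rng.uniform(1, 10, 246)
        r, p = hub_vulnerability(self._strength(mu),
                                 self._loss(rng.normal(0, 0.1, 246)))
        assert abs(r) < 0.15
        assert p > 0.05

    def test_label_mismatch_rejected(self):
        s = self._strength(np.ones(3) * 2)
        loss = self._loss(np.zeros(3))
        loss.region_labels = np.array([1, 2, 9])
        with pytest.raises(ValueError, match="labels"):
            hub_vulnerability(s, loss)


class TestClinicalCorrelation:
    def test_linear_score_gives_unit_correlation(self):
        metrics = pd.DataFrame({"global_plfcs": [0.1, 0.2, 0.3, 0.4]},
                               index=list("abcd"))
        scores = pd.DataFrame(
            {"mmse": [28, 26, 24, 22], "cdr_sb": [1.0, 2.0, 3.0, 4.0]},
            index=list("abcd"),
        )
        res = clinical_correlation(metrics, scores).set_index("score")
        assert res.loc["mmse", "r"] == pytest.approx(-1.0)
        assert res.loc["cdr_sb", "r"] == pytest.approx(1.0)

    def test_shuffled_scores_average_to_zero(self):
        rng = np.random.default_rng(28)
        metric = rng.standard_normal(30)
        rs = []
        for _ in range(60):
            scores = pd.DataFrame({"mmse": rng.permutation(metric)})
            metrics = pd.DataFrame({"m": metric})
            rs.append(clinical_correlation(metrics, scores)["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.08

    def test_constant_score_flagged_degenerate(self):
        metrics = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        scores = pd.DataFrame({"mmse": [30.0, 30.0, 30.0]})
        res = clinical_correlation(metrics, scores)
        assert res["degenerate"].iloc[0]

    def test_nonfinite_scores_rejected(self):
        metrics = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        scores = pd.DataFrame({"mmse": [30.0, np.nan, 28.0]})
        with pytest.raises(ValueError, match="finite"):
            clinical_correlation(metrics, scores)


class TestGlobalGroupComparison:
    def test_separated_group_detected_with_post_hoc(self):
        rng = np.random.default_rng(29)
        jitter = rng.normal(0, 1e-3, 6)
        res = global_group_comparison(
            {
                "NC": np.array([0.0, 0.0]) + jitter[:2],
                "MCI": np.array([0.0, 0.0]) + jitter[2:4],
                "AD": np.array([10.0, 10.0]) + jitter[4:],
            }
        )
        assert res.p_value < 1e-3
        sig = res.significant_pairs(alpha=0.05)
        assert ("NC", "AD") in sig and ("MCI", "AD") in sig
        assert ("NC", "MCI") not in sig

    def test_bonferroni_is_three_times_raw_capped_at_one(self):
        rng = np.random.default_rng(30)
        groups = {g: rng.standard_normal(8) for g in ("NC", "MCI", "AD")}
        res = global_group_comparison(groups)
        for (g1, g2), adj in res.pairwise_p.items():
            _, raw = sps.ttest_ind(groups[g1], groups[g2])
            assert adj == pytest.approx(min(1.0, 3 * raw), abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(300):
            ps.append(
                global_group_comparison(
                    {g: rng.standard_normal(10) for g in ("NC", "MCI", "AD")}
                ).p_value
            )
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= rate <= 0.09
        assert sps.kstest(ps, "uniform").pvalue > 1e-4

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            global_group_comparison({"NC": [1.0], "MCI": [1.0, 2.0], "AD": [1.0, 2.0]})
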