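import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endosafe import methindex
from endosafe.deconv import CellProportions
from endosafe.io import BetaMatrix, SampleSheet
from endosafe.methindex import (IndexError_, IndexModel, apply_index,
                                compute_auc, compute_calibration,
                                default_feature_counts,
                                estimate_delta_beta_ic0,
                                fit_cpg_adjusted_models, rank_and_select_cpgs,
                                split_cohort, train_penalized_classifier)


def _sheet(n, groups, subjects=None, ages=None, timepoints=None):
    return SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "subject_id": subjects or [f"p{i}" for i in range(n)],
        "group": groups,
        "timepoint": timepoints or "NA",
        "age": ages if ages is not None else [40.0] * n,
    }))


def _props(sample_ids, epithelial, fibroblast, immune):
    return CellProportions(level1=pd.DataFrame(
        {"epithelial": epithelial, "fibroblast": fibroblast,
         "immune": immune}, index=sample_ids))


class TestSplitCohort:
    def test_fraction_and_stratification(self):
        sheet = _sheet(100, ["case"] * 60 + ["control"] * 40)
        split = split_cohort(sheet, 0.7, seed=0)
        assert len(split.train_ids) == 70
        groups = sheet.indexed()["group"]
        for part in (split.train_ids, split.test_ids):
            assert set(groups.loc[part]) == {"case", "control"}
        # class balance preserved within one sample
        assert abs((groups.loc[split.train_ids] == "case").sum() - 42) <= 1

    def test_subjects_never_straddle_sets(self):
        sheet = _sheet(20, ["case"] * 10 + ["control"] * 10,
                       subjects=[f"p{i // 2}" for i in range(20)],
                       timepoints=["pre", "post"] * 10)
        for seed in range(5):
            split = split_cohort(sheet, 0.7, group_by_subject=True, seed=seed)
            assign = split.assignment
            subj = sheet.indexed()["subject_id"]
            assert subj.groupby(subj).size().max() == 2
            per_subject = assign.groupby(subj.loc[assign.index]).nunique()
            assert (per_subject == 1).all()

    def test_deterministic_under_seed(self):
        sheet = _sheet(30, ["case"] * 15 + ["control"] * 15)
        a = split_cohort(sheet, 0.7, seed=3).assignment
        b = split_cohort(sheet, 0.7, seed=3).assignment
        assert a.equals(b)


class TestAdjustedModels:
    def test_exact_linear_relation_recovered(self):
        sheet = _sheet(8, ["control"] * 4 + ["case"] * 4,
                       ages=[35, 44, 39, 50, 36, 47, 41, 51])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        beta = 0.3 + 0.1 * group
        m = BetaMatrix(pd.DataFrame([beta], index=["cg1"],
                                    columns=[f"s{i}" for i in range(8)]))
        ic = np.array([0.05, 0.12, 0.08, 0.15, 0.06, 0.13, 0.1, 0.09])
        props = _props([f"s{i}" for i in range(8)],
                       1 - 0.2 - ic, [0.2] * 8, ic)
        rec = fit_cpg_adjusted_models(m, sheet, props)
        assert rec["group_coefficient"].iloc[0] == pytest.approx(0.1, abs=1e-10)
        assert rec["p_value"].iloc[0] < 1e-10

    def test_matches_normal_equations_oracle_on_toy(self):
        """Coefficients and p-values equal a closed-form OLS oracle."""
        rng = np.random.default_rng(2)
        n = 6
        sheet = _sheet(n, ["control"] * 3 + ["case"] * 3,
                       ages=rng.uniform(30, 50, n).round(1))
        ic = rng.uniform(0, 0.3, n)
        props = _props([f"s{i}" for i in range(n)], 1 - ic - 0.1, [0.1] * n, ic)
        Y = rng.uniform(0.2, 0.8, (4, n))
        m = BetaMatrix(pd.DataFrame(Y, index=[f"cg{i}" for i in range(4)],
                                    columns=[f"s{i}" for i in range(n)]))
        rec = fit_cpg_adjusted_models(m, sheet, props)
        X = np.column_stack([np.ones(n), [0, 0, 0, 1, 1, 1],
                             sheet.data["age"], ic])
        for i in range(4):
            coef = np.linalg.solve(X.T @ X, X.T @ Y[i])
            resid = Y[i] - X @ coef
            s2 = resid @ resid / (n - 4)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = coef[1] / se
            p = 2 * stats.t.sf(abs(t), n - 4)
            assert rec["group_coefficient"].iloc[i] == pytest.approx(coef[1],
                                                                     abs=1e-10)
            assert rec["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_constant_cpg_flagged_with_p_one(self):
        sheet = _sheet(6, ["control"] * 3 + ["case"] * 3)
        m = BetaMatrix(pd.DataFrame([[0.5] * 6], index=["cg1"],
                                    columns=[f"s{i}" for i in range(6)]))
        ic = np.linspace(0.05, 0.15, 6)
        props = _props([f"s{i}" for i in range(6)], 1 - 0.1 - ic, [0.1] * 6,
                       ic)
        rec = fit_cpg_adjusted_models(m, sheet, props)
        assert rec["flagged"].iloc[0]
        assert rec["p_value"].iloc[0] == 1.0

    def test_bh_q_values_monotone_in_p(self, small_cohort, profiles_l1):
        from endosafe.deconv import estimate_proportions
        betas, sheet, _ = small_cohort
        props = estimate_proportions(betas, profiles_l1)
        rec = fit_cpg_adjusted_models(betas, sheet, props).sort_values("p_value")
        assert rec["q_value"].is_monotonic_increasing or \
            (rec["q_value"].diff().dropna() >= -1e-12).all()
        assert (rec["q_value"] >= rec["p_value"] - 1e-12).all()


class TestDeltaBetaIc0:
    def test_exact_lines_give_intercept_difference(self):
        ic = np.array([0.0, 0.1, 0.2, 0.3, 0.05, 0.15, 0.25, 0.35])
        group = ["control"] * 4 + ["case"] * 4
        beta = np.where(np.array(group) == "control",
                        0.2 + 0.5 * ic, 0.6 + 0.1 * ic)
        sheet = _sheet(8, group)
        m = BetaMatrix(pd.DataFrame([beta], index=["cg1"],
                                    columns=[f"s{i}" for i in range(8)]))
        props = _props([f"s{i}" for i in range(8)], 1 - ic - 0.05,
                       [0.05] * 8, ic)
        rec = estimate_delta_beta_ic0(m, sheet, props)
        assert rec["delta_beta_ic0"].iloc[0] == pytest.approx(0.4, abs=1e-12)

    def test_identical_groups_give_zero(self):
        ic = np.array([0.0, 0.1, 0.2, 0.3] * 2)
        beta = 0.3 + 0.2 * ic
        sheet = _sheet(8, ["control"] * 4 + ["case"] * 4)
        m = BetaMatrix(pd.DataFrame([beta], index=["cg1"],
                                    columns=[f"s{i}" for i in range(8)]))
        props = _props([f"s{i}" for i in range(8)], 1 - ic - 0.05,
                       [0.05] * 8, ic)
        rec = estimate_delta_beta_ic0(m, sheet, props)
        assert rec["delta_beta_ic0"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_shared_ic_linear_trend(self):
        rng = np.random.default_rng(8)
        ic = rng.uniform(0, 0.4, 20)
        group = ["control"] * 10 + ["case"] * 10
        base = rng.uniform(0.2, 0.6, (3, 20))
        sheet = _sheet(20, group)
        ids = [f"s{i}" for i in range(20)]
        props = _props(ids, 1 - ic - 0.05, [0.05] * 20, ic)
        m1 = BetaMatrix(pd.DataFrame(base, index=list("abc"), columns=ids))
        shifted = np.clip(base + 0.3 * ic[None, :], 0, 1)
        m2 = BetaMatrix(pd.DataFrame(shifted, index=list("abc"), columns=ids))
        r1 = estimate_delta_beta_ic0(m1, sheet, props)["delta_beta_ic0"]
        r2 = estimate_delta_beta_ic0(m2, sheet, props)["delta_beta_ic0"]
        assert np.allclose(r1, r2, atol=1e-10)

    def test_constant_ic_within_group_is_an_error(self):
        sheet = _sheet(8, ["control"] * 4 + ["case"] * 4)
        ids = [f"s{i}" for i in range(8)]
        props = _props(ids, [0.8] * 8, [0.1] * 8, [0.1] * 8)
        m = BetaMatrix(pd.DataFrame(np.full((1, 8), 0.4), index=["cg1"],
                                    columns=ids))
        with pytest.raises(IndexError_, match="ic constant"):
            estimate_delta_beta_ic0(m, sheet, props)


class TestRanking:
    def test_sorts_by_absolute_delta_with_lexicographic_ties(self):
        rec = pd.DataFrame({
            "cpg_id": ["cpg1", "cpg2", "cpg3", "cpg4", "cpg5"],
            "delta_beta_ic0": [0.4, -0.5, 0.1, 0.3, 0.2],
            "q_value": [0.01] * 5,
        })
        assert rank_and_select_cpgs(rec, top_n=2) == ["cpg2", "cpg1"]
        tied = pd.DataFrame({"cpg_id": ["b", "a"],
                             "delta_beta_ic0": [0.2, -0.2],
                             "q_value": [0.01, 0.01]})
        assert rank_and_select_cpgs(tied, top_n=2) == ["a", "b"]

    def test_fdr_filter_and_default_top_n(self):
        rec = pd.DataFrame({"cpg_id": ["a", "b"],
                            "delta_beta_ic0": [0.5, 0.4],
                            "q_value": [0.01, 0.2]})
        assert rank_and_select_cpgs(rec) == ["a"]
        assert rank_and_select_cpgs(rec, require_fdr=False) == ["a", "b"]
        assert default_feature_counts()[:4] == (100, 500, 1000, 2000)
        assert default_feature_counts()[-1] == 30000


class TestPenalizedClassifier:
    def test_separable_toy_reaches_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        y = ["control"] * 20 + ["case"] * 20
        x1 = np.r_[rng.normal(0, 0.2, 20), rng.normal(3, 0.2, 20)]
        X = pd.DataFrame([x1, rng.normal(size=n)], index=["f1", "f2"],
                         columns=[f"s{i}" for i in range(n)])
        model = train_penalized_classifier(X, y, alpha=0.0, seed=0)
        scores = apply_index(model, X)
        assert compute_auc(scores, y) == 1.0

    def test_lasso_concentrates_weight_on_informative_features(self):
        """Lasso recovers the full informative support and concentrates at
        least 80% of the coefficient mass there (5 signal features among 95
        pure-noise ones, n = 200)."""
        rng = np.random.default_rng(1)
        n, p_noise = 200, 95
        y = np.array(["control"] * 100 + ["case"] * 100)
        signal = np.vstack([rng.normal((y == "case") * 1.5, 1.0)
                            for _ in range(5)])
        noise = rng.normal(size=(p_noise, n))
        X = pd.DataFrame(np.vstack([signal, noise]),
                         index=[f"inf{i}" for i in range(5)]
                         + [f"noise{i}" for i in range(p_noise)],
                         columns=[f"s{i}" for i in range(n)])
        model = train_penalized_classifier(X, y.tolist(), alpha=1.0, seed=1,
                                           penalty_selection="1se")
        nz = model.nonzero_features
        assert set(f"inf{i}" for i in range(5)) <= set(nz)
        w = pd.Series(np.abs(model.coefficients), index=model.feature_ids)
        informative_mass = w[[f for f in w.index if f.startswith("inf")]].sum()
        assert informative_mass / w.sum() >= 0.8

    def test_zero_variance_features_dropped(self):
        y = ["control"] * 5 + ["case"] * 5
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            np.vstack([np.full(10, 0.5), rng.normal(size=10)]),
            index=["flat", "ok"], columns=[f"s{i}" for i in range(10)])
        model = train_penalized_classifier(X, y, alpha=0.0, seed=0)
        assert model.feature_ids == ["ok"]


class TestMetrics:
    def test_auc_by_pair_enumeration(self):
        assert compute_auc([0.2, 0.8], ["control", "case"]) == 1.0
        assert compute_auc([0.5, 0.5, 0.5, 0.5],
                           ["control", "case", "control", "case"]) == 0.5
        # 3 concordant of 4 pairs
        assert compute_auc([1, 2, 3, 4],
                           ["control", "case", "control", "case"]) == 0.75

    def test_calibration_exact_on_matched_two_point_design(self):
        p = np.array([0.2] * 10 + [0.8] * 10)
        y = (["control"] * 8 + ["case"] * 2) + (["control"] * 2 + ["case"] * 8)
        slope, intercept = compute_calibration(p, y)
        assert slope == pytest.approx(1.0, abs=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_calibration_detects_sharpened_probabilities(self):
        """Doubling the true log-odds halves the calibration slope."""
        rng = np.random.default_rng(4)
        n = 5000
        true_logit = rng.normal(0, 1.5, n)
        p_true = 1 / (1 + np.exp(-true_logit))
        y = np.where(rng.uniform(size=n) < p_true, "case", "control")
        sharp = 1 / (1 + np.exp(-2 * true_logit))
        slope, _ = compute_calibration(np.clip(sharp, 1e-12, 1 - 1e-12),
                                       y.tolist())
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(IndexError_):
            compute_calibration([0.5, 0.5], ["case", "control"])
        with pytest.raises(IndexError_):
            compute_auc([1.0, 2.0], ["case", "case"])


class TestApplyIndex:
    def _model(self):
        return IndexModel(feature_ids=["a", "b"], means=[0.4, 0.6],
                          sds=[0.1, 0.2], coefficients=[1.0, -2.0],
                          intercept=0.7, alpha=0.0, penalty_strength=1.0,
                          n_features_requested=2)

    def test_sample_at_feature_means_scores_intercept(self):
        m = self._model()
        X = pd.DataFrame({"s1": [0.4, 0.6]}, index=["a", "b"])
        assert apply_index(m, X)["s1"] == pytest.approx(0.7)

    def test_zero_coefficients_score_intercept_everywhere(self):
        m = self._model()
        m.coefficients = np.zeros(2)
        X = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (2, 4)),
                         index=["a", "b"], columns=list("wxyz"))
        assert np.allclose(apply_index(m, X), 0.7)

    def test_missing_feature_imputed_at_mean_within_overlap_gate(self):
        feats = [f"f{i}" for i in range(20)]
        m = IndexModel(feature_ids=feats, means=np.full(20, 0.5),
                       sds=np.full(20, 0.1), coefficients=np.ones(20),
                       intercept=0.0, alpha=0.0, penalty_strength=1.0,
                       n_features_requested=20)
        X = pd.DataFrame(np.full((19, 1), 0.6), index=feats[:19],
                         columns=["s"])
        # 1 of 20 missing contributes 0; the 19 present contribute 1 each
        assert apply_index(m, X)["s"] == pytest.approx(19.0)
        too_few = pd.DataFrame(np.full((10, 1), 0.6), index=feats[:10],
                               columns=["s"])
        with pytest.raises(IndexError_, match="features present"):
            apply_index(m, too_few)

    def test_json_round_trip(self, tmp_path):
        m = self._model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = IndexModel.from_json(path)
        assert back.feature_ids == m.feature_ids
        assert np.allclose(back.coefficients, m.coefficients)
        assert back.intercept == m.intercept
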