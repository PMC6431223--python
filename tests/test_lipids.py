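"""Lipid normalization, series merging and the repeated-CV LASSO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastidrive import (
    LipidLassoPredictor,
    LipidMatrix,
    class_enrichment,
    lasso_cv_run,
    merge_series,
    normalize_series,
    run_repeated,
    select_predictive,
)
from plastidrive.lipids import _alpha_1se
from plastidrive.simulate import simulate_lipidome


def _tiny_matrix(levels, classes, series=None, genotypes=None):
    levels = pd.DataFrame(levels)
    n = len(levels)
    samples = pd.DataFrame(
        {
            "genotype": genotypes or [f"G{i}" for i in range(n)],
            "series": series or [1] * n,
            "replicate": [1] * n,
            "inheritance_class": classes,
        },
        index=levels.index,
    )
    lipid_classes = pd.Series("PC", index=levels.columns)
    return LipidMatrix(levels=levels, samples=samples, lipid_classes=lipid_classes)


class TestNormalization:
    def test_class1_values_e_become_zero(self):
        e = float(np.e)
        m = _tiny_matrix({"lipA": [e, e, e]}, classes=[1, 1, 1])
        out = normalize_series(m)
        assert np.allclose(out.levels["lipA"], 0.0)

    def test_class1_median_forced_to_zero(self, rng):
        m = _tiny_matrix(
            {f"lip{j}": rng.lognormal(1, 0.5, 8) for j in range(5)},
            classes=[1, 1, 1, 2, 3, 4, 5, 5],
        )
        out = normalize_series(m)
        class1 = out.samples.inheritance_class == 1
        assert np.allclose(out.levels[class1].median(axis=0), 0.0, atol=1e-12)

    def test_direct_arithmetic(self):
        # log(5) minus a class-1 log-median of 1
        m = _tiny_matrix(
            {"lip": [np.e, np.e, 5.0]}, classes=[1, 1, 3]
        )
        out = normalize_series(m)
        assert out.levels["lip"].iloc[2] == pytest.approx(np.log(5.0) - 1.0)

    def test_per_series_centering_removes_series_offset(self, rng):
        base = rng.lognormal(0, 0.3, 4)
        m = _tiny_matrix(
            {"lip": np.concatenate([base, base * 10.0])},
            classes=[1, 1, 2, 3] * 2,
            series=[1] * 4 + [2] * 4,
            genotypes=["A", "B", "C", "D"] * 2,
        )
        out = normalize_series(m)
        assert np.allclose(
            out.levels["lip"].iloc[:4], out.levels["lip"].iloc[4:], atol=1e-12
        )

    def test_double_normalization_rejected(self):
        m = _tiny_matrix({"lip": [1.0, 2.0, 3.0]}, classes=[1, 2, 3])
        with pytest.raises(ValueError):
            normalize_series(normalize_series(m))

    def test_nonpositive_level_names_offender(self):
        m = _tiny_matrix({"lipBad": [1.0, 0.0, 3.0]}, classes=[1, 2, 3])
        with pytest.raises(ValueError, match="lipBad"):
            normalize_series(m)

    def test_series_without_class1_rejected(self):
        m = _tiny_matrix({"lip": [1.0, 2.0, 3.0]}, classes=[2, 3, 4])
        with pytest.raises(ValueError, match="class"):
            normalize_series(m)


class TestMerge:
    def test_identical_sets_drop_nothing(self):
        a = normalize_series(
            _tiny_matrix({"A": [1.0, 2.0], "B": [1.0, 3.0]}, classes=[1, 2],
                         genotypes=["g1", "g2"])
        )
        merged = merge_series([a])
        assert merged.lipids == ["A", "B"] and merged.dropped_lipids == []

    def test_intersection_semantics(self):
        def series_matrix(lipids, series, genos):
            levels = {l: [1.0, 2.0] for l in lipids}
            m = _tiny_matrix(levels, classes=[1, 2], series=[series] * 2,
                             genotypes=genos)
            m.levels.index = [f"{g}_s{series}" for g in genos]
            m.samples.index = m.levels.index
            return normalize_series(m)

        mats = [
            series_matrix(["A", "B", "C"], 1, ["g1", "g2"]),
            series_matrix(["A", "B"], 2, ["g1", "g2"]),
            series_matrix(["B"], 3, ["g1", "g2"]),
        ]
        merged = merge_series(mats)
        assert merged.lipids == ["B"]
        assert set(merged.dropped_lipids) == {"A", "C"}

    def test_constructed_dropout_reduces_184_to_102(self):
        matrix, manifest = simulate_lipidome(seed=3)
        merged = merge_series(normalize_series(matrix))
        assert len(merged.lipids) == 102
        assert len(merged.dropped_lipids) == 82
        assert set(merged.lipids) == set(manifest["shared_lipids"])
        assert not merged.levels.isna().any().any()

    def test_unnormalized_rejected(self):
        m = _tiny_matrix({"A": [1.0, 2.0]}, classes=[1, 2], genotypes=["g1", "g2"])
        with pytest.raises(ValueError):
            merge_series([m])


@pytest.fixture(scope="module")
def merged_lipidome():
    matrix, manifest = simulate_lipidome(seed=11)
    return merge_series(normalize_series(matrix)), manifest


class TestLassoRuns:
    def test_infinite_penalty_gives_null_model(self, merged_lipidome):
        merged, _ = merged_lipidome
        res = lasso_cv_run(merged, random_state=0, alpha=1e9)
        assert np.allclose(res.coef, 0.0)
        train_mean = merged.samples.loc[
            ~merged.samples.genotype.isin(res.holdout_genotypes), "inheritance_class"
        ].mean()
        assert np.allclose(res.y_pred, train_mean)
        assert np.isnan(res.cv_r)  # constant predictions -> undefined

    def test_penalty_at_lambda_max_zeroes_all_coefficients(self, merged_lipidome):
        merged, _ = merged_lipidome
        X = merged.levels.to_numpy()
        y = merged.samples.inheritance_class.to_numpy(dtype=float)
        rng = np.random.default_rng(5)
        held = rng.choice(np.unique(merged.samples.genotype), 2, replace=False)
        train = ~merged.samples.genotype.isin(held).to_numpy()
        Xs = (X[train] - X[train].mean(0)) / X[train].std(0)
        lam_max = np.abs(Xs.T @ (y[train] - y[train].mean())).max() / train.sum()
        res = lasso_cv_run(merged, random_state=5, alpha=lam_max * 1.001)
        assert np.count_nonzero(res.coef) == 0

    def test_near_zero_penalty_equals_ols_on_reduced_instance(self, rng):
        """With p << n and lambda -> 0 the LASSO solution is the
        unpenalized least-squares fit."""
        n, p = 120, 4
        X = rng.normal(size=(n, p))
        beta = np.array([1.5, -2.0, 0.5, 3.0])
        y = X @ beta + rng.normal(0, 0.1, n)
        genos = np.repeat([f"G{i}" for i in range(12)], 10)
        levels = pd.DataFrame(X, columns=[f"l{j}" for j in range(p)])
        samples = pd.DataFrame(
            {"genotype": genos, "series": 1, "replicate": 1, "inheritance_class": y},
            index=levels.index,
        )
        m = LipidMatrix(levels, samples, pd.Series("PC", index=levels.columns),
                        normalized=True)
        res = lasso_cv_run(m, random_state=1, alpha=1e-10, standardize=False)
        train = ~np.isin(genos, res.holdout_genotypes)
        D = np.column_stack([np.ones(train.sum()), X[train]])
        ols = np.linalg.lstsq(D, y[train], rcond=None)[0]
        assert np.allclose(res.coef, ols[1:], atol=1e-5)

    def test_planted_single_predictor_recovered(self, rng):
        n_geno, reps = 12, 6
        genos = np.repeat([f"G{i}" for i in range(n_geno)], reps)
        cls = np.repeat((np.arange(n_geno) % 5) + 1, reps).astype(float)
        X = rng.normal(size=(n_geno * reps, 20))
        X[:, 1] = cls / 2.0 + rng.normal(0, 0.05, n_geno * reps)
        model = LipidLassoPredictor(n_runs=10, inner_cv=5, random_state=2).fit(
            X, cls, genotypes=genos
        )
        assert np.nanmean(model.cv_r_) > 0.9
        assert np.argmax(model.avg_weights_) == 1

    def test_constant_holdout_classes_flagged(self, rng):
        genos = np.repeat(["A", "B", "C", "D", "E"], 4)
        cls = np.where(np.isin(genos, ["A", "B"]), 1.0, 3.0)
        X = rng.normal(size=(20, 5)) + cls[:, None]
        found_nan = False
        for seed in range(20):
            res = lasso_cv_run(
                _tiny_frame(X, cls, genos), random_state=seed, alpha=0.01
            )
            held_cls = cls[np.isin(genos, res.holdout_genotypes)]
            if len(np.unique(held_cls)) == 1:
                assert np.isnan(res.cv_r)
                found_nan = True
        assert found_nan

    def test_repeated_runs_deterministic(self, merged_lipidome):
        merged, _ = merged_lipidome
        kw = dict(n_runs=4, random_state=9, inner_cv=4, n_alphas=30)
        m1, h1 = run_repeated(merged, **kw)
        m2, h2 = run_repeated(merged, **kw)
        assert np.allclose(m1.coef_matrix_, m2.coef_matrix_)
        assert np.allclose(m1.cv_r_, m2.cv_r_, equal_nan=True)
        assert h1.equals(h2)

    def test_alpha_1se_rule(self):
        alphas = np.array([1.0, 0.5, 0.1, 0.01])
        mse = np.array(
            [[3.0, 3.2], [2.0, 2.2], [1.0, 1.2], [1.05, 1.15]]
        )
        # min mean = 1.1 at alpha 0.1, se = 0.1; 1-SE band is [., 1.2]:
        # alpha 0.01 (mean 1.10) and 0.1 qualify -> largest is 0.1
        assert _alpha_1se(alphas, mse) == 0.1


class TestPredictiveSelection:
    def test_all_zero_coefficients_nothing_predictive(self):
        model = LipidLassoPredictor.__new__(LipidLassoPredictor)
        model.avg_weights_ = np.zeros(10)
        model.mean_coef_ = np.zeros(10)
        model.weight_threshold_ = 0.0
        model.predictive_mask_ = model.avg_weights_ > 0.0
        report = select_predictive(model)
        assert not report.predictive.any()

    def test_single_dominant_lipid(self):
        avg = np.zeros(102)
        avg[7] = 10.0
        model = LipidLassoPredictor.__new__(LipidLassoPredictor)
        model.avg_weights_ = avg
        model.mean_coef_ = avg.copy()
        model.weight_threshold_ = float(np.std(avg, ddof=1))
        model.predictive_mask_ = avg > model.weight_threshold_
        report = select_predictive(model)
        assert model.weight_threshold_ == pytest.approx(
            np.std(avg, ddof=1)
        ) and model.weight_threshold_ < 10
        assert report.predictive.sum() == 1 and report.predictive[7]


class TestEnrichment:
    def _report(self, predictive_flags, lipid_ids):
        return pd.DataFrame(
            {"lipid_id": lipid_ids, "avgW": 1.0, "mean_coef": 1.0,
             "predictive": predictive_flags}
        )

    def test_proportional_representation_or_one(self):
        ids = [f"L{i}" for i in range(20)]
        classes = pd.Series(["PC"] * 10 + ["TAG"] * 10, index=ids)
        flags = [True] * 2 + [False] * 8 + [True] * 2 + [False] * 8
        out = class_enrichment(self._report(flags, ids), classes).set_index("lipid_class")
        assert out.loc["PC", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["PC", "p"] == pytest.approx(1.0)

    def test_hypergeometric_oracle(self):
        ids = [f"L{i}" for i in range(100)]
        classes = pd.Series(["PC"] * 5 + ["other"] * 95, index=ids)
        flags = [True] * 5 + [True] * 5 + [False] * 90
        out = class_enrichment(self._report(flags, ids), classes).set_index("lipid_class")
        rv = stats.hypergeom(100, 5, 10)
        support = np.arange(0, 6)
        pmf = rv.pmf(support)
        expected = float(pmf[pmf <= rv.pmf(5) * (1 + 1e-9)].sum())
        assert out.loc["PC", "p"] == pytest.approx(expected, abs=1e-12)

    def test_empty_predictive_set_all_p_one(self):
        ids = [f"L{i}" for i in range(10)]
        classes = pd.Series(["PC"] * 5 + ["TAG"] * 5, index=ids)
        out = class_enrichment(self._report([False] * 10, ids), classes)
        assert (out.p == 1.0).all()

    def test_unassigned_lipid_rejected(self):
        ids = ["L1", "L2"]
        classes = pd.Series({"L1": "PC"})
        with pytest.raises(ValueError):
            class_enrichment(self._report([True, False], ids), classes)


def _tiny_frame(X, cls, genos):
    levels = pd.DataFrame(X, columns=[f"l{j}" for j in range(X.shape[1])])
    samples = pd.DataFrame(
        {"genotype": genos, "series": 1, "replicate": 1, "inheritance_class": cls},
        index=levels.index,
    )
    return LipidMatrix(levels, samples, pd.Series("PC", index=levels.columns),
                       normalized=True)
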