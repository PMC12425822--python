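import numpy as np
import pandas as pd
import pytest

from pherskit.model import (
    DEFAULT_CS,
    DEFAULT_L1_RATIOS,
    FitError,
    HyperGrid,
    PheRS,
    SplitError,
    SplitSpec,
    fit_phers,
    loo_importance,
    rank_coefficients,
    split_cohort,
    transfer_score,
)


def make_training_data(n=800, p=6, n_signal=2, beta=1.2, seed=0, prevalence=0.25):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        (rng.random((n, p)) < prevalence).astype(float),
        columns=[f"ph{j}" for j in range(p)],
    )
    X["age"] = rng.integers(32, 71, n).astype(float)
    X["sex"] = rng.integers(0, 2, n).astype(float)
    logit = -2.0 + beta * X.iloc[:, :n_signal].sum(axis=1) + 0.02 * (X["age"] - 51)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return X, y


TINY_GRID = HyperGrid(l1_ratios=(0.5,), Cs=(0.1,), cv_folds=3)


class TestSplit:
    def test_sizes_n1000(self):
        idx = np.arange(1000)
        y = (idx < 50).astype(int)
        parts = split_cohort(idx, y, SplitSpec(seed=3))
        assert len(parts["test"]) == 500
        assert len(parts["train"]) == 425
        assert len(parts["holdout"]) == 75
        all_ids = np.concatenate(list(parts.values()))
        assert len(np.unique(all_ids)) == 1000  # disjoint and exhaustive

    def test_deterministic_under_seed(self):
        idx = np.arange(400)
        y = (idx % 10 == 0).astype(int)
        a = split_cohort(idx, y, SplitSpec(seed=11))
        b = split_cohort(idx, y, SplitSpec(seed=11))
        for k in a:
            assert np.array_equal(np.sort(a[k]), np.sort(b[k]))

    def test_stratification_within_one_case(self):
        idx = np.arange(1000)
        y = (idx < 50).astype(int)  # 5% prevalence
        parts = split_cohort(idx, y, SplitSpec(seed=5))
        ys = pd.Series(y, index=idx)
        assert abs(ys.loc[parts["test"]].sum() - 25) <= 1
        assert abs(ys.loc[parts["train"]].sum() - 21.25) <= 1
        assert abs(ys.loc[parts["holdout"]].sum() - 3.75) <= 1

    def test_zero_case_split_rejected(self):
        idx = np.arange(40)
        y = np.zeros(40, int)
        y[0] = 1
        with pytest.raises(SplitError):
            split_cohort(idx, y, SplitSpec(seed=0))


class TestGridProtocol:
    def test_full_grid_enumeration(self):
        grid = HyperGrid()
        assert len(grid.l1_ratios) == 19
        assert len(grid.Cs) == 11
        assert grid.size == 209
        assert grid.l1_ratios[0] == pytest.approx(0.05)
        assert grid.l1_ratios[-1] == pytest.approx(0.95)

    def test_ridge_preset_drops_l1_dimension(self):
        model = PheRS(penalty="ridge", Cs=(0.1, 1.0))
        cands = model._candidates()
        assert all(c["l1_ratio"] == [0.0] for c in cands)
        assert len(cands) == 2

    def test_tie_break_order_prefers_sparser(self):
        model = PheRS(l1_ratios=(0.1, 0.9), Cs=(0.01, 1.0))
        cands = model._candidates()
        assert cands[0] == {"l1_ratio": [0.9], "C": [1.0]}


class TestFit:
    def test_no_signal_reduces_to_age_sex(self):
        rng = np.random.default_rng(1)
        X, y = make_training_data(seed=1)
        X[[c for c in X.columns if c.startswith("ph")]] = 0.0
        model = fit_phers(X, y, grid=TINY_GRID, seed=0)
        assert np.allclose(model.phecode_coefficients().to_numpy(), 0.0)

    def test_single_class_rejected(self):
        X, _ = make_training_data(n=100)
        with pytest.raises(FitError):
            fit_phers(X, np.zeros(100, int), grid=TINY_GRID)

    def test_infinite_feature_rejected(self):
        X, y = make_training_data(n=100)
        X.iloc[0, 0] = np.inf
        with pytest.raises(FitError):
            fit_phers(X, y, grid=TINY_GRID)

    def test_column_permutation_invariance(self):
        X, y = make_training_data(seed=2)
        m1 = fit_phers(X, y, grid=TINY_GRID, seed=9)
        perm = list(X.columns[::-1])
        m2 = fit_phers(X[perm], y, grid=TINY_GRID, seed=9)
        c1 = pd.Series(m1.coef_, index=m1.feature_names_in_)
        c2 = pd.Series(m2.coef_, index=m2.feature_names_in_).reindex(c1.index)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-5)

    def test_ridge_shrinkage_monotone_in_C(self):
        X, y = make_training_data(seed=3)
        norms = []
        for C in (1.0, 1e-2, 1e-4):
            m = fit_phers(X, y, grid=HyperGrid(l1_ratios=(0.0,), Cs=(C,)),
                          penalty="ridge", seed=0)
            norms.append(np.abs(m.phecode_coefficients().to_numpy()).max())
        assert norms[0] > norms[1] > norms[2]

    def test_missing_values_imputed_to_train_mean(self):
        X, y = make_training_data(seed=4)
        X.iloc[5:25, 0] = np.nan
        model = fit_phers(X, y, grid=TINY_GRID, seed=0)
        observed_mean = X.iloc[:, 0].mean(skipna=True)
        assert model.feature_means_[0] == pytest.approx(observed_mean)
        assert np.isfinite(model.decision_function(X)).all()


@pytest.fixture(scope="module")
def fitted_scoring():
    X, y = make_training_data(seed=5)
    return fit_phers(X, y, grid=TINY_GRID, seed=1), X


@pytest.fixture(scope="module")
def fitted_transfer():
    X, y = make_training_data(seed=6)
    return fit_phers(X, y, grid=TINY_GRID, seed=1), X


class TestScoring:

    def test_score_at_train_means_is_intercept(self, fitted_scoring):
        model, X = fitted_scoring
        means = pd.DataFrame([model.feature_means_], columns=model.feature_names_in_)
        assert model.decision_function(means)[0] == pytest.approx(model.intercept_, abs=1e-12)

    def test_linearity_in_single_feature(self, fitted_scoring):
        model, X = fitted_scoring
        a = X.iloc[[0]].copy()
        b = a.copy()
        b["ph0"] = a["ph0"] + 1.0
        j = list(model.feature_names_in_).index("ph0")
        delta = model.decision_function(b)[0] - model.decision_function(a)[0]
        assert delta == pytest.approx(model.coef_[j] / model.feature_sds_[j], abs=1e-12)

    def test_dot_product_oracle(self, fitted_scoring):
        model, X = fitted_scoring
        sample = X.iloc[:5]
        expected = []
        for _, row in sample.iterrows():
            s = model.intercept_
            for j, name in enumerate(model.feature_names_in_):
                s += model.coef_[j] * (row[name] - model.feature_means_[j]) / model.feature_sds_[j]
            expected.append(s)
        assert np.allclose(model.decision_function(sample), expected, atol=1e-12)


class TestTransfer:

    def test_identity_on_same_features(self, fitted_transfer):
        model, X = fitted_transfer
        direct = model.decision_function(X)
        transferred = transfer_score(model, X).to_numpy()
        assert np.allclose(direct, transferred, atol=1e-12)

    def test_dropped_column_changes_score_by_exact_term(self, fitted_transfer):
        model, X = fitted_transfer
        j = list(model.feature_names_in_).index("ph1")
        full = model.decision_function(X)
        reduced = transfer_score(model, X.drop(columns=["ph1"])).to_numpy()
        term = model.coef_[j] * (X["ph1"] - model.feature_means_[j]) / model.feature_sds_[j]
        assert np.allclose(full - reduced, term, atol=1e-12)

    def test_absent_phecode_contributes_exactly_zero(self, fitted_transfer):
        model, X = fitted_transfer
        target = X.drop(columns=["ph0", "ph1"])
        manual = model.intercept_
        for j, name in enumerate(model.feature_names_in_):
            if name in ("ph0", "ph1"):
                continue  # multiplied by zero
            manual = manual + model.coef_[j] * (X[name] - model.feature_means_[j]) / model.feature_sds_[j]
        assert np.allclose(transfer_score(model, target).to_numpy(), manual, atol=1e-12)

    def test_common_code_restriction(self, fitted_transfer):
        model, X = fitted_transfer
        restricted = transfer_score(model, X, common_codes=["ph0"])
        manual = transfer_score(model, X[["ph0", "age", "sex"]])
        assert np.allclose(restricted.to_numpy(), manual.to_numpy(), atol=1e-12)

    def test_no_overlap_warns_but_scores(self, fitted_transfer):
        model, X = fitted_transfer
        with pytest.warns(UserWarning, match="no overlap"):
            s = transfer_score(model, X[["age", "sex"]])
        assert np.isfinite(s).all()


class TestSerialization:
    def test_json_round_trip_bit_exact(self):
        X, y = make_training_data(seed=7)
        model = fit_phers(X, y, grid=TINY_GRID, seed=2, disease="d", source_cohort="c0")
        clone = PheRS.from_json(model.to_json())
        assert np.array_equal(model.coef_, clone.coef_)
        assert np.array_equal(model.feature_means_, clone.feature_means_)
        assert np.array_equal(model.feature_sds_, clone.feature_sds_)
        assert model.intercept_ == clone.intercept_
        assert list(model.feature_names_in_) == list(clone.feature_names_in_)
        X2 = X.iloc[:10]
        assert np.array_equal(model.decision_function(X2), clone.decision_function(X2))


class TestRanking:
    def make_model(self, coefs):
        m = PheRS()
        names = [f"ph{i}" for i in range(len(coefs))] + ["age", "sex"]
        m.feature_names_in_ = np.array(names, dtype=object)
        m.coef_ = np.array(list(coefs) + [0.1, 0.2])
        m.intercept_ = 0.0
        m.feature_means_ = np.zeros(len(names))
        m.feature_sds_ = np.ones(len(names))
        return m

    def test_rank_order(self):
        table = rank_coefficients(self.make_model([3.0, 1.0, 2.0]))
        assert list(table.loc[["ph0", "ph1", "ph2"], "rank"]) == [1, 3, 2]

    def test_scaled_mean_zero_sd_one(self):
        table = rank_coefficients(self.make_model([3.0, 1.0, 2.0, -1.0]))
        assert table["scaled_coefficient"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["scaled_coefficient"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_ties_stable_and_flagged(self):
        table = rank_coefficients(self.make_model([2.0, 2.0, 1.0]))
        assert list(table.loc[["ph0", "ph1", "ph2"], "rank"]) == [1, 2, 3]
        assert table.loc["ph0", "tied"] and table.loc["ph1", "tied"]
        assert not table.loc["ph2", "tied"]

    def test_single_coefficient_skips_scaling(self):
        with pytest.warns(UserWarning):
            table = rank_coefficients(self.make_model([1.5]))
        assert np.isnan(table["scaled_coefficient"]).all()


class TestLeaveOneOut:
    def test_signal_column_has_largest_drop(self):
        X, y = make_training_data(n=1500, p=5, n_signal=1, beta=1.5, seed=8)
        Xe, ye = make_training_data(n=800, p=5, n_signal=1, beta=1.5, seed=9)
        table = loo_importance(X, y, Xe, ye, grid=HyperGrid(l1_ratios=(0.0,), Cs=(0.1,)),
                               seed=0)
        assert table["delta"].idxmin() == "ph0"
        # noise columns barely matter
        assert table.drop(index="ph0")["delta"].abs().max() < abs(table.loc["ph0", "delta"])
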