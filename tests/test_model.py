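"""Pipeline fitting, LOO grid search, signatures and prediction metrics."""

import numpy as np
import pytest

from rpnsig.connectome import ConnectivityMatrix
from rpnsig.model import (
    ConnectomePredictiveModel,
    HyperparamGrid,
    PipelineHyperparams,
    extract_signature,
    fit_pipeline,
    kkt_violation,
    learning_curve,
    loo_grid_search,
    prediction_metrics,
)
from rpnsig.signature import apply_signature, default_node_order, load_rpn_signature


def planted_data(n=100, p=50, noise=0.1, seed=0, signal_col=5, slope=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = slope * X[:, signal_col] + noise * rng.normal(size=n)
    return X, y


class TestFitPipeline:
    def test_huge_alpha_shrinks_everything_to_intercept(self):
        X, y = planted_data()
        fp = fit_pipeline(X, y, PipelineHyperparams(10, 0.5, 1e6))
        assert np.all(fp.coef == 0)
        assert fp.intercept == pytest.approx(y.mean())
        assert fp.predict(X) == pytest.approx(np.full_like(y, y.mean()))

    def test_planted_signal_selected_and_predictive(self):
        X, y = planted_data(seed=3)
        Xte, yte = planted_data(seed=4)
        fp = fit_pipeline(X, y, PipelineHyperparams(10, 0.5, 0.01))
        assert 5 in fp.selected
        w = fp.coef[np.where(fp.selected == 5)[0][0]]
        assert w > 0
        r = np.corrcoef(yte, fp.predict(Xte))[0, 1]
        assert r > 0.9

    @pytest.mark.parametrize("hp", [
        PipelineHyperparams(10, 0.5, 0.01),
        PipelineHyperparams(25, 0.999, 0.005),
        PipelineHyperparams(5, 0.1, 0.1),
    ])
    def test_kkt_optimality_certificate(self, hp):
        X, y = planted_data(seed=8)
        fp = fit_pipeline(X, y, hp)
        assert kkt_violation(fp, X, y) < 1e-4

    def test_zero_iqr_feature_gets_unit_scale(self):
        X, y = planted_data(n=40, p=6, seed=1)
        X[:, 2] = 7.0  # constant feature
        fp = fit_pipeline(X, y, PipelineHyperparams(3, 0.5, 0.05))
        assert fp.iqr[2] == 1.0
        assert np.isfinite(fp.predict(X)).all()

    def test_errors(self):
        X, y = planted_data(n=20, p=10)
        with pytest.raises(ValueError, match="k_best"):
            fit_pipeline(X, y, PipelineHyperparams(11, 0.5, 0.1))
        with pytest.raises(ValueError, match="constant"):
            fit_pipeline(X, np.ones(20), PipelineHyperparams(5, 0.5, 0.1))

    def test_affine_feature_transform_invariance(self):
        """Robust scaling absorbs per-feature affine maps: predictions agree."""
        X, y = planted_data(n=60, p=20, seed=6)
        hp = PipelineHyperparams(8, 0.5, 0.05)
        scale = np.linspace(0.5, 3.0, 20)
        shift = np.linspace(-5, 5, 20)
        Xa = X * scale + shift
        p1 = fit_pipeline(X, y, hp).predict(X)
        p2 = fit_pipeline(Xa, y, hp).predict(Xa)
        assert p1 == pytest.approx(p2, abs=1e-6)


class TestLooGridSearch:
    def test_produces_n_folds(self):
        X, y = planted_data(n=20, p=15, seed=2)
        grid = HyperparamGrid(k_values=(5,), l1_ratios=(0.5,), alphas=(0.05,))
        best, ycv = loo_grid_search(X, y, grid)
        assert ycv.shape == (20,)
        assert best == PipelineHyperparams(5, 0.5, 0.05)

    def test_single_cell_matches_direct_loo(self):
        X, y = planted_data(n=15, p=10, seed=9)
        hp = PipelineHyperparams(4, 0.7, 0.02)
        grid = HyperparamGrid(k_values=(4,), l1_ratios=(0.7,), alphas=(0.02,))
        _, ycv = loo_grid_search(X, y, grid)
        direct = np.array([
            fit_pipeline(np.delete(X, i, 0), np.delete(y, i), hp).predict(X[i:i+1])[0]
            for i in range(15)
        ])
        assert ycv == pytest.approx(direct, abs=1e-12)

    def test_grid_selects_low_error_cell(self):
        X, y = planted_data(n=40, p=20, seed=12)
        grid = HyperparamGrid(k_values=(5, 10), l1_ratios=(0.5,), alphas=(0.01, 1e5))
        best, ycv, table = loo_grid_search(X, y, grid, return_table=True)
        assert best.alpha == 0.01
        assert len(table) == 4
        assert table["loo_mse"].min() == pytest.approx(np.mean((y - ycv) ** 2))

    def test_label_permutation_gives_no_skill(self):
        """No-leakage: with permuted labels the pooled LOO explained variance
        stays at chance over seeded replicates."""
        rng = np.random.default_rng(21)
        evs = []
        grid = HyperparamGrid(k_values=(5,), l1_ratios=(0.5,), alphas=(0.05,))
        for _ in range(5):
            X = rng.normal(size=(25, 40))
            y = rng.permutation(rng.normal(size=25))
            _, ycv = loo_grid_search(X, y, grid)
            evs.append(prediction_metrics(y, ycv)["explained_variance"])
        assert np.mean(evs) <= 0.05


class TestLearningCurve:
    def test_deterministic_given_seed(self):
        X, y = planted_data(n=60, p=20, seed=5)
        hp = PipelineHyperparams(8, 0.5, 0.05)
        a = learning_curve(X, y, hp, train_fractions=(0.4, 0.8), n_repeats=5, seed=3)
        b = learning_curve(X, y, hp, train_fractions=(0.4, 0.8), n_repeats=5, seed=3)
        assert a.equals(b)

    def test_generalisation_gap_shrinks_with_n(self):
        X, y = planted_data(n=140, p=30, noise=0.8, seed=10)
        hp = PipelineHyperparams(10, 0.5, 0.01)
        lc = learning_curve(
            X, y, hp, train_fractions=(0.15, 0.7), n_repeats=20, seed=0
        )
        gap = lc["test_mse_mean"] - lc["train_mse_mean"]
        assert gap.iloc[0] > gap.iloc[1]

    def test_too_small_subset_rejected(self):
        X, y = planted_data(n=20, p=10)
        with pytest.raises(ValueError):
            learning_curve(X, y, PipelineHyperparams(3, 0.5, 0.1),
                           train_fractions=(0.1,), n_repeats=2, seed=0)


class TestSignatureExtractApply:
    def test_round_trip_equals_pipeline_predictions(self):
        X, y = planted_data(n=50, p=45, seed=7)
        n_nodes = 10  # 45 = 10*9/2
        labels = [f"node{i}" for i in range(n_nodes)]
        fp = fit_pipeline(X, y, PipelineHyperparams(12, 0.7, 0.02))
        sig = extract_signature(fp, labels)
        scores = apply_signature(sig, X, labels=labels)
        assert scores == pytest.approx(fp.predict(X), abs=1e-10)

    def test_entry_count_is_nonzero_weight_count(self):
        X, y = planted_data(n=50, p=45, seed=7)
        fp = fit_pipeline(X, y, PipelineHyperparams(12, 0.999, 0.05))
        sig = extract_signature(fp, [f"n{i}" for i in range(10)])
        assert sig.n_connections == int(np.count_nonzero(fp.coef))

    def test_all_zero_fit_keeps_intercept(self):
        X, y = planted_data(n=30, p=10)
        fp = fit_pipeline(X, y, PipelineHyperparams(5, 0.5, 1e6))
        sig = extract_signature(fp, [f"n{i}" for i in range(5)])
        assert sig.n_connections == 0
        scores = apply_signature(sig, X, labels=[f"n{i}" for i in range(5)])
        assert scores == pytest.approx(np.full(30, fp.intercept))

    def test_hand_computed_full_mode_score(self):
        from rpnsig.signature import SignatureEntry, TrainedSignature

        sig = TrainedSignature(
            entries=[SignatureEntry("a", "b", 2.0, median=0.0, iqr=1.0)],
            intercept=0.5,
        )
        conn = ConnectivityMatrix(
            values=np.array([[0, 0.3], [0.3, 0]]), labels=["a", "b"]
        )
        assert apply_signature(sig, conn) == pytest.approx(1.1)

    def test_weights_only_is_affine_in_full_scores(self):
        """With equal IQRs, weights-only scores are an increasing affine
        function of full-mode scores."""
        from dataclasses import replace

        X, y = planted_data(n=50, p=45, seed=13)
        labels = [f"n{i}" for i in range(10)]
        fp = fit_pipeline(X, y, PipelineHyperparams(8, 0.7, 0.02))
        sig = extract_signature(fp, labels)
        const_iqr = [replace(e, iqr=1.0) for e in sig.entries]
        full = replace(sig, entries=const_iqr)
        wonly = replace(
            sig, entries=[replace(e, median=None, iqr=None) for e in const_iqr],
            mode="weights_only", intercept=None,
        )
        s_full = apply_signature(full, X, labels=labels)
        s_w = apply_signature(wonly, X, labels=labels)
        fit = np.polyfit(s_full, s_w, 1)
        assert fit[0] > 0
        assert s_w == pytest.approx(np.polyval(fit, s_full), abs=1e-8)

    def test_missing_node_pair_reported(self):
        sig = load_rpn_signature()
        conn = ConnectivityMatrix(values=np.zeros((4, 4)), labels=list("abcd"))
        with pytest.raises(KeyError, match="pPut"):
            apply_signature(sig, conn)

    def test_packaged_signature_uses_21_connections(self, rng):
        sig = load_rpn_signature()
        labels = [n["label"] for n in default_node_order()]
        atlas = [n["atlas_index"] for n in default_node_order()]
        assert sig.n_connections == 21
        x = rng.normal(size=123 * 122 // 2)
        score = apply_signature(sig, x, labels=labels, atlas_indices=atlas)
        # score is exactly the dot product over the 21 mapped connections
        from rpnsig.connectome import feature_index
        from rpnsig.signature import resolve_entry_positions

        pos = resolve_entry_positions(sig, labels, atlas)
        assert len(pos) == 21
        manual = sum(
            e.weight * x[feature_index(i, j, 123)]
            for e, (i, j) in zip(sig.entries, pos)
        )
        assert score == pytest.approx(manual, abs=1e-12)


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.5, -0.3, 1.2])
        m = prediction_metrics(y, y)
        assert m["mse"] == 0 and m["mae"] == 0
        assert m["explained_variance"] == pytest.approx(1.0)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_hand_computed_case(self):
        m = prediction_metrics([0, 1, 2], [0, 1, 1])
        assert m["mse"] == pytest.approx(1 / 3)
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["explained_variance"] == pytest.approx(2 / 3)
        assert m["pearson_r"] == pytest.approx(np.sqrt(3) / 2, abs=1e-6)

    def test_constant_prediction(self):
        m = prediction_metrics([0.0, 1.0, 2.0], [0.5, 0.5, 0.5])
        assert m["explained_variance"] == pytest.approx(0.0)
        assert np.isnan(m["pearson_r"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            prediction_metrics([1, 2, 3], [1, 2])


class TestModelResultsSurface:
    def test_fit_and_summary(self):
        X, y = planted_data(n=40, p=45, seed=2)
        labels = [f"n{i}" for i in range(10)]
        model = ConnectomePredictiveModel(X, y, node_labels=labels)
        res = model.fit(PipelineHyperparams(8, 0.7, 0.02))
        text = res.summary()
        assert "K-best: 8" in text
        assert res.kkt_violation() < 1e-4
        assert res.predict().shape == (40,)

    def test_fit_loo_carries_cv_metrics(self):
        X, y = planted_data(n=15, p=10, seed=4)
        model = ConnectomePredictiveModel(X, y)
        grid = HyperparamGrid(k_values=(4,), l1_ratios=(0.5,), alphas=(0.05,))
        res = model.fit_loo(grid)
        assert res.y_cv.shape == (15,)
        assert set(res.cv_metrics) == {"mse", "mae", "explained_variance", "pearson_r"}

    def test_from_matrices(self, rng):
        mats = []
        for _ in range(6):
            m = rng.normal(size=(5, 5))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(ConnectivityMatrix(values=m, labels=list("abcde")))
        model = ConnectomePredictiveModel.from_matrices(mats, rng.normal(size=6))
        assert model.n_features == 10
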