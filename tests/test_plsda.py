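"""PLS-DA: NIPALS algebra, VIP, BER cross-validation, selection, validation."""

import numpy as np
import pandas as pd
import pytest

from metabodisc import (
    InputError,
    balanced_error_rate,
    cross_validate,
    fit,
    iterative_selection,
    permuted_validate,
    predict,
    transform,
    validate,
    vip_scores,
)
from metabodisc.plsda import _aggregate_report, _dummy_matrix

from conftest import two_group_labels


def _separable_data(n_per_group=13, p=8, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_group, p))
    X[n_per_group:, 0] += gap  # H shifted on variable 1
    return X, two_group_labels(n_per_group)


def _noisy_data(n_per_group=13, p=10, effect=1.0, n_inf=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_group, p))
    X[n_per_group:, :n_inf] += effect
    return X, two_group_labels(n_per_group)


class TestFit:
    def test_separable_case_weight_and_training_error(self):
        X, y = _separable_data()
        model = fit(X, y, 2)
        assert np.argmax(np.abs(model.weights[:, 0])) == 0
        assert balanced_error_rate(y, predict(model, X)) == 0.0

    def test_component1_matches_svd_oracle(self):
        """The first NIPALS weight vector is the dominant left singular
        vector of Xᵀ·Y_dummy (both centered)."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((8, 5))
        y = np.array(["H", "L", "H", "L", "H", "L", "H", "L"])
        model = fit(X, y, 1)
        Xc = X - X.mean(axis=0)
        u, _, _ = np.linalg.svd(Xc.T @ _dummy_matrix(y, ("H", "L")))
        cosine = abs(model.weights[:, 0] @ u[:, 0])
        assert cosine >= 1 - 1e-10

    def test_matches_sklearn_nipals(self):
        """Independent cross-check against scikit-learn's PLSRegression on
        the centered class-indicator response (same NIPALS convention)."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _noisy_data(seed=3)
        model = fit(X, y, 2)
        ref = sklearn_pls.PLSRegression(n_components=2, scale=False).fit(
            X, _dummy_matrix(y, ("H", "L"))
        )
        for a in range(2):
            sign = np.sign(model.weights[:, a] @ ref.x_weights_[:, a])
            np.testing.assert_allclose(
                model.weights[:, a], sign * ref.x_weights_[:, a], atol=1e-8
            )
            np.testing.assert_allclose(
                model.x_scores[:, a], sign * ref.x_scores_[:, a], atol=1e-8
            )

    def test_vip_matches_mixomics_reference(self):
        """Frozen cross-check: VIP from Bioconductor mixOmics 6.26 vip() on
        this exact seeded fixture (plsda, ncomp=2, scale=FALSE)."""
        rng = np.random.default_rng(123)
        X = rng.standard_normal((12, 6))
        y = np.array(["H"] * 6 + ["L"] * 6)
        X[:6, 0] += 1.5
        model = fit(X, y, 2)
        expected = [1.315212, 0.676222, 0.763057, 0.833493, 1.424853, 0.711174]
        np.testing.assert_allclose(model.vip, expected, atol=1e-5)

    def test_row_permutation_equivariance(self):
        X, y = _noisy_data(seed=5)
        model = fit(X, y, 2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        permuted = fit(X[perm], y[perm], 2)
        np.testing.assert_allclose(permuted.weights, model.weights, atol=1e-9)
        np.testing.assert_allclose(permuted.x_scores, model.x_scores[perm], atol=1e-9)

    def test_score_orthogonality(self):
        X, y = _noisy_data(p=15, seed=6)
        model = fit(X, y, 4)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        with pytest.raises(InputError):
            fit(X, np.array(["H"] * 6), 1)


class TestPredict:
    def test_sample_on_centroid_gets_that_class(self):
        X, y = _separable_data()
        model = fit(X, y, 2)
        # synthesize observations whose scores sit exactly on each centroid
        for cls in model.classes:
            target = model.class_centroids[cls]
            # x = mean + P t reproduces score t under the rotation projector
            x = model.x_mean + model.x_loadings @ target
            assert predict(model, x[None, :])[0] == cls

    def test_matches_brute_force_mahalanobis(self):
        X, y = _noisy_data(seed=8)
        model = fit(X, y, 2)
        X_new = np.random.default_rng(9).standard_normal((7, X.shape[1]))
        scores = transform(model, X_new)
        cov_inv = np.linalg.inv(model.score_covariance)
        expected = []
        for t in scores:
            d = {
                c: (t - model.class_centroids[c]) @ cov_inv @ (t - model.class_centroids[c])
                for c in model.classes
            }
            expected.append(min(d, key=d.get))
        assert list(predict(model, X_new)) == expected

    def test_one_component_reduces_to_nearest_centroid(self):
        X, y = _noisy_data(seed=10)
        model = fit(X, y, 1)
        scores = transform(model, X)[:, 0]
        c = {cls: model.class_centroids[cls][0] for cls in model.classes}
        expected = [min(c, key=lambda k: (s - c[k]) ** 2) for s in scores]
        assert list(predict(model, X)) == expected

    def test_column_mismatch_rejected(self):
        X, y = _noisy_data()
        model = fit(X, y, 1)
        with pytest.raises(InputError):
            predict(model, X[:, :3])


class TestVip:
    def test_squared_vip_sums_to_p(self):
        for seed in (0, 1, 2):
            X, y = _noisy_data(p=12, seed=seed)
            model = fit(X, y, 3)
            assert np.sum(model.vip**2) == pytest.approx(X.shape[1], abs=1e-8)

    def test_single_component_collapse(self):
        X, y = _noisy_data(seed=4)
        model = fit(X, y, 1)
        w = model.weights[:, 0]
        expected = np.sqrt(X.shape[1]) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(model.vip, expected, atol=1e-10)

    def test_matches_direct_formula(self):
        X, y = _noisy_data(seed=12)
        model = fit(X, y, 2)
        W, T, Q = model.weights, model.x_scores, model.y_loadings
        p = W.shape[0]
        ss = np.array(
            [(Q[:, a] @ Q[:, a]) * (T[:, a] @ T[:, a]) for a in range(2)]
        )
        expected = np.sqrt(
            [
                p * sum(ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2 for a in range(2))
                / ss.sum()
                for j in range(p)
            ]
        )
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-10)


class TestCrossValidation:
    def test_ber_definition(self):
        y_true = np.array(["L"] * 10 + ["H"] * 10)
        y_pred = y_true.copy()
        y_pred[:1] = "H"  # 10% error in L
        y_pred[10:13] = "L"  # 30% error in H
        assert balanced_error_rate(y_true, y_pred) == pytest.approx(0.20)

    def test_separable_data_reaches_zero_ber(self):
        X, y = _separable_data()
        cv = cross_validate(X, y, max_ncomp=3, repeats=20, seed=1)
        assert cv.best_ber <= 0.02
        assert cv.ber_by_ncomp[cv.chosen_ncomp - 1] == min(cv.ber_by_ncomp)

    def test_randomized_labels_give_chance_ber(self):
        """Permutation null: a fresh label shuffle per repeat keeps the mean
        BER at the 50% chance level."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((26, 10))
        y = two_group_labels(13)
        bers = [
            cross_validate(
                X, rng.permutation(y), max_ncomp=2, repeats=1, seed=200 + r
            ).ber_by_ncomp.mean()
            for r in range(120)
        ]
        assert abs(np.mean(bers) - 0.5) < 0.05

    def test_deterministic_given_seed(self):
        X, y = _noisy_data(seed=20)
        a = cross_validate(X, y, repeats=10, seed=5)
        b = cross_validate(X, y, repeats=10, seed=5)
        np.testing.assert_array_equal(a.ber_by_ncomp, b.ber_by_ncomp)


class TestIterativeSelection:
    def test_threshold_zero_terminates_immediately(self):
        X, y = _noisy_data(seed=1)
        _, _, trace = iterative_selection(
            X, y, seed=1, tune_repeats=5, vip_threshold=0.0
        )
        assert len(trace) == 1

    def test_returned_ber_is_trace_minimum(self):
        X, y = _noisy_data(p=30, n_inf=5, effect=1.2, seed=7)
        model, cv, trace = iterative_selection(X, y, seed=2, tune_repeats=10)
        assert cv.best_ber == min(t["ber"] for t in trace)
        assert len(model.retained_ids) in {t["n_variables"] for t in trace}

    def test_selection_enriches_informative_variables(self):
        """With 3 of 30 variables carrying signal, the pruned set should be
        enriched for them (quick version of the enrichment property)."""
        X, y = _noisy_data(p=30, n_inf=3, effect=2.0, seed=9)
        Xdf = pd.DataFrame(X, columns=[f"V{j + 1}" for j in range(30)])
        model, _, _ = iterative_selection(Xdf, y, seed=3, tune_repeats=10)
        informative = {"V1", "V2", "V3"}
        hits = informative & set(model.retained_ids)
        frac_sel = len(hits) / len(model.retained_ids)
        assert frac_sel > 3 / 30  # denser than chance


class TestValidation:
    def test_counts_arithmetic(self):
        counts = pd.DataFrame(
            [[8.0, 1.0], [2.0, 9.0]], index=["H", "L"], columns=["H", "L"]
        )
        rep = _aggregate_report(counts, folds=4, repeats=1, seed=0, permuted=False)
        # positive class L: TP=9, FN=2, FP=1, TN=8
        assert rep.precision == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(17 / 20)
        assert rep.confusion_percent.loc["L", "L"] == pytest.approx(9 / 11 * 100)
        assert np.allclose(rep.confusion_percent.sum(axis=1), 100.0)

    def test_perfect_classifier(self):
        X, y = _separable_data(gap=10.0)
        model = fit(X, y, 1)
        rep = validate(model, X, y, repeats=30, seed=4)
        assert rep.accuracy == 1.0
        assert rep.precision == 1.0
        assert rep.confusion_percent.loc["L", "L"] == 100.0

    def test_monte_carlo_stability_across_seeds(self):
        """Two independent validation runs agree to within a couple of
        points per class at several hundred repeats."""
        X, y = _noisy_data(effect=1.0, seed=15)
        model = fit(X, y, 2)
        r1 = validate(model, X, y, repeats=400, seed=1)
        r2 = validate(model, X, y, repeats=400, seed=2)
        diff = (r1.confusion_percent - r2.confusion_percent).abs().to_numpy()
        assert diff.max() < 2.0

    def test_permuted_tp_percent_near_chance(self):
        X, y = _noisy_data(effect=2.0, seed=16)
        model = fit(X, y, 2)
        rep = permuted_validate(model, X, y, repeats=200, seed=5)
        assert rep.permuted
        assert abs(rep.tp_percent - 50.0) < 5.0
        assert np.allclose(rep.confusion_percent.sum(axis=1), 100.0)
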