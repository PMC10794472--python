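import numpy as np
import pytest
import scipy.stats

from pa_ssid.classify import (
    anova_bonferroni,
    confidence_ellipse,
    confusion_and_accuracy,
    features_to_matrix,
    fit_lda,
    predict,
    run_benchmark,
    transform_lda,
)
from pa_ssid.synthetic import SimulationConfig


class TestAnovaBonferroni:
    def test_identical_groups(self):
        gc = anova_bonferroni({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        assert gc.anova_F == pytest.approx(0.0)
        info = gc.pairwise[("A", "B")]
        assert info["p_adj"] == 1.0
        assert info["stars"] == ""

    def test_bonferroni_arithmetic(self):
        # 5 classes -> 10 pairs; every adjusted p must equal min(1, 10 * raw)
        rng = np.random.default_rng(0)
        data = {c: rng.normal(k, 1, size=6) for k, c in enumerate("ABCDE")}
        gc = anova_bonferroni(data)
        assert len(gc.pairwise) == 10
        for info in gc.pairwise.values():
            assert info["p_adj"] == pytest.approx(min(1.0, 10 * info["p_raw"]))

    def test_star_grades(self):
        rng = np.random.default_rng(1)
        data = {"A": rng.normal(0, 1, 50), "B": rng.normal(5, 1, 50)}
        gc = anova_bonferroni(data)
        assert gc.pairwise[("A", "B")]["stars"] == "***"

    def test_star_thresholds(self):
        from pa_ssid.classify import _stars

        assert _stars(0.04) == "*"
        assert _stars(0.009) == "**"
        assert _stars(0.0009) == "***"
        assert _stars(0.2) == ""

    def test_type_one_error_rate(self):
        # 5 null classes, 1000 replicates: rejection rate ~ 5% +/- 1.5%
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(size=7) for _ in range(5)]
            _, p = scipy.stats.f_oneway(*groups)
            data = {c: g for c, g in zip("ABCDE", groups)}
            gc = anova_bonferroni(data)
            assert gc.anova_p == pytest.approx(p)
            rejections += gc.anova_p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.015

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_bonferroni({"A": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_bonferroni({"A": [1.0], "B": [2.0, 3.0]})
        with pytest.raises(ValueError):
            anova_bonferroni({"A": [1.0, 1.0], "B": [1.0, 1.0]})


class TestLDA:
    def test_two_separated_1d_classes(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 1, 50), rng.normal(10, 1, 50)].reshape(-1, 1)
        y = ["a"] * 50 + ["b"] * 50
        model = fit_lda(X, y, shrinkage=0.0)
        assert model.discriminant_basis.shape == (1, 1)
        assert predict(model, X) == y  # training accuracy 100%

    def test_discriminant_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = [c for c in "ABCDE" for _ in range(10)]
        X[:, 0] += [ord(c) for c in y]
        model = fit_lda(X, y, shrinkage=0.0)
        assert model.discriminant_basis.shape == (4, 4)
        assert model.priors.sum() == pytest.approx(1.0)

    def test_affine_invariance_of_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = [c for c in "ABC" for _ in range(20)]
        X += np.array([[3.0 * ord(c) % 7, 0, ord(c) % 3, 0] for c in y])
        base = predict(fit_lda(X, y, shrinkage=0.0), X)
        for _ in range(20):
            T = rng.normal(size=(4, 4))
            while abs(np.linalg.det(T)) < 0.1:
                T = rng.normal(size=(4, 4))
            Xt = X @ T
            assert predict(fit_lda(Xt, y, shrinkage=0.0), Xt) == base

    def test_mean_scores_are_projected_centroids(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        y = [c for c in "ABCDE" for _ in range(10)]
        X[:, 0] += [ord(c) % 5 for c in y]
        model = fit_lda(X, y, shrinkage=0.0)
        scores = transform_lda(model, model.class_means)
        W = model.discriminant_basis[:, :2]
        assert np.allclose(scores, model.class_means @ W)

    def test_constant_shift_preserves_geometry(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        X[:20, 0] += 4
        X[40:, 1] += 4
        model = fit_lda(X, y, shrinkage=0.0)
        s1 = transform_lda(model, X)
        s2 = transform_lda(model, X + np.array([1.0, -2.0, 0.5]))
        d1 = s1[:5] - s1[5:10]
        d2 = s2[:5] - s2[5:10]
        assert np.allclose(d1, d2)

    def test_ld1_carries_most_between_class_variance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        y = [c for c in "ABCDE" for _ in range(20)]
        X[:, 0] += [3.0 * (ord(c) % 5) for c in y]
        X[:, 1] += [0.5 * (ord(c) % 3) for c in y]
        model = fit_lda(X, y, shrinkage=0.0)
        scores = transform_lda(model, X)

        def between_var(col):
            means = [scores[[l == c for l in y], col].mean() for c in "ABCDE"]
            return np.var(means)

        assert between_var(0) >= between_var(1)

    def test_class_mean_predicts_own_class(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        y = ["a"] * 20 + ["b"] * 20
        X[:20] += 5
        model = fit_lda(X, y, shrinkage=0.0)
        assert predict(model, model.class_means) == ["a", "b"]

    def test_tie_breaks_lexicographic(self):
        # mirror-symmetric classes, probe exactly between the means
        pts = np.array([[1.0, 0.5], [1.5, -0.5], [0.5, 0.0]])
        X = np.vstack([pts, -pts])
        y = ["a", "a", "a", "b", "b", "b"]
        model = fit_lda(X, y, shrinkage=0.0)
        assert predict(model, np.array([[0.0, 0.0]])) == ["a"]

    def test_feature_name_mismatch_errors(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        y = ["a"] * 10 + ["b"] * 10
        model = fit_lda(X, y, feature_names=["u", "v"], shrinkage=0.0)
        with pytest.raises(ValueError):
            transform_lda(model, X, feature_names=["v", "u"])

    def test_well_separated_five_class_holdout(self):
        rng = np.random.default_rng(8)
        means = np.eye(5, 4) * 20
        Xtr = np.vstack([rng.normal(m, 1, size=(10, 4)) for m in means])
        ytr = [c for c in "ABCDE" for _ in range(10)]
        Xte = np.vstack([rng.normal(m, 1, size=(4, 4)) for m in means])
        yte = [c for c in "ABCDE" for _ in range(4)]
        model = fit_lda(Xtr, ytr)
        rep = confusion_and_accuracy(yte, predict(model, Xte), model.class_labels)
        assert rep.accuracy == 100.0


class TestConfusion:
    def test_nineteen_of_twenty(self):
        true = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 10 + ["b"] * 9 + ["a"]
        rep = confusion_and_accuracy(true, pred)
        assert rep.accuracy == pytest.approx(95.0)

    def test_perfect_prediction_diagonal(self):
        true = ["a", "b", "c", "a"]
        rep = confusion_and_accuracy(true, true)
        assert rep.accuracy == 100.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_single_column_collapse(self):
        true = ["a", "b", "b", "c"]
        pred = ["b"] * 4
        rep = confusion_and_accuracy(true, pred)
        b = rep.class_labels.index("b")
        assert rep.confusion[:, b].sum() == 4
        assert rep.accuracy == pytest.approx(100 * 2 / 4)

    def test_marginals_and_trace_exact(self):
        rng = np.random.default_rng(0)
        labels = list("ABC")
        true = [labels[i] for i in rng.integers(0, 3, 60)]
        pred = [labels[i] for i in rng.integers(0, 3, 60)]
        rep = confusion_and_accuracy(true, pred)
        for k, c in enumerate(rep.class_labels):
            assert rep.confusion[k].sum() == true.count(c)
        assert rep.confusion.sum() == 60
        assert rep.accuracy == 100.0 * np.trace(rep.confusion) / 60

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            confusion_and_accuracy(["a", "b"], ["a", "z"], class_labels=["a", "b"])


class TestConfidenceEllipse:
    def test_isotropic_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200000, 2)) * 2.0
        e = confidence_ellipse(pts)
        expected = 2.0 * np.sqrt(scipy.stats.chi2.ppf(0.95, 2))
        assert np.allclose(e.semi_axes, expected, rtol=0.02)

    def test_coverage_monte_carlo(self):
        rng = np.random.default_rng(1)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=10000)
        e = confidence_ellipse(pts)
        # count points inside the ellipse
        R = np.array(
            [
                [np.cos(e.rotation), np.sin(e.rotation)],
                [-np.sin(e.rotation), np.cos(e.rotation)],
            ]
        )
        z = (pts - e.center) @ R.T / e.semi_axes
        inside = np.sum(np.sum(z**2, axis=1) <= 1.0) / len(pts)
        assert abs(inside - 0.95) <= 0.01

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.multivariate_normal([0, 0], [[3.0, 0], [0, 1.0]], size=500)
        e0 = confidence_ellipse(pts)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        e1 = confidence_ellipse(pts @ R.T)
        d = (e1.rotation - e0.rotation - th) % np.pi
        assert min(d, np.pi - d) < 1e-6

    def test_degenerate_errors(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            confidence_ellipse(pts)
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))


@pytest.fixture(scope="module")
def result():
    return run_benchmark(SimulationConfig(snr_db=30, seed=7))


class TestRunBenchmark:

    def test_all_families_present(self, result):
        assert set(result["families"]) == {"TD", "FD", "ARMA", "SS"}

    def test_reports_on_20_test_samples(self, result):
        for fam, res in result["families"].items():
            assert res["report"].confusion.sum() == 20, fam

    def test_ss_beats_best_baseline_on_average(self):
        # paired comparison over 20 seeds
        accs = {f: [] for f in ("TD", "FD", "ARMA", "SS")}
        for seed in range(1, 21):
            r = run_benchmark(SimulationConfig(snr_db=30, seed=seed))
            for fam, res in r["families"].items():
                accs[fam].append(res["report"].accuracy)
        best_baseline = max(np.mean(accs[f]) for f in ("TD", "FD", "ARMA"))
        assert np.mean(accs["SS"]) >= best_baseline

    def test_determinism(self):
        a = run_benchmark(SimulationConfig(snr_db=30, seed=3), families=("TD", "SS"))
        b = run_benchmark(SimulationConfig(snr_db=30, seed=3), families=("TD", "SS"))
        for fam in ("TD", "SS"):
            assert np.array_equal(
                a["families"][fam]["report"].confusion,
                b["families"][fam]["report"].confusion,
            )

    def test_resubstitution_flagged(self):
        r = run_benchmark(
            SimulationConfig(snr_db=30, seed=3),
            families=("TD",),
            split_spec="resubstitution",
        )
        rep = r["families"]["TD"]["report"]
        assert rep.meta["split_spec"] == "resubstitution"
        assert rep.confusion.sum() == 35

    def test_group_comparisons_present(self, result):
        assert set(result["group_comparisons"]) == {"alpha", "omega_n", "c1", "c2"}
        for gc in result["group_comparisons"].values():
            assert len(gc.pairwise) == 10

    def test_nrmse_by_class(self, result):
        assert set(result["nrmse_by_class"]) == {"HF", "HM", "A1", "A2", "L"}
        for v in result["nrmse_by_class"].values():
            assert v > 90.0


def test_features_to_matrix_roundtrip():
    from pa_ssid.modal import FeatureVector

    fvs = [
        FeatureVector("s0", "a", "TD", {"x": 1.0, "y": 2.0}),
        FeatureVector("s1", "b", "TD", {"x": 3.0, "y": 4.0}),
    ]
    X, labels, names = features_to_matrix(fvs)
    assert X.tolist() == [[1.0, 2.0], [3.0, 4.0]]
    assert labels == ["a", "b"]
    assert names == ["x", "y"]
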