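"""Cross-validation, hyperparameter search, benchmark grid, SMILES classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from diadtox.fingerprints import featurize_dataset
from diadtox.models import (
    ALGORITHMS,
    DiadClassifier,
    ModelConfig,
    benchmark_grid,
    cross_validate,
    evaluate,
    hyperparameter_grid,
    make_classifier,
    select_best,
    tune_hyperparameters,
)


def _planted_bits(n=120, d=12, seed=0, flip=0.0):
    """Sparse binary matrix whose column 0 equals the label.

    Background bits fire at density 0.15, the sparsity regime of real
    substructure fingerprints (keeps Tanimoto neighbourhoods meaningful).
    """
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
    X = (rng.random(size=(n, d)) < 0.15).astype(np.uint8)
    X[:, 0] = y
    if flip:
        noise = rng.random(n) < flip
        X[noise, 0] = 1 - X[noise, 0]
    return X, y


class TestCrossValidate:
    def test_separable_data_near_perfect(self):
        X, y = _planted_bits()
        for algo in ("SVM", "DT", "RF"):
            r = cross_validate(ModelConfig(algo, seed=1), X, y)
            assert r.acc >= 0.95 and r.mcc >= 0.9, algo

    def test_permuted_labels_auc_near_half(self):
        X, y = _planted_bits(n=200, seed=2)
        rng = np.random.default_rng(5)
        aucs = [cross_validate(ModelConfig("NB", seed=3), X, rng.permutation(y)).auc
                for _ in range(8)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_deterministic_given_seed(self):
        X, y = _planted_bits(seed=4, flip=0.2)
        r1 = cross_validate(ModelConfig("RF", seed=9), X, y)
        r2 = cross_validate(ModelConfig("RF", seed=9), X, y)
        assert (r1.cm.tp, r1.cm.fp, r1.cm.tn, r1.cm.fn) == \
               (r2.cm.tp, r2.cm.fp, r2.cm.tn, r2.cm.fn)
        assert r1.auc == r2.auc

    def test_every_record_in_exactly_one_test_fold(self):
        X, y = _planted_bits(n=97)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(len(y), dtype=int)
        for _, test_idx in skf.split(X, y):
            seen[test_idx] += 1
        assert np.all(seen == 1)


class TestTuning:
    def test_single_point_grid_returned(self):
        X, y = _planted_bits()
        cfg = tune_hyperparameters(ModelConfig("SVM"), X, y,
                                   grid=[{"C": 4.0, "gamma": 0.25}])
        assert cfg.hyperparameters == {"C": 4.0, "gamma": 0.25}

    def test_empty_explicit_grid_errors(self):
        X, y = _planted_bits()
        with pytest.raises(ValueError):
            tune_hyperparameters(ModelConfig("SVM"), X, y, grid=[])

    def test_fixed_default_algorithms_unchanged(self):
        X, y = _planted_bits()
        cfg = ModelConfig("RF", hyperparameters={"n_estimators": 50})
        assert tune_hyperparameters(cfg, X, y) is cfg

    def test_knn_tie_break_prefers_larger_k(self):
        # classes occupy disjoint bit supports with one shared anchor bit
        # each: every odd k scores 1.0, so the tie resolves to the largest k
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(40, dtype=int), np.zeros(40, dtype=int)]
        X = np.zeros((80, 6), dtype=np.uint8)
        X[:40, 0] = 1
        X[:40, 1:3] = rng.random((40, 2)) < 0.4
        X[40:, 3] = 1
        X[40:, 4:6] = rng.random((40, 2)) < 0.4
        cfg = tune_hyperparameters(ModelConfig("kNN", seed=0), X, y)
        ks = [g["n_neighbors"] for g in hyperparameter_grid("kNN")]
        assert cfg.hyperparameters["n_neighbors"] == max(ks)

    def test_svm_reaches_perfect_cv_on_separable_data(self):
        X, y = _planted_bits(n=60)
        grid = [{"C": c, "gamma": g} for c in (0.5, 8.0) for g in (0.05, 0.5)]
        cfg = tune_hyperparameters(ModelConfig("SVM", seed=0), X, y, grid=grid)
        r = cross_validate(cfg, X, y)
        assert r.acc == 1.0

    def test_published_grid_shape(self):
        svm = hyperparameter_grid("SVM")
        cs = sorted({g["C"] for g in svm})
        gammas = sorted({g["gamma"] for g in svm})
        assert cs[0] == 2.0**-5 and cs[-1] == 2.0**15
        assert gammas[0] == 2.0**-15 and gammas[-1] == 2.0**3
        assert [g["n_neighbors"] for g in hyperparameter_grid("kNN")] == \
               list(range(1, 22, 2))


class TestEvaluate:
    def test_holdout_roc_and_metrics(self):
        X, y = _planted_bits(n=100, seed=6)
        idx = np.random.default_rng(8).permutation(100)  # mix classes
        tr, te = idx[:70], idx[70:]
        model = make_classifier("SVM", seed=0).fit(X[tr].astype(bool), y[tr])
        r = evaluate(model, X[te], y[te])
        assert r.acc >= 0.9 and r.auc is not None and r.roc is not None

    def test_single_class_validation_flagged(self):
        X, y = _planted_bits(n=60, seed=7)
        model = make_classifier("DT", seed=0).fit(X.astype(bool), y)
        r = evaluate(model, X[y == 1], y[y == 1])
        assert "single_class_validation" in r.flags


class TestBenchmarkGrid:
    def test_rows_and_best_selection(self, separable_set):
        dataset, _, provider = separable_set
        table = benchmark_grid(dataset, schemes=[provider], algorithms=["SVM", "kNN"],
                               seed=0)
        assert len(table) == 2
        assert set(table["Model"]) == {f"{provider.name}_SVM",
                                       f"{provider.name}_kNN"}
        assert (table["error"] == "").all()
        best = select_best(table)
        assert best in set(table["Model"])

    def test_failed_scheme_flagged_grid_continues(self, separable_set):
        dataset, _, provider = separable_set
        table = benchmark_grid(dataset, schemes=["KRFP", provider],
                               algorithms=["NB"], seed=0)
        krfp_row = table[table["Model"] == "KRFP_NB"].iloc[0]
        assert "definition" in krfp_row["error"]
        ok_row = table[table["Model"] == f"{provider.name}_NB"].iloc[0]
        assert ok_row["error"] == ""

    def test_deterministic_rerun(self, separable_set):
        dataset, _, provider = separable_set
        t1 = benchmark_grid(dataset, [provider], ["SVM"], seed=5)
        t2 = benchmark_grid(dataset, [provider], ["SVM"], seed=5)
        pd.testing.assert_frame_equal(t1.drop(columns=["hyperparameters"]),
                                      t2.drop(columns=["hyperparameters"]))


class TestDiadClassifier:
    def test_fit_predict_on_smiles(self, separable_set):
        dataset, _, provider = separable_set
        clf = DiadClassifier(scheme=provider, algorithm="SVM", seed=0)
        clf.fit(dataset.smiles(), dataset.labels())
        assert clf.cv_report_.mcc >= 0.95
        preds = clf.predict(dataset.smiles()[:10])
        assert set(preds) <= {0, 1}
        table = clf.score_table([r.id for r in dataset.records[:5]],
                                dataset.smiles()[:5])
        assert list(table.columns) == ["id", "label", "score"]

    def test_sklearn_clone_compatible(self):
        clf = DiadClassifier(algorithm="kNN", seed=3)
        params = clone(clf).get_params()
        assert params["algorithm"] == "kNN" and params["seed"] == 3

    def test_nonbinary_labels_rejected(self):
        clf = DiadClassifier()
        with pytest.raises(ValueError):
            clf.fit(["CCO", "CCN"], [1, 2])


def test_algorithm_aliases_resolve():
    assert ModelConfig("CT").algorithm == "DT"
    assert ModelConfig("SVM-RBF").algorithm == "SVM"
    with pytest.raises(ValueError):
        ModelConfig("perceptron")
    assert set(ALGORITHMS) == {"SVM", "NB", "kNN", "DT", "RF"}
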