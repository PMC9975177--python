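import numpy as np
import pytest

from patchscreen import (
    AnomalySpec,
    ConfusionCounts,
    PhantomConfig,
    PipelineConfig,
    SSLConfig,
    auroc,
    confusion_metrics,
    cross_validate,
)
from patchscreen.evaluation import counts_from_decisions, evaluate_scores
from patchscreen.exceptions import InvalidInputError
from patchscreen.synthetic_data import generate_normal, inject_anomaly


def pair_counting_auroc(labels, scores):
    """Brute-force Mann-Whitney oracle: ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_worked_count_table(self):
        m = confusion_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (m.accuracy, m.precision, m.sensitivity, m.specificity) == (1, 1, 1, 1)

    def test_undefined_ratios_flagged_not_zeroed(self):
        m = confusion_metrics(ConfusionCounts(TP=0, FP=0, TN=4, FN=0))
        assert m.sensitivity is None  # no abnormal images at all
        assert m.precision is None  # no positive predictions
        assert m.specificity == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            ConfusionCounts(TP=0, FP=0, TN=0, FN=0)

    @pytest.mark.parametrize(
        "tp,fp,tn,fn", [(3, 1, 4, 2), (1, 0, 9, 0), (2, 5, 3, 7), (10, 1, 1, 10)]
    )
    def test_accuracy_decomposes_into_class_rates(self, tp, fp, tn, fn):
        m = confusion_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        P, N = tp + fn, tn + fp
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_scores_tied(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_worked_example(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties
            scores = np.round(rng.uniform(size=n), 1)
            assert auroc(labels, scores) == pytest.approx(
                pair_counting_auroc(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_invariant_to_evaluation_order(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        scores = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert auroc(labels, scores) == auroc(labels[perm], scores[perm])


def test_counts_from_decisions():
    counts = counts_from_decisions(
        [1, 1, 0, 0], ["abnormal", "normal", "abnormal", "normal"]
    )
    assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 1, 1, 1)


def test_evaluate_scores_bundles_all_metrics():
    out = evaluate_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], threshold=0.5)
    assert out["auroc"] == 1.0 and out["accuracy"] == 1.0


@pytest.fixture(scope="module")
def tiny_cv_problem():
    """A miniature one-class CV problem: 32x32 phantoms, one patch size."""
    phantom = PhantomConfig(side=32, rib_period_px=7.0, jitter=0.01)
    spec = AnomalySpec(diameter_range=(6.0, 12.0), contrast_range=(0.3, 0.5))
    rng = np.random.default_rng(0)
    normal_pool = [(f"n{i}", generate_normal(phantom, rng)) for i in range(8)]
    test = []
    for i in range(3):
        test.append((f"tn{i}", generate_normal(phantom, rng), 0))
    for i in range(3):
        img, _, _ = inject_anomaly(
            generate_normal(phantom, rng), spec, rng, background=phantom.background
        )
        test.append((f"ta{i}", img, 1))
    config = PipelineConfig(
        image_side=32,
        patch_sizes=(16,),
        weights=(1.0,),
        ssl=SSLConfig(
            epochs=1, batch_pairs=4, patches_per_epoch=8, feature_dim=8,
            projection_dim=4, hidden_dim=16, pool_side=8, input_scale=1.0,
        ),
        seed=0,
    )
    return normal_pool, test, config


class TestCrossValidate:
    def test_deterministic_with_balanced_folds(self, tiny_cv_problem):
        normal_pool, test, config = tiny_cv_problem
        r1 = cross_validate(normal_pool, test, config, n_folds=2, seed=3)
        r2 = cross_validate(normal_pool, test, config, n_folds=2, seed=3)
        assert r1.per_fold.equals(r2.per_fold)
        assert len(r1.per_fold) == 2

    def test_metrics_bounded_and_mean_is_arithmetic(self, tiny_cv_problem):
        normal_pool, test, config = tiny_cv_problem
        r = cross_validate(normal_pool, test, config, n_folds=2, seed=1)
        vals = r.per_fold[["accuracy", "auroc"]].to_numpy(dtype=float)
        assert np.all((0 <= vals) & (vals <= 1))
        assert r.mean["auroc"] == pytest.approx(r.per_fold["auroc"].mean())

    def test_report_files(self, tiny_cv_problem, tmp_path):
        normal_pool, test, config = tiny_cv_problem
        r = cross_validate(normal_pool, test, config, n_folds=2, seed=1)
        r.to_csv(tmp_path / "r.csv")
        r.to_json(tmp_path / "r.json")
        import pandas as pd

        table = pd.read_csv(tmp_path / "r.csv")
        assert len(table) == 3  # 2 folds + mean row
        assert table.iloc[-1]["fold"] == "mean"

    def test_single_class_test_pool_rejected(self, tiny_cv_problem):
        normal_pool, test, config = tiny_cv_problem
        only_normals = [t for t in test if t[2] == 0]
        with pytest.raises(InvalidInputError):
            cross_validate(normal_pool, only_normals, config, n_folds=2, seed=0)

    def test_insufficient_normals_rejected(self, tiny_cv_problem):
        normal_pool, test, config = tiny_cv_problem
        with pytest.raises(InvalidInputError):
            cross_validate(normal_pool[:3], test, config, n_folds=2, seed=0)
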