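import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

import acpkit as a
from acpkit.train_eval import ConfusionMatrix, _mean_record

counts = st.integers(min_value=0, max_value=200)


def quick_config(**over):
    base = dict(
        scheme="bpf", architecture="basic", n_units=4, dense_units=8,
        epochs=10, batch_size=8, seed=1,
    )
    base.update(over)
    return a.ModelConfig(**base)


class TestConfusion:
    def test_all_correct(self):
        cm = a.confusion(np.array([0.9, 0.8, 0.1, 0.2]), [1, 1, 0, 0])
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (2, 2, 0, 0)

    def test_half_threshold_counts_positive(self):
        cm = a.confusion(np.array([0.5]), [0])
        assert cm.FP == 1

    def test_enumeration_example(self):
        cm = a.confusion(np.array([0.9, 0.2, 0.8, 0.1]), [1, 1, 0, 0])
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (1, 1, 1, 1)

    def test_accepts_probability_pairs(self):
        pairs = np.array([[0.1, 0.9], [0.8, 0.2]])
        cm = a.confusion(pairs, [1, 0])
        assert (cm.TP, cm.TN) == (1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            a.confusion(np.array([0.5, 0.5]), [1])


class TestMetrics:
    def test_perfect(self):
        m = a.metrics(ConfusionMatrix(TP=50, TN=50, FP=0, FN=0))
        assert (m.acc, m.sen, m.spc, m.mcc) == (100.0, 100.0, 100.0, 1.0)

    def test_independent_test_row_from_counts(self):
        # 172 ACPs + 172 non-ACPs with 152 and 126 correct respectively
        m = a.metrics(ConfusionMatrix(TP=152, FN=20, TN=126, FP=46))
        assert m.acc == pytest.approx(80.81, abs=0.005)
        assert m.sen == pytest.approx(88.37, abs=0.005)
        assert m.spc == pytest.approx(73.26, abs=0.005)
        assert m.mcc == pytest.approx(0.623, abs=0.0005)

    def test_chance_level(self):
        m = a.metrics(ConfusionMatrix(TP=25, TN=25, FP=25, FN=25))
        assert m.mcc == 0.0
        assert m.acc == 50.0

    def test_zero_denominator_convention(self):
        m = a.metrics(ConfusionMatrix(TP=0, TN=10, FP=0, FN=0))
        assert m.mcc == 0.0
        assert m.sen == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            a.metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    def test_mcc_bounds_swap_symmetry_and_sklearn(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = a.metrics(ConfusionMatrix(tp, tn, fp, fn))
        assert -1.0 <= m.mcc <= 1.0
        swapped = a.metrics(ConfusionMatrix(TP=tn, TN=tp, FP=fn, FN=fp))
        assert m.mcc == pytest.approx(swapped.mcc, abs=1e-12)
        # numerators recoverable from the percentages
        assert round(m.acc / 100 * (tp + tn + fp + fn)) == tp + tn
        # cross-check against sklearn on reconstructed label vectors
        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        if len(set(y_true)) == 2 or len(set(y_pred)) == 2:
            assert m.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9
            )


class TestRocAuc:
    def test_perfect_separation(self):
        assert a.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert a.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            a.roc_auc([0.1, 0.9], [1, 1])

    @staticmethod
    def pair_count_oracle(scores, labels):
        scores, labels = np.asarray(scores), np.asarray(labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        return total / (len(pos) * len(neg))

    def test_matches_pair_count_oracle(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            labels = rng.integers(0, 2, size=30)
            if len(set(labels.tolist())) < 2:
                continue
            scores = np.round(rng.random(30), 1)  # coarse grid forces ties
            assert a.roc_auc(scores, labels) == pytest.approx(
                self.pair_count_oracle(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        labels = np.array([1, 0] * 10)
        scores = rng.random(20)
        assert a.roc_auc(scores, labels) == pytest.approx(
            a.roc_auc(np.exp(3 * scores), labels), abs=1e-12
        )


class TestTrain:
    def test_separable_data_reaches_perfect_train_accuracy(self, separable_dataset):
        model = a.train(quick_config(), separable_dataset)
        probs = model.forward(a.encode_dataset(separable_dataset, "bpf"))
        cm = a.confusion(probs, separable_dataset.labels)
        assert a.metrics(cm).acc == 100.0
        assert len(model.training_log) == 10

    def test_epochs_zero_rejected(self):
        with pytest.raises(ValueError):
            quick_config(epochs=0)

    def test_single_class_rejected(self):
        ds = a.PeptideDataset([a.Peptide(f"p{i}", "KKK", label=1) for i in range(4)])
        with pytest.raises(ValueError, match="both classes"):
            a.train(quick_config(), ds)

    def test_seed_determinism(self, separable_dataset):
        m1 = a.train(quick_config(epochs=3), separable_dataset)
        m2 = a.train(quick_config(epochs=3), separable_dataset)
        assert m1.training_log[-1]["loss"] == m2.training_log[-1]["loss"]


class TestCrossValidate:
    def test_five_fold_records_and_mean(self, separable_dataset):
        res = a.cross_validate(
            quick_config(epochs=20, learning_rate=0.01), separable_dataset, K=5, seed=0
        )
        assert len(res.fold_metrics) == 5
        assert res.mean.acc == pytest.approx(
            np.mean([m.acc for m in res.fold_metrics])
        )
        # fully separable data: every fold classifies perfectly
        assert res.mean.acc == 100.0
        assert res.mean.mcc == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list(a.ALPHABET))
        peps = [
            a.Peptide(
                f"r{i}",
                "".join(rng.choice(alphabet, size=12)),
                label=int(i % 2),
            )
            for i in range(60)
        ]
        ds = a.PeptideDataset(peps)
        res = a.cross_validate(quick_config(epochs=2), ds, K=5, seed=0)
        assert abs(res.mean.mcc) < 0.45


class TestGridSearch:
    def test_single_config_is_best(self, separable_dataset):
        cfg = quick_config(epochs=2)
        res = a.grid_search([cfg], separable_dataset, K=2, seed=0)
        assert res.best.config == cfg

    def test_trained_beats_crippled(self, separable_dataset):
        crippled = quick_config(epochs=1, learning_rate=1e-7)
        trained = quick_config(epochs=8)
        res = a.grid_search([crippled, trained], separable_dataset, K=2, seed=0)
        assert res.best.config == trained
        assert res.best.mean.mcc == max(r.mean.mcc for r in res.results)

    def test_duplicate_configs_tie_break_deterministic(self, separable_dataset):
        cfg = quick_config(epochs=2)
        res = a.grid_search([cfg, cfg], separable_dataset, K=2, seed=0)
        assert res.best is res.results[0]

    def test_empty_grid(self, separable_dataset):
        with pytest.raises(ValueError, match="empty grid"):
            a.grid_search([], separable_dataset)


def test_mean_record_arithmetic():
    from acpkit.train_eval import MetricsRecord

    r1 = MetricsRecord(acc=80, sen=70, spc=90, mcc=0.6, auc=0.9)
    r2 = MetricsRecord(acc=90, sen=80, spc=100, mcc=0.8, auc=1.0)
    m = _mean_record([r1, r2])
    assert (m.acc, m.sen, m.spc, m.mcc, m.auc) == (85, 75, 95, 0.7, 0.95)
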