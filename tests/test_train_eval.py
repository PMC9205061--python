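import math

import numpy as np
import pytest

from wgnn_dta import (
    ModelConfig,
    PairDataset,
    PairRecord,
    TrainConfig,
    concordance_index,
    evaluate,
    f1,
    make_folds,
    mse,
    pearson,
    pkd_transform,
    precision,
    recall,
    subsample_negatives,
    train,
)
from wgnn_dta.train_eval import classification_metrics

from conftest import make_cmap


class TestScalarMetrics:
    @pytest.mark.parametrize("tp,fp,expect", [(9, 1, 0.9), (0, 5, 0.0), (5, 0, 1.0)])
    def test_precision(self, tp, fp, expect):
        assert precision(tp, fp) == pytest.approx(expect)

    @pytest.mark.parametrize("tp,fn,expect", [(8, 2, 0.8), (0, 3, 0.0), (3, 0, 1.0)])
    def test_recall(self, tp, fn, expect):
        assert recall(tp, fn) == pytest.approx(expect)

    @pytest.mark.parametrize(
        "p,r,expect", [(1, 1, 1.0), (0.5, 0.5, 0.5), (0.9, 0.6, 0.72), (0, 0, 0.0)]
    )
    def test_f1_harmonic_mean(self, p, r, expect):
        assert f1(p, r) == pytest.approx(expect)

    def test_precision_undefined_flags_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(precision(0, 0))

    @pytest.mark.parametrize(
        "kd,expect", [(10000, 5.0), (1, 9.0), (1e9, 0.0)]
    )
    def test_pkd_transform(self, kd, expect):
        assert pkd_transform(kd) == pytest.approx(expect)

    def test_pkd_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pkd_transform(0.0)


class TestConcordanceIndex:
    def test_perfect_and_reversed_rankings(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert concordance_index(y, y) == 1.0
        assert concordance_index(y, y[::-1]) == 0.0

    def test_one_discordant_pair_of_three(self):
        assert concordance_index([1, 2, 3], [1, 3, 2]) == pytest.approx(2 / 3)

    def test_prediction_ties_get_half_credit(self):
        assert concordance_index([1, 2], [5, 5]) == pytest.approx(0.5)

    def test_no_ordered_pairs_flags_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(concordance_index([2, 2, 2], [1, 2, 3]))

    def test_matches_brute_force_enumeration(self, rng):
        yt = rng.normal(size=40)
        yp = np.round(rng.normal(size=40), 1)  # rounding forces some ties
        num = den = 0.0
        for i in range(40):
            for j in range(40):
                if yt[i] > yt[j]:
                    den += 1
                    if yp[i] > yp[j]:
                        num += 1
                    elif yp[i] == yp[j]:
                        num += 0.5
        assert concordance_index(yt, yp) == pytest.approx(num / den)

    def test_matches_lifelines_reference(self, rng):
        lifelines = pytest.importorskip("lifelines.utils")
        yt = rng.normal(size=50)
        yp = rng.normal(size=50)
        assert concordance_index(yt, yp) == pytest.approx(
            lifelines.concordance_index(yt, yp)
        )


class TestVectorMetrics:
    def test_mse_and_pearson_textbook_formulas(self, rng):
        yt = rng.normal(size=30)
        yp = rng.normal(size=30)
        assert mse(yt, yp) == pytest.approx(np.mean((yt - yp) ** 2))
        r = np.corrcoef(yt, yp)[0, 1]
        assert pearson(yt, yp) == pytest.approx(r)

    def test_classification_metrics_hand_counts(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.2, 0.7, 0.1, 0.3]  # tp=2 fp=1 fn=1 tn=2
        m = classification_metrics(y, s)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert 0 <= m.auc <= 1


class TestSplits:
    def test_five_folds_of_ten_partition_evenly(self):
        folds = make_folds(10, k=5, seed=0)
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = make_folds(23, k=5, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_deterministic_per_seed(self):
        a = make_folds(30, k=5, seed=9)
        b = make_folds(30, k=5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds(10, k=1)

    def test_train_and_validation_never_share_indices(self):
        folds = make_folds(37, k=5, seed=2)
        for i, val in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            assert not set(val) & set(train_idx)


def _binary_dataset(n_pos, n_neg):
    seq = "ACDEFGHIKL"
    cmaps = {"P0": make_cmap(len(seq), {})}
    records = [
        PairRecord(f"M{i}", "CC", "P0", 1.0) for i in range(n_pos)
    ] + [
        PairRecord(f"M{n_pos + i}", "CCC", "P0", 0.0) for i in range(n_neg)
    ]
    return PairDataset(records, {"P0": seq}, cmaps, task="cpi")


class TestSubsampleNegatives:
    def test_one_to_one_ratio(self):
        out = subsample_negatives(_binary_dataset(100, 1000), 1.0, seed=0)
        labels = out.labels
        assert (labels == 1).sum() == 100 and (labels == 0).sum() == 100

    def test_one_to_five_ratio(self):
        out = subsample_negatives(_binary_dataset(100, 1000), 5.0, seed=0)
        assert (out.labels == 0).sum() == 500

    def test_clamped_to_availability_with_warning(self):
        with pytest.warns(UserWarning, match="keeping all"):
            out = subsample_negatives(_binary_dataset(100, 1000), 20.0, seed=0)
        assert (out.labels == 0).sum() == 1000

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            subsample_negatives(_binary_dataset(5, 0), 1.0)


class TestTraining:
    def test_constant_label_dataset_fits_to_mse_below_1e3(self, small_dta_dataset):
        ds, _ = small_dta_dataset
        const = PairDataset(
            [r.__class__(r.mol_id, r.smiles, r.prot_id, 4.0) for r in ds.records[:12]],
            ds.sequences,
            ds.contact_maps,
            task="dta",
        )
        _, history = train(
            const,
            ModelConfig(task="dta", dropout=0.0),
            TrainConfig(epochs=200, learning_rate=0.05, seed=0),
        )
        assert history[-1] < 1e-3

    def test_same_seed_reproduces_first_epoch_loss(self, small_dta_dataset):
        ds, _ = small_dta_dataset
        cfgs = (ModelConfig(task="dta"), TrainConfig(epochs=2, seed=3))
        _, h1 = train(ds, *cfgs)
        _, h2 = train(ds, *cfgs)
        assert h1[0] == h2[0]

    def test_loss_trends_downward_on_learnable_signal(self, small_dta_dataset):
        ds, _ = small_dta_dataset
        _, history = train(
            ds,
            ModelConfig(task="dta"),
            TrainConfig(epochs=40, learning_rate=0.005, seed=1),
        )
        assert history[-1] < 0.5 * history[0]

    def test_task_mismatch_rejected(self, small_dta_dataset):
        ds, _ = small_dta_dataset
        with pytest.raises(ValueError, match="task"):
            train(ds, ModelConfig(task="cpi"), TrainConfig(epochs=1))

    def test_unweighted_ablation_trains_and_evaluates(self, small_dta_dataset):
        ds, _ = small_dta_dataset
        model, history = train(
            ds,
            ModelConfig(task="dta", use_edge_weights=False),
            TrainConfig(epochs=10, learning_rate=0.01, seed=0),
        )
        m = evaluate(model, ds)
        assert np.isfinite(m.mse) and np.isfinite(m.ci)

    def test_cpi_training_and_metrics_end_to_end(self):
        from wgnn_dta import generate_synthetic_dataset

        ds, _ = generate_synthetic_dataset(
            40, task="cpi", seed=5, max_seq_len=200
        )
        model, history = train(
            ds,
            ModelConfig(task="cpi"),
            TrainConfig(epochs=25, learning_rate=0.01, seed=0),
        )
        m = evaluate(model, ds)
        for v in (m.auc, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0
        assert m.auc > 0.5  # better than chance on training data
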