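"""Labels, cohort filtering, splits, sampling, AUROC and the trainer."""

import numpy as np
import pandas as pd
import pytest

from milslide import nn
from milslide.errors import (DegenerateInputError, NumericError, ParameterError,
                             StratificationError, UndefinedMetricError)
from milslide.experiment import (TrainConfig, auroc, derive_labels, evaluate,
                                 filter_cohort, sample_bag, split_bags,
                                 split_cohort, train_model)
from milslide.fixtures import BagSpec, make_bags
from milslide.mil import Bag, create_model


def cohort_frame(values, patients=None):
    n = len(values)
    return pd.DataFrame({
        "slide_id": [f"s{i}" for i in range(n)],
        "patient_id": patients or [f"p{i}" for i in range(n)],
        "n_patches": [1500] * n,
        "marker_value": values,
    })


class TestDeriveLabels:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1]),
        ([1, 2, 2, 3], [0, 0, 0, 1]),      # ties at the median -> label 0
    ])
    def test_median_split_with_tie_policy(self, values, expected):
        out = derive_labels(cohort_frame(values))
        assert list(out.label) == expected

    def test_odd_cohort_splits_strictly_above_median(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(np.arange(1001, dtype=float) * 1.7)
        out = derive_labels(cohort_frame(list(values)))
        # oracle: count of values strictly above the sample median
        assert out.label.sum() == int((values > np.median(values)).sum()) == 500

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            derive_labels(cohort_frame([5.0] * 8))


class TestFilterCohort:
    def test_strictly_greater_boundary(self):
        df = cohort_frame([1, 2, 3, 4])
        df["n_patches"] = [1500, 999, 1000, 2000]
        kept = filter_cohort(df, min_patches=1000)
        assert sorted(kept.n_patches) == [1500, 2000]

    def test_zero_threshold_keeps_all(self):
        df = cohort_frame([1, 2, 3, 4])
        assert len(filter_cohort(df, min_patches=0)) == 4

    def test_all_below_warns_and_returns_empty(self):
        df = cohort_frame([1, 2])
        df["n_patches"] = [10, 20]
        with pytest.warns(UserWarning):
            kept = filter_cohort(df, min_patches=1000)
        assert kept.empty


class TestSplitCohort:
    def test_ten_balanced_slides_split_8_2(self):
        df = derive_labels(cohort_frame(list(range(10))))
        out = split_cohort(df, seed=0)
        assert (out.split == "train").sum() == 8
        assert (out.split == "test").sum() == 2
        test_rows = out[out.split == "test"]
        assert set(test_rows.label) == {0, 1}   # one test slide per class

    def test_split_is_seed_deterministic(self):
        df = derive_labels(cohort_frame(list(np.random.default_rng(1)
                                             .permutation(100).astype(float))))
        a = split_cohort(df, seed=7)
        b = split_cohort(df, seed=7)
        c = split_cohort(df, seed=8)
        assert list(a.split) == list(b.split)
        assert list(a.split) != list(c.split)

    def test_patient_groups_never_span_splits(self):
        values = list(range(12))
        patients = [f"p{i // 2}" for i in range(12)]  # two slides per patient
        df = derive_labels(cohort_frame(values, patients))
        out = split_cohort(df, seed=3)
        spans = out.groupby("patient_id")["split"].nunique()
        assert (spans == 1).all()

    def test_small_class_raises_stratification_error(self):
        df = cohort_frame([1, 2, 3])
        df["label"] = [0, 0, 1]
        with pytest.raises(StratificationError):
            split_cohort(df, seed=0)

    def test_split_partitions_and_preserves_proportions(self):
        rng = np.random.default_rng(5)
        df = derive_labels(cohort_frame(list(rng.permutation(200).astype(float))))
        out = split_cohort(df, seed=0)
        assert set(out.split) == {"train", "test"}
        for lab in (0, 1):
            stratum = out[out.label == lab]
            assert (stratum.split == "test").sum() == round(0.2 * len(stratum))

    def test_k_fold_near_equal_sizes(self):
        df = derive_labels(cohort_frame(list(range(23))))
        out = split_cohort(df, k_folds=5, seed=0)
        sizes = out.split.value_counts()
        assert sizes.max() - sizes.min() <= 2
        assert set(out.split) == {f"fold_{i}" for i in range(5)}

    def test_missing_labels_rejected(self):
        with pytest.raises(ParameterError):
            split_cohort(cohort_frame([1, 2]), seed=0)


class TestSampleBag:
    def bag(self, n=10, d=4):
        rng = np.random.default_rng(0)
        return Bag("b", rng.standard_normal((n, d)),
                   np.arange(2 * n).reshape(n, 2), label=1)

    def test_deterministic_given_seed(self):
        b = self.bag()
        s1 = sample_bag(b, 4, seed=5)
        s2 = sample_bag(b, 4, seed=5)
        assert np.array_equal(s1.H, s2.H)
        assert np.array_equal(s1.coords, s2.coords)

    def test_oversampling_returns_full_bag_in_order(self):
        b = self.bag()
        s = sample_bag(b, 99, seed=0)
        assert np.array_equal(s.H, b.H)

    def test_coords_stay_aligned(self):
        b = self.bag()
        s = sample_bag(b, 4, seed=1)
        for row, coord in zip(s.H, s.coords):
            i = int(np.flatnonzero((b.coords == coord).all(axis=1))[0])
            assert np.array_equal(b.H[i], row)

    def test_uniform_inclusion_frequency(self):
        b = self.bag(n=10)
        counts = np.zeros(10)
        for rep in range(10000):
            s = sample_bag(b, 4, seed=rep)
            for coord in s.coords:
                counts[int(np.flatnonzero((b.coords == coord)
                                          .all(axis=1))[0])] += 1
        freq = counts / 10000
        assert np.all(np.abs(freq - 0.4) <= 0.02)


def brute_force_auroc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_and_antiperfect(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_tied_scores_get_half_credit(self):
        assert auroc([0.7, 0.3, 0.7, 0.2], [1, 0, 0, 1]) == \
            pytest.approx(brute_force_auroc([0.7, 0.3, 0.7, 0.2], [1, 0, 0, 1])) \
            == 0.375

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)    # induce ties
            assert auroc(scores, labels) == \
                pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.5, 0.6], [1, 1])


def tiny_bags(n=16, d=4, seed=0, shift=2.0):
    bags, _, _ = make_bags(BagSpec(n_bags=n, instances_per_bag=8, d=d,
                                   witness_rate=0.5, shift=shift, seed=seed))
    return bags


class TestTrainer:
    def test_frozen_model_stops_after_two_epochs(self):
        bags = tiny_bags()
        cfg = TrainConfig(method="tl", max_epochs=50, early_stop_patience=1,
                          learning_rate=0.0, seed=0)
        res = train_model(bags[:12], bags[12:], cfg)
        assert len(res.history) == 2

    def test_same_seed_reproduces_metric_history(self):
        bags = tiny_bags()
        cfg = TrainConfig(method="abmil", max_epochs=4, seed=3,
                          learning_rate=1e-3, model_kwargs={"hidden": 8})
        h1 = train_model(bags[:12], bags[12:], cfg).history
        h2 = train_model(bags[:12], bags[12:], cfg).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_non_finite_loss_aborts_with_diagnostic(self):
        bags = tiny_bags()
        bags[0].H[0, 0] = np.nan
        cfg = TrainConfig(method="tl", max_epochs=2, seed=0)
        with pytest.raises(NumericError, match="epoch"):
            train_model(bags, bags[:4], cfg)

    def test_abmil_solves_separable_witness_bags(self):
        """With a 3-sigma witness shift the classes are cleanly separable and
        gated attention should reach near-perfect validation AUROC quickly."""
        bags, _, _ = make_bags(BagSpec(seed=0, shift=3.0, witness_rate=0.3))
        train, val, test = split_bags(bags, 0.2, 0.15, seed=0)
        cfg = TrainConfig(method="abmil", seed=0, max_epochs=30,
                          early_stop_patience=30, learning_rate=1e-3,
                          model_kwargs={"hidden": 64})
        res = train_model(train, val, cfg)
        assert res.best_val_auroc >= 0.95
        assert res.best_epoch <= 30

    def test_batch_size_fixed_at_one(self):
        with pytest.raises(ParameterError):
            TrainConfig(batch_size=4)


class TestGradientAccumulation:
    def test_accumulated_window_equals_mean_loss_gradient(self):
        """Accumulating k bag losses scaled by 1/k reproduces, to float
        precision, the gradient of the mean loss over those k bags."""
        bags = tiny_bags(n=8)
        model = create_model("tl", d=4, seed=0)
        model.zero_grad()
        for b in bags[:4]:
            (model.loss(b) * 0.25).backward()
        acc = [p.grad.copy() for p in model.parameters()]

        model.zero_grad()
        total = model.loss(bags[0]) * 0.25
        for b in bags[1:4]:
            total = total + model.loss(b) * 0.25
        total.backward()
        direct = [p.grad.copy() for p in model.parameters()]
        for a, d in zip(acc, direct):
            assert np.allclose(a, d, atol=1e-6)

    def test_sgd_step_on_accumulated_gradients_matches_mean_loss_step(self):
        bags = tiny_bags(n=8)
        m1 = create_model("tl", d=4, seed=0)
        m2 = create_model("tl", d=4, seed=0)
        opt1 = nn.SGD(m1.parameters(), lr=0.1)
        opt2 = nn.SGD(m2.parameters(), lr=0.1)

        opt1.zero_grad()
        for b in bags[:4]:
            (m1.loss(b) * 0.25).backward()
        opt1.step()

        opt2.zero_grad()
        total = m2.loss(bags[0]) * 0.25
        for b in bags[1:4]:
            total = total + m2.loss(b) * 0.25
        total.backward()
        opt2.step()

        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.allclose(p1.data, p2.data, atol=1e-6)


def test_evaluate_returns_scores_and_auroc():
    bags = tiny_bags()
    model = create_model("tl", d=4, seed=0)
    scores, a = evaluate(model, bags)
    assert scores.shape == (len(bags),)
    assert 0.0 <= a <= 1.0
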