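"""Fine-tree tissue classifier: greedy split optimality, determinism,
accuracy on separable and overlapping priors, and tissue aggregation."""

import numpy as np
import pandas as pd
import pytest

from wormquant.classify import (
    TreeModel,
    _best_split,
    aggregate_by_tissue,
    classify,
    evaluate,
    normalized_total_intensity,
    train_tree,
)
from wormquant.priors import TISSUE_CLASSES, bayes_accuracy, sample_features
from wormquant.segmentation import NucleusObject


def _labelled(area, labels):
    X = np.column_stack([area, np.zeros(len(area)), np.sqrt(4 * np.asarray(area) / np.pi)])
    return X, np.asarray(labels, dtype=object)


def exhaustive_best_split(X, y, classes=TISSUE_CLASSES):
    """Brute-force enumeration of every (feature, midpoint) split."""
    idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([idx[v] for v in y])

    def gini(sub):
        if len(sub) == 0:
            return 0.0
        p = np.bincount(sub, minlength=len(classes)) / len(sub)
        return 1.0 - float((p * p).sum())

    n = len(y_idx)
    parent = gini(y_idx)
    best = None
    for f in range(X.shape[1]):
        for t in np.unique(X[:, f])[:-1]:
            uniq = np.unique(X[:, f])
            mid = 0.5 * (t + uniq[uniq > t][0])
            left = y_idx[X[:, f] <= mid]
            right = y_idx[X[:, f] > mid]
            dec = parent - (len(left) / n * gini(left) + len(right) / n * gini(right))
            if best is None or dec > best[2]:
                best = (f, mid, dec)
    return best


class TestTraining:
    def test_perfectly_separable_two_classes_one_split(self):
        X, y = _labelled([10, 20, 30, 70, 80, 90], ["neuron"] * 3 + ["intestine"] * 3)
        model = train_tree(X, y)
        assert model.n_splits == 1
        acc, _ = evaluate(model, X, y)
        assert acc == 1.0
        assert model.root.feature == 0 and 30 < model.root.threshold < 70

    @pytest.mark.parametrize("seed", range(8))
    def test_root_split_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        X = rng.uniform(0, 100, size=(n, 3))
        y = rng.choice(np.array(TISSUE_CLASSES, dtype=object), size=n)
        if len(np.unique(y)) < 2:
            y[0] = "neuron" if y[1] != "neuron" else "intestine"
        model = train_tree(X, y, max_splits=1)
        ref = exhaustive_best_split(X, y)
        assert model.root.feature == ref[0]
        assert model.root.threshold == pytest.approx(ref[1], rel=1e-12)

    def test_zero_splits_gives_majority_predictor(self):
        X, y = _labelled([10, 20, 70, 80, 90], ["neuron"] * 2 + ["intestine"] * 3)
        model = train_tree(X, y, max_splits=0)
        assert model.n_splits == 0
        assert set(model.predict(X)) == {"intestine"}

    def test_training_is_permutation_invariant(self):
        X, y = sample_features(80, overlap=0.5, rng=7)
        model = train_tree(X, y)
        perm = np.random.default_rng(1).permutation(len(y))
        model_p = train_tree(X[perm], y[perm])
        Xv, _ = sample_features(200, overlap=0.5, rng=8)
        assert (model.predict(Xv) == model_p.predict(Xv)).all()

    def test_single_class_input_warns_and_predicts_that_class(self):
        X, y = _labelled([10, 20, 30], ["neuron"] * 3)
        with pytest.warns(UserWarning, match="single-class"):
            model = train_tree(X, y)
        assert set(model.predict(X)) == {"neuron"}

    def test_split_budget_caps_tree_growth(self):
        X, y = sample_features(100, overlap=0.8, rng=3)
        small = train_tree(X, y, max_splits=1)
        big = train_tree(X, y, max_splits=100)
        assert small.n_splits == 1 and big.n_splits <= 100
        acc_small, _ = evaluate(small, X, y)
        acc_big, _ = evaluate(big, X, y)
        assert acc_small <= acc_big  # nested training accuracy

    def test_nonfinite_features_rejected(self):
        X, y = _labelled([10.0, np.nan, 30.0], ["neuron", "neuron", "intestine"])
        with pytest.raises(ValueError):
            train_tree(X, y)


class TestClassify:
    def test_separable_priors_classify_perfectly(self):
        X, y = sample_features(150, overlap=0.0, rng=1)
        model = train_tree(X, y)
        Xv, yv = sample_features(400, overlap=0.0, rng=2)
        acc, cm = evaluate(model, Xv, yv)
        assert acc == 1.0
        assert cm.to_numpy().sum() == len(yv)
        assert np.all(cm.to_numpy().diagonal() == 400)

    def test_every_class_reachable(self):
        X, y = sample_features(150, overlap=0.0, rng=1)
        model = train_tree(X, y)
        Xv, _ = sample_features(100, overlap=0.0, rng=3)
        assert set(model.predict(Xv)) == set(TISSUE_CLASSES)

    def test_classification_is_repeatable(self):
        X, y = sample_features(100, overlap=0.3, rng=4)
        model = train_tree(X, y)
        Xv, _ = sample_features(50, overlap=0.3, rng=5)
        assert (model.predict(Xv) == model.predict(Xv)).all()

    def test_missing_feature_error_names_the_nucleus(self):
        nuc = NucleusObject(
            slice_index=0, centroid=(1.0, 1.0), area_px=50, eccentricity=float("nan"),
            solidity=1.0, extent=0.8, equivalent_diameter_px=8.0, total_intensity=10.0,
        )
        X, y = sample_features(50, overlap=0.0, rng=6)
        model = train_tree(X, y)
        with pytest.raises(ValueError, match="eccentricity"):
            classify(model, [nuc])

    def test_empty_validation_set_rejected(self):
        X, y = sample_features(50, overlap=0.0, rng=6)
        model = train_tree(X, y)
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 3)), np.array([]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = sample_features(100, overlap=0.4, rng=9)
        model = train_tree(X, y)
        path = tmp_path / "tree.json"
        model.to_json(path)
        loaded = TreeModel.from_json(path)
        Xv, _ = sample_features(100, overlap=0.4, rng=10)
        assert (model.predict(Xv) == loaded.predict(Xv)).all()

    def test_overlap_accuracy_tracks_bayes_rate(self):
        overlap = 0.4
        X, y = sample_features(150, overlap, rng=11)
        model = train_tree(X, y)
        Xv, yv = sample_features(500, overlap, rng=12)
        acc, _ = evaluate(model, Xv, yv)
        bayes = bayes_accuracy(overlap, n_mc=100_000, rng=13)
        assert bayes - 0.05 <= acc <= bayes + 0.02

    def test_agrees_with_independent_cart_reference(self):
        from sklearn.tree import DecisionTreeClassifier

        X, y = sample_features(150, overlap=0.3, rng=14)
        mine = train_tree(X, y)
        ref = DecisionTreeClassifier(max_leaf_nodes=101, random_state=0).fit(X, y)
        Xv, yv = sample_features(1000, overlap=0.3, rng=15)
        acc_mine, _ = evaluate(mine, Xv, yv)
        acc_ref = ref.score(Xv, yv)
        assert abs(acc_mine - acc_ref) < 0.03


def _nuc(tissue, intensity, area=50):
    n = NucleusObject(
        slice_index=0, centroid=(0.0, 0.0), area_px=area, eccentricity=0.1,
        solidity=1.0, extent=0.8, equivalent_diameter_px=8.0, total_intensity=intensity,
    )
    n.tissue = tissue
    return n


class TestAggregation:
    def test_simple_totals_and_per_cell(self):
        nuclei = [_nuc("neuron", 10.0) for _ in range(3)]
        summary = aggregate_by_tissue(nuclei)
        assert summary.loc["neuron", "total_intensity"] == 30.0
        assert summary.loc["neuron", "intensity_per_cell"] == 10.0
        assert summary.loc["intestine", "cell_count"] == 0
        assert not summary.loc["intestine", "per_cell_defined"]

    def test_class_totals_conserve_worm_total(self):
        rng = np.random.default_rng(0)
        nuclei = [
            _nuc(rng.choice(TISSUE_CLASSES), float(rng.uniform(5, 50)))
            for _ in range(40)
        ]
        summary = aggregate_by_tissue(nuclei)
        assert summary["total_intensity"].sum() == pytest.approx(
            sum(n.total_intensity for n in nuclei), rel=1e-12
        )

    def test_many_small_neurons_vs_few_large_intestine_ordering(self):
        # hundreds of neurons vs ~20 intestinal cells: neurons win in total,
        # intestine wins per cell
        nuclei = [_nuc("neuron", 12.0, area=40) for _ in range(100)]
        nuclei += [_nuc("intestine", 45.0, area=400) for _ in range(10)]
        s = aggregate_by_tissue(nuclei)
        assert s.loc["neuron", "total_intensity"] > s.loc["intestine", "total_intensity"]
        assert s.loc["intestine", "intensity_per_cell"] > s.loc["neuron", "intensity_per_cell"]
        assert s.loc["neuron", "mean_pixel_intensity"] > s.loc["intestine", "mean_pixel_intensity"]

    def test_unlabelled_nuclei_rejected(self):
        nuc = _nuc("neuron", 1.0)
        nuc.tissue = None
        with pytest.raises(ValueError):
            aggregate_by_tissue([nuc])

    def test_normalisation_modes(self):
        cond = aggregate_by_tissue([_nuc("neuron", 20.0), _nuc("intestine", 30.0)])
        ctrl = aggregate_by_tissue([_nuc("neuron", 10.0), _nuc("intestine", 10.0)])
        fold = normalized_total_intensity(cond, ctrl, mode="control")
        assert fold["neuron"] == 2.0 and fold["intestine"] == 3.0
        frac = normalized_total_intensity(cond, mode="fraction")
        assert frac.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalized_total_intensity(cond, mode="zscore")
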