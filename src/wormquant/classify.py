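"""Decision-tree tissue classification of segmented nuclei.

Nuclei are assigned to one of four somatic classes — intestine, neuron,
hypodermis, muscle — from three shape features: area, eccentricity and
equivalent diameter.  The classifier is a CART-style binary tree with Gini
impurity and a high split budget (a "fine" tree, default max 100 splits),
grown best-first: at every step the leaf whose best axis-aligned split gives
the largest total impurity decrease is split.  Candidate thresholds are the
midpoints between consecutive sorted unique feature values, and ties are
broken deterministically (lowest feature index, then lowest threshold, then
leaf creation order), so training is invariant to the order of the input.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .priors import FEATURE_NAMES, TISSUE_CLASSES
from .segmentation import NucleusObject

log = logging.getLogger(__name__)


@dataclass
class TreeNode:
    class_counts: np.ndarray
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        return int(np.argmax(self.class_counts))


@dataclass
class TreeModel:
    root: TreeNode
    classes: tuple[str, ...]
    max_splits: int
    n_splits: int = 0
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        out = np.empty(X.shape[0], dtype=object)
        for i, x in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = self.classes[node.prediction]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        def encode(node: TreeNode) -> dict:
            d: dict = {"class_counts": node.class_counts.tolist()}
            if not node.is_leaf:
                d.update(
                    feature=self.feature_names[node.feature],
                    threshold=node.threshold,
                    left=encode(node.left),
                    right=encode(node.right),
                )
            return d

        payload = json.dumps(
            {
                "classes": list(self.classes),
                "feature_names": list(self.feature_names),
                "max_splits": self.max_splits,
                "n_splits": self.n_splits,
                "root": encode(self.root),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TreeModel":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) and Path(str(source)).exists() else str(source)
        data = json.loads(text)
        names = tuple(data["feature_names"])

        def decode(d: dict) -> TreeNode:
            node = TreeNode(class_counts=np.asarray(d["class_counts"], dtype=float))
            if "feature" in d:
                node.feature = names.index(d["feature"])
                node.threshold = float(d["threshold"])
                node.left = decode(d["left"])
                node.right = decode(d["right"])
            return node

        return cls(
            root=decode(data["root"]),
            classes=tuple(data["classes"]),
            max_splits=int(data["max_splits"]),
            n_splits=int(data["n_splits"]),
            feature_names=names,
        )


def _as_matrix(X, feature_names=FEATURE_NAMES) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.loc[:, list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return X


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, y_idx: np.ndarray, n_classes: int):
    """Best (feature, threshold, decrease) for one node; None if no gain.

    Iterates features in ascending index and thresholds in ascending value,
    keeping a candidate only on a strictly larger impurity decrease, which
    implements the lowest-feature / lowest-threshold tie-break.
    """
    n = len(y_idx)
    parent_counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    parent_gini = _gini(parent_counts)
    best = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y_idx[order]
        uniq_mask = np.diff(xs) > 0
        if not uniq_mask.any():
            continue
        left_counts = np.zeros(n_classes)
        i = 0
        for cut in np.nonzero(uniq_mask)[0]:
            while i <= cut:
                left_counts[ys[i]] += 1
                i += 1
            threshold = 0.5 * (xs[cut] + xs[cut + 1])
            right_counts = parent_counts - left_counts
            nl = left_counts.sum()
            decrease = parent_gini - (
                nl / n * _gini(left_counts) + (n - nl) / n * _gini(right_counts)
            )
            if best is None or decrease > best[2]:
                best = (f, threshold, decrease)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def train_tree(
    X,
    y,
    max_splits: int = 100,
    rng_seed: int = 0,
    classes: tuple[str, ...] = TISSUE_CLASSES,
) -> TreeModel:
    """Fit the fine tree on labelled feature vectors.

    ``X`` is (n, 3) in the order (area, eccentricity, equivalent_diameter) or
    a DataFrame with those columns; ``y`` holds tissue-class strings.  The
    ``rng_seed`` is accepted for interface uniformity — training is fully
    deterministic.  A single-class input yields a depth-0 majority tree with
    a warning.
    """
    del rng_seed
    X = _as_matrix(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and y must be non-empty and aligned")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    unknown = set(np.unique(y)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside known classes: {sorted(unknown)}")
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[label] for label in y])
    root = TreeNode(class_counts=np.bincount(y_idx, minlength=len(classes)).astype(float))
    if len(np.unique(y_idx)) < 2:
        warnings.warn("single-class training set: returning a depth-0 majority tree")
        return TreeModel(root=root, classes=tuple(classes), max_splits=max_splits, n_splits=0)

    # best-first growth: (leaf node, row indices, best split), split the leaf
    # with the largest decrease; creation order breaks exact ties.
    frontier: list[tuple[TreeNode, np.ndarray, tuple | None]] = [
        (root, np.arange(X.shape[0]), _best_split(X, y_idx, len(classes)))
    ]
    n_splits = 0
    while n_splits < max_splits:
        candidates = [(i, e) for i, e in enumerate(frontier) if e[2] is not None]
        if not candidates:
            break
        total = len(y_idx)
        pick_i, (node, rows, split) = max(
            candidates,
            key=lambda item: (len(item[1][1]) / total * item[1][2][2], -item[0]),
        )
        f, t, _ = split
        go_left = X[rows, f] <= t
        lrows, rrows = rows[go_left], rows[~go_left]
        node.feature, node.threshold = f, t
        node.left = TreeNode(class_counts=np.bincount(y_idx[lrows], minlength=len(classes)).astype(float))
        node.right = TreeNode(class_counts=np.bincount(y_idx[rrows], minlength=len(classes)).astype(float))
        frontier[pick_i] = (node.left, lrows, _best_split(X[lrows], y_idx[lrows], len(classes)))
        frontier.append((node.right, rrows, _best_split(X[rrows], y_idx[rrows], len(classes))))
        n_splits += 1
    return TreeModel(root=root, classes=tuple(classes), max_splits=max_splits, n_splits=n_splits)


def nuclei_feature_frame(nuclei: list[NucleusObject]) -> pd.DataFrame:
    rows = []
    for i, nuc in enumerate(nuclei):
        feats = {
            "area": float(nuc.area_px),
            "eccentricity": nuc.eccentricity,
            "equivalent_diameter": nuc.equivalent_diameter_px,
        }
        for name, value in feats.items():
            if value is None or not np.isfinite(value):
                raise ValueError(f"nucleus {i} (slice {nuc.slice_index}) missing feature {name!r}")
        rows.append(feats)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def classify(model: TreeModel, nuclei):
    """Label nuclei (or a raw feature matrix) with tissue classes.

    Given a list of :class:`NucleusObject` the labels are written onto the
    objects and the list returned; otherwise an array of labels is returned.
    """
    if isinstance(nuclei, list) and (not nuclei or isinstance(nuclei[0], NucleusObject)):
        if not nuclei:
            return nuclei
        labels = model.predict(nuclei_feature_frame(nuclei))
        for nuc, label in zip(nuclei, labels):
            nuc.tissue = str(label)
        return nuclei
    return model.predict(nuclei)


def evaluate(model: TreeModel, X, y_true) -> tuple[float, pd.DataFrame]:
    """Accuracy and 4x4 confusion matrix on a labelled validation set."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("validation set is empty")
    y_pred = model.predict(_as_matrix(X, model.feature_names))
    acc = float(np.mean(y_pred == y_true))
    cm = confusion_matrix(y_true, y_pred, labels=list(model.classes))
    frame = pd.DataFrame(cm, index=list(model.classes), columns=list(model.classes))
    return acc, frame


def aggregate_by_tissue(nuclei: list[NucleusObject]) -> pd.DataFrame:
    """Per-tissue intensity summary of labelled nuclei.

    Columns: total_intensity (sum over the class), cell_count, per-cell
    intensity (total / count, flagged undefined for empty classes rather than
    NaN-propagated) and mean pixel intensity (sum intensity / sum area).
    Class totals sum to the whole-worm total by construction.
    """
    if any(n.tissue is None for n in nuclei):
        raise ValueError("all nuclei must be labelled before aggregation")
    rows = []
    for tissue in TISSUE_CLASSES:
        members = [n for n in nuclei if n.tissue == tissue]
        total = sum(n.total_intensity for n in members)
        count = len(members)
        area = sum(n.area_px for n in members)
        rows.append(
            {
                "tissue": tissue,
                "total_intensity": total,
                "cell_count": count,
                "intensity_per_cell": total / count if count else 0.0,
                "per_cell_defined": bool(count),
                "mean_pixel_intensity": total / area if area else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def normalized_total_intensity(
    summary: pd.DataFrame, control_summary: pd.DataFrame | None = None, mode: str = "control"
) -> pd.Series:
    """Normalised per-tissue totals.

    ``mode="control"`` divides each tissue total by the same tissue's
    ad-libitum control total (per-condition fold change); ``mode="fraction"``
    divides by the worm's own whole-animal total.
    """
    totals = summary["total_intensity"]
    if mode == "control":
        if control_summary is None:
            raise ValueError("control summary required for control normalisation")
        ref = control_summary["total_intensity"]
        return (totals / ref.replace(0, np.nan)).rename("normalized_total_intensity")
    if mode == "fraction":
        whole = totals.sum()
        return (totals / whole if whole else totals * 0.0).rename("normalized_total_intensity")
    raise ValueError(f"unknown normalisation mode {mode!r}")
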