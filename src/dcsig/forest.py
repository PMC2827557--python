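"""Bootstrap ensemble of classification trees with out-of-bag machinery.

Each tree is a CART classifier (Gini impurity, grown to purity by default)
fitted on an independent bootstrap sample of the training set; the ensemble
classifies by majority vote. Bootstrap indices are stored per tree so the
out-of-bag (OOB) error — the misclassification rate of each sample under
the trees that did not see it — can be recomputed exactly, and so tests can
re-evaluate every stored tree by brute force.

The individual trees come from scikit-learn; the bagging loop, OOB voting,
and unnormalized mean-decrease-in-Gini importance are implemented here so
their contracts (stored indices, tie-breaking toward the non-inflammatory
class, seed determinism) are explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._constants import NON_INFLAMMATORY


@dataclass
class ForestModel:
    """A fitted bagged-tree ensemble and everything needed to replay it."""

    trees: list[DecisionTreeClassifier]
    bootstrap_indices: list[np.ndarray]  # per tree, indices into train samples
    gene_ids: list[str]
    sample_ids: list[str]
    classes_: np.ndarray  # label strings, sorted; trees predict indices into this
    mtry: int
    seed: int
    min_samples_leaf: int = 1
    tie_class: str = NON_INFLAMMATORY

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _tie_index(self) -> int:
        # ties go to the configured conservative class when present,
        # otherwise to the lexicographically first label
        hits = np.flatnonzero(self.classes_ == self.tie_class)
        return int(hits[0]) if hits.size else 0

    def vote_matrix(self, X: np.ndarray) -> np.ndarray:
        """Per-tree predicted class indices, shape (n_trees, n_samples)."""
        return np.stack([tree.predict(X).astype(int) for tree in self.trees])

    def predict_from_votes(self, votes: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Majority vote over trees; ``mask`` (trees x samples) selects voters.

        Returns -1 for samples with no eligible voter. An exact tie goes to
        the tie class.
        """
        n_trees, n_samples = votes.shape
        counts = np.zeros((len(self.classes_), n_samples))
        for c in range(len(self.classes_)):
            sel = votes == c
            if mask is not None:
                sel = sel & mask
            counts[c] = sel.sum(axis=0)
        total = counts.sum(axis=0)
        pred = counts.argmax(axis=0)
        top = counts.max(axis=0)
        n_top = (counts == top).sum(axis=0)
        pred[n_top > 1] = self._tie_index()
        pred[total == 0] = -1
        return pred


def _as_matrix(matrix: pd.DataFrame) -> np.ndarray:
    return matrix.to_numpy(dtype=float).T  # samples x genes


def _encode_labels(
    labels: Mapping[str, str] | pd.Series, sample_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    y_raw = np.asarray([labels[s] for s in sample_ids], dtype=object)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("degenerate labels: a single class is present")
    y = np.searchsorted(classes, y_raw)
    return y.astype(int), classes


def train_forest(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Fit ``n_trees`` CART trees, one independent bootstrap sample each.

    ``matrix`` is genes x training samples; ``labels`` maps sample id to
    class. ``mtry``, the number of candidate genes examined per split,
    defaults to floor(sqrt(n_genes)). The whole ensemble is reproducible
    from ``seed``: bootstrap indices and per-tree split randomness both
    derive from it.
    """
    sample_ids = list(matrix.columns)
    X = _as_matrix(matrix)
    y, classes = _encode_labels(labels, sample_ids)
    n = len(sample_ids)
    if min((y == c).sum() for c in range(len(classes))) < 2:
        raise ValueError("degenerate labels: need at least 2 samples per class")
    p = matrix.shape[0]
    if mtry is None:
        mtry = max(1, int(math.floor(math.sqrt(p))))

    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    boots: list[np.ndarray] = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=min_samples_leaf,
            random_state=tree_seed,
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
    return ForestModel(
        trees=trees,
        bootstrap_indices=boots,
        gene_ids=list(matrix.index),
        sample_ids=sample_ids,
        classes_=classes,
        mtry=mtry,
        seed=seed,
        min_samples_leaf=min_samples_leaf,
    )


def tree_impurity_importance(tree: DecisionTreeClassifier, n_features: int) -> np.ndarray:
    """Unnormalized mean-decrease-in-Gini for one fitted tree.

    For every internal node splitting on feature f, accumulate
    (n_node / n_root) * (impurity_node - weighted mean child impurity).
    """
    t = tree.tree_
    imp = np.zeros(n_features)
    root_w = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        decrease = (
            w[node] * t.impurity[node]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        ) / root_w
        imp[t.feature[node]] += decrease
    return imp


def gini_importance(model: ForestModel) -> pd.Series:
    """Per-gene Gini importance averaged over the ensemble's trees.

    Non-negative; exactly 0 for genes never used in any split.
    """
    p = len(model.gene_ids)
    total = np.zeros(p)
    for tree in model.trees:
        total += tree_impurity_importance(tree, p)
    return pd.Series(total / model.n_trees, index=model.gene_ids, name="importance")


@dataclass
class OOBResult:
    """Out-of-bag error with coverage metadata."""

    error: float
    n_evaluated: int
    n_never_oob: int
    per_sample: pd.Series = field(repr=False)  # predicted label or NaN


def oob_error(
    model: ForestModel,
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    details: bool = False,
) -> float | OOBResult:
    """Fraction of training samples misclassified by their OOB trees.

    For each sample, only trees whose bootstrap excluded it vote. Samples
    that appear in every bootstrap have no OOB vote and are skipped (their
    count is reported when ``details=True``).
    """
    sample_ids = list(matrix.columns)
    if sample_ids != model.sample_ids:
        raise ValueError("matrix samples differ from the model's training samples")
    X = _as_matrix(matrix.loc[model.gene_ids])
    y, classes = _encode_labels(labels, sample_ids)
    if not np.array_equal(classes, model.classes_):
        raise ValueError("label classes differ from the model's classes")
    n = len(sample_ids)
    votes = model.vote_matrix(X)
    oob_mask = np.ones((model.n_trees, n), dtype=bool)
    for t, idx in enumerate(model.bootstrap_indices):
        oob_mask[t, np.unique(idx)] = False
    pred = model.predict_from_votes(votes, mask=oob_mask)
    evaluated = pred >= 0
    n_eval = int(evaluated.sum())
    err = float((pred[evaluated] != y[evaluated]).mean()) if n_eval else float("nan")
    if not details:
        return err
    per_sample = pd.Series(
        [model.classes_[p] if p >= 0 else np.nan for p in pred], index=sample_ids
    )
    return OOBResult(error=err, n_evaluated=n_eval, n_never_oob=n - n_eval, per_sample=per_sample)


def classify(model: ForestModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote classification of new samples.

    ``matrix`` must contain every gene the model was trained on (extra genes
    are ignored; order is realigned). Returns a DataFrame with the predicted
    class and, per class, the fraction of trees voting for it. Exact vote
    ties go to the non-inflammatory (tie) class.
    """
    missing = [g for g in model.gene_ids if g not in matrix.index]
    if missing:
        raise ValueError(f"genes missing from matrix: {missing[:10]}")
    X = _as_matrix(matrix.loc[model.gene_ids])
    votes = model.vote_matrix(X)
    pred = model.predict_from_votes(votes)
    out = pd.DataFrame(index=matrix.columns)
    out["predicted_class"] = [model.classes_[p] for p in pred]
    for c, label in enumerate(model.classes_):
        out[f"vote_fraction_{label}"] = (votes == c).mean(axis=0)
    return out
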