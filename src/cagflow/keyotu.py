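"""Random-forest discrimination of group pairs and key-OTU selection.

A bagged forest of CART trees is fitted per screened group pair on
relative abundances. Importance is the out-of-bag mean decrease in
accuracy (MDA): for each tree, the drop in its OOB accuracy when one
OTU's values are permuted among the OOB samples, averaged over trees.
Only models whose OOB majority-vote class error is zero are considered
successful; key OTUs are the non-redundant union of OTUs with MDA above
a fixed threshold across successful models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


@dataclasses.dataclass
class PairModel:
    pair: str
    oob_class_error: float
    importance: pd.Series  # OTU -> mean decrease in accuracy
    n_trees: int
    seed: int


@dataclasses.dataclass
class KeyOtuSet:
    otu_ids: list[str]
    provenance: dict[str, list[str]]  # OTU -> contributing pair models

    def __contains__(self, otu: str) -> bool:
        return otu in self.provenance

    def __len__(self) -> int:
        return len(self.otu_ids)


def _tree_predict(tree: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    """Low-level class prediction bypassing per-call input validation."""
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:
        proba = proba[:, 0, :]
    return tree.classes_[np.argmax(proba, axis=1)]


def fit_pair_model(
    X: pd.DataFrame,
    labels,
    n_trees: int = 1000,
    seed: int = 0,
    pair: str | None = None,
) -> PairModel:
    """Fit a two-class random forest and compute OOB error and MDA.

    ``X`` is a samples x OTUs matrix of relative abundances; ``labels``
    gives exactly two classes with at least 2 samples each. Trees use
    sqrt(p) feature subsampling and bootstrap resampling; the OOB class
    error is the majority-vote error over samples that were out of bag
    at least once.
    """
    y = np.asarray(
        labels.loc[X.index] if isinstance(labels, pd.Series) else labels
    )
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("pair models require exactly 2 classes")
    if np.bincount(y_codes).min() < 2:
        raise ValueError("each class needs at least 2 samples")
    n, p = X.shape
    X32 = np.ascontiguousarray(X.to_numpy(), dtype=np.float32)
    rng = np.random.default_rng(seed)

    votes = np.zeros((n, 2))
    mda_sum = np.zeros(p)
    n_scored_trees = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X32[boot], y_codes[boot])
        if oob.size == 0:
            continue
        X_oob = X32[oob]
        pred = _tree_predict(tree, X_oob)
        correct = pred == y_codes[oob]
        votes[oob, pred] += 1.0
        acc0 = correct.mean()
        n_scored_trees += 1
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            acc_j = (_tree_predict(tree, Xp) == y_codes[oob]).mean()
            mda_sum[j] += acc0 - acc_j
    if n_scored_trees == 0:
        raise ValueError("no tree had out-of-bag samples")
    voted = votes.sum(axis=1) > 0
    oob_pred = np.argmax(votes[voted], axis=1)
    oob_error = float(np.mean(oob_pred != y_codes[voted]))
    importance = pd.Series(mda_sum / n_scored_trees, index=X.columns, name="mda")
    return PairModel(
        pair=pair or f"{classes[0]}_vs_{classes[1]}",
        oob_class_error=oob_error,
        importance=importance,
        n_trees=n_trees,
        seed=seed,
    )


def select_key_otus(
    models: list[PairModel],
    mda_threshold: float = 0.003,
    max_class_error: float = 0.0,
) -> KeyOtuSet:
    """Union of high-MDA OTUs across successful (class-error-0) models.

    Models with OOB class error above ``max_class_error`` are discarded
    entirely; from the survivors every OTU with MDA strictly above
    ``mda_threshold`` enters the set once, with its contributing models
    recorded as provenance.
    """
    provenance: dict[str, list[str]] = {}
    for model in models:
        if model.oob_class_error > max_class_error:
            continue
        hits = model.importance.index[model.importance > mda_threshold]
        for otu in hits:
            provenance.setdefault(otu, []).append(model.pair)
    otu_ids = sorted(provenance)
    return KeyOtuSet(otu_ids=otu_ids, provenance=provenance)
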