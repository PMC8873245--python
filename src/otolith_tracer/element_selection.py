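"""Ranking elements by their contribution to discriminating sampling
sites, and selecting the working element subset.

Importance is out-of-bag permutation importance ("mean decrease in
accuracy", percent): for each tree in a random forest trained to predict
capture site from edge fingerprints, accuracy on the tree's out-of-bag
samples is compared with accuracy after permuting one element's values
among those samples; the per-tree decreases are averaged and the whole
procedure repeated over seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .transect_io import EdgeSignature

def _oob_indices(tree_random_state: int, n: int) -> np.ndarray:
    """Out-of-bag sample indices for one tree of a bootstrap forest."""
    try:  # sklearn's own bootstrap bookkeeping, if the private API is usable
        from sklearn.ensemble._forest import _generate_unsampled_indices

        try:
            return _generate_unsampled_indices(tree_random_state, n, n, None)
        except TypeError:
            return _generate_unsampled_indices(tree_random_state, n, n)
    except ImportError:
        # replicate sklearn's bootstrap: randint(0, n, n) on the tree seed
        rng = np.random.RandomState(tree_random_state)
        sampled = rng.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        return np.where(mask)[0]


__all__ = [
    "ImportanceTable",
    "signatures_to_frame",
    "oob_permutation_importance",
    "rank_element_importance",
    "select_elements",
]


@dataclass
class ImportanceTable:
    river_system: str
    scores: pd.DataFrame  # index = element; columns = mean_decrease_accuracy_pct, sd_pct

    @property
    def elements(self) -> list[str]:
        return list(self.scores.index)

    def score_of(self, element: str) -> float:
        return float(self.scores.loc[element, "mean_decrease_accuracy_pct"])


def signatures_to_frame(signatures: Sequence[EdgeSignature]) -> pd.DataFrame:
    """Stack edge signatures into a (fish x element) frame with site labels."""
    if not signatures:
        raise ValueError("no edge signatures supplied")
    elements = signatures[0].elements
    for s in signatures:
        if s.elements != elements:
            raise ValueError("edge signatures carry inconsistent element lists")
    df = pd.DataFrame(
        [s.fingerprint for s in signatures],
        columns=list(elements),
        index=[s.fish_id for s in signatures],
    )
    df.insert(0, "site_id", [s.site_id for s in signatures])
    return df


def oob_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature mean decrease in OOB accuracy (fraction, not percent)
    for one forest fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, k = X.shape
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, bootstrap=True, n_jobs=1
    )
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    decreases = np.zeros((len(forest.estimators_), k))
    counted = np.zeros(len(forest.estimators_), dtype=bool)

    def tree_labels(tree, Xq):  # trees emit encoded class indices
        return forest.classes_[tree.predict(Xq).astype(int)]

    for t, tree in enumerate(forest.estimators_):
        oob = _oob_indices(tree.random_state, n)
        if oob.size == 0:
            continue
        counted[t] = True
        base = np.mean(tree_labels(tree, X[oob]) == y[oob])
        for j in range(k):
            Xp = X[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            decreases[t, j] = base - np.mean(tree_labels(tree, Xp) == y[oob])
    if not counted.any():
        raise RuntimeError("no tree had out-of-bag samples")
    return decreases[counted].mean(axis=0)


def rank_element_importance(
    signatures: Sequence[EdgeSignature],
    river_system: str,
    n_repeats: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceTable:
    """Mean-decrease-in-accuracy importance of each element for telling
    this river system's sites apart, averaged over seeded repeats."""
    df = signatures_to_frame(signatures)
    sites = df["site_id"].to_numpy()
    uniq, counts = np.unique(sites, return_counts=True)
    if len(uniq) < 2:
        raise ValueError(
            f"{river_system}: importance undefined with a single site"
        )
    if counts.min() < 2:
        raise ValueError(f"{river_system}: every site needs at least 2 fish")
    elements = [c for c in df.columns if c != "site_id"]
    X = df[elements].to_numpy(dtype=float)
    runs = np.vstack(
        [
            oob_permutation_importance(X, sites, n_trees=n_trees, seed=seed + r)
            for r in range(n_repeats)
        ]
    )
    scores = pd.DataFrame(
        {
            "mean_decrease_accuracy_pct": 100.0 * runs.mean(axis=0),
            "sd_pct": 100.0 * runs.std(axis=0, ddof=1 if n_repeats > 1 else 0),
        },
        index=pd.Index(elements, name="element"),
    )
    return ImportanceTable(river_system=river_system, scores=scores)


def select_elements(
    tables: Sequence[ImportanceTable] | Mapping[str, ImportanceTable],
    threshold_pct: float = 5.0,
) -> list[str]:
    """Retain an element unless its importance is below ``threshold_pct``
    in EVERY river system (intersection semantics)."""
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    if not tables:
        raise ValueError("no importance tables supplied")
    elements = tables[0].elements
    for t in tables:
        if t.elements != elements:
            raise ValueError("importance tables cover different element lists")
    retained = [
        el
        for el in elements
        if any(t.score_of(el) >= threshold_pct for t in tables)
    ]
    if not retained:
        raise ValueError("element selection removed every element")
    return retained
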