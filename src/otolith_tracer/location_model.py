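"""Per-river classifiers that assign partitions to sampling sites.

Training rows come from two sources: the last (most recent) partition of
every fish whose core was found, and the edge signature of every fish
without an identifiable core.  Before predicting a fish's partitions, its
own last-partition row is removed from the training set so that training
and evaluation stay independent.  Model quality is quantified as the
out-of-bag accuracy distribution over 100 seeded fits; predictions report
the fraction of ensemble members voting each site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .segmentation import PartitionSet
from .transect_io import EdgeSignature, ElementalTransect

__all__ = [
    "TrainingRow",
    "TrainingSet",
    "LocationModel",
    "PartitionPrediction",
    "last_partition_row",
    "coreless_edge_row",
    "build_training_set",
    "train_location_model",
    "predict_partition_location",
    "summarize_oob",
    "compact_letters",
]


@dataclass(frozen=True)
class TrainingRow:
    fish_id: str
    site_id: str
    fingerprint: np.ndarray
    elements: tuple[str, ...]
    source: str  # "last_partition" | "coreless_edge"


@dataclass
class TrainingSet:
    river_system: str
    rows: list[TrainingRow]
    holdout_fish: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.river_system}: empty training set")
        if len(self.classes) < 2:
            raise ValueError(f"{self.river_system}: fewer than 2 site classes")

    @property
    def elements(self) -> tuple[str, ...]:
        return self.rows[0].elements

    @property
    def classes(self) -> list[str]:
        return sorted({r.site_id for r in self.rows})

    @property
    def X(self) -> np.ndarray:
        return np.vstack([r.fingerprint for r in self.rows])

    @property
    def y(self) -> np.ndarray:
        return np.array([r.site_id for r in self.rows])

    def audit_independence(self, evaluated_fish: Iterable[str]) -> None:
        """Raise if a fish being predicted contributed a last-partition row."""
        trained = {r.fish_id for r in self.rows if r.source == "last_partition"}
        overlap = trained & set(evaluated_fish)
        if overlap:
            raise AssertionError(
                f"{self.river_system}: training/evaluation overlap for {sorted(overlap)}"
            )


@dataclass
class LocationModel:
    river_system: str
    forest: RandomForestClassifier
    classes: list[str]
    elements: tuple[str, ...]
    oob_accuracies: np.ndarray  # one entry per seeded training run
    per_class_recall: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.oob_accuracies < 0) | (self.oob_accuracies > 1)):
            raise ValueError("OOB accuracies must lie in [0, 1]")

    @property
    def oob_mean(self) -> float:
        return float(self.oob_accuracies.mean())

    @property
    def oob_sd(self) -> float:
        return float(self.oob_accuracies.std(ddof=1))


@dataclass(frozen=True)
class PartitionPrediction:
    fish_id: str
    partition_rank: int
    predicted_site: str
    vote_proportions: dict[str, float]
    tie: bool = False

    def __post_init__(self) -> None:
        total = sum(self.vote_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("vote proportions must sum to 1")


def last_partition_row(
    pset: PartitionSet, transect: ElementalTransect, elements: Sequence[str]
) -> TrainingRow:
    idx = [transect.element_index(e) for e in elements]
    return TrainingRow(
        fish_id=pset.fish_id,
        site_id=transect.capture_site_id,
        fingerprint=pset.partitions[-1].fingerprint[idx],
        elements=tuple(elements),
        source="last_partition",
    )


def coreless_edge_row(sig: EdgeSignature, elements: Sequence[str]) -> TrainingRow:
    idx = [sig.elements.index(e) for e in elements]
    return TrainingRow(
        fish_id=sig.fish_id,
        site_id=sig.site_id,
        fingerprint=sig.fingerprint[idx],
        elements=tuple(elements),
        source="coreless_edge",
    )


def build_training_set(
    river_system: str,
    cored_rows: Sequence[TrainingRow],
    coreless_rows: Sequence[TrainingRow],
    holdout_fish: Iterable[str] = (),
) -> TrainingSet:
    """Assemble the two-source training set, dropping the last-partition
    rows of held-out fish.  Coreless edge rows are never held out — only
    last partitions are also evaluation rows."""
    holdout = frozenset(holdout_fish)
    rows = [r for r in cored_rows if r.fish_id not in holdout]
    rows += list(coreless_rows)
    ts = TrainingSet(river_system=river_system, rows=rows, holdout_fish=holdout)
    counts = pd.Series([r.site_id for r in rows]).value_counts()
    thin = counts[counts < 2]
    if len(thin):
        import warnings

        warnings.warn(
            f"{river_system}: site classes with < 2 training rows: "
            f"{sorted(thin.index)}",
            stacklevel=2,
        )
    return ts


def train_location_model(
    training: TrainingSet,
    n_runs: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> LocationModel:
    """Fit ``n_runs`` independently seeded forests, keep the OOB-accuracy
    distribution, and deploy the fit with the median OOB accuracy."""
    X, y = training.X, training.y
    if len(np.unique(y)) < 2:
        raise ValueError(f"{training.river_system}: single-class training set")
    fits: list[RandomForestClassifier] = []
    oob = np.empty(n_runs)
    for r in range(n_runs):
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            bootstrap=True,
            random_state=seed + r,
            n_jobs=1,
        )
        forest.fit(X, y)
        fits.append(forest)
        oob[r] = forest.oob_score_
    # deployed model = the run whose OOB accuracy sits at the median
    median_idx = int(np.argsort(oob, kind="stable")[n_runs // 2])
    forest = fits[median_idx]
    pred = forest.predict(X)
    recall = {
        c: float(np.mean(pred[y == c] == c)) for c in sorted(np.unique(y))
    }
    return LocationModel(
        river_system=training.river_system,
        forest=forest,
        classes=sorted(forest.classes_.tolist()),
        elements=training.elements,
        oob_accuracies=oob,
        per_class_recall=recall,
    )


def _tree_votes(forest: RandomForestClassifier, x: np.ndarray) -> dict[str, float]:
    """Fraction of trees voting each class (not averaged probabilities)."""
    votes = np.array([t.predict(x.reshape(1, -1))[0] for t in forest.estimators_])
    labels = forest.classes_[votes.astype(int)] if votes.dtype.kind in "if" else votes
    counts = pd.Series(labels).value_counts()
    total = len(forest.estimators_)
    return {str(c): counts.get(c, 0) / total for c in forest.classes_}


def predict_partition_location(
    model: LocationModel,
    fingerprint: np.ndarray,
    elements: Sequence[str],
    fish_id: str = "",
    partition_rank: int = 0,
) -> PartitionPrediction:
    """Plurality-vote site assignment for one partition fingerprint.

    Exact vote ties go to the site earliest in alphabetical order, with
    the tie flagged.
    """
    missing = [e for e in model.elements if e not in elements]
    if missing:
        raise ValueError(f"fingerprint missing model elements: {missing}")
    idx = [list(elements).index(e) for e in model.elements]
    x = np.asarray(fingerprint, dtype=float)[idx]
    votes = _tree_votes(model.forest, x)
    best = max(votes.values())
    winners = sorted(site for site, v in votes.items() if v == best)
    return PartitionPrediction(
        fish_id=fish_id,
        partition_rank=partition_rank,
        predicted_site=winners[0],
        vote_proportions=votes,
        tie=len(winners) > 1,
    )


def compact_letters(names: list[str], significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact-letter display: groups NOT significantly different share a
    letter (insert-and-absorb on the pairwise significance relation)."""
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all(not significant.get(tuple(sorted((name, other))), False) for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb subsets
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {n: "" for n in names}
    for letter, s in zip(alphabet, letter_sets):
        for n in names:
            if n in s:
                out[n] += letter
    return out


def summarize_oob(models: Sequence[LocationModel]) -> pd.DataFrame:
    """Per-river OOB error summary with a one-way ANOVA across rivers on
    the per-run error values and a compact-letter grouping."""
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    errors = {m.river_system: 1.0 - m.oob_accuracies for m in models}
    names = sorted(errors)
    f_stat, p_value = stats.f_oneway(*[errors[n] for n in names])
    significant: dict[tuple[str, str], bool] = {}
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, p = stats.ttest_ind(errors[a], errors[b])
            significant[(a, b)] = bool(p * n_pairs < 0.05)  # Bonferroni
    letters = compact_letters(names, significant)
    rows = [
        {
            "river_system": n,
            "oob_error_mean": float(errors[n].mean()),
            "oob_error_sd": float(errors[n].std(ddof=1)),
            "n_runs": len(errors[n]),
            "group": letters[n],
            "anova_F": float(f_stat),
            "anova_p": float(p_value),
        }
        for n in names
    ]
    return pd.DataFrame(rows)
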