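"""Permutation-based multivariate comparisons of edge signatures.

One-way PERMANOVA on Euclidean distances (Anderson's sum-of-squares
partitioning), pairwise post hoc tests reported as t = sqrt(pseudo-F),
rank-based per-element comparisons, and a per-location seasonal check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
    "per_element_tests",
    "season_effect_test",
    "holm_adjust",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    term: str
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    uniq, inv = np.unique(labels, return_inverse=True)
    H = np.zeros((len(labels), len(uniq)))
    H[np.arange(len(labels)), inv] = 1.0
    return H, H.sum(axis=0), list(uniq)


def _pseudo_f_from_d2(D2: np.ndarray, H: np.ndarray, sizes: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared-distance matrix and one-hot groups."""
    n = len(D2)
    k = len(sizes)
    ss_total = D2.sum() / (2 * n)
    # within: for each group, sum of squared distances inside the group / n_g
    within_blocks = np.einsum("ig,ij,jg->g", H, D2, H)
    ss_within = float(np.sum(within_blocks / sizes)) / 2
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    fingerprints: np.ndarray,
    labels,
    n_permutations: int = 9999,
    seed: int = 0,
    term: str = "habitat",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances between fingerprints.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` with labels
    permuted freely.  With ``exhaustive=True`` every distinct ordering is
    enumerated instead (small n only) and p is the exact fraction of
    orderings, identity included, with F >= F_obs.
    """
    X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels and fingerprints disagree in length")
    H, sizes, uniq = _group_onehot(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if sizes.min() < 2:
        small = [u for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"groups of size 1: {small}")
    sq = np.sum(X**2, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    f_obs = _pseudo_f_from_d2(D2, H, sizes)

    if exhaustive:
        n = len(X)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            Hp = H[list(perm)]
            if _pseudo_f_from_d2(D2, Hp, sizes) >= f_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        n_perm_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            Hp = H[rng.permutation(len(X))]
            if _pseudo_f_from_d2(D2, Hp, sizes) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        n_perm_used = n_permutations
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm_used,
        term=term,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
    )


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def pairwise_permanova(
    fingerprints: np.ndarray,
    labels,
    n_permutations: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group PERMANOVA for every unordered pair of groups.

    t = sqrt(pseudo-F).  The significance flag follows the unadjusted
    permutation p (matching the usual post hoc presentation); Holm-adjusted
    p-values are reported alongside.
    """
    X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    labels = np.asarray(labels)
    groups = sorted(np.unique(labels).tolist())
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(groups, 2)):
        mask = (labels == a) | (labels == b)
        res = permanova(
            X[mask],
            labels[mask],
            n_permutations=n_permutations,
            seed=seed + i,
            term=f"{a} vs {b}",
        )
        rows.append(
            {
                "group_a": str(a),
                "group_b": str(b),
                "t": math.sqrt(res.pseudo_f),
                "pseudo_F": res.pseudo_f,
                "p_perm": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_perm"].tolist())
    table["significant"] = table["p_perm"] < alpha
    return table


def per_element_tests(
    fingerprints: np.ndarray,
    labels,
    elements: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis per element with pairwise Mann-Whitney follow-ups
    and a directional summary (which group runs higher, by median)."""
    X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    labels = np.asarray(labels)
    groups = sorted(np.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for j, el in enumerate(elements):
        samples = [X[labels == g, j] for g in groups]
        try:
            h_stat, p = stats.kruskal(*samples)
        except ValueError:  # all values identical
            h_stat, p = 0.0, 1.0
        medians = {g: float(np.median(s)) for g, s in zip(groups, samples)}
        ranked = sorted(medians, key=medians.get, reverse=True)
        direction = " > ".join(str(g) for g in ranked) if p < alpha else ""
        pair_ps = {}
        for a, b in itertools.combinations(groups, 2):
            try:
                _, mw_p = stats.mannwhitneyu(
                    X[labels == a, j], X[labels == b, j], alternative="two-sided"
                )
            except ValueError:
                mw_p = 1.0
            pair_ps[f"{a}|{b}"] = float(mw_p)
        rows.append(
            {
                "element": el,
                "kruskal_H": float(h_stat),
                "p": float(p),
                "significant": p < alpha,
                "direction": direction,
                "highest_group": str(ranked[0]),
                **{f"p_{k}": v for k, v in pair_ps.items()},
            }
        )
    return pd.DataFrame(rows)


def season_effect_test(
    fingerprints: np.ndarray,
    locations,
    seasons,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, PermanovaResult]:
    """Per-location PERMANOVA with season as the grouping term.

    Locations with fewer than two seasons, or with any season represented
    by fewer than two fish, are skipped with a warning.
    """
    X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    locations = np.asarray(locations)
    seasons = np.asarray(seasons)
    out: dict[str, PermanovaResult] = {}
    for i, loc in enumerate(sorted(np.unique(locations).tolist())):
        mask = locations == loc
        season_counts = pd.Series(seasons[mask]).value_counts()
        if len(season_counts) < 2 or season_counts.min() < 2:
            warnings.warn(
                f"location {loc!r}: under-replicated seasons, skipped",
                stacklevel=2,
            )
            continue
        out[str(loc)] = permanova(
            X[mask],
            seasons[mask],
            n_permutations=n_permutations,
            seed=seed + i,
            term="season",
        )
    return out
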