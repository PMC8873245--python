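"""Turning chronological partition predictions into movement events,
displacements, estuarine-signature flags and life-history labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .location_model import LocationModel, PartitionPrediction, predict_partition_location
from .transect_io import SamplingSite

__all__ = [
    "MovementEvent",
    "MovementHistory",
    "reconstruct_movement",
    "max_displacement",
    "detect_estuarine_signature",
    "classify_life_history",
    "summarize_recruitment",
]

LIFE_HISTORIES = (
    "freshwater_resident",
    "estuarine_resident",
    "amphidromous",
    "undetermined",
)


@dataclass(frozen=True)
class MovementEvent:
    from_site: str
    to_site: str
    direction: str  # upstream | downstream | lateral


@dataclass
class MovementHistory:
    fish_id: str
    predicted_sites: list[str]  # chronological: first = earliest recorded
    vote_proportions: list[dict[str, float]]
    events: list[MovementEvent]
    max_displacement_km: float
    estuarine_flags: list[bool] = field(default_factory=list)
    life_history: str = ""

    def __post_init__(self) -> None:
        if self.max_displacement_km < 0:
            raise ValueError("displacement must be non-negative")


def _direction(a: SamplingSite, b: SamplingSite) -> str:
    if b.river_km > a.river_km:
        return "upstream"
    if b.river_km < a.river_km:
        return "downstream"
    return "lateral"


def reconstruct_movement(
    predictions: Sequence[PartitionPrediction],
    sites: Mapping[str, SamplingSite],
) -> MovementHistory:
    """Derive movement events from consecutive distinct predicted sites.

    Direction follows along-river km: moving to a site with larger
    river_km is upstream.  A homogeneous prediction sequence yields zero
    events (resident pattern).
    """
    if not predictions:
        raise ValueError("no partition predictions supplied")
    ordered = sorted(predictions, key=lambda p: p.partition_rank)
    seq = [p.predicted_site for p in ordered]
    for sid in seq:
        if sid not in sites:
            raise ValueError(f"predicted site {sid!r} missing from site table")
        _ = sites[sid].river_km  # raises in SamplingSite if undefined
    events = [
        MovementEvent(a, b, _direction(sites[a], sites[b]))
        for a, b in zip(seq[:-1], seq[1:])
        if a != b
    ]
    history = MovementHistory(
        fish_id=ordered[0].fish_id,
        predicted_sites=seq,
        vote_proportions=[p.vote_proportions for p in ordered],
        events=events,
        max_displacement_km=0.0,
    )
    history.max_displacement_km = max_displacement(history, sites)
    return history


def max_displacement(
    history: MovementHistory, sites: Mapping[str, SamplingSite]
) -> float:
    """Largest |river-km difference| over all pairs of visited sites."""
    kms = [sites[s].river_km for s in set(history.predicted_sites)]
    return float(max(kms) - min(kms)) if kms else 0.0


def detect_estuarine_signature(
    fingerprints: np.ndarray,
    elements: Sequence[str],
    estuary_model: LocationModel,
    estuarine_class: str = "estuary",
    threshold: float = 0.5,
    fish_id: str = "",
) -> tuple[list[bool], bool]:
    """Flag partitions whose pooled-estuary-model vote for the estuarine
    class reaches ``threshold``; the fish-level flag is any-partition."""
    if estuarine_class not in estuary_model.classes:
        raise ValueError(
            f"estuary model has classes {estuary_model.classes}, "
            f"not {estuarine_class!r}"
        )
    fingerprints = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    flags = []
    for rank, fp in enumerate(fingerprints):
        pred = predict_partition_location(
            estuary_model, fp, elements, fish_id=fish_id, partition_rank=rank
        )
        flags.append(pred.vote_proportions[estuarine_class] >= threshold)
    return flags, any(flags)


def classify_life_history(
    history: MovementHistory,
    capture_habitat: str,
) -> str:
    """Label from the estuarine partition flags and the capture habitat.

    amphidromous        — at least one estuarine and one non-estuarine partition
    estuarine_resident  — every partition estuarine, captured in an estuary
    freshwater_resident — no estuarine partition
    undetermined        — contradictory combinations (e.g. all partitions
                          estuarine but captured in fresh water)
    """
    flags = history.estuarine_flags
    if len(flags) != len(history.predicted_sites):
        raise ValueError("estuarine flags not computed for every partition")
    any_est = any(flags)
    all_est = all(flags)
    if any_est and not all_est:
        label = "amphidromous"
    elif not any_est:
        label = "freshwater_resident"
    elif capture_habitat == "estuary":
        label = "estuarine_resident"
    else:
        label = "undetermined"
    history.life_history = label
    return label


def summarize_recruitment(histories: Sequence[MovementHistory]) -> pd.DataFrame:
    """Counts and integer percentages of each life-history class."""
    if not histories:
        raise ValueError("no movement histories supplied")
    labels = [h.life_history for h in histories]
    if any(not l for l in labels):
        raise ValueError("all fish must be labeled before summarising")
    counts = pd.Series(labels).value_counts()
    total = len(labels)
    rows = []
    for cls in LIFE_HISTORIES:
        n = int(counts.get(cls, 0))
        rows.append(
            {
                "life_history": cls,
                "n": n,
                "fraction": n / total,
                "percent": int(round(100 * n / total)),
            }
        )
    return pd.DataFrame(rows)
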