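"""Reading, validation and filtering of otolith elemental transect tables.

Transects are per-fish ordered series of element concentrations (molar
ratios to Ca) along the laser-ablation path, together with below-detection
flags and capture metadata.  Two CSV/TSV dialects are accepted:

* wide  — one row per ablation point, one column per element, optional
  ``<El>_below_dl`` flag columns;
* long  — columns ``fish_id, site_id, position_um, element, value`` and an
  optional ``below_dl`` column.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElementRegistry",
    "ElementalTransect",
    "SamplingSite",
    "EdgeSignature",
    "DEFAULT_REGISTRY",
    "read_transects",
    "write_transects",
    "read_sites",
    "write_sites",
    "filter_elements",
    "extract_edge_signature",
]


@dataclass(frozen=True)
class ElementRegistry:
    """Ordered set of monitored elements with their mass numbers.

    Concentrations are expressed as molar ratios to the Ca internal
    standard throughout.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("element symbols must be unique")
        for sym, mass in self.entries:
            if not (isinstance(mass, (int, np.integer)) and mass > 0):
                raise ValueError(f"mass number for {sym} must be a positive integer")

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def mass_of(self, symbol: str) -> int:
        for sym, mass in self.entries:
            if sym == symbol:
                return mass
        raise KeyError(symbol)

    def subset(self, symbols: Sequence[str]) -> "ElementRegistry":
        keep = [e for e in self.entries if e[0] in set(symbols)]
        return ElementRegistry(tuple(keep))


# Ba monitored mass is reported inconsistently upstream (183 vs 138);
# 138 is the physically sensible default, inputs may declare otherwise.
DEFAULT_REGISTRY = ElementRegistry(
    (
        ("Li", 7),
        ("B", 11),
        ("Mg", 25),
        ("P", 31),
        ("K", 39),
        ("Mn", 55),
        ("Rb", 85),
        ("Sr", 88),
        ("Ba", 138),
    )
)


@dataclass
class ElementalTransect:
    """One fish's ordered concentration series along the ablation path."""

    fish_id: str
    capture_site_id: str
    positions: np.ndarray  # µm along the ablation path, strictly increasing
    concentrations: np.ndarray  # (n_points, n_elements), molar ratio to Ca
    elements: list[str]
    below_dl: np.ndarray  # bool, same shape as concentrations
    season: str = ""
    orientation: str = "raw"  # "raw" | "core_to_edge"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.below_dl = np.asarray(self.below_dl, dtype=bool)
        n, k = self.concentrations.shape
        if self.positions.shape != (n,):
            raise ValueError(f"{self.fish_id}: positions/concentrations shape mismatch")
        if self.below_dl.shape != (n, k):
            raise ValueError(f"{self.fish_id}: below_dl shape mismatch")
        if len(self.elements) != k:
            raise ValueError(f"{self.fish_id}: element list does not match matrix width")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"{self.fish_id}: positions must be strictly increasing")
        if np.any(~np.isfinite(self.concentrations)):
            raise ValueError(f"{self.fish_id}: non-finite concentrations")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def element_index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise KeyError(f"{self.fish_id}: element {symbol!r} not present") from None

    def restrict_elements(self, symbols: Sequence[str]) -> "ElementalTransect":
        idx = [self.element_index(s) for s in symbols]
        return replace(
            self,
            concentrations=self.concentrations[:, idx],
            below_dl=self.below_dl[:, idx],
            elements=list(symbols),
        )


@dataclass(frozen=True)
class SamplingSite:
    site_id: str
    river_system: str
    section: str  # estuary | lower | middle | upper | lake
    habitat: str  # estuary | lower river | middle river | upper river | lake
    river_km: float

    def __post_init__(self) -> None:
        if self.river_km < 0:
            raise ValueError(f"{self.site_id}: river_km must be non-negative")


@dataclass(frozen=True)
class EdgeSignature:
    """Mean multi-elemental signature over the sub-surface edge window."""

    fish_id: str
    site_id: str
    fingerprint: np.ndarray
    elements: tuple[str, ...]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("edge signature needs at least one in-window point")
        if len(self.fingerprint) != len(self.elements):
            raise ValueError("fingerprint length does not match element list")


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


_LONG_REQUIRED = {"fish_id", "position_um", "element", "value"}


def read_transects(
    source: str | Path | pd.DataFrame,
    registry: ElementRegistry = DEFAULT_REGISTRY,
) -> tuple[list[ElementalTransect], pd.DataFrame]:
    """Parse a transect table into per-fish :class:`ElementalTransect` objects.

    Returns the transects (positions sorted ascending) and a report of
    rejected rows (empty when everything parsed).  Duplicate
    (fish, position) pairs and unknown element columns raise.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(
            source, sep=_sniff_delimiter(source), float_precision="round_trip"
        )
    df.columns = [str(c) for c in df.columns]

    if _LONG_REQUIRED.issubset(df.columns):
        return _from_long(df, registry)
    return _from_wide(df, registry)


def _coerce_numeric(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coerce columns to float; split off rows with unparseable values."""
    coerced = df.copy()
    for c in cols:
        coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
    bad = coerced[cols].isna().any(axis=1)
    report = df.loc[bad].copy()
    if len(report):
        report["reason"] = "unparseable numeric value"
    return coerced.loc[~bad], report


def _from_long(df: pd.DataFrame, registry: ElementRegistry) -> tuple[list[ElementalTransect], pd.DataFrame]:
    known = set(registry.symbols)
    unknown = sorted(set(df["element"].astype(str)) - known)
    if unknown:
        raise ValueError(
            f"unknown element(s) {unknown}; registry has {registry.symbols}"
        )
    if "below_dl" not in df.columns:
        df = df.assign(below_dl=False)
    if "site_id" not in df.columns:
        df = df.assign(site_id="")
    if "season" not in df.columns:
        df = df.assign(season="")
    df, report = _coerce_numeric(df, ["position_um", "value"])

    elements = [s for s in registry.symbols if s in set(df["element"])]
    transects: list[ElementalTransect] = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        dup = sub.duplicated(subset=["position_um", "element"])
        if dup.any():
            raise ValueError(f"duplicate (fish, position) rows for fish {fish_id!r}")
        wide_v = sub.pivot(index="position_um", columns="element", values="value")
        wide_f = sub.pivot(index="position_um", columns="element", values="below_dl")
        if wide_v.isna().any().any():
            raise ValueError(f"fish {fish_id!r}: missing element values at some positions")
        wide_v = wide_v[elements].sort_index()
        wide_f = wide_f[elements].sort_index()
        transects.append(
            ElementalTransect(
                fish_id=str(fish_id),
                capture_site_id=str(sub["site_id"].iloc[0]),
                season=str(sub["season"].iloc[0]),
                positions=wide_v.index.to_numpy(dtype=float),
                concentrations=wide_v.to_numpy(dtype=float),
                elements=elements,
                below_dl=wide_f.to_numpy(dtype=bool),
            )
        )
    return transects, report


def _from_wide(df: pd.DataFrame, registry: ElementRegistry) -> tuple[list[ElementalTransect], pd.DataFrame]:
    meta = {"fish_id", "site_id", "position_um", "season"}
    flag_cols = [c for c in df.columns if c.endswith("_below_dl")]
    elem_cols = [c for c in df.columns if c not in meta and c not in flag_cols]
    unknown = sorted(set(elem_cols) - set(registry.symbols))
    if unknown:
        raise ValueError(
            f"unknown element column(s) {unknown}; registry has {registry.symbols}"
        )
    if "fish_id" not in df.columns or "position_um" not in df.columns:
        raise ValueError("wide table requires fish_id and position_um columns")
    if "site_id" not in df.columns:
        df = df.assign(site_id="")
    if "season" not in df.columns:
        df = df.assign(season="")
    elements = [s for s in registry.symbols if s in elem_cols]
    df, report = _coerce_numeric(df, ["position_um"] + elements)

    transects: list[ElementalTransect] = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        if sub["position_um"].duplicated().any():
            raise ValueError(f"duplicate (fish, position) rows for fish {fish_id!r}")
        sub = sub.sort_values("position_um")
        flags = np.zeros((len(sub), len(elements)), dtype=bool)
        for j, el in enumerate(elements):
            col = f"{el}_below_dl"
            if col in sub.columns:
                flags[:, j] = sub[col].astype(bool).to_numpy()
        transects.append(
            ElementalTransect(
                fish_id=str(fish_id),
                capture_site_id=str(sub["site_id"].iloc[0]),
                season=str(sub["season"].iloc[0]),
                positions=sub["position_um"].to_numpy(dtype=float),
                concentrations=sub[elements].to_numpy(dtype=float),
                elements=elements,
                below_dl=flags,
            )
        )
    return transects, report


def write_transects(transects: Iterable[ElementalTransect], path: str | Path) -> None:
    """Write transects in the wide CSV dialect (round-trips bit-exactly
    through :func:`read_transects` via repr-precision floats)."""
    frames = []
    for t in transects:
        d = {
            "fish_id": t.fish_id,
            "site_id": t.capture_site_id,
            "season": t.season,
            "position_um": t.positions,
        }
        for j, el in enumerate(t.elements):
            d[el] = t.concentrations[:, j]
        for j, el in enumerate(t.elements):
            d[f"{el}_below_dl"] = t.below_dl[:, j]
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_sites(source: str | Path | pd.DataFrame) -> dict[str, SamplingSite]:
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=_sniff_delimiter(source))
    required = {"site_id", "river_system", "section", "habitat", "river_km"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    sites: dict[str, SamplingSite] = {}
    seen_keys = set()
    for row in df.itertuples(index=False):
        key = (row.river_system, row.site_id)
        if key in seen_keys:
            raise ValueError(f"duplicate site {key}")
        seen_keys.add(key)
        sites[str(row.site_id)] = SamplingSite(
            site_id=str(row.site_id),
            river_system=str(row.river_system),
            section=str(row.section),
            habitat=str(row.habitat),
            river_km=float(row.river_km),
        )
    return sites


def write_sites(sites: Mapping[str, SamplingSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "river_system": s.river_system,
                "section": s.section,
                "habitat": s.habitat,
                "river_km": s.river_km,
            }
            for s in sites.values()
        ]
    ).to_csv(path, index=False)


def filter_elements(
    transects: Sequence[ElementalTransect],
    dl_fraction_threshold: float = 0.25,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude elements whose pooled below-detection fraction is strictly
    greater than ``dl_fraction_threshold``.

    The fraction is pooled over every measurement of every fish in the run.
    Surviving below-detection points keep their reported concentration (the
    filter drops elements, not points).  Returns the retained element list
    and a per-element exclusion report.
    """
    if not 0 < dl_fraction_threshold < 1:
        raise ValueError("dl_fraction_threshold must lie in (0, 1)")
    if not transects:
        raise ValueError("no transects supplied")
    elements = transects[0].elements
    for t in transects:
        if t.elements != elements:
            raise ValueError("transects carry inconsistent element lists")
    below = np.sum([t.below_dl.sum(axis=0) for t in transects], axis=0)
    total = sum(t.n_points for t in transects)
    frac = below / total
    retained = [el for el, f in zip(elements, frac) if f <= dl_fraction_threshold]
    report = pd.DataFrame(
        {
            "element": elements,
            "n_below_dl": below.astype(int),
            "n_total": total,
            "fraction_below_dl": frac,
            "excluded": frac > dl_fraction_threshold,
        }
    )
    if not retained:
        raise ValueError("all elements excluded by the detection-limit filter")
    return retained, report


def extract_edge_signature(
    transect: ElementalTransect,
    window: tuple[float, float] = (2.0, 7.0),
    surface_position: float | None = None,
) -> EdgeSignature:
    """Average concentrations over the sub-surface edge window.

    ``window`` is (min, max) distance from the otolith surface in µm,
    inclusive at both ends.  Readings closer than the lower bound are never
    included (surface contamination).  The surface defaults to the largest
    recorded position, i.e. the end of the ablation path.
    """
    lo, hi = window
    if not 0 <= lo < hi:
        raise ValueError("window must satisfy 0 <= lo < hi")
    surface = float(transect.positions.max()) if surface_position is None else surface_position
    dist = surface - transect.positions
    mask = (dist >= lo) & (dist <= hi)
    if not mask.any():
        raise ValueError(
            f"fish {transect.fish_id!r}: no measurements within "
            f"{lo}-{hi} µm of the surface"
        )
    fingerprint = transect.concentrations[mask].mean(axis=0)
    return EdgeSignature(
        fish_id=transect.fish_id,
        site_id=transect.capture_site_id,
        fingerprint=fingerprint,
        elements=tuple(transect.elements),
        n_points=int(mask.sum()),
    )
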