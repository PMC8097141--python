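"""Heterogeneous PYR model database: grid sweep, phenotyping, band selection.

A database is built by sweeping the four parameters that shape excitability
and adaptation — ``a`` (recovery time constant), ``b`` (recovery
sensitivity), ``d`` (after-spike increment) and ``k_low`` (subthreshold
scaling) — over a Cartesian grid around the default strongly adapting cell,
holding all other parameters fixed.  Every grid point is phenotyped with the
three feature protocols, giving a table of (model_id, parameters, SFA, Rheo,
PIR) rows.

Feature *bands* partition the observed feature distributions:

* Low / Medium / High — tertile split of each feature's defined values.
* Narrow / Broad — symmetric intervals about the base (default-cell) value
  covering a configurable central fraction of the observed range.

Populations for network building are drawn (seeded, with replacement) from
the rows whose triplet falls inside a requested band triplet, mirroring how
heterogeneous 10,000-cell populations are assembled from far fewer distinct
models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import PYR_DEFAULTS, DEFAULT_DT, CellParams
from .features import FeatureTriplet, quantify_features

__all__ = [
    "GridSpec",
    "ModelDatabase",
    "FeatureBands",
    "PopulationSpec",
    "Selection",
    "EmptySelectionError",
    "build_database",
    "derive_bands",
    "select_population",
    "default_grid",
]

FEATURES = ("sfa", "rheo", "pir")
#: Base feature values of the default cell, used as band centers.
BASE_TRIPLET = {"sfa": 0.46, "rheo": 4.0, "pir": -5.0}
#: Histogram bin widths per feature (Hz/pA for SFA, pA otherwise).
HIST_BIN_WIDTHS = {"sfa": 0.05, "rheo": 0.5, "pir": 0.5}


class EmptySelectionError(ValueError):
    """No database row satisfies the requested band constraints."""


@dataclass(frozen=True)
class GridSpec:
    """Value lists for the four swept parameters; the rest stay at defaults."""

    a: tuple
    b: tuple
    d: tuple
    k_low: tuple
    base: CellParams = PYR_DEFAULTS

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "k_low"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ValueError(f"empty value list for parameter {name!r}")
            object.__setattr__(self, name, vals)
        if any(v <= 0 for v in self.a) or any(v <= 0 for v in self.k_low):
            raise ValueError("a and k_low values must be positive")
        if any(v < 0 for v in self.d):
            raise ValueError("d values must be non-negative")

    @property
    def size(self) -> int:
        return len(self.a) * len(self.b) * len(self.d) * len(self.k_low)

    def points(self):
        """Yield (a, b, d, k_low) tuples in row-major (itertools) order."""
        return itertools.product(self.a, self.b, self.d, self.k_low)


def default_grid(n_per_param: int = 10) -> GridSpec:
    """Reference grid bracketing the default cell.

    ``a`` and ``k_low`` are log-spaced (they act multiplicatively on time
    scale and input conductance), ``b`` and ``d`` linearly spaced.  With
    the default 10 values per parameter this gives a 10,000-model
    database.  The exact default values are appended-by-construction:
    each list is chosen so the default is a member.
    """
    # geomspace/linspace endpoints chosen to bracket the defaults; the
    # default value itself is inserted by snapping the nearest grid point.
    a_vals = np.geomspace(0.0004, 0.004, n_per_param)
    k_vals = np.geomspace(0.05, 0.2, n_per_param)
    b_vals = np.linspace(1.0, 5.0, n_per_param)
    d_vals = np.linspace(2.0, 20.0, n_per_param)

    def snap(vals, default):
        vals = vals.copy()
        vals[np.argmin(np.abs(vals - default))] = default
        return tuple(np.round(vals, 10))

    return GridSpec(a=snap(a_vals, 0.0012), b=snap(b_vals, 3.0),
                    d=snap(d_vals, 10.0), k_low=snap(k_vals, 0.1))


@dataclass
class ModelDatabase:
    """Phenotyped model table.

    ``table`` columns: model_id, a, b, d, k_low, sfa, rheo, pir,
    all_undefined (flag for rows where no feature could be quantified).
    """

    table: pd.DataFrame
    base: CellParams = PYR_DEFAULTS

    def __len__(self) -> int:
        return len(self.table)

    def params_for_row(self, row) -> CellParams:
        return self.base.with_(a=row.a, b=row.b, d=row.d, k_low=row.k_low)

    def params_for_id(self, model_id: int) -> CellParams:
        row = self.table.loc[self.table.model_id == model_id].iloc[0]
        return self.params_for_row(row)

    def feature_histogram(self, feature: str):
        """Histogram of a feature's defined values at its standard bin width.

        Bin edges are aligned to multiples of the bin width so the
        histograms are comparable across databases.  Returns
        (counts, edges).
        """
        width = HIST_BIN_WIDTHS[feature]
        vals = self.table[feature].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"feature {feature!r} has no defined values")
        lo = np.floor(vals.min() / width) * width
        hi = np.ceil(vals.max() / width) * width
        n = max(int(round((hi - lo) / width)), 1)
        edges = lo + width * np.arange(n + 1)
        counts, _ = np.histogram(vals, bins=edges)
        return counts, edges

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, base: CellParams = PYR_DEFAULTS) -> "ModelDatabase":
        return ModelDatabase(pd.read_csv(path), base=base)


def build_database(grid: GridSpec, *, dt: float = DEFAULT_DT,
                   progress: bool = False) -> ModelDatabase:
    """Phenotype the full Cartesian grid.

    Rows where all three features are undefined are retained but flagged
    ``all_undefined``.
    """
    rows = []
    for model_id, (a, b, d, k_low) in enumerate(grid.points()):
        params = grid.base.with_(a=a, b=b, d=d, k_low=k_low)
        trip = quantify_features(params, dt=dt)
        rows.append({
            "model_id": model_id, "a": a, "b": b, "d": d, "k_low": k_low,
            "sfa": trip.sfa, "rheo": trip.rheo, "pir": trip.pir,
            "all_undefined": trip.sfa is None and trip.rheo is None
                             and trip.pir is None,
        })
        if progress and (model_id + 1) % 100 == 0:
            print(f"  phenotyped {model_id + 1}/{grid.size} models")
    table = pd.DataFrame(rows)
    for f in FEATURES:
        table[f] = table[f].astype(float)  # None -> NaN
    return ModelDatabase(table=table, base=grid.base)


@dataclass(frozen=True)
class FeatureBands:
    """Per-feature Low/Medium/High and Narrow/Broad intervals.

    ``lmh[feature]`` is a tuple of three (lo, hi) intervals partitioning
    the observed range of defined values at the tertiles; ``narrow`` and
    ``broad`` map features to (lo, hi) intervals centered on the base
    value.  All intervals are closed.
    """

    lmh: dict
    narrow: dict
    broad: dict

    def interval(self, feature: str, band: str):
        band = band.upper()
        if band in ("L", "M", "H"):
            return self.lmh[feature]["LMH".index(band)]
        if band == "N":
            return self.narrow[feature]
        if band == "B":
            return self.broad[feature]
        raise ValueError(f"unknown band {band!r}")

    def band_of(self, feature: str, value: float) -> str:
        """Which of L/M/H the value falls in (ties go to the lower band)."""
        for label, (lo, hi) in zip("LMH", self.lmh[feature]):
            if lo <= value <= hi:
                return label
        raise ValueError(f"{feature}={value} outside observed range")


def derive_bands(db: ModelDatabase, *,
                 narrow_fraction: float = 0.2,
                 broad_fraction: float = 0.6,
                 base_values: dict = None) -> FeatureBands:
    """Tertile L/M/H split and base-centered Narrow/Broad intervals.

    L/M/H edges are the 1/3 and 2/3 quantiles (linear interpolation) of
    each feature's defined values.  Narrow and Broad are symmetric about
    the base value, with half-width = fraction/2 of the observed range.
    """
    if not 0 < narrow_fraction <= broad_fraction <= 1:
        raise ValueError("require 0 < narrow_fraction <= broad_fraction <= 1")
    base_values = dict(BASE_TRIPLET if base_values is None else base_values)
    lmh, narrow, broad = {}, {}, {}
    for f in FEATURES:
        vals = db.table[f].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"all values undefined for feature {f!r}")
        lo, hi = float(vals.min()), float(vals.max())
        q1, q2 = (float(q) for q in np.quantile(vals, [1 / 3, 2 / 3]))
        lmh[f] = ((lo, q1), (q1, q2), (q2, hi))
        span = hi - lo
        ctr = base_values[f]
        narrow[f] = (ctr - narrow_fraction * span / 2,
                     ctr + narrow_fraction * span / 2)
        broad[f] = (ctr - broad_fraction * span / 2,
                    ctr + broad_fraction * span / 2)
    return FeatureBands(lmh=lmh, narrow=narrow, broad=broad)


@dataclass(frozen=True)
class PopulationSpec:
    """Band triplet plus population size and sampling seed.

    ``bands`` is a mapping feature -> band label (L/M/H/N/B), e.g.
    ``{"sfa": "H", "rheo": "M", "pir": "L"}``.
    """

    bands: dict
    size: int
    seed: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("population size must be positive")
        if set(self.bands) != set(FEATURES):
            raise ValueError(f"bands must cover exactly {FEATURES}")

    @property
    def label(self) -> str:
        return "".join(self.bands[f].upper() for f in FEATURES)


@dataclass
class Selection:
    """Drawn heterogeneous population."""

    cells: list            # CellParams, length == spec.size
    model_ids: np.ndarray  # drawn model_id per cell
    qualifying_ids: np.ndarray
    spec: PopulationSpec

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.model_ids))


def qualifying_rows(db: ModelDatabase, bands: FeatureBands,
                    band_triplet: dict) -> pd.DataFrame:
    """Rows whose defined triplet lies inside all three band intervals."""
    mask = np.ones(len(db.table), dtype=bool)
    for f in FEATURES:
        lo, hi = bands.interval(f, band_triplet[f])
        col = db.table[f].to_numpy(dtype=float)
        mask &= np.isfinite(col) & (col >= lo) & (col <= hi)
    return db.table.loc[mask]


def select_population(db: ModelDatabase, bands: FeatureBands,
                      spec: PopulationSpec) -> Selection:
    """Seeded uniform draw with replacement from the qualifying rows.

    Raises
    ------
    EmptySelectionError
        If no row satisfies all three band constraints (the empty
        vertices of the L/M/H triplet cube).
    """
    rows = qualifying_rows(db, bands, spec.bands)
    if len(rows) == 0:
        raise EmptySelectionError(
            f"no models qualify for band triplet {spec.label}")
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, len(rows), size=spec.size)
    drawn = rows.iloc[idx]
    cells = [db.params_for_row(r) for r in drawn.itertuples()]
    return Selection(cells=cells,
                     model_ids=drawn.model_id.to_numpy(),
                     qualifying_ids=rows.model_id.to_numpy(),
                     spec=spec)
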