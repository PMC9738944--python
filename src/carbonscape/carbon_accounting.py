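"""Four-pool carbon-density bookkeeping over categorical land-cover grids.

Each land-cover class *i* carries four carbon pools (Mg/hm²): aboveground
biomass, belowground biomass, soil organic carbon, and dead organic matter.
The class total is their sum,

    C_i,tot = C_i,above + C_i,below + C_i,soil + C_i,dead

and landscape storage is area-weighted bookkeeping: with areas in km² and
densities in Mg/hm² (1 km² = 100 hm²), storage reported in 10⁴ Mg is

    storage_i = area_i[km²] × C_i,tot / 100.

Densities are assumed constant in time, so storage change between two epochs
is entirely driven by land-cover transitions. Reported storage values are
rounded half-up to 2 decimals at the reporting boundary only; full precision
is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_raster import (
    ClassMap,
    DEFAULT_CLASS_CODES,
    DEFAULT_CLASS_NAMES,
    _require_aligned,
)

POOLS = ("c_above", "c_below", "c_soil", "c_dead")


def round_report(x: float, decimals: int = 2) -> float:
    """Round half-up (not banker's) — the convention used for reported storage."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def total_density(c_above: float, c_below: float, c_soil: float, c_dead: float) -> float:
    """Total carbon density of a class: the sum of its four pools (Mg/hm²)."""
    pools = (c_above, c_below, c_soil, c_dead)
    if any(p < 0 for p in pools):
        raise ValueError(f"carbon pool densities must be non-negative, got {pools}")
    return float(sum(pools))


@dataclass(frozen=True)
class CarbonDensityTable:
    """Per-class four-pool carbon densities (Mg/hm²) with derived totals."""

    table: pd.DataFrame  # index: class_code; columns: class_name + POOLS + c_tot

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in POOLS if c not in df.columns]
        if missing:
            raise ValueError(f"density table missing pool columns: {missing}")
        if (df[list(POOLS)] < 0).any().any():
            raise ValueError("carbon pool densities must be non-negative")
        df["c_tot"] = df[list(POOLS)].sum(axis=1)
        object.__setattr__(self, "table", df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CarbonDensityTable":
        df = pd.read_csv(path).set_index("class_code")
        return cls(df)

    @classmethod
    def from_dict(
        cls, pools: Mapping[int, tuple[float, float, float, float]],
        names: Mapping[int, str] | None = None,
    ) -> "CarbonDensityTable":
        names = names or DEFAULT_CLASS_NAMES
        rows = {
            code: {"class_name": names.get(code, str(code)), **dict(zip(POOLS, v))}
            for code, v in pools.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "class_code"
        return cls(df)

    def c_tot(self, class_code: int) -> float:
        try:
            return float(self.table.loc[class_code, "c_tot"])
        except KeyError:
            raise KeyError(f"no carbon density row for class {class_code}") from None

    def c_tot_vector(self, class_codes) -> np.ndarray:
        return np.array([self.c_tot(c) for c in class_codes])

    def require_classes(self, codes) -> None:
        missing = [c for c in codes if c not in self.table.index]
        if missing:
            raise KeyError(f"no carbon density row for classes {missing}")


@dataclass(frozen=True)
class AreaSummary:
    """Per-class area (km²) and storage (10⁴ Mg) with a totals row.

    ``table`` keeps full-precision storage; :meth:`report` rounds storage
    half-up to 2 decimals for output.
    """

    table: pd.DataFrame  # index class_code (+ "total"); columns class_name, area_km2, storage_1e4Mg

    @property
    def total_area(self) -> float:
        return float(self.table.loc["total", "area_km2"])

    @property
    def total_storage(self) -> float:
        return float(self.table.loc["total", "storage_1e4Mg"])

    def storage(self, class_code: int) -> float:
        return float(self.table.loc[class_code, "storage_1e4Mg"])

    def area(self, class_code: int) -> float:
        return float(self.table.loc[class_code, "area_km2"])

    def report(self) -> pd.DataFrame:
        out = self.table.copy()
        out["storage_1e4Mg"] = out["storage_1e4Mg"].map(round_report)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.report().to_csv(path, index_label="class_code")


def storage_from_area_table(
    areas_km2: Mapping[int, float],
    density: CarbonDensityTable,
    names: Mapping[int, str] | None = None,
) -> AreaSummary:
    """Storage bookkeeping from a per-class area table (no raster needed).

    storage_i (10⁴ Mg) = area_i (km²) × C_i,tot (Mg/hm²) / 100.
    """
    names = names or DEFAULT_CLASS_NAMES
    if any(a < 0 for a in areas_km2.values()):
        raise ValueError("areas must be non-negative")
    density.require_classes(areas_km2.keys())
    rows = []
    for code, area in areas_km2.items():
        rows.append(
            {
                "class_code": code,
                "class_name": names.get(code, str(code)),
                "area_km2": float(area),
                "storage_1e4Mg": float(area) * density.c_tot(code) / 100.0,
            }
        )
    df = pd.DataFrame(rows).set_index("class_code")
    total = pd.DataFrame(
        {
            "class_name": ["total"],
            "area_km2": [df["area_km2"].sum()],
            "storage_1e4Mg": [df["storage_1e4Mg"].sum()],
        },
        index=pd.Index(["total"], name="class_code"),
    )
    return AreaSummary(pd.concat([df, total]))


def carbon_storage(cmap: ClassMap, density: CarbonDensityTable) -> AreaSummary:
    """Per-class area and carbon storage of a class map.

    Identical arithmetic to :func:`storage_from_area_table` applied to the
    map's class areas; the two entry points agree exactly by construction.
    """
    density.require_classes(c for c, n in cmap.class_counts().items() if n > 0)
    areas = {c: a for c, a in cmap.class_areas().items()}
    return storage_from_area_table(areas, density)


def carbon_change_map(
    map_t0: ClassMap, map_t1: ClassMap, density: CarbonDensityTable
) -> np.ndarray:
    """Per-cell carbon storage change between two epochs, in Mg per cell.

    delta = (C_tot[class_t1] − C_tot[class_t0]) × cell_area × 100
    (100 hm² per km²). Unchanged cells are exactly 0; cells that are nodata
    in either epoch are NaN. The map total equals the landscape storage
    delta: Σ delta / 10⁴ = total_storage(t1) − total_storage(t0).
    """
    _require_aligned(map_t0, map_t1)
    present = set(np.unique(map_t0.grid[map_t0.valid_mask])) | set(
        np.unique(map_t1.grid[map_t1.valid_mask])
    )
    density.require_classes(present)
    # lookup table indexed by class code; nodata slots stay NaN
    max_code = max(list(map_t0.class_codes) + [map_t0.nodata_code, map_t1.nodata_code])
    lut = np.full(max_code + 1, np.nan)
    for code in map_t0.class_codes:
        if code in density.table.index:
            lut[code] = density.c_tot(code)
    delta = (lut[map_t1.grid] - lut[map_t0.grid]) * map_t0.cell_area * 100.0
    delta[map_t0.grid == map_t1.grid] = 0.0
    valid = map_t0.valid_mask & map_t1.valid_mask
    delta[~valid] = np.nan
    return delta


# ---------------------------------------------------------------------------
# packaged reference tables (Guizhou Province)
# ---------------------------------------------------------------------------

GUIZHOU_EPOCHS = (2010, 2020, 2030, 2050)
GUIZHOU_TOTAL_AREA_SIMULATED = 173_702  # km², constant across simulated epochs


def _data_path(name: str):
    return resources.files("carbonscape.data").joinpath(name)


def guizhou_density_table() -> CarbonDensityTable:
    """The packaged Guizhou carbon-density reference table (Mg/hm²)."""
    with resources.as_file(_data_path("carbon_density_guizhou.csv")) as p:
        return CarbonDensityTable.from_csv(p)


def guizhou_area_table(reconcile: bool = True) -> pd.DataFrame:
    """Published Guizhou per-class areas (km²) for 2010/2020/2030/2050.

    The published 2050 forest area (9012 km²) is inconsistent with both the
    constant simulated landscape total (173,702 km²) and the published 2050
    forest storage; with ``reconcile=True`` (default) it is recovered by area
    conservation as the total minus the other five classes (90,123 km²).
    """
    with resources.as_file(_data_path("guizhou_class_areas.csv")) as p:
        df = pd.read_csv(p).set_index("class_code")
    if reconcile:
        others = df.loc[df.index != 2, "area_2050"].sum()
        df.loc[2, "area_2050"] = GUIZHOU_TOTAL_AREA_SIMULATED - others
    return df


def guizhou_epoch_areas(year: int, reconcile: bool = True) -> dict[int, float]:
    """Per-class area dict for one published epoch."""
    if year not in GUIZHOU_EPOCHS:
        raise ValueError(f"no published areas for {year}; have {GUIZHOU_EPOCHS}")
    df = guizhou_area_table(reconcile=reconcile)
    return {int(c): float(a) for c, a in df[f"area_{year}"].items()}
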