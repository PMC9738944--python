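"""Synthetic two-epoch landscapes, driver stacks, and indicator tables.

Every downstream stage (carbon bookkeeping, transition accounting, LEAS,
Markov demand, the patch CA, entropy scoring) gets a fully known test
surface from this module: spatially autocorrelated class maps built by
thresholding a smoothed Gaussian field at class-fraction quantiles, driver
layers with planted class-dependent mean shifts, a second epoch evolved
under exact per-pair conversion counts steered by chosen drivers, and
region × indicator tables with optional planted dominance.

All generators are pure functions of their spec plus a seed; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .carbon_accounting import guizhou_area_table, guizhou_density_table
from .core_raster import (
    ClassMap,
    DEFAULT_CLASS_CODES,
    DriverStack,
    write_class_map,
    write_driver_stack,
)
from .sustainability_index import IndicatorTable


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one autocorrelated categorical landscape."""

    shape: tuple[int, int] = (200, 200)
    class_fractions: dict[int, float] = field(default_factory=dict)
    autocorrelation_scale: float = 6.0  # Gaussian smoothing length, cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 10 or self.shape[1] < 10:
            raise ValueError("landscape must be at least 10x10")
        if not self.class_fractions:
            object.__setattr__(self, "class_fractions", guizhou_like_fractions())
        fr = self.class_fractions
        if any(f < 0 for f in fr.values()):
            raise ValueError("class fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fr.values())}")


@dataclass(frozen=True)
class DriverSpec:
    """One continuous driver: smooth noise plus class-dependent mean shifts.

    ``affinity`` maps class code → shift (in noise standard deviations) of
    the driver mean over that class; positive shifts make the driver high
    where the class sits. Strength ~2 gives a clearly separable signal,
    0 gives a class-independent null driver.
    """

    name: str
    affinity: dict[int, float] = field(default_factory=dict)
    smoothing: float = 4.0


@dataclass(frozen=True)
class Conversion:
    """One planted class-to-class flow: exactly ``count`` cells convert."""

    from_code: int
    to_code: int
    count: int
    driver_affinity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvolutionSpec:
    """Planted transition structure taking epoch t0 to epoch t1."""

    conversions: tuple[Conversion, ...]
    seed: int = 0
    stochastic: bool = False  # sample conversions ∝ affinity instead of top-k


def guizhou_like_fractions(year: int = 2020) -> dict[int, float]:
    """Class shares matching the published provincial composition of a year."""
    df = guizhou_area_table()
    areas = df[f"area_{year}"]
    total = areas.sum()
    return {int(c): float(a / total) for c, a in areas.items()}


def _smooth_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def generate_landscape(spec: LandscapeSpec) -> ClassMap:
    """Threshold a smoothed Gaussian field at class-fraction quantiles.

    Cells are ranked by field value and split into contiguous rank bands
    sized by the target fractions, so realised shares are exact up to
    integer rounding and spatial clustering grows with the smoothing scale.
    """
    rng = np.random.default_rng(spec.seed)
    fld = _smooth_field(spec.shape, spec.autocorrelation_scale, rng)
    n = fld.size
    order = np.argsort(fld.ravel(), kind="stable")
    codes = sorted(spec.class_fractions)
    targets = np.array([spec.class_fractions[c] for c in codes])
    counts = np.floor(targets * n).astype(int)
    # hand leftover cells to the largest fractional remainders
    rem = targets * n - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    grid = np.empty(n, dtype=np.int64)
    start = 0
    for code, cnt in zip(codes, counts):
        grid[order[start : start + cnt]] = code
        start += cnt
    return ClassMap(grid=grid.reshape(spec.shape))


def generate_drivers(
    cmap: ClassMap, driver_specs: Sequence[DriverSpec], seed: int = 0
) -> DriverStack:
    """Driver stack aligned with ``cmap``: planted shifts + smooth unit noise."""
    if not driver_specs:
        raise ValueError("at least one driver spec is required")
    rng = np.random.default_rng(seed)
    layers = []
    for ds in driver_specs:
        layer = _smooth_field(cmap.shape, ds.smoothing, rng)
        for code, strength in ds.affinity.items():
            layer = layer + strength * (cmap.grid == code)
        layers.append((ds.name, layer))
    return DriverStack(layers=tuple(layers))


def default_driver_specs() -> list[DriverSpec]:
    """Drivers emulating a mountainous-province stack: terrain keeps forest
    high and settlement low; economic surfaces pull settlement; distance to
    road repels settlement; climate tracks grassland; one null driver."""
    return [
        DriverSpec("elevation", affinity={2: 1.8, 5: -1.2}),
        DriverSpec("slope", affinity={2: 1.2, 1: -0.8}),
        DriverSpec("gdp", affinity={5: 2.0}),
        DriverSpec("population", affinity={5: 1.6, 1: 0.6}),
        DriverSpec("dist_road", affinity={5: -1.8}),
        DriverSpec("precipitation", affinity={3: 1.0, 4: 0.8}),
        DriverSpec("temperature", affinity={}),
    ]


def evolve_landscape(
    map_t0: ClassMap,
    drivers: DriverStack,
    evo: EvolutionSpec,
    allowed: np.ndarray | None = None,
) -> ClassMap:
    """Apply the planted conversions to produce the second epoch.

    For each conversion the source cells are scored by the weighted sum of
    (standardised) driver values named in ``driver_affinity``; the top
    ``count`` scorers convert (ties and the no-affinity case broken by a
    seeded shuffle). With ``stochastic=True`` cells are drawn with
    probability proportional to softmax scores instead. A cell converts at
    most once; all other cells are untouched, so the transition matrix of
    (t0, t1) reproduces the planted counts exactly.
    """
    if drivers.shape != map_t0.shape:
        raise ValueError("drivers misaligned with landscape")
    codes = map_t0.class_codes
    code_idx = {c: i for i, c in enumerate(codes)}
    rng = np.random.default_rng(evo.seed)
    grid = map_t0.grid.copy().ravel()
    converted = np.zeros(grid.size, dtype=bool)
    zdrv = {
        name: (a - np.nanmean(a)) / (np.nanstd(a) or 1.0)
        for name, a in ((n, drivers[n]) for n in drivers.names)
    }
    for conv in evo.conversions:
        if allowed is not None and not allowed[code_idx[conv.from_code], code_idx[conv.to_code]]:
            raise ValueError(
                f"conversion {conv.from_code}->{conv.to_code} violates the transition mask"
            )
        pool = np.flatnonzero((grid == conv.from_code) & ~converted & map_t0.valid_mask.ravel())
        if conv.count > pool.size:
            raise ValueError(
                f"conversion {conv.from_code}->{conv.to_code} requests {conv.count} "
                f"cells but only {pool.size} are available"
            )
        if conv.count == 0:
            continue
        score = np.zeros(pool.size)
        for name, w in conv.driver_affinity.items():
            score += w * zdrv[name].ravel()[pool]
        shuffle = rng.permutation(pool.size)  # seeded tie-break
        pool, score = pool[shuffle], score[shuffle]
        if evo.stochastic:
            p = np.exp(score - score.max())
            p /= p.sum()
            chosen = rng.choice(pool.size, size=conv.count, replace=False, p=p)
        else:
            chosen = np.argsort(-score, kind="stable")[: conv.count]
        cells = pool[chosen]
        grid[cells] = conv.to_code
        converted[cells] = True
    return map_t0.with_grid(grid.reshape(map_t0.shape))


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    orientation: str  # "+" or "-"
    low: float = 0.0
    high: float = 100.0


def generate_indicator_table(
    n_regions: int,
    indicator_specs: Sequence[IndicatorSpec],
    seed: int = 0,
    dominant_region: str | None = None,
) -> IndicatorTable:
    """Random region × indicator table, optionally with a planted dominator.

    The dominant region (if named) is set strictly best on every indicator —
    maximal for positive, minimal for negative — pinning the downstream
    score ordering.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions (entropy uses k = 1/ln n)")
    if not indicator_specs:
        raise ValueError("need at least one indicator")
    rng = np.random.default_rng(seed)
    regions = [f"region_{i + 1}" for i in range(n_regions)]
    if dominant_region is not None and dominant_region not in regions:
        regions[0] = dominant_region
    data = {}
    for ind in indicator_specs:
        vals = rng.uniform(ind.low, ind.high, size=n_regions)
        if dominant_region is not None:
            i = regions.index(dominant_region)
            span = ind.high - ind.low
            if ind.orientation == "+":
                vals[i] = vals.max() + 0.05 * span
            else:
                vals[i] = vals.min() - 0.05 * span
        data[ind.name] = vals
    values = pd.DataFrame(data, index=pd.Index(regions, name="region"))
    return IndicatorTable(
        values=values, orientations={i.name: i.orientation for i in indicator_specs}
    )


# ---------------------------------------------------------------------------
# standard two-epoch study fixture
# ---------------------------------------------------------------------------

def default_conversions(n_cells: int) -> tuple[Conversion, ...]:
    """Planted flows proportional to the observed provincial decade of change.

    The dominant published flows (farmland↔forest↔grassland exchange plus
    settlement and water expansion, each roughly 0.3–1% of the landscape per
    decade) are scaled to the fixture's cell count, steered by the drivers
    that plausibly govern them.
    """
    f = n_cells / 176_098.0  # published-landscape cells per fixture cell
    s = lambda km2: max(5, int(round(km2 * f)))
    return (
        Conversion(1, 2, s(1649), {"slope": 1.0, "elevation": 0.6}),
        Conversion(1, 3, s(614), {"precipitation": 0.8}),
        Conversion(2, 1, s(1677), {"slope": -1.0, "population": 0.5}),
        Conversion(2, 3, s(677), {"precipitation": 0.6, "elevation": -0.4}),
        Conversion(3, 1, s(599), {"population": 0.6}),
        Conversion(3, 2, s(608), {"elevation": 0.8}),
        Conversion(1, 5, s(1300), {"gdp": 1.2, "dist_road": -0.8}),
        Conversion(3, 5, s(436), {"gdp": 1.0, "dist_road": -0.6}),
        Conversion(1, 4, s(500), {"precipitation": 0.7}),
        Conversion(3, 4, s(204), {"precipitation": 0.7}),
    )


def two_epoch_fixture(
    shape: tuple[int, int] = (200, 200),
    seed: int = 0,
    fractions_year: int = 2010,
) -> tuple[ClassMap, ClassMap, DriverStack, EvolutionSpec]:
    """Standard study fixture: t0 landscape with provincial class shares,
    the default driver stack, and a t1 epoch evolved under the default
    planted flows. Returns (t0, t1, drivers, evolution spec)."""
    spec = LandscapeSpec(
        shape=shape, class_fractions=guizhou_like_fractions(fractions_year), seed=seed
    )
    t0 = generate_landscape(spec)
    drivers = generate_drivers(t0, default_driver_specs(), seed=seed + 1)
    evo = EvolutionSpec(conversions=default_conversions(t0.grid.size), seed=seed + 2)
    t1 = evolve_landscape(t0, drivers, evo)
    return t0, t1, drivers, evo


def write_fixture_bundle(
    out_dir: str | Path,
    shape: tuple[int, int] = (200, 200),
    seed: int = 0,
) -> dict[str, Path]:
    """Emit a complete input bundle for end-to-end CLI runs.

    Writes the two epoch rasters, the driver rasters, the packaged carbon
    density table, a synthetic indicator table, and a YAML manifest of the
    generating parameters. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0, t1, drivers, evo = two_epoch_fixture(shape=shape, seed=seed)
    paths: dict[str, Path] = {}
    paths["t0"] = write_class_map(t0, out_dir / "landcover_t0.tif")
    paths["t1"] = write_class_map(t1, out_dir / "landcover_t1.tif")
    driver_paths = write_driver_stack(drivers, out_dir / "drivers")
    paths["drivers"] = out_dir / "drivers"
    density = guizhou_density_table()
    paths["density"] = out_dir / "carbon_density.csv"
    density.table.drop(columns="c_tot").to_csv(paths["density"], index_label="class_code")
    indicators = generate_indicator_table(
        9,
        [
            IndicatorSpec("cultivated_area", "+"),
            IndicatorSpec("grain_output", "+"),
            IndicatorSpec("industry_share", "+"),
            IndicatorSpec("agri_output", "+"),
            IndicatorSpec("gdp_per_capita", "+"),
            IndicatorSpec("urbanization", "+"),
            IndicatorSpec("rocky_desertification", "-"),
            IndicatorSpec("forest_cover", "+"),
            IndicatorSpec("soil_erosion", "-"),
            IndicatorSpec("energy_intensity_drop", "+"),
            IndicatorSpec("wastewater", "-"),
            IndicatorSpec("so2_emissions", "-"),
            IndicatorSpec("fertilizer_use", "-"),
        ],
        seed=seed + 3,
    )
    paths["indicators"] = out_dir / "indicators.csv"
    indicators.to_csv(paths["indicators"])
    manifest = {
        "shape": list(shape),
        "seed": seed,
        "drivers": [p.name for p in driver_paths],
        "conversions": [
            {"from": c.from_code, "to": c.to_code, "count": c.count}
            for c in evo.conversions
        ],
    }
    paths["manifest"] = out_dir / "fixture.yaml"
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=False))
    return paths
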