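"""Core grid types and raster/table I/O shared by every pipeline stage.

The common currency of the pipeline is the :class:`ClassMap`: a 2-D integer
grid of first-level ecosystem classes (1=farmland, 2=forest, 3=grassland,
4=aquatic, 5=settlement, 6=other) with an explicit nodata code and a per-cell
area in km². Continuous covariates travel as a :class:`DriverStack` aligned
cell-for-cell with a companion class map.

Rasters are stored as single-band TIFF files; georeference metadata (affine
transform, CRS string, cell area, nodata code) rides in a JSON document in
the TIFF ImageDescription tag and is carried through untouched — no
reprojection or resampling is performed anywhere, inputs must be pre-aligned
(:func:`align_check` enforces this).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

DEFAULT_CLASS_CODES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
DEFAULT_CLASS_NAMES: dict[int, str] = {
    1: "farmland",
    2: "forest",
    3: "grassland",
    4: "aquatic",
    5: "settlement",
    6: "other",
}
DEFAULT_NODATA = 0

_META_KEY = "carbonscape"


class RasterFormatError(ValueError):
    """Raised when a raster violates the class-map contract."""


@dataclass(frozen=True)
class ClassMap:
    """Categorical land-cover grid.

    Parameters
    ----------
    grid
        2-D integer array of class codes. Cells equal to ``nodata_code`` are
        excluded from every tally.
    cell_area
        Area of one cell in km² (default 1, matching 1-km analysis grids).
    nodata_code
        Integer marking invalid cells; must not collide with a class code.
    class_codes
        Ordered tuple of legal class codes.
    georeference
        Opaque mapping (affine transform, CRS, ...) carried through I/O.
    """

    grid: np.ndarray
    cell_area: float = 1.0
    nodata_code: int = DEFAULT_NODATA
    class_codes: tuple[int, ...] = DEFAULT_CLASS_CODES
    georeference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise RasterFormatError(f"class grid must be 2-D, got shape {grid.shape}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise RasterFormatError(f"class grid must be integer, got dtype {grid.dtype}")
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be > 0, got {self.cell_area}")
        if self.nodata_code in self.class_codes:
            raise ValueError(
                f"nodata_code {self.nodata_code} collides with a class code"
            )
        legal = set(self.class_codes) | {self.nodata_code}
        bad = np.setdiff1d(np.unique(grid), sorted(legal))
        if bad.size:
            raise RasterFormatError(
                f"grid contains codes outside the classification: {bad.tolist()}"
            )
        object.__setattr__(self, "grid", grid)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata_code

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def aligned_with(self, other: "ClassMap") -> bool:
        return (
            self.shape == other.shape
            and self.cell_area == other.cell_area
            and self.georeference == other.georeference
        )

    # -- tallies ----------------------------------------------------------
    def class_counts(self) -> dict[int, int]:
        """Cell count per class code (all codes present, zeros included)."""
        counts = {c: 0 for c in self.class_codes}
        codes, n = np.unique(self.grid[self.valid_mask], return_counts=True)
        counts.update(dict(zip(codes.tolist(), n.tolist())))
        return counts

    def class_areas(self) -> dict[int, float]:
        """Area per class code in km² (count × cell_area)."""
        return {c: n * self.cell_area for c, n in self.class_counts().items()}

    def with_grid(self, grid: np.ndarray) -> "ClassMap":
        """New ClassMap sharing this one's geometry but a different grid."""
        return replace(self, grid=grid)


@dataclass(frozen=True)
class DriverStack:
    """Named continuous covariate layers aligned with a class map."""

    layers: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("driver stack needs at least one layer")
        names = [n for n, _ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate driver names: {names}")
        shapes = {a.shape for _, a in self.layers}
        if len(shapes) != 1:
            raise ValueError(f"driver layers disagree on shape: {sorted(shapes)}")
        layers = tuple((n, np.asarray(a, dtype=float)) for n, a in self.layers)
        object.__setattr__(self, "layers", layers)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0][1].shape

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        for n, a in self.layers:
            if n == name:
                return a
        raise KeyError(name)

    def feature_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) matrix of driver values, optionally masked."""
        flat = [a[mask] if mask is not None else a.ravel() for _, a in self.layers]
        return np.column_stack(flat)


@dataclass(frozen=True)
class AlignmentReport:
    ok: bool
    mismatch: str = ""

    def __bool__(self) -> bool:
        return self.ok


def align_check(*grids) -> AlignmentReport:
    """Verify that class maps / driver stacks share shape, cell size, georeference.

    Accepts any mix of :class:`ClassMap` and :class:`DriverStack`; the first
    disagreement is named in the report. Driver stacks are checked on shape
    only (they carry no geometry of their own).
    """
    if len(grids) < 2:
        raise ValueError("alignment check needs at least two grids")
    ref = grids[0]
    ref_shape = ref.shape
    ref_area = ref.cell_area if isinstance(ref, ClassMap) else None
    ref_geo = ref.georeference if isinstance(ref, ClassMap) else None
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref_shape:
            return AlignmentReport(False, f"grid {i}: shape {g.shape} != {ref_shape}")
        if isinstance(g, ClassMap):
            if ref_area is None:
                ref_area, ref_geo = g.cell_area, g.georeference
                continue
            if g.cell_area != ref_area:
                return AlignmentReport(
                    False, f"grid {i}: cell_area {g.cell_area} != {ref_area}"
                )
            if g.georeference != ref_geo:
                return AlignmentReport(False, f"grid {i}: georeference differs")
    return AlignmentReport(True)


def _require_aligned(*grids) -> None:
    report = align_check(*grids)
    if not report:
        raise ValueError(f"misaligned inputs: {report.mismatch}")


# ---------------------------------------------------------------------------
# raster I/O (single-band TIFF + JSON metadata tag)
# ---------------------------------------------------------------------------

def _metadata_json(cell_area: float, nodata: int | float, georeference: dict) -> str:
    return json.dumps(
        {_META_KEY: {"cell_area": cell_area, "nodata": nodata, "georeference": georeference}}
    )


def _read_metadata(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description or ""
    try:
        doc = json.loads(desc)
        return doc.get(_META_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        return {}


def write_class_map(cmap: ClassMap, path: str | Path) -> Path:
    """Write a class map as a single-band int32 TIFF with JSON metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        cmap.grid.astype(np.int32),
        description=_metadata_json(cmap.cell_area, cmap.nodata_code, cmap.georeference),
    )
    return path


def read_class_map(
    path: str | Path,
    nodata_code: int | None = None,
    class_codes: Sequence[int] = DEFAULT_CLASS_CODES,
) -> ClassMap:
    """Read a single-band integer TIFF as a :class:`ClassMap`.

    Any cell value outside ``class_codes`` plus the nodata code is rejected
    with an error naming the offending values. ``nodata_code`` overrides the
    value stored in the file metadata (default 0).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        grid = tif.asarray()
        meta = _read_metadata(tif)
    if grid.ndim != 2:
        raise RasterFormatError(f"{path}: expected single-band raster, got shape {grid.shape}")
    if not np.issubdtype(grid.dtype, np.integer):
        raise RasterFormatError(f"{path}: class raster band must be integer, got {grid.dtype}")
    if nodata_code is None:
        nodata_code = int(meta.get("nodata", DEFAULT_NODATA))
    try:
        return ClassMap(
            grid=grid.astype(np.int64),
            cell_area=float(meta.get("cell_area", 1.0)),
            nodata_code=nodata_code,
            class_codes=tuple(class_codes),
            georeference=meta.get("georeference", {}),
        )
    except RasterFormatError as exc:
        raise RasterFormatError(f"{path}: {exc}") from exc


def write_float_raster(
    arr: np.ndarray,
    path: str | Path,
    cell_area: float = 1.0,
    nodata: float = float("nan"),
    georeference: dict | None = None,
) -> Path:
    """Write a continuous surface (driver, suitability, change map) as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(arr, dtype=np.float32),
        description=_metadata_json(cell_area, nodata, georeference or {}),
    )
    return path


def read_float_raster(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise RasterFormatError(f"{path}: expected single-band raster, got shape {arr.shape}")
    return np.asarray(arr, dtype=float)


def write_driver_stack(stack: DriverStack, directory: str | Path) -> list[Path]:
    """Write each driver layer as <name>.tif under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_float_raster(arr, directory / f"{name}.tif") for name, arr in stack.layers]


def read_driver_stack(paths: Iterable[str | Path]) -> DriverStack:
    """Assemble a DriverStack from float rasters; layer name = file stem."""
    layers = tuple((Path(p).stem, read_float_raster(p)) for p in paths)
    return DriverStack(layers=layers)
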