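"""Area-flow accounting between two land-cover epochs and map agreement.

The transition matrix cross-tabulates the two epochs cell-by-cell: entry
(i, j) is the area (km²) that moved from class i to class j. Its row sums
reproduce the first epoch's class areas and its column sums the second's.
Agreement between a reference and a simulated map is summarised by overall
accuracy (trace / total) and Cohen's kappa, the chance-corrected agreement
computed from the confusion-matrix marginals. Cells that are nodata in
either epoch are excluded from both tallies so that marginals stay
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_raster import ClassMap, DEFAULT_CLASS_NAMES, _require_aligned


@dataclass(frozen=True)
class TransitionCountMatrix:
    """Class-to-class area flows between two epochs (km²)."""

    matrix: np.ndarray  # (k, k) areas, rows = t0 class, cols = t1 class
    class_codes: tuple[int, ...]
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.class_codes),) * 2:
            raise ValueError(f"matrix shape {m.shape} does not match class codes")
        if (m < 0).any():
            raise ValueError("transition areas must be non-negative")
        object.__setattr__(self, "matrix", m)

    def index_of(self, code: int) -> int:
        return self.class_codes.index(code)

    def flow(self, from_code: int, to_code: int) -> float:
        return float(self.matrix[self.index_of(from_code), self.index_of(to_code)])

    def areas_t0(self) -> dict[int, float]:
        return dict(zip(self.class_codes, self.matrix.sum(axis=1).tolist()))

    def areas_t1(self) -> dict[int, float]:
        return dict(zip(self.class_codes, self.matrix.sum(axis=0).tolist()))

    @property
    def total_area(self) -> float:
        return float(self.matrix.sum())

    def cell_counts(self) -> np.ndarray:
        """The matrix in cells rather than km² (exact integers for integral flows)."""
        return np.rint(self.matrix / self.cell_area).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        names = [DEFAULT_CLASS_NAMES.get(c, str(c)) for c in self.class_codes]
        return pd.DataFrame(self.matrix, index=names, columns=names)


def transition_matrix(map_t0: ClassMap, map_t1: ClassMap) -> TransitionCountMatrix:
    """Exact cross-tabulation of two aligned class maps, scaled to km²."""
    _require_aligned(map_t0, map_t1)
    codes = map_t0.class_codes
    valid = map_t0.valid_mask & map_t1.valid_mask
    k = len(codes)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    # map codes to 0..k-1 then bincount the pair index
    idx0 = np.vectorize(code_to_idx.get)(map_t0.grid[valid]) if valid.any() else np.array([], int)
    idx1 = np.vectorize(code_to_idx.get)(map_t1.grid[valid]) if valid.any() else np.array([], int)
    counts = np.bincount(idx0 * k + idx1, minlength=k * k).reshape(k, k)
    return TransitionCountMatrix(
        matrix=counts * map_t0.cell_area, class_codes=codes, cell_area=map_t0.cell_area
    )


@dataclass(frozen=True)
class AgreementReport:
    """Confusion matrix (cells) with overall accuracy and Cohen's kappa."""

    confusion: np.ndarray
    class_codes: tuple[int, ...]
    overall_accuracy: float
    kappa: float


def agreement(map_ref: ClassMap, map_sim: ClassMap) -> AgreementReport:
    """Overall accuracy and kappa of a simulated map against a reference.

    kappa = (p_o − p_e) / (1 − p_e) with p_o the observed agreement and p_e
    the chance agreement from the confusion marginals. Degenerate case
    p_e = 1 (both maps constant): kappa is 1 if the maps agree, else 0.
    """
    _require_aligned(map_ref, map_sim)
    valid = map_ref.valid_mask & map_sim.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("agreement undefined: zero jointly-valid cells")
    tm = transition_matrix(map_ref, map_sim)
    confusion = tm.cell_counts()
    p_o = float(np.trace(confusion)) / n
    marg_ref = confusion.sum(axis=1) / n
    marg_sim = confusion.sum(axis=0) / n
    p_e = float(marg_ref @ marg_sim)
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(
        confusion=confusion,
        class_codes=map_ref.class_codes,
        overall_accuracy=p_o,
        kappa=kappa,
    )
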