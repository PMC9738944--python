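"""First-order Markov projection of per-class land-use demand.

The observed transition matrix between two epochs is row-normalised into a
transition-probability matrix P; demand at n steps ahead is the current area
vector propagated through Pⁿ. One step spans the calibration interval
(a decade for 2010→2020 calibration), so a 2030 horizon is one step and 2050
three. Integer cell targets for the cellular automaton are produced by
largest-remainder rounding, which conserves the total cell count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .transition_analysis import TransitionCountMatrix


@dataclass(frozen=True)
class MarkovModel:
    """Row-stochastic land-use transition chain."""

    P: np.ndarray
    class_codes: tuple[int, ...]
    step_span: int = 10  # years per step

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (len(self.class_codes),) * 2:
            raise ValueError("P shape does not match class codes")
        if (P < -1e-12).any() or (P > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsum = P.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got {rowsum}")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class DemandVector:
    """Per-class area and integer cell targets for one horizon."""

    areas_km2: dict[int, float]
    cells: dict[int, int]
    horizon_steps: int

    @property
    def total_area(self) -> float:
        return float(sum(self.areas_km2.values()))

    @property
    def total_cells(self) -> int:
        return int(sum(self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_km2": pd.Series(self.areas_km2),
                "target_cells": pd.Series(self.cells),
            }
        ).rename_axis("class_code")


def estimate_markov(
    counts: TransitionCountMatrix, step_span: int = 10
) -> MarkovModel:
    """Estimate the chain by row normalisation: P[i,j] = flow(i,j) / area_t0(i).

    Classes absent at t0 (empty rows) get an identity row — an absent class
    stays absent rather than producing undefined probabilities.
    """
    m = counts.matrix
    rowsum = m.sum(axis=1)
    k = m.shape[0]
    P = np.eye(k)
    nz = rowsum > 0
    P[nz] = m[nz] / rowsum[nz, None]
    return MarkovModel(P=P, class_codes=counts.class_codes, step_span=step_span)


def largest_remainder_cells(areas_km2: np.ndarray, total_cells: int, cell_area: float) -> np.ndarray:
    """Apportion ``total_cells`` to classes proportional to area, exactly.

    Floors the exact quotas then hands remaining cells to the largest
    fractional remainders (ties to the lower class index).
    """
    quota = areas_km2 / cell_area
    floors = np.floor(quota).astype(np.int64)
    short = total_cells - int(floors.sum())
    if short < 0:
        raise ValueError("quotas exceed the cell total; inconsistent areas")
    remainders = quota - floors
    order = np.argsort(-remainders, kind="stable")
    floors[order[:short]] += 1
    return floors


def project_demand(
    areas_t: Mapping[int, float],
    model: MarkovModel,
    n_steps: int,
    cell_area: float = 1.0,
) -> DemandVector:
    """Demand after ``n_steps``: areas_t · Pⁿ, plus exact integer cell targets.

    Total area is conserved by the chain (P row-stochastic); cell targets sum
    exactly to the total valid cell count via largest-remainder rounding.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    codes = model.class_codes
    v = np.array([float(areas_t.get(c, 0.0)) for c in codes])
    demand = v @ np.linalg.matrix_power(model.P, n_steps)
    total_cells = int(round(v.sum() / cell_area))
    cells = largest_remainder_cells(demand, total_cells, cell_area)
    return DemandVector(
        areas_km2=dict(zip(codes, demand.tolist())),
        cells=dict(zip(codes, cells.tolist())),
        horizon_steps=n_steps,
    )
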