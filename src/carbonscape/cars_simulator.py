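"""Demand-driven patch-generating cellular automaton (multi-random-seed CA).

The CA allocates Markov-projected class demand over the landscape under
three forces: the per-class development probability learned by the LEAS
stage, a neighborhood effect (the local density of the candidate class), and
a per-class domain weight. For a cell currently of class c and a candidate
class k the overall probability is

    OP_k = P_dev_k × Ω_k × w_k

where Ω_k is the class-k fraction of the cell's neighborhood. When Ω_k = 0
(no class-k neighbor), the cell may still nucleate a new patch: with
probability ``expansion_coeff × seed_fraction`` it is offered
OP_k = P_dev_k × w_k × r with r ~ U(0,1) — the multi-random-seed mechanism.
A candidate class is drawn by roulette wheel over the OP values and the
conversion is accepted only if its OP beats a global threshold τ, which
starts at the 90th percentile of first-round OP values and decays
multiplicatively (factor ``patch_decay``) whenever a round leaves demand
unmet — the threshold-decreasing mechanism that lets patches grow outward
first and nucleate later.

Demand is approached monotonically: cells may convert only out of classes
above their demanded count and only into classes below it, and a 0/1
transition mask vetoes forbidden conversions outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .carbon_accounting import AreaSummary, CarbonDensityTable, carbon_storage
from .core_raster import ClassMap, DriverStack, _require_aligned
from .leas_suitability import (
    DomainWeights,
    RFSettings,
    SuitabilityStack,
    extract_expansion,
    expansion_share_weights,
    fit_suitability,
)
from .markov_demand import DemandVector, estimate_markov, project_demand
from .transition_analysis import transition_matrix

logger = logging.getLogger(__name__)


def _default_allowed(k: int) -> np.ndarray:
    return np.ones((k, k), dtype=int)


@dataclass(frozen=True)
class CAConfig:
    """Cellular-automaton parameters.

    Defaults mirror standard patch-generating simulation settings:
    3×3 neighborhood, decay coefficient 0.5, expansion coefficient 0.5,
    seed percentage 0.05.
    """

    neighborhood_size: int = 3
    patch_decay: float = 0.5
    expansion_coeff: float = 0.5
    seed_fraction: float = 0.05
    allowed: np.ndarray | None = None  # (k, k) 0/1; diagonal must be 1
    domain_weights: DomainWeights | None = None
    demand_tolerance: int = 0
    max_rounds: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.neighborhood_size % 2 == 0 or self.neighborhood_size < 3:
            raise ValueError("neighborhood window must be odd and >= 3")
        for name in ("patch_decay", "expansion_coeff", "seed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.allowed is not None:
            a = np.asarray(self.allowed, dtype=int)
            if not np.all(np.diag(a) == 1):
                raise ValueError("transition mask diagonal must be all 1 (staying put is always allowed)")
            object.__setattr__(self, "allowed", a)


@dataclass(frozen=True)
class SimulationResult:
    """Final map plus the per-round allocation log."""

    final_map: ClassMap
    rounds: pd.DataFrame  # round, conversions, threshold, count_<code>...
    demanded: dict[int, int]
    achieved: dict[int, int]
    converged: bool


def neighborhood_effect(cmap: ClassMap, class_k: int, window: int = 3) -> np.ndarray:
    """Fraction of class-k cells in each cell's window, center excluded.

    Edge cells use the truncated window; nodata cells are excluded from both
    numerator and denominator. Cells whose window holds no valid neighbor
    get 0.
    """
    if window % 2 == 0:
        raise ValueError("neighborhood window must be odd")
    valid = cmap.valid_mask.astype(float)
    is_k = ((cmap.grid == class_k) & cmap.valid_mask).astype(float)
    kernel = np.ones((window, window))
    num = ndimage.correlate(is_k, kernel, mode="constant", cval=0.0) - is_k
    den = ndimage.correlate(valid, kernel, mode="constant", cval=0.0) - valid
    out = np.zeros(cmap.shape)
    np.divide(num, den, out=out, where=den > 0)
    return np.clip(out, 0.0, 1.0)


def _check_feasible(
    counts: np.ndarray, demand: np.ndarray, allowed: np.ndarray, codes: Sequence[int]
) -> None:
    over = counts > demand
    for j, code in enumerate(codes):
        if counts[j] < demand[j]:
            sources = [i for i in range(len(codes)) if over[i] and allowed[i, j]]
            if not sources:
                raise ValueError(
                    f"demand infeasible: class {code} needs {int(demand[j] - counts[j])} "
                    "more cells but no surplus class may convert into it"
                )


def simulate(
    map_t0: ClassMap,
    suitability: SuitabilityStack,
    demand: DemandVector,
    cfg: CAConfig,
) -> SimulationResult:
    """Allocate demanded class counts over the landscape by the patch CA.

    Deterministic for a fixed ``cfg.rng_seed``. Conversions forbidden by the
    transition mask never occur; total cell count is conserved every round;
    classes at or above demand never gain cells.
    """
    codes = list(map_t0.class_codes)
    k = len(codes)
    code_idx = {c: i for i, c in enumerate(codes)}
    allowed = cfg.allowed if cfg.allowed is not None else _default_allowed(k)
    weights = np.array(
        [cfg.domain_weights[c] if cfg.domain_weights else 1.0 for c in codes]
    )
    valid = map_t0.valid_mask
    n_valid = int(valid.sum())
    demand_cells = np.array([int(demand.cells.get(c, 0)) for c in codes])
    if demand_cells.sum() != n_valid:
        raise ValueError(
            f"demand total {demand_cells.sum()} != valid cell count {n_valid}"
        )
    grid = map_t0.grid.copy()
    counts = np.array([int(((grid == c) & valid).sum()) for c in codes])
    _check_feasible(counts, demand_cells, allowed, codes)

    # per-class development probability, flattened; nodata/missing -> 0
    pdev = np.zeros((k, grid.size))
    for c, i in code_idx.items():
        surf = suitability.probabilities.get(c)
        if surf is not None:
            pdev[i] = np.nan_to_num(surf.ravel(), nan=0.0)

    rng = np.random.default_rng(cfg.rng_seed)
    spontaneous_p = cfg.expansion_coeff * cfg.seed_fraction
    tol = cfg.demand_tolerance
    tau = None
    log_rows = []
    working = map_t0.with_grid(grid)  # shares the mutable grid array

    for rnd in range(1, cfg.max_rounds + 1):
        deficit = np.maximum(demand_cells - counts, 0)
        if deficit.max() <= tol and np.maximum(counts - demand_cells, 0).max() <= tol:
            break
        omega = np.stack(
            [neighborhood_effect(working, c, cfg.neighborhood_size).ravel() for c in codes]
        )
        if tau is None:
            # threshold starts at the 90th percentile of first-round OP values
            op_all = pdev * omega * weights[:, None]
            op_pos = op_all[:, valid.ravel()]
            op_pos = op_pos[op_pos > 0]
            tau = float(np.percentile(op_pos, 90)) if op_pos.size else 0.0
        over_mask = np.zeros_like(grid, dtype=bool)
        for c, i in code_idx.items():
            if counts[i] > demand_cells[i]:
                over_mask |= (grid == c) & valid
        cand_cells = np.flatnonzero(over_mask.ravel())
        cand_cells = rng.permutation(cand_cells)
        flat = grid.ravel()
        conversions = 0
        for cell in cand_cells:
            ci = code_idx[int(flat[cell])]
            if counts[ci] <= demand_cells[ci]:
                continue  # source class already released down to demand
            ops = np.zeros(k)
            for ti in range(k):
                if ti == ci or not allowed[ci, ti] or counts[ti] >= demand_cells[ti]:
                    continue
                om = omega[ti, cell]
                if om > 0:
                    ops[ti] = pdev[ti, cell] * om * weights[ti]
                elif rng.random() < spontaneous_p:
                    ops[ti] = pdev[ti, cell] * weights[ti] * rng.random()
            total = ops.sum()
            if total <= 0:
                continue
            ti = int(rng.choice(k, p=ops / total))
            if ops[ti] > tau:
                flat[cell] = codes[ti]
                counts[ci] -= 1
                counts[ti] += 1
                conversions += 1
        remaining = int(np.maximum(demand_cells - counts, 0).sum())
        log_rows.append(
            {
                "round": rnd,
                "conversions": conversions,
                "threshold": tau,
                **{f"count_{c}": int(counts[i]) for c, i in code_idx.items()},
            }
        )
        if conversions < remaining:
            tau *= cfg.patch_decay
    achieved = {c: int(counts[i]) for c, i in code_idx.items()}
    demanded = {c: int(demand_cells[i]) for c, i in code_idx.items()}
    converged = all(abs(achieved[c] - demanded[c]) <= tol for c in codes)
    if not converged:
        logger.warning(
            "CA hit max_rounds=%d with unmet demand: %s",
            cfg.max_rounds,
            {c: achieved[c] - demanded[c] for c in codes if achieved[c] != demanded[c]},
        )
    return SimulationResult(
        final_map=map_t0.with_grid(grid),
        rounds=pd.DataFrame(log_rows),
        demanded=demanded,
        achieved=achieved,
        converged=converged,
    )


def random_allocation_baseline(
    map_t0: ClassMap, demand: DemandVector, seed: int = 0
) -> ClassMap:
    """Demand-matched null model: meet the same class counts by converting
    uniformly random surplus cells, ignoring suitability and neighborhoods.

    The CA must beat this baseline's agreement with the truth for its
    spatial structure to mean anything.
    """
    codes = list(map_t0.class_codes)
    rng = np.random.default_rng(seed)
    grid = map_t0.grid.copy()
    flat = grid.ravel()
    valid = map_t0.valid_mask.ravel()
    counts = {c: int(((flat == c) & valid).sum()) for c in codes}
    surplus_cells = []
    for c in codes:
        extra = counts[c] - int(demand.cells.get(c, 0))
        if extra > 0:
            pool = np.flatnonzero((flat == c) & valid)
            surplus_cells.append(rng.choice(pool, size=extra, replace=False))
    if surplus_cells:
        cells = np.concatenate(surplus_cells)
        targets = np.concatenate(
            [
                np.full(int(demand.cells.get(c, 0)) - counts[c], c)
                for c in codes
                if demand.cells.get(c, 0) > counts[c]
            ]
        )
        if cells.size != targets.size:
            raise ValueError("demand total does not match the valid cell count")
        rng.shuffle(cells)
        flat[cells] = targets
    return map_t0.with_grid(grid)


@dataclass(frozen=True)
class ProjectionResult:
    """Artifacts of the full LEAS → Markov → CA → carbon pipeline."""

    suitability: SuitabilityStack
    domain_weights: DomainWeights
    markov_P: np.ndarray
    demands: dict[int, DemandVector]  # horizon year -> demand
    simulations: dict[int, SimulationResult]
    summaries: dict[int, AreaSummary]


def run_projection(
    map_t0: ClassMap,
    map_t1: ClassMap,
    drivers: DriverStack,
    cfg: CAConfig,
    horizons: Sequence[int],
    t1_year: int = 2020,
    step_span: int = 10,
    density: CarbonDensityTable | None = None,
    rf_settings: RFSettings = RFSettings(),
    sampling_rate: float | None = None,
    weight_basis: str = "expansion",
    given_weights: Mapping[int, float] | None = None,
    chain_from_map: bool = False,
    seed: int = 0,
) -> ProjectionResult:
    """End-to-end projection: expansion sampling → RF suitability → Markov
    demand → CA allocation (→ carbon storage when a density table is given).

    Each horizon year must be a whole number of ``step_span`` years past
    ``t1_year``. Later horizons start from the previously simulated map;
    their demand comes from chained Markov vectors by default
    (``chain_from_map=True`` re-estimates demand from each simulated map
    instead).
    """
    _require_aligned(map_t0, map_t1, drivers)
    rate = rf_settings.sampling_rate if sampling_rate is None else sampling_rate
    samples = {
        c: extract_expansion(map_t0, map_t1, c, sampling_rate=rate, seed=seed)
        for c in map_t0.class_codes
    }
    valid = map_t0.valid_mask & map_t1.valid_mask
    suitability = fit_suitability(samples, drivers, valid, rf_settings, seed=seed)
    counts = transition_matrix(map_t0, map_t1)
    dw = (
        expansion_share_weights(counts, basis="given", given=given_weights)
        if weight_basis == "given"
        else expansion_share_weights(counts)
    )
    model = estimate_markov(counts, step_span=step_span)
    areas_t1 = map_t1.class_areas()
    demands: dict[int, DemandVector] = {}
    simulations: dict[int, SimulationResult] = {}
    summaries: dict[int, AreaSummary] = {}
    current = map_t1
    for h, year in enumerate(sorted(horizons)):
        span = year - t1_year
        if span <= 0 or span % step_span:
            raise ValueError(
                f"horizon {year} is not a positive multiple of {step_span} years past {t1_year}"
            )
        if chain_from_map:
            base = current.class_areas()
            steps = (year - t1_year) // step_span - (
                (sorted(horizons)[h - 1] - t1_year) // step_span if h else 0
            )
            demand = project_demand(base, model, steps, cell_area=map_t1.cell_area)
        else:
            demand = project_demand(
                areas_t1, model, span // step_span, cell_area=map_t1.cell_area
            )
        run_cfg = CAConfig(
            neighborhood_size=cfg.neighborhood_size,
            patch_decay=cfg.patch_decay,
            expansion_coeff=cfg.expansion_coeff,
            seed_fraction=cfg.seed_fraction,
            allowed=cfg.allowed,
            domain_weights=dw if cfg.domain_weights is None else cfg.domain_weights,
            demand_tolerance=cfg.demand_tolerance,
            max_rounds=cfg.max_rounds,
            rng_seed=cfg.rng_seed + h,
        )
        result = simulate(current, suitability, demand, run_cfg)
        demands[year] = demand
        simulations[year] = result
        if density is not None:
            summaries[year] = carbon_storage(result.final_map, density)
        current = result.final_map
    return ProjectionResult(
        suitability=suitability,
        domain_weights=dw,
        markov_P=model.P,
        demands=demands,
        simulations=simulations,
        summaries=summaries,
    )
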