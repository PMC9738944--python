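"""Land Expansion Analysis Strategy (LEAS): learn where each class expands.

Between two observed epochs, the cells newly gained by class k (absent at
t0, class k at t1) are positive examples and cells never of class k are
negatives. A random forest per class, fed the driver stack at sampled cells,
yields a development-probability surface P_dev_k over the landscape and
impurity-based driver contributions. A per-class neighborhood ("domain")
weight — the class's share of total observed expansion area — scales its
competitive strength in the cellular automaton downstream.

Defaults follow common patch-generating simulation practice: 20 trees,
mtry 9 when at least 9 drivers are available (otherwise two-thirds of the
driver count), random sampling of cells at rate 0.01, and probabilities
taken as the forest's class-vote fraction without recalibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core_raster import ClassMap, DriverStack, _require_aligned
from .transition_analysis import TransitionCountMatrix

logger = logging.getLogger(__name__)

#: Published Guizhou domain-weight vector (reproduced verbatim via basis="given").
GUIZHOU_DOMAIN_WEIGHTS: dict[int, float] = {
    1: 0.1470,  # farmland
    2: 0.1841,  # forest
    3: 0.0774,  # grassland
    4: 0.0055,  # aquatic
    5: 0.0117,  # settlement
    6: 0.0001,  # other
}

MIN_SAMPLES_PER_SIDE = 20


@dataclass(frozen=True)
class RFSettings:
    """Random-forest hyper-parameters for the suitability fit."""

    n_trees: int = 20
    mtry: int = 9
    sampling_rate: float = 0.01

    def effective_mtry(self, n_drivers: int) -> int:
        if n_drivers >= self.mtry:
            return self.mtry
        return max(1, (2 * n_drivers) // 3)


@dataclass(frozen=True)
class ExpansionSample:
    """Sampled positive (newly class-k) and negative (never class-k) cells."""

    class_code: int
    positives: np.ndarray  # flat cell indices, after subsampling
    negatives: np.ndarray
    n_positive_full: int  # expansion cell count before subsampling
    warning: str = ""

    @property
    def empty(self) -> bool:
        return self.positives.size == 0


@dataclass(frozen=True)
class SuitabilityStack:
    """Per-class development-probability surfaces and driver contributions."""

    probabilities: dict[int, np.ndarray]  # class -> 2-D surface in [0, 1]
    contributions: dict[int, dict[str, float]]  # class -> driver -> share (sums to 1)
    rf_settings: RFSettings
    skipped: tuple[int, ...] = ()

    def surface(self, class_code: int) -> np.ndarray:
        return self.probabilities[class_code]


@dataclass(frozen=True)
class DomainWeights:
    """Per-class CA competitive weights, stored as given (not renormalised)."""

    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("domain weights must be non-negative")

    def __getitem__(self, code: int) -> float:
        return self.weights[code]


def extract_expansion(
    map_t0: ClassMap,
    map_t1: ClassMap,
    class_k: int,
    sampling_rate: float = 0.01,
    seed: int = 0,
) -> ExpansionSample:
    """Positive/negative cell sample for class k's expansion between epochs.

    Positives are cells not of class k at t0 that became class k at t1;
    negatives are cells of class k at neither epoch. Both sides are
    independently subsampled at ``sampling_rate`` with a seeded RNG; with
    rate 1.0 the full sets are returned. Subsamples at lower rates are
    drawn from a seeded permutation, so they nest within higher-rate draws.
    """
    _require_aligned(map_t0, map_t1)
    valid = map_t0.valid_mask & map_t1.valid_mask
    g0, g1 = map_t0.grid.ravel(), map_t1.grid.ravel()
    v = valid.ravel()
    pos = np.flatnonzero(v & (g0 != class_k) & (g1 == class_k))
    neg = np.flatnonzero(v & (g0 != class_k) & (g1 != class_k))
    rng = np.random.default_rng(seed)

    def _take(idx: np.ndarray, rate: float) -> np.ndarray:
        n = max(1, int(round(idx.size * rate))) if idx.size else 0
        perm = rng.permutation(idx.size)
        return idx[perm[:n]]

    pos_s = _take(pos, sampling_rate)
    neg_s = _take(neg, sampling_rate)
    warning = ""
    if pos.size == 0:
        warning = f"class {class_k}: no expansion cells between epochs"
        logger.warning(warning)
    return ExpansionSample(
        class_code=class_k,
        positives=pos_s,
        negatives=neg_s,
        n_positive_full=int(pos.size),
        warning=warning,
    )


def fit_suitability(
    samples: Mapping[int, ExpansionSample],
    drivers: DriverStack,
    valid_mask: np.ndarray,
    rf_settings: RFSettings = RFSettings(),
    seed: int = 0,
) -> SuitabilityStack:
    """Fit one random forest per class and predict its suitability surface.

    Classes with fewer than 20 positives or negatives are skipped: they get a
    uniform 0.5 surface, equal driver contributions, and a logged warning.
    Driver layers are canonicalised to name order before fitting so results
    do not depend on stack ordering. Negatives are balanced 1:1 against
    positives (seeded draw) before fitting.
    """
    order = np.argsort(drivers.names, kind="stable")
    names = [drivers.names[i] for i in order]
    shape = drivers.shape
    X_all = drivers.feature_matrix()[:, order]
    if not np.isfinite(X_all[valid_mask.ravel()]).all():
        raise ValueError("driver features must be finite over valid cells")
    probabilities: dict[int, np.ndarray] = {}
    contributions: dict[int, dict[str, float]] = {}
    skipped: list[int] = []
    for class_k in sorted(samples):
        s = samples[class_k]
        rng = np.random.default_rng((seed, class_k))
        neg = s.negatives
        if s.positives.size and neg.size > s.positives.size:
            neg = neg[rng.choice(neg.size, size=s.positives.size, replace=False)]
        if s.positives.size < MIN_SAMPLES_PER_SIDE or neg.size < MIN_SAMPLES_PER_SIDE:
            logger.warning(
                "class %s: %d positives / %d negatives below the minimum of %d; "
                "using a uniform 0.5 surface",
                class_k, s.positives.size, neg.size, MIN_SAMPLES_PER_SIDE,
            )
            surf = np.full(shape, 0.5)
            surf[~valid_mask] = np.nan
            probabilities[class_k] = surf
            contributions[class_k] = {n: 1.0 / len(names) for n in names}
            skipped.append(class_k)
            continue
        idx = np.concatenate([s.positives, neg])
        y = np.concatenate([np.ones(s.positives.size), np.zeros(neg.size)])
        rf = RandomForestClassifier(
            n_estimators=rf_settings.n_trees,
            max_features=rf_settings.effective_mtry(len(names)),
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(X_all[idx], y)
        proba = rf.predict_proba(X_all)[:, list(rf.classes_).index(1.0)]
        surf = proba.reshape(shape).astype(float)
        surf[~valid_mask] = np.nan
        probabilities[class_k] = surf
        imp = rf.feature_importances_
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
        contributions[class_k] = dict(zip(names, imp.tolist()))
    return SuitabilityStack(
        probabilities=probabilities,
        contributions=contributions,
        rf_settings=rf_settings,
        skipped=tuple(skipped),
    )


def expansion_share_weights(
    counts: TransitionCountMatrix,
    basis: str = "expansion",
    given: Mapping[int, float] | None = None,
) -> DomainWeights:
    """Domain weights from each class's share of total observed expansion.

    basis="expansion": w_k = (column sum k − diagonal k) / total expansion,
    summing to 1. basis="given": pass a user-supplied vector through
    verbatim (e.g. a published calibration).
    """
    if basis == "given":
        if given is None:
            raise ValueError('basis="given" requires a weights mapping')
        return DomainWeights(weights={int(c): float(w) for c, w in given.items()})
    if basis != "expansion":
        raise ValueError(f"unknown basis {basis!r}")
    gained = counts.matrix.sum(axis=0) - np.diag(counts.matrix)
    total = gained.sum()
    if total <= 0:
        raise ValueError("zero total expansion; domain weights undefined")
    return DomainWeights(
        weights=dict(zip(counts.class_codes, (gained / total).tolist()))
    )
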