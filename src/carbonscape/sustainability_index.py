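"""Entropy-weight multi-criteria sustainability scoring of regions.

Given a regions × indicators table with per-indicator orientations, the
method (1) min–max standardises each indicator to [0, 1] respecting its
orientation, (2) converts each column to proportions R_ij, (3) computes the
normalised Shannon entropy S_j = −(1/ln n) Σ_i R_ij ln R_ij, (4) weights
indicators by their information content W_j = (1 − S_j) / Σ_j (1 − S_j) —
dispersed indicators discriminate between regions and earn more weight —
and (5) scores each region as the weighted sum of its standardised values.

Two deliberate formula variants are preserved. Some published presentations
swap the positive/negative standardisation maps and/or compute the final
score on raw rather than standardised values; ``form="as_printed"`` /
``basis="as_printed"`` reproduce those literal equations, while the defaults
follow the conventional (scale-free, orientation-consistent) method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "+"
NEGATIVE = "-"


@dataclass(frozen=True)
class IndicatorTable:
    """Regions × indicators with an orientation per indicator."""

    values: pd.DataFrame  # index: region, columns: indicators
    orientations: dict[str, str]  # indicator -> "+" (larger is better) / "-"

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("entropy weighting needs at least 2 regions (k = 1/ln n)")
        if self.values.isna().any().any():
            raise ValueError("indicator table has missing values")
        missing = [c for c in self.values.columns if c not in self.orientations]
        if missing:
            raise ValueError(f"no orientation given for indicators: {missing}")
        bad = {k: v for k, v in self.orientations.items() if v not in (POSITIVE, NEGATIVE)}
        if bad:
            raise ValueError(f"orientations must be '+' or '-': {bad}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndicatorTable":
        """Read a CSV whose first column is the region and whose first data
        row (region label ``orientation``) carries the +/- orientations."""
        raw = pd.read_csv(path, index_col=0)
        if "orientation" not in raw.index:
            raise ValueError("indicator CSV needs an 'orientation' row of +/- flags")
        orient = raw.loc["orientation"].astype(str).str.strip().to_dict()
        values = raw.drop(index="orientation").astype(float)
        return cls(values=values, orientations=orient)

    def to_csv(self, path: str | Path) -> None:
        orient_row = pd.DataFrame(
            [self.orientations], index=pd.Index(["orientation"], name=self.values.index.name)
        )
        pd.concat([orient_row, self.values]).to_csv(path)


def standardize(table: IndicatorTable, form: str = "conventional") -> pd.DataFrame:
    """Orientation-aware min–max standardisation to [0, 1].

    form="conventional": positive → (P−Pmin)/(Pmax−Pmin), negative →
    (Pmax−P)/(Pmax−Pmin). form="as_printed" applies those maps with the
    orientations swapped (the literal published equations). Constant columns
    carry no information; they are set to 0.5 with a logged warning.
    """
    if form not in ("conventional", "as_printed"):
        raise ValueError(f"unknown standardisation form {form!r}")
    out = {}
    for col in table.values.columns:
        p = table.values[col].astype(float)
        pmin, pmax = p.min(), p.max()
        positive = table.orientations[col] == POSITIVE
        if form == "as_printed":
            positive = not positive
        if pmax == pmin:
            logger.warning("indicator %r is constant; standardised to 0.5", col)
            out[col] = pd.Series(0.5, index=p.index)
            continue
        if positive:
            out[col] = (p - pmin) / (pmax - pmin)
        else:
            out[col] = (pmax - p) / (pmax - pmin)
    return pd.DataFrame(out, index=table.values.index)


def entropy(standardized: pd.DataFrame) -> pd.Series:
    """Normalised Shannon entropy S_j per indicator, in [0, 1].

    R_ij = S_ij / Σ_i S_ij; S_j = −(1/ln n) Σ_i R_ij ln R_ij with
    0·ln 0 := 0. An all-zero column has no defined proportions and is
    assigned S_j = 1 (maximal uncertainty, zero weight), logged.
    """
    n = len(standardized)
    if n < 2:
        raise ValueError("entropy needs at least 2 regions")
    k = 1.0 / np.log(n)
    out = {}
    for col in standardized.columns:
        s = standardized[col].to_numpy(dtype=float)
        total = s.sum()
        if total <= 0:
            logger.warning("indicator %r is all-zero after standardisation; entropy set to 1", col)
            out[col] = 1.0
            continue
        r = s / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(r > 0, r * np.log(r), 0.0)
        out[col] = float(np.clip(-k * terms.sum(), 0.0, 1.0))
    return pd.Series(out, name="entropy")


def weights(entropies: pd.Series) -> pd.Series:
    """Entropy weights W_j = (1 − S_j) / Σ_j (1 − S_j), summing to 1.

    If every indicator has maximal entropy (no information anywhere), equal
    weights are returned with a warning.
    """
    info = 1.0 - entropies
    total = info.sum()
    if total <= 0:
        logger.warning("all indicators have maximal entropy; falling back to equal weights")
        return pd.Series(1.0 / len(entropies), index=entropies.index, name="weight")
    return (info / total).rename("weight")


def score(
    standardized: pd.DataFrame,
    w: pd.Series,
    basis: str = "standardized",
    raw: pd.DataFrame | None = None,
) -> pd.Series:
    """Composite score per region: E_i = Σ_j S_ij W_j (default basis).

    basis="as_printed" uses the raw indicator values instead of the
    standardised ones (scale-dependent; retained for comparability with
    published presentations; requires ``raw``).
    """
    if basis == "standardized":
        mat = standardized
    elif basis == "as_printed":
        if raw is None:
            raise ValueError('basis="as_printed" requires the raw value table')
        mat = raw
    else:
        raise ValueError(f"unknown score basis {basis!r}")
    w = w.reindex(mat.columns)
    if w.isna().any():
        raise ValueError("weights do not cover all indicators")
    return (mat * w).sum(axis=1).rename("score")


def assess(
    table: IndicatorTable,
    form: str = "conventional",
    basis: str = "standardized",
) -> tuple[pd.Series, pd.Series]:
    """Full pipeline: standardise → entropy → weights → scores.

    Returns (weights, scores).
    """
    std = standardize(table, form=form)
    w = weights(entropy(std))
    e = score(std, w, basis=basis, raw=table.values)
    return w, e


def quantile_bands(scores: pd.Series, n_bands: int = 4) -> pd.Series:
    """Classify scores into quantile bands (1 = lowest) for mapping."""
    ranks = scores.rank(method="first")
    return pd.Series(
        pd.qcut(ranks, n_bands, labels=range(1, n_bands + 1)).astype(int),
        index=scores.index,
        name="band",
    )
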