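"""Quadrat correlation matrix (QCM): co-occurrence screening of cell-type pairs.

The window is tiled into square quadrats (default edge 100 µm) and, per
unordered pair of cell types, the Pearson correlation of the two quadrat
count vectors is compared against a null distribution obtained by randomly
shuffling cell-type labels over the fixed positions. Only labels move, so
each type's total count and the underlying spatial structure of the point
set are preserved — correlations that arise purely from the shared spatial
arrangement are absorbed into the null. Pairs with a positive coefficient
and BH-adjusted q below the screening alpha pass on to cross-PCF analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellPattern
from .stats import bh_fdr

__all__ = ["QCMResult", "quadrat_counts", "qcm_screen"]


@dataclass
class QCMResult:
    """Screening outcome for one ROI: one row per unordered type pair."""

    roi_id: str
    condition: str
    quadrat_size: float
    n_shuffles: int
    seed: int
    pass_alpha: float
    table: pd.DataFrame = field(repr=False)

    def passing_pairs(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["pass"]]
        return list(zip(sub["type_a"], sub["type_b"]))

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "condition", self.condition)
        df.insert(0, "roi_id", self.roi_id)
        return df


def quadrat_counts(
    pattern: CellPattern, quadrat_size: float, types: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Counts per quadrat per type; quadrats tile from the origin, half-open bins.

    Returns (counts matrix of shape (n_quadrats, n_types), type order).
    Edge quadrats may be partial; every cell lands in exactly one quadrat via
    floor(x/q), floor(y/q).
    """
    if quadrat_size <= 0:
        raise ValueError("quadrat_size must be positive")
    if types is None:
        types = pattern.types
    nx = int(np.ceil(pattern.window.width / quadrat_size))
    ny = int(np.ceil(pattern.window.height / quadrat_size))
    qx = np.floor(pattern.cells["x"].to_numpy() / quadrat_size).astype(int)
    qy = np.floor(pattern.cells["y"].to_numpy() / quadrat_size).astype(int)
    quadrat = qy * nx + qx
    tindex = {t: i for i, t in enumerate(types)}
    tcode = pattern.cells["cell_type"].map(tindex).to_numpy()
    counts = np.zeros((nx * ny, len(types)), dtype=np.int64)
    np.add.at(counts, (quadrat, tcode), 1)
    return counts, list(types)


def _pair_correlations(counts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the count columns; NaN on zero variance."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(counts.T.astype(float))
    return np.atleast_2d(c)


def qcm_screen(
    pattern: CellPattern,
    quadrat_size: float = 100.0,
    n_shuffles: int = 1000,
    seed: int = 0,
    pass_alpha: float = 0.05,
    types: list[str] | None = None,
) -> QCMResult:
    """Label-shuffle screening of all unordered cell-type pairs in one ROI.

    Two-sided empirical p with add-one smoothing,
    p = (1 + #{|null| ≥ |obs|}) / (n_shuffles + 1), BH-adjusted across pairs;
    pass = positive coefficient ∧ q < pass_alpha. Types absent from the ROI
    yield undefined coefficients and never pass.
    """
    if types is None:
        types = pattern.types
    if len(types) < 2:
        raise ValueError("need at least 2 cell types to screen")
    counts, types = quadrat_counts(pattern, quadrat_size, types=types)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 quadrats")
    n_types = len(types)
    obs = _pair_correlations(counts)

    # null: permute labels over fixed positions => permute type codes over
    # the fixed per-cell quadrat index
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(pattern.window.width / quadrat_size))
    qx = np.floor(pattern.cells["x"].to_numpy() / quadrat_size).astype(int)
    qy = np.floor(pattern.cells["y"].to_numpy() / quadrat_size).astype(int)
    quadrat = qy * nx + qx
    tindex = {t: i for i, t in enumerate(types)}
    tcode = pattern.cells["cell_type"].map(tindex).to_numpy()

    n_quadrats = counts.shape[0]
    exceed = np.zeros((n_types, n_types), dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(n_shuffles):
        perm = rng.permutation(tcode)
        null_counts = np.zeros((n_quadrats, n_types), dtype=np.int64)
        np.add.at(null_counts, (quadrat, perm), 1)
        null_corr = np.abs(_pair_correlations(null_counts))
        with np.errstate(invalid="ignore"):
            exceed += (null_corr >= abs_obs).astype(np.int64)

    rows = []
    pvals = []
    present = {t: pattern.count(t) > 0 for t in types}
    for i, j in itertools.combinations(range(n_types), 2):
        a, b = types[i], types[j]
        coef = obs[i, j]
        if not (present[a] and present[b]) or np.isnan(coef):
            rows.append((a, b, np.nan, np.nan))
            pvals.append(np.nan)
        else:
            p = (1 + exceed[i, j]) / (n_shuffles + 1)
            rows.append((a, b, float(coef), float(p)))
            pvals.append(float(p))
    qvals = bh_fdr(pvals)
    table = pd.DataFrame(rows, columns=["type_a", "type_b", "coefficient", "p"])
    table["q"] = qvals
    table["pass"] = (table["coefficient"] > 0) & (table["q"] < pass_alpha)
    table["pass"] = table["pass"].fillna(False)
    return QCMResult(
        roi_id=pattern.roi_id,
        condition=pattern.condition,
        quadrat_size=quadrat_size,
        n_shuffles=n_shuffles,
        seed=seed,
        pass_alpha=pass_alpha,
        table=table,
    )
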