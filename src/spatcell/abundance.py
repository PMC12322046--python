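"""Per-ROI cell densities and the cross-type abundance correlation screen.

Densities are reported in cells/mm² of tissue. Within each condition the
screen correlates the per-ROI densities of every unordered pair of cell
types (Pearson r, two-sided t-based p with df = n − 2) and applies BH FDR
across all pairs of the condition — a purely compositional view of which
cell types rise and fall together across regions, independent of any
within-ROI spatial structure.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .data import CellPattern
from .stats import bh_fdr, pearson_with_p

__all__ = ["densities", "abundance_correlation"]


def densities(patterns: list[CellPattern], types: list[str] | None = None) -> pd.DataFrame:
    """Tidy table (roi_id, condition, cell_type, count, density) zero-filled."""
    if types is None:
        types = sorted({t for p in patterns for t in p.types})
    rows = []
    for p in patterns:
        tc = p.type_counts(types=types)
        dens = tc.densities
        for t in types:
            rows.append(
                {
                    "roi_id": p.roi_id,
                    "condition": p.condition,
                    "cell_type": t,
                    "count": tc.counts[t],
                    "density": dens[t],
                }
            )
    return pd.DataFrame(rows)


def abundance_correlation(
    table: pd.DataFrame, condition: str, min_rois: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlation of densities across a condition's ROIs.

    Pairs in conditions with fewer than ``min_rois`` ROIs, or with a
    zero-variance density vector, are flagged ``evaluated=False`` with NaN
    statistics. q-values are BH across the condition's evaluated pairs.
    """
    sub = table[table["condition"] == condition]
    wide = sub.pivot_table(index="roi_id", columns="cell_type", values="density")
    types = sorted(wide.columns)
    n_rois = len(wide)
    rows = []
    for a, b in itertools.combinations(types, 2):
        if n_rois < min_rois:
            r = p = np.nan
            evaluated = False
        else:
            r, p = pearson_with_p(wide[a], wide[b])
            evaluated = not np.isnan(r)
        rows.append(
            {
                "condition": condition,
                "type_a": a,
                "type_b": b,
                "n_rois": n_rois,
                "r": r,
                "p": p,
                "evaluated": evaluated,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"]) if len(df) else []
    return df
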