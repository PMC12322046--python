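"""Three-type neighbourhood correlation function (NCF).

For three cell types C1, C2, C3 every cross-type triplet defines a
"neighbourhood": the minimum enclosing circle (MEC) of the three centroids,
with radius R. The NCF at radius r compares the number of neighbourhoods
whose radius falls in [r, r + dr) with the number expected if all three
types were distributed under complete spatial randomness in the same window:

    NCF(r) = #{triplets: R ∈ [r, r+dr)} / (N1·N2·N3 · p3(r))

where p3(r), the probability that three uniform points have MEC radius in
the bin, is estimated by Monte-Carlo sampling (M triples). Uncertainty is
assessed with a label-shuffle bootstrap: positions stay fixed while the
labels of the participating cells are permuted, the MEC histogram is
recomputed per replicate, and the 5th/95th percentiles per bin form the
envelope. NCF ≈ 1 under CSR; values above the envelope at small r indicate
three-way clustering at that length scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import CellPattern, Window
from .geometry import mec_radius_from_distances

__all__ = ["NCFParams", "NCFResult", "estimate_p3", "ncf", "ncf_condition"]


@dataclass(frozen=True)
class NCFParams:
    """Binning, Monte-Carlo and bootstrap settings for the NCF.

    ``M`` is the number of CSR triples used to estimate p3 (the default 10^7
    follows the reference estimation; reduce for quick exploration).
    ``subsample_cap`` bounds the number of triplets enumerated exactly; above
    it a seeded uniform subsample of that size is used and the normalisation
    rescales to the sampled count.
    """

    bin_width: float = 5.0
    max_radius: float = 150.0
    M: int = 10_000_000
    n_boot: int = 1000
    seed: int = 0
    subsample_cap: int = 5_000_000
    shuffle_universe: str = "triplet_types"  # or "all_cells"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.M < 10_000:
            raise ValueError("M must be at least 10^4")
        if self.shuffle_universe not in ("triplet_types", "all_cells"):
            raise ValueError("shuffle_universe must be 'triplet_types' or 'all_cells'")

    @property
    def bin_edges(self) -> np.ndarray:
        n = int(np.ceil(self.max_radius / self.bin_width))
        return np.arange(n + 1) * self.bin_width


@dataclass
class NCFResult:
    """Binned NCF with Monte-Carlo reference and bootstrap envelope."""

    roi_id: str
    condition: str
    types: tuple[str, str, str]
    params: NCFParams
    bin_edges: np.ndarray = field(repr=False, default=None)
    hist: np.ndarray = field(repr=False, default=None)  # observed MEC counts per bin
    p3: np.ndarray = field(repr=False, default=None)
    p3_overflow: float = 0.0
    n_triplets: int = 0  # triplets actually enumerated/sampled
    counts: tuple[int, int, int] = (0, 0, 0)  # N1, N2, N3
    boot_hists: np.ndarray = field(repr=False, default=None)  # (n_boot, n_bins)
    defined: bool = True

    @property
    def bin_lefts(self) -> np.ndarray:
        return self.bin_edges[:-1]

    def _normalise(self, hist) -> np.ndarray:
        denom = self.n_triplets * self.p3
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, hist / np.where(denom > 0, denom, 1.0), np.nan)
        return out

    @property
    def ncf(self) -> np.ndarray:
        """NCF per bin; NaN where the CSR reference has no mass."""
        return self._normalise(self.hist)

    @property
    def envelope(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(median, 5th pct, 95th pct) of the bootstrap, on the NCF scale."""
        med, lo, hi = self.count_envelope
        return self._normalise(med), self._normalise(lo), self._normalise(hi)

    @property
    def count_envelope(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(median, 5th, 95th) of the bootstrap MEC histograms (count scale).

        Percentiles are order statistics (floor for the 5th, ceiling for the
        95th): histogram counts are integers and interpolating between order
        statistics would make the envelope spuriously narrow for discrete
        counts.
        """
        return (
            np.median(self.boot_hists, axis=0),
            np.percentile(self.boot_hists, 5, axis=0, method="lower"),
            np.percentile(self.boot_hists, 95, axis=0, method="higher"),
        )

    def at(self, r: float) -> float:
        """NCF of the bin containing radius r."""
        idx = int(np.searchsorted(self.bin_edges, r, side="right")) - 1
        if idx < 0 or idx >= len(self.hist):
            raise ValueError(f"radius {r} outside the binned range")
        return float(self.ncf[idx])

    def to_frame(self) -> pd.DataFrame:
        med, lo, hi = self.envelope
        return pd.DataFrame(
            {
                "condition": self.condition,
                "roi_id": self.roi_id,
                "c1": self.types[0],
                "c2": self.types[1],
                "c3": self.types[2],
                "r_bin": self.bin_lefts,
                "ncf": self.ncf,
                "boot_median": med,
                "env_low": lo,
                "env_high": hi,
                "n_mec": self.hist,
                "p3": self.p3,
            }
        )


# ---------------------------------------------------------------------------
# p3 Monte-Carlo reference (cached per window geometry / bins / M / seed)

@lru_cache(maxsize=32)
def _estimate_p3_cached(width, height, bin_width, max_radius, M, seed):
    edges = NCFParams(bin_width=bin_width, max_radius=max_radius, M=max(M, 10_000)).bin_edges
    rng = np.random.default_rng(seed)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    overflow = 0
    chunk = 1_000_000
    done = 0
    while done < M:
        n = min(chunk, M - done)
        pts = rng.uniform(0, [width, height], size=(n, 3, 2))
        d12 = np.hypot(pts[:, 0, 0] - pts[:, 1, 0], pts[:, 0, 1] - pts[:, 1, 1])
        d13 = np.hypot(pts[:, 0, 0] - pts[:, 2, 0], pts[:, 0, 1] - pts[:, 2, 1])
        d23 = np.hypot(pts[:, 1, 0] - pts[:, 2, 0], pts[:, 1, 1] - pts[:, 2, 1])
        r = mec_radius_from_distances(d12, d13, d23)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        overflow += int(n - h.sum())
        done += n
    return counts / M, overflow / M


def estimate_p3(
    window: Window, bin_width: float = 5.0, max_radius: float = 150.0,
    M: int = 100_000, seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo estimate of p3 per bin, plus the overflow mass beyond max_radius.

    Draws M independent uniform triples in the window and bins their MEC
    radii; the overflow bucket keeps the total at exactly 1.
    """
    if M < 10_000:
        raise ValueError("M must be at least 10^4")
    return _estimate_p3_cached(
        float(window.width), float(window.height), float(bin_width),
        float(max_radius), int(M), int(seed),
    )


# ---------------------------------------------------------------------------
# MEC histograms over cross-type triplets

def _mec_hist_full(D12, D13, D23, edges, chunk_rows=64):
    """Histogram of MEC radii over the full N1×N2×N3 triplet grid."""
    n1 = D12.shape[0]
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for i0 in range(0, n1, chunk_rows):
        i1 = min(i0 + chunk_rows, n1)
        a = D12[i0:i1, :, None]
        b = D13[i0:i1, None, :]
        c = D23[None, :, :]
        r = mec_radius_from_distances(a, b, c)
        h, _ = np.histogram(r, bins=edges)
        counts += h
    return counts


def _mec_hist_sampled(P1, P2, P3, edges, cap, rng):
    i = rng.integers(0, len(P1), cap)
    j = rng.integers(0, len(P2), cap)
    k = rng.integers(0, len(P3), cap)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    chunk = 2_000_000
    for s in range(0, cap, chunk):
        e = min(s + chunk, cap)
        a = np.hypot(*(P1[i[s:e]] - P2[j[s:e]]).T)
        b = np.hypot(*(P1[i[s:e]] - P3[k[s:e]]).T)
        c = np.hypot(*(P2[j[s:e]] - P3[k[s:e]]).T)
        r = mec_radius_from_distances(a, b, c)
        h, _ = np.histogram(r, bins=edges)
        counts += h
    return counts


def _triplet_hist(P1, P2, P3, edges, cap, rng):
    """(histogram, n_triplets_used) for one labelled configuration."""
    n_total = len(P1) * len(P2) * len(P3)
    if n_total == 0:
        return np.zeros(len(edges) - 1, dtype=np.int64), 0
    if n_total <= cap:
        D12 = cdist(P1, P2)
        D13 = cdist(P1, P3)
        D23 = cdist(P2, P3)
        return _mec_hist_full(D12, D13, D23, edges), n_total
    return _mec_hist_sampled(P1, P2, P3, edges, cap, rng), cap


def ncf(
    pattern: CellPattern,
    c1: str,
    c2: str,
    c3: str,
    params: NCFParams = NCFParams(),
    compute_bootstrap: bool = True,
) -> NCFResult:
    """NCF of one ROI for the type triplet (c1, c2, c3) with bootstrap envelope.

    The bootstrap permutes cell-type labels over the pooled positions of the
    participating cells (``params.shuffle_universe`` widens this to all
    cells), holding every position and all three counts fixed, and recomputes
    the MEC histogram n_boot times. The result is symmetric in the three type
    arguments.
    """
    edges = params.bin_edges
    counts3 = (pattern.count(c1), pattern.count(c2), pattern.count(c3))
    base = NCFResult(
        roi_id=pattern.roi_id,
        condition=pattern.condition,
        types=(c1, c2, c3),
        params=params,
        bin_edges=edges,
        counts=counts3,
    )
    if min(counts3) == 0:
        base.defined = False
        base.hist = np.zeros(len(edges) - 1, dtype=np.int64)
        base.p3 = np.full(len(edges) - 1, np.nan)
        base.boot_hists = np.zeros((0, len(edges) - 1))
        return base

    rng = np.random.default_rng(params.seed)
    P1, P2, P3 = pattern.points(c1), pattern.points(c2), pattern.points(c3)
    hist, n_used = _triplet_hist(P1, P2, P3, edges, params.subsample_cap, rng)
    p3, p3_over = estimate_p3(
        pattern.window, params.bin_width, params.max_radius, params.M, params.seed
    )
    base.hist = hist
    base.p3 = p3
    base.p3_overflow = p3_over
    base.n_triplets = n_used

    if compute_bootstrap and params.n_boot > 0:
        if params.shuffle_universe == "all_cells":
            pool = pattern.points()
        else:
            pool = np.vstack([P1, P2, P3])
        n1, n2, n3 = counts3
        boot = np.zeros((params.n_boot, len(edges) - 1), dtype=np.int64)
        for b in range(params.n_boot):
            idx = rng.permutation(len(pool))
            Q1 = pool[idx[:n1]]
            Q2 = pool[idx[n1 : n1 + n2]]
            Q3 = pool[idx[n1 + n2 : n1 + n2 + n3]]
            h, _ = _triplet_hist(Q1, Q2, Q3, edges, params.subsample_cap, rng)
            boot[b] = h
        base.boot_hists = boot
    else:
        base.boot_hists = np.zeros((0, len(edges) - 1))
    return base


def ncf_condition(results: list[NCFResult]) -> NCFResult:
    """Pool per-ROI NCFs for one condition.

    Observed MEC radii are concatenated (histograms summed); per replicate
    index the ROI bootstrap histograms are summed, giving n_boot pooled
    histograms; p3 is the per-ROI estimate weighted by each ROI's triplet
    count, so the pooled NCF is total_hist(r) / Σ_i n_i p3_i(r).
    """
    defined = [r for r in results if r.defined]
    if not defined:
        raise ValueError("no defined per-ROI NCF results to pool")
    first = defined[0]
    for r in defined[1:]:
        if not np.array_equal(r.bin_edges, first.bin_edges):
            raise ValueError("per-ROI results use different bins")
        if set(r.types) != set(first.types):
            raise ValueError("cannot pool different type triplets")
        if r.boot_hists.shape[0] != first.boot_hists.shape[0]:
            raise ValueError("per-ROI results use different n_boot")
    total_hist = np.sum([r.hist for r in defined], axis=0)
    boot = np.sum([r.boot_hists for r in defined], axis=0)
    n_total = sum(r.n_triplets for r in defined)
    # triplet-count weighted p3: pooled denominator Σ n_i p3_i = n_total · p3_pooled
    p3_pooled = np.sum([r.n_triplets * r.p3 for r in defined], axis=0) / n_total
    over = sum(r.n_triplets * r.p3_overflow for r in defined) / n_total
    return NCFResult(
        roi_id="pooled",
        condition=first.condition,
        types=first.types,
        params=first.params,
        bin_edges=first.bin_edges,
        hist=total_hist,
        p3=p3_pooled,
        p3_overflow=over,
        n_triplets=n_total,
        counts=tuple(np.sum([r.counts for r in defined], axis=0)),
        boot_hists=boot,
    )
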