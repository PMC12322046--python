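"""Cross-pair correlation function g(r) and the topographical correlation map.

The cross-PCF between cell types A and B measures how frequently B cells are
found in an annulus [r, r + dr) centred on A cells, relative to the
expectation under complete spatial randomness (CSR) at the observed B
intensity. With anchor cells a at distance-dependent clipped annulus areas
W_a(r) (the exact annulus∩window area, the edge correction):

    g(r) = [ Σ_a n_a(r) / W_a(r) ] / ( N_A · N_B / |Ω| )

so g ≡ 1 under CSR, g > 1 indicates co-location at separation r. Confidence
intervals come from bootstrap resampling of the anchor cells' per-anchor
contributions. The topographical correlation map (TCM) is the corresponding
local indicator of spatial association: each anchor's relative excess of B
cells within a threshold radius, rendered as a smoothed spatial field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import CellPattern
from .geometry import annulus_window_area, circle_window_area

__all__ = ["PCFParams", "PCFResult", "TCMField", "cross_pcf", "pool_pcf", "tcm"]


@dataclass(frozen=True)
class PCFParams:
    """Annulus geometry and bootstrap settings.

    ``inner_radius``/``annulus_width`` define the headline statistic g(20)
    (annulus [20, 30) µm — roughly one cell diameter); ``curve_radii`` is the
    grid of inner radii for the full g(r) curve.
    """

    inner_radius: float = 20.0
    annulus_width: float = 10.0
    curve_radii: tuple = tuple(np.arange(0.0, 301.0, 5.0))
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.inner_radius < 0 or self.annulus_width <= 0:
            raise ValueError("need inner_radius >= 0 and annulus_width > 0")
        r = np.asarray(self.curve_radii)
        if len(r) and np.any(np.diff(r) <= 0):
            raise ValueError("curve_radii must be strictly increasing")

    @property
    def radii(self) -> np.ndarray:
        """Evaluation grid including the headline inner radius."""
        r = np.asarray(self.curve_radii, dtype=float)
        if self.inner_radius not in r:
            r = np.sort(np.append(r, self.inner_radius))
        return r


@dataclass
class PCFResult:
    """g(r) curve with bootstrap CI for one ROI and ordered type pair."""

    roi_id: str
    condition: str
    type_a: str
    type_b: str
    params: PCFParams
    radii: np.ndarray = field(repr=False, default=None)
    g: np.ndarray = field(repr=False, default=None)
    ci_low: np.ndarray = field(repr=False, default=None)
    ci_high: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)
    expected: np.ndarray = field(repr=False, default=None)
    n_a: int = 0
    n_b: int = 0
    window_area: float = float("nan")
    defined: bool = True
    ci_defined: bool = True
    # per-anchor annulus counts and clipped areas, kept for pooling/bootstraps
    _counts: np.ndarray = field(repr=False, default=None)
    _areas: np.ndarray = field(repr=False, default=None)

    def at(self, r: float) -> float:
        """g at the grid radius r (headline: r = 20)."""
        idx = int(np.argmin(np.abs(self.radii - r)))
        if not np.isclose(self.radii[idx], r):
            raise ValueError(f"radius {r} not on the evaluation grid")
        return float(self.g[idx])

    def ci_at(self, r: float) -> tuple[float, float]:
        idx = int(np.argmin(np.abs(self.radii - r)))
        return float(self.ci_low[idx]), float(self.ci_high[idx])

    @property
    def g_max(self) -> float:
        """Peak of the g(r) curve."""
        return float(np.nanmax(self.g)) if self.defined else float("nan")

    @property
    def r_at_g_max(self) -> float:
        return float(self.radii[int(np.nanargmax(self.g))]) if self.defined else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_id,
                "condition": self.condition,
                "type_a": self.type_a,
                "type_b": self.type_b,
                "r": self.radii,
                "g": self.g,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "observed": self.observed,
                "expected": self.expected,
            }
        )


def _annulus_counts(pattern, type_a, type_b, radii, dr):
    """Per-anchor B counts in [r, r+dr) and clipped annulus areas.

    Counts for all (possibly overlapping) annuli come from one cumulative
    histogram of the A–B distances per anchor over the merged edge set.
    """
    A = pattern.points(type_a)
    B = pattern.points(type_b)
    n_a, n_b = len(A), len(B)
    d = cdist(A, B)
    if type_a == type_b:
        np.fill_diagonal(d, np.inf)  # exclude self-pairs
    edges = np.unique(np.concatenate([radii, radii + dr]))
    # counts below each edge, per anchor
    hist = np.stack([np.histogram(row, bins=np.concatenate(([0.0], edges)))[0] for row in d])
    cum = np.cumsum(hist, axis=1)  # cum[:, k] = #{d < edges[k]}
    lo = np.searchsorted(edges, radii)
    hi = np.searchsorted(edges, radii + dr)
    counts = cum[:, hi] - cum[:, lo]
    w, h = pattern.window.width, pattern.window.height
    areas = annulus_window_area(
        A[:, 0][:, None], A[:, 1][:, None], radii[None, :], radii[None, :] + dr, w, h
    )
    return counts, areas, n_a, n_b


def _g_and_ci(counts, areas, n_a, n_b, omega, n_boot, seed):
    with np.errstate(invalid="ignore", divide="ignore"):
        # NaN where the annulus lies entirely outside the window (W_a = 0)
        contrib = counts / areas  # per-anchor local density in each annulus
    lam_b = n_b / omega
    g = contrib.sum(axis=0) / (n_a * lam_b)
    observed = counts.sum(axis=0)
    expected = lam_b * areas.sum(axis=0)
    if n_a >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        # resampling anchors with replacement == multinomial row weights
        wts = rng.multinomial(n_a, np.full(n_a, 1.0 / n_a), size=n_boot)
        reps = (wts @ contrib) / (n_a * lam_b)
        ci_low = np.percentile(reps, 2.5, axis=0)
        ci_high = np.percentile(reps, 97.5, axis=0)
        ci_defined = True
    else:
        ci_low = np.full(len(g), np.nan)
        ci_high = np.full(len(g), np.nan)
        ci_defined = False
    return g, ci_low, ci_high, observed, expected, ci_defined


def cross_pcf(
    pattern: CellPattern, type_a: str, type_b: str, params: PCFParams = PCFParams()
) -> PCFResult:
    """Cross-PCF of B around A anchors with bootstrap percentile CIs.

    The CI resamples the N_A anchors' per-anchor contributions with
    replacement (n_boot replicates, percentile 2.5/97.5). When either type is
    absent the result is flagged undefined rather than zero; with a single
    anchor the curve is defined but the CI is not.
    """
    radii = params.radii
    n_a, n_b = pattern.count(type_a), pattern.count(type_b)
    base = PCFResult(
        roi_id=pattern.roi_id,
        condition=pattern.condition,
        type_a=type_a,
        type_b=type_b,
        params=params,
        radii=radii,
        n_a=n_a,
        n_b=n_b,
        window_area=pattern.window.area,
    )
    if n_a == 0 or n_b == 0 or (type_a == type_b and n_b < 2):
        nanv = np.full(len(radii), np.nan)
        return replace(
            base, g=nanv, ci_low=nanv.copy(), ci_high=nanv.copy(),
            observed=nanv.copy(), expected=nanv.copy(), defined=False, ci_defined=False,
        )
    counts, areas, n_a, n_b = _annulus_counts(
        pattern, type_a, type_b, radii, params.annulus_width
    )
    g, lo, hi, obs, exp, ci_ok = _g_and_ci(
        counts, areas, n_a, n_b, pattern.window.area, params.n_boot, params.seed
    )
    return replace(
        base, g=g, ci_low=lo, ci_high=hi, observed=obs, expected=exp,
        ci_defined=ci_ok, _counts=counts, _areas=areas,
    )


def pool_pcf(results: list[PCFResult]) -> PCFResult:
    """Condition-level g(r) by pooling counts and clipped areas across ROIs.

    Per-anchor contributions from all ROIs are concatenated, so the pooled
    curve is the count-weighted combination (not an average of per-ROI g) and
    the bootstrap resamples anchors across the whole condition. B intensity is
    taken per ROI (each anchor's contribution normalised by its own ROI's
    λ_B), keeping E[g] = 1 under CSR even when ROI densities differ.
    """
    defined = [r for r in results if r.defined and r._counts is not None]
    if not defined:
        raise ValueError("no defined per-ROI PCF results to pool")
    first = defined[0]
    radii = first.radii
    for r in defined[1:]:
        if not np.array_equal(r.radii, radii):
            raise ValueError("per-ROI results evaluated on different radius grids")
        if (r.type_a, r.type_b) != (first.type_a, first.type_b):
            raise ValueError("cannot pool different type pairs")
    # normalise each anchor by its own ROI's λ_B so contributions share a scale
    contribs = []
    for res in defined:
        lam_b = res.n_b / res.window_area
        with np.errstate(invalid="ignore", divide="ignore"):
            contribs.append(res._counts / (res._areas * lam_b))
    contrib = np.vstack(contribs)
    n_a_total = contrib.shape[0]
    g = contrib.mean(axis=0)
    observed = np.vstack([res._counts for res in defined]).sum(axis=0)
    expected = np.vstack(
        [res._areas * (res.n_b / res.window_area) for res in defined]
    ).sum(axis=0)
    rng = np.random.default_rng(first.params.seed)
    n_boot = first.params.n_boot
    if n_a_total >= 2 and n_boot > 0:
        wts = rng.multinomial(n_a_total, np.full(n_a_total, 1.0 / n_a_total), size=n_boot)
        reps = (wts @ contrib) / n_a_total
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        ci_ok = True
    else:
        lo = hi = np.full(len(g), np.nan)
        ci_ok = False
    return PCFResult(
        roi_id="pooled",
        condition=first.condition,
        type_a=first.type_a,
        type_b=first.type_b,
        params=first.params,
        radii=radii,
        g=g,
        ci_low=lo,
        ci_high=hi,
        observed=observed,
        expected=expected,
        n_a=n_a_total,
        n_b=sum(res.n_b for res in defined),
        window_area=sum(res.window_area for res in defined),
        ci_defined=ci_ok,
    )


@dataclass
class TCMField:
    """Per-anchor local co-location scores and the smoothed raster."""

    roi_id: str
    condition: str
    type_a: str
    type_b: str
    threshold: float
    cells: pd.DataFrame = field(repr=False, default=None)  # cell_id,x,y,gamma,observed,expected
    grid: np.ndarray = field(repr=False, default=None)
    grid_spacing: float = 10.0

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.copy()
        df.insert(0, "condition", self.condition)
        df.insert(0, "roi_id", self.roi_id)
        return df


def tcm(
    pattern: CellPattern,
    type_a: str,
    type_b: str,
    threshold: float = 100.0,
    grid_spacing: float = 10.0,
) -> TCMField:
    """Topographical correlation map: per-anchor relative excess of B cells.

    Γ_a = observed_a / expected_a − 1 with expected_a = N_B · W_a / |Ω| and
    W_a the disc(threshold)∩window area, so Γ is bounded below by −1 (no B
    within the threshold) and positive where B is locally enriched relative
    to CSR. Each anchor's (1 + Γ_a) integrates the anchor's contribution to
    the cross-K function up to the threshold. The visualization raster is a
    Gaussian-kernel (bandwidth threshold/2) weighted average of Γ over a grid.
    """
    A = pattern.points(type_a)
    B = pattern.points(type_b)
    if len(A) == 0:
        raise ValueError(f"no anchor cells of type {type_a!r}")
    d = cdist(A, B)
    if type_a == type_b:
        np.fill_diagonal(d, np.inf)
    observed = (d < threshold).sum(axis=1).astype(float)
    n_b = len(B) - (1 if type_a == type_b else 0)
    w, h = pattern.window.width, pattern.window.height
    W_a = circle_window_area(A[:, 0], A[:, 1], threshold, w, h)
    expected = n_b * W_a / pattern.window.area
    gamma = observed / expected - 1.0

    anchors = pattern.cells[pattern.cells["cell_type"] == type_a]
    cells = pd.DataFrame(
        {
            "cell_id": anchors["cell_id"].to_numpy(),
            "x": A[:, 0],
            "y": A[:, 1],
            "gamma": gamma,
            "observed": observed,
            "expected": expected,
        }
    )

    sigma = threshold / 2.0
    gx = np.arange(grid_spacing / 2, w, grid_spacing)
    gy = np.arange(grid_spacing / 2, h, grid_spacing)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    d2 = cdist(pts, A, "sqeuclidean")
    wts = np.exp(-d2 / (2 * sigma * sigma))
    denom = wts.sum(axis=1)
    num = wts @ gamma
    smoothed = np.where(denom > 1e-300, num / np.maximum(denom, 1e-300), 0.0)
    grid = smoothed.reshape(len(gy), len(gx))
    return TCMField(
        roi_id=pattern.roi_id,
        condition=pattern.condition,
        type_a=type_a,
        type_b=type_b,
        threshold=threshold,
        cells=cells,
        grid=grid,
        grid_spacing=grid_spacing,
    )
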