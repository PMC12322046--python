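"""Synthetic multi-type point patterns and matching label masks.

Every statistic in the suite is normalised against complete spatial
randomness (CSR), so the test bed provides generators with known ground
truth: homogeneous Poisson patterns (the null), exact-distance A–B pairing
(a closed-form cross-PCF target), tight three-type triplet clusters (an NCF
alternative), and Thomas cluster processes. Planted structure is kept away
from window boundaries by construction so that analytic targets are
insensitive to the edge-correction choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellPattern, LabelMask, Window

__all__ = [
    "SimSpec",
    "CSR",
    "PairedAttraction",
    "TripletClusters",
    "Thomas",
    "InfeasibleSpecError",
    "simulate",
    "simulate_csr",
    "simulate_paired",
    "simulate_triplets",
    "simulate_thomas",
    "synthesize_mask",
]


class InfeasibleSpecError(ValueError):
    """The requested structure cannot fit in the window."""


@dataclass(frozen=True)
class CSR:
    """Homogeneous Poisson pattern for every type in ``intensity``."""


@dataclass(frozen=True)
class PairedAttraction:
    """Each type-a cell gets exactly one type-b partner at a fixed distance.

    Anchors are CSR in the window eroded by ``margin`` (default
    offset_distance + 10 µm), so partners and their annuli stay inside the
    window. ``n_pairs`` fixes the anchor count exactly; when None the count
    is Poisson with the type_a intensity over the eroded window.
    ``min_separation`` enforces a hard-core distance between anchors
    (sequential dart throwing): choosing it larger than offset_distance plus
    the annulus outer radius guarantees each anchor's annulus holds exactly
    its own partner, which makes the cross-PCF value a closed form.
    """

    type_a: str
    type_b: str
    offset_distance: float
    n_pairs: int | None = None
    margin: float | None = None
    min_separation: float | None = None


@dataclass(frozen=True)
class TripletClusters:
    """n_clusters CSR parents, one cell of each of t1,t2,t3 per parent disc."""

    t1: str
    t2: str
    t3: str
    n_clusters: int
    cluster_radius: float


@dataclass(frozen=True)
class Thomas:
    """Thomas cluster process: Poisson parents, Gaussian offspring shared by types."""

    parent_intensity: float
    offspring_per_parent: float
    sd: float
    shared_types: tuple[str, ...]


@dataclass(frozen=True)
class SimSpec:
    """Full description of one simulated ROI.

    ``intensity`` is cells/µm² per type; for structured generators it supplies
    anchor intensities and/or CSR background on top of the planted structure.
    """

    window: Window
    intensity: dict = field(default_factory=dict)
    structure: object = field(default_factory=CSR)
    seed: int = 0
    roi_id: str = "sim"
    condition: str = "sim"


def _pattern(spec: SimSpec, xs, ys, types) -> CellPattern:
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xs) + 1, dtype=int),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "cell_type": np.asarray(types, dtype=object),
        }
    )
    return CellPattern(spec.roi_id, spec.condition, spec.window, cells)


def _uniform(rng, n, x0, x1, y0, y1):
    return rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)


def _csr_points(rng, window: Window, intensity: dict):
    xs, ys, ts = [], [], []
    for t in sorted(intensity):
        lam = intensity[t]
        if lam < 0:
            raise ValueError("intensities must be >= 0")
        n = rng.poisson(lam * window.area)
        x, y = _uniform(rng, n, 0, window.width, 0, window.height)
        xs.append(x)
        ys.append(y)
        ts.append(np.full(n, t, dtype=object))
    if not xs:
        return np.array([]), np.array([]), np.array([], dtype=object)
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(ts)


def simulate_csr(spec: SimSpec) -> CellPattern:
    """Independent homogeneous Poisson pattern per type."""
    rng = np.random.default_rng(spec.seed)
    xs, ys, ts = _csr_points(rng, spec.window, spec.intensity)
    return _pattern(spec, xs, ys, ts)


def simulate_paired(spec: SimSpec) -> CellPattern:
    """Anchors of type_a with exactly one type_b partner each at exact distance."""
    st = spec.structure
    if not isinstance(st, PairedAttraction):
        raise ValueError("structure must be PairedAttraction")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.window.width, spec.window.height
    margin = st.margin if st.margin is not None else st.offset_distance + 10.0
    if 2 * margin >= w or 2 * margin >= h:
        raise InfeasibleSpecError(
            f"margin {margin} µm leaves no room in a {w}×{h} µm window"
        )
    if st.n_pairs is not None:
        n_a = int(st.n_pairs)
    else:
        lam = spec.intensity.get(st.type_a, 0.0)
        n_a = rng.poisson(lam * (w - 2 * margin) * (h - 2 * margin))
    if st.min_separation is None:
        ax, ay = _uniform(rng, n_a, margin, w - margin, margin, h - margin)
    else:
        ax = np.empty(n_a)
        ay = np.empty(n_a)
        placed = 0
        attempts = 0
        max_attempts = 10_000 * max(n_a, 1)
        while placed < n_a:
            if attempts >= max_attempts:
                raise InfeasibleSpecError(
                    f"could not place {n_a} anchors with min_separation "
                    f"{st.min_separation} µm in the eroded window"
                )
            x, y = rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)
            attempts += 1
            if placed and np.min(np.hypot(ax[:placed] - x, ay[:placed] - y)) < st.min_separation:
                continue
            ax[placed], ay[placed] = x, y
            placed += 1
    theta = rng.uniform(0, 2 * np.pi, n_a)
    bx = ax + st.offset_distance * np.cos(theta)
    by = ay + st.offset_distance * np.sin(theta)
    xs = np.concatenate([ax, bx])
    ys = np.concatenate([ay, by])
    ts = np.concatenate([np.full(n_a, st.type_a, dtype=object), np.full(n_a, st.type_b, dtype=object)])
    # optional CSR background for types other than the planted pair
    bg = {t: lam for t, lam in spec.intensity.items() if t not in (st.type_a, st.type_b)}
    gx, gy, gt = _csr_points(rng, spec.window, bg)
    return _pattern(spec, np.concatenate([xs, gx]), np.concatenate([ys, gy]), np.concatenate([ts, gt]))


def simulate_triplets(spec: SimSpec) -> CellPattern:
    """Tight three-type clusters: one cell of each type per parent disc."""
    st = spec.structure
    if not isinstance(st, TripletClusters):
        raise ValueError("structure must be TripletClusters")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.window.width, spec.window.height
    if st.cluster_radius <= 0:
        raise ValueError("cluster_radius must be positive")
    margin = st.cluster_radius + 10.0
    if st.n_clusters > 0 and (2 * margin >= w or 2 * margin >= h):
        raise InfeasibleSpecError("cluster margin leaves no room in the window")
    px, py = _uniform(rng, st.n_clusters, margin, w - margin, margin, h - margin)
    xs, ys, ts = [], [], []
    for t in (st.t1, st.t2, st.t3):
        # uniform in disc of cluster_radius around each parent
        r = st.cluster_radius * np.sqrt(rng.uniform(0, 1, st.n_clusters))
        th = rng.uniform(0, 2 * np.pi, st.n_clusters)
        xs.append(px + r * np.cos(th))
        ys.append(py + r * np.sin(th))
        ts.append(np.full(st.n_clusters, t, dtype=object))
    bg = {t: lam for t, lam in spec.intensity.items()}
    gx, gy, gt = _csr_points(rng, spec.window, bg)
    xs = np.concatenate(xs + [gx]) if xs else gx
    ys = np.concatenate(ys + [gy]) if ys else gy
    ts = np.concatenate(ts + [gt]) if ts else gt
    return _pattern(spec, xs, ys, ts)


def simulate_thomas(spec: SimSpec) -> CellPattern:
    """Thomas process: offspring of the shared types cluster around common parents."""
    st = spec.structure
    if not isinstance(st, Thomas):
        raise ValueError("structure must be Thomas")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.window.width, spec.window.height
    n_parents = rng.poisson(st.parent_intensity * spec.window.area)
    px, py = _uniform(rng, n_parents, 0, w, 0, h)
    xs, ys, ts = [], [], []
    for t in st.shared_types:
        n_off = rng.poisson(st.offspring_per_parent, n_parents)
        ox = np.repeat(px, n_off) + rng.normal(0, st.sd, int(n_off.sum()))
        oy = np.repeat(py, n_off) + rng.normal(0, st.sd, int(n_off.sum()))
        keep = (ox >= 0) & (ox < w) & (oy >= 0) & (oy < h)
        xs.append(ox[keep])
        ys.append(oy[keep])
        ts.append(np.full(int(keep.sum()), t, dtype=object))
    bg = {t: lam for t, lam in spec.intensity.items() if t not in st.shared_types}
    gx, gy, gt = _csr_points(rng, spec.window, bg)
    xs = np.concatenate(xs + [gx]) if xs else gx
    ys = np.concatenate(ys + [gy]) if ys else gy
    ts = np.concatenate(ts + [gt]) if ts else gt
    return _pattern(spec, xs, ys, ts)


_DISPATCH = {
    CSR: simulate_csr,
    PairedAttraction: simulate_paired,
    TripletClusters: simulate_triplets,
    Thomas: simulate_thomas,
}


def simulate(spec: SimSpec) -> CellPattern:
    """Dispatch on ``spec.structure``."""
    return _DISPATCH[type(spec.structure)](spec)


def synthesize_mask(pattern: CellPattern, pixel_size: float = 1.0, cell_radius: float = 5.0) -> LabelMask:
    """Rasterise each cell as a disc; overlaps go to the nearest centroid.

    Ties (and coincident-pixel centroids) resolve to the lower cell_id, and
    every cell is guaranteed to own at least its centroid pixel.
    """
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    if len(pattern) and int(pattern.cells["cell_id"].min()) <= 0:
        raise ValueError("cell_ids must be positive to appear in a label mask")
    w, h = pattern.window.width, pattern.window.height
    ncols = int(np.ceil(w / pixel_size))
    nrows = int(np.ceil(h / pixel_size))
    labels = np.zeros((nrows, ncols), dtype=np.int64)
    best = np.full((nrows, ncols), np.inf)

    cells = pattern.cells.sort_values("cell_id")
    rad_pix = cell_radius / pixel_size
    for cid, x, y in zip(cells["cell_id"], cells["x"], cells["y"]):
        # centroid in pixel coordinates (pixel centre (r,c) at ((c+.5)s,(r+.5)s))
        pc = x / pixel_size - 0.5
        pr = y / pixel_size - 0.5
        r0 = max(int(np.floor(pr - rad_pix)), 0)
        r1 = min(int(np.ceil(pr + rad_pix)) + 1, nrows)
        c0 = max(int(np.floor(pc - rad_pix)), 0)
        c1 = min(int(np.ceil(pc + rad_pix)) + 1, ncols)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d = np.hypot(rr - pr, cc - pc) * pixel_size
        sub = (slice(r0, r1), slice(c0, c1))
        # strict improvement: earlier (lower) cell_id wins exact ties
        win = (d <= cell_radius) & (d < best[sub])
        best[sub][win] = d[win]
        labels[sub][win] = cid
    # guarantee the centroid pixel (lowest id wins a shared pixel)
    seen: dict[tuple[int, int], int] = {}
    for cid, x, y in zip(cells["cell_id"], cells["x"], cells["y"]):
        r = min(int(y / pixel_size), nrows - 1)
        c = min(int(x / pixel_size), ncols - 1)
        if (r, c) in seen:
            warnings.warn(
                f"cells {seen[(r, c)]} and {cid} share centroid pixel ({r},{c}); "
                "lower cell_id keeps it",
                stacklevel=2,
            )
            continue
        seen[(r, c)] = int(cid)
        labels[r, c] = cid
    return LabelMask(labels, pixel_size=pixel_size)
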