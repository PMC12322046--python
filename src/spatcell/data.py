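"""Data model for ROIs: rectangular windows, labelled point patterns and label masks.

A region of interest (ROI) is represented by a :class:`CellPattern` — cell
centroids in continuous µm coordinates with flat categorical cell-type labels,
observed inside a rectangular :class:`Window`. Coordinates use the imaging
convention: origin top-left, y increasing downward, half-open window
[0, width) × [0, height). Optional :class:`LabelMask` images (one integer cell
id per pixel, 0 = background) carry the segmentation needed for physical
contact analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Window",
    "CellPattern",
    "LabelMask",
    "TypeCounts",
    "SchemaError",
    "ParseError",
    "FormatError",
    "read_cell_table",
    "write_cell_table",
    "read_label_mask",
    "write_label_mask",
    "centroids_from_mask",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A table cell could not be parsed as the expected type."""


class FormatError(ValueError):
    """An image is not a valid integer label image."""


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, dimensions in µm."""

    width: float
    height: float

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window dimensions must be positive")

    @property
    def area(self) -> float:
        """Window area in µm²."""
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area / 1e6


@dataclass
class CellPattern:
    """Labelled planar point pattern for one ROI.

    ``cells`` is a DataFrame with columns ``cell_id`` (unique ints), ``x``,
    ``y`` (µm, inside the window) and ``cell_type`` (opaque strings).
    """

    roi_id: str
    condition: str
    window: Window
    cells: pd.DataFrame

    def __post_init__(self):
        required = {"cell_id", "x", "y", "cell_type"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        self.cells = self.cells.reset_index(drop=True)
        x = self.cells["x"].to_numpy(dtype=float)
        y = self.cells["y"].to_numpy(dtype=float)
        if len(x) and (
            x.min() < 0 or y.min() < 0 or x.max() >= self.window.width or y.max() >= self.window.height
        ):
            raise ValueError("cell centroids must lie in [0,width)×[0,height)")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique within an ROI")
        if len(self.cells) and self.cells["cell_type"].nunique() < 1:
            raise ValueError("at least one cell type must be present")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def types(self) -> list[str]:
        """Sorted list of cell types present."""
        return sorted(self.cells["cell_type"].unique())

    def points(self, cell_type: str | None = None) -> np.ndarray:
        """(n, 2) array of centroids, optionally restricted to one type."""
        df = self.cells if cell_type is None else self.cells[self.cells["cell_type"] == cell_type]
        return df[["x", "y"]].to_numpy(dtype=float)

    def count(self, cell_type: str) -> int:
        return int((self.cells["cell_type"] == cell_type).sum())

    def type_counts(self, types: list[str] | None = None) -> "TypeCounts":
        return TypeCounts.from_pattern(self, types=types)

    def with_types(self, new_types: np.ndarray) -> "CellPattern":
        """Copy of the pattern with cell-type labels replaced (positions fixed)."""
        cells = self.cells.copy()
        cells["cell_type"] = np.asarray(new_types)
        return CellPattern(self.roi_id, self.condition, self.window, cells)


@dataclass
class TypeCounts:
    """Per-type cell counts and densities (cells/mm²) for one ROI."""

    counts: dict[str, int]
    window: Window

    @classmethod
    def from_pattern(cls, pattern: CellPattern, types: list[str] | None = None) -> "TypeCounts":
        vc = pattern.cells["cell_type"].value_counts()
        if types is None:
            types = pattern.types
        return cls({t: int(vc.get(t, 0)) for t in types}, pattern.window)

    @property
    def densities(self) -> dict[str, float]:
        """Cells per mm² of tissue."""
        return {t: n / self.window.area_mm2 for t, n in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LabelMask:
    """Integer cell-id image; 0 = background, k > 0 = cell id ``k``."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label mask must be a 2-D image")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError("label mask pixels must be integers")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present."""
        lab = np.unique(self.pixels)
        return lab[lab > 0]


# ---------------------------------------------------------------------------
# table I/O

_STANDARD_COLUMNS = ("x", "y", "cell_type", "roi_id", "condition")


def _infer_extent(values: np.ndarray) -> float:
    """Smallest whole-µm extent strictly containing max(values) (half-open window)."""
    m = float(values.max())
    e = math.ceil(m)
    return float(e + 1) if e == m else float(e)


def read_cell_table(
    path,
    schema: dict | None = None,
    delimiter: str | None = None,
) -> list[CellPattern]:
    """Read a delimited cell table into one :class:`CellPattern` per ROI.

    ``schema`` maps the standard field names (``x``, ``y``, ``cell_type``,
    ``roi_id``, ``condition``) to the file's column names, and may also carry
    ``window`` — either a ``(width, height)`` tuple applied to every ROI or a
    ``{roi_id: (width, height)}`` dict — and ``defaults``, constant values
    used for ``roi_id``/``condition`` when the file has no such column. When
    no window is supplied it is inferred per ROI as the bounding box rounded
    up to whole µm. Row order within each ROI defines ``cell_id`` assignment
    (1-based).
    """
    schema = dict(schema or {})
    window_spec = schema.pop("window", None)
    defaults = dict(schema.pop("defaults", {}))
    colmap = {std: schema.get(std, std) for std in _STANDARD_COLUMNS}

    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    for std, col in colmap.items():
        if col not in df.columns:
            if std in ("roi_id", "condition") and std in defaults:
                df[col] = defaults[std]
                continue
            raise SchemaError(f"required column {col!r} (for field {std!r}) not found in {path}")

    for std in ("x", "y"):
        col = colmap[std]
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna() | bad)[0])
            raise ParseError(f"non-numeric {std} coordinate at row {row} in {path}")
        if not np.isfinite(parsed.to_numpy(dtype=float)).all():
            row = int(np.flatnonzero(~np.isfinite(parsed.to_numpy(dtype=float)))[0])
            raise ParseError(f"non-finite {std} coordinate at row {row} in {path}")
        df[col] = parsed.astype(float)

    patterns = []
    for roi_id, grp in df.groupby(colmap["roi_id"], sort=True):
        roi_id = str(roi_id)
        conditions = grp[colmap["condition"]].astype(str).unique()
        if len(conditions) > 1:
            raise ParseError(f"ROI {roi_id} maps to multiple conditions: {sorted(conditions)}")
        if isinstance(window_spec, dict):
            window = Window(*window_spec[roi_id])
        elif window_spec is not None:
            window = Window(*window_spec)
        else:
            window = Window(
                _infer_extent(grp[colmap["x"]].to_numpy()),
                _infer_extent(grp[colmap["y"]].to_numpy()),
            )
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, len(grp) + 1, dtype=int),
                "x": grp[colmap["x"]].to_numpy(dtype=float),
                "y": grp[colmap["y"]].to_numpy(dtype=float),
                "cell_type": grp[colmap["cell_type"]].astype(str).to_numpy(),
            }
        )
        patterns.append(CellPattern(roi_id, str(conditions[0]), window, cells))
    return patterns


def write_cell_table(patterns, path) -> None:
    """Write patterns as CSV with columns roi_id,condition,cell_id,x,y,cell_type."""
    if isinstance(patterns, CellPattern):
        patterns = [patterns]
    frames = []
    for p in patterns:
        df = p.cells[["cell_id", "x", "y", "cell_type"]].copy()
        df.insert(0, "condition", p.condition)
        df.insert(0, "roi_id", p.roi_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mask I/O

def read_label_mask(path, pixel_size: float = 1.0) -> LabelMask:
    """Read a single-plane integer label image (TIFF/OME-TIFF)."""
    pixels = tifffile.imread(path)
    pixels = np.squeeze(pixels)
    if pixels.ndim != 2:
        raise FormatError(f"expected a single-plane label image, got shape {pixels.shape}")
    if np.issubdtype(pixels.dtype, np.floating):
        rounded = np.rint(pixels)
        if not np.array_equal(rounded, pixels):
            raise FormatError("floating-point image does not hold exact integer labels")
        pixels = rounded.astype(np.int64)
    elif not np.issubdtype(pixels.dtype, np.integer):
        raise FormatError(f"unsupported label image dtype {pixels.dtype}")
    return LabelMask(pixels.astype(np.int64), pixel_size=pixel_size)


def write_label_mask(mask: LabelMask, path) -> None:
    """Write the label image as an int32 TIFF."""
    if mask.pixels.size and mask.pixels.max() > np.iinfo(np.int32).max:
        raise ValueError("label ids exceed int32 range")
    tifffile.imwrite(path, mask.pixels.astype(np.int32))


def centroids_from_mask(mask: LabelMask) -> pd.DataFrame:
    """Per-label centroids in µm, pixel (r, c) centre at ((c+0.5)·s, (r+0.5)·s).

    Returns a DataFrame (cell_id, x, y) ordered by label id — the consistency
    bridge between mask and table inputs.
    """
    pix = mask.pixels
    labels = mask.labels
    if labels.size == 0:
        raise ValueError("mask has an empty label set")
    rows, cols = np.nonzero(pix)
    vals = pix[rows, cols]
    order = np.argsort(vals, kind="stable")
    vals, rows, cols = vals[order], rows[order], cols[order]
    counts = np.bincount(vals)[labels]
    sums_r = np.bincount(vals, weights=rows)[labels]
    sums_c = np.bincount(vals, weights=cols)[labels]
    s = mask.pixel_size
    return pd.DataFrame(
        {
            "cell_id": labels.astype(int),
            "x": (sums_c / counts + 0.5) * s,
            "y": (sums_r / counts + 0.5) * s,
        }
    )
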