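"""Cell segmentation, per-cell channel normalization and subpixel nucleoid contours.

Per-cell analysis follows the two-level contouring idea used to delimit the
nucleoid in DAPI images: pixel values are normalized to [0, 1] within each
cell, and iso-intensity contours are extracted with subpixel accuracy by
marching squares (linear interpolation between pixel centers).  Two levels
are used: a high one bounding the densest DNA regions and a lower one
bounding the diffuse nucleoid; the annulus between them is the "peripheral"
zone of the nucleoid.

Coordinate convention: 0-based, pixel centers at integer positions,
``x`` = column, ``y`` = row.  Contour vertices are continuous in this frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

#: contours enclosing less than this many px^2 are discarded as noise
MIN_CONTOUR_AREA = 2.0
#: value used to fill outside-cell pixels before contouring; below any
#: level in (0, 1) so contours clipped by the cell edge close along it
_OUTSIDE_FILL = -0.1


@dataclass
class SegmentationParams:
    """Knobs for phase-contrast cell segmentation."""

    min_area: float = 100.0      # px^2
    max_area: float = 5000.0     # px^2
    cells_are_dark: bool = True  # phase contrast: cells darker than background
    watershed_split: bool = True
    core_fraction: float = 0.7   # distance-transform core level for watershed seeds
    smoothing_sigma: float = 1.0


@dataclass
class CellRegion:
    """A single segmented cell: integer id, boolean mask, bounding box."""

    cell_id: int
    mask: np.ndarray          # boolean, full-frame
    bbox: tuple               # (min_row, min_col, max_row, max_col), half-open
    area: float

    @classmethod
    def from_labeled(cls, labels: np.ndarray, label: int) -> "CellRegion":
        mask = labels == label
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        return cls(cell_id=int(label), mask=mask, bbox=bbox, area=float(mask.sum()))

    def crop(self, raster: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return raster[r0:r1, c0:c1]

    def crop_mask(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return self.mask[r0:r1, c0:c1]


@dataclass
class Contour:
    """Closed polygon in continuous image coordinates at one iso-level."""

    vertices: np.ndarray      # (N, 2) array of (x, y), closed (first == last)
    level: float
    channel: str = ""
    area: float = 0.0

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class NucleoidZones:
    """Dual-level nucleoid contours of one cell.

    ``dense`` polygons (high level) are geometrically nested inside the
    union of ``diffuse`` polygons (low level).
    """

    cell_id: int
    dense: list = field(default_factory=list)    # list[Contour]
    diffuse: list = field(default_factory=list)  # list[Contour]

    def dense_union(self):
        return unary_union([c.polygon() for c in self.dense]) if self.dense else None

    def diffuse_union(self):
        return unary_union([c.polygon() for c in self.diffuse]) if self.diffuse else None


def segment_cells(
    raster: np.ndarray,
    params: SegmentationParams | None = None,
    truth_mask: np.ndarray | None = None,
) -> list[CellRegion]:
    """Identify single cells in a phase-contrast image (or pass a mask through).

    When ``truth_mask`` (a labeled integer image) is supplied it is used
    verbatim — each positive label becomes one :class:`CellRegion`.
    Otherwise the raster is thresholded (Otsu; inverted for dark cells),
    holes are filled, touching cells are split by a distance-transform
    watershed, and regions outside the configured area range are dropped.
    """
    params = params or SegmentationParams()

    if truth_mask is not None:
        labels = np.unique(truth_mask)
        return [CellRegion.from_labeled(truth_mask, l) for l in labels if l > 0]

    if raster.ndim != 2:
        raise ValueError("expected a 2-D raster")

    img = ndimage.gaussian_filter(raster.astype(float), params.smoothing_sigma)
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    fg = img < thr if params.cells_are_dark else img > thr
    fg = ndimage.binary_fill_holes(fg)
    fg = ndimage.binary_opening(fg, structure=np.ones((3, 3)))
    if not fg.any():
        return []

    if params.watershed_split:
        # Seed one marker per distance-transform "core": pixels above a
        # fraction of their component's maximum distance.  A rod's ridge is a
        # plateau, so point maxima would over-split straight cells; the core
        # of a single rod is one connected band, while two cells joined by a
        # narrow neck have disconnected cores and get separated.
        dist = ndimage.distance_transform_edt(fg)
        comp, ncomp = ndimage.label(fg)
        core = np.zeros_like(fg, dtype=bool)
        for l in range(1, ncomp + 1):
            m = comp == l
            core |= m & (dist > params.core_fraction * dist[m].max())
        markers, _ = ndimage.label(core)
        labels = segmentation.watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndimage.label(fg)

    regions = []
    next_id = 1
    for l in np.unique(labels):
        if l == 0:
            continue
        area = float((labels == l).sum())
        if params.min_area <= area <= params.max_area:
            reg = CellRegion.from_labeled(labels, int(l))
            reg.cell_id = next_id
            next_id += 1
            regions.append(reg)
    return regions


def normalize_channel(raster: np.ndarray, cell: CellRegion) -> np.ndarray:
    """Min–max normalize a channel to [0, 1] over one cell's pixels.

    Returns a full-frame float array; pixels outside the cell are NaN
    (undefined).  A flat channel (max == min) normalizes to all zeros with
    a warning, so downstream contouring degrades gracefully.
    """
    if not cell.mask.any():
        raise ValueError(f"cell {cell.cell_id}: empty mask")
    vals = raster[cell.mask].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(raster.shape, np.nan)
    if hi == lo:
        warnings.warn(f"cell {cell.cell_id}: flat channel, normalized to zeros")
        out[cell.mask] = 0.0
    else:
        out[cell.mask] = (raster[cell.mask].astype(float) - lo) / (hi - lo)
    return out


def _close_and_clean(verts_rc: np.ndarray, offset: tuple[float, float]) -> Polygon | None:
    """Convert a marching-squares contour (row, col) to a simple shapely polygon."""
    xy = np.column_stack([verts_rc[:, 1] + offset[1], verts_rc[:, 0] + offset[0]])
    if len(xy) < 4:
        return None
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)  # resolves rare self-touching vertices
        if poly.is_empty:
            return None
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    return poly


def contour_at_level(
    norm_raster: np.ndarray,
    level: float,
    cell: CellRegion | None = None,
    channel: str = "",
) -> list[Contour]:
    """Extract closed subpixel iso-contours of a normalized raster.

    Marching squares with linear interpolation between pixel centers.
    When a cell is given, the computation is restricted to its bounding
    box and pixels outside the cell mask are treated as below-level, so
    contours clipped by the cell edge close along the mask boundary
    (within half a pixel).  Contours enclosing < 2 px^2 are discarded.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")

    if cell is not None:
        img = cell.crop(norm_raster).astype(float).copy()
        img[~cell.crop_mask()] = _OUTSIDE_FILL
        r0, c0 = cell.bbox[0], cell.bbox[1]
    else:
        img = np.asarray(norm_raster, dtype=float).copy()
        r0 = c0 = 0
        # no crossings at all (e.g. a constant raster) -> no contours; the
        # padding below must not manufacture a ring around such a raster
        finite = img[np.isfinite(img)]
        if finite.size == 0 or finite.min() >= level or finite.max() < level:
            return []
    img = np.nan_to_num(img, nan=_OUTSIDE_FILL)
    # pad so every contour closes inside the array (along the mask edge or,
    # without a cell, along the image border)
    img = np.pad(img, 1, constant_values=_OUTSIDE_FILL)

    contours = []
    for verts in measure.find_contours(img, level):
        poly = _close_and_clean(verts, offset=(r0 - 1, c0 - 1))
        if poly is None or poly.area < MIN_CONTOUR_AREA:
            continue
        coords = np.asarray(poly.exterior.coords)
        contours.append(Contour(vertices=coords, level=level, channel=channel, area=poly.area))
    return contours


def nucleoid_zones(
    norm_dapi: np.ndarray,
    cell: CellRegion,
    l_dense: float = 0.5,
    l_diffuse: float = 0.2,
) -> NucleoidZones:
    """Extract the dense and diffuse nucleoid contours of one cell.

    ``l_dense`` and ``l_diffuse`` are iso-levels of the per-cell normalized
    DAPI channel.  Because both level sets come from the same function,
    every dense polygon must nest inside the diffuse union; a violation
    after numerical closure indicates a contouring bug and raises.
    """
    if not (0.0 < l_diffuse < l_dense < 1.0):
        raise ValueError("require 0 < l_diffuse < l_dense < 1")
    dense = contour_at_level(norm_dapi, l_dense, cell, channel="dapi")
    diffuse = contour_at_level(norm_dapi, l_diffuse, cell, channel="dapi")

    if dense and diffuse:
        dense_u = unary_union([c.polygon() for c in dense])
        diffuse_u = unary_union([c.polygon() for c in diffuse])
        outside = dense_u.difference(diffuse_u.buffer(0.25)).area
        if outside > 0.05 * max(dense_u.area, 1e-9):
            raise RuntimeError(
                f"cell {cell.cell_id}: dense contour escapes the diffuse contour "
                f"({outside:.2f} px^2 outside) — contour closure bug"
            )
    elif dense and not diffuse:
        raise RuntimeError(
            f"cell {cell.cell_id}: dense contours present but no diffuse contour"
        )
    return NucleoidZones(cell_id=cell.cell_id, dense=dense, diffuse=diffuse)
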