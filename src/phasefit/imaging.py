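"""Cell and focus segmentation with per-cell fluorescence partitioning.

Reimplements the particle-analysis recipe used for the confocal data:
cells are connected components of pixels within a fluorescence band,
kept when their physical area and circularity fall inside configured
windows; foci are brighter, smaller components assigned to the cell
containing their centroid.  Per cell, the integrated focus fluorescence
is subtracted from the integrated total to give the cytosolic (free
protein) signal:

    F_CYTO = F_TOTAL - F_FOCI   (exact, per cell)

Default thresholds: cells 20-255 a.u., 8-50 um^2, circularity 0.25-1;
foci 40-255 a.u., 0.2-10 um^2.  Intensity bands are inclusive closed
intervals on 8-bit values, circularity is the particle-analysis
convention 4*pi*area/perimeter^2 capped at 1 (digitisation can push it
above), components are 8-connected, and regions touching the image
border are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as _label, regionprops as _regionprops

from .core import CELL_COLUMNS, Strain
from .synthetic import SyntheticImage

__all__ = [
    "SegmentationParams",
    "segment_cells",
    "segment_foci",
    "measure_cells",
    "classify_foci_size",
    "analyze_image",
    "read_image",
    "match_labels",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold windows of the particle analysis, in physical units."""

    cell_intensity: tuple = (20, 255)
    cell_area_um2: tuple = (8.0, 50.0)
    cell_circularity: tuple = (0.25, 1.0)
    foci_intensity: tuple = (40, 255)
    foci_area_um2: tuple = (0.2, 10.0)
    pixel_scale: float = 0.2  # um per pixel

    def __post_init__(self):
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        for name in ("cell_intensity", "cell_area_um2", "cell_circularity",
                     "foci_intensity", "foci_area_um2"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must be non-degenerate, got ({lo}, {hi})")


def read_image(path) -> np.ndarray:
    """Load a single-channel 8-bit grayscale TIFF/PNG as a 2-D array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    return img


def _circularity(region) -> float:
    perim = region.perimeter
    if perim == 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * region.area / perim**2)


def _band_mask(image: np.ndarray, band: tuple) -> np.ndarray:
    lo, hi = band
    return (image >= lo) & (image <= hi)


def _area_in_range(area_um2: float, bounds: tuple) -> bool:
    # closed interval with a relative epsilon: pixel-count * scale^2 can
    # land a few ulp above an exactly-representable bound (1250 px at
    # 0.2 um/px is 50 + 1e-14 um^2) and must still count as inside
    lo, hi = bounds
    eps = 1e-9 * max(1.0, hi)
    return lo - eps <= area_um2 <= hi + eps


def segment_cells(image, params: SegmentationParams):
    """Detect cells: intensity band -> 8-connected components -> area and
    circularity filters -> border exclusion.

    Accepts a raw 2-D array or a :class:`~phasefit.synthetic.SyntheticImage`
    (whose pixel scale then overrides the params' value).  Returns
    ``(label_mask, regions)`` where the mask relabels passing components
    1..n and ``regions`` is a table of per-cell geometry.
    """
    if isinstance(image, SyntheticImage):
        params = SegmentationParams(**{**params.__dict__, "pixel_scale": image.pixel_scale})
        image = image.pixels
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    scale2 = params.pixel_scale**2
    raw = _label(_band_mask(image, params.cell_intensity), connectivity=2)
    out = np.zeros_like(raw, dtype=np.int32)
    rows = []
    next_id = 0
    h, w = image.shape
    for region in _regionprops(raw):
        rmin, cmin, rmax, cmax = region.bbox
        if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
            continue  # touches the border
        area_um2 = region.area * scale2
        if not _area_in_range(area_um2, params.cell_area_um2):
            continue
        circ = _circularity(region)
        if not params.cell_circularity[0] <= circ <= params.cell_circularity[1]:
            continue
        next_id += 1
        out[raw == region.label] = next_id
        cy, cx = region.centroid
        rows.append({"cell_id": next_id, "area_um2": area_um2,
                     "circularity": circ, "centroid_y": cy, "centroid_x": cx})
    regions = pd.DataFrame(rows, columns=["cell_id", "area_um2", "circularity",
                                          "centroid_y", "centroid_x"])
    return out, regions


def segment_foci(image, cell_mask: np.ndarray, params: SegmentationParams):
    """Detect foci and assign each to the cell containing its centroid.

    Foci whose centroid falls outside every detected cell are discarded.
    Returns ``(foci_label_mask, foci_table)`` with the parent cell id per
    focus.
    """
    if isinstance(image, SyntheticImage):
        params = SegmentationParams(**{**params.__dict__, "pixel_scale": image.pixel_scale})
        image = image.pixels
    image = np.asarray(image)
    scale2 = params.pixel_scale**2
    raw = _label(_band_mask(image, params.foci_intensity), connectivity=2)
    out = np.zeros_like(raw, dtype=np.int32)
    rows = []
    next_id = 0
    for region in _regionprops(raw):
        area_um2 = region.area * scale2
        if not _area_in_range(area_um2, params.foci_area_um2):
            continue
        cy, cx = region.centroid
        parent = int(cell_mask[int(round(cy)), int(round(cx))])
        if parent == 0:
            continue  # outside any cell
        next_id += 1
        out[raw == region.label] = next_id
        rows.append({"focus_id": next_id, "cell_id": parent, "area_um2": area_um2})
    table = pd.DataFrame(rows, columns=["focus_id", "cell_id", "area_um2"])
    return out, table


def measure_cells(image, cell_mask: np.ndarray, foci_mask: np.ndarray,
                  strain: "Strain | str" = Strain.AGG,
                  pixel_scale: float | None = None) -> pd.DataFrame:
    """Integrated fluorescence per cell, partitioned into foci and cytosol.

    F_TOTAL sums the image over the cell region, F_FOCI over the cell's
    foci pixels, F_CYTO is their difference (exact).  Returns the
    canonical cell table plus focus counts and the cytosolic density
    F_CYTO / area.
    """
    if isinstance(image, SyntheticImage):
        if pixel_scale is None:
            pixel_scale = image.pixel_scale
        image = image.pixels
    if pixel_scale is None:
        raise ValueError("pixel_scale required when measuring a raw array")
    image = np.asarray(image, dtype=float)
    strain = Strain.parse(strain)
    scale2 = pixel_scale**2
    rows = []
    for cid in range(1, int(cell_mask.max()) + 1):
        in_cell = cell_mask == cid
        if not in_cell.any():
            continue
        f_total = float(image[in_cell].sum())
        foci_here = np.unique(foci_mask[in_cell & (foci_mask > 0)])
        f_foci = float(image[in_cell & (foci_mask > 0)].sum())
        rows.append({
            "cell_id": cid,
            "strain": strain.name,
            "area_um2": float(in_cell.sum()) * scale2,
            "f_total": f_total,
            "f_foci": f_foci,
            "f_cyto": f_total - f_foci,
            "n_foci": int(foci_here.size),
        })
    cells = pd.DataFrame(rows, columns=["cell_id", *CELL_COLUMNS[1:], "n_foci"])
    if len(cells):
        cells["cyto_density"] = cells["f_cyto"] / cells["area_um2"]
    else:
        cells["cyto_density"] = pd.Series(dtype=float)
    return cells


def match_labels(detected: np.ndarray, truth: np.ndarray) -> dict:
    """Map detected label ids to ground-truth ids by majority pixel overlap.

    Detected regions with no overlap map to 0.  Useful for validating a
    segmentation against a :class:`~phasefit.synthetic.SyntheticImage`'s
    truth masks, where label numbering need not coincide.
    """
    mapping = {}
    for did in range(1, int(detected.max()) + 1):
        overlap = truth[detected == did]
        overlap = overlap[overlap > 0]
        mapping[did] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return mapping


def classify_foci_size(f_foci: float, f_total: float, threshold: float = 0.70) -> str:
    """Classify a cell as BIG when its foci hold at least ``threshold``
    (default 70%) of the total fluorescence, else SMALL."""
    if f_total <= 0:
        raise ValueError("f_total must be positive to classify foci size")
    return "BIG" if f_foci / f_total >= threshold else "SMALL"


def analyze_image(image, params: SegmentationParams,
                  strain: "Strain | str" = Strain.AGG) -> pd.DataFrame:
    """Full per-image pipeline: segment cells, segment foci, measure.

    Adds a ``foci_class`` column (BIG/SMALL) for cells with positive
    total fluorescence.
    """
    if isinstance(image, SyntheticImage):
        params = SegmentationParams(**{**params.__dict__, "pixel_scale": image.pixel_scale})
        pixels = image.pixels
    else:
        pixels = np.asarray(image)
    cell_mask, _ = segment_cells(pixels, params)
    foci_mask, _ = segment_foci(pixels, cell_mask, params)
    cells = measure_cells(pixels, cell_mask, foci_mask, strain=strain,
                          pixel_scale=params.pixel_scale)
    if len(cells):
        cells["foci_class"] = [
            classify_foci_size(ff, ft) if ft > 0 else None
            for ff, ft in zip(cells["f_foci"], cells["f_total"])
        ]
    return cells
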