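"""Envelope-defect quantification: periplasmic leakage and OM blebs.

Both classifiers calibrate a percentile threshold on a reference
population and then apply fixed printed rules:

* **Leakage** — a cell is leaky when its median contour fluorescence
  falls strictly below the 98th percentile of the median contour
  fluorescences of a reference population with known severe outer-
  membrane defects (a ΔtolA-like strain).
* **Blebs** — candidate puncta are connected components of pixels
  brighter than the 99.7th percentile of reference (wild-type) cell
  brightness, outside the cell masks; accepted blebs additionally have
  mean brightness above that threshold, area < 4 µm², and lie within
  0.3 µm of a segmented cell contour.

Quantiles use the linear-interpolation convention throughout, so the
calibrated thresholds are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import STRtree
from shapely.geometry import LineString, Point
from skimage import measure

from .errors import CalibrationError
from .profile import ContourTrace
from .segment import CellObject

DEFAULT_LEAK_QUANTILE = 0.98
DEFAULT_BLEB_QUANTILE = 0.997
DEFAULT_AREA_MAX_UM2 = 4.0
DEFAULT_PROXIMITY_MAX_UM = 0.3
MIN_REFERENCE_CELLS = 50


@dataclass
class LeakageCall:
    cell_id: int
    median_contour_fluorescence: float
    threshold_used: float
    is_leaky: bool


@dataclass
class BlebCall:
    bleb_id: int
    centroid_um: tuple[float, float]    # (y, x) = (row, col) * pixel_size
    area_um2: float
    mean_brightness: float
    distance_to_nearest_cell_um: float
    cell_id: int | None


def leakage_threshold(
    reference_traces: list[ContourTrace],
    quantile: float = DEFAULT_LEAK_QUANTILE,
    min_reference: int = MIN_REFERENCE_CELLS,
) -> float:
    """Percentile threshold from a leaky reference population.

    The per-cell median contour fluorescences are pooled and the
    `quantile` (default 98th percentile, linear interpolation) is
    returned.  Raises CalibrationError below `min_reference` cells.
    """
    if len(reference_traces) < min_reference:
        raise CalibrationError(
            f"need at least {min_reference} reference cells, got {len(reference_traces)}"
        )
    medians = np.array([t.median_value for t in reference_traces], dtype=float)
    return float(np.quantile(medians, quantile))


def classify_leakage(
    traces: list[ContourTrace], threshold: float
) -> list[LeakageCall]:
    """Call leakage by strict comparison of each median to the threshold.

    A median exactly equal to the threshold is *not* leaky (strict `<`).
    """
    return [
        LeakageCall(
            cell_id=t.cell_id,
            median_contour_fluorescence=t.median_value,
            threshold_used=threshold,
            is_leaky=bool(t.median_value < threshold),
        )
        for t in traces
    ]


class LeakageClassifier:
    """Calibrate-then-classify wrapper around the leakage rule.

    Parameters
    ----------
    quantile : percentile of the reference medians used as threshold.
    min_reference : minimum reference population size.

    After `fit`, `threshold_` and `n_reference_` are set.
    """

    def __init__(
        self,
        quantile: float = DEFAULT_LEAK_QUANTILE,
        min_reference: int = MIN_REFERENCE_CELLS,
    ):
        self.quantile = quantile
        self.min_reference = min_reference

    def fit(self, reference_traces: list[ContourTrace]) -> "LeakageClassifier":
        self.threshold_ = leakage_threshold(
            reference_traces, self.quantile, self.min_reference
        )
        self.n_reference_ = len(reference_traces)
        return self

    def predict(self, traces: list[ContourTrace]) -> list[LeakageCall]:
        if not hasattr(self, "threshold_"):
            raise CalibrationError("classifier not fitted")
        return classify_leakage(traces, self.threshold_)


def brightness_reference(
    reference_cells: list[CellObject],
    fluor_image: np.ndarray,
    quantile: float = DEFAULT_BLEB_QUANTILE,
    min_reference: int = MIN_REFERENCE_CELLS,
    mode: str = "per_pixel",
) -> float:
    """Brightness threshold from reference (wild-type) cells.

    mode='per_pixel' pools every pixel inside the reference masks and
    takes the `quantile` (default 99.7th percentile) of the pooled
    values; puncta are pixel-scale objects, so a pixel-level null is the
    comparison that matters.  mode='per_cell_mean' instead takes the
    quantile over per-cell mean brightnesses.
    """
    if len(reference_cells) < min_reference:
        raise CalibrationError(
            f"need at least {min_reference} reference cells, got {len(reference_cells)}"
        )
    if mode == "per_pixel":
        pooled = np.concatenate(
            [fluor_image[cell.mask_pixels()].ravel() for cell in reference_cells]
        )
    elif mode == "per_cell_mean":
        pooled = np.array(
            [float(np.mean(fluor_image[cell.mask_pixels()])) for cell in reference_cells]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.quantile(pooled.astype(float), quantile))


def detect_blebs(
    fluor_image: np.ndarray,
    cells: list[CellObject],
    brightness_threshold: float,
    pixel_size: float,
    area_max_um2: float = DEFAULT_AREA_MAX_UM2,
    proximity_max_um: float = DEFAULT_PROXIMITY_MAX_UM,
) -> list[BlebCall]:
    """Detect OM blebs/vesicles as isolated bright puncta near cells.

    Candidates are 8-connected components of pixels strictly above
    `brightness_threshold` lying outside every cell mask (blebs are
    extracellular structures).  A candidate is accepted iff its mean
    brightness exceeds the threshold, its area is strictly below
    `area_max_um2`, and its minimum Euclidean distance to a cell contour
    polyline is at most `proximity_max_um`; it is assigned to that
    nearest cell.  Distances are sub-pixel (pixel centres to contour
    polylines).  An empty list is a valid result.
    """
    fluor_image = np.asarray(fluor_image, dtype=float)
    cell_union = np.zeros(fluor_image.shape, dtype=bool)
    for cell in cells:
        rows, cols = cell.mask_pixels()
        cell_union[rows, cols] = True

    candidates = (fluor_image > brightness_threshold) & ~cell_union
    labels = measure.label(candidates, connectivity=2)

    contours = [
        LineString(np.vstack([cell.contour, cell.contour[:1]]))
        for cell in cells
    ]
    tree = STRtree(contours) if contours else None

    calls: list[BlebCall] = []
    bleb_id = 0
    for region in measure.regionprops(labels, intensity_image=fluor_image):
        area_um2 = region.area * pixel_size**2
        if area_um2 >= area_max_um2:
            continue
        mean_brightness = float(region.intensity_mean)
        if mean_brightness <= brightness_threshold:
            continue
        if tree is None:
            continue
        pts = [Point(r, c) for r, c in region.coords]
        best_dist_px = np.inf
        best_cell = None
        for pt in pts:
            idx = int(tree.nearest(pt))
            d = pt.distance(contours[idx])
            if d < best_dist_px:
                best_dist_px, best_cell = d, idx
        dist_um = best_dist_px * pixel_size
        if dist_um > proximity_max_um:
            continue
        bleb_id += 1
        cy, cx = region.centroid
        calls.append(
            BlebCall(
                bleb_id=bleb_id,
                centroid_um=(cy * pixel_size, cx * pixel_size),
                area_um2=area_um2,
                mean_brightness=mean_brightness,
                distance_to_nearest_cell_um=dist_um,
                cell_id=cells[best_cell].cell_id if best_cell is not None else None,
            )
        )
    return calls


class BlebDetector:
    """Calibrate-then-detect wrapper around the bleb rules.

    `fit` computes the brightness threshold from wild-type reference
    cells; `detect` applies the three printed rules (brightness, area,
    proximity).  After `fit`, `brightness_threshold_` is set.
    """

    def __init__(
        self,
        quantile: float = DEFAULT_BLEB_QUANTILE,
        area_max_um2: float = DEFAULT_AREA_MAX_UM2,
        proximity_max_um: float = DEFAULT_PROXIMITY_MAX_UM,
        min_reference: int = MIN_REFERENCE_CELLS,
        mode: str = "per_pixel",
    ):
        self.quantile = quantile
        self.area_max_um2 = area_max_um2
        self.proximity_max_um = proximity_max_um
        self.min_reference = min_reference
        self.mode = mode

    def fit(
        self, reference_cells: list[CellObject], fluor_image: np.ndarray
    ) -> "BlebDetector":
        self.brightness_threshold_ = brightness_reference(
            reference_cells, fluor_image, self.quantile, self.min_reference, self.mode
        )
        return self

    def detect(
        self,
        fluor_image: np.ndarray,
        cells: list[CellObject],
        pixel_size: float,
    ) -> list[BlebCall]:
        if not hasattr(self, "brightness_threshold_"):
            raise CalibrationError("detector not fitted")
        return detect_blebs(
            fluor_image,
            cells,
            self.brightness_threshold_,
            pixel_size,
            self.area_max_um2,
            self.proximity_max_um,
        )
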