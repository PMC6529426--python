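"""Green-channel segmentation and per-object measurement.

The chain implemented here turns a green-channel micrograph into a table of
single-cell measurements:

1. a global Otsu threshold on the 256-bin intensity histogram;
2. binarization (foreground = intensity strictly above ``t * 255``);
3. connected-component labeling (8-connectivity by default);
4. removal of objects under 100 pixels or touching the image edge;
5. per-object measurement on the hole-filled mask: area, boundary-trace
   perimeter, mean green intensity;
6. a morphological filter keeping objects with area in [300, 1000] px and
   perimeter <= 165 px, the operating range of a single bacterial cell at
   the acquisition magnification.

An optional rolling-ball background subtraction (grayscale opening with a
spherical-cap structuring element) is provided for stains that need it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _sk_label
from skimage.morphology import thin as _sk_thin

logger = logging.getLogger(__name__)


class DegenerateHistogramError(ValueError):
    """The image has a single intensity value and cannot be thresholded."""


class ParameterError(ValueError):
    """A filter or structuring-element parameter is out of range."""


@dataclass
class FilterParams:
    """Object- and dataset-level filter constants.

    Defaults are the published operating values: objects under
    ``min_object_px`` (100 px) or touching the edge are discarded before
    measurement; only cells with area in ``[area_min, area_max]``
    (300-1000 px) and perimeter at most ``perimeter_max`` (165 px) are
    retained; images whose Otsu threshold falls more than
    ``qc_sd_multiplier`` standard deviations from the dataset mean are
    dropped.  ``rolling_ball_radius`` (20 px) applies only when background
    subtraction is enabled.
    """

    min_object_px: int = 100
    area_min: int = 300
    area_max: int = 1000
    perimeter_max: int = 165
    qc_sd_multiplier: float = 1.0
    connectivity: int = 8
    rolling_ball_radius: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.area_min <= self.area_max):
            raise ParameterError(
                f"need 0 < area_min <= area_max, got [{self.area_min}, {self.area_max}]"
            )
        if self.min_object_px <= 0:
            raise ParameterError("min_object_px must be positive")
        if self.perimeter_max <= 0:
            raise ParameterError("perimeter_max must be positive")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass
class BinaryMask:
    pixels: np.ndarray  # H x W boolean
    threshold_used: float  # normalized to [0, 1]


@dataclass
class LabeledObjects:
    """Connected foreground components, labeled 1..n_objects in raster-scan
    order of each component's first pixel (0 = background)."""

    labels: np.ndarray
    n_objects: int


@dataclass
class ObjectMeasurement:
    """Measurements of one labeled object, taken on its hole-filled mask."""

    object_id: int
    area: int
    perimeter: int
    mean_intensity: float
    touches_edge: bool
    centroid: tuple[float, float]
    image_id: str = ""


def otsu_threshold(img) -> float:
    """Global Otsu threshold of an 8-bit image, normalized to [0, 1].

    The threshold is the cut level ``k`` (foreground = intensity > k)
    maximizing the between-class variance of the 256-bin histogram,
    returned as ``k / 255``.  When several cuts tie, the lowest is
    returned, so the result is deterministic.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (a single histogram bin): no cut separates
        two classes and the caller should drop the image with a warning.
    """
    px = np.asarray(getattr(img, "pixels", img))
    counts = np.bincount(px.ravel().astype(np.int64), minlength=256)[:256].astype(float)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "constant image: histogram has a single bin, Otsu threshold undefined"
        )
    total = counts.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(counts)  # weight of class {<= k} for each cut k
    m0 = np.cumsum(counts * levels)
    mean_all = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / (total - w0)
        between = w0 * (total - w0) * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf  # cuts leaving an empty class
    k = int(np.argmax(between))  # argmax takes the first (lowest) maximizer
    return k / 255.0


def binarize(img, t: float) -> BinaryMask:
    """Threshold a scalar image at normalized level ``t``.

    A pixel is foreground iff its intensity is strictly greater than
    ``t * 255``.
    """
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"normalized threshold must be in [0, 1], got {t}")
    px = np.asarray(getattr(img, "pixels", img))
    return BinaryMask(pixels=px > t * 255.0, threshold_used=float(t))


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def label_objects(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> LabeledObjects:
    """Label maximal connected foreground components.

    Labels are consecutive integers 1..n in raster-scan order of each
    component's first pixel; an empty mask yields ``n_objects = 0``.
    """
    px = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = _sk_label(px, connectivity=2 if connectivity == 8 else 1, return_num=True)
    return LabeledObjects(labels=labels.astype(np.int32), n_objects=int(n))


def remove_small_and_edge(objs: LabeledObjects, params: FilterParams) -> LabeledObjects:
    """Drop objects with fewer than ``min_object_px`` raw pixels ("less
    than" is strict: a 100-px object survives) or with any pixel on the
    first/last row or column.  Survivors are relabeled 1..n preserving the
    original order."""
    labels = objs.labels
    n = objs.n_objects
    if n == 0:
        return LabeledObjects(labels=labels.copy(), n_objects=0)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    edge_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    keep = counts >= params.min_object_px
    keep[0] = False
    keep[edge_labels] = False
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return LabeledObjects(labels=mapping[labels], n_objects=int(keep.sum()))


def measure_objects(objs: LabeledObjects, img) -> list[ObjectMeasurement]:
    """Measure area, perimeter and mean intensity of each labeled object.

    Interior holes are filled first and the filled mask is used for all
    three measurements.  Area is the filled pixel count.  Perimeter is the
    pixel count of the object's unit-width boundary trace: the filled-mask
    pixels with at least one background 8-neighbor; for line-like objects
    with no interior (where that set is the whole object) the mask is
    thinned to unit width instead.  Mean intensity is the arithmetic mean
    of the green channel over the filled mask.
    """
    px = np.asarray(getattr(img, "pixels", img))
    image_id = getattr(img, "id", "")
    labels = objs.labels
    if labels.shape != px.shape:
        raise ParameterError(
            f"label map shape {labels.shape} != image shape {px.shape}"
        )
    H, W = labels.shape
    full = np.ones((3, 3), dtype=bool)
    out: list[ObjectMeasurement] = []
    slices = ndi.find_objects(labels, max_label=objs.n_objects)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rs, cs = sl
        mask = labels[sl] == lab
        filled = ndi.binary_fill_holes(mask)
        area = int(filled.sum())
        # pad so boundary detection sees background beyond the crop
        padded = np.pad(filled, 1)
        interior = ndi.binary_erosion(padded, structure=full)
        if interior.any():
            boundary = padded & ~interior
            perimeter = int(boundary.sum())
        else:
            perimeter = int(_sk_thin(padded).sum())
        touches_edge = bool(
            (rs.start == 0 and filled[0, :].any())
            or (rs.stop == H and filled[-1, :].any())
            or (cs.start == 0 and filled[:, 0].any())
            or (cs.stop == W and filled[:, -1].any())
        )
        rows, cols = np.nonzero(filled)
        centroid = (float(rows.mean() + rs.start), float(cols.mean() + cs.start))
        mean_intensity = float(px[sl][filled].mean())
        out.append(
            ObjectMeasurement(
                object_id=lab,
                area=area,
                perimeter=perimeter,
                mean_intensity=mean_intensity,
                touches_edge=touches_edge,
                centroid=centroid,
                image_id=image_id,
            )
        )
    return out


def morphological_filter(
    measurements: list[ObjectMeasurement], params: FilterParams, group: str = ""
):
    """Keep measurements with ``area_min <= area <= area_max`` (both bounds
    inclusive) and ``perimeter <= perimeter_max``; the single-cell
    morphology window."""
    from .stats import CellTable

    rows = [
        m
        for m in measurements
        if params.area_min <= m.area <= params.area_max
        and m.perimeter <= params.perimeter_max
    ]
    return CellTable(group=group, rows=rows)


def _ball_element(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and cap heights of a spherical-cap structuring element."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= r**2
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(r**2 - d2[footprint])
    return footprint, heights


def rolling_ball_subtract(img, radius: int = 20):
    """Subtract the rolling-ball background estimate from an image.

    The background is the grayscale opening of the image with a
    spherical-cap (ball) structuring element of the given radius in pixels:
    the surface traced by the top of a ball of that radius rolled under the
    intensity landscape.  Edges are handled by replication.  Negative
    residuals are clamped to 0.  Flat backgrounds map to exactly 0; peaks
    narrower than the ball footprint are preserved.

    Returns a new object of the same kind as ``img`` with float pixels.
    """
    from .io import ScalarImage

    px = np.asarray(getattr(img, "pixels", img)).astype(float)
    if radius < 1:
        raise ParameterError(f"rolling-ball radius must be >= 1, got {radius}")
    if radius > px.shape[0] and radius > px.shape[1]:
        raise ParameterError(
            f"rolling-ball radius {radius} exceeds both image dimensions {px.shape}"
        )
    footprint, heights = _ball_element(radius)
    eroded = ndi.grey_erosion(px, structure=heights, footprint=footprint, mode="nearest")
    background = ndi.grey_dilation(
        eroded, structure=heights, footprint=footprint, mode="nearest"
    )
    result = np.clip(px - background, 0.0, None)
    if hasattr(img, "pixels"):
        return ScalarImage(
            pixels=result, id=getattr(img, "id", ""), group=getattr(img, "group", "")
        )
    return result


def segment_image(
    img, params: FilterParams | None = None, group: str = ""
):
    """Run the full per-image chain: Otsu, binarize, label, small/edge
    removal, measurement, morphological filter.

    Returns ``(CellTable, stage_counts)`` where ``stage_counts`` maps stage
    names to object counts, for the per-image QC log.
    """
    params = params or FilterParams()
    t = otsu_threshold(img)
    mask = binarize(img, t)
    objs = label_objects(mask, connectivity=params.connectivity)
    n_raw = objs.n_objects
    objs = remove_small_and_edge(objs, params)
    measurements = measure_objects(objs, img)
    table = morphological_filter(measurements, params, group=group)
    counts = {
        "labeled": n_raw,
        "after_small_edge": objs.n_objects,
        "after_morphology": table.n_cells,
    }
    logger.info(
        "image %s: otsu=%.4f objects=%d after_small_edge=%d cells=%d",
        getattr(img, "id", "?"), t, n_raw, objs.n_objects, table.n_cells,
    )
    return table, counts
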