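"""Raster and tabular I/O for the quantification pipeline.

Raster convention used throughout the package: row-major arrays, origin at
the top-left corner, ``(row, col)`` indexing, 0-based.  Micrographs are
8-bit RGB (channel order red, green, blue); the green channel carries the
ThT signal and is the only channel measured.

Tabular outputs are RFC-4180 CSV with ``.`` as the decimal separator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np


class FormatError(ValueError):
    """An input file does not satisfy the expected raster layout."""


@dataclass
class RasterImage:
    """An 8-bit RGB micrograph.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``H x W x 3`` array of uint8 intensities, channels in RGB order.
    id : str
        Image identifier (derived from the filename on read).
    group : str
        Condition / time-point label, e.g. ``"toxin_0h"``.
    """

    pixels: np.ndarray
    id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"RasterImage requires an H x W x 3 array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise FormatError(
                    f"RasterImage requires 8-bit intensities, got dtype {px.dtype}"
                )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ScalarImage:
    """A single-channel working image.

    Integer 8-bit on input; real-valued (still >= 0) after background
    subtraction.
    """

    pixels: np.ndarray
    id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(
                f"ScalarImage requires an H x W array, got shape {px.shape}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | Path, group: str = "", *, allow_grayscale: bool = False) -> RasterImage:
    """Read an 8-bit RGB TIFF or PNG micrograph.

    Parameters
    ----------
    path : path-like
        File to read.  Must decode as 8-bit RGB (or, with
        ``allow_grayscale=True``, 8-bit single-plane, which is replicated
        into three identical channels).
    group : str
        Condition label attached to the returned image.
    allow_grayscale : bool
        Accept single-plane images by replicating the plane.  Off by
        default: the quantification procedure is defined on RGB input.

    Raises
    ------
    FormatError
        If the file is not 8-bit, not RGB (without the flag), or carries an
        alpha channel.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific error types vary
        raise FormatError(f"cannot decode {path.name}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path.name}: bit depth is {arr.dtype}, expected 8-bit"
        )
    if arr.ndim == 2:
        if not allow_grayscale:
            raise FormatError(
                f"{path.name}: grayscale image; pass allow_grayscale=True to "
                "replicate the plane into RGB"
            )
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        raise FormatError(f"{path.name}: RGBA layout; expected 3-channel RGB")
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path.name}: unexpected layout with shape {arr.shape}; expected RGB"
        )
    return RasterImage(pixels=arr, id=path.stem, group=group)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write an RGB image as 8-bit PNG or TIFF (by extension)."""
    iio.imwrite(Path(path), img.pixels)


def extract_green(img: RasterImage) -> ScalarImage:
    """Return the green channel as the working scalar image.

    Only the green channel of the RGB micrograph is used for processing;
    ``id`` and ``group`` are carried over.
    """
    return ScalarImage(pixels=img.pixels[:, :, 1].copy(), id=img.id, group=img.group)


CELL_TABLE_HEADER = [
    "image_id",
    "object_id",
    "area",
    "perimeter",
    "mean_intensity",
    "centroid_row",
    "centroid_col",
]

COMPARISON_HEADER = [
    "group_a",
    "group_b",
    "n_a",
    "n_b",
    "fc",
    "u_stat",
    "p_value",
    "p10_a",
    "p25_a",
    "p50_a",
    "p75_a",
    "p90_a",
    "p10_b",
    "p25_b",
    "p50_b",
    "p75_b",
    "p90_b",
]


def write_cell_table(table: "CellTable", path: str | Path) -> None:
    """Write one row per surviving cell: image id, object id, area,
    perimeter, mean intensity, centroid."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CELL_TABLE_HEADER)
        for m in table.rows:
            writer.writerow(
                [
                    m.image_id,
                    m.object_id,
                    m.area,
                    m.perimeter,
                    repr(float(m.mean_intensity)),
                    repr(float(m.centroid[0])),
                    repr(float(m.centroid[1])),
                ]
            )


def read_cell_table(path: str | Path, group: str = "") -> "CellTable":
    """Read a cell table CSV written by :func:`write_cell_table`."""
    from .segmentation import ObjectMeasurement
    from .stats import CellTable

    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CELL_TABLE_HEADER:
            raise FormatError(f"{path}: unexpected cell-table header {reader.fieldnames}")
        for rec in reader:
            rows.append(
                ObjectMeasurement(
                    object_id=int(rec["object_id"]),
                    area=int(rec["area"]),
                    perimeter=int(rec["perimeter"]),
                    mean_intensity=float(rec["mean_intensity"]),
                    touches_edge=False,
                    centroid=(float(rec["centroid_row"]), float(rec["centroid_col"])),
                    image_id=rec["image_id"],
                )
            )
    return CellTable(group=group, rows=rows)


def write_comparison(result: "ComparisonResult", path: str | Path) -> None:
    """Write a one-row CSV: group labels, n per group, FC, U, p and the
    10/25/50/75/90 percentiles of each group."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPARISON_HEADER)
        writer.writerow(
            [result.group_a, result.group_b, result.n_a, result.n_b,
             repr(float(result.fc)), repr(float(result.u_stat)),
             repr(float(result.p_value))]
            + [repr(float(v)) for v in result.percentiles_a]
            + [repr(float(v)) for v in result.percentiles_b]
        )


def read_comparison(path: str | Path) -> "ComparisonResult":
    """Read a comparison CSV written by :func:`write_comparison`."""
    from .stats import ComparisonResult

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COMPARISON_HEADER:
            raise FormatError(f"{path}: unexpected comparison header {reader.fieldnames}")
        rec = next(iter(reader))
    return ComparisonResult(
        group_a=rec["group_a"],
        group_b=rec["group_b"],
        n_a=int(rec["n_a"]),
        n_b=int(rec["n_b"]),
        fc=float(rec["fc"]),
        u_stat=float(rec["u_stat"]),
        p_value=float(rec["p_value"]),
        percentiles_a=tuple(float(rec[f"p{q}_a"]) for q in (10, 25, 50, 75, 90)),
        percentiles_b=tuple(float(rec[f"p{q}_b"]) for q in (10, 25, 50, 75, 90)),
    )
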