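"""Seeded synthetic micrographs of ThT-stained bacterial fields.

No raw micrographs are published for this assay, so the generator produces
images with known ground truth that exercise every stage of the pipeline:
a dark background with additive Gaussian noise and bright quasi-elliptical
cells whose per-cell mean green intensity is drawn from a condition-specific
normal distribution (truncated to the 8-bit range), plus controlled
fractions of sub-100-px debris, edge-touching cells, and merged pairs
("clumps") whose union exceeds the 1000-px single-cell limit.

Cells are rendered as filled ellipses — a deliberate simplification of
rod-shaped bacteria with the same behavior under the area and perimeter
filters.  Scenes are deterministic given the seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .io import RasterImage


class GenerationError(RuntimeError):
    """The requested scene cannot be realized (cells do not fit)."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic micrograph.

    Geometry defaults give filled ellipse areas of roughly 300-800 px and
    boundary perimeters well under 165 px, i.e. single cells inside the
    morphological acceptance window at the emulated magnification.
    Intensities are on the 8-bit scale: per-cell mean ~ N(mean_intensity,
    cell_sigma) truncated to [0, 255], pixel noise ~ N(0, pixel_sigma),
    background ~ N(background_mean, background_sigma).
    """

    height: int = 512
    width: int = 512
    n_cells: int = 45
    major_axis_range: tuple[float, float] = (16.0, 26.0)  # semi-axis, px
    minor_axis_range: tuple[float, float] = (6.0, 10.0)  # semi-axis, px
    mean_intensity: float = 120.0
    cell_sigma: float = 15.0
    pixel_sigma: float = 10.0
    background_mean: float = 8.0
    background_sigma: float = 3.0
    fraction_small: float = 0.1
    fraction_edge: float = 0.1
    fraction_clump: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.fraction_small, self.fraction_edge, self.fraction_clump)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError(f"category fractions must lie in [0,1] and sum <= 1: {fracs}")
        if self.height < 1 or self.width < 1 or self.n_cells < 0:
            raise ValueError("height, width must be >= 1 and n_cells >= 0")

    def category_counts(self) -> dict[str, int]:
        """Deterministic per-category cell counts (clumps come in pairs)."""
        n_small = round(self.fraction_small * self.n_cells)
        n_edge = round(self.fraction_edge * self.n_cells)
        n_clump = 2 * (round(self.fraction_clump * self.n_cells) // 2)
        n_in = self.n_cells - n_small - n_edge - n_clump
        if n_in < 0:
            raise ValueError("category fractions leave no room for in-range cells")
        return {"in-range": n_in, "small": n_small, "edge": n_edge, "clump": n_clump}

    def to_config(self) -> str:
        """Serialize as plain-text ``key = value`` lines."""
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SceneSpec":
        kwargs = {}
        casts = {f.name: f for f in fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in casts:
                raise ValueError(f"unknown scene parameter {key!r}")
            if key.endswith("_range"):
                lo, hi = val.split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key in ("height", "width", "n_cells", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (major, minor), px
    orientation: float  # radians
    true_mean: float
    category: str  # in-range | small | edge | clump-member


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    label_mask: np.ndarray  # H x W int32; clump members keep distinct labels

    def in_range_means(self) -> np.ndarray:
        return np.array(
            [c.true_mean for c in self.cells if c.category == "in-range"], dtype=float
        )


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Draw from N(mu, sigma) truncated to [0, 255] by resampling."""
    if sigma == 0:
        return float(np.clip(mu, 0.0, 255.0))
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if 0.0 <= x <= 255.0:
            return float(x)
    raise GenerationError(f"cannot draw intensity in [0,255] from N({mu}, {sigma})")


def _ellipse_pixels(center, axes, theta, shape):
    rr, cc = _draw_ellipse(center[0], center[1], axes[1], axes[0],
                           shape=shape, rotation=theta)
    return rr, cc


def generate_scene(spec: SceneSpec) -> tuple[RasterImage, GroundTruth]:
    """Render one synthetic micrograph with its ground truth.

    The background field is rendered first; cells are composited onto the
    green channel by per-pixel maximum, then all channels are clipped to
    [0, 255] and quantized to 8 bits.  Red and blue carry background only.
    Non-clump cells are placed by rejection sampling until disjoint (with a
    2-px separation margin); an unplaceable spec raises
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    counts = spec.category_counts()

    green = spec.background_mean + rng.normal(0.0, spec.background_sigma, (H, W))
    occupancy = np.zeros((H, W), dtype=bool)
    label_mask = np.zeros((H, W), dtype=np.int32)
    cells: list[CellTruth] = []
    max_tries = 200

    def draw_geometry(kind: str):
        if kind == "small":
            a = rng.uniform(3.0, 5.0)
            b = rng.uniform(2.0, 3.0)
        else:
            a = rng.uniform(*spec.major_axis_range)
            b = rng.uniform(*spec.minor_axis_range)
        theta = rng.uniform(0.0, math.pi)
        return a, b, theta

    def try_place(kind: str):
        """Find a non-overlapping position; returns (center, axes, theta, rr, cc)."""
        for _ in range(max_tries):
            a, b, theta = draw_geometry(kind)
            pad = a + 3.0
            if kind == "edge":
                side = rng.integers(0, 4)
                d = rng.uniform(0.0, b / 2.0)  # < minor semi-axis: must cross
                if side == 0:
                    r0, c0 = d, rng.uniform(pad, W - pad)
                elif side == 1:
                    r0, c0 = H - 1 - d, rng.uniform(pad, W - pad)
                elif side == 2:
                    r0, c0 = rng.uniform(pad, H - pad), d
                else:
                    r0, c0 = rng.uniform(pad, H - pad), W - 1 - d
            else:
                if H - 2 * pad <= 0 or W - 2 * pad <= 0:
                    raise GenerationError(
                        f"cells of extent {pad:.0f} px cannot fit in {H}x{W}"
                    )
                r0 = rng.uniform(pad, H - pad)
                c0 = rng.uniform(pad, W - pad)
            grr, gcc = _ellipse_pixels((r0, c0), (a + 2, b + 2), theta, (H, W))
            if not occupancy[grr, gcc].any():
                rr, cc = _ellipse_pixels((r0, c0), (a, b), theta, (H, W))
                return (r0, c0), (a, b), theta, rr, cc, grr, gcc
        raise GenerationError(
            f"could not place a {kind} cell after {max_tries} attempts; "
            "reduce n_cells or enlarge the image"
        )

    def stamp(center, axes, theta, rr, cc, grr, gcc, category):
        mean = _truncated_normal(rng, spec.mean_intensity, spec.cell_sigma)
        vals = mean + (
            rng.normal(0.0, spec.pixel_sigma, rr.size) if spec.pixel_sigma > 0 else 0.0
        )
        np.maximum.at(green, (rr, cc), vals)
        occupancy[grr, gcc] = True
        label_mask[rr, cc] = len(cells) + 1
        cells.append(CellTruth(center, axes, theta, mean, category))

    for _ in range(counts["in-range"]):
        stamp(*try_place("in-range"), "in-range")
    for _ in range(counts["small"]):
        stamp(*try_place("small"), "small")
    for _ in range(counts["edge"]):
        stamp(*try_place("edge"), "edge")

    # clump pairs: second member offset so the union is connected and > 1000 px
    for _ in range(counts["clump"] // 2):
        for _try in range(max_tries):
            center, axes, theta, rr, cc, grr, gcc = try_place("in-range")
            a1, b1 = axes
            a2 = rng.uniform(*spec.major_axis_range)
            b2 = rng.uniform(*spec.minor_axis_range)
            th2 = rng.uniform(0.0, math.pi)
            phi = rng.uniform(0.0, 2 * math.pi)
            dist = 0.9 * (b1 + b2)
            r2 = center[0] + dist * math.sin(phi)
            c2 = center[1] + dist * math.cos(phi)
            if not (a2 + 3 <= r2 <= H - a2 - 3 and a2 + 3 <= c2 <= W - a2 - 3):
                continue
            rr2, cc2 = _ellipse_pixels((r2, c2), (a2, b2), th2, (H, W))
            grr2, gcc2 = _ellipse_pixels((r2, c2), (a2 + 2, b2 + 2), th2, (H, W))
            # member 2 may only touch member 1, nothing else
            probe = occupancy.copy()
            probe[grr, gcc] = False
            if probe[grr2, gcc2].any():
                continue
            union = np.zeros((H, W), dtype=bool)
            union[rr, cc] = True
            n1 = int(union.sum())
            union[rr2, cc2] = True
            if int(union.sum()) <= 1000 or int(union.sum()) == n1 + rr2.size:
                continue  # too small or not actually merged
            stamp(center, axes, theta, rr, cc, grr, gcc, "clump-member")
            stamp((r2, c2), (a2, b2), th2, rr2, cc2, grr2, gcc2, "clump-member")
            break
        else:
            raise GenerationError("could not place a clump pair")

    red = spec.background_mean + rng.normal(0.0, spec.background_sigma, (H, W))
    blue = spec.background_mean + rng.normal(0.0, spec.background_sigma, (H, W))
    rgb = np.stack([red, green, blue], axis=-1)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    img = RasterImage(pixels=pixels, id=f"scene_{spec.seed}", group="")
    return img, GroundTruth(cells=cells, label_mask=label_mask)


def generate_experiment(
    spec_before: SceneSpec,
    spec_after: SceneSpec | None = None,
    n_images: int = 30,
    *,
    ratio: float | None = None,
    seed: int | None = None,
    labels: tuple[str, str] = ("before", "after"),
) -> dict[str, list[tuple[RasterImage, GroundTruth]]]:
    """Generate two labeled groups of seeded scenes.

    The after-group per-cell intensity mean is ``ratio`` times the
    before-group mean (``spec_after`` may instead be given explicitly).
    Per-image seeds are derived from ``seed`` (default: the before-spec
    seed), so the whole experiment is reproducible from one integer.
    """
    if spec_after is None:
        if ratio is None:
            raise ValueError("give either spec_after or ratio")
        if ratio <= 0:
            raise ValueError(f"intensity ratio must be positive, got {ratio}")
        spec_after = replace(spec_before, mean_intensity=ratio * spec_before.mean_intensity)
    if n_images < 2:
        raise ValueError("need at least 2 images per group")
    root = np.random.default_rng(spec_before.seed if seed is None else seed)
    out: dict[str, list[tuple[RasterImage, GroundTruth]]] = {}
    for label, spec in zip(labels, (spec_before, spec_after)):
        scenes = []
        for i in range(n_images):
            sub = int(root.integers(0, 2**31 - 1))
            img, gt = generate_scene(replace(spec, seed=sub))
            img.id = f"{label}_{i:03d}"
            img.group = label
            scenes.append((img, gt))
        out[label] = scenes
    return out


def ground_truth_rows(image_id: str, gt: GroundTruth) -> list[dict]:
    """Flatten one scene's ground truth to CSV-ready records."""
    return [
        {
            "image_id": image_id,
            "cell_index": i + 1,
            "center_row": f"{c.center[0]:.2f}",
            "center_col": f"{c.center[1]:.2f}",
            "semi_major": f"{c.semi_axes[0]:.2f}",
            "semi_minor": f"{c.semi_axes[1]:.2f}",
            "orientation": f"{c.orientation:.4f}",
            "true_mean": f"{c.true_mean:.4f}",
            "category": c.category,
        }
        for i, c in enumerate(gt.cells)
    ]


def write_scene(img: RasterImage, gt: GroundTruth, directory: str | Path) -> None:
    """Write a scene as 8-bit RGB PNG plus ground-truth CSV and label-mask PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{img.id}.png", img.pixels)
    mask = gt.label_mask
    mask_u = mask.astype(np.uint16) if mask.max() > 255 else mask.astype(np.uint8)
    iio.imwrite(directory / f"{img.id}_labels.png", mask_u)
    rows = ground_truth_rows(img.id, gt)
    with open(directory / f"{img.id}_truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "image_id", "cell_index", "center_row", "center_col",
                "semi_major", "semi_minor", "orientation", "true_mean", "category",
            ],
        )
        writer.writeheader()
        writer.writerows(rows)
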