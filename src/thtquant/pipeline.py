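"""End-to-end orchestration: micrographs in, comparison statistics out.

For each of exactly two condition groups the pipeline reads the images,
takes the green channel (optionally rolling-ball background-subtracted),
computes per-image Otsu thresholds, applies the dataset threshold QC,
segments and measures the kept images, and pools the surviving cells
across images into one :class:`~thtquant.stats.CellTable` per group.  The
two tables are then compared (percentile summary, Mann-Whitney U, fold
change).  Every stage's object counts are logged, and per-cell, QC and
comparison CSVs are written.

Cells are pooled across images within a group; per-image survivor counts
remain available in the stage log to expose image-level batch effects.
Rolling-ball preprocessing is OFF by default: ThT quantification operates
on the raw green channel.
"""

from __future__ import annotations

import glob as _glob
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as tio
from .qc import DatasetQC, ThresholdRecord, threshold_filter, write_qc_report
from .segmentation import (
    DegenerateHistogramError,
    FilterParams,
    binarize,
    label_objects,
    measure_objects,
    morphological_filter,
    remove_small_and_edge,
    rolling_ball_subtract,
)
from .segmentation import otsu_threshold
from .stats import CellTable, ComparisonResult, compare_cell_tables

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """The pipeline cannot produce a comparison (e.g. a group lost all images)."""


@dataclass
class PipelineConfig:
    """Configuration of one comparison run.

    ``groups`` maps exactly two condition labels to directory globs, in
    (before, after) order.
    """

    groups: dict[str, str]
    params: FilterParams = field(default_factory=FilterParams)
    fc_mode: str = "mean"
    rolling_ball: bool = False
    output_dir: str | Path = "thtquant_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError(
                f"a comparison run needs exactly two groups, got {list(self.groups)}"
            )


@dataclass
class GroupAnalysis:
    """Per-group intermediate results, kept for reporting."""

    table: CellTable
    records: list[ThresholdRecord]
    qc: DatasetQC
    stage_counts: dict[str, dict[str, int]]  # image_id -> stage -> count
    skipped: list[str]  # degenerate (constant) images


def analyze_green_images(
    images: list, group: str, params: FilterParams | None = None,
    rolling_ball: bool = False,
) -> GroupAnalysis:
    """Segment and pool a list of green-channel images for one group.

    Constant images (undefined Otsu threshold) are skipped with a warning.
    Raises :class:`PipelineError` if QC keeps no image.
    """
    params = params or FilterParams()
    if rolling_ball:
        images = [rolling_ball_subtract(im, params.rolling_ball_radius) for im in images]
    records: list[ThresholdRecord] = []
    usable = {}
    skipped: list[str] = []
    for im in images:
        try:
            t = otsu_threshold(im)
        except DegenerateHistogramError:
            logger.warning("image %s is constant; skipped", getattr(im, "id", "?"))
            skipped.append(getattr(im, "id", "?"))
            continue
        records.append(ThresholdRecord(image_id=im.id, threshold=t, group=group))
        usable[im.id] = (im, t)
    if len(records) < 2:
        raise PipelineError(
            f"group {group!r}: fewer than 2 thresholdable images"
        )
    qc = threshold_filter(records, params)
    if not qc.kept_ids:
        raise PipelineError(f"group {group!r}: no image kept after threshold QC")
    pooled = CellTable(group=group)
    stage_counts: dict[str, dict[str, int]] = {}
    for image_id in qc.kept_ids:
        im, t = usable[image_id]
        mask = binarize(im, t)
        objs = label_objects(mask, connectivity=params.connectivity)
        n_raw = objs.n_objects
        objs = remove_small_and_edge(objs, params)
        measurements = measure_objects(objs, im)
        table = morphological_filter(measurements, params, group=group)
        stage_counts[image_id] = {
            "labeled": n_raw,
            "after_small_edge": objs.n_objects,
            "after_morphology": table.n_cells,
        }
        logger.info(
            "group %s image %s: otsu=%.4f labeled=%d after_small_edge=%d cells=%d",
            group, image_id, t, n_raw, objs.n_objects, table.n_cells,
        )
        pooled.extend(table)
    logger.info("group %s: pooled %d cells from %d kept images",
                group, pooled.n_cells, len(qc.kept_ids))
    return GroupAnalysis(pooled, records, qc, stage_counts, skipped)


def compare_image_groups(
    images_a: list, images_b: list, labels: tuple[str, str] = ("before", "after"),
    params: FilterParams | None = None, fc_mode: str = "mean",
    rolling_ball: bool = False,
) -> tuple[ComparisonResult, GroupAnalysis, GroupAnalysis]:
    """In-memory comparison of two groups of green-channel images."""
    ga = analyze_green_images(images_a, labels[0], params, rolling_ball)
    gb = analyze_green_images(images_b, labels[1], params, rolling_ball)
    result = compare_cell_tables(ga.table, gb.table, fc_mode=fc_mode)
    return result, ga, gb


def _load_group(pattern: str, group: str) -> list:
    paths = sorted(_glob.glob(pattern))
    images = []
    for p in paths:
        if Path(p).suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        try:
            raster = tio.read_image(p, group=group)
        except tio.FormatError as exc:
            logger.warning("skipping unreadable image %s: %s", p, exc)
            continue
        images.append(tio.extract_green(raster))
    if len(images) < 2:
        raise PipelineError(
            f"group {group!r}: found {len(images)} readable images under "
            f"{pattern!r}, need >= 2"
        )
    return images


def run_comparison(config: PipelineConfig) -> ComparisonResult:
    """Run the full comparison described by ``config`` and write outputs.

    Writes, under ``config.output_dir``: ``cells_<label>.csv`` per group,
    ``qc_report.csv`` (both groups), and ``comparison.csv``.
    """
    (label_a, pat_a), (label_b, pat_b) = config.groups.items()
    images_a = _load_group(pat_a, label_a)
    images_b = _load_group(pat_b, label_b)
    result, ga, gb = compare_image_groups(
        images_a, images_b, (label_a, label_b),
        params=config.params, fc_mode=config.fc_mode,
        rolling_ball=config.rolling_ball,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_cell_table(ga.table, out / f"cells_{label_a}.csv")
    tio.write_cell_table(gb.table, out / f"cells_{label_b}.csv")
    write_qc_report(ga.records + gb.records,
                    DatasetQC(
                        mean_threshold=float("nan"), sd_threshold=float("nan"),
                        kept_ids=ga.qc.kept_ids + gb.qc.kept_ids,
                        dropped_ids=ga.qc.dropped_ids + gb.qc.dropped_ids,
                    ),
                    out / "qc_report.csv")
    tio.write_comparison(result, out / "comparison.csv")
    logger.info(
        "comparison %s vs %s: n=%d/%d FC=%.3f U=%.1f P %s",
        label_a, label_b, result.n_a, result.n_b,
        result.fc, result.u_stat, result.display_p(),
    )
    return result
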