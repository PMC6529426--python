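"""Dataset-level image quality control.

Images whose global Otsu threshold is an outlier of the dataset's threshold
distribution tend to be out of focus, empty, or saturated.  The filter
keeps an image iff its threshold lies within ``k`` standard deviations of
the dataset mean (``k = 1`` by default).  Mean and standard deviation
(sample, n-1 denominator) are computed once over the full dataset, not
recomputed after drops; the interval is inclusive at both ends.

The "dataset" is normally one acquisition group (one condition x time
point); pooling across groups is the caller's choice of which records to
pass in.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .segmentation import FilterParams

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than two threshold records: the standard deviation is undefined."""


@dataclass
class ThresholdRecord:
    image_id: str
    threshold: float  # normalized to [0, 1]
    group: str = ""


@dataclass
class DatasetQC:
    """Outcome of the threshold-distribution filter for one dataset."""

    mean_threshold: float
    sd_threshold: float
    kept_ids: list[str]
    dropped_ids: list[str]


def threshold_filter(
    records: list[ThresholdRecord], params: FilterParams | None = None
) -> DatasetQC:
    """Apply the k-standard-deviation threshold filter.

    Keeps a record iff ``|threshold - mean| <= k * sd`` with
    ``k = params.qc_sd_multiplier``.  With zero spread every image is kept
    (logged).  Record order is preserved within the kept and dropped lists.
    """
    params = params or FilterParams()
    if len(records) < 2:
        raise InsufficientDataError(
            f"threshold filter needs >= 2 records, got {len(records)}"
        )
    thresholds = np.array([r.threshold for r in records], dtype=float)
    mean = float(thresholds.mean())
    sd = float(thresholds.std(ddof=1))
    if sd == 0.0:
        logger.info("threshold distribution has zero spread; keeping all %d images",
                    len(records))
        return DatasetQC(mean, sd, [r.image_id for r in records], [])
    k = params.qc_sd_multiplier
    kept, dropped = [], []
    for r in records:
        (kept if abs(r.threshold - mean) <= k * sd else dropped).append(r.image_id)
    logger.info(
        "threshold QC: mean=%.4f sd=%.4f kept=%d dropped=%d",
        mean, sd, len(kept), len(dropped),
    )
    return DatasetQC(mean, sd, kept, dropped)


def write_qc_report(
    records: list[ThresholdRecord], qc: DatasetQC, path: str | Path
) -> None:
    """Write the per-image QC verdict: image_id, threshold, kept flag, group."""
    kept = set(qc.kept_ids)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "threshold", "kept", "group"])
        for r in records:
            writer.writerow(
                [r.image_id, f"{r.threshold:.6f}", int(r.image_id in kept), r.group]
            )
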