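"""Physical-scale normalization, point-to-point error, and outlier statistics.

Hand radiographs carry no physical resolution, so distances are converted to
millimetres through an image-specific scale that declares the wrist (the
segment between two wrist landmarks) to be 50 mm wide. Accuracy is then
summarized by the median / mean / SD of the point-to-point error (PE) plus
the number and percentage of predictions farther than 2 / 4 / 10 mm from
their targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet

WRIST_WIDTH_MM = 50.0
DEFAULT_OUTLIER_RADII_MM = (2.0, 4.0, 10.0)


class DegenerateScaleError(ValueError):
    """Raised when the two wrist landmarks coincide."""


def normalization_constant(
    landmarks: LandmarkSet, wrist_a: int = 2, wrist_b: int = 6
) -> float:
    """Millimetres-per-pixel scale for one image.

    The wrist segment between landmarks ``wrist_a`` and ``wrist_b``
    (1-based indices; 2 and 6 by convention) is defined to span 50 mm, so
    the scale is ``50 / ||l_a - l_b||``.
    """
    la, lb = landmarks.get(wrist_a), landmarks.get(wrist_b)
    dist = float(np.linalg.norm(la - lb))
    if dist <= 0.0 or not np.isfinite(dist):
        raise DegenerateScaleError(
            f"wrist landmarks {wrist_a} and {wrist_b} coincide; scale undefined"
        )
    return WRIST_WIDTH_MM / dist


def point_error(
    pred: Sequence[float], target: Sequence[float], scale: float
) -> float:
    """Point-to-point error in millimetres: ``scale * ||pred - target||``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * float(np.linalg.norm(np.asarray(pred, float) - np.asarray(target, float)))


@dataclass
class MetricsSummary:
    """Aggregate PE statistics over a set of predictions.

    ``outlier_counts[r]`` is the number of errors strictly greater than the
    radius ``r`` (in mm); a prediction exactly at the radius is not an
    outlier. Percentages use ``n_predictions`` as denominator.
    """

    median_mm: float
    mean_mm: float
    sd_mm: float
    outlier_counts: Mapping[float, float]
    outlier_pct: Mapping[float, float]
    n_predictions: int

    def as_dict(self) -> dict:
        d = {
            "median_mm": self.median_mm,
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "n_predictions": self.n_predictions,
        }
        for r in self.outlier_counts:
            d[f"n_outliers_gt_{r:g}mm"] = self.outlier_counts[r]
            d[f"pct_outliers_gt_{r:g}mm"] = self.outlier_pct[r]
        return d


def outlier_percentage(count: float, n_predictions: int, decimals: int | None = 2) -> float:
    """Percentage of outliers, optionally rounded for reporting."""
    pct = 100.0 * count / n_predictions
    return pct if decimals is None else round(pct, decimals)


def summarize(
    errors_mm: Iterable[float],
    radii_mm: Sequence[float] = DEFAULT_OUTLIER_RADII_MM,
) -> MetricsSummary:
    """Median/mean/SD of errors plus strict-``>`` outlier counts per radius.

    SD is the sample standard deviation (ddof=1); with a single error it is
    reported as 0.
    """
    errors = np.asarray(list(errors_mm), dtype=float)
    if errors.size == 0:
        raise ValueError("cannot summarize an empty error list")
    if np.any(errors < 0):
        raise ValueError("errors must be non-negative")
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    counts = {float(r): int(np.sum(errors > r)) for r in radii_mm}
    pct = {r: 100.0 * c / errors.size for r, c in counts.items()}
    return MetricsSummary(
        median_mm=float(np.median(errors)),
        mean_mm=float(np.mean(errors)),
        sd_mm=sd,
        outlier_counts=counts,
        outlier_pct=pct,
        n_predictions=int(errors.size),
    )


def errors_for_image(
    pred: LandmarkSet, target: LandmarkSet, scale: float, mask_invisible: bool = True
) -> np.ndarray:
    """Per-landmark PE (mm) for one image.

    Every supplied prediction is treated equally; when ``mask_invisible`` is
    set, landmarks flagged invisible in the *target* annotation are dropped
    (there is no ground truth to compare against).
    """
    diffs = np.linalg.norm(pred.coords - target.coords, axis=1) * scale
    if mask_invisible:
        diffs = diffs[target.visible]
    return diffs


def write_report(summary: MetricsSummary, path_csv: str | Path) -> None:
    """Write a metric,value CSV and a JSON twin next to it."""
    path_csv = Path(path_csv)
    d = summary.as_dict()
    pd.DataFrame({"metric": list(d), "value": list(d.values())}).to_csv(
        path_csv, index=False
    )
    path_csv.with_suffix(".json").write_text(json.dumps(d, indent=2))


def write_error_table(
    rows: Iterable[tuple[str, int, float]], path_csv: str | Path
) -> None:
    """Per-image per-landmark error table: image_id, landmark, pe_mm."""
    pd.DataFrame(rows, columns=["image_id", "landmark", "pe_mm"]).to_csv(
        Path(path_csv), index=False
    )
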