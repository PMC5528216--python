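"""The adipocyte index and derived adiposity quantities.

The adipocyte index (AI) scores one thresholded image by how much of it is
intervacuolar matrix rather than lipid-filled adipocyte: more matrix means
smaller (emptier) adipocytes and hence lower energy reserves.  Two
definitions are supported.  With adipocyte pixel fraction ``a``:

* ``total_over_adipocyte`` (default): AI = 1 / a, i.e. total image area
  over adipocyte area.  Bounded below by 1, with equality exactly when the
  image contains no matrix.  This is the reading consistent with observed
  AI ranges whose minimum is exactly 1.
* ``intervacuolar_over_adipocyte``: AI = (1 - a) / a, the strict
  matrix-to-adipocyte ratio, bounded below by 0.

The two differ by exactly 1 for every mask.  Every AI carries the
definition, image area and threshold that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ImageTooSmallError, UndefinedIndexError, ValidationError
from .image import BinaryMask

#: Minimum image area for a valid AI, in square micrometres.
MIN_IMAGE_AREA_UM2 = 167_687.3336

#: Cubic micrometres per nanolitre.
UM3_PER_NL = 1e6

TOTAL_OVER_ADIPOCYTE = "total_over_adipocyte"
INTERVACUOLAR_OVER_ADIPOCYTE = "intervacuolar_over_adipocyte"


@dataclass(frozen=True)
class AdipocyteIndex:
    value: float
    definition: str
    image_area_um2: float
    threshold: float | None = None


def ai_from_fraction(
    adipocyte_fraction: float, definition: str = TOTAL_OVER_ADIPOCYTE
) -> float:
    """AI from the adipocyte pixel fraction ``a`` of an image."""
    a = float(adipocyte_fraction)
    if not 0.0 <= a <= 1.0:
        raise ValidationError(f"adipocyte fraction {a} outside [0, 1]")
    if a == 0.0:
        raise UndefinedIndexError("no adipocyte pixels; AI undefined")
    if definition == TOTAL_OVER_ADIPOCYTE:
        return 1.0 / a
    if definition == INTERVACUOLAR_OVER_ADIPOCYTE:
        return (1.0 - a) / a
    raise ValidationError(f"unknown AI definition {definition!r}")


def compute_adipocyte_index(
    mask: BinaryMask,
    definition: str = TOTAL_OVER_ADIPOCYTE,
    *,
    min_image_area_um2: float = MIN_IMAGE_AREA_UM2,
    force: bool = False,
) -> AdipocyteIndex:
    """Compute the AI of one binary mask.

    The image must cover at least ``min_image_area_um2`` (a representative
    field of view) unless ``force`` is set.
    """
    if mask.area_um2 < min_image_area_um2 and not force:
        raise ImageTooSmallError(mask.area_um2, min_image_area_um2)
    value = ai_from_fraction(mask.adipocyte_fraction, definition)
    return AdipocyteIndex(
        value=value,
        definition=definition,
        image_area_um2=mask.area_um2,
        threshold=mask.provenance.get("threshold_dark_high"),
    )


def sphere_volume_from_area(area_um2: float) -> float:
    """Volume (nl) of a sphere whose great-circle area is ``area_um2``.

    r = sqrt(area / pi); V = 4/3 pi r^3 um^3, converted at 10^6 um^3 per nl.
    """
    if area_um2 <= 0:
        raise ValidationError("area must be positive")
    r = np.sqrt(area_um2 / np.pi)
    return float(4.0 / 3.0 * np.pi * r**3 / UM3_PER_NL)


def geometric_mean(values) -> float:
    """exp(mean(log x)); every value must be strictly positive."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("geometric mean of an empty set")
    if np.any(v <= 0):
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def percent_reduction(early_value: float, late_value: float) -> float:
    """100 * (early - late) / early."""
    if early_value <= 0:
        raise ValidationError("early value must be positive")
    return 100.0 * (early_value - late_value) / early_value


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-metric, per-cohort n / geometric mean / mean / min / max.

    ``records`` needs a ``cohort`` column plus any of the metric columns;
    missing values are excluded metric-wise.  Empty cohorts yield n = 0
    rows with NaN statistics.
    """
    metric_cols = [
        c for c in records.columns if c not in ("sample_id", "cohort", "year")
    ]
    rows = []
    cohorts = ["early", "late"] if "cohort" in records else []
    for metric in metric_cols:
        for cohort in cohorts:
            v = records.loc[records["cohort"] == cohort, metric].dropna()
            rows.append(
                {
                    "metric": metric,
                    "cohort": cohort,
                    "n": int(len(v)),
                    "geometric_mean": geometric_mean(v) if len(v) else np.nan,
                    "mean": float(v.mean()) if len(v) else np.nan,
                    "min": float(v.min()) if len(v) else np.nan,
                    "max": float(v.max()) if len(v) else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "cohort", "n", "geometric_mean", "mean", "min", "max"]
    )
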