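"""Metrics-table IO, pipeline configuration, and report writing.

The metrics table is the pipeline's central exchange format: one CSV row
per biopsy with columns sample_id, cohort, year (optional), and the three
adiposity metrics.  Cohort labels are normalized at this boundary
(any-case "early"/"late" on disk; early = 0, late = 1 inside the models).
Every CSV report gets a machine-readable JSON twin, and every pipeline run
writes its resolved configuration beside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .metrics import MIN_IMAGE_AREA_UM2, TOTAL_OVER_ADIPOCYTE
from .segmentation import SPECK_FLOOR_PX

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "cohort")
METRIC_COLUMNS = ("adipocyte_area_um2", "ai", "lipid_percent")
OPTIONAL_COLUMNS = ("year",)


@dataclass
class PipelineConfig:
    """Resolved run configuration; defaults follow the standard protocol."""

    threshold_16bit: int = 65527
    threshold_8bit: int = 255
    intensity_convention: str = "light_high"
    um_per_px: float = 1.0
    min_cells: int = 100
    min_image_area_um2: float = MIN_IMAGE_AREA_UM2
    ai_definition: str = TOTAL_OVER_ADIPOCYTE
    speck_floor_px: int = SPECK_FLOOR_PX
    watershed: bool = False
    min_adipocyte_fraction: float = 0.5  # QC gate for image selection
    p_out: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def threshold(self, bit_depth: int) -> int:
        return self.threshold_16bit if bit_depth == 16 else self.threshold_8bit


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-sample metrics CSV.

    Returns a typed DataFrame with normalized cohort labels.  Missing
    required columns, duplicate sample ids, unparseable numbers and
    unknown cohort labels raise :class:`~adipo.errors.ValidationError`
    naming the offending column or CSV line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    present_metrics = [c for c in METRIC_COLUMNS if c in df.columns]
    if not present_metrics:
        raise ValidationError(
            f"at least one metric column required: {METRIC_COLUMNS}"
        )

    out = pd.DataFrame({"sample_id": df["sample_id"].str.strip()})
    if out["sample_id"].duplicated().any():
        dupes = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id values: {sorted(set(dupes))}")

    cohort = df["cohort"].str.strip().str.lower()
    bad = ~cohort.isin(["early", "late"])
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header is line 1
        raise ValidationError(
            f"unrecognized cohort labels on CSV lines {lines} "
            "(expected early/late)"
        )
    out["cohort"] = cohort

    if "year" in df.columns:
        out["year"] = pd.to_numeric(
            df["year"].replace("", np.nan), errors="coerce"
        )

    for col in present_metrics:
        raw = df[col].str.strip().replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        malformed = vals.isna() & raw.notna()
        if malformed.any():
            lines = (np.flatnonzero(malformed.to_numpy()) + 2).tolist()
            raise ValidationError(
                f"column {col!r}: unparseable values on CSV lines {lines}"
            )
        out[col] = vals
    for col in METRIC_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan

    n_missing = {c: int(out[c].isna().sum()) for c in METRIC_COLUMNS}
    log.info(
        "read %d records from %s; missing per metric: %s",
        len(out), path, n_missing,
    )
    return out


def write_metrics_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "cohort"] + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    cols += [c for c in METRIC_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format="%.6g")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results, path: str | Path) -> list[Path]:
    """Write a report DataFrame as CSV plus a JSON twin.

    Column order is whatever the caller fixed in the DataFrame (the report
    schemas below are deterministic); numbers are printed with six
    significant digits.  Returns the paths written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        jpath = path.with_suffix(".json")
    else:
        jpath = path if path.suffix == ".json" else path.with_suffix(".json")
    with open(jpath, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
        fh.write("\n")
    written.append(jpath)
    return written


def model_table_report(results: dict) -> pd.DataFrame:
    """One row per (model, step, predictor): coefficients, SEs, ORs, CIs."""
    rows = []
    for name, res in results.items():
        if res.skipped or res.trace is None:
            continue
        # reconstruct per-step fits from the trace by refitting is avoided:
        # report the final fit per model, plus the step structure
        for step_no, step in enumerate(res.trace.steps, start=1):
            for pred in step.retained or ["(intercept only)"]:
                rows.append(
                    {
                        "model": name,
                        "n": res.n,
                        "step": step_no,
                        "predictor": pred,
                        "removed_this_step": step.removed or "",
                    }
                )
        fit = res.fit
        for i, pred in enumerate(fit.predictors):
            rows.append(
                {
                    "model": name,
                    "n": res.n,
                    "step": len(res.trace.steps),
                    "predictor": f"{pred} (final)",
                    "B": fit.coef[i + 1],
                    "SE": fit.se[i + 1],
                    "p": fit.wald_p[i + 1],
                    "odds_ratio": fit.odds_ratio[i],
                    "ci_low": fit.ci_low[i],
                    "ci_high": fit.ci_high[i],
                }
            )
    return pd.DataFrame(rows)


def fit_table_report(results: dict) -> pd.DataFrame:
    """One row per model: Nagelkerke R2 and Hosmer–Lemeshow fit."""
    rows = []
    for name, res in results.items():
        if res.skipped or res.diagnostics is None:
            continue
        d = res.diagnostics
        rows.append(
            {
                "model": name,
                "predictors": " ".join(res.fit.predictors) or "(intercept only)",
                "nagelkerke_r2": d.nagelkerke_r2,
                "hl_chi2": d.hl_chi2,
                "hl_df": d.hl_df,
                "hl_p": d.hl_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["model", "predictors", "nagelkerke_r2", "hl_chi2", "hl_df", "hl_p"],
    )
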