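"""Synthetic blubber histology with known ground truth.

Two generators live here:

* :func:`generate_tissue_image` renders a field of packed, lipid-filled
  adipocytes (light discs) in a darker-staining intervacuolar matrix,
  together with the exact label mask used to render it.  Every downstream
  stage (thresholding, labelling, area measurement, AI) can therefore be
  checked against known truth.

* :func:`generate_cohort_table` draws per-sample metric tables (adipocyte
  area, AI, lipid percent) for an early- and a late-migration cohort with
  controlled means, cross-metric correlation (Gaussian copula) and
  missingness, emulating the structure of a field study's per-sample data.

Both are deterministic given their seed: one ``numpy.random.default_rng``
stream per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleCorrelationError, PackingError, ValidationError
from .image import DARK_HIGH, RasterImage

# Intensity poles on the dark-is-high scale, as fractions of full range.
# The matrix sits near the dark pole, adipocyte lipid near the light pole;
# specks mimic nuclei/debris.
_MATRIX_LEVEL = 0.95
_CELL_LEVEL = 0.08
_SPECK_LEVEL = 0.92


@dataclass
class TissueSpec:
    """Parameters of one synthetic tissue image.

    Radii are drawn from a lognormal: ``exp(N(radius_log_mean,
    radius_log_sd))`` micrometres.  ``matrix_gap_um`` is the minimum
    centre-to-centre clearance beyond the sum of radii, i.e. the thinnest
    intervacuolar septum.  ``noise_sd`` is Gaussian intensity noise as a
    fraction of the full dynamic range; ``speck_rate`` is dark specks per
    1,000 square micrometres.  ``target_cell_fraction`` asks the packer for
    a given adipocyte area fraction; None packs to saturation.
    """

    width_px: int = 1024
    height_px: int = 1024
    um_per_px: float = 0.5
    bit_depth: int = 16
    radius_log_mean: float = math.log(14.0)
    radius_log_sd: float = 0.25
    matrix_gap_um: float = 1.0
    noise_sd: float = 0.03
    speck_rate: float = 0.3
    target_cell_fraction: float | None = None
    max_attempts: int = 100_000
    elliptical: bool = False
    aspect_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be positive")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")
        if self.radius_log_sd < 0 or self.noise_sd < 0 or self.speck_rate < 0:
            raise ValidationError("radius_log_sd, noise_sd, speck_rate must be >= 0")
        if self.matrix_gap_um < 0:
            raise ValidationError("matrix_gap_um must be >= 0")
        # cells must be at least 2 px across at this calibration
        if math.exp(self.radius_log_mean) < self.um_per_px:
            raise ValidationError(
                "median cell diameter below 2 px at this calibration"
            )
        if self.target_cell_fraction is not None and not (
            0 < self.target_cell_fraction < 1
        ):
            raise ValidationError("target_cell_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Exact rendering truth for one synthetic image.

    ``label_mask`` is 0 in the intervacuolar matrix and k >= 1 inside cell k.
    ``cell_areas_um2`` are rendered pixel areas per cell (index k-1), so
    pixel conservation holds exactly: cell pixels + matrix pixels = total.
    ``true_ai`` is the total/adipocyte area ratio implied by
    ``intervacuolar_fraction``.
    """

    label_mask: np.ndarray
    cell_areas_um2: np.ndarray
    intervacuolar_fraction: float
    true_ai: float
    centers_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    radii_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cells(self) -> int:
        return len(self.cell_areas_um2)

    def interior_labels(self) -> np.ndarray:
        """Labels of cells not touching the image border."""
        m = self.label_mask
        border = np.unique(
            np.concatenate([m[0], m[-1], m[:, 0], m[:, -1]])
        )
        all_labels = np.arange(1, self.n_cells + 1)
        return np.setdiff1d(all_labels, border)


def _pack_discs(spec: TissueSpec, rng: np.random.Generator):
    """Random sequential adsorption of non-overlapping discs (in um).

    Accepted discs are bucketed on a coarse grid so each candidate only
    checks nearby discs; the run stops after ``max_attempts`` consecutive
    rejections (saturation) or at ``target_cell_fraction``.
    """
    w_um = spec.width_px * spec.um_per_px
    h_um = spec.height_px * spec.um_per_px
    cap = 4096  # growable storage for accepted discs
    cx = np.empty(cap)
    cy = np.empty(cap)
    cr = np.empty(cap)
    n = 0
    area = w_um * h_um
    covered = 0.0
    fails = 0
    batch = 1024
    done = False
    while not done:
        if spec.radius_log_sd > 0:
            rs = np.exp(rng.normal(spec.radius_log_mean, spec.radius_log_sd, batch))
        else:
            rs = np.full(batch, math.exp(spec.radius_log_mean))
        xs = rng.uniform(0, w_um, batch)
        ys = rng.uniform(0, h_um, batch)
        too_small = rs < spec.um_per_px  # would rasterize below 2 px diameter
        # screen the whole batch against already-accepted discs at once
        if n:
            d2 = (xs[:, None] - cx[None, :n]) ** 2 + (ys[:, None] - cy[None, :n]) ** 2
            lim = rs[:, None] + cr[None, :n] + spec.matrix_gap_um
            clash = (d2 < lim**2).any(axis=1)
        else:
            clash = np.zeros(batch, dtype=bool)
        for i in range(batch):
            if (
                spec.target_cell_fraction is not None
                and covered / area >= spec.target_cell_fraction
            ):
                done = True
                break
            if too_small[i] or clash[i]:
                fails += 1
                if fails >= spec.max_attempts:
                    done = True
                    break
                continue
            # re-check against discs accepted earlier in this batch
            if n:
                d2i = (cx[:n] - xs[i]) ** 2 + (cy[:n] - ys[i]) ** 2
                limi = cr[:n] + rs[i] + spec.matrix_gap_um
                if (d2i < limi**2).any():
                    fails += 1
                    if fails >= spec.max_attempts:
                        done = True
                        break
                    continue
            if n == cap:
                cap *= 2
                cx, cy, cr = (
                    np.resize(cx, cap), np.resize(cy, cap), np.resize(cr, cap)
                )
            cx[n], cy[n], cr[n] = xs[i], ys[i], rs[i]
            n += 1
            # full disc area is a cheap coverage bound (border discs overcount)
            covered += math.pi * rs[i] ** 2
            fails = 0
    if (
        spec.target_cell_fraction is not None
        and covered / area < spec.target_cell_fraction
    ):
        raise PackingError(spec.target_cell_fraction, covered / area)
    return np.stack([cx[:n], cy[:n]], axis=1), cr[:n].copy()


def _rasterize(spec: TissueSpec, centers: np.ndarray, radii: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Paint each disc into an int32 label grid (discs never overlap)."""
    labels = np.zeros((spec.height_px, spec.width_px), dtype=np.int32)
    s = spec.um_per_px
    for k, ((x, y), r) in enumerate(zip(centers, radii), start=1):
        if spec.elliptical and spec.aspect_sd > 0:
            aspect = float(np.exp(rng.normal(0.0, spec.aspect_sd)))
            theta = float(rng.uniform(0, math.pi))
        else:
            aspect, theta = 1.0, 0.0
        rx, ry = r * aspect, r / aspect
        rmax = max(rx, ry)
        j0 = max(int((x - rmax) / s) - 1, 0)
        j1 = min(int((x + rmax) / s) + 2, spec.width_px)
        i0 = max(int((y - rmax) / s) - 1, 0)
        i1 = min(int((y + rmax) / s) + 2, spec.height_px)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        px = (jj + 0.5) * s - x
        py = (ii + 0.5) * s - y
        if aspect != 1.0:
            c, sn = math.cos(theta), math.sin(theta)
            px, py = c * px + sn * py, -sn * px + c * py
        inside = (px / rx) ** 2 + (py / ry) ** 2 <= 1.0
        block = labels[i0:i1, j0:j1]
        block[inside] = k
    return labels


def generate_tissue_image(spec: TissueSpec) -> tuple[RasterImage, GroundTruth]:
    """Render one synthetic histology image and its exact ground truth.

    The returned image is on the dark-is-high scale (matrix dark, lipid
    light); ground truth reflects the rendered mask *before* noise and
    specks, so a mid-range threshold on a noise-free image recovers it
    exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers, radii = _pack_discs(spec, rng)
    labels = _rasterize(spec, centers, radii, rng)

    px_area = spec.um_per_px**2
    counts = np.bincount(labels.ravel(), minlength=len(radii) + 1)
    cell_areas = counts[1:].astype(float) * px_area
    total_px = labels.size
    iv_fraction = float(counts[0]) / total_px
    adip_fraction = 1.0 - iv_fraction
    true_ai = math.inf if adip_fraction == 0 else 1.0 / adip_fraction

    max_i = (1 << spec.bit_depth) - 1
    img = np.where(labels > 0, _CELL_LEVEL, _MATRIX_LEVEL).astype(np.float64)

    if spec.speck_rate > 0:
        area_um2 = total_px * px_area
        n_specks = rng.poisson(spec.speck_rate * area_um2 / 1000.0)
        for _ in range(n_specks):
            sx = rng.uniform(0, spec.width_px)
            sy = rng.uniform(0, spec.height_px)
            sr = rng.uniform(1.0, 2.5) / spec.um_per_px  # nucleus-sized
            i0, i1 = max(int(sy - sr) - 1, 0), min(int(sy + sr) + 2, spec.height_px)
            j0, j1 = max(int(sx - sr) - 1, 0), min(int(sx + sr) + 2, spec.width_px)
            jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
            inside = (jj + 0.5 - sx) ** 2 + (ii + 0.5 - sy) ** 2 <= sr**2
            block = img[i0:i1, j0:j1]
            block[inside] = _SPECK_LEVEL

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    pixels = np.clip(np.rint(img * max_i), 0, max_i).astype(
        np.uint8 if spec.bit_depth == 8 else np.uint16
    )
    raster = RasterImage(
        pixels=pixels,
        bit_depth=spec.bit_depth,
        um_per_px=spec.um_per_px,
        convention=DARK_HIGH,
    )
    truth = GroundTruth(
        label_mask=labels,
        cell_areas_um2=cell_areas,
        intervacuolar_fraction=iv_fraction,
        true_ai=true_ai,
        centers_px=centers / spec.um_per_px,
        radii_um=radii,
    )
    return raster, truth


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

METRICS = ("adipocyte_area_um2", "ai", "lipid_percent")


@dataclass
class MetricSpec:
    """Marginal distribution of one metric, per cohort.

    Means/SDs are on the generation scale: the raw scale, or log10 if
    ``log10_scale`` (the metric is then 10**normal, i.e. the mean is the
    log10 of the geometric mean).  Values are clipped to [lower, upper].
    """

    early_mean: float
    early_sd: float
    late_mean: float
    late_sd: float
    log10_scale: bool = False
    lower: float | None = None
    upper: float | None = None

    def realize(self, z: np.ndarray, cohort_late: np.ndarray) -> np.ndarray:
        mean = np.where(cohort_late, self.late_mean, self.early_mean)
        sd = np.where(cohort_late, self.late_sd, self.early_sd)
        v = mean + sd * z
        if self.log10_scale:
            v = 10.0**v
        if self.lower is not None or self.upper is not None:
            v = np.clip(v, self.lower, self.upper)
        return v


@dataclass
class CohortTableSpec:
    """Two-cohort metric table with a Gaussian-copula correlation structure.

    ``corr`` is the 3x3 latent correlation matrix over
    (adipocyte_area_um2, ai, lipid_percent).  Missingness is specified
    either as ``pattern_counts`` — per observed-metric pattern, how many
    early/late samples carry exactly those metrics (exact control of
    listwise-deletion subset sizes) — or as per-metric ``missing_rates``.
    """

    n_early: int
    n_late: int
    area: MetricSpec
    ai: MetricSpec
    lipid: MetricSpec
    corr: np.ndarray
    pattern_counts: dict[tuple[str, ...], tuple[int, int]] | None = None
    missing_rates: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_early < 0 or self.n_late < 0:
            raise ValidationError("cohort counts must be >= 0")
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(
            np.diag(c), 1.0
        ):
            raise InfeasibleCorrelationError(
                "corr must be symmetric 3x3 with unit diagonal"
            )
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise InfeasibleCorrelationError(
                "corr matrix is not positive semi-definite"
            )
        if self.pattern_counts is not None:
            e = sum(v[0] for v in self.pattern_counts.values())
            l = sum(v[1] for v in self.pattern_counts.values())
            if (e, l) != (self.n_early, self.n_late):
                raise ValidationError(
                    f"pattern counts sum to ({e}, {l}); expected "
                    f"({self.n_early}, {self.n_late})"
                )
            for pat in self.pattern_counts:
                unknown = set(pat) - set(METRICS)
                if unknown:
                    raise ValidationError(f"unknown metrics in pattern: {unknown}")

    @classmethod
    def study_default(cls, seed: int = 0) -> "CohortTableSpec":
        """Conditions emulating the humpback-whale field study's table.

        98 early / 105 late samples; adipocyte area normal per cohort
        (means 792.10 / 597.65 um^2, SDs estimated as range/4), AI
        lognormal (cohort geometric means 1.35 / 1.49, combined 1.42,
        floor 1), lipid percent with equal cohort means (no fasting
        signal); latent correlations (area, AI) = -0.784,
        (area, lipid) = 0.388, (AI, lipid) = -0.468.  Missingness patterns
        reproduce the study's listwise-deletion subsets: 83 samples with
        area, 139 with lipid (all of which also carry AI), 77 with all
        three, AI on every sample.
        """
        corr = np.array(
            [
                [1.0, -0.784, 0.388],
                [-0.784, 1.0, -0.468],
                [0.388, -0.468, 1.0],
            ]
        )
        patterns = {
            ("adipocyte_area_um2", "ai", "lipid_percent"): (37, 40),
            ("adipocyte_area_um2", "ai"): (5, 1),
            ("ai", "lipid_percent"): (1, 61),
            ("ai",): (55, 3),
        }
        return cls(
            n_early=98,
            n_late=105,
            area=MetricSpec(792.10, 222.0, 597.65, 139.0, lower=150.0),
            ai=MetricSpec(
                math.log10(1.35), 0.065, math.log10(1.49), 0.065,
                log10_scale=True, lower=1.0,
            ),
            lipid=MetricSpec(43.0, 16.0, 43.0, 16.0, lower=1.0, upper=100.0),
            corr=corr,
            pattern_counts=patterns,
            seed=seed,
        )


def generate_cohort_table(spec: CohortTableSpec) -> pd.DataFrame:
    """Draw a per-sample metrics table with the requested structure.

    Returns a DataFrame with columns sample_id, cohort (early/late),
    adipocyte_area_um2, ai, lipid_percent; missing cells are NaN.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_early + spec.n_late
    if n == 0:
        return pd.DataFrame(columns=["sample_id", "cohort", *METRICS])

    corr = np.asarray(spec.corr, dtype=float)
    # copula draw: latent MVN via eigen factor (PSD-safe)
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 3)) @ factor.T

    cohort_late = np.repeat([False, True], [spec.n_early, spec.n_late])
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "cohort": np.where(cohort_late, "late", "early"),
            "adipocyte_area_um2": spec.area.realize(z[:, 0], cohort_late),
            "ai": spec.ai.realize(z[:, 1], cohort_late),
            "lipid_percent": spec.lipid.realize(z[:, 2], cohort_late),
        }
    )

    if spec.pattern_counts is not None:
        for late, n_c in ((False, spec.n_early), (True, spec.n_late)):
            idx = np.flatnonzero(cohort_late == late)
            idx = rng.permutation(idx)
            pos = 0
            for pat, (e_cnt, l_cnt) in spec.pattern_counts.items():
                cnt = l_cnt if late else e_cnt
                rows = idx[pos : pos + cnt]
                pos += cnt
                for metric in METRICS:
                    if metric not in pat:
                        df.loc[rows, metric] = np.nan
    elif spec.missing_rates:
        for metric, rate in spec.missing_rates.items():
            if metric not in METRICS:
                raise ValidationError(f"unknown metric {metric!r}")
            k = int(round(rate * n))
            rows = rng.choice(n, size=k, replace=False)
            df.loc[rows, metric] = np.nan
    return df
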