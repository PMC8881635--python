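"""Minimal first-level GLM engine for subjective-value parametric modulation.

Builds HRF-convolved design matrices from an events table (one onset
regressor plus one mean-centered SV modulator per task, polynomial drift,
intercept), fits every voxel by ordinary least squares, and provides the
contrasts the analysis needs: moral-vs-financial modulator t-maps,
minimum-statistic conjunctions, and spherical ROI means.

Deliberately simple: white-noise OLS (no AR(1) prewhitening), no
orthogonalization of modulators beyond mean-centering, canonical
double-gamma HRF without derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .errors import ValidationError

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "RoiSpec",
    "double_gamma_hrf",
    "build_design",
    "fit_glm",
    "contrast_sv_domains",
    "conjunction",
    "roi_mean",
]


def double_gamma_hrf(
    dt: float,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak-normalized.

    Difference of two gamma densities (shape = delay, unit scale) with the
    undershoot scaled down by ``ratio`` — the widespread canonical kernel
    (response delay 6 s, undershoot delay 16 s, 1:6 ratio).
    """
    if dt <= 0 or duration_s <= dt:
        raise ValidationError("need dt > 0 and duration_s > dt")
    t = np.arange(0.0, duration_s, dt)
    h = _gamma_dist.pdf(t, peak_delay) - _gamma_dist.pdf(t, undershoot_delay) / ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """Time × regressor matrix with named columns."""

    frame: pd.DataFrame
    tr: float
    hrf: np.ndarray
    full_rank: bool

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_scans(self) -> int:
        return len(self.frame)


def _convolve_sampled(impulses_hr: np.ndarray, hrf: np.ndarray, oversample: int, n_scans: int):
    convolved = np.convolve(impulses_hr, hrf)[: len(impulses_hr)]
    return convolved[::oversample][:n_scans]


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    hrf_params: dict | None = None,
    drift_order: int = 2,
    modulator_col: str = "sv",
    oversample: int = 16,
) -> DesignMatrix:
    """Design matrix from an events table.

    For each task (``trial_type``) two regressors are built on a grid
    oversampled ``oversample``-fold relative to the TR and then sampled at
    scan onsets: a unit stick at each trial onset ("<task>_onset"), and the
    same sticks scaled by the within-task mean-centered modulator
    ("<task>_sv"), both convolved with the canonical HRF.  Legendre
    polynomial drift columns (1..``drift_order``) and an intercept are
    appended.  A rank-deficient matrix is flagged, not silently fitted.
    """
    if tr <= 0 or n_scans <= 0:
        raise ValidationError("tr and n_scans must be positive")
    if len(events) and events["onset"].max() >= n_scans * tr:
        raise ValidationError("event onsets extend beyond the scan horizon")
    if len(events) and modulator_col not in events.columns:
        raise ValidationError(f"events table lacks modulator column {modulator_col!r}")

    dt = tr / oversample
    hrf = double_gamma_hrf(dt, **(hrf_params or {}))
    n_hr = n_scans * oversample

    columns: dict[str, np.ndarray] = {}
    for task in sorted(events["trial_type"].unique()) if len(events) else []:
        sel = events[events["trial_type"] == task]
        idx = np.floor(sel["onset"].to_numpy(float) / dt).astype(int)
        sticks = np.zeros(n_hr)
        np.add.at(sticks, idx, 1.0)
        mod = sel[modulator_col].to_numpy(float)
        mod_sticks = np.zeros(n_hr)
        np.add.at(mod_sticks, idx, mod - mod.mean())
        columns[f"{task}_onset"] = _convolve_sampled(sticks, hrf, oversample, n_scans)
        columns[f"{task}_sv"] = _convolve_sampled(mod_sticks, hrf, oversample, n_scans)

    # Legendre drift on [-1, 1]
    x = np.linspace(-1.0, 1.0, n_scans)
    for order in range(1, drift_order + 1):
        columns[f"drift_{order}"] = np.polynomial.legendre.Legendre.basis(order)(x)
    columns["intercept"] = np.ones(n_scans)

    frame = pd.DataFrame(columns)
    full_rank = np.linalg.matrix_rank(frame.to_numpy()) == frame.shape[1]
    return DesignMatrix(frame=frame, tr=tr, hrf=hrf, full_rank=full_rank)


@dataclass
class GLMResult:
    """Per-voxel OLS estimates on a voxel grid."""

    betas: np.ndarray  # (p, x, y, z)
    names: list[str]
    residual_df: int
    sigma2: np.ndarray  # (x, y, z), NaN where residual variance is zero
    xtx_inv: np.ndarray
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma2.shape

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[self._index(name)]

    def _index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown regressor {name!r}; have {self.names}") from None

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self._index(name)] = w
        return c

    def t_map(self, weights: dict[str, float]) -> np.ndarray:
        """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c); NaN at zero-variance voxels."""
        c = self.contrast_vector(weights)
        effect = np.tensordot(c, self.betas, axes=1)
        var_scale = float(c @ self.xtx_inv @ c)
        with np.errstate(invalid="ignore", divide="ignore"):
            return effect / np.sqrt(self.sigma2 * var_scale)


def fit_glm(bold, design: DesignMatrix) -> GLMResult:
    """Mass-univariate OLS of a 4D volume against the design.

    ``bold`` may be a :class:`~moralsv.synthetic.SyntheticBold`, a nibabel
    spatial image, or a plain (x, y, z, t) array (identity affine assumed).
    """
    if hasattr(bold, "data") and hasattr(bold, "affine"):
        data, affine = np.asarray(bold.data, float), np.asarray(bold.affine)
    elif hasattr(bold, "get_fdata"):
        data, affine = bold.get_fdata(), bold.affine
    else:
        data, affine = np.asarray(bold, float), np.eye(4)
    if data.ndim != 4:
        raise ValidationError("BOLD data must be 4D (x, y, z, t)")
    x = design.matrix
    if data.shape[-1] != x.shape[0]:
        raise ValidationError(
            f"time dimension mismatch: {data.shape[-1]} scans vs {x.shape[0]} design rows"
        )
    if not design.full_rank:
        raise ValidationError("design matrix is rank deficient; refusing to fit")

    shape = data.shape[:3]
    y = data.reshape(-1, x.shape[0]).T  # (t, v)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    residual_df = x.shape[0] - int(rank)
    ssr = np.sum(resid**2, axis=0)
    # voxels fitted exactly (e.g. constant timeseries) have no residual
    # variance up to round-off; their t-statistics are undefined
    tol = np.sum(y**2, axis=0) * np.finfo(float).eps * 100.0
    sigma2 = np.where(ssr > tol, ssr / residual_df, np.nan)
    xtx_inv = np.linalg.inv(x.T @ x)
    return GLMResult(
        betas=beta.reshape(x.shape[1], *shape),
        names=design.names,
        residual_df=residual_df,
        sigma2=sigma2.reshape(shape),
        xtx_inv=xtx_inv,
        affine=affine,
    )


def contrast_sv_domains(
    result: GLMResult,
    pair: tuple[str, str] = ("moral_sv", "financial_sv"),
) -> np.ndarray:
    """t-map of the difference between two SV modulators.

    ``pair = (a, b)`` yields the contrast a − b; prefix a name with ``-``
    to flip its sign (e.g. ``("-moral_sv", "financial_sv")`` tests
    −SV_moral − SV_financial).  Negating a modulator this way is exactly
    equivalent to having negated the modulator column itself.
    """
    weights: dict[str, float] = {}
    for name, base_w in zip(pair, (1.0, -1.0)):
        if name.startswith("-"):
            weights[name[1:]] = weights.get(name[1:], 0.0) - base_w
        else:
            weights[name] = weights.get(name, 0.0) + base_w
    return result.t_map(weights)


def conjunction(t_map_a: np.ndarray, t_map_b: np.ndarray, threshold: float) -> np.ndarray:
    """Minimum-statistic conjunction: voxels where min(t_a, t_b) > threshold.

    NaN statistics never survive the conjunction.
    """
    t_map_a = np.asarray(t_map_a)
    t_map_b = np.asarray(t_map_b)
    if t_map_a.shape != t_map_b.shape:
        raise ValidationError(
            f"t-map grids differ: {t_map_a.shape} vs {t_map_b.shape}"
        )
    with np.errstate(invalid="ignore"):
        return np.fmin(t_map_a, t_map_b) > threshold  # NaN compares False


@dataclass
class RoiSpec:
    """Spherical region of interest on an isotropic voxel grid."""

    center: tuple[int, int, int]  # voxel indices, 0-based
    radius_mm: float = 8.0
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.voxel_size_mm <= 0:
            raise ValidationError("radius and voxel size must be positive")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.indices(shape).astype(float)
        dist2 = sum(
            ((grids[d] - self.center[d]) * self.voxel_size_mm) ** 2 for d in range(3)
        )
        return dist2 <= self.radius_mm**2


def roi_mean(map3d: np.ndarray, roi: RoiSpec) -> float:
    """Mean of a statistic map over the voxels inside the ROI sphere."""
    map3d = np.asarray(map3d)
    mask = roi.mask(map3d.shape)
    if not mask.any():
        raise ValidationError("ROI sphere contains no voxels within the volume")
    return float(np.nanmean(map3d[mask]))
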