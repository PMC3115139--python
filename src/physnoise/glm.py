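"""Voxel-wise nuisance regression and temporal-SNR maps.

The central objects follow the model/results idiom: :class:`NuisanceGLM` is
built from an :class:`EpiSeries` and a :class:`~.regressors.RegressorSet`, and
its :meth:`~NuisanceGLM.fit` returns a :class:`NuisanceGLMResults` carrying
per-voxel coefficients, residual standard deviations, degrees of freedom, and
methods to residualize the series, map adjusted R-squared, and summarise the
fit.  Thin functional wrappers (:func:`fit_nuisance`, :func:`residualize`,
:func:`tsnr`, :func:`r2_adj`) expose the same operations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .regressors import RegressorSet

__all__ = [
    "EpiSeries",
    "RoiMask",
    "NuisanceGLM",
    "NuisanceGLMResults",
    "fit_nuisance",
    "residualize",
    "tsnr",
    "r2_adj",
    "roi_summary",
    "percent_improvement",
    "save_map",
]

log = logging.getLogger(__name__)


@dataclass
class EpiSeries:
    """A 4-D EPI time series (x, y, z, volume) with acquisition metadata."""

    data: np.ndarray
    volume_tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got shape {self.data.shape}")
        if self.n_volumes < 8:
            raise ValueError(f"need >= 8 volumes, got {self.n_volumes}")
        if self.volume_tr <= 0:
            raise ValueError("volume_tr must be positive")
        check = self.data if self.mask is None else self.data[self.mask]
        if not np.all(np.isfinite(check)):
            raise ValueError("non-finite intensities inside mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def default_mask(self, fraction: float = 0.10) -> np.ndarray:
        """Voxels whose temporal mean exceeds ``fraction`` of the robust
        (99.5th percentile) maximum of the mean image."""
        mean = self.data.mean(axis=3)
        robust_max = np.percentile(mean, 99.5)
        return mean > fraction * robust_max

    @classmethod
    def from_nifti(cls, path: str | Path, volume_tr: float | None = None) -> "EpiSeries":
        img = nib.load(str(path))
        tr = volume_tr if volume_tr is not None else float(img.header.get_zooms()[3])
        return cls(np.asarray(img.get_fdata()), volume_tr=tr, affine=img.affine)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.volume_tr))
        nib.save(img, str(path))


@dataclass
class RoiMask:
    """Boolean region-of-interest volume with a label."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_nifti(cls, path: str | Path, label: str = "roi") -> "RoiMask":
        return cls(np.asarray(nib.load(str(path)).get_fdata()) > 0.5, label)


class NuisanceGLM:
    """Ordinary least squares of a nuisance design on every voxel time series.

    An intercept is always added internally; the design is mean-centred if it
    is not already, so the intercept carries the voxel mean.
    """

    def __init__(
        self,
        series: EpiSeries,
        design: RegressorSet,
        model_id: int | None = None,
        mask: np.ndarray | RoiMask | None = None,
    ):
        if design.n_volumes != series.n_volumes:
            raise ValueError(
                f"design has {design.n_volumes} rows for {series.n_volumes} volumes"
            )
        self.series = series
        self.design = design.mean_center()
        self.model_id = model_id
        if isinstance(mask, RoiMask):
            mask = mask.mask
        if mask is None:
            mask = series.mask
        self.mask = (
            np.ones(series.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        )

    def fit(self) -> "NuisanceGLMResults":
        n = self.series.n_volumes
        X = np.column_stack([np.ones(n), self.design.matrix])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"rank-deficient design (rank {rank} < {X.shape[1]} columns); "
                "solving by pseudoinverse",
                stacklevel=2,
            )
        Y = self.series.data[self.mask].T  # (n_volumes, n_voxels)
        betas = np.linalg.pinv(X) @ Y
        resid = Y - X @ betas
        residual_sd = np.std(resid, axis=0, ddof=1)
        return NuisanceGLMResults(model=self, betas=betas, residual_sd_flat=residual_sd)


class NuisanceGLMResults:
    """Per-voxel OLS results of a nuisance design."""

    def __init__(self, model: NuisanceGLM, betas: np.ndarray, residual_sd_flat: np.ndarray):
        self.model = model
        self.betas = betas  # (1 + p, n_masked_voxels); row 0 is the intercept
        self._residual_sd_flat = residual_sd_flat
        n = model.series.n_volumes
        self.df_tot = n - 1
        self.df_err = self.df_tot - model.design.n_regressors
        if self.df_err < 1:
            raise ValueError(
                f"df_err = {self.df_err} < 1: design too large for {n} volumes"
            )

    @property
    def model_id(self) -> int | None:
        return self.model.model_id

    @property
    def residual_sd(self) -> np.ndarray:
        """3-D map of residual standard deviations (NaN outside the mask)."""
        out = np.full(self.model.series.shape, np.nan)
        out[self.model.mask] = self._residual_sd_flat
        return out

    def residualize(self) -> EpiSeries:
        """Subtract the fitted nuisance effect, retaining the intercept.

        The voxel mean is preserved; voxels outside the mask pass through
        unchanged.
        """
        series = self.model.series
        fitted_nuisance = self.model.design.matrix @ self.betas[1:, :]
        corrected = series.data.copy()
        corrected[self.model.mask] = (series.data[self.model.mask].T - fitted_nuisance).T
        return EpiSeries(
            corrected, volume_tr=series.volume_tr, affine=series.affine, mask=series.mask
        )

    def r2_adj(self, df_convention: str = "standard") -> np.ndarray:
        """3-D map of the adjusted coefficient of determination.

        R2_adj = 1 - (SS_err / SS_tot) * (df_tot / df_err), with SS the sample
        variances of residual and data, df_tot = n - 1 and (standard
        convention) df_err = df_tot - p.  ``df_convention="conservative"``
        uses df_err = df_tot - 1 - p instead.
        """
        p = self.model.design.n_regressors
        if df_convention == "standard":
            df_err = self.df_tot - p
        elif df_convention == "conservative":
            df_err = self.df_tot - 1 - p
        else:
            raise ValueError(f"unknown df_convention {df_convention!r}")
        if df_err < 1:
            raise ValueError(f"df_err = {df_err} < 1")
        Y = self.model.series.data[self.model.mask].T
        ss_tot = np.var(Y, axis=0, ddof=1)
        ss_err = self._residual_sd_flat**2
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - (ss_err / ss_tot) * (self.df_tot / df_err)
        out = np.full(self.model.series.shape, np.nan)
        out[self.model.mask] = r2
        return out

    def summary(self) -> str:
        lines = [
            "Nuisance GLM results",
            "====================",
            f"model id:        {self.model_id}",
            f"volumes:         {self.model.series.n_volumes}",
            f"design columns:  {self.model.design.n_regressors} (+ intercept)",
            f"masked voxels:   {int(self.model.mask.sum())}",
            f"df_tot / df_err: {self.df_tot} / {self.df_err}",
            f"median residual sd: {np.median(self._residual_sd_flat):.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers and map utilities


def fit_nuisance(
    series: EpiSeries, design: RegressorSet, model_id: int | None = None
) -> NuisanceGLMResults:
    """OLS fit of a mean-centred nuisance design to every voxel."""
    return NuisanceGLM(series, design, model_id=model_id).fit()


def residualize(series: EpiSeries, fit: NuisanceGLMResults) -> EpiSeries:
    if fit.model.series is not series:
        raise ValueError("fit was computed on a different series")
    return fit.residualize()


def tsnr(series: EpiSeries) -> np.ndarray:
    """Temporal SNR map: voxel mean / sample standard deviation over time.

    Voxels with zero temporal standard deviation are undefined (NaN).
    """
    mean = series.data.mean(axis=3)
    sd = series.data.std(axis=3, ddof=1)
    n_flagged = int(np.sum(sd == 0))
    if n_flagged:
        log.info("tsnr: %d voxels with zero temporal sd set to NaN", n_flagged)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / sd, np.nan)
    return out


def r2_adj(
    series: EpiSeries, fit: NuisanceGLMResults, df_convention: str = "standard"
) -> np.ndarray:
    if fit.model.series is not series:
        raise ValueError("fit was computed on a different series")
    return fit.r2_adj(df_convention)


def roi_summary(map_values: np.ndarray, roi: RoiMask) -> float:
    """Mean of a map over the defined (finite) voxels of an ROI."""
    vals = map_values[roi.mask]
    defined = np.isfinite(vals)
    n_undef = int(np.sum(~defined))
    if n_undef:
        log.info("roi_summary(%s): %d undefined voxels excluded", roi.label, n_undef)
    if not defined.any():
        raise ValueError(f"ROI {roi.label!r} contains no defined voxels")
    return float(vals[defined].mean())


def percent_improvement(value_n, value_ref):
    """Percent change 100*(value_n/value_ref - 1); undefined where ref is."""
    value_n = np.asarray(value_n, dtype=float)
    value_ref = np.asarray(value_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (value_n / value_ref - 1.0)
    out = np.where(np.isfinite(value_ref) & (value_ref != 0), out, np.nan)
    return float(out) if out.ndim == 0 else out


def save_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3-D map as NIfTI on the given grid."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine), str(path))
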