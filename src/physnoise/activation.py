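"""Block-design activation analysis with nuisance regression.

Implements the visual block paradigm (left / fixation / right / fixation,
20 s blocks in an 80 s cycle repeated five times), canonical-HRF design
construction, volume-wise Gaussian smoothing, voxel-wise t-tests for each
condition against baseline, and significant-voxel counting under family-wise
error control (Bonferroni by default, max-statistic permutation optionally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.special import gammaln

from .glm import EpiSeries, RoiMask
from .physio import SliceTimingModel
from .regressors import RegressorSet

__all__ = [
    "StimulusDesign",
    "ActivationResult",
    "canonical_hrf",
    "build_design",
    "smooth_gaussian",
    "fit_task_glm",
    "count_significant",
    "permutation_threshold",
    "percent_diff_counts",
]


@dataclass
class StimulusDesign:
    """Timing of the two-condition block paradigm."""

    onsets: dict[str, np.ndarray]  # condition -> onset times (s)
    duration: float = 20.0
    cycle: float = 80.0
    n_cycles: int = 5
    hrf: str = "canonical"

    def __post_init__(self) -> None:
        events = []
        for cond, on in self.onsets.items():
            on = np.asarray(on, dtype=float)
            self.onsets[cond] = on
            events.extend((t, t + self.duration, cond) for t in on)
        events.sort()
        for (s0, e0, c0), (s1, e1, c1) in zip(events, events[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping blocks: {c0} [{s0},{e0}) and {c1} at {s1}")


@dataclass
class ActivationResult:
    """Voxel-wise t-map for one contrast, plus counting results."""

    t_map: np.ndarray
    df: int
    contrast: str
    model_id: int | None = None
    estimable: bool = True
    threshold: float | None = None
    n_significant: dict[str, int] = field(default_factory=dict)


def canonical_hrf(dt: float = 0.1, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak 6 s, undershoot
    16 s, undershoot ratio 1/6), normalised to unit peak."""
    t = np.arange(0.0, duration, dt)
    def gpdf(x, a, b):
        return np.exp(a * np.log(b) + (a - 1) * np.log(np.maximum(x, 1e-12)) - b * x - gammaln(a))
    h = gpdf(t, 6.0, 1.0) - gpdf(t, 16.0, 1.0) / 6.0
    return h / h.max()


def build_design(
    timing: SliceTimingModel,
    n_cycles: int = 5,
    block: float = 20.0,
    cycle: float | None = None,
    dt: float = 0.1,
) -> tuple[RegressorSet, StimulusDesign]:
    """Condition boxcars convolved with the canonical HRF, one column per side.

    Left blocks start each cycle, right blocks start half a cycle later
    (left; fixation; right; fixation).  Regressors are sampled at each
    volume's reference-slice time.
    """
    if cycle is None:
        cycle = 4.0 * block
    onsets = {
        "left": np.arange(n_cycles) * cycle,
        "right": np.arange(n_cycles) * cycle + 2.0 * block,
    }
    design = StimulusDesign(onsets=onsets, duration=block, cycle=cycle, n_cycles=n_cycles)
    t_ref = timing.reference_times
    t_end = max(t_ref[-1], n_cycles * cycle) + 32.0
    grid = np.arange(0.0, t_end, dt)
    hrf = canonical_hrf(dt)
    cols = []
    for cond in ("left", "right"):
        boxcar = np.zeros(grid.size)
        for on in onsets[cond]:
            boxcar[(grid >= on) & (grid < on + block)] = 1.0
        conv = np.convolve(boxcar, hrf)[: grid.size] * dt
        cols.append(np.interp(t_ref, grid, conv))
    matrix = np.column_stack(cols)
    matrix /= matrix.max()  # unit plateau for a fully developed block
    return RegressorSet(matrix, ["left", "right"]), design


def smooth_gaussian(series: EpiSeries, fwhm: float) -> EpiSeries:
    """Volume-wise isotropic Gaussian smoothing with the given FWHM in mm.

    The per-axis sigma in voxel units is derived from the affine's voxel
    sizes; sigma = FWHM / sqrt(8 ln 2) in mm.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return series
    voxel_sizes = np.sqrt((series.affine[:3, :3] ** 2).sum(axis=0))
    sigma_mm = fwhm / np.sqrt(8.0 * np.log(2.0))
    sigma_vox = tuple(sigma_mm / voxel_sizes) + (0.0,)
    smoothed = ndimage.gaussian_filter(series.data, sigma=sigma_vox, mode="nearest")
    return EpiSeries(
        smoothed, volume_tr=series.volume_tr, affine=series.affine, mask=series.mask
    )


def fit_task_glm(
    series: EpiSeries,
    task: RegressorSet,
    nuisance: RegressorSet | None = None,
    hp: RegressorSet | None = None,
    model_id: int | None = None,
    mask: np.ndarray | RoiMask | None = None,
) -> list[ActivationResult]:
    """OLS of [task, nuisance, high-pass, intercept]; one t-map per condition.

    t = contrast estimate / its standard error, df = n - rank(X).  A contrast
    made inestimable by rank deficiency (e.g. the task duplicated among the
    nuisance regressors) is flagged with ``estimable=False`` and a NaN map.
    """
    n = series.n_volumes
    parts = [task]
    if nuisance is not None and nuisance.n_regressors:
        parts.append(nuisance)
    if hp is not None and hp.n_regressors:
        parts.append(hp)
    for part in parts:
        if part.n_volumes != n:
            raise ValueError(
                f"regressor rows ({part.n_volumes}) do not match volumes ({n})"
            )
    X = np.column_stack([np.ones(n)] + [p.matrix for p in parts])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient task design (rank {rank} < {X.shape[1]})", stacklevel=2
        )
    if isinstance(mask, RoiMask):
        mask = mask.mask
    if mask is None:
        mask = series.mask if series.mask is not None else np.ones(series.shape, bool)
    Y = series.data[mask].T
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = pinv @ pinv.T  # pseudoinverse of X'X
    xtx = X.T @ X

    results = []
    for j, cond in enumerate(task.labels):
        c = np.zeros(X.shape[1])
        c[1 + j] = 1.0  # column order: intercept, task, ...
        estimable = bool(np.allclose(xtx @ xtx_inv @ c, c, atol=1e-8))
        t_map = np.full(series.shape, np.nan)
        if estimable:
            se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_map[mask] = np.where(se > 0, (c @ betas) / se, np.nan)
        else:
            warnings.warn(f"contrast {cond!r} inestimable", stacklevel=2)
        results.append(
            ActivationResult(t_map=t_map, df=df, contrast=cond, model_id=model_id,
                             estimable=estimable)
        )
    return results


def count_significant(
    result: ActivationResult,
    roi: RoiMask,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    brain_mask: np.ndarray | None = None,
    t_threshold: float | None = None,
) -> int:
    """Count ROI voxels significant at family-wise error level ``alpha``.

    Bonferroni correction is taken over all in-brain voxels (one-sided test
    of positive activation).  With ``correction="precomputed"`` a max-statistic
    permutation threshold from :func:`permutation_threshold` can be supplied.
    """
    if brain_mask is None:
        brain_mask = np.isfinite(result.t_map)
    n_brain = int(brain_mask.sum())
    if correction == "bonferroni":
        if n_brain == 0:
            raise ValueError("empty brain mask")
        thr = float(stats.t.isf(alpha / n_brain, result.df))
    elif correction == "precomputed":
        if t_threshold is None:
            raise ValueError("t_threshold required for precomputed correction")
        thr = float(t_threshold)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    result.threshold = thr
    vals = result.t_map[roi.mask & brain_mask]
    count = int(np.sum(vals > thr))
    result.n_significant[roi.label] = count
    return count


def permutation_threshold(
    series: EpiSeries,
    task: RegressorSet,
    nuisance: RegressorSet | None = None,
    hp: RegressorSet | None = None,
    contrast: str = "left",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> float:
    """Max-statistic FWE threshold by permuting the task-regressor rows.

    Permutation of the volume order of the task columns (nuisance and
    high-pass regressors fixed) yields the null distribution of the maximal
    voxel t; the (1 - alpha) quantile is the corrected threshold.
    """
    rng = np.random.default_rng(seed)
    j = task.labels.index(contrast)
    max_t = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(task.n_volumes)
        task_p = RegressorSet(task.matrix[perm], task.labels, task.mean_centered)
        res = fit_task_glm(series, task_p, nuisance, hp, mask=mask)[j]
        max_t[i] = np.nanmax(res.t_map)
    return float(np.quantile(max_t, 1.0 - alpha))


def percent_diff_counts(count_n: int, count_1: int) -> float:
    """Percent difference in significant-voxel counts vs the reference model.

    Undefined (NaN) when the reference count is zero.
    """
    if count_1 == 0:
        return float("nan")
    return 100.0 * (count_n / count_1 - 1.0)
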