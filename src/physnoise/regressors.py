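"""Nuisance regressor construction for EPI time series.

Builds the regressor families used for physiological noise correction:

* **CRP** — cardiac and respiratory phase Fourier sets (RETROICOR-style),
  extending to the 3rd harmonic by default (12 columns);
* **RV** — respiratory volume: sliding-window standard deviation of the belt
  signal convolved with a respiratory response function;
* **HR** — heart rate: inverse mean beat-to-beat interval convolved with a
  cardiac response function;
* **MP** — the six rigid-body motion parameters;
* **HW** — linear and quadratic drifts in image number;
* a discrete-cosine high-pass basis (128 s cut-off by default).

All regressors are sampled at the reference slice of each volume and can be
assembled into the twelve standard model combinations via
:func:`assemble_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .physio import EventTimes, PhysioRecording, SliceTimingModel

__all__ = [
    "PhaseSeries",
    "ResponseFunction",
    "RegressorSet",
    "default_rrf",
    "default_crf",
    "cardiac_phase",
    "respiratory_phase",
    "fourier_expand",
    "build_crp",
    "sliding_window_std",
    "rv_regressor",
    "heart_rate_series",
    "hr_regressor",
    "motion_regressors",
    "motion_regressors_from_array",
    "drift_regressors",
    "highpass_basis",
    "assemble_model",
    "MODEL_PARTS",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseSeries:
    """Per-volume physiological phase in [0, 2*pi)."""

    values: np.ndarray
    source: str  # "cardiac" or "respiratory"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite phase values")
        if np.any((self.values < 0) | (self.values >= TWO_PI)):
            raise ValueError("phases must lie in [0, 2*pi)")
        if self.source not in ("cardiac", "respiratory"):
            raise ValueError(f"unknown phase source {self.source!r}")


@dataclass
class ResponseFunction:
    """Sampled impulse response kernel (RRF or CRF)."""

    dt: float
    samples: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite response-function samples")
        if self.duration < 30.0:
            raise ValueError(f"{self.name}: duration {self.duration:.1f} s < 30 s")

    @property
    def duration(self) -> float:
        return self.dt * self.samples.size


def default_rrf(dt: float = 0.05, duration: float = 60.0) -> ResponseFunction:
    """Respiratory response function: double-gamma kernel.

    RRF(t) = 0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25), t in seconds.
    Positive peak near 3.4 s, broad negative lobe around 15 s.
    """
    t = np.arange(0.0, duration, dt)
    s = 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(-t / 4.25)
    return ResponseFunction(dt=dt, samples=s, name="RRF")


def default_crf(dt: float = 0.05, duration: float = 60.0) -> ResponseFunction:
    """Cardiac response function: gamma peak plus late inverted Gaussian.

    CRF(t) = 0.6 t^2.7 exp(-t/1.6) - 16/sqrt(18*pi) exp(-(t-12)^2/18).
    Positive peak near 4 s, negative lobe centred at 12 s.
    """
    t = np.arange(0.0, duration, dt)
    s = 0.6 * t**2.7 * np.exp(-t / 1.6) - 16.0 / np.sqrt(18.0 * np.pi) * np.exp(
        -((t - 12.0) ** 2) / 18.0
    )
    return ResponseFunction(dt=dt, samples=s, name="CRF")


class RegressorSet:
    """A labeled per-volume design matrix (n_volumes x p)."""

    def __init__(self, matrix: np.ndarray, labels: list[str], mean_centered: bool = False):
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if matrix.shape[1] != len(labels):
            raise ValueError(
                f"{len(labels)} labels for {matrix.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("non-finite entries in regressor matrix")
        self.matrix = matrix
        self.labels = list(labels)
        self.mean_centered = mean_centered

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def mean_center(self) -> "RegressorSet":
        """Remove each column's mean (idempotent)."""
        if self.mean_centered:
            return self
        m = self.matrix - self.matrix.mean(axis=0, keepdims=True)
        return RegressorSet(m, self.labels, mean_centered=True)

    @classmethod
    def concat(cls, sets: list["RegressorSet"]) -> "RegressorSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        n = {s.n_volumes for s in sets}
        if len(n) != 1:
            raise ValueError(f"row-count mismatch across parts: {sorted(n)}")
        matrix = np.hstack([s.matrix for s in sets])
        labels = [lab for s in sets for lab in s.labels]
        return cls(matrix, labels, mean_centered=all(s.mean_centered for s in sets))

    def to_tsv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write the design as TSV with a header row; optional JSON sidecar."""
        pd.DataFrame(self.matrix, columns=self.labels).to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# phase regressors


def cardiac_phase(beats: EventTimes, timing: SliceTimingModel) -> PhaseSeries:
    """Cardiac phase at each volume's reference-slice time.

    Within a beat-to-beat interval [t_k, t_{k+1}) the phase advances linearly,
    phi(t) = 2*pi*(t - t_k)/(t_{k+1} - t_k).  Times outside the beat span are
    clamped to the nearest interval and extrapolated (wrapped into [0, 2*pi)).
    """
    bt = beats.times
    if bt.size < 2:
        raise ValueError("at least 2 beats required for phase assignment")
    t = timing.reference_times
    k = np.searchsorted(bt, t, side="right") - 1
    k = np.clip(k, 0, bt.size - 2)
    phase = TWO_PI * (t - bt[k]) / (bt[k + 1] - bt[k])
    return PhaseSeries(np.mod(phase, TWO_PI), source="cardiac")


def _resample(rec_times: np.ndarray, x: np.ndarray, fs_out: float) -> tuple[np.ndarray, np.ndarray]:
    t_out = np.arange(rec_times[0], rec_times[-1], 1.0 / fs_out)
    return t_out, np.interp(t_out, rec_times, x)


def respiratory_phase(
    rec: PhysioRecording,
    timing: SliceTimingModel,
    fs_resample: float = 20.0,
    n_bins: int = 100,
) -> PhaseSeries:
    """Respiratory phase via amplitude-histogram equalization of the belt.

    The belt is resampled to the slice-acquisition frequency (20 Hz), its
    run-wide amplitude histogram defines a cumulative transfer function
    H(b) in [0, 1], and phi = pi*H(b) during inhalation (belt derivative >= 0)
    or 2*pi - pi*H(b) during exhalation.  The result is sampled at each
    volume's reference time.
    """
    if rec.respiratory is None:
        raise ValueError("recording has no respiratory channel")
    b_raw = rec.respiratory
    if np.ptp(b_raw) == 0:
        raise ValueError("respiratory phase undefined for a constant belt signal")
    t20, b = _resample(rec.times, b_raw, fs_resample)
    hist, edges = np.histogram(b, bins=n_bins)
    cdf = np.cumsum(hist) / b.size
    bins = np.clip(np.digitize(b, edges[1:-1]), 0, n_bins - 1)
    h = cdf[bins]
    dbdt = np.gradient(b, t20)
    phase = np.where(dbdt >= 0, np.pi * h, TWO_PI - np.pi * h)
    idx = np.clip(
        np.searchsorted(t20, timing.reference_times), 0, t20.size - 1
    )
    return PhaseSeries(np.mod(phase[idx], TWO_PI), source="respiratory")


def fourier_expand(phase: PhaseSeries, n_harmonics: int = 3) -> RegressorSet:
    """Sine/cosine expansion [sin k*phi, cos k*phi] for k = 1..n_harmonics."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    cols, labels = [], []
    prefix = "c" if phase.source == "cardiac" else "r"
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(k * phase.values))
        labels.append(f"{prefix}_sin{k}")
        cols.append(np.cos(k * phase.values))
        labels.append(f"{prefix}_cos{k}")
    return RegressorSet(np.column_stack(cols), labels)


def build_crp(
    beats: EventTimes,
    rec: PhysioRecording,
    timing: SliceTimingModel,
    n_harmonics: int = 3,
) -> RegressorSet:
    """Cardiac + respiratory phase Fourier sets (4*n_harmonics columns)."""
    cp = fourier_expand(cardiac_phase(beats, timing), n_harmonics)
    rp = fourier_expand(respiratory_phase(rec, timing), n_harmonics)
    return RegressorSet.concat([cp, rp])


# ---------------------------------------------------------------------------
# low-frequency cardio-respiratory regressors


def sliding_window_std(series: np.ndarray, fs: float, window: float = 6.0) -> np.ndarray:
    """Standard deviation over a centred sliding window, truncated at edges.

    Sample (N-1) standard deviation; the window covers ``window`` seconds at
    sampling rate ``fs`` and is truncated (not NaN-padded) at the run edges.
    """
    x = np.asarray(series, dtype=float)
    n_w = int(round(window * fs))
    if n_w < 2:
        raise ValueError("window must span at least 2 samples")
    n = x.size
    half = n_w // 2
    out = np.empty(n)
    if n >= n_w:
        views = sliding_window_view(x, n_w)  # windows starting at 0..n-n_w
        interior = np.std(views, axis=1, ddof=1)
        # window for sample i starts at i - half; valid for i in [half, n-n_w+half]
        out[half : n - n_w + half + 1] = interior
    for i in range(min(half, n)):
        seg = x[: min(i - half + n_w, n)]
        out[i] = np.std(seg, ddof=1) if seg.size > 1 else 0.0
    for i in range(max(n - n_w + half + 1, 0), n):
        seg = x[max(i - half, 0) :]
        out[i] = np.std(seg, ddof=1) if seg.size > 1 else 0.0
    return out


def _convolve_response(
    x: np.ndarray, dt: float, rf: ResponseFunction
) -> np.ndarray:
    """Causal zero-padded convolution of x with a response kernel."""
    kernel = rf.samples
    if not np.isclose(dt, rf.dt, rtol=1e-6):
        t_old = np.arange(kernel.size) * rf.dt
        t_new = np.arange(0.0, rf.duration, dt)
        kernel = np.interp(t_new, t_old, kernel)
    return np.convolve(x, kernel)[: x.size] * dt


def rv_regressor(
    rec: PhysioRecording,
    timing: SliceTimingModel,
    rrf: ResponseFunction | None = None,
    window: float = 6.0,
    fs_resample: float = 20.0,
) -> RegressorSet:
    """Respiratory-volume regressor: windowed belt std convolved with the RRF."""
    if rec.respiratory is None:
        raise ValueError("recording has no respiratory channel")
    if rrf is None:
        rrf = default_rrf()
    t20, belt = _resample(rec.times, rec.respiratory, fs_resample)
    rv = sliding_window_std(belt, fs_resample, window)
    conv = _convolve_response(rv, 1.0 / fs_resample, rrf)
    col = np.interp(timing.reference_times, t20, conv)
    return RegressorSet(col[:, None], ["RV"])


def heart_rate_series(
    beats: EventTimes,
    window: float = 6.0,
    fs: float = 20.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Heart rate (1/s) on a uniform grid: inverse mean beat-to-beat interval.

    At each grid point the mean is taken over the intervals that intersect the
    centred ``window``-second span; grid points whose window contains no
    interval fall back to the nearest interval.
    """
    bt = beats.times
    if bt.size < 2:
        raise ValueError("at least 2 beats required")
    if t_start is None:
        t_start = bt[0]
    if t_end is None:
        t_end = bt[-1]
    t = np.arange(t_start, t_end + 0.5 / fs, 1.0 / fs)
    intervals = np.diff(bt)
    starts, ends = bt[:-1], bt[1:]
    half = window / 2.0
    hr = np.empty(t.size)
    for i, ti in enumerate(t):
        lo, hi = ti - half, ti + half
        # intervals (starts[j], ends[j]) overlapping (lo, hi)
        j0 = np.searchsorted(ends, lo, side="right")
        j1 = np.searchsorted(starts, hi, side="left")
        if j1 <= j0:
            j0 = min(max(j0, 0), intervals.size - 1)
            hr[i] = 1.0 / intervals[j0]
        else:
            hr[i] = 1.0 / np.mean(intervals[j0:j1])
    return t, hr


def hr_regressor(
    beats: EventTimes,
    timing: SliceTimingModel,
    crf: ResponseFunction | None = None,
    window: float = 6.0,
    fs: float = 20.0,
) -> RegressorSet:
    """Heart-rate regressor: windowed rate convolved with the CRF."""
    if crf is None:
        crf = default_crf()
    t_start = min(beats.times[0], timing.reference_times[0])
    t_end = max(beats.times[-1], timing.reference_times[-1])
    t, hr = heart_rate_series(beats, window=window, fs=fs, t_start=t_start, t_end=t_end)
    conv = _convolve_response(hr, 1.0 / fs, crf)
    col = np.interp(timing.reference_times, t, conv)
    return RegressorSet(col[:, None], ["HR"])


# ---------------------------------------------------------------------------
# motion, drift and high-pass regressors


def motion_regressors_from_array(params: np.ndarray, n_volumes: int) -> RegressorSet:
    """Validate and wrap a (n_volumes x 6) rigid-body parameter array."""
    params = np.asarray(params, dtype=float)
    if params.shape != (n_volumes, 6):
        raise ValueError(
            f"motion parameters must be {n_volumes} x 6, got {params.shape}"
        )
    labels = ["tx", "ty", "tz", "rx", "ry", "rz"]
    return RegressorSet(params, labels)


def motion_regressors(motion_path: str | Path, n_volumes: int) -> RegressorSet:
    """Read 6-column whitespace-delimited motion parameters (mm / radians)."""
    params = np.loadtxt(motion_path, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(
            f"{motion_path}: expected 6 columns (3 translations, 3 rotations), "
            f"found {params.shape[1]}"
        )
    return motion_regressors_from_array(params, n_volumes)


def drift_regressors(n_volumes: int) -> RegressorSet:
    """Linear and quadratic drift in image number (hardware drift model).

    Columns are centred and scaled to unit maximum for conditioning; after
    mean-centering they are mutually orthogonal for any run length.
    """
    i = np.arange(n_volumes) - (n_volumes - 1) / 2.0
    lin = i / np.max(np.abs(i)) if n_volumes > 1 else i
    quad = i**2
    quad = quad / np.max(quad) if n_volumes > 1 else quad
    return RegressorSet(np.column_stack([lin, quad]), ["HW1", "HW2"])


def highpass_basis(n_volumes: int, volume_tr: float, cutoff: float = 128.0) -> RegressorSet:
    """Discrete-cosine confound basis for high-pass filtering.

    Includes every DCT component with period >= ``cutoff`` seconds, i.e.
    floor(2 * n_volumes * volume_tr / cutoff) columns.
    """
    n_cols = int(np.floor(2.0 * n_volumes * volume_tr / cutoff))
    i = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n_volumes)) for k in range(1, n_cols + 1)]
    matrix = np.column_stack(cols) if cols else np.empty((n_volumes, 0))
    return RegressorSet(matrix, [f"HP{k}" for k in range(1, n_cols + 1)])


# ---------------------------------------------------------------------------
# model assembly

#: Regressor families entering each of the 12 standard model combinations.
MODEL_PARTS: dict[int, tuple[str, ...]] = {
    1: ("HW",),
    2: ("HW", "CP", "RP"),
    3: ("HW", "RV", "HR"),
    4: ("HW", "CP", "RP", "RV", "HR"),
    5: ("HW", "MP"),
    6: ("HW", "CP", "RP", "RV", "HR", "MP"),
    7: ("HW", "CP"),
    8: ("HW", "RP"),
    9: ("HW", "RV"),
    10: ("HW", "HR"),
    11: ("HW", "CP", "RP", "MP"),
    12: ("HW", "RV", "HR", "MP"),
}


def assemble_model(
    model_id: int,
    parts: dict[str, RegressorSet],
    include_baseline: bool = True,
) -> RegressorSet:
    """Assemble one of the 12 model combinations into a mean-centred design.

    ``parts`` maps family names (HW, CP, RP, RV, HR, MP) to their regressor
    sets.  With ``include_baseline=False`` the HW drift family is omitted
    (used when a high-pass basis replaces it in activation analyses).
    """
    if model_id not in MODEL_PARTS:
        raise ValueError(f"model_id must be 1..12, got {model_id}")
    wanted = MODEL_PARTS[model_id]
    if not include_baseline:
        wanted = tuple(p for p in wanted if p != "HW")
    pieces = []
    for name in wanted:
        if name not in parts:
            raise ValueError(f"model {model_id} requires missing part {name!r}")
        pieces.append(parts[name])
    if not pieces:
        n = next(iter(parts.values())).n_volumes
        return RegressorSet(np.empty((n, 0)), [], mean_centered=True)
    return RegressorSet.concat(pieces).mean_center()
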