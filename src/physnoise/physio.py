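"""Peripheral physiological recordings: reading, event detection, scan timing.

Recordings follow the common physio-log convention of a tab-separated trace
file (one column per channel) plus a JSON sidecar declaring the sampling
frequency, the start time of the first sample relative to the first retained
EPI volume, and the column names.  Cardiac traces are pulse-oximeter-like
waveforms; the respiratory trace is an (uncalibrated) pneumatic belt voltage;
the trigger channel carries the scanner's slice-synchronization pulses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysioRecording",
    "EventTimes",
    "SliceTimingModel",
    "read_physio",
    "write_events",
    "detect_cardiac_beats",
    "detect_slice_triggers",
    "slice_timing_from_triggers",
    "uniform_slice_timing",
]


@dataclass
class PhysioRecording:
    """Uniformly sampled physiological channels tied to the scan clock.

    ``t0`` is the time of the first sample relative to the first retained EPI
    volume (negative when recording started before the scan).
    """

    sampling_rate: float
    cardiac: np.ndarray | None = None
    respiratory: np.ndarray | None = None
    trigger: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        lengths = {
            name: len(ch)
            for name, ch in [
                ("cardiac", self.cardiac),
                ("respiratory", self.respiratory),
                ("trigger", self.trigger),
            ]
            if ch is not None
        }
        if not lengths:
            raise ValueError("at least one channel is required")
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch: {lengths}")
        for name in lengths:
            ch = np.asarray(getattr(self, name), dtype=float)
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise ValueError(
                    f"non-finite samples in channel {name!r} at rows {bad[:10].tolist()}"
                )
            setattr(self, name, ch)

    @property
    def n_samples(self) -> int:
        for ch in (self.cardiac, self.respiratory, self.trigger):
            if ch is not None:
                return len(ch)
        raise AssertionError("unreachable")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on the scan clock."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EventTimes:
    """Strictly increasing event times (seconds) of one kind."""

    times: np.ndarray
    kind: str  # "beat" or "slice_trigger"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SliceTimingModel:
    """Acquisition timing: one reference-slice time per volume."""

    volume_tr: float
    n_slices: int
    n_volumes: int
    reference_slice: int
    reference_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.reference_slice < self.n_slices:
            raise ValueError(
                f"reference_slice {self.reference_slice} outside [0, {self.n_slices})"
            )
        if self.reference_times is None:
            raise ValueError("reference_times required (or use uniform_slice_timing)")
        self.reference_times = np.asarray(self.reference_times, dtype=float)
        if self.reference_times.size != self.n_volumes:
            raise ValueError("one reference time per volume required")
        if self.n_volumes > 1 and not np.all(np.diff(self.reference_times) > 0):
            raise ValueError("reference_times must be strictly increasing")


def read_physio(trace_path: str | Path, sidecar_path: str | Path) -> PhysioRecording:
    """Read a tab-separated physio trace plus its JSON sidecar.

    The sidecar must declare ``SamplingFrequency`` (Hz) and ``Columns``
    (channel names, in file order); ``StartTime`` (seconds relative to the
    first retained EPI volume) defaults to 0.
    """
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if "SamplingFrequency" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} missing SamplingFrequency")
    fs = float(sidecar["SamplingFrequency"])
    if fs <= 0:
        raise ValueError(f"SamplingFrequency must be positive, got {fs}")
    columns = sidecar.get("Columns")
    if not columns:
        raise ValueError(f"sidecar {sidecar_path} missing Columns")
    t0 = float(sidecar.get("StartTime", 0.0))

    table = pd.read_csv(trace_path, sep="\t", header=None, comment="#")
    if table.shape[1] != len(columns):
        raise ValueError(
            f"{trace_path}: expected {len(columns)} columns per sidecar, "
            f"found {table.shape[1]}"
        )
    channels: dict[str, np.ndarray] = {}
    for i, name in enumerate(columns):
        col = pd.to_numeric(table.iloc[:, i], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise ValueError(
                f"{trace_path}: non-finite values in column {name!r} "
                f"at rows {bad[:10].tolist()}"
            )
        channels[name] = col
    known = {k: v for k, v in channels.items() if k in ("cardiac", "respiratory", "trigger")}
    if not known:
        raise ValueError(
            f"no recognized channel among {list(channels)}; "
            "expected cardiac/respiratory/trigger"
        )
    return PhysioRecording(sampling_rate=fs, t0=t0, **known)


def write_events(events: EventTimes, path: str | Path) -> None:
    """Write detected events as a two-column TSV (time_s, kind)."""
    pd.DataFrame({"time_s": events.times, "kind": events.kind}).to_csv(
        path, sep="\t", index=False
    )


def _rising_crossings(x: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of samples where x crosses threshold from below."""
    above = x >= threshold
    return np.flatnonzero(~above[:-1] & above[1:]) + 1


def detect_cardiac_beats(
    rec: PhysioRecording,
    min_interval: float = 0.25,
    threshold_quantile: float = 0.60,
) -> EventTimes:
    """Detect heart beats as rising edges of the cardiac pulse waveform.

    The threshold sits at ``threshold_quantile`` of the channel's amplitude
    range; an upward crossing within ``min_interval`` seconds of the previous
    accepted beat is suppressed (refractory rule), which makes the detector
    robust to dicrotic notches in pulse-oximeter waveforms.
    """
    if rec.cardiac is None:
        raise ValueError("recording has no cardiac channel")
    if min_interval <= 0:
        raise ValueError("min_interval must be positive")
    x = rec.cardiac
    lo, hi = float(np.min(x)), float(np.max(x))
    threshold = lo + threshold_quantile * (hi - lo)
    idx = _rising_crossings(x, threshold)
    times = rec.t0 + idx / rec.sampling_rate
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_interval:
            kept.append(float(t))
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 beats detected ({len(kept)}); phase assignment impossible"
        )
    return EventTimes(np.asarray(kept), kind="beat")


def detect_slice_triggers(rec: PhysioRecording, threshold: float | None = None) -> EventTimes:
    """Rising-edge times of the scanner slice-synchronization channel.

    Each pulse is counted once regardless of its width (edge, not level,
    detection).  Default threshold: midpoint of the channel range.
    """
    if rec.trigger is None:
        raise ValueError("recording has no trigger channel")
    x = rec.trigger
    if threshold is None:
        threshold = 0.5 * (float(np.min(x)) + float(np.max(x)))
    idx = _rising_crossings(x, threshold)
    if idx.size == 0:
        raise ValueError("zero slice triggers detected")
    return EventTimes(rec.t0 + idx / rec.sampling_rate, kind="slice_trigger")


def slice_timing_from_triggers(
    triggers: EventTimes,
    n_slices: int,
    n_volumes: int,
    reference_slice: int,
    slice_order: Sequence[int] | None = None,
) -> SliceTimingModel:
    """Bind the trigger stream to a per-volume reference-slice timing model.

    Triggers are assumed to arrive in ascending within-volume slice order
    unless ``slice_order`` (acquisition order of slice indices) says otherwise.
    """
    expected = n_slices * n_volumes
    if len(triggers) != expected:
        raise ValueError(
            f"trigger count mismatch: expected {expected} "
            f"({n_slices} slices x {n_volumes} volumes), observed {len(triggers)}"
        )
    order = list(slice_order) if slice_order is not None else list(range(n_slices))
    if sorted(order) != list(range(n_slices)):
        raise ValueError("slice_order must be a permutation of slice indices")
    pos_in_volume = order.index(reference_slice)
    grid = triggers.times.reshape(n_volumes, n_slices)
    ref = grid[:, pos_in_volume]
    tr = float(np.median(np.diff(ref))) if n_volumes > 1 else float(
        n_slices * np.median(np.diff(triggers.times))
    )
    return SliceTimingModel(
        volume_tr=tr,
        n_slices=n_slices,
        n_volumes=n_volumes,
        reference_slice=reference_slice,
        reference_times=ref,
    )


def uniform_slice_timing(
    volume_tr: float,
    n_slices: int,
    n_volumes: int,
    reference_slice: int = 0,
) -> SliceTimingModel:
    """Fallback timing model when no trigger channel was recorded.

    Assumes ascending equidistant slice acquisition within each TR.
    """
    ref = (np.arange(n_volumes) + reference_slice / n_slices) * volume_tr
    return SliceTimingModel(
        volume_tr=volume_tr,
        n_slices=n_slices,
        n_volumes=n_volumes,
        reference_slice=reference_slice,
        reference_times=ref,
    )
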