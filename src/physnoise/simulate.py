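"""Synthetic physiological recordings and EPI series with known ground truth.

The generator emulates the statistical structure the analysis assumes:
quasi-periodic cardiac pulses (~1 s period) and breathing (~3 s period) with
slow rate and depth variation, signal-proportional physiological fluctuations
plus additive thermal noise (the Krueger-type structure behind the
lambda/kappa model), spoiled gradient-echo steady-state baselines across flip
angles (T1 = 1.9 s, TR = 2 s), respiration-coupled apparent motion, low-order
drifts, no-excitation noise volumes, and block-design activation.  Every
injected component and parameter is recorded in :class:`GroundTruth`, so each
analysis module can be validated against known truth without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .glm import EpiSeries, RoiMask
from .physio import EventTimes, PhysioRecording, uniform_slice_timing
from .regressors import (
    RegressorSet,
    cardiac_phase,
    drift_regressors,
    fourier_expand,
    hr_regressor,
    respiratory_phase,
    rv_regressor,
)
from .snr import NoiseVolumes, spgr_signal

__all__ = [
    "PhysioSimConfig",
    "EpiSimConfig",
    "GroundTruth",
    "simulate_physio",
    "simulate_epi",
    "simulate_activation",
    "make_rois",
]


@dataclass
class PhysioSimConfig:
    """Parameters of the peripheral-recording simulator."""

    duration: float = 310.0  # seconds; must cover the EPI run plus a tail
    fs: float = 100.0  # samples/second
    hr_mean: float = 1.0  # mean heart rate, 1/s (60 bpm)
    hr_sd: float = 0.05  # slow heart-rate variation, 1/s
    br_mean: float = 1.0 / 3.0  # mean breathing rate, 1/s (~3 s period)
    br_sd: float = 0.02  # slow breathing-rate variation, 1/s
    depth_mod: float = 0.2  # fractional breathing-depth modulation
    lead_in: float = 1.0  # seconds recorded before the first slice trigger
    volume_tr: float = 2.0
    n_slices: int = 12
    n_volumes: int = 150
    trigger_volts: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_mean <= 0 or self.br_mean <= 0:
            raise ValueError("rates must be positive")
        if self.duration <= 30.0:
            raise ValueError("duration must exceed 30 s")
        if self.duration * self.hr_mean < 2:
            raise ValueError("configured rate implies fewer than 2 beats")
        if self.duration < self.n_volumes * self.volume_tr:
            raise ValueError("recording shorter than the EPI run")


@dataclass
class EpiSimConfig:
    """Parameters of the multi-flip-angle EPI simulator.

    ``amp_*`` are fractional (of local baseline signal) standard deviations of
    the injected fluctuation components; ``amp_unexplained`` is the
    signal-proportional fluctuation no nuisance regressor can model (it sets
    the post-correction tSNR asymptote).  ``kappa_true`` enters as a
    multiplicative miscalibration of the stored thermal-noise scale, emulating
    multi-channel noise covariance in the SNR0' measure.
    """

    grid: tuple[int, int, int] = (24, 24, 12)
    volume_tr: float = 2.0
    n_volumes: int = 150
    flip_angles: tuple[float, ...] = (8.0, 16.0, 26.0, 38.0, 70.0)
    t1: float = 1.9
    s_max: float = 1000.0
    amp_cardiac: float = 0.0055
    amp_resp: float = 0.0045
    amp_rv: float = 0.0012
    amp_hr: float = 0.0010
    amp_mp: float = 0.0055
    amp_unexplained: float = 0.00625
    motion_amp: float = 0.15  # mm (and ~mrad) scale of the motion traces
    resp_motion_coupling: float = 0.5
    drift_coeffs: tuple[float, float] = (0.002, 0.001)
    sigma_thermal: float = 1.96
    kappa_true: float = 1.7
    act_amp: float = 0.0  # percent signal change, applied by simulate_activation
    n_noise_volumes: int = 20
    voxel_size: float = 3.0  # mm isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amp_cardiac", "amp_resp", "amp_rv", "amp_hr", "amp_mp",
                     "amp_unexplained", "motion_amp", "sigma_thermal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(a <= 0 or a > 90 for a in self.flip_angles):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.kappa_true < 1:
            raise ValueError("kappa_true must be >= 1")

    @property
    def n_slices(self) -> int:
        return self.grid[2]

    @property
    def reference_slice(self) -> int:
        return self.grid[2] // 2

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size] * 3 + [1.0])
        return a

    def physio_config(self, **overrides) -> PhysioSimConfig:
        """A matching recording configuration (run length plus a 10 s tail)."""
        base = dict(
            duration=self.n_volumes * self.volume_tr + 10.0,
            volume_tr=self.volume_tr,
            n_slices=self.n_slices,
            n_volumes=self.n_volumes,
            seed=self.seed,
        )
        base.update(overrides)
        return PhysioSimConfig(**base)


@dataclass
class GroundTruth:
    """Injected components and true parameters of a simulated run."""

    beat_times: np.ndarray | None = None
    belt: np.ndarray | None = None
    breathing_rate: np.ndarray | None = None
    motion: np.ndarray | None = None  # n_volumes x 6, mm / radians
    regressors: RegressorSet | None = None  # injected components per volume
    lambda_true: float | None = None  # pre-correction fractional fluctuation
    lambda_residual_true: float | None = None  # unexplained component only
    kappa_true: float | None = None
    sigma_thermal: float | None = None
    active_mask: np.ndarray | None = None
    act_amp: float | None = None
    amplitudes: dict = field(default_factory=dict)
    baseline_profile: np.ndarray | None = None  # spatial profile g(v)


def _bounded_walk(rng, n: int, mean: float, sd: float, step_frac: float = 0.25) -> np.ndarray:
    """Random walk around ``mean`` reflected at +/- 2 sd."""
    if sd == 0:
        return np.full(n, mean)
    steps = rng.normal(0.0, sd * step_frac, n)
    x = np.empty(n)
    x[0] = mean + rng.normal(0.0, sd * 0.5)
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    for i in range(1, n):
        v = x[i - 1] + steps[i]
        if v > hi:
            v = hi - (v - hi)
        elif v < lo:
            v = lo + (lo - v)
        x[i] = min(max(v, lo), hi)
    return x


def simulate_physio(cfg: PhysioSimConfig) -> tuple[PhysioRecording, GroundTruth]:
    """Generate cardiac, respiratory and trigger channels with ground truth.

    Beat-to-beat intervals follow a bounded random walk of the heart rate;
    each beat adds a gamma-shaped pulse with a fast upstroke at the beat time.
    The belt is a sinusoid at a slowly varying breathing rate with depth
    modulation; the trigger channel carries 2-sample square pulses at every
    slice acquisition.
    """
    rng = np.random.default_rng(cfg.seed)
    t0 = -cfg.lead_in  # recording starts before the first slice trigger
    n = int(round((cfg.duration + cfg.lead_in) * cfg.fs))
    t = t0 + np.arange(n) / cfg.fs

    # --- cardiac: rate walk -> beat times -> pulse waveform
    n_beats_max = int((cfg.duration + cfg.lead_in) * (cfg.hr_mean + 2 * cfg.hr_sd)) + 2
    rates = _bounded_walk(rng, n_beats_max, cfg.hr_mean, cfg.hr_sd)
    beats = []
    tb = t0 + 0.2 + rng.uniform(0.0, 0.5 / cfg.hr_mean)
    k = 0
    while tb < cfg.duration - 0.5 and k < n_beats_max:
        beats.append(tb)
        tb += 1.0 / rates[k]
        k += 1
    beat_times = np.asarray(beats)
    if beat_times.size < 2:
        raise ValueError("configuration produced fewer than 2 beats")
    # snap true upstrokes to the sampling grid; the pulse has a one-sample
    # systolic upstroke followed by an exponential decay (pulse-oximeter-like)
    beat_times = np.round((beat_times - t0) * cfg.fs) / cfg.fs + t0
    tk = np.arange(0.0, 0.5, 1.0 / cfg.fs)
    kernel = np.exp(-tk / 0.15)
    cardiac = np.zeros(n)
    for tb in beat_times:
        i0 = int(round((tb - t0) * cfg.fs))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            cardiac[i0 : i0 + seg] += kernel[:seg]

    # --- respiration: slowly varying rate and depth
    n_sec = int(np.ceil(cfg.duration + cfg.lead_in)) + 1
    br_sec = _bounded_walk(rng, n_sec, cfg.br_mean, cfg.br_sd)
    br = np.interp(t - t0, np.arange(n_sec, dtype=float), br_sec)
    breath_phase = 2.0 * np.pi * np.cumsum(br) / cfg.fs
    depth = 1.0 + cfg.depth_mod * np.sin(2.0 * np.pi * 0.015 * t + rng.uniform(0, 2 * np.pi))
    belt = depth * np.sin(breath_phase)

    # --- slice triggers: 2-sample square pulses
    trigger = np.zeros(n)
    slice_times = (
        np.arange(cfg.n_volumes)[:, None] * cfg.volume_tr
        + np.arange(cfg.n_slices)[None, :] * cfg.volume_tr / cfg.n_slices
    ).ravel()
    idx = np.round((slice_times - t0) * cfg.fs).astype(int)
    for i in idx:
        trigger[i : i + 2] = cfg.trigger_volts

    rec = PhysioRecording(
        sampling_rate=cfg.fs, cardiac=cardiac, respiratory=belt, trigger=trigger, t0=t0
    )
    truth = GroundTruth(beat_times=beat_times, belt=belt, breathing_rate=br)
    return rec, truth


def _orthonormal_columns(m: np.ndarray) -> np.ndarray:
    """Orthogonalize centred columns and scale each to unit sample sd."""
    c = m - m.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(c)
    return q / q.std(axis=0, ddof=1, keepdims=True)


def _scale_to_sd(x: np.ndarray, sd: float) -> np.ndarray:
    x = x - x.mean()
    s = x.std(ddof=1)
    return x * (sd / s) if s > 0 and sd > 0 else np.zeros_like(x)


def simulate_epi(
    cfg: EpiSimConfig,
    physio: PhysioRecording,
    truth: GroundTruth,
) -> tuple[dict[float, EpiSeries], NoiseVolumes, GroundTruth]:
    """Generate one EPI series per flip angle, noise volumes, and ground truth.

    Per voxel v and volume t,

        y = S(alpha) g(v) [1 + p(t) + m(v, t) + d(t) + u(v, t)] + eps,

    where S(alpha) is the spoiled steady-state signal, g a smooth spatial
    profile, p the shared cardio-respiratory fluctuation (cardiac/respiratory
    phase harmonics, RV, HR), m a motion term coupling the true motion
    parameters to spatial gradients, d a low-order drift, u white
    signal-proportional fluctuation of amplitude ``amp_unexplained``, and
    eps ~ N(0, sigma_thermal).  Noise volumes are pure thermal noise with the
    stored scale divided by ``kappa_true`` (multi-channel miscalibration of
    the SNR0' measure).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    nx, ny, nz = cfg.grid
    nt = cfg.n_volumes
    timing = uniform_slice_timing(cfg.volume_tr, cfg.n_slices, nt, cfg.reference_slice)
    beats = EventTimes(truth.beat_times, kind="beat")

    # --- shared cardio-respiratory fluctuation at reference times
    decay = np.array([1.0, 1.0, 0.5, 0.5, 0.25, 0.25])
    comps: dict[str, np.ndarray] = {}
    cp = fourier_expand(cardiac_phase(beats, timing), 3).matrix
    comps["cardiac"] = _scale_to_sd(cp @ (rng.normal(size=6) * decay), cfg.amp_cardiac)
    rp = fourier_expand(respiratory_phase(physio, timing), 3).matrix
    comps["resp"] = _scale_to_sd(rp @ (rng.normal(size=6) * decay), cfg.amp_resp)
    comps["rv"] = _scale_to_sd(rv_regressor(physio, timing).matrix[:, 0], cfg.amp_rv)
    comps["hr"] = _scale_to_sd(hr_regressor(beats, timing).matrix[:, 0], cfg.amp_hr)
    p_shared = comps["cardiac"] + comps["resp"] + comps["rv"] + comps["hr"]

    # --- true motion parameters, partially coupled to breathing
    belt_ref = np.interp(timing.reference_times, physio.times, truth.belt)
    belt_std = _scale_to_sd(belt_ref, 1.0)
    c = cfg.resp_motion_coupling
    walks = np.cumsum(rng.normal(0.0, 1.0, (nt, 6)), axis=0)
    walks = np.apply_along_axis(_scale_to_sd, 0, walks, 1.0)
    m_tilde = np.sqrt(max(1.0 - c**2, 0.0)) * walks + c * belt_std[:, None]
    motion = cfg.motion_amp * m_tilde
    q_motion = _orthonormal_columns(m_tilde)  # spans the same space as motion

    # --- spatial fields
    ax = [np.linspace(-1, 1, s) for s in cfg.grid]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    g = 0.75 + 0.25 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 0.6**2))
    fields = np.stack([X, Y, Z, X * Y, X * Z, Y * Z], axis=-1)
    norm = np.sqrt((fields**2).sum(axis=-1, keepdims=True))
    u_dirs = fields / np.maximum(norm, 1e-12)  # sum_j u_j^2 = 1 per voxel
    mp_sig = cfg.amp_mp * np.einsum("xyzj,tj->xyzt", u_dirs, q_motion)

    # --- drift
    hw = drift_regressors(nt).matrix
    d = cfg.drift_coeffs[0] * hw[:, 0] + cfg.drift_coeffs[1] * hw[:, 1]

    s_ref = spgr_signal(max(cfg.flip_angles), cfg.volume_tr, cfg.t1)
    series: dict[float, EpiSeries] = {}
    for alpha in cfg.flip_angles:
        s_rel = spgr_signal(alpha, cfg.volume_tr, cfg.t1) / s_ref
        baseline = cfg.s_max * s_rel * g
        u = rng.normal(0.0, cfg.amp_unexplained, (nx, ny, nz, nt)) if cfg.amp_unexplained else 0.0
        frac = p_shared[None, None, None, :] + mp_sig + d[None, None, None, :] + u
        eps = rng.normal(0.0, cfg.sigma_thermal, (nx, ny, nz, nt))
        data = baseline[..., None] * (1.0 + frac) + eps
        series[alpha] = EpiSeries(data, volume_tr=cfg.volume_tr, affine=cfg.affine)

    noise = NoiseVolumes(
        rng.normal(0.0, cfg.sigma_thermal / cfg.kappa_true, (nx, ny, nz, cfg.n_noise_volumes))
    )

    # --- realized pre-correction fluctuation amplitude (after drift removal)
    hw_basis = np.column_stack([np.ones(nt), hw])
    proj = hw_basis @ np.linalg.pinv(hw_basis)
    p_detr = p_shared - proj @ p_shared
    lambda_true = float(
        np.sqrt(np.var(p_detr, ddof=1) + cfg.amp_mp**2 + cfg.amp_unexplained**2)
    )

    labels = ["cardiac", "resp", "rv", "hr"] + [f"motion_q{j}" for j in range(6)] + ["drift"]
    injected = np.column_stack(
        [comps["cardiac"], comps["resp"], comps["rv"], comps["hr"], q_motion, d]
    )
    truth = replace(
        truth,
        motion=motion,
        regressors=RegressorSet(injected, labels),
        lambda_true=lambda_true,
        lambda_residual_true=cfg.amp_unexplained,
        kappa_true=cfg.kappa_true,
        sigma_thermal=cfg.sigma_thermal,
        amplitudes={k: getattr(cfg, f"amp_{k2}") for k, k2 in
                    [("cardiac", "cardiac"), ("resp", "resp"), ("rv", "rv"),
                     ("hr", "hr"), ("mp", "mp"), ("unexplained", "unexplained")]},
        baseline_profile=g,
    )
    return series, noise, truth


def simulate_activation(
    series: EpiSeries,
    task: RegressorSet,
    act_amp: float,
    roi: RoiMask,
) -> tuple[EpiSeries, GroundTruth]:
    """Add a block-design BOLD response inside an ROI.

    The HRF-convolved condition regressors (summed over conditions, unit
    plateau) are scaled to ``act_amp`` percent of each voxel's baseline and
    added inside ``roi``.  With ``act_amp=0`` the series is returned unchanged.
    """
    truth = GroundTruth(active_mask=roi.mask.copy(), act_amp=act_amp)
    if act_amp == 0:
        return series, truth
    if task.n_volumes != series.n_volumes:
        raise ValueError("task regressors do not match series length")
    response = task.matrix.sum(axis=1)
    data = series.data.copy()
    baseline = series.data[roi.mask].mean(axis=1, keepdims=True)
    data[roi.mask] = series.data[roi.mask] + (act_amp / 100.0) * baseline * response[None, :]
    out = EpiSeries(data, volume_tr=series.volume_tr, affine=series.affine, mask=series.mask)
    return out, truth


def make_rois(
    grid: tuple[int, int, int],
    vc_voxels: int = 500,
    lgn_voxels: int = 40,
) -> dict[str, RoiMask]:
    """A large posterior slab (VC-like) and two small deep blobs (LGN-like).

    Masks are disjoint, within the grid, and have exactly the requested
    voxel counts.
    """
    nx, ny, nz = grid
    if vc_voxels + lgn_voxels > nx * ny * nz:
        raise ValueError("requested ROI voxels exceed the grid")
    vc = np.zeros(grid, dtype=bool)
    count = 0
    for y in range(ny):  # fill posterior (low y) layers first
        for x in range(nx):
            for z in range(nz):
                if count < vc_voxels:
                    vc[x, y, z] = True
                    count += 1
    # LGN: two blobs around deep anterior centres, by distance rank
    centers = np.array(
        [[nx // 2 - nx // 5, 3 * ny // 4, nz // 2], [nx // 2 + nx // 5, 3 * ny // 4, nz // 2]],
        dtype=float,
    )
    ix = np.stack(np.meshgrid(*[np.arange(s) for s in grid], indexing="ij"), axis=-1)
    dist = np.min(
        np.linalg.norm(ix[..., None, :] - centers[None, None, None, :, :], axis=-1), axis=-1
    )
    dist[vc] = np.inf
    flat_order = np.argsort(dist, axis=None, kind="stable")
    lgn = np.zeros(grid, dtype=bool)
    lgn.ravel()[flat_order[:lgn_voxels]] = True
    return {
        "VC": RoiMask(vc, label="VC"),
        "LGN": RoiMask(lgn, label="LGN"),
    }
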