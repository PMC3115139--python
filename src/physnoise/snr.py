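"""Image SNR measurement and the extended signal-dependent noise model.

At high field the time-series noise of gradient-echo EPI contains a component
proportional to the signal itself (cardio-respiratory and motion-driven
fluctuations) on top of additive thermal noise.  With lambda the fractional
amplitude of the signal-dependent component, temporal SNR saturates as

    tSNR = SNR0 / sqrt(1 + lambda^2 * SNR0^2),

so 1/lambda is the tSNR asymptote that no increase in image SNR can exceed.
The image SNR actually measured from no-excitation noise volumes with a
multi-channel receive coil is biased by channel covariance; writing
SNR0' = kappa * SNR0 and substituting gives the fitted form

    tSNR = SNR0' / sqrt(kappa^2 + lambda^2 * SNR0'^2).

:class:`SnrModel` fits (lambda, kappa) to measured (SNR0', tSNR) points by
Nelder-Mead least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "NoiseVolumes",
    "thermal_noise_map",
    "snr0_map",
    "model_tsnr",
    "SnrModel",
    "SnrModelFit",
    "fit_snr_model",
    "ernst_angle",
    "spgr_signal",
]


@dataclass
class NoiseVolumes:
    """EPI volumes acquired with no RF excitation (pure noise)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("noise volumes must form a 4-D array")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 noise volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def thermal_noise_map(noise: NoiseVolumes, correction: float = 1.0) -> np.ndarray:
    """Per-voxel thermal-noise estimate: sample sd across the noise volumes.

    ``correction`` is an optional multiplicative factor (e.g. a chi-statistics
    correction for n-channel magnitude noise); the default 1.0 leaves any
    multi-channel bias to be absorbed by the model parameter kappa.
    """
    return correction * np.std(noise.data, axis=3, ddof=1)


def snr0_map(series, noise_sd: np.ndarray) -> np.ndarray:
    """Measured image SNR (SNR0'): temporal mean / thermal-noise sd.

    Undefined (NaN) where the noise estimate is zero.
    """
    mean = series.data.mean(axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(noise_sd > 0, mean / noise_sd, np.nan)


def model_tsnr(snr0_prime, lam: float, kappa: float):
    """Modelled tSNR at measured image SNR ``snr0_prime``.

    Strictly increasing in SNR0' with supremum 1/lambda; for lambda = 0 it is
    the straight line SNR0'/kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    s = np.asarray(snr0_prime, dtype=float)
    out = s / np.sqrt(kappa**2 + lam**2 * s**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class SnrModelFit:
    """Estimates of (lambda, kappa) with fit diagnostics."""

    lam: float
    kappa: float
    sse: float
    converged: bool
    n_points: int
    snr0: np.ndarray | None = None
    tsnr: np.ndarray | None = None

    @property
    def inv_lambda(self) -> float:
        """tSNR asymptote 1/lambda (inf for a degenerate lambda = 0)."""
        return float(np.inf) if self.lam == 0 else 1.0 / self.lam

    def predict(self, snr0_prime):
        return model_tsnr(snr0_prime, self.lam, self.kappa)

    def summary(self) -> str:
        lines = [
            "Extended tSNR-vs-SNR0' model fit",
            "================================",
            f"n points:   {self.n_points}",
            f"lambda:     {self.lam:.6g}",
            f"1/lambda:   {self.inv_lambda:.4g}   (tSNR asymptote)",
            f"kappa:      {self.kappa:.4g}   (SNR0'/SNR0 scale factor)",
            f"SSE:        {self.sse:.4g}",
            f"converged:  {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, label: str | None = None):
        """Plot the measured (SNR0', tSNR) points and the fitted curve.

        Returns the matplotlib axes; the 1/lambda asymptote is drawn as a
        horizontal dashed line when finite.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.snr0 is not None:
            ax.plot(self.snr0, self.tsnr, "o", label=label)
            grid = np.linspace(0, 1.1 * float(np.max(self.snr0)), 200)
        else:
            grid = np.linspace(0, 1000, 200)
        ax.plot(grid, self.predict(grid), "-",
                color=ax.lines[-1].get_color() if ax.lines else None)
        if np.isfinite(self.inv_lambda):
            ax.axhline(self.inv_lambda, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("SNR0'")
        ax.set_ylabel("tSNR")
        if label:
            ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "inv_lambda": self.inv_lambda,
            "kappa": self.kappa,
            "sse": self.sse,
            "n_points": self.n_points,
            "converged": self.converged,
        }


class SnrModel:
    """Least-squares model of tSNR as a function of measured image SNR."""

    def __init__(self, snr0_prime, tsnr):
        snr0_prime = np.asarray(snr0_prime, dtype=float)
        tsnr = np.asarray(tsnr, dtype=float)
        if snr0_prime.shape != tsnr.shape or snr0_prime.ndim != 1:
            raise ValueError("snr0_prime and tsnr must be 1-D of equal length")
        if not (np.all(np.isfinite(snr0_prime)) and np.all(np.isfinite(tsnr))):
            raise ValueError("non-finite inputs")
        if np.unique(snr0_prime).size < 3:
            raise ValueError("need >= 3 points with distinct SNR0'")
        if np.any(snr0_prime <= 0) or np.any(tsnr <= 0):
            raise ValueError("SNR values must be positive")
        order = np.argsort(snr0_prime)
        self.snr0 = snr0_prime[order]
        self.tsnr = tsnr[order]

    def _objective(self, logp: np.ndarray) -> float:
        lam, kappa = np.exp(logp)
        r = self.tsnr - model_tsnr(self.snr0, lam, kappa)
        return float(r @ r)

    def fit(self, tol: float = 1e-9, maxiter: int = 4000) -> SnrModelFit:
        """Nelder-Mead minimisation in (log lambda, log kappa).

        The log parameterisation keeps the search unconstrained while
        enforcing positivity.  Initialisation is deterministic:
        lambda0 = 1/max(tSNR) and kappa0 from the two lowest-SNR points,
        where the curve is close to the thermal line SNR0'/kappa.
        """
        lam0 = 1.0 / float(np.max(self.tsnr))
        kappa0 = float(np.median(self.snr0[:2] / self.tsnr[:2]))
        kappa0 = max(kappa0, 1e-3)
        x0 = np.log([lam0, kappa0])
        res = minimize(
            self._objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": maxiter},
        )
        # one restart from the optimum polishes the simplex
        res = minimize(
            self._objective,
            res.x,
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": maxiter},
        )
        lam, kappa = np.exp(res.x)
        return SnrModelFit(
            lam=float(lam),
            kappa=float(kappa),
            sse=float(res.fun),
            converged=bool(res.success),
            n_points=self.snr0.size,
            snr0=self.snr0,
            tsnr=self.tsnr,
        )


def fit_snr_model(points) -> SnrModelFit:
    """Fit (lambda, kappa) to a list of (SNR0', tSNR) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (snr0_prime, tsnr) pairs")
    return SnrModel(pts[:, 0], pts[:, 1]).fit()


def ernst_angle(volume_tr: float, t1: float) -> float:
    """Flip angle (degrees) maximising spoiled steady-state signal."""
    if volume_tr <= 0 or t1 <= 0:
        raise ValueError("volume_tr and t1 must be positive")
    return float(np.degrees(np.arccos(np.exp(-volume_tr / t1))))


def spgr_signal(alpha_deg, volume_tr: float, t1: float):
    """Relative spoiled gradient-echo steady-state signal.

    S = sin(a) (1 - E1) / (1 - E1 cos(a)), E1 = exp(-TR/T1).
    """
    if volume_tr <= 0 or t1 <= 0:
        raise ValueError("volume_tr and t1 must be positive")
    a = np.radians(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-volume_tr / t1)
    out = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return float(out) if out.ndim == 0 else out
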