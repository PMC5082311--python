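"""Synthetic resting-state-fMRI-like multichannel generator.

Real ROI time series are not raw neural signals: they are slow, positively
autocorrelated, weakly cross-coupled, smoothed by the hemodynamic response,
ride on shared slow drifts, and are sampled at the scanner TR on top of
measurement noise. :func:`generate_fmri_like` emulates exactly these
features with a small generative model:

1. a latent stable VAR(1) on a fine 0.1 s grid, with diagonal (positive)
   autocorrelation ``autocorr_strength`` and sparse random cross-couplings
   of either sign scaled by ``coupling_scale`` (Erdos-Renyi topology,
   density 0.2, 50/50 sign split);
2. a shared slow drift: a scalar AR(1) with coefficient 0.995 per fine step
   (~0.008 Hz corner frequency, i.e. below the conventional 0.01-0.08 Hz
   resting-state band), loaded onto every channel with weight
   ``autocorr_strength`` -- so the degenerate white-noise case stays white;
3. causal exponential smoothing with time constant 1.3 s, a stand-in for
   the hemodynamic response;
4. decimation to the requested TR (nearest-integer subsampling of the fine
   grid) and additive white observation noise.

The smoothing step is what makes the selected VAR order rise at shorter TR:
a decimated VAR(1) alone is again exactly a VAR(1), so subsampling by itself
cannot produce any TR dependence of the order.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError, UnstableModelError
from .panel import TimeSeriesPanel

__all__ = ["generate_fmri_like"]

FINE_STEP_S = 0.1


def generate_fmri_like(
    n_channels: int,
    n_timepoints: int,
    sampling_interval_s: float,
    autocorr_strength: float = 0.8,
    coupling_scale: float = 0.05,
    seed=None,
    *,
    coupling_density: float = 0.2,
    drift_coeff: float = 0.995,
    smoothing_tau_s: float = 1.3,
    obs_noise_sd: float = 0.5,
    burn_in: int = 800,
) -> TimeSeriesPanel:
    """Generate an fMRI-like multichannel panel.

    Parameters
    ----------
    n_channels, n_timepoints : int
        Panel dimensions (rows are scans at the TR).
    sampling_interval_s : float
        The TR, in seconds; decimation factor is ``round(TR / 0.1 s)``.
    autocorr_strength : float in [0, 1)
        Diagonal lag-1 coefficient of the latent fine-grid VAR, and the
        loading of the shared slow drift. 0 gives mutually independent
        channels.
    coupling_scale : float >= 0
        Magnitude scale of the sparse random cross-couplings.
    seed : int, SeedSequence or Generator
        Determinism: identical arguments and seed give identical output.
    obs_noise_sd : float
        Standard deviation of white measurement noise added after
        decimation.

    Raises
    ------
    UnstableModelError
        If the drawn latent coupling matrix has spectral radius >= 1.
    """
    if n_channels < 1 or n_timepoints < 1:
        raise InputError("n_channels and n_timepoints must be positive")
    if sampling_interval_s <= 0:
        raise InputError("sampling_interval_s must be positive")
    if not 0.0 <= autocorr_strength < 1.0:
        raise InputError("autocorr_strength must lie in [0, 1)")
    if coupling_scale < 0:
        raise InputError("coupling_scale must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_channels
    m = max(1, round(sampling_interval_s / FINE_STEP_S))
    total = n_timepoints * m + burn_in

    # latent fine-grid VAR(1): positive diagonal + sparse signed couplings
    mask = (rng.random((n, n)) < coupling_density) & ~np.eye(n, dtype=bool)
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    mags = rng.uniform(0.5, 1.5, size=(n, n))
    coupling = np.where(mask, coupling_scale * signs * mags, 0.0)
    a_mat = np.diag(np.full(n, float(autocorr_strength))) + coupling
    rho = float(np.max(np.abs(np.linalg.eigvals(a_mat))))
    if rho >= 1.0:
        raise UnstableModelError(
            f"latent coupling matrix has spectral radius {rho:.3f} >= 1; "
            "reduce coupling_scale or autocorr_strength"
        )

    eps = rng.standard_normal((total, n))
    drift_noise = rng.standard_normal(total) * np.sqrt(1.0 - drift_coeff**2)
    obs_noise = rng.standard_normal((n_timepoints, n)) * obs_noise_sd

    latent = np.zeros((total, n))
    drift = np.zeros(total)
    for t in range(1, total):
        latent[t] = a_mat @ latent[t - 1] + eps[t]
        drift[t] = drift_coeff * drift[t - 1] + drift_noise[t]
    signal = latent + autocorr_strength * drift[:, None]

    # hemodynamic-like causal exponential smoothing (unit gain)
    if smoothing_tau_s > 0:
        klen = max(1, int(round(6.0 * smoothing_tau_s / FINE_STEP_S)))
        kernel = np.exp(-np.arange(klen) * FINE_STEP_S / smoothing_tau_s)
        kernel /= kernel.sum()
        smoothed = np.empty_like(signal)
        for j in range(n):
            smoothed[:, j] = np.convolve(signal[:, j], kernel)[:total]
        signal = smoothed

    sampled = signal[burn_in::m][:n_timepoints]
    values = sampled + obs_noise
    labels = [f"roi{i + 1}" for i in range(n)]
    return TimeSeriesPanel(values, labels, sampling_interval_s)
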