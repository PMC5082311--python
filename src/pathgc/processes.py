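"""VAR data-generating processes: presets, stability, simulation, moments.

The convention throughout is

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + eps_t,   eps_t ~ N(0, noise_cov)

with no intercept. Entry ``A_k[i, j]`` is the linear effect of channel j at
lag k on channel i at time t.

Four bivariate presets are provided, indexed by a grid parameter k in 1..20.
They share the structure of a lag-2 antisymmetric interaction (or a lag-1 one
for ``model3``) plus a negative lag-3 influence c from the second channel (Y)
onto the first (X):

* ``model1``  -- no lag-1 terms, lag-2 couplings +/-0.6, c = -0.5 - 0.02 k.
* ``model1b`` -- a pure order-1 process whose lag-1 matrix mimics what an
  underfitted order-1 regression recovers from ``model1``.
* ``model2``  -- like model1 but with positive lag-1 autocorrelation 0.18 and
  lag-2 couplings +/-0.8; c = -0.1 - 0.04 k.
* ``model3``  -- dominant lag-1 couplings +/-0.5, no lag-2 term, same c grid
  as model2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .exceptions import InputError, UnstableModelError
from .panel import TimeSeriesPanel

__all__ = [
    "VarProcess",
    "build_preset",
    "spectral_radius",
    "companion_matrix",
    "simulate",
    "stationary_autocovariance",
    "PRESET_NAMES",
]

PRESET_NAMES = ("model1", "model1b", "model2", "model3")

#: default number of initial time points discarded by :func:`simulate`
DEFAULT_BURN_IN = 500


@dataclass(frozen=True)
class VarProcess:
    """A VAR(p) data-generating process.

    Attributes
    ----------
    lag_coeffs : tuple of (n, n) ndarrays
        Coefficient matrices A_1 .. A_p.
    noise_cov : (n, n) ndarray
        Innovation covariance; identity (unit-variance Gaussian noise) by
        default.
    """

    lag_coeffs: tuple[np.ndarray, ...]
    noise_cov: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lags = tuple(np.asarray(a, dtype=float) for a in self.lag_coeffs)
        if not lags:
            raise InputError("a VAR process needs at least one lag matrix")
        n = lags[0].shape[0]
        for k, a in enumerate(lags, start=1):
            if a.shape != (n, n):
                raise InputError(f"lag matrix {k} has shape {a.shape}, expected ({n}, {n})")
        object.__setattr__(self, "lag_coeffs", lags)
        cov = self.noise_cov
        cov = np.eye(n) if cov is None else np.asarray(cov, dtype=float)
        if cov.shape != (n, n):
            raise InputError(f"noise_cov has shape {cov.shape}, expected ({n}, {n})")
        if not np.allclose(cov, cov.T, atol=1e-12, rtol=0.0):
            raise InputError("noise_cov must be symmetric (tolerance 1e-12)")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise InputError("noise_cov must be positive definite") from None
        object.__setattr__(self, "noise_cov", cov)

    @property
    def n_channels(self) -> int:
        return self.lag_coeffs[0].shape[0]

    @property
    def order(self) -> int:
        return len(self.lag_coeffs)

    def is_stable(self) -> bool:
        return spectral_radius(self) < 1.0


def companion_matrix(model: VarProcess) -> np.ndarray:
    """(n p) x (n p) companion matrix of the VAR."""
    n, p = model.n_channels, model.order
    top = np.hstack(model.lag_coeffs)
    if p == 1:
        return top
    below = np.hstack([np.eye(n * (p - 1)), np.zeros((n * (p - 1), n))])
    return np.vstack([top, below])


def spectral_radius(model: VarProcess) -> float:
    """Largest eigenvalue modulus of the companion matrix.

    A value below 1 certifies a stable (jointly stationary) process.
    """
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(model)))))


def _check_k(k) -> int:
    if k is None or int(k) != k or not 1 <= int(k) <= 20:
        raise InputError(f"grid index k must be an integer in 1..20, got {k!r}")
    return int(k)


def build_preset(name: str, k: int | None = None, *, c: float | None = None) -> VarProcess:
    """Build one of the four preset bivariate processes.

    Parameters
    ----------
    name : {'model1', 'model1b', 'model2', 'model3'}
    k : int in 1..20, optional
        Grid index; sets c = -0.5 - 0.02 k (model1), c = -0.1 - 0.04 k
        (model2, model3) or the k-dependent lag-1 entries of model1b.
    c : float, optional
        Explicit lag-3 influence Y -> X, as an alternative to ``k`` (not
        available for model1b, whose grid moves two entries at once).

    Returns
    -------
    VarProcess
        With identity noise covariance.
    """
    if name not in PRESET_NAMES:
        raise InputError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if (k is None) == (c is None):
        raise InputError("specify exactly one of k (grid index) or c (explicit value)")
    z = np.zeros((2, 2))
    if name == "model1b":
        if c is not None:
            raise InputError("model1b is indexed by k only")
        k = _check_k(k)
        a1 = np.array([[0.5, -0.071 - 0.011 * k], [0.186 + 0.005 * k, 0.5]])
        return VarProcess((a1,))
    if k is not None:
        k = _check_k(k)
        c = (-0.5 - 0.02 * k) if name == "model1" else (-0.1 - 0.04 * k)
    c = float(c)
    a3 = np.array([[0.0, c], [0.0, 0.0]])
    if name == "model1":
        return VarProcess((z, np.array([[0.0, 0.6], [-0.6, 0.0]]), a3))
    if name == "model2":
        return VarProcess((0.18 * np.eye(2), np.array([[0.0, 0.8], [-0.8, 0.0]]), a3))
    # model3
    return VarProcess((np.array([[0.0, 0.5], [-0.5, 0.0]]), z, a3))


def simulate(
    model: VarProcess,
    n_timepoints: int,
    seed,
    burn_in: int = DEFAULT_BURN_IN,
    *,
    allow_unstable: bool = False,
    channel_labels=None,
    sampling_interval_s: float | None = None,
) -> TimeSeriesPanel:
    """Simulate a panel from a VAR process.

    The recursion starts at zeros and the first ``burn_in`` points are
    discarded, which removes the influence of the arbitrary initial state.
    Identical ``(model, n_timepoints, seed, burn_in)`` give byte-identical
    output.

    Parameters
    ----------
    model : VarProcess
    n_timepoints : int
        Length of the returned panel (after burn-in).
    seed : int, SeedSequence or Generator
    burn_in : int
        Discarded initial points; must be >= the model order.
    allow_unstable : bool
        Explicitly override the stationarity guard.
    """
    if n_timepoints < 1:
        raise InputError("n_timepoints must be positive")
    p = model.order
    if burn_in < p:
        raise InputError(f"burn_in must be >= model order ({p})")
    if not allow_unstable:
        rho = spectral_radius(model)
        if rho >= 1.0:
            raise UnstableModelError(
                f"companion spectral radius {rho:.4f} >= 1; the process is "
                "non-stationary. Pass allow_unstable=True to simulate anyway."
            )
    rng = np.random.default_rng(seed)
    n = model.n_channels
    total = n_timepoints + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    eps = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    lags = model.lag_coeffs
    for t in range(p, total):
        acc = eps[t].copy()
        for j, a in enumerate(lags, start=1):
            acc += a @ x[t - j]
        x[t] = acc
    return TimeSeriesPanel(x[burn_in:], channel_labels, sampling_interval_s)


def stationary_autocovariance(model: VarProcess, max_lag: int) -> np.ndarray:
    """Theoretical autocovariances Gamma(0..max_lag) of a stable VAR.

    Solves the discrete Lyapunov equation for the companion-form state
    covariance and extends by the Yule-Walker recursion
    Gamma(h) = sum_k A_k Gamma(h - k), with Gamma(-m) = Gamma(m)^T.

    Returns
    -------
    ndarray, shape (max_lag + 1, n, n)
        ``out[h] = E[x_t x_{t-h}^T]``.
    """
    if not model.is_stable():
        raise UnstableModelError("autocovariance only defined for a stable process")
    n, p = model.n_channels, model.order
    comp = companion_matrix(model)
    q = np.zeros((n * p, n * p))
    q[:n, :n] = model.noise_cov
    big = sla.solve_discrete_lyapunov(comp, q)
    gammas = [big[:n, j * n:(j + 1) * n] for j in range(p)]  # Gamma(0)..Gamma(p-1)
    out = list(gammas[: max_lag + 1])
    for h in range(len(out), max_lag + 1):
        acc = np.zeros((n, n))
        for j, a in enumerate(model.lag_coeffs, start=1):
            g = out[h - j] if h - j >= 0 else out[j - h].T
            acc += a @ g
        out.append(acc)
    return np.stack(out[: max_lag + 1])
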