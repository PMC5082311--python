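"""VAR least-squares estimation and information-criterion order selection.

The model object / results object split follows the usual statistical-
modelling convention: :class:`VectorAutoregression` is built from a
:class:`~pathgc.panel.TimeSeriesPanel`; :meth:`VectorAutoregression.fit`
returns a :class:`VarResults` carrying coefficient estimates, residuals and
the ML residual covariance; :meth:`VectorAutoregression.select_order`
returns an :class:`OrderSelection` with per-candidate AICc/BIC values.

Conventions (they matter for reproducing the simulation study):

* no intercept; panels are mean-centered before fitting;
* ``sigma_ml`` uses the maximum-likelihood divisor T_eff (the number of
  regression rows), not a degrees-of-freedom correction;
* the parameter count is K = p * n**2;
* AICc = T ln det(Sigma) + 2 K T / (T - K - 1), BIC = T ln det(Sigma)
  + K ln T, both with natural logarithms and T = T_eff;
* by default each candidate order p is fitted on its own maximal sample
  (the first p rows dropped); ``common_sample=True`` instead fits every
  candidate on the rows left after dropping ``p_max``;
* arg-min ties break toward the smallest order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError, InputError, UndefinedCriterionError
from .panel import TimeSeriesPanel

__all__ = [
    "VectorAutoregression",
    "VarResults",
    "OrderSelection",
    "fit_var",
    "select_order",
    "aicc",
    "bic",
]

logger = logging.getLogger(__name__)


@dataclass
class VarResults:
    """A fitted VAR(p).

    Attributes
    ----------
    order : int
        Number of lags p.
    coeff_matrices : tuple of (n, n) ndarrays
        Estimates of A_1 .. A_p; ``coeff_matrices[k-1][i, j]`` is the
        effect of channel j at lag k on channel i.
    residuals : (T_eff, n) ndarray
    sigma_ml : (n, n) ndarray
        Residual cross-product matrix divided by T_eff.
    n_obs_used : int
        T_eff, the number of regression rows.
    n_params : int
        K = p * n**2.
    channel_labels : list of str
    """

    order: int
    coeff_matrices: tuple[np.ndarray, ...]
    residuals: np.ndarray
    sigma_ml: np.ndarray
    n_obs_used: int
    channel_labels: list[str]

    @property
    def n_channels(self) -> int:
        return self.sigma_ml.shape[0]

    @property
    def n_params(self) -> int:
        return self.order * self.n_channels**2

    @property
    def lag1(self) -> np.ndarray:
        """The lag-1 coefficient matrix A_1."""
        return self.coeff_matrices[0]

    @property
    def aicc(self) -> float:
        return aicc(self)

    @property
    def bic(self) -> float:
        return bic(self)

    def summary(self) -> str:
        lines = [
            f"VAR({self.order}) fit on {self.n_obs_used} rows, "
            f"{self.n_channels} channels, K={self.n_params}",
        ]
        for k, a in enumerate(self.coeff_matrices, start=1):
            lines.append(f"A{k} =")
            lines.extend("   " + "  ".join(f"{v: .4f}" for v in row) for row in a)
        lines.append("sigma_ml =")
        lines.extend("   " + "  ".join(f"{v: .4f}" for v in row) for row in self.sigma_ml)
        try:
            lines.append(f"AICc = {self.aicc:.3f}   BIC = {self.bic:.3f}")
        except UndefinedCriterionError:
            lines.append(f"AICc undefined (T - K - 1 <= 0)   BIC = {self.bic:.3f}")
        return "\n".join(lines)


def aicc(fit: VarResults) -> float:
    """Small-sample-corrected Akaike criterion of a fitted VAR.

    T ln det(Sigma) + 2 K T / (T - K - 1); undefined when T - K - 1 <= 0.
    """
    t, k = fit.n_obs_used, fit.n_params
    if t - k - 1 <= 0:
        raise UndefinedCriterionError(
            f"AICc undefined: T - K - 1 = {t - k - 1} <= 0 (T={t}, K={k})"
        )
    return float(t * _log_det(fit.sigma_ml) + 2.0 * k * t / (t - k - 1))


def bic(fit: VarResults) -> float:
    """Bayesian information criterion: T ln det(Sigma) + K ln T."""
    t, k = fit.n_obs_used, fit.n_params
    return float(t * _log_det(fit.sigma_ml) + k * np.log(t))


def _log_det(sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise UndefinedCriterionError("residual covariance is singular")
    return logdet


@dataclass
class OrderSelection:
    """Per-candidate information criteria and the arg-min orders.

    ``aicc_values``/``bic_values`` are aligned with ``candidate_orders``;
    NaN marks a candidate whose criterion is undefined (excluded from the
    arg-min). Selected orders are None when every candidate is undefined.
    """

    candidate_orders: np.ndarray
    aicc_values: np.ndarray
    bic_values: np.ndarray
    selected_order_aicc: int | None
    selected_order_bic: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": self.candidate_orders,
                "aicc": self.aicc_values,
                "bic": self.bic_values,
            }
        )

    def summary(self) -> str:
        table = self.to_frame().to_string(index=False)
        return (
            f"{table}\nselected: AICc -> {self.selected_order_aicc}, "
            f"BIC -> {self.selected_order_bic}"
        )


class VectorAutoregression:
    """Multivariate least-squares VAR model for a time-series panel.

    Parameters
    ----------
    panel : TimeSeriesPanel
    center : bool
        Remove per-channel means before fitting (default). The regression
        itself carries no intercept.
    """

    def __init__(self, panel: TimeSeriesPanel, center: bool = True):
        self.panel = panel
        data = panel.values
        self._data = data - data.mean(axis=0) if center else data

    # -- fitting -----------------------------------------------------------

    def _design(self, order: int, drop: int):
        data = self._data
        t, n = data.shape
        y = data[drop:]
        z = np.hstack([data[drop - k : t - k] for k in range(1, order + 1)])
        return y, z

    def fit(self, order: int, *, drop: int | None = None) -> VarResults:
        """OLS fit of all lag matrices jointly.

        Parameters
        ----------
        order : int
            Number of lags p >= 1.
        drop : int, optional
            Rows dropped from the start of the sample (>= order); defaults
            to ``order``. Used by order selection to put candidates on a
            common sample.
        """
        if order < 1:
            raise InputError("order must be a positive integer")
        t, n = self._data.shape
        drop = order if drop is None else int(drop)
        if drop < order:
            raise InputError(f"drop ({drop}) must be >= order ({order})")
        if t - drop <= order * n + 1:
            raise InputError(
                f"panel too short: {t} rows cannot support order {order} "
                f"with {n} channels (need > {drop + order * n + 1})"
            )
        y, z = self._design(order, drop)
        coefs, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
        if rank < z.shape[1]:
            raise EstimationError(self._rank_message(z, order))
        resid = y - z @ coefs
        t_eff = y.shape[0]
        sigma = resid.T @ resid / t_eff
        mats = tuple(coefs[(k - 1) * n : k * n, :].T for k in range(1, order + 1))
        return VarResults(
            order=order,
            coeff_matrices=mats,
            residuals=resid,
            sigma_ml=sigma,
            n_obs_used=t_eff,
            channel_labels=list(self.panel.channel_labels),
        )

    def _rank_message(self, z: np.ndarray, order: int) -> str:
        labels = self.panel.channel_labels
        n = len(labels)
        bad = [labels[j] for j in range(n) if np.ptp(self._data[:, j]) == 0.0]
        dup = []
        for i in range(n):
            for j in range(i + 1, n):
                if np.allclose(self._data[:, i], self._data[:, j]):
                    dup.append(f"{labels[i]}~{labels[j]}")
        detail = []
        if bad:
            detail.append(f"constant channels: {', '.join(bad)}")
        if dup:
            detail.append(f"duplicated channels: {', '.join(dup)}")
        extra = f" ({'; '.join(detail)})" if detail else ""
        return f"rank-deficient regressor matrix at order {order}{extra}"

    # -- order selection ---------------------------------------------------

    def select_order(
        self,
        p_max: int = 10,
        criterion: str = "both",
        *,
        common_sample: bool = False,
    ) -> OrderSelection:
        """Fit orders 1..p_max and locate the AICc/BIC minima.

        Candidates whose criterion is undefined (e.g. the AICc correction
        term's denominator T - K - 1 <= 0, which happens for wide panels)
        are excluded with a logged warning. Ties break toward the smallest
        order.
        """
        if criterion not in ("aicc", "bic", "both"):
            raise InputError("criterion must be 'aicc', 'bic' or 'both'")
        if p_max < 1:
            raise InputError("p_max must be >= 1")
        orders = np.arange(1, p_max + 1)
        aiccs = np.full(p_max, np.nan)
        bics = np.full(p_max, np.nan)
        for i, p in enumerate(orders):
            drop = p_max if common_sample else int(p)
            try:
                res = self.fit(int(p), drop=drop)
            except (InputError, EstimationError) as exc:
                logger.warning("order %d skipped: %s", p, exc)
                continue
            try:
                aiccs[i] = aicc(res)
            except UndefinedCriterionError as exc:
                logger.warning("order %d: %s", p, exc)
            try:
                bics[i] = bic(res)
            except UndefinedCriterionError as exc:
                logger.warning("order %d: %s", p, exc)

        def argmin(values: np.ndarray) -> int | None:
            if np.all(np.isnan(values)):
                return None
            return int(orders[np.nanargmin(values)])  # first min = smallest order

        return OrderSelection(
            candidate_orders=orders,
            aicc_values=aiccs,
            bic_values=bics,
            selected_order_aicc=argmin(aiccs),
            selected_order_bic=argmin(bics),
        )


def fit_var(panel: TimeSeriesPanel, order: int) -> VarResults:
    """Functional form of :meth:`VectorAutoregression.fit`."""
    return VectorAutoregression(panel).fit(order)


def select_order(
    panel: TimeSeriesPanel,
    p_max: int = 10,
    criterion: str = "both",
    *,
    common_sample: bool = False,
) -> OrderSelection:
    """Functional form of :meth:`VectorAutoregression.select_order`."""
    return VectorAutoregression(panel).select_order(
        p_max, criterion, common_sample=common_sample
    )
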