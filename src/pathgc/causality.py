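"""Granger-causality measures: residual-based and signed path coefficients.

Two notions of causal strength are computed from the same panel:

* **residual Granger causality** F_{source->target} = ln(var(restricted
  residual) / var(unrestricted residual)), where the restricted model
  regresses the target on its own past only and the unrestricted model adds
  the source's past, both at the same order and on the same sample rows.
  Because the restricted regressors are nested in the unrestricted ones,
  F >= 0 exactly.
* **signed path coefficients**: the off-diagonal entries of the lag-1
  coefficient matrix of a jointly fitted order-1 VAR. This is the quantity
  whose sign the "excitatory/inhibitory" interpretation relies on -- and
  whose failure modes the simulation study demonstrates when the true
  process order exceeds one.

For panels with more than two channels the residual measure is computed
pairwise-bivariate, while the signed coefficients come from the full joint
order-1 fit across all channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedStatisticError
from .panel import TimeSeriesPanel
from .var import VectorAutoregression

__all__ = [
    "GrangerCausality",
    "CausalityResult",
    "signed_path_coefficients",
    "residual_gc",
    "residual_gc_matrix",
    "sign_bias",
]


def signed_path_coefficients(panel: TimeSeriesPanel) -> np.ndarray:
    """Lag-1 coefficient matrix of the joint order-1 VAR fit.

    Entry ``[i, j]`` with i != j is the signed path coefficient from
    channel j to channel i; diagonal entries are the fitted lag-1
    autocorrelations.
    """
    return VectorAutoregression(panel).fit(1).lag1


def residual_gc(
    panel: TimeSeriesPanel, order: int, pair: tuple[int | str, int | str]
) -> float:
    """Residual Granger causality source -> target at a given order.

    Parameters
    ----------
    panel : TimeSeriesPanel
    order : int
        Lag order of both the restricted and unrestricted regressions;
        workflows "under optimal order" pass the AICc-selected order.
    pair : (target, source)
        Channel indices or labels.

    Returns
    -------
    float
        ln(var(restricted) / var(unrestricted)), non-negative up to exact
        arithmetic because the fits share the sample rows and the
        restricted regressors are nested in the unrestricted ones.
    """
    target, source = (panel.channel_index(c) for c in pair)
    if target == source:
        raise InputError("target and source must be distinct channels")
    sub = panel.select([target, source])
    model = VectorAutoregression(sub)
    unrestricted = model.fit(order)
    restricted = VectorAutoregression(sub.select([0])).fit(order)
    var_u = float(unrestricted.sigma_ml[0, 0])
    var_r = float(restricted.sigma_ml[0, 0])
    return float(np.log(var_r / var_u))


def residual_gc_matrix(panel: TimeSeriesPanel, order: int) -> np.ndarray:
    """All pairwise-bivariate residual-GC values.

    Entry ``[i, j]`` is F_{j -> i}; the diagonal is 0.
    """
    n = panel.n_channels
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = residual_gc(panel, order, (i, j))
    return out


def sign_bias(coeff_values) -> float:
    """Normalized excess of positive over negative values.

    (A+ - A-) / (A+ + A-), with exact zeros excluded from both counts.
    """
    values = np.asarray(coeff_values, dtype=float).ravel()
    if values.size == 0:
        raise UndefinedStatisticError("sign bias of an empty collection")
    pos = int(np.sum(values > 0))
    neg = int(np.sum(values < 0))
    if pos + neg == 0:
        raise UndefinedStatisticError("sign bias undefined: all values are zero")
    return (pos - neg) / (pos + neg)


@dataclass
class CausalityResult:
    """Pairwise causality measures for one panel.

    Attributes
    ----------
    f_residual : (n, n) ndarray
        Residual GC, entry [i, j] = F_{j -> i}; diagonal 0.
    signed_coeffs : (n, n) ndarray
        Lag-1 matrix of the joint order-1 fit.
    order_used_residual : int
        Order of the residual-GC fits.
    pvalues : (n, n) ndarray or None
        Two-tailed permutation p-values of the signed coefficients
        (diagonal NaN); None when no permutation test was run.
    significance_mask : (n, n) boolean ndarray or None
    alpha : float
    channel_labels : list of str
    """

    f_residual: np.ndarray
    signed_coeffs: np.ndarray
    order_used_residual: int
    pvalues: np.ndarray | None
    significance_mask: np.ndarray | None
    alpha: float
    channel_labels: list[str]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        labels = self.channel_labels
        frames = {
            "f_residual": pd.DataFrame(self.f_residual, index=labels, columns=labels),
            "signed_coeffs": pd.DataFrame(self.signed_coeffs, index=labels, columns=labels),
        }
        if self.pvalues is not None:
            frames["pvalues"] = pd.DataFrame(self.pvalues, index=labels, columns=labels)
        return frames

    def summary(self) -> str:
        parts = [f"residual GC at order {self.order_used_residual} (entry [i,j] = j->i):"]
        for name, frame in self.to_frames().items():
            parts.append(f"{name}:\n{frame.round(4).to_string()}")
        return "\n".join(parts)


class GrangerCausality:
    """Causality model over a panel: both measures plus permutation tests.

    Examples
    --------
    >>> res = GrangerCausality(panel).fit(order="aicc", n_perm=1000, seed=7)
    >>> res.signed_coeffs, res.f_residual, res.pvalues
    """

    def __init__(self, panel: TimeSeriesPanel):
        self.panel = panel

    def fit(
        self,
        order: int | str = "aicc",
        p_max: int = 10,
        n_perm: int = 0,
        alpha: float = 0.05,
        seed=None,
    ) -> CausalityResult:
        """Compute residual GC, signed path coefficients and (optionally)
        permutation significance of the coefficients.

        Parameters
        ----------
        order : int or {'aicc', 'bic'}
            Lag order for the residual measure; a criterion name selects
            it from the data with candidates 1..p_max.
        n_perm : int
            Number of time-shuffled surrogates; 0 disables the test.
        """
        panel = self.panel
        if isinstance(order, str):
            sel = VectorAutoregression(panel).select_order(p_max, criterion=order)
            chosen = {"aicc": sel.selected_order_aicc, "bic": sel.selected_order_bic}.get(order)
            if chosen is None:
                raise InputError(
                    f"order must be an integer or 'aicc'/'bic' (got {order!r}), "
                    "or no candidate had a defined criterion"
                )
            order = chosen
        f_mat = residual_gc_matrix(panel, int(order))
        coeffs = signed_path_coefficients(panel)
        pvals = mask = None
        if n_perm:
            from .inference import lag1_permutation_pvalues

            pvals, mask = lag1_permutation_pvalues(
                panel, n_perm=n_perm, alpha=alpha, seed=seed
            )
        return CausalityResult(
            f_residual=f_mat,
            signed_coeffs=coeffs,
            order_used_residual=int(order),
            pvalues=pvals,
            significance_mask=mask,
            alpha=alpha,
            channel_labels=list(panel.channel_labels),
        )
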