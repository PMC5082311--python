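"""Permutation (surrogate) significance testing.

Surrogates are built by shuffling the order of the time points, which
destroys any serial -- hence any Granger-causal -- structure while exactly
preserving each channel's marginal distribution. By default each channel is
permuted independently, a stronger null that also destroys instantaneous
cross-correlation; ``joint=True`` applies one shared row permutation
instead.

The two-tailed p-value uses the add-one convention
p = (1 + #{|null| >= |observed|}) / (n_perm + 1), so p is never zero and
lies in [1/(n_perm+1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .causality import signed_path_coefficients
from .exceptions import InputError
from .panel import TimeSeriesPanel

__all__ = ["PermutationResult", "shuffle_surrogate", "permutation_test",
           "lag1_permutation_pvalues"]


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    pvalue: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.pvalue <= self.alpha

    @property
    def n_perm(self) -> int:
        return int(self.null_values.size)


def shuffle_surrogate(panel: TimeSeriesPanel, seed=None, *, joint: bool = False) -> TimeSeriesPanel:
    """Time-shuffled copy of a panel.

    Each channel's time indices are independently permuted (``joint=True``
    permutes whole rows instead), so the sorted values of every channel are
    identical to the input's.
    """
    if panel.n_timepoints < 2:
        raise InputError("need at least 2 time points to shuffle")
    rng = np.random.default_rng(seed)
    values = panel.values
    if joint:
        out = values[rng.permutation(values.shape[0])]
    else:
        out = np.column_stack(
            [values[rng.permutation(values.shape[0]), j] for j in range(values.shape[1])]
        )
    return TimeSeriesPanel(out, list(panel.channel_labels), panel.sampling_interval_s)


def permutation_test(
    panel: TimeSeriesPanel,
    statistic: Callable[[TimeSeriesPanel], float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    *,
    joint: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test of a panel statistic against zero.

    Parameters
    ----------
    statistic : callable
        Maps a panel to a real number, e.g.
        ``lambda p: signed_path_coefficients(p)[1, 0]``.
    n_perm : int >= 100
    seed : int, SeedSequence or Generator
        The full test is deterministic per seed.
    """
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    observed = float(statistic(panel))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(shuffle_surrogate(panel, rng, joint=joint))
    pvalue = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null_values=null,
                             pvalue=float(pvalue), alpha=alpha)


def lag1_permutation_pvalues(
    panel: TimeSeriesPanel,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    *,
    joint: bool = False,
):
    """Permutation p-values for every off-diagonal signed path coefficient.

    One set of surrogates serves all coefficients: each surrogate is fitted
    once with the joint order-1 VAR and every off-diagonal entry of its
    lag-1 matrix contributes to the corresponding null distribution.

    Returns
    -------
    pvalues : (n, n) ndarray with NaN diagonal
    mask : (n, n) boolean ndarray, ``pvalues <= alpha`` (False on diagonal)
    """
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    observed = signed_path_coefficients(panel)
    n = observed.shape[0]
    null = np.empty((n_perm, n, n))
    for b in range(n_perm):
        null[b] = signed_path_coefficients(shuffle_surrogate(panel, rng, joint=joint))
    exceed = np.sum(np.abs(null) >= np.abs(observed)[None, :, :], axis=0)
    pvalues = (1.0 + exceed) / (n_perm + 1.0)
    off = ~np.eye(n, dtype=bool)
    pvalues = np.where(off, pvalues, np.nan)
    mask = np.where(off, pvalues <= alpha, False)
    return pvalues, mask
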