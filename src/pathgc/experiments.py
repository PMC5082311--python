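"""Monte-Carlo sweeps and ROI-group experiments.

:func:`run_model_sweep` drives the preset processes across their parameter
grid: per grid point it simulates replicate panels and aggregates order
selection, signed path coefficients, residual GC at the per-replicate
AICc-selected order, and permutation significance. The resulting
:class:`SweepSummary` is the machine-readable form of the study's summary
tables (sign counts #A+/#A-, mean selected orders) plus the quantities the
figures plot (mean coefficients, mean F, significant fractions).

:func:`run_roi_sweep` applies order selection and the joint order-1 fit to
channel groups of increasing size, formed by cyclic windows over the
channels -- the protocol used for ROI groups of 2..32 regions -- and
:func:`compare_filtering` repeats it on a band-pass filtered copy.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as ssig

from .causality import residual_gc, sign_bias, signed_path_coefficients
from .exceptions import EstimationError, InputError
from .inference import lag1_permutation_pvalues
from .panel import TimeSeriesPanel
from .processes import DEFAULT_BURN_IN, build_preset, simulate
from .var import VectorAutoregression

__all__ = [
    "SweepSummary",
    "RoiSweepSummary",
    "FilteringComparison",
    "run_model_sweep",
    "run_roi_sweep",
    "bandpass_filter",
    "compare_filtering",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "c", "a_plus", "a_minus", "mean_order_aicc", "mean_order_bic",
    "mean_coeff_xy", "mean_coeff_yx", "mean_f_xy", "mean_f_yx",
    "sig_frac_xy", "sig_frac_yx", "sign_bias", "k",
]

ROI_COLUMNS = [
    "group_size", "mean_order_aicc", "mean_order_bic", "sign_bias",
    "mean_coeff", "a_plus", "a_minus", "n_combinations",
]


def _model1b_c(k: int) -> float:
    # the negative cross influence plays the role of model1's c
    return -0.071 - 0.011 * k


@dataclass
class SweepSummary:
    """Per-grid-point Monte-Carlo aggregates of a preset sweep.

    ``replicates`` keeps the per-replicate raw quantities (selected orders,
    coefficients, residual GC, significance flags) so that statistics other
    than means -- e.g. the modal selected order -- can be computed without
    re-running the sweep.
    """

    table: pd.DataFrame
    preset: str
    params: dict = field(default_factory=dict)
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n_reps = self.params.get("n_reps")
        if n_reps is not None and len(self.table):
            counts = self.table["a_plus"] + self.table["a_minus"]
            if not (counts == 2 * n_reps).all():
                raise ValueError("sign counts must total 2 * n_reps per grid point")

    def to_frame(self) -> pd.DataFrame:
        return self.table[SWEEP_COLUMNS].copy()

    def plot(self, ax=None):
        """Mean coefficients and mean residual GC against the grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
        t = self.table
        ax[0].plot(t["c"], t["mean_f_xy"], "o-", label="F X->Y")
        ax[0].plot(t["c"], t["mean_f_yx"], "s-", label="F Y->X")
        ax[0].set_xlabel("c"); ax[0].set_ylabel("residual GC"); ax[0].legend()
        ax[1].plot(t["c"], t["mean_coeff_xy"], "o-", label="coeff X->Y")
        ax[1].plot(t["c"], t["mean_coeff_yx"], "s-", label="coeff Y->X")
        ax[1].axhline(0.0, color="k", lw=0.5)
        ax[1].set_xlabel("c"); ax[1].set_ylabel("signed path coefficient"); ax[1].legend()
        return ax


def run_model_sweep(
    preset: str,
    k_range=None,
    n_reps: int = 100,
    length: int = 1000,
    seed: int = 0,
    p_max: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    burn_in: int = DEFAULT_BURN_IN,
    *,
    common_sample: bool = False,
) -> SweepSummary:
    """Monte-Carlo sweep of a preset process over its grid.

    Per grid index k and replicate: simulate a panel, select the order with
    both criteria, fit the joint order-1 VAR (signed path coefficients),
    compute residual GC in both directions at the AICc-selected order and,
    if ``n_perm`` > 0, permutation significance of both coefficients.

    Fully seeded: identical arguments reproduce the summary bit-identically.
    A failing replicate aborts the sweep rather than being skipped.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    ks = list(k_range) if k_range is not None else list(range(1, 21))
    if any(int(k) != k or not 1 <= k <= 20 for k in ks):
        raise InputError("k_range entries must be integers in 1..20")
    root = np.random.SeedSequence(seed)
    per_k = root.spawn(len(ks))
    rows = []
    rep_rows = []
    for k, k_seq in zip(ks, per_k):
        t0 = time.perf_counter()
        model = build_preset(preset, int(k))
        c_val = _model1b_c(int(k)) if preset == "model1b" else float(model.lag_coeffs[-1][0, 1])
        orders_a, orders_b = [], []
        coeff_xy, coeff_yx, f_xy, f_yx = [], [], [], []
        sig_xy, sig_yx = [], []
        for rep, rep_seq in enumerate(k_seq.spawn(n_reps)):
            sim_seq, perm_seq = rep_seq.spawn(2)
            panel = simulate(model, length, sim_seq, burn_in)
            sel = VectorAutoregression(panel).select_order(
                p_max, common_sample=common_sample
            )
            if sel.selected_order_aicc is None or sel.selected_order_bic is None:
                raise EstimationError(
                    f"order selection failed for preset {preset} at k={k}"
                )
            orders_a.append(sel.selected_order_aicc)
            orders_b.append(sel.selected_order_bic)
            a1 = signed_path_coefficients(panel)
            coeff_xy.append(a1[1, 0])
            coeff_yx.append(a1[0, 1])
            f_xy.append(residual_gc(panel, sel.selected_order_aicc, (1, 0)))
            f_yx.append(residual_gc(panel, sel.selected_order_aicc, (0, 1)))
            if n_perm:
                _, mask = lag1_permutation_pvalues(
                    panel, n_perm=n_perm, alpha=alpha, seed=perm_seq
                )
                sig_xy.append(bool(mask[1, 0]))
                sig_yx.append(bool(mask[0, 1]))
            rep_rows.append(
                {
                    "k": int(k), "rep": rep,
                    "order_aicc": sel.selected_order_aicc,
                    "order_bic": sel.selected_order_bic,
                    "coeff_xy": coeff_xy[-1], "coeff_yx": coeff_yx[-1],
                    "f_xy": f_xy[-1], "f_yx": f_yx[-1],
                    "sig_xy": sig_xy[-1] if n_perm else np.nan,
                    "sig_yx": sig_yx[-1] if n_perm else np.nan,
                }
            )
        offdiag = np.concatenate([coeff_xy, coeff_yx])
        a_plus = int(np.sum(offdiag > 0))
        a_minus = int(np.sum(offdiag < 0))
        rows.append(
            {
                "c": c_val,
                "a_plus": a_plus,
                "a_minus": a_minus,
                "mean_order_aicc": float(np.mean(orders_a)),
                "mean_order_bic": float(np.mean(orders_b)),
                "mean_coeff_xy": float(np.mean(coeff_xy)),
                "mean_coeff_yx": float(np.mean(coeff_yx)),
                "mean_f_xy": float(np.mean(f_xy)),
                "mean_f_yx": float(np.mean(f_yx)),
                "sig_frac_xy": float(np.mean(sig_xy)) if n_perm else np.nan,
                "sig_frac_yx": float(np.mean(sig_yx)) if n_perm else np.nan,
                "sign_bias": sign_bias(offdiag),
                "k": int(k),
            }
        )
        logger.info(
            "sweep %s k=%d done in %.1fs (AICc %.2f, BIC %.2f, A+ %d, A- %d)",
            preset, k, time.perf_counter() - t0, rows[-1]["mean_order_aicc"],
            rows[-1]["mean_order_bic"], a_plus, a_minus,
        )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    params = dict(
        preset=preset, k_range=[int(k) for k in ks], n_reps=n_reps, length=length,
        seed=seed, p_max=p_max, n_perm=n_perm, alpha=alpha, burn_in=burn_in,
        common_sample=common_sample,
    )
    return SweepSummary(table=table, preset=preset, params=params,
                        replicates=pd.DataFrame(rep_rows))


@dataclass
class RoiSweepSummary:
    """Per-group-size aggregates of the ROI-combination experiment."""

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.table):
            bias = self.table["sign_bias"].dropna()
            if ((bias < -1) | (bias > 1)).any():
                raise ValueError("sign bias must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return self.table[ROI_COLUMNS].copy()


def run_roi_sweep(
    panel: TimeSeriesPanel,
    group_sizes=(2, 4, 8, 16, 32),
    n_combinations: int = 90,
    p_max: int = 10,
    *,
    combination_mode: str = "cyclic",
    seed=None,
) -> RoiSweepSummary:
    """Order selection and order-1 coefficient signs over channel groups.

    For each group size g, ``n_combinations`` groups are formed by the
    cyclic rule (channels k .. k+g-1 modulo n, for k = 0, 1, ...); per
    group the optimal orders (both criteria) and the off-diagonal entries
    of the joint order-1 lag matrix are computed, then aggregated. Groups
    whose AICc is undefined at every candidate contribute NaN to the AICc
    mean (this happens when g**2 * p approaches the series length).

    ``combination_mode='random'`` draws groups at random instead (seeded).
    """
    n = panel.n_channels
    group_sizes = [int(g) for g in group_sizes]
    if any(g < 2 for g in group_sizes):
        raise InputError("group sizes must be >= 2")
    if max(group_sizes) > n:
        raise InputError(
            f"group size {max(group_sizes)} exceeds the panel's {n} channels"
        )
    if combination_mode not in ("cyclic", "random"):
        raise InputError("combination_mode must be 'cyclic' or 'random'")
    if n_combinations < 1:
        raise InputError("n_combinations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for g in group_sizes:
        t0 = time.perf_counter()
        orders_a, orders_b, coeffs = [], [], []
        for k in range(n_combinations):
            if combination_mode == "cyclic":
                idx = [(k + j) % n for j in range(g)]
            else:
                idx = list(rng.choice(n, size=g, replace=False))
            sub = panel.select(idx)
            sel = VectorAutoregression(sub).select_order(p_max)
            orders_a.append(np.nan if sel.selected_order_aicc is None
                            else sel.selected_order_aicc)
            orders_b.append(np.nan if sel.selected_order_bic is None
                            else sel.selected_order_bic)
            a1 = signed_path_coefficients(sub)
            coeffs.extend(a1[~np.eye(g, dtype=bool)])
        coeffs = np.asarray(coeffs)
        rows.append(
            {
                "group_size": g,
                "mean_order_aicc": float(np.nanmean(orders_a)) if not np.all(np.isnan(orders_a)) else np.nan,
                "mean_order_bic": float(np.nanmean(orders_b)) if not np.all(np.isnan(orders_b)) else np.nan,
                "sign_bias": sign_bias(coeffs),
                "mean_coeff": float(np.mean(coeffs)),
                "a_plus": int(np.sum(coeffs > 0)),
                "a_minus": int(np.sum(coeffs < 0)),
                "n_combinations": n_combinations,
            }
        )
        logger.info("roi sweep g=%d done in %.1fs", g, time.perf_counter() - t0)
    table = pd.DataFrame(rows, columns=ROI_COLUMNS)
    params = dict(group_sizes=group_sizes, n_combinations=n_combinations,
                  p_max=p_max, combination_mode=combination_mode)
    return RoiSweepSummary(table=table, params=params)


def bandpass_filter(
    panel: TimeSeriesPanel, low_hz: float, high_hz: float, *, filter_order: int = 2
) -> TimeSeriesPanel:
    """Zero-phase Butterworth band-pass of every channel.

    Requires the panel to carry its sampling interval; the band must
    satisfy 0 < low < high < Nyquist.
    """
    if panel.sampling_interval_s is None:
        raise InputError("panel has no sampling interval; cannot filter")
    fs = 1.0 / panel.sampling_interval_s
    nyq = fs / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise InputError(
            f"band ({low_hz}, {high_hz}) Hz invalid: need 0 < low < high < "
            f"Nyquist ({nyq:.4g} Hz)"
        )
    sos = ssig.butter(filter_order, [low_hz, high_hz], btype="bandpass",
                      fs=fs, output="sos")
    filtered = ssig.sosfiltfilt(sos, panel.values, axis=0)
    return TimeSeriesPanel(filtered, list(panel.channel_labels),
                           panel.sampling_interval_s)


@dataclass
class FilteringComparison:
    """Raw-vs-filtered pair of ROI sweeps on the same panel."""

    raw: RoiSweepSummary
    filtered: RoiSweepSummary
    band: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        raw = self.raw.to_frame().set_index("group_size")
        filt = self.filtered.to_frame().set_index("group_size")
        return raw.join(filt, lsuffix="_raw", rsuffix="_filtered").reset_index()


def compare_filtering(
    panel: TimeSeriesPanel,
    band: tuple[float, float] = (0.01, 0.08),
    group_sizes=(2, 4, 8, 16, 32),
    n_combinations: int = 90,
    p_max: int = 10,
) -> FilteringComparison:
    """ROI sweep on the raw panel and on a band-pass filtered copy."""
    low, high = band
    filtered_panel = bandpass_filter(panel, low, high)
    raw = run_roi_sweep(panel, group_sizes, n_combinations, p_max)
    filt = run_roi_sweep(filtered_panel, group_sizes, n_combinations, p_max)
    return FilteringComparison(raw=raw, filtered=filt, band=(float(low), float(high)))
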