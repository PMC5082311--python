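"""Monte-Carlo sweeps, ROI-group experiments and band-pass filtering."""

import numpy as np
import pandas as pd
import pytest

from pathgc import (
    InputError,
    TimeSeriesPanel,
    bandpass_filter,
    compare_filtering,
    run_model_sweep,
    run_roi_sweep,
)
from pathgc.experiments import ROI_COLUMNS, SWEEP_COLUMNS


def test_sweep_sign_count_conservation():
    summary = run_model_sweep("model1", [5], n_reps=1, length=300, seed=1, n_perm=0)
    row = summary.table.iloc[0]
    assert row["a_plus"] + row["a_minus"] == 2
    assert row["c"] == pytest.approx(-0.6)


def test_sweep_reproducible_bit_identical():
    kwargs = dict(k_range=[1, 2], n_reps=2, length=200, seed=7, p_max=4, n_perm=100)
    a = run_model_sweep("model2", **kwargs)
    b = run_model_sweep("model2", **kwargs)
    pd.testing.assert_frame_equal(a.table, b.table)
    pd.testing.assert_frame_equal(a.replicates, b.replicates)


def test_sweep_table_layout_and_grids():
    summary = run_model_sweep("model1", [1, 20], n_reps=1, length=300, seed=0, n_perm=0)
    assert list(summary.to_frame().columns) == SWEEP_COLUMNS
    np.testing.assert_allclose(summary.table["c"], [-0.52, -0.90])
    m2 = run_model_sweep("model2", [1], n_reps=1, length=300, seed=0, n_perm=0)
    assert m2.table["c"].iloc[0] == pytest.approx(-0.14)
    assert m2.replicates.shape[0] == 1


def test_sweep_input_validation():
    with pytest.raises(InputError):
        run_model_sweep("model1", [0], n_reps=1, length=300, seed=0, n_perm=0)
    with pytest.raises(InputError):
        run_model_sweep("model1", [1], n_reps=0, length=300, seed=0, n_perm=0)


def test_scaled_down_sweep_agrees_with_full_size():
    """A 25-replicate sweep reproduces the 100-replicate aggregates within
    generous sampling-error bounds (binomial for counts)."""
    small = run_model_sweep("model2", [10], n_reps=25, length=1000, seed=3, n_perm=0)
    big = run_model_sweep("model2", [10], n_reps=100, length=1000, seed=4, n_perm=0)
    s, b = small.table.iloc[0], big.table.iloc[0]
    frac_s = s["a_plus"] / 50.0
    frac_b = b["a_plus"] / 200.0
    se = np.sqrt(frac_b * (1 - frac_b) * (1 / 50 + 1 / 200)) + 1e-6
    assert abs(frac_s - frac_b) <= 3 * se + 0.05
    assert abs(s["mean_order_aicc"] - b["mean_order_aicc"]) <= 0.4
    assert abs(s["mean_coeff_xy"] - b["mean_coeff_xy"]) <= 0.06


class TestBandpass:
    def test_in_band_sinusoid_amplitude_preserved(self):
        dt = 0.645
        t = np.arange(3000) * dt
        x = np.sin(2 * np.pi * 0.03 * t)
        panel = TimeSeriesPanel(x[:, None], sampling_interval_s=dt)
        out = bandpass_filter(panel, 0.01, 0.08).values[:, 0]
        trim = slice(300, -300)
        rms_in = np.sqrt(np.mean(x[trim] ** 2))
        rms_out = np.sqrt(np.mean(out[trim] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_constant_channel_removed(self):
        panel = TimeSeriesPanel(np.full((500, 1), 4.2), sampling_interval_s=1.0)
        out = bandpass_filter(panel, 0.01, 0.08)
        assert abs(out.values.mean()) < 1e-6

    @pytest.mark.parametrize("band", [(0.05, 0.05), (0.0, 0.08), (0.01, 0.9)])
    def test_invalid_band_rejected(self, band, make_white_panel):
        panel = make_white_panel(100, 2, sampling_interval_s=0.645)
        with pytest.raises(InputError):
            bandpass_filter(panel, *band)

    def test_missing_sampling_interval_rejected(self, make_white_panel):
        with pytest.raises(InputError):
            bandpass_filter(make_white_panel(100, 2), 0.01, 0.08)


def test_roi_sweep_group_size_exceeding_channels():
    rng = np.random.default_rng(0)
    panel = TimeSeriesPanel(rng.standard_normal((200, 4)))
    with pytest.raises(InputError):
        run_roi_sweep(panel, group_sizes=(2, 8), n_combinations=4)


def test_roi_sweep_layout_and_modes():
    rng = np.random.default_rng(1)
    panel = TimeSeriesPanel(rng.standard_normal((300, 6)))
    summary = run_roi_sweep(panel, group_sizes=(2, 3), n_combinations=6, p_max=3)
    assert list(summary.to_frame().columns) == ROI_COLUMNS
    assert list(summary.table["group_size"]) == [2, 3]
    rand = run_roi_sweep(panel, group_sizes=(2,), n_combinations=6, p_max=2,
                         combination_mode="random", seed=3)
    assert rand.table["a_plus"].iloc[0] + rand.table["a_minus"].iloc[0] == 12
    with pytest.raises(InputError):
        run_roi_sweep(panel, group_sizes=(2,), n_combinations=4,
                      combination_mode="bogus")


def test_roi_sweep_white_noise_has_no_sign_bias():
    """Independent noise channels: pooled coefficient signs are balanced;
    averaged over several panels the bias stays near zero for every group
    size."""
    biases = {2: [], 4: []}
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        panel = TimeSeriesPanel(rng.standard_normal((300, 45)))
        summary = run_roi_sweep(panel, group_sizes=(2, 4), n_combinations=45, p_max=2)
        for g in biases:
            biases[g].append(
                summary.table.set_index("group_size").loc[g, "sign_bias"]
            )
    for g, vals in biases.items():
        assert abs(np.mean(vals)) < 0.1, f"group size {g}"


def test_compare_filtering_roundtrip(make_white_panel):
    panel = make_white_panel(400, 4, seed=5, sampling_interval_s=0.645)
    comp = compare_filtering(panel, band=(0.01, 0.08), group_sizes=(2,),
                             n_combinations=4, p_max=2)
    frame = comp.to_frame()
    assert {"sign_bias_raw", "sign_bias_filtered"} <= set(frame.columns)
    assert abs(comp.raw.table["sign_bias"].iloc[0]) <= 1.0
    with pytest.raises(InputError):
        compare_filtering(panel, band=(0.05, 0.05), group_sizes=(2,),
                          n_combinations=2, p_max=2)
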