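"""VAR estimation: OLS oracle equivalence, criteria, order selection."""

import numpy as np
import pytest

from pathgc import (
    EstimationError,
    InputError,
    TimeSeriesPanel,
    UndefinedCriterionError,
    VarResults,
    VectorAutoregression,
    aicc,
    bic,
    build_preset,
    fit_var,
    select_order,
    simulate,
)


def normal_equations_oracle(values: np.ndarray, order: int):
    """Brute-force (Z'Z)^-1 Z'Y solution on the mean-centered panel."""
    x = values - values.mean(axis=0)
    t, n = x.shape
    y = x[order:]
    z = np.hstack([x[order - k : t - k] for k in range(1, order + 1)])
    coefs = np.linalg.solve(z.T @ z, z.T @ y)
    return [coefs[(k - 1) * n : k * n, :].T for k in range(1, order + 1)]


def test_fit_matches_normal_equations_on_random_panels():
    rng = np.random.default_rng(7)
    for _ in range(50):
        t = int(rng.integers(30, 51))
        n = int(rng.integers(1, 4))
        order = int(rng.integers(1, 4))
        values = rng.standard_normal((t, n))
        res = fit_var(TimeSeriesPanel(values), order)
        oracle = normal_equations_oracle(values, order)
        for got, want in zip(res.coeff_matrices, oracle):
            assert np.max(np.abs(got - want)) <= 1e-8


def test_fit_matches_normal_equations_on_tiny_fixed_panel(small_panel):
    res = fit_var(small_panel, 1)
    oracle = normal_equations_oracle(small_panel.values, 1)
    assert np.max(np.abs(res.lag1 - oracle[0])) <= 1e-10


def test_fit_matches_statsmodels_var():
    """Independent cross-check against statsmodels' VAR (no intercept)."""
    sm_var = pytest.importorskip("statsmodels.tsa.api").VAR
    panel = simulate(build_preset("model1b", 5), 500, seed=3)
    data = panel.values - panel.values.mean(axis=0)
    ours = VectorAutoregression(TimeSeriesPanel(data), center=False).fit(2)
    theirs = sm_var(data).fit(2, trend="n")
    np.testing.assert_allclose(np.stack(ours.coeff_matrices), theirs.coefs, atol=1e-8)
    np.testing.assert_allclose(ours.sigma_ml, theirs.sigma_u_mle, atol=1e-8)


def _dummy_fit(t=100, n=2, order=1, sigma=None):
    return VarResults(
        order=order,
        coeff_matrices=tuple(np.zeros((n, n)) for _ in range(order)),
        residuals=np.zeros((t, n)),
        sigma_ml=np.eye(n) if sigma is None else sigma,
        n_obs_used=t,
        channel_labels=[f"ch{i+1}" for i in range(n)],
    )


def test_criterion_closed_form_values():
    fit = _dummy_fit()  # T=100, n=2, p=1 -> K=4, ln det Sigma = 0
    assert aicc(fit) == pytest.approx(800.0 / 95.0, abs=1e-12)
    assert bic(fit) == pytest.approx(4.0 * np.log(100.0), abs=1e-12)


def test_aicc_monotone_in_residual_determinant():
    smaller = aicc(_dummy_fit(sigma=np.eye(2)))
    larger = aicc(_dummy_fit(sigma=2.0 * np.eye(2)))
    assert larger > smaller


def test_aicc_undefined_when_correction_denominator_nonpositive():
    with pytest.raises(UndefinedCriterionError):
        aicc(_dummy_fit(t=5, n=2, order=1))  # T - K - 1 = 0


def test_bic_never_selects_higher_order_than_aicc(make_white_panel):
    """BIC's K ln T penalty exceeds AICc's ~2K once T > e^2, so its arg-min
    order can never exceed the AICc one on the same criterion table."""
    for seed in range(8):
        panel = make_white_panel(300, 2, seed=seed)
        sel = select_order(panel, 6)
        assert sel.selected_order_bic <= sel.selected_order_aicc
    for k in (2, 12):
        panel = simulate(build_preset("model2", k), 600, seed=k)
        sel = select_order(panel, 8)
        assert sel.selected_order_bic <= sel.selected_order_aicc


def test_bic_selects_order_one_on_white_noise(make_white_panel):
    hits = sum(
        select_order(make_white_panel(1000, 2, seed=s), 10).selected_order_bic == 1
        for s in range(100)
    )
    assert hits >= 95


def test_coefficient_recovery_improves_with_length():
    model = build_preset("model3", 10)
    truth = np.stack(model.lag_coeffs)
    maes = []
    for t in (500, 2000, 8000):
        errs = []
        for seed in range(3):
            panel = simulate(model, t, seed=seed)
            res = fit_var(panel, 3)
            errs.append(np.mean(np.abs(np.stack(res.coeff_matrices) - truth)))
        maes.append(np.mean(errs))
    assert maes[0] > maes[1] > maes[2]


def test_long_run_estimates_recover_model3_coefficients():
    model = build_preset("model3", 10)
    res = fit_var(simulate(model, 100000, seed=1), 3)
    for got, want in zip(res.coeff_matrices, model.lag_coeffs):
        assert np.max(np.abs(got - want)) < 0.02


def test_rank_deficiency_names_offending_channels():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    panel = TimeSeriesPanel(np.column_stack([x, x]), ["a", "b"])
    with pytest.raises(EstimationError, match="a~b"):
        fit_var(panel, 1)
    panel2 = TimeSeriesPanel(
        np.column_stack([rng.standard_normal(50), np.full(50, 3.0)]), ["a", "flat"]
    )
    with pytest.raises(EstimationError, match="flat"):
        fit_var(panel2, 1)


def test_common_sample_logdet_non_increasing_in_order():
    panel = simulate(build_preset("model2", 8), 400, seed=2)
    model = VectorAutoregression(panel)
    logdets = []
    for p in range(1, 6):
        res = model.fit(p, drop=5)
        logdets.append(np.linalg.slogdet(res.sigma_ml)[1])
    assert all(b <= a + 1e-10 for a, b in zip(logdets, logdets[1:]))


def test_selection_common_sample_option_uses_shared_rows():
    panel = simulate(build_preset("model1b", 5), 300, seed=9)
    sel = VectorAutoregression(panel).select_order(5, common_sample=True)
    assert sel.selected_order_aicc is not None
    # all candidates share T_eff under the common-sample rule: recompute one
    res = VectorAutoregression(panel).fit(2, drop=5)
    assert res.n_obs_used == 295


def test_fit_and_selection_input_validation(make_white_panel):
    panel = make_white_panel(50, 2)
    with pytest.raises(InputError):
        fit_var(panel, 0)
    with pytest.raises(InputError):
        VectorAutoregression(panel).fit(3, drop=2)
    with pytest.raises(InputError):
        select_order(panel, 0)
    with pytest.raises(InputError):
        select_order(panel, 3, criterion="aic")
    short = make_white_panel(8, 3)
    with pytest.raises(InputError):
        fit_var(short, 3)


def test_wide_panel_candidates_excluded_not_fatal(make_white_panel):
    """When T - K - 1 <= 0 for large orders the AICc arg-min is taken over
    the remaining candidates instead of failing."""
    panel = make_white_panel(120, 6, seed=4)  # K = 36 p; p >= 4 undefined
    sel = select_order(panel, 5)
    assert np.isnan(sel.aicc_values[4])
    assert sel.selected_order_aicc is not None
    assert sel.selected_order_bic is not None
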