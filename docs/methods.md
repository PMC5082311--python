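# Methods notes

These notes record the modelling conventions, the design choices that were
genuinely open, and what the synthetic experiments do and do not show.

## VAR estimation conventions

Everything downstream (criteria, causality measures, sweeps) depends on a
handful of estimation conventions, so they are fixed explicitly:

* **No intercept.** The preset processes are zero-mean and the parameter
  count `K = p n^2` leaves no room for one. As a safeguard against
  non-zero-mean input, panels are mean-centered per channel before any
  regression.
* **ML residual covariance.** `sigma_ml` divides the residual
  cross-product by the number of regression rows `T_eff`, not by a
  degrees-of-freedom-corrected denominator.
* **Criterion sample size.** `T` in both criteria is `T_eff`, the rows the
  candidate actually used.
* **Own-sample candidate fits.** During order selection each candidate p
  is fitted on its own maximal sample (first p rows dropped). The
  alternative — fitting all candidates on the rows left after dropping
  `p_max` so that criteria share a sample — is available via
  `common_sample=True`. Own-sample is the default because it reproduces
  the reference Monte-Carlo order statistics of the preset sweeps (mean
  AICc-selected orders ≈ 3.2–3.4 for the lag-3 presets at length 1000);
  the common-sample rule systematically selects slightly lower orders
  (≈ 3.1–3.15) under identical conditions. The difference is O(p/T) in
  the criteria but visible in the selection frequencies.
* **Natural logarithms** in both criteria, including the `K ln T` BIC
  penalty.
* **Ties** in the criterion arg-min break toward the smallest order
  (parsimony).
* **Undefined AICc candidates.** The correction term `2KT/(T-K-1)` is
  undefined for `T - K - 1 <= 0`, which genuinely occurs for wide panels
  (e.g. 16 channels: `K = 256 p` passes `T ≈ 900` at `p = 4`). Such
  candidates are excluded from the arg-min with a logged warning rather
  than extrapolated; for large ROI groups this caps the effective
  candidate range, which is itself part of the wide-panel story (the
  penalty growth with `n^2` dominating selection).
* **Rank deficiency** (constant or duplicated channels) aborts with the
  offending channel labels rather than silently pseudo-inverting.

## Causality measures

Residual Granger causality is computed **pairwise-bivariate**: for a
source/target pair the restricted (target's own past) and unrestricted
(both channels' past) models are fitted at the same order on the same
rows, so the restricted regressor set is nested in the unrestricted one
and `F = ln(var_r / var_u) >= 0` holds exactly, not merely in expectation.
A conditional multivariate variant is deliberately out of scope. Signed
path coefficients, by contrast, always come from the **joint** order-1 fit
over all channels supplied, because that is how the audited method is used
on ROI groups.

The sign-bias statistic `(A+ − A−)/(A+ + A−)` classifies every off-diagonal
coefficient by sign; exact zeros (a probability-zero event for continuous
data) are excluded from both counts, and an all-zero input is an error
rather than 0/0.

## Permutation inference

Surrogates shuffle each channel's time indices **independently**, which
destroys serial *and* instantaneous cross-structure; a joint row shuffle
(preserving instantaneous correlation) is available via `joint=True`. The
two-tailed p-value uses the add-one convention
`p = (1 + #{|null| >= |obs|}) / (n_perm + 1)`, so `p ∈ [1/(n_perm+1), 1]`
and is never zero. Default `n_perm = 1000`; the calibration check in the
acceptance suite uses 500 surrogates on 500 independent-noise panels and
requires the per-coefficient rejection rate at α = 0.05 to fall in
[0.03, 0.07].

## Preset processes

The four bivariate presets are indexed by k = 1..20 with identity noise
covariance:

| preset  | lag-1 | lag-2 | lag-3 (Y→X) |
|---------|-------|-------|--------------|
| model1  | 0     | ±0.6  | c = −0.5 − 0.02k |
| model1b | full matrix, entries 0.5 (diag), 0.186+0.005k, −0.071−0.011k | — | — |
| model2  | 0.18 I | ±0.8 | c = −0.1 − 0.04k |
| model3  | ±0.5  | 0     | c = −0.1 − 0.04k |

`build_preset` also accepts an explicit `c` for the three c-indexed
presets. Every preset is stable across its whole grid (verified by the
companion spectral radius). Simulation starts the recursion at zeros and
discards a burn-in of 500 points by default — comfortably longer than the
slowest preset's mixing time, which makes the initialization immaterial.
The burn-in must be at least the model order; unstable processes are
refused unless `allow_unstable=True` is passed explicitly.

`stationary_autocovariance` solves the companion-form discrete Lyapunov
equation and extends by the Yule–Walker recursion; the test suite checks
long simulations against it at three batch-mean standard errors, and the
acceptance suite uses an independently coded Lyapunov/Yule–Walker oracle
for the residual-GC innovation variances.

## The fMRI-like generator

`generate_fmri_like` emulates the statistical features of resting-state
ROI averages that drive the audit's empirical findings, with a four-stage
model (all at a fine 0.1 s latent step):

1. **latent VAR(1)**: diagonal `autocorr_strength` (default 0.8), sparse
   Erdős–Rényi cross-couplings (density 0.2, 50/50 sign split, magnitudes
   `coupling_scale × U(0.5, 1.5)`, default scale 0.05). Instability of the
   drawn matrix is refused, not silently rescaled.
2. **shared slow drift**: a scalar AR(1) with coefficient 0.995 per fine
   step (≈ 0.008 Hz corner — *below* the conventional 0.01–0.08 Hz band),
   loaded onto every channel with weight `autocorr_strength`. This stands
   in for scanner drift and global slow fluctuations, and is the source of
   the positive cross-correlation that biases order-1 off-diagonal
   coefficients positive. Tying the loading to `autocorr_strength` keeps
   the degenerate case (`autocorr_strength = 0, coupling_scale = 0`)
   a set of mutually independent channels.
3. **hemodynamic-like smoothing**: causal exponential kernel, time
   constant 1.3 s, unit gain. This is essential, not cosmetic: a decimated
   VAR(1) is *exactly* a VAR(1) again, so without a smoothing-induced
   moving-average component no TR dependence of the selected order could
   exist at all. With it, the MA structure spans more samples at shorter
   TR and the AICc order rises accordingly.
4. **decimation + observation noise**: nearest-integer subsampling to the
   requested TR and white noise of sd 0.5 (thermal/scanner noise), which
   turns the observed process into a VARMA that finite-order VAR fits
   approximate — the other ingredient of TR- and filtering-dependent
   order selection.

Defaults were chosen once to look like genuine resting-state data at
TR 0.645 s (selected orders of small groups ≈ 2–4, strongly positive
coefficient sign bias, near-zero bias after 0.01–0.08 Hz filtering) and
are exercised by the trend tests over 20 seeds each.

What the generator does **not** emulate: a real hemodynamic response
shape (the kernel is exponential, not a double-gamma), spatial structure
of couplings, head-motion or physiological artefacts, inter-subject
variability. Consequently the synthetic experiments reproduce the
*qualitative* trends (order vs group size, TR and filtering; sign-bias
appearance/disappearance), and no numeric agreement with real-data
magnitudes is claimed or tested. Note also that with
`autocorr_strength = 0` the channels are independent but not white — the
smoothing stage always leaves serial correlation, as real BOLD noise does.

## Experiment drivers

`run_model_sweep` seeds every replicate from a `SeedSequence` tree, so a
sweep is bit-identical under the same arguments, and keeps per-replicate
results (`SweepSummary.replicates`) so modal orders and other
non-mean statistics need no re-run. Residual GC "under optimal order" uses
the per-replicate AICc-selected order. A failed replicate aborts the sweep;
nothing is skipped silently. For `model1b`, whose grid moves two lag-1
entries at once, the summary's `c` column reports the negative cross
influence −0.071 − 0.011k (the entry playing the role of the other
presets' c).

`run_roi_sweep` forms channel groups by cyclic windows
(channels k..k+g−1 mod n), matching the ROI-combination protocol; a
random-combination mode is available behind a flag. The band-pass
comparison defaults to 0.01–0.08 Hz — the de-facto resting-state standard
— applied as a zero-phase (forward-backward) order-2 Butterworth.

## Problem sizes

The Monte-Carlo experiments in the test and acceptance suites use the
study's native sizes where they are cheap (100 replicates of length 1000
for the preset sweeps; 500 panels for permutation calibration) and
scaled-down sizes chosen for tight feedback elsewhere (20 seeds for the
fMRI-like trend checks, 8–16 channel combinations per group size instead
of 90). The scaled-down sweep consistency test verifies that 25-replicate
aggregates agree with 100-replicate ones within sampling error.

## Known limitations

* Residual GC is bivariate only; indirect influences through a third
  channel are not conditioned away.
* Frequency-domain causality measures (spectral GC, DTF/PDC families) are
  out of scope.
* The criteria assume Gaussian innovations through `ln det(Sigma)`.
* Order selection compares full VAR(p) models only; subset/non-uniform
  lag selection is not implemented.
* The permutation test addresses "coefficient ≠ 0" for the order-1 fit;
  it inherits that fit's misspecification, which is precisely the point
  of the audit.
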