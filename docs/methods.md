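# Methods

## Signal model and its assumptions

The transient grating is treated as a single Fourier mode. During
excitation the thermal mode θ and the concentration mode g obey

    dθ/dt = (1 − θ)/τ_th,      dg/dt = (θ − g)/τ,      ζ(t) = θ − A₀·g,

from rest (θ = g = 0); after switch-off the source term vanishes and both
modes decay freely. The closed forms implemented in `tdfrs.core` are the
exact solutions of this system; the degenerate case τ → τ_th is handled by
an analytic-limit branch (threshold |τ − τ_th| < 1e−9·τ_th) because the
generic expression contains (τ − τ_th)⁻¹ and loses precision near
coincidence. A₀ may be negative (thermophilic solute); no sign restriction
is imposed. Constructing `SignalParams` with τ/τ_th < 10 issues a warning —
the two modes are then strongly correlated in a fit — but is not an error.

Assumptions worth keeping in mind: single-mode (no multi-q) optics, additive
detector noise, no baseline drift, a binary (pseudobinary) mixture, and no
convection. Units are SI internally; temperatures cross module interfaces in
°C. The mass density appears in the flux law but cancels in steady state and
is therefore optional metadata only.

## Fitting heterodyne traces

`normalize_trace` sets the thermal plateau to one. A windowed estimate
(median over [5, 10]·τ_th of the rise, thermal shortfall divided out, τ_th
from the first 1 − 1/e crossing) provides initialization; the scale itself
comes from a least-squares fit of the two-mode model with a free overall
amplitude to the excitation-on samples. The bare windowed median carries a
relative bias of order A₀·τ_th/τ (the concentration mode leaks into the
window) that propagates multiplicatively into every derived Soret
coefficient; the free-amplitude refinement removes it exactly on conforming
traces and is what makes normalization idempotent. When the model fit is
impossible (too few samples, degenerate signal) the windowed estimate is
used and a fit downstream will reveal the discrepancy.

`fit_signal` performs bounded nonlinear least squares (τ_th ∈ [Δt, span],
τ ∈ [Δt, 100·span], A₀ ∈ [−2, 2]) weighted by per-point standard deviations
when shot averaging provides them, unweighted otherwise. Initialization:
τ_th from the 1 − 1/e crossing (first crossing on ties), A₀ from one minus
the final value, τ from the 1/e decay of the late slow component with a
span/3 fallback. Off-phase fits use the source-free closed form; when the
excitation-on duration is known from metadata the initial state (θ₀, g₀) is
computed from (τ_th, τ) through the on-phase solution, otherwise steady
state is assumed. Non-convergence is reported (`converged=False`, NaN
covariance), never imputed. Repeated measurements (on/off phases, repeats)
are pooled as mean ± standard error of the mean, matching how multi-point
averages are usually reported for this experiment.

## Temperature law and ΔS_T

`S_T(T) = S_T^∞ + A·exp(−T/T₀)` is fitted by weighted nonlinear least
squares with initialization S_T^∞ from the hottest point, T₀ from half the
span, and A from the coldest-point residual; T₀ is bounded to (1e−3, 1e4) °C.
The temperature enters the exponential in °C, so T₀ and the sign-change
temperature T* = T₀·ln(−A/S_T^∞) are in °C; the model is equivalent under a
unit shift up to reparametrization of (A, T₀). When A and S_T^∞ share a
sign there is no sign change and T* is reported as absent rather than an
error.

ΔS_T(ΔT) = S_T(40 °C) − S_T(15 °C) is computed from measured points when
both endpoints exist within 0.5 °C (uncertainty by quadrature) and from the
fitted curve otherwise (delta-method on the fit covariance); the mode is
always recorded.

A known limitation, quantified by the seeded recovery studies: with seven
points over 15–45 °C and noise of 1e−3 1/K, the maximum-likelihood estimates
of (S_T^∞, A, T₀) are heavy-tailed — in a few percent of noise realizations
the bending scale is nearly unidentifiable and the ensemble-mean parameter
error is tens of percent even though median recovery of S_T^∞ and T₀ is
≪ 1% and 95% confidence intervals cover the truth at nominal rate. The
amplitude additionally carries a ~6% small-sample skew. ΔS_T, in contrast,
is a stable functional of the data (recovered to ≪ 1% end-to-end); analyses
should prefer it over raw curve parameters, which is exactly how it is used
here.

## Condition-level correlation

ΔS_T versus α-helical content is fitted by closed-form weighted least
squares (weights 1/σ², unit weights when σ is absent; with unit weights the
parameter covariance is scaled by the residual variance). Helix-content
uncertainties are reported but not folded into the fit (no
errors-in-variables); the relationship is summarized by Pearson's r without
a p-value since n is a handful of conditions. Leave-one-out slopes flag any
condition whose removal changes the slope by more than 50% — the strongly
acid-unfolded state is the expected candidate. Ranking by ΔS_T uses
descending order with lexicographic tie-breaks.

## Synthetic data: what it emulates and what it does not

The generator integrates the two-mode system with a fixed-step classical
RK4 scheme (step ≤ τ_th/50, implemented as the exact affine per-step map of
the linear system), deliberately independent of the closed forms used for
fitting, and adds i.i.d. Gaussian noise per sample and shot. All generators
are seeded and bit-reproducible; consuming the noise stream in chunks for
the memory-bounded shot average draws the same numbers as materializing
every shot.

Default study conditions, chosen once to mirror the experimental protocol
and field-typical magnitudes: water thermal diffusivity D_th = 1.45e−7 m²/s;
protein diffusion coefficient D = 1.1e−10 m²/s (a ~17 kDa globular protein),
so τ/τ_th = D_th/D ≈ 1318; grating with τ_th = 1 ms (q ≈ 8.3e4 m⁻¹);
contrast factors ∂n/∂T = −1.0e−4 K⁻¹ and ∂n/∂c = 0.17; weight fraction
0.007 (7 mg/mL); 3000 shots per average; per-shot noise sd 0.01 (the
per-shot noise magnitude is a convention — instrument noise is not
published). The S_T(T) generator samples 15–45 °C in 5 °C steps; the
condition generator uses the measured helix contents of the six pH/buffer
states (51, 50, 43, 34, 33, 4%) with a linear ΔS_T relation (slope 5e−4
K⁻¹ per %, intercept −2e−3 K⁻¹, helix jitter 2%, ΔS_T noise 2e−3 K⁻¹)
spanning the few-1e−2 K⁻¹ sensitivity range typical of proteins.

What passing tests therefore show: the estimation chain is unbiased and
correctly calibrated *for data that follow the two-mode model with additive
Gaussian noise*. Real traces additionally contain baseline drift,
multiplicative/photon noise, slow aggregation drifts (phosphate buffer at
high temperature), and possible multi-species signals — none of which are
emulated, and all of which the fit will fold into its three parameters
rather than diagnose. Recovery studies in the test suite use a faster
(τ_th = 1 ms, τ = 100 ms) lumped configuration for the per-seed ensembles
and the physical τ/τ_th ≈ 1318 conditions for the end-to-end loop; problem
sizes (100 seeds, 3000 shots, 7 temperatures) are stated in each test.

## Numerical and design choices

* Nonlinear fits use `scipy.optimize.curve_fit` (Levenberg–Marquardt /
  trust-region reflective with bounds); covariances come from the Jacobian
  at the optimum, `absolute_sigma=True` whenever measurement sigmas exist.
* The independent oracle for the signal model in the tests is
  `scipy.integrate.solve_ivp` at rtol 1e−11; the package's own RK4
  generator is checked against the closed form to < 1e−6 everywhere.
* Sequence molecular weights use Biopython's ProtParam (average masses);
  extinction coefficients use the Pace/ExPASy convention
  (5500/1490/125 M⁻¹cm⁻¹, all cysteines reduced by default) — the only
  convention consistent with the sequence-derived E₁% used for
  concentration determination.
* The default pKa table is the Bjellqvist/ExPASy set (Asp 4.05, Glu 4.45,
  His 5.98, Cys 9.0, Tyr 10.0, Lys 10.0, Arg 12.0, N-term 7.5,
  C-term 3.55), overridable via `PkaSet`; charge and pI depend materially
  on this choice, and this set reproduces the ExPASy-style near-neutral pI
  of apomyoglobin. pI is found by root bracketing on pH ∈ [0, 14].
* Buffer presets keep the printed mole fractions: acetate 0.8/0.2
  (hydration index 0.8·1 + 0.2·5 = 1.8) and phosphate 0.9/0.1 with 4/11
  immobilized waters, giving 0.9·4 + 0.1·11 = 4.7. Note the exact
  Henderson–Hasselbalch fractions differ slightly from the printed ones
  (phosphate at pH 6 with pKa₂ 7.21 gives 0.94; acetate at pH 4 with pKa
  4.76 gives 0.85); `speciation` computes the exact values, the presets
  preserve the conventional rounded inputs, and the resulting phosphate
  hydration index is reported as computed rather than adjusted.
* Trace files are '#'-keyed CSV (hand-inspectable, diff-able); reports are
  JSON with sorted keys so reruns are byte-identical. The pipeline
  continues over failing traces and reports failure counts, since each
  state point pools several fits.

## Known limitations

No theory predicts T*; the temperature law is purely empirical and is not
extrapolated beyond the fitted range by any default. Buffer contributions to
the measured signal are neglected (pseudobinary treatment, justified at
20 mM); multi-exponential signals, electrophoretic characterization and
structure-based pKa prediction are out of scope. The hydration index is a
mole-fraction-weighted mean of literature immobilized-water counts, a coarse
hydrophilicity indicator rather than a thermodynamic quantity.
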