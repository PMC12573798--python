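# tdfrs

Analysis toolkit for **thermodiffusion (Soret effect) measurements of
protein solutions** by infrared transient-grating / thermal diffusion forced
Rayleigh scattering (IR-TDFRS), built around the apomyoglobin pH/buffer
series: extracting Soret and diffusion coefficients from heterodyne
diffraction signals, modelling the temperature dependence of the Soret
coefficient, and correlating its temperature sensitivity with α-helical
content as a hydrophilicity proxy.

It is written for experimentalists and modellers working with TDFRS or
microscale-thermophoresis-style data who need a tested, scriptable pipeline
from raw averaged shots to condition-level statistics.

## The model

A holographic temperature grating drives two coupled relaxation modes — a
fast thermal mode (time constant τ_th) and a slow concentration mode (time
constant τ) fed by the Soret effect. The normalized heterodyne intensity
during excitation is

    ζ(t) = 1 − e^(−t/τ_th) − A₀ (τ − τ_th)⁻¹ [ τ(1 − e^(−t/τ)) − τ_th(1 − e^(−t/τ_th)) ]

with steady-state amplitude

    A₀ = (∂n/∂c)(∂n/∂T)⁻¹ · S_T · c(1 − c)

so that a fit of ζ(t) plus the independently measured refractive-index
increments yields the transport coefficients via τ_th = (D_th q²)⁻¹,
τ = (D q²)⁻¹ and S_T = D_T / D. The temperature dependence of the Soret
coefficient follows the empirical law

    S_T(T) = S_T^∞ + A·exp(−T/T₀),    T* = T₀ ln(−A/S_T^∞)

whose sensitivity statistic ΔS_T(ΔT) = S_T(40 °C) − S_T(15 °C) correlates
linearly with the protein's α-helical content across pH/buffer conditions.
Auxiliary calculations cover sequence-derived molecular weight, ε₂₈₀ and
E₁%, Henderson–Hasselbalch net charge and pI, buffer speciation, and the
mole-fraction-weighted immobilized-water (hydration) index of buffers.

## Worked example

```python
import numpy as np
from tdfrs import (SignalParams, SimulationConfig, simulate_averaged_trace,
                   split_phases, fit_signal, amplitude_to_soret)
from tdfrs.simulate import study_contrast

# simulate a 3000-shot averaged experiment (tau_th = 1 ms, tau = 100 ms)
cfg = SimulationConfig(params=SignalParams(1e-3, 0.1, 0.6),
                       t_on=0.5, t_off=0.5, noise_sd=0.01, n_shots=3000, seed=1)
trace = simulate_averaged_trace(cfg)
on, off = split_phases(trace, trace.metadata.t_excitation_off_s)
fit = fit_signal(on, "on")
print(f"tau_th = {fit.params.tau_th:.6g} s, tau = {fit.params.tau:.6g} s, "
      f"A0 = {fit.params.a0:.5g}")
print(f"S_T = {amplitude_to_soret(fit.params.a0, study_contrast(), 0.007):.5g} 1/K")
```

prints

```
tau_th = 0.00100002 s, tau = 0.0999947 s, A0 = 0.59999
S_T = -0.050775 1/K
```

i.e. the fit recovers the generating relaxation times and amplitude to
better than 0.01% from a realistically noisy 3000-shot average, and the
amplitude converts to a Soret coefficient through the optical contrast
factors and the solute weight fraction. Sequence-level properties:

```python
from tdfrs import apomyoglobin_sequence, extinction_280, molecular_weight, mass_to_molar
seq = apomyoglobin_sequence()            # 153-residue horse apomyoglobin
mw = molecular_weight(seq)               # 16951.3 Da
eps, e1pct = extinction_280(seq)         # 13980 1/(M cm), E_1% = 8.25
print(round(e1pct, 2), round(mass_to_molar(7.0, mw), 1))   # 8.25 0.4
```

A command-line interface mirrors the pipeline stages
(`tdfrs simulate | fit-signal | fit-soret | correlate | protprops | report`).

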