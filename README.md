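# darkphos

Quantitative ³¹P NMR analysis of **spectroscopically dark phosphate
assemblies** in aqueous solution.

Phosphate solutions show an anomaly: the ³¹P line *broadens* as the
sample is heated, R₂ exceeds R₁ by one to two orders of magnitude, and
CEST (chemical-exchange saturation transfer) dips are several times wider
than the no-exchange expectation of twice the rf nutation frequency.  All
of this is explained by a small, temperature-growing population of
NMR-invisible phosphate assemblies in fast exchange with the visible
monomers.  `darkphos` implements that model end to end, for spectroscopists
who want to simulate, fit, or design such experiments:

* **Two-state thermodynamics + Arrhenius kinetics** —
  p_B = exp(−ΔG/RT)/(1+exp(−ΔG/RT)) with ΔG = ΔH − TΔS;
  k_f = k₀·e^(−E_a/RT); k_b = k_f(1−p_B)/p_B (detailed balance); the
  fast-exchange average R₂ ≈ R₂^A + p_B·ΔR₂ and its inversion for R₂^B.
* **Two-pool Bloch–McConnell simulator** — exact matrix-exponential
  propagation of (M_A, M_B) under cw saturation → Z-spectra, dip widths,
  and observed R₁/R₂ under exchange.
* **Relaxation/hydrodynamics** — random-field R₁/R₂ vs correlation time
  (R₁ maximal at τ = 1/ω₀), Stokes–Einstein (d = k_BT/3πηD) and
  Stokes–Einstein–Debye (τ = πηd³/6k_BT) conversions, water-viscosity
  correlation, hydration-shell water counting, R₂ = π·FWHM.
* **DOSY** — Stejskal–Tanner attenuation ψ = e^(−Dg²γ²δ²(Δ−δ/3)),
  log-linear diffusion fitting with a single-component linearity check,
  and gradient-schedule design.
* **Synthetic studies + joint fitting** — a generator with known ground
  truth emulating the full measurement campaign, and the joint
  R₂(T)/CEST fit recovering ΔH, ΔS, k₀, E_a and the dark-pool R₂
  schedule, with recovery reporting.

## Worked example

```python
import numpy as np, dataclasses
from darkphos import bloch, synthetic, thermo

params = thermo.ThermoKineticParams(dH=25e3, dS=30.0, k0=20e3, Ea=10e3)
for T in (293.0, 353.0):
    st = thermo.exchange_state(params, T)
    print(f"T={T:.0f} K  pB={st.pB:.4f}  kf={st.kf:.0f} s^-1  kb={st.kb:.3g} s^-1")

truth = synthetic.default_truth()
scheme = bloch.SaturationScheme(nutation=150.0, duration=5.0,
                                offsets=np.arange(-4000.0, 4001.0, 100.0))
for T in (298.0, 353.0):
    s_on = synthetic.spin_system_at(truth, T)
    s_off = dataclasses.replace(s_on, pB=0.0, kf=0.0, kb=0.0)
    w_on = bloch.dip_width(bloch.simulate_z_spectrum(s_on, scheme))
    w_off = bloch.dip_width(bloch.simulate_z_spectrum(s_off, scheme))
    print(f"T={T:.0f} K  dip width with exchange {w_on:.0f} Hz vs without {w_off:.0f} Hz")
```

prints

```
T=293 K  pB=0.0013  kf=330 s^-1  kb=2.56e+05 s^-1
T=353 K  pB=0.0073  kf=663 s^-1  kb=8.99e+04 s^-1
T=298 K  dip width with exchange 690 Hz vs without 120 Hz
T=353 K  dip width with exchange 1977 Hz vs without 113 Hz
```

The dark fraction grows from 0.13% to 0.73% between 293 and 353 K, and
exchange broadens the 150 Hz-saturation CEST dip several-fold — the
experimental fingerprint of the invisible pool.  A command-line interface
exposes the same pipeline (`darkphos simulate | zspec | fit | dosy |
hydro | recover`); for instance

```
$ darkphos hydro --tau-s 10e-9 --temp-k 298
water viscosity at 298 K: 8.9349e-04 Pa s
tau = 1/omega0: 795.8 ps
rotational diameter for tau = 1e-08 s: 4.45 nm
```

converts a 10 ns rotational correlation time into a ≈4.4 nm hydrodynamic
diameter, and `darkphos recover --seed 1` runs a closed-loop synthetic
study and prints the truth-vs-estimate table for all six fitted
parameters.

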