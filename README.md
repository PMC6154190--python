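# oxflow

Analysis pipeline for a hybrid broadband near-infrared spectroscopy
(B-NIRS) / diffuse correlation spectroscopy (DCS) neuromonitor: an
instrument class built to watch the newborn brain during hypoxia-ischemia
by tracking three complementary signals at the bedside —

* **StO₂**, tissue oxygen saturation, from broadband diffuse reflectance;
* **CBF**, absolute cerebral blood flow (ml/100g/min), from DCS calibrated
  by an indocyanine-green bolus;
* **ΔoxCCO**, the oxidation state of cytochrome c oxidase (the terminal
  electron acceptor of oxidative metabolism), from broadband attenuation
  changes.

The package implements the complete data-processing chain for such an
instrument, together with a seeded synthetic experiment generator, so every
stage is testable without hardware or animal data.

## The models

**Baseline spectroscopy.** The reflectance spectrum is
`R(λ) = log10((spectrum−dark)/(reference−dark))`.  Its 1st/2nd spectral
derivatives are fitted with the extrapolated-boundary semi-infinite
diffusion solution, with

    µs′(λ) = A·(λ/800 nm)^−α
    µa(λ)  = WF·µa_w(λ) + Hb_b·ε_Hb(λ) + HbO2_b·ε_HbO2(λ)

by a three-step constrained least-squares scheme (2nd derivative 815–845 nm
→ WF; 2nd derivative 680–800 nm → Hb_b; 1st derivative 680–845 nm →
HbO2_b, A, α) followed by a simultaneous all-window refinement.  Baseline
saturation is `StO2 = HbO2_b/(Hb_b + HbO2_b)`.

**Dynamic tracking.** Changes in Hb, HbO₂ and oxCCO are recovered over
770–900 nm with a linear multi-wavelength (modified Beer-Lambert) solver,
`ΔA(λ) = L·w(λ)·ε(λ)·Δc`, using a dynamic pathlength `L` refit per spectrum
from the 2nd-derivative water feature at 815–845 nm.

**Blood flow.** Each autocorrelation curve is fitted with the
correlation-diffusion solution through the Siegert relation
`g2(τ) = 1 + β|g1(τ)|²` (Brownian dynamics, ⟨Δr²⟩ = 6·Db·τ), giving the
coherence factor β and blood flow index BFi ≡ Db (cm²/s).  Absolute CBF
comes from a dye-bolus experiment, `Cb(t) = CBF·R(t) ∗ Ca(t)`, deconvolved
by truncated SVD; since the impulse residue function satisfies R(0) = 1,
CBF is the initial value of the recovered CBF·R(t), and it anchors the BFi
series: `CBF(t) = BFi(t)·CBF_anchor/⟨BFi⟩_anchor`.

## Worked example

```python
import numpy as np
from oxflow import (ChromophoreLibrary, fit_baseline, simulate_experiment)
from oxflow.bnirs_dynamic import pathlength_wavelength_factor, track_timeseries

lib = ChromophoreLibrary.default()
exp = simulate_experiment(seed=5)                 # full hypoxia-ischemia run
mask = exp.spectra.times <= 300                   # 5-min pre-clamp baseline
r = exp.spectra.reflectance()

bl = fit_baseline(lib.grid, r[mask].mean(axis=0), lib)
print({k: round(v, 3) for k, v in list(bl.to_dict().items())[:6]})

w = pathlength_wavelength_factor(bl.tissue, lib)
ts = track_timeseries(lib.grid, r, exp.spectra.times, bl, lib,
                      baseline_mask=mask, wavelength_factor=w)
i = np.argmin(abs(ts.time.values - 1200))         # deep in the insult
print(f"t=1200 s: StO2={ts.StO2[i]:.3f}  dCCO={ts.dCCO[i]:.2f} uM")
```

prints (seed 5)

```
{'WF': 0.71, 'Hb_b': 11.794, 'HbO2_b': 36.212, 'A': 0.926, 'alpha': 2.56,
 'StO2_b': 0.754}
t=1200 s: StO2=0.300  dCCO=-3.37 uM
```

The baseline saturation (0.754, truth 0.755) is recovered tightly even when
individual structural parameters scatter at single-experiment photon
budgets; during the insult the tracker reports the collapse of StO₂ and the
delayed decline of oxCCO (truth at that instant: StO₂ 0.259, ΔoxCCO
−4.97 µM; the linear tracker compresses large excursions — see
`docs/methods.md`).

A command-line interface mirrors the library
(`oxflow simulate | fit-baseline | fit-timeseries | fit-dcs | calibrate |
mc-validate | bin-correlate`); run `oxflow --help`.

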