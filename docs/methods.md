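# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Forward models

Both fitting kernels are closed-form diffusion-approximation solutions for
a semi-infinite homogeneous medium with an extrapolated boundary
(refractive indices 1.4 tissue / 1.0 exterior; internal-reflection
coefficient from the Groenhuis/Haskell polynomial, A ≈ 3.25 at n = 1.4;
isotropic source depth z0 = 1/(µa+µs′), extrapolation length
zb = 2A/3(µa+µs′)).

* CW reflectance: two-dipole flux expression, used both to simulate spectra
  and as the model whose spectral derivatives are fitted.  The identical
  code path serves simulator and fitter, so any change to the boundary
  treatment stays consistent on both sides.
* DCS: the CW solution with µa → µa + 2µs′k0²·Db·τ (Brownian scatterer
  dynamics), normalised to g1(0)=1, squared into g2 through the Siegert
  relation with coherence factor β.  k0 = 2πn/λ0, n = 1.4, λ0 = 785 nm.
  The blood flow index is identified with Db (cm²/s).

Both the refractive index and the boundary condition are configuration
knobs in `forward_models`; the defaults above are the standard soft-tissue
choices.

## Baseline fitting

The three-step scheme fits derivative spectra (Savitzky–Golay, window 11,
order 3, on the 1-nm grid; the same operator is applied to data and model,
so the filter's pass-band bias cancels).  Steps: (1) 2nd derivative,
815–845 nm, all five parameters free, WF retained; (2) WF fixed, 2nd
derivative 680–800 nm, Hb_b retained; (3) WF and Hb_b fixed, 1st derivative
680–845 nm, HbO2_b, A, α retained.  Each step minimises the sum of squared
derivative differences with a bounded Nelder–Mead simplex (xatol = fatol =
1e-9, ≤2000 evaluations) followed by a bounded trust-region least-squares
polish.

**Why a final joint refinement exists.**  Within the water window alone the
model has a near-exact degeneracy: scaling the water contribution down
(smaller WF) can be compensated by a longer differential pathlength
(smaller scattering amplitude A), with the residual mismatch far below
realistic photon noise.  Any single-window optimiser therefore performs a
random walk along a noise-tilted valley and WF precision does not improve
with spectral averaging.  The profile of the *joint* objective — the
concatenated derivative residuals of all three windows — is identifiable,
because the feature-rich 680–845 nm window pins A and α and thereby fixes
the water-band scale.  `fit_baseline` therefore ends with one simultaneous
bounded least-squares refinement of all five parameters over the three
windows, started from the sequential estimates (`joint_refine=False`
restores the plain sequential scheme).  On noiseless input the refinement
is a no-op (the sequential fit already sits at the global minimum);
on noisy input it is what makes averaging effective.

Estimates are clipped by their bounds (Table of initial values/bounds in
`config.py`; concentrations in µM, A ∈ [1e-6, 1.3] mm⁻¹ since µs′=0 is not
a valid medium); parameters landing on a bound are flagged.

## Dynamic (differential) stage

Attenuation changes are computed in optical density against the mean
baseline-period spectrum and unmixed over 770–900 nm by Moore–Penrose
pseudoinverse of the [ε_Hb, ε_HbO2, ε_oxCCO] matrix — well conditioned at
1-nm sampling, so no regularisation is applied.  The optical pathlength is
re-estimated per spectrum by projecting the measured 2nd-derivative
attenuation on the water-band derivative shape (closed-form scalar
projection); a rolling-median smoothing across cycles is available but off
by default.  The wavelength dependence of the pathlength, w(λ), defaults to
the identity in `ucln_solve`; the pipeline helper
`pathlength_wavelength_factor` derives it instead from the baseline tissue
model as the normalised differential pathlength −∂lnR/∂µa of the diffusion
model, anchored to 1 at 830 nm (the centre of the water-fit window).  Any
externally tabulated factor can be passed in its place.

Because the tracker is linear while the underlying reflectance is not,
large excursions are compressed: in the synthetic insult (StO₂ falling
from 0.755 to 0.25) the recovered ΔoxCCO nadir is ~10% shallower than
truth at high SNR, while StO₂ — a ratio — is recovered to ~0.03.  This is
inherent to modified-Beer-Lambert tracking with a scalar pathlength, not an
implementation artefact.

## DCS fitting and calibration

g2 curves are tail-anchored (plateau of the last decade of lags normalised
to 1) and fitted over the lags where g2−1 exceeds 1% of the zero-lag
amplitude; free parameters (β, log10 Db) with bounds β ∈ (0, 1.2],
Db ∈ [1e-11, 1e-5] cm²/s, initial values 0.5 and 1e-8.  Degenerate curves
(no decaying correlation) are returned flagged rather than raising, so a
stream survives occasional bad acquisitions.  Calibration multiplies the
BFi series by CBF_anchor/⟨BFi⟩ over a user-chosen anchor window; it is
scale-equivariant and idempotent.

## DCE deconvolution

The convolution system is assembled as a lower-triangular Toeplitz matrix
of the arterial curve (Δt = 0.4 s sampling) and inverted by truncated SVD,
discarding singular values below 10% of the largest — common
bolus-tracking practice.  CBF is the initial value of the recovered
flow-scaled residue, computed as the maximum of its first three samples
because the truncation smooths the leading edge.  With the default
synthetic bolus (below) the noiseless round trip recovers CBF to about
−4%; the residue family and the truncation threshold are both parameters.

## Synthetic experiments

The generator emulates a neonatal hypoxia-ischemia protocol: 300 s
baseline; carotid occlusion dropping CBF immediately to 45% of baseline
(region i, 120 s); added hypoxia driving CBF to a 10% nadir held 900 s
(region ii); recovery.  StO₂ steps with flow (0.755 → 0.60 → 0.25);
ΔoxCCO follows a *delayed* first-order response to the flow deficit
(delay 60 s, time constant 150 s, asymptotic drop 5 µM ≈ 10% of the
hemoglobin pool), so its half-decline lags CBF's and it continues to fall
after the flow nadir — the qualitative ordering the instrument is built to
reveal.  Transitions are logistic with 15-s width.  Control runs are flat.

Acquisition follows the 14-s multiplex cycle (0.5 s guard, 12 spectra over
3 s, 0.5 s guard, 2 DCS curves over 10 s) that keeps the broadband source
from contaminating the photon-counting DCS channel.

* Spectra: counts = gain · halogen shape (3000 K blackbody) · reflectance,
  with Poisson noise per wavelength per frame.  The count scale (3.5e3
  expected counts at the brightest channel per 0.25-s frame) was calibrated
  once so that the single-acquisition StO₂ scatter of the Monte Carlo study
  is ≈3.9 percentage points, and is not adjusted per run.
* DCS: Db(t) proportional to CBF(t); additive Gaussian correlator noise
  with a simplified lag profile σ(τ) ∝ (0.05 + |g1(τ)|)/√T — larger where
  the correlation is strong, shrinking with integration time.  This is a
  deliberate simplification of full correlator noise estimators; it
  reproduces the two properties the analysis relies on (lag dependence,
  1/√T averaging) and nothing more.
* DCE: gamma-variate arterial input (shape 2, scale 0.8 s — a fast
  intravenous push — area-normalised to 40 µM·s), exponential residue with
  MTT = 6 s (blood volume ≈ 3 ml/100g at CBF 28 ml/100g/min), 400-ms
  sampling, 1% additive noise on the tissue curve.

The bundled extinction tables are **synthetic parametric spectra** (sums of
Gaussians and exponential edges) with the literature band positions and
magnitude scale: Hb peak at 758 nm, HbO₂ rise toward 900–960 nm, water
bands at 740/830/970 nm, oxCCO difference peak at 835 nm.  The 830-nm water
band is deliberately narrow so that its curvature dominates the 815–845 nm
window over the smooth hemoglobin tails — the property of the real water
feature that makes water-anchored fitting work.  Consequences: every
simulation/fit round trip in this package is self-consistent, but absolute
concentrations fitted from *real* spectrometer data require replacing these
tables (two-column text files, `ChromophoreLibrary.from_files`) with a
measured compilation.  Passing tests demonstrate the correctness of the
algorithms under the stated noise models, not the accuracy of any specific
extinction compilation, and the synthetic trajectories target qualitative
ordering (delay, post-nadir decline), not any particular animal's curves.

## Evaluation procedures

The Monte Carlo study generates spectra at a known truth (WF 0.8, Hb 13 µM,
HbO₂ 40 µM, A 0.8 mm⁻¹, α 2.6 — StO₂ 75.5%), averages N ∈ {1, 8, 64, 512}
Poisson realisations, fits, and repeats; summaries are per-parameter
means ± SD.  The default sizes here are 100 repetitions per level (300 for
the single-acquisition scatter, whose SD estimator is the noisiest) —
reduced from the 500 a full study would use, a size chosen to keep the
whole evaluation in the minutes range on one CPU.

The flow-binned correlation analysis normalises each subject's CBF series
to its pre-occlusion mean, partitions (0, 1] into ten 10%-reduction bins
(above-baseline flow joins the top bin), averages within bins per subject,
then reports cross-subject mean ± SEM with per-bin subject counts.
Departures from the baseline bin are flagged by subject-wise paired
differences tested with a one-sample t-test and Holm adjustment at
α = 0.05 — a documented replacement for an otherwise unspecified
multivariate ANOVA; bins with fewer than two paired subjects are marked
untestable rather than flagged.

## Known limitations

* Homogeneous semi-infinite medium only; no layered or time-resolved
  models, no few-mode-fiber or incoherent-contamination physics.
* ΔoxCCO is differential only; no absolute CCO concentration.
* The linear tracker's compression of large excursions (above).
* Synthetic extinction tables (above); the fitted parameter *values* on
  synthetic data carry no biological meaning beyond the generator's truth.
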