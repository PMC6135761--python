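# Methods

This note documents the models, defaults, and numerical choices behind
fscvkit, and what the synthetic generators do and do not emulate.

## Waveform and session model

The applied program is a symmetric triangle from `v_hold` (−0.4 V) to
`v_peak` (+1.3 V) at 400 V/s, repeated at 10 Hz, digitized at 214 samples
per scan. The grid places sample 0 at `v_hold` and the apex exactly at
sample `n/2`; the last sample sits one grid step (≈15.9 mV) above `v_hold`,
closing the triangle at the start of the next scan. The inter-scan hold at
`v_hold` is not digitized — sessions contain only in-scan samples, so a
session is a (scans × 214) current matrix in nA with scan times at 100 ms
spacing.

An in vivo potential offset (0.1–0.3 V, compensating a drifted Ag/AgCl
reference) is stored on the waveform; the chemistry-facing potential axis
(`Waveform.potentials`) is offset-corrected, so "current at +0.6 V" always
refers to the dopamine oxidation potential regardless of offset.

Potential lookup uses the nearest grid sample on the requested sweep half,
no interpolation: the grid step is small against redox peak widths
(σ ≈ 150–200 mV) and nearest-sample lookup is deterministic. On the default
grid the sample nearest +0.600 V lies at +0.601 V.

Background subtraction removes the per-column mean of a user-chosen scan
window. The default window is 10 scans ending 1 s before the stimulation
window when one is recorded (pre-stimulus baseline), else the first 20
scans. Subtraction is idempotent and zeroes the window's column means by
construction. Note that subtracting a mean of *n* background scans inflates
white noise by √(1 + 1/n); with the default windows this is a ≤5% effect.

## Synthetic-data model

The generators define the study conditions under which the pipeline is
tested; their defaults are fixed and are not tuning knobs.

* **Dopamine template.** Gaussian bumps in potential: oxidation at +0.6 V
  (σ = 0.15 V) on the anodic half, reduction at −0.2 V (σ = 0.2 V) on the
  cathodic half with amplitude ratio −0.4. Each bump is normalized to unit
  grid maximum, so the anodic peak current is *exactly*
  `sensitivity_slope × concentration` and amplitude is exactly linear in
  concentration. The default slope of 50 nA/µM matches the tens-of-nA/µM
  scale of measured carbon-fiber sensitivities.
* **pH template.** Two wide Gaussian lobes spanning the sweep (centers
  +1.15 V and −0.35 V, σ = 0.45/0.55 V), linear in ΔpH at 120 nA per pH
  unit, valid for |ΔpH| ≤ 0.4. The lobe weights were fixed once so the
  shape correlates with the dopamine template at |r| ≈ 0.19 (< 0.5), which
  is what makes the two species separable in component space. Real pH
  voltammograms are not literally Gaussian; only their breadth, linearity,
  and weak dopamine-correlation matter to the pipeline.
* **Capacitive background.** A square-wave-like CV whose sign follows sweep
  direction, grid maximum `background_amplitude` (default 900 nA), with a
  mild potential-dependent tilt and a slow multiplicative drift
  (`drift_rate`, default 0.05 nA/s at the background maximum). Real FSCV
  backgrounds have richer structure; the pipeline only relies on the
  background being large, scan-stable, and slowly drifting.
* **Flow-cell sessions.** 10 s baseline, then step boluses (5 s each,
  default concentrations 0.25/0.5/1 µM × 3 replicates, 5 s gaps) with white
  Gaussian current noise of RMS 0.1 nA — the in vitro noise scale.
* **Evoked sessions.** Δ[DA](t) rises linearly over the stimulus train
  (default onset 5 s, duration 0.4 s ≈ 24 pulses at 60 Hz) and decays as a
  single exponential (`decay_tau`, default 150 ms), giving a closed-form
  max-to-half-max time of τ·ln 2. Current noise defaults to 0.04 nA — the
  chronic noise scale. Real in vivo transients are diffusion-distorted and
  not single-exponential; the minimal model is chosen for its analytic
  half-decay.
* **Fault sessions.** Perforated insulation (noise RMS 2.5 nA), fiber break
  (background 50 nA), and saturation (background clipped at ±2000 nA).
* **Histology images.** Rotationally symmetric about the track origin:
  intensity 0 inside the displacement hole, background ×
  (1 + (peak − 1)·exp(−(r − hole)²/2σ²)) outside (halo σ default 30 µm),
  plus optional Gaussian count noise. Real sections have anatomical
  structure, anisotropy, and registration error that the generator does not
  model — the arc parameter exists precisely because real profiling must
  avoid such structure.

All generators are deterministic given their seed. Because the generators
share the template/background constructors with nothing in the analysis
path (the analysis never assumes Gaussian peaks or square backgrounds),
recovery tests are meaningful: they exercise background subtraction, PCR,
and the estimators, not a shared shortcut.

## PCR calibration

Standards are mean-centered and decomposed by PCA (scikit-learn, full SVD).
The retained dimension k is the smallest with cumulative explained variance
≥ `variance_threshold` (default 0.995), floored at one component per
calibrated species present (dopamine, pH, drift) so every interferent
subspace is spanned. Labels (Δ[DA] nM, ΔpH) are regressed on scores by
least squares; drift standards carry zero targets, which is what nulls the
drift direction. Predicting adds back the label mean, so projecting the
calibration's own mean CV returns the mean label and noiseless standards
are recovered exactly.

Default standards: dopamine at 250/500/1000 nM, pH at −0.2…−0.05 (the
acidic side of the bath titration — the template is sign-symmetric and the
regression linear, so excursions of either sign are rejected, while a
single-signed standard set forms one compact pH cluster in score space),
and drift shapes at ±1, ±2 nA; three replicates each. Standards are global,
not per-probe. No residual (Q-statistic) filtering is applied.

Concentration noise is the RMS of the mean-removed projected trace over the
background window, and LOD = 3 × that noise. With the default synthetic
conditions the projected concentration noise (~0.15 nM) is far below the
~1.9 nM of chronic recordings: projection through 214-sample loadings
averages the white current noise, and real recordings carry structured
residuals the generator does not model. Comparisons against LOD in tests
therefore use each trace's own computed LOD.

Cluster separation in score space is centroid distance divided by
√(s_A² + s_B²), where s_g is the RMS distance of group members from their
own centroid; > 2 is reported as separated.

## Sensor metrics

* Sensitivity: `scipy.stats.linregress` of oxidation current vs
  concentration. Flow-cell oxidation currents are measured against *local*
  pre-bolus baselines (10 scans ending 2 scans before onset) so slow drift
  stays out of the calibration line; with a session-start baseline instead,
  drift accumulated over the ~100 s run biases the slope by several
  percent. Normalized sensitivity uses the maximum |current| of the raw
  background CV as the area proxy.
* Functionality rules run in the fixed order saturation → low background →
  high noise, and the first violation is reported; the order is a
  determinism choice, significant only for multiply-faulted sessions.
* Decay time: first crossing of half-peak after the peak, linearly
  interpolated between the bracketing 100 ms samples. For a sampled
  exponential this recovers τ·ln 2 to within ~1–5 ms for τ in the
  physiological 150–350 ms range; the error is largest (~6–10 ms) when the
  half-crossing falls mid-gap (τ near 100 or 200 ms), since linear
  interpolation of a convex decay overestimates the crossing time.
  Log-space interpolation would be exact for exponentials but is not used:
  real transients are not exponential, and the linear estimator is
  shape-agnostic.
* Geometry: area πd²/4, second moment πd⁴/64, rigidity K = E·I, axial
  stiffness E·A/L, with SI conversions internal. Young's moduli are user
  inputs; the documented defaults (fused silica 72 GPa, carbon fiber
  234 GPa, Pt/Ir 168 GPa) reproduce the standard rigidity bounds for a
  90 µm silica shaft (2.3 × 10⁻⁷ N·m²) and a 7 µm carbon fiber
  (< 8 × 10⁻¹¹ N·m²).

## Histology profiling

Rays at 0.5° steps within the arc, bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1) at 2 µm bin centers (1, 3, …,
499 µm), background from the 600–620 µm annulus on the same rays; the
normalized profile is scale-invariant by construction. Ray sampling was
chosen over pixel-annulus binning to follow the radial-line protocol; a
brute-force annulus average serves as an independent cross-check in the
tests (agreement within 2% on toy images). The hole interior is included in
the profile; `exclude_hole` only restricts the peak search. Displacement
radius is the first bin with normalized intensity ≥ 0.9 (background within
10% — the threshold is a package choice); a profile already at background
in its innermost bin reports 0. Per-section normalization precedes any
averaging across sections.

## Longitudinal statistics

Trend = OLS slope of metric vs day with Pearson R and the two-sided t-test
(n − 2 df) of R against zero; the slope equals cov(x,y)/var(x) identically.
Z-scores use the sample SD (ddof = 1). Month bins are 30-day months with
">3 months" = day > 90; per-bin 95% CI half-width is exactly 1.96 × SEM,
undefined for single-record bins. Group comparisons are the classical
unpaired two-tailed t-test and one-way ANOVA; no multiple-testing
correction is applied, and reports say so.

## Problem sizes and determinism

Recovery statistics use 100 evoked simulations (peaks 56–700 nM), 20
sessions for the CV-fidelity floor, 50 random halo configurations on
640 × 640 µm corner-origin images, and 1000 null simulations for type-I
calibration — sizes at which the binomial/KS margins in the tests are
comfortable. Every stochastic test fixes its seed; generator determinism
(same seed ⇒ bit-identical output) is itself under test.

## Known limitations

* No electrochemical physics: adsorption, kinetics, and electrode aging are
  outside the generator; synthetic SNR is realistic but synthetic residual
  structure is not.
* The PCR model assumes linear mixing of template shapes; saturating
  responses at high concentration are not modeled.
* Histology assumes a single channel, an upstream-registered origin, and
  manual arc selection; no automated track detection.
* Trend statistics treat sessions as independent observations; no
  mixed-effects modeling across animals.
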