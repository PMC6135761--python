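# fscvkit

Analysis pipeline for chronic dopamine monitoring with fast-scan cyclic
voltammetry (FSCV) microsensors: voltammogram processing, chemometric
dopamine extraction, sensor-performance metrics, evoked-transient kinetics,
longitudinal stability statistics, and radial histological quantification
of the tissue response around implant tracks.

## Who this is for

Labs running chronic FSCV experiments — carbon-fiber microelectrodes or
cellular-scale micro-invasive probes implanted in striatum, with
stimulation-evoked dopamine release recorded over weeks to months — and
needing a tested, scriptable path from raw current matrices to
concentration traces, sensor health reports, and tissue-response profiles.
Every input the pipeline consumes can also be generated synthetically with
known ground truth, so the whole chain is testable without animal data.

## The science in brief

**Acquisition model.** FSCV applies a triangular potential sweep (default
−0.4 → +1.3 V at 400 V/s, repeated at 10 Hz, 214 samples per scan) to a
carbon-fiber electrode. Each scan yields a cyclic voltammogram (CV) of
current vs potential; dopamine oxidizes near +0.6 V on the anodic sweep and
its quinone reduces near −0.2 V on the cathodic sweep. The large capacitive
background is removed by subtracting the mean CV of a signal-free window,
giving the background-subtracted "color plot" Δi(scan, sample).

**Chemometrics.** Calibration standards (dopamine at known nM, pH
excursions, background-drift shapes) are mean-centered and decomposed by
PCA. Known labels are regressed on the retained principal-component scores
(principal-component regression, PCR); projecting an in vivo CV through the
same loadings yields Δ[DA] per scan while pH and drift, captured by their
own components, are rejected:

    scores = (x − x̄) Vᵀ,   (Δ[DA], ΔpH) = ȳ + scores·B

**Sensor metrics.** Sensitivity is the OLS slope of oxidation current vs
concentration (nA/µM); normalized sensitivity divides the per-nM slope by
the background current (a proxy for exposed fiber area). Noise is the RMS
of the mean-removed signal over a signal-free window; the limit of
detection is LOD = 3 × concentration noise (SNR ≥ 3 criterion). A sensor is
nonfunctional on saturation (|i| ≥ 2000 nA), low background (< 100 nA,
fiber break), or high noise (> 1 nA, perforated insulation) — checked in
that order. Evoked transients are summarized by peak Δ[DA] and the
max-to-half-max decay time (linear interpolation between 100 ms samples).

**Histology.** Fluorescence intensity (GFAP, Iba1, IgG, DAPI) is profiled
along rays at 0.5° steps within a chosen 90° arc, averaged in 2 µm bins to
500 µm from the implant-track origin, and normalized by a 600–620 µm
background annulus. Summary statistics: peak relative intensity and — for
DAPI channels with a central void — the displacement radius where intensity
returns to background.

**Longitudinal statistics.** Per-probe trends (OLS slope vs days
postimplant, Pearson R with its t-test), Z-scores, monthly bins with
95% CI = 1.96 × SEM, and unpaired t-tests / one-way ANOVA across probes and
animals.

## Worked example

Calibrate on standards, simulate a stimulation-evoked session (true peak
250 nM, decay constant 171.7 ms), and extract everything:

```python
import numpy as np
from fscvkit import *

wf = build_waveform()                       # -0.4 -> 1.3 V, 400 V/s, 10 Hz
spec = TemplateSpec()                       # redox peaks at +0.6 / -0.2 V

cvs, labels = make_calibration_standards(spec, wf, current_noise_rms=0.1, seed=0)
results = PCRCalibration(CalibrationSet(cvs, labels, wf)).fit()
print(results.summary())

session, truth = simulate_evoked_session(
    EvokedConfig(true_peak_conc=250.0, decay_tau=0.1717, seed=1), spec, wf)
plot = subtract_background(session, default_background_window(session))
trace = results.project(plot)
tm = transient_metrics(trace)
status = classify_sensor(session)
```

Output:

```
PCR calibration summary
===============================================
standards:            33 (9 DA, 12 pH, 12 drift)
CV length:            214 samples
components retained:  3
variance explained:   0.7600, 0.2311, 0.0088
DA coefficients (nM per unit score): +1.925, +4.033, -2.905
DA residual RMS:      0.516 nM

functional: True (noise 0.047 nA, background 900 nA)
concentration noise: 0.14 nM  ->  LOD 0.42 nM
evoked peak: 249.9 nM at t = 5.4 s
decay to half maximum: 124.0 ms
CV vs dopamine standard: Pearson R = 1.000
```

Reading this: the calibration kept three components (dopamine, pH, drift
subspaces), the sensor passes all three functionality rules, the 250 nM
ground-truth peak is recovered to 0.04%, and the measured half-decay
(124 ms) matches the analytic τ·ln 2 = 119 ms of the generator within the
interpolation error of 100 ms sampling. The extracted CV at the evoked peak
is indistinguishable from an in vitro dopamine standard (R = 1.000).

The same stages are scriptable from a shell:

```bash
fscvkit simulate-fscv --preset evoked --seed 7 --out runs/
fscvkit calibrate --seed 1 --out runs/
fscvkit extract --session runs/session_evoked_seed7.csv \
                --model runs/pcr_model.json --out runs/
fscvkit simulate-histology --hole-um 34 --peak 6.73 --out runs/
fscvkit profile --image runs/histology_seed0.tiff --out runs/
```

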