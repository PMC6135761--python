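"""Sensor characterization: sensitivity, noise, LOD, functionality,
evoked-transient kinetics, and implant geometry/mechanics.

Conventions
-----------
* Sensitivity is the OLS slope of oxidation-peak current vs dopamine
  concentration (nA/µM); normalized sensitivity divides the per-nM slope by
  the background (capacitive) current, which scales with the exposed
  carbon-fiber area, giving an area-corrected figure in nA·nM^-1·nA^-1.
* Noise is the RMS of the mean-removed signal over a signal-free window,
  applied identically to current traces (nA) and PCA-extracted
  concentration traces (nM).  LOD = 3 x concentration noise (SNR >= 3).
* A sensor is nonfunctional if any sample saturates the ±2000 nA
  transducer, if the background current magnitude stays below 100 nA
  (mechanical break of the fiber), or if current noise exceeds 1 nA
  (perforated insulation).  Rules are applied in that fixed order and the
  first violation is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .chemometrics import ConcentrationTrace
from .session import TRANSDUCER_RANGE_NA, ScanSession, current_at_potential

__all__ = [
    "SensitivityFit",
    "NoiseReport",
    "SensorStatus",
    "TransientMetrics",
    "fit_sensitivity",
    "bolus_peak_currents",
    "noise_rms",
    "compute_lod",
    "classify_sensor",
    "transient_metrics",
    "cross_section_area",
    "second_moment",
    "flexural_rigidity",
    "axial_stiffness",
    "NoTransientError",
    "SILICA_E_GPA",
    "CARBON_FIBER_E_GPA",
    "PT_IR_E_GPA",
    "NOISE_LIMIT_NA",
    "MIN_BACKGROUND_NA",
]

# Functionality thresholds (acquisition-system conventions)
NOISE_LIMIT_NA = 1.0
MIN_BACKGROUND_NA = 100.0

# Young's moduli are user inputs; these defaults reproduce the published
# rigidity bounds for a 90 µm fused-silica CFE shaft and a 7 µm carbon fiber.
SILICA_E_GPA = 72.0
CARBON_FIBER_E_GPA = 234.0
PT_IR_E_GPA = 168.0


class NoTransientError(ValueError):
    """Raised when no evoked transient rises above the noise."""


@dataclass
class SensitivityFit:
    """OLS calibration line of oxidation current vs concentration."""

    slope: float  # nA per µM
    intercept: float  # nA
    pearson_r: float  # NaN when undefined (zero variance in currents)
    normalized_slope: Optional[float] = None  # nA nM^-1 nA^-1
    background_current: Optional[float] = None  # nA

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.pearson_r)


@dataclass
class NoiseReport:
    """Current noise, concentration noise, and the implied LOD."""

    current_noise_rms: float  # nA
    concentration_noise_rms: float  # nM
    lod: float  # nM

    def __post_init__(self) -> None:
        if min(self.current_noise_rms, self.concentration_noise_rms) < 0:
            raise ValueError("noise values must be nonnegative")
        if not math.isclose(self.lod, 3.0 * self.concentration_noise_rms,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("LOD must equal 3x concentration noise")


@dataclass
class SensorStatus:
    """Functionality verdict with the first violated rule and diagnostics."""

    functional: bool
    reason: str  # "none" | "saturation" | "low_background" | "high_noise"
    noise_rms_nA: float
    max_background_nA: float
    min_current_nA: float
    max_current_nA: float

    def __post_init__(self) -> None:
        if self.functional != (self.reason == "none"):
            raise ValueError("functional flag must match reason == 'none'")


@dataclass
class TransientMetrics:
    """Evoked-transient summary: peak amplitude and decay kinetics."""

    peak_dDA_nM: float
    time_of_peak_s: float
    decay_half_time_ms: Optional[float]  # None when the trace never halves

    @property
    def decay_defined(self) -> bool:
        return self.decay_half_time_ms is not None


def bolus_peak_currents(
    session: ScanSession,
    boluses: list[dict],
    potential: float = 0.6,
    pre_scans: int = 10,
    pre_gap: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Oxidation currents per flow-cell bolus against local pre-bolus baselines.

    For each bolus window (``{"conc_uM", "start_scan", "stop_scan"}``), the
    background is the per-column mean of ``pre_scans`` scans ending
    ``pre_gap`` scans before the bolus onset, the background-subtracted CV is
    averaged over the bolus window, and the current at ``potential`` on the
    anodic sweep is read off.  Using local baselines (standard flow-cell
    practice) keeps slow background drift out of the calibration line.

    Returns ``(concs_uM, currents_nA)`` ready for :func:`fit_sensitivity`.
    """
    concs, currents = [], []
    for b in boluses:
        lo = b["start_scan"] - pre_gap - pre_scans
        hi = b["start_scan"] - pre_gap
        if lo < 0:
            raise ValueError(
                f"bolus at scan {b['start_scan']} has no room for a "
                f"{pre_scans}-scan pre-bolus baseline"
            )
        baseline = session.currents[lo:hi].mean(axis=0)
        mean_cv = session.currents[b["start_scan"]:b["stop_scan"]].mean(axis=0) - baseline
        concs.append(b["conc_uM"])
        currents.append(
            current_at_potential(mean_cv, session.waveform, potential, "anodic")
        )
    return np.asarray(concs), np.asarray(currents)


def fit_sensitivity(
    concs_uM: np.ndarray,
    peak_currents_nA: np.ndarray,
    background_current_nA: Optional[float] = None,
) -> SensitivityFit:
    """Fit the calibration line of oxidation-peak current vs concentration.

    With a background current supplied, the normalized sensitivity
    ``(slope/1000) / background`` (nA·nM^-1·nA^-1) is also reported.
    """
    concs = np.asarray(concs_uM, dtype=float)
    currents = np.asarray(peak_currents_nA, dtype=float)
    if concs.shape != currents.shape or concs.ndim != 1:
        raise ValueError("concentrations and currents must be equal-length 1-D")
    if len(np.unique(concs)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if np.ptp(currents) == 0:
        # Degenerate: flat response. Slope 0, correlation undefined.
        fit = SensitivityFit(slope=0.0, intercept=float(currents[0]),
                             pearson_r=float("nan"))
    else:
        res = stats.linregress(concs, currents)
        fit = SensitivityFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            pearson_r=float(res.rvalue),
        )
    if background_current_nA is not None:
        if background_current_nA == 0:
            raise ValueError("background current must be nonzero to normalize")
        fit.background_current = float(background_current_nA)
        fit.normalized_slope = (fit.slope / 1000.0) / background_current_nA
    return fit


def noise_rms(signal: np.ndarray, window: Optional[tuple[int, int]] = None) -> float:
    """RMS of the mean-removed signal over ``window`` (>= 10 samples)."""
    signal = np.asarray(signal, dtype=float).ravel()
    if window is not None:
        lo, hi = window
        signal = signal[lo:hi]
    if signal.size < 10:
        raise ValueError("noise window must contain >= 10 samples")
    return float(np.sqrt(np.mean((signal - signal.mean()) ** 2)))


def compute_lod(concentration_noise_rms_nM: float) -> float:
    """Limit of detection: 3 x concentration noise (the SNR >= 3 criterion)."""
    if concentration_noise_rms_nM < 0:
        raise ValueError("noise must be nonnegative")
    return 3.0 * concentration_noise_rms_nM


def classify_sensor(
    session: ScanSession,
    background_window: Optional[tuple[int, int]] = None,
) -> SensorStatus:
    """Apply the functionality rules: saturation -> low background -> noise.

    The background CV is the per-column mean over ``background_window``
    (default: the first 20 scans, a signal-free baseline by construction of
    both flow-cell and evoked protocols).  Noise is the RMS of the residual
    current within that window after background removal.
    """
    if session.n_scans == 0:
        raise ValueError("empty session")
    if background_window is None:
        background_window = (0, min(20, session.n_scans))
    lo, hi = background_window
    rows = session.currents[lo:hi]
    if rows.shape[0] < 1:
        raise ValueError("background window empty")
    bg_cv = rows.mean(axis=0)
    residual = rows - bg_cv
    noise = float(np.sqrt(np.mean(residual**2))) if rows.shape[0] > 1 else 0.0
    max_bg = float(np.max(np.abs(bg_cv)))
    mn = float(session.currents.min())
    mx = float(session.currents.max())

    if max(abs(mn), abs(mx)) >= TRANSDUCER_RANGE_NA:
        reason = "saturation"
    elif max_bg < MIN_BACKGROUND_NA:
        reason = "low_background"
    elif noise > NOISE_LIMIT_NA:
        reason = "high_noise"
    else:
        reason = "none"
    return SensorStatus(
        functional=(reason == "none"),
        reason=reason,
        noise_rms_nA=noise,
        max_background_nA=max_bg,
        min_current_nA=mn,
        max_current_nA=mx,
    )


def transient_metrics(
    trace: ConcentrationTrace,
    analysis_window: Optional[tuple[int, int]] = None,
) -> TransientMetrics:
    """Peak Delta[DA] and max-to-half-max decay time of an evoked transient.

    The decay time is found by locating the first crossing of half the peak
    after the peak and linearly interpolating between the bracketing scans
    (10 Hz sampling implies 100 ms spacing; interpolation recovers
    sub-sample decay times, e.g. tau*ln2 for an exponential).  A peak below
    3x the concentration noise raises :class:`NoTransientError`; a trace
    that never falls to half within the window gets ``decay_half_time_ms``
    = None.
    """
    dda = trace.dda_nM
    times = trace.scan_times
    if analysis_window is None:
        analysis_window = (0, len(dda))
    lo, hi = analysis_window
    if not (0 <= lo < hi <= len(dda)):
        raise ValueError(f"analysis window {analysis_window} outside trace")
    seg = dda[lo:hi]
    peak_rel = int(np.argmax(seg))
    peak_idx = lo + peak_rel
    peak = float(dda[peak_idx])
    if peak <= 3.0 * trace.noise_rms_nM:
        raise NoTransientError(
            f"peak {peak:.3g} nM does not exceed 3x noise "
            f"({3 * trace.noise_rms_nM:.3g} nM)"
        )
    half = peak / 2.0
    decay_ms: Optional[float] = None
    for j in range(peak_idx + 1, hi):
        if dda[j] <= half:
            prev, cur = dda[j - 1], dda[j]
            frac = (prev - half) / (prev - cur) if prev != cur else 0.0
            t_half = times[j - 1] + frac * (times[j] - times[j - 1])
            decay_ms = (t_half - times[peak_idx]) * 1e3
            break
    return TransientMetrics(
        peak_dDA_nM=peak,
        time_of_peak_s=float(times[peak_idx]),
        decay_half_time_ms=decay_ms,
    )


def cross_section_area(diameter_um: float) -> float:
    """Circular cross-sectional area pi*d^2/4 in µm^2."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter_um**2 / 4.0


def second_moment(diameter_um: float) -> float:
    """Area moment of inertia I = pi*d^4/64 of a circular section, in m^4."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_m = diameter_um * 1e-6
    return math.pi * d_m**4 / 64.0


def flexural_rigidity(diameter_um: float, youngs_modulus_gpa: float) -> float:
    """Bending stiffness K = E*I in N·m^2 for a circular fiber/shaft."""
    if youngs_modulus_gpa <= 0:
        raise ValueError("Young's modulus must be positive")
    return youngs_modulus_gpa * 1e9 * second_moment(diameter_um)


def axial_stiffness(
    diameter_um: float, youngs_modulus_gpa: float, length_mm: float
) -> float:
    """Axial stiffness k = E*A/L in N/m."""
    if youngs_modulus_gpa <= 0 or length_mm <= 0:
        raise ValueError("modulus and length must be positive")
    area_m2 = cross_section_area(diameter_um) * 1e-12
    return youngs_modulus_gpa * 1e9 * area_m2 / (length_mm * 1e-3)
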