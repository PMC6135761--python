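"""Scan sessions, background subtraction, color plots, and CV extraction.

A recording session is a matrix of measured current: one row per triangular
scan, one column per in-scan sample.  The dominant component of every row is
the capacitive charging current (hundreds of nA); faradaic signals such as
dopamine oxidation are isolated by subtracting the per-column mean of a
signal-free background window, yielding the background-subtracted "color
plot" from which single cyclic voltammograms (CVs) are extracted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .waveform import Waveform

__all__ = [
    "ScanSession",
    "ColorPlot",
    "subtract_background",
    "extract_cv",
    "current_at_potential",
    "TRANSDUCER_RANGE_NA",
]

logger = logging.getLogger(__name__)

# Dynamic range of the acquisition transducer; samples at the rail indicate
# saturation and are handled by sensor classification, not rejected here.
TRANSDUCER_RANGE_NA = 2000.0


@dataclass
class ScanSession:
    """A voltammetric recording: currents (scans x in-scan samples) + timing.

    ``metadata`` carries probe_id, day postimplant and, when present, the
    stimulation window as a ``(start_scan, stop_scan)`` tuple under the key
    ``"stim_window"``.
    """

    currents: np.ndarray
    waveform: Waveform
    scan_times: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be a 2-D scans x samples matrix")
        if self.currents.shape[1] != self.waveform.samples_per_scan:
            raise ValueError(
                f"row length {self.currents.shape[1]} != samples_per_scan "
                f"{self.waveform.samples_per_scan}"
            )
        if self.scan_times.shape != (self.currents.shape[0],):
            raise ValueError("scan_times must have one entry per scan")
        if self.n_scans > 1:
            dt = np.diff(self.scan_times)
            if np.any(dt <= 0):
                raise ValueError("scan_times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return self.currents.shape[0]

    @property
    def stim_window(self) -> Optional[tuple[int, int]]:
        return self.metadata.get("stim_window")

    def saturated(self) -> bool:
        """True if any sample sits at the transducer rail (|i| >= 2000 nA)."""
        return bool(np.any(np.abs(self.currents) >= TRANSDUCER_RANGE_NA))


@dataclass
class ColorPlot:
    """Background-subtracted current-change matrix (scans x samples)."""

    bg_subtracted: np.ndarray
    background_window: tuple[int, int]
    waveform: Waveform
    scan_times: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.bg_subtracted.shape[0]

    def background_scans(self) -> np.ndarray:
        lo, hi = self.background_window
        return self.bg_subtracted[lo:hi]


def default_background_window(session: ScanSession, n_scans: int = 10) -> tuple[int, int]:
    """Default background window: ``n_scans`` scans ending 1 s before the
    stimulation window (pre-stimulus baseline); without a recorded stimulation
    window, the first ``max(n_scans, 20)`` scans."""
    stim = session.stim_window
    if stim is None:
        return (0, min(max(n_scans, 20), session.n_scans))
    hi = stim[0] - int(round(session.waveform.rep_freq))
    lo = hi - n_scans
    if lo < 0:
        raise ValueError(
            "session too short for a pre-stimulus background window"
        )
    return (lo, hi)


def subtract_background(
    session: ScanSession, background_window: tuple[int, int]
) -> ColorPlot:
    """Subtract the per-column mean of the background window from every scan.

    ``background_window`` is a half-open ``(start, stop)`` scan-index range.
    Subtracting a plot against its own window a second time is a no-op, and
    the column means of the window rows are zero afterwards by construction.
    A window overlapping a known stimulation window is suspicious (the
    "background" would contain evoked signal) and is logged as a warning.
    """
    lo, hi = background_window
    if not (0 <= lo < hi <= session.n_scans):
        raise ValueError(
            f"background window {background_window} empty or outside session "
            f"of {session.n_scans} scans"
        )
    stim = session.stim_window
    if stim is not None and lo < stim[1] and stim[0] < hi:
        logger.warning(
            "background window %s overlaps stimulation window %s", background_window, stim
        )
    baseline = session.currents[lo:hi].mean(axis=0)
    return ColorPlot(
        bg_subtracted=session.currents - baseline,
        background_window=(lo, hi),
        waveform=session.waveform,
        scan_times=session.scan_times.copy(),
        metadata=dict(session.metadata),
    )


def extract_cv(plot: ColorPlot, scan_index: int) -> np.ndarray:
    """Return the background-subtracted CV (one row) at ``scan_index``."""
    if not (-plot.n_scans <= scan_index < plot.n_scans):
        raise IndexError(
            f"scan index {scan_index} out of range for {plot.n_scans} scans"
        )
    return plot.bg_subtracted[scan_index].copy()


def current_at_potential(
    cv: np.ndarray, waveform: Waveform, potential: float, sweep: str
) -> float:
    """Current (nA) at the grid sample nearest ``potential`` on one sweep half.

    ``sweep`` is ``"anodic"`` or ``"cathodic"``; the potential is interpreted
    on the offset-corrected axis (dopamine oxidizes near +0.6 V anodic and
    reduces near -0.2 V cathodic under the standard waveform).  Nearest-sample
    lookup is used: the ~16 mV grid step is small against redox peak widths.
    """
    cv = np.asarray(cv, dtype=float)
    if cv.shape != (waveform.samples_per_scan,):
        raise ValueError(
            f"CV length {cv.shape} does not match samples_per_scan "
            f"{waveform.samples_per_scan}"
        )
    idx = waveform.index_at_potential(potential, sweep)
    return float(cv[idx])
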