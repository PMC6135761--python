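"""Triangular FSCV waveform construction.

Fast-scan cyclic voltammetry applies a rapid triangular potential sweep
(typically -0.4 V -> +1.3 V -> -0.4 V at 400 V/s) to a carbon-fiber
electrode, repeated at ~10 Hz.  Between scans the electrode is held at the
holding potential; only the in-scan samples are digitized, so a session row
contains exactly ``samples_per_scan`` values.

An in vivo potential offset (0.1-0.3 V) compensates for the drifted
potential of a chronically implanted Ag/AgCl reference.  The offset shifts
the *applied* grid; all chemistry-facing potential queries (e.g. "current at
the 0.6 V dopamine oxidation potential") are interpreted on the
offset-corrected axis, which is what :attr:`Waveform.potentials` exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform", "build_waveform", "InvalidWaveformError"]


class InvalidWaveformError(ValueError):
    """Raised when waveform parameters cannot produce a valid scan."""


@dataclass(frozen=True)
class Waveform:
    """The applied triangular potential program and its per-scan sample grid.

    Parameters
    ----------
    v_hold : float
        Holding (start) potential in V.  Default -0.4 V.
    v_peak : float
        Apex (switching) potential in V.  Default 1.3 V.
    scan_rate : float
        Sweep rate in V/s.  Default 400 V/s.
    rep_freq : float
        Scan repetition frequency in Hz.  Default 10 Hz.
    samples_per_scan : int
        Number of digitized samples per scan (even, >= 4).  Default 214.
    potential_offset : float
        Applied in vivo offset in V, stored but removed from the
        chemistry-facing potential axis.
    """

    v_hold: float = -0.4
    v_peak: float = 1.3
    scan_rate: float = 400.0
    rep_freq: float = 10.0
    samples_per_scan: int = 214
    potential_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_peak > self.v_hold:
            raise InvalidWaveformError("v_peak must exceed v_hold")
        if self.scan_rate <= 0:
            raise InvalidWaveformError("scan_rate must be positive")
        if self.rep_freq <= 0:
            raise InvalidWaveformError("rep_freq must be positive")
        n = self.samples_per_scan
        if n < 4 or n % 2 != 0:
            raise InvalidWaveformError("samples_per_scan must be even and >= 4")
        if self.scan_duration >= 1.0 / self.rep_freq:
            raise InvalidWaveformError(
                f"scan duration {self.scan_duration * 1e3:.2f} ms does not fit "
                f"in the {1e3 / self.rep_freq:.2f} ms scan period"
            )

    @property
    def scan_duration(self) -> float:
        """Duration of one up-down sweep in seconds: 2*(v_peak - v_hold)/rate."""
        return 2.0 * (self.v_peak - self.v_hold) / self.scan_rate

    @property
    def grid_step(self) -> float:
        """Potential increment between adjacent samples (V)."""
        return 2.0 * (self.v_peak - self.v_hold) / self.samples_per_scan

    @property
    def apex_index(self) -> int:
        return self.samples_per_scan // 2

    @property
    def potentials(self) -> np.ndarray:
        """Offset-corrected triangular potential grid, length samples_per_scan.

        Sample 0 is at ``v_hold``; the apex ``v_peak`` falls exactly on
        sample ``samples_per_scan // 2``; the final sample sits one grid step
        above ``v_hold`` (the triangle closes at the start of the next scan).
        """
        n = self.samples_per_scan
        i = np.arange(n)
        dv = self.grid_step
        up = self.v_hold + dv * i
        down = self.v_peak - dv * (i - self.apex_index)
        return np.where(i <= self.apex_index, up, down)

    @property
    def applied_potentials(self) -> np.ndarray:
        """Potential grid actually applied at the electrode (offset included)."""
        return self.potentials + self.potential_offset

    def anodic_indices(self) -> np.ndarray:
        """Sample indices of the anodic (rising) half, including the apex."""
        return np.arange(0, self.apex_index + 1)

    def cathodic_indices(self) -> np.ndarray:
        """Sample indices of the cathodic (falling) half, including the apex."""
        return np.arange(self.apex_index, self.samples_per_scan)

    def sample_times(self) -> np.ndarray:
        """In-scan sample times (s), uniform over the scan duration."""
        return np.arange(self.samples_per_scan) * (
            self.scan_duration / self.samples_per_scan
        )

    def index_at_potential(self, potential: float, sweep: str) -> int:
        """Nearest grid sample to ``potential`` on the requested sweep half.

        ``sweep`` is ``"anodic"`` or ``"cathodic"``.  Potentials are on the
        offset-corrected axis.  Raises ``ValueError`` outside the swept range.
        """
        if sweep == "anodic":
            idx = self.anodic_indices()
        elif sweep == "cathodic":
            idx = self.cathodic_indices()
        else:
            raise ValueError(f"sweep must be 'anodic' or 'cathodic', got {sweep!r}")
        half_step = 0.5 * self.grid_step
        if not (self.v_hold - half_step <= potential <= self.v_peak + half_step):
            raise ValueError(
                f"potential {potential} V outside swept range "
                f"[{self.v_hold}, {self.v_peak}] V"
            )
        grid = self.potentials[idx]
        return int(idx[np.argmin(np.abs(grid - potential))])


def build_waveform(
    v_hold: float = -0.4,
    v_peak: float = 1.3,
    scan_rate: float = 400.0,
    rep_freq: float = 10.0,
    samples_per_scan: int = 214,
    potential_offset: float = 0.0,
) -> Waveform:
    """Construct and validate a triangular FSCV waveform."""
    return Waveform(
        v_hold=v_hold,
        v_peak=v_peak,
        scan_rate=scan_rate,
        rep_freq=rep_freq,
        samples_per_scan=samples_per_scan,
        potential_offset=potential_offset,
    )
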