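"""Readers and writers for the pipeline's on-disk formats.

Formats (all UTF-8, ``.`` decimal):

* **Session CSV** — ``#`` header lines carrying ``key=value`` acquisition
  metadata (waveform parameters, probe_id, day, optional stim_window), then
  one row per scan: ``scan_time_s`` followed by ``samples_per_scan`` current
  values in nA, written at full (repr) precision.
* **Calibration CSV** — one row per standard: ``label_type`` (DA|pH),
  ``label_value``, then the CV samples.
* **Trace CSV** — ``scan_time_s,dDA_nM`` plus ``#`` metadata lines.
* **Metrics JSON** — the per-session sensor report.
* **TIFF** — single-channel grayscale, written as 16-bit counts.
* **Config** — YAML mapping of nested parameter blocks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import tifffile
import yaml

from .chemometrics import CalibrationSet, ConcentrationTrace, PCRResults
from .histology import HistologyImage, RadialProfile
from .session import ScanSession
from .waveform import Waveform

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_metrics_json",
    "write_histology_tiff",
    "read_histology_tiff",
    "write_profile_csv",
    "write_pcr_model_json",
    "read_pcr_model_json",
    "load_config",
]

PathLike = Union[str, Path]

_WAVEFORM_KEYS = ("v_hold", "v_peak", "scan_rate", "rep_freq",
                  "samples_per_scan", "potential_offset")


def write_session_csv(path: PathLike, session: ScanSession) -> None:
    """Write a session in the ``#``-header CSV dialect at full precision."""
    wf = session.waveform
    lines = []
    for key in _WAVEFORM_KEYS:
        lines.append(f"# {key}={getattr(wf, key)!r}")
    for key in ("probe_id", "day"):
        if key in session.metadata:
            lines.append(f"# {key}={session.metadata[key]}")
    stim = session.metadata.get("stim_window")
    if stim is not None:
        lines.append(f"# stim_window={stim[0]},{stim[1]}")
    for t, row in zip(session.scan_times, session.currents):
        lines.append(",".join([repr(float(t))] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session_csv(path: PathLike) -> ScanSession:
    """Read a session CSV; raises ``ValueError`` naming the offending line."""
    meta: dict[str, Any] = {}
    times: list[float] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed metadata line {raw!r}")
            key, value = body.split("=", 1)
            meta[key.strip()] = value.strip()
            continue
        try:
            values = [float(v) for v in line.split(",")]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
        times.append(values[0])
        rows.append(values[1:])
    missing = [k for k in _WAVEFORM_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing waveform metadata keys {missing}")
    wf = Waveform(
        v_hold=float(meta["v_hold"]),
        v_peak=float(meta["v_peak"]),
        scan_rate=float(meta["scan_rate"]),
        rep_freq=float(meta["rep_freq"]),
        samples_per_scan=int(float(meta["samples_per_scan"])),
        potential_offset=float(meta["potential_offset"]),
    )
    metadata: dict[str, Any] = {}
    if "probe_id" in meta:
        metadata["probe_id"] = meta["probe_id"]
    if "day" in meta:
        metadata["day"] = int(float(meta["day"]))
    if "stim_window" in meta:
        lo, hi = meta["stim_window"].split(",")
        metadata["stim_window"] = (int(lo), int(hi))
    return ScanSession(
        currents=np.array(rows, dtype=float),
        waveform=wf,
        scan_times=np.array(times, dtype=float),
        metadata=metadata,
    )


def write_calibration_csv(
    path: PathLike, cvs: list[np.ndarray], labels: list[tuple[str, float]]
) -> None:
    lines = []
    for cv, (label_type, label_value) in zip(cvs, labels):
        fields = [label_type, repr(float(label_value))]
        fields += [repr(float(v)) for v in np.asarray(cv)]
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_calibration_csv(
    path: PathLike, waveform: Optional[Waveform] = None
) -> CalibrationSet:
    cvs: list[np.ndarray] = []
    labels: list[tuple[str, float]] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: too few fields")
        try:
            labels.append((fields[0], float(fields[1])))
            cvs.append(np.array([float(v) for v in fields[2:]]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
    return CalibrationSet(cvs=cvs, labels=labels, waveform=waveform)


def write_trace_csv(
    path: PathLike, trace: ConcentrationTrace, extra_meta: Optional[dict] = None
) -> None:
    lines = [
        f"# noise_rms_nM={trace.noise_rms_nM!r}",
        f"# lod_nM={trace.lod_nM!r}",
        f"# background_window={trace.background_window[0]},{trace.background_window[1]}",
    ]
    for key, value in (extra_meta or {}).items():
        lines.append(f"# {key}={value}")
    lines.append("scan_time_s,dDA_nM")
    for t, v in zip(trace.scan_times, trace.dda_nM):
        lines.append(f"{float(t)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace_csv(path: PathLike) -> ConcentrationTrace:
    meta: dict[str, str] = {}
    times: list[float] = []
    dda: list[float] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, value = line[1:].strip().split("=", 1)
            meta[key.strip()] = value.strip()
            continue
        if line.startswith("scan_time_s"):
            continue
        t, v = line.split(",")
        times.append(float(t))
        dda.append(float(v))
    lo, hi = meta["background_window"].split(",")
    return ConcentrationTrace(
        dda_nM=np.array(dda),
        scan_times=np.array(times),
        noise_rms_nM=float(meta["noise_rms_nM"]),
        background_window=(int(lo), int(hi)),
    )


def write_metrics_json(path: PathLike, report: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def write_histology_tiff(path: PathLike, img: HistologyImage) -> None:
    """Write the image as 16-bit grayscale TIFF (counts clipped to uint16)."""
    data = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_size_um": img.pixel_size_um,
            "origin_x_um": img.origin_um[0],
            "origin_y_um": img.origin_um[1],
            "channel": img.channel,
        },
    )


def read_histology_tiff(
    path: PathLike,
    pixel_size_um: Optional[float] = None,
    origin_um: Optional[tuple[float, float]] = None,
    channel: str = "other",
) -> HistologyImage:
    """Read a grayscale TIFF; geometry falls back to embedded metadata."""
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray().astype(float)
        stored = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pixel_size_um is None:
        pixel_size_um = float(stored.get("pixel_size_um", 1.0))
    if origin_um is None:
        if "origin_x_um" in stored:
            origin_um = (float(stored["origin_x_um"]), float(stored["origin_y_um"]))
        else:
            raise ValueError(f"{path}: origin not given and not embedded")
    if channel == "other":
        channel = stored.get("channel", "other")
    return HistologyImage(
        pixels=pixels, pixel_size_um=pixel_size_um, origin_um=origin_um,
        channel=channel,
    )


def write_profile_csv(path: PathLike, profile: RadialProfile) -> None:
    lines = [
        f"# background_intensity={profile.background_intensity!r}",
        f"# arc_start_deg={profile.arc[0]!r}",
        f"# arc_span_deg={profile.arc[1]!r}",
        f"# n_rays={profile.n_rays}",
        "bin_center_um,normalized_intensity",
    ]
    for c, v in zip(profile.bin_centers, profile.normalized_intensity):
        lines.append(f"{float(c)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pcr_model_json(path: PathLike, results: PCRResults) -> None:
    """Persist a fitted calibration (JSON keeps the deliverable text-only
    and the model human-inspectable)."""
    payload = {
        "mean_cv": results.mean_cv.tolist(),
        "loadings": results.loadings.tolist(),
        "k": results.k,
        "coefs": results.coefs.tolist(),
        "label_mean": results.label_mean.tolist(),
        "explained_variance_ratio": results.explained_variance_ratio.tolist(),
    }
    Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")


def read_pcr_model_json(path: PathLike) -> PCRResults:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PCRResults(
        model=None,  # standalone reload: the standards are not persisted
        mean_cv=np.array(payload["mean_cv"]),
        loadings=np.array(payload["loadings"]),
        k=int(payload["k"]),
        coefs=np.array(payload["coefs"]),
        label_mean=np.array(payload["label_mean"]),
        explained_variance_ratio=np.array(payload["explained_variance_ratio"]),
        standard_scores=np.empty((0, int(payload["k"]))),
        residuals=np.empty((0, 2)),
    )


def load_config(path: PathLike) -> dict[str, Any]:
    """Load a YAML run configuration; must be a mapping at top level."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return data
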