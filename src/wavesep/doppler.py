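"""Virtual Doppler ultrasound on a cross-sectional velocity field.

Given a time series of through-plane velocities over a 2-D lumen
cross-section, this module emulates the velocity traces a Doppler
examination would produce: a square sample volume covering a fraction of
the minimum effective lumen diameter is placed at the time-averaged lumen
centroid, and three traces are extracted per frame —

* ``dop_env``  : 95th-percentile velocity inside the sample volume (the
  spectral envelope a sonographer would trace),
* ``dop_mean`` : mean velocity inside the sample volume,
* ``peak_u``   : 95th-percentile velocity over the whole lumen (an ideal
  sample volume covering the lumen exactly),

alongside ``true_mean``, the whole-lumen mean velocity that represents
volumetric flow.  Traces are post-processed the way clinical traces are:
offset to zero at beat onset and zeroed during diastole.  Because the
envelope follows near-peak velocities and the sample volume covers only
part of the lumen, a skewed velocity profile makes these traces
misrepresent the true mean — the error mechanism this simulator isolates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import BeatLandmarks, Waveform, detect_landmarks
from .errors import InvalidInputError

__all__ = [
    "VelocityField",
    "SampleVolume",
    "DopplerTraces",
    "place_sample_volume",
    "extract_traces",
    "postprocess_trace",
    "read_velocity_field",
    "write_velocity_field",
]


@dataclass(frozen=True)
class VelocityField:
    """Per-frame through-plane velocities on a 2-D pixel grid.

    ``u`` and ``mask`` have shape (n_frames, ny, nx); ``x`` and ``y`` hold
    pixel-centre coordinates in mm; velocities are cm/s (any consistent
    unit works — downstream indices depend only on waveform shape).
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pixel_area: float
    mask: np.ndarray
    u: np.ndarray
    cycle_length: float

    def __post_init__(self) -> None:
        nf = self.frames.size
        if self.u.shape != (nf, self.y.size, self.x.size):
            raise InvalidInputError(
                f"u shape {self.u.shape} does not match frames/grid "
                f"({nf}, {self.y.size}, {self.x.size})"
            )
        if self.mask.shape != self.u.shape:
            raise InvalidInputError("mask and u shapes differ")
        if not np.all(np.isfinite(self.u)):
            raise InvalidInputError("velocity field contains non-finite values")
        counts = self.mask.reshape(nf, -1).sum(axis=1)
        if np.any(counts == 0):
            raise InvalidInputError(
                f"empty lumen mask at frame {int(np.argmin(counts))}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def lumen_area(self) -> np.ndarray:
        """Per-frame lumen area (mask count times pixel area)."""
        return self.mask.reshape(self.n_frames, -1).sum(axis=1) * self.pixel_area


@dataclass(frozen=True)
class SampleVolume:
    """Square sample volume: centre (mm) and side length (mm)."""

    center: tuple[float, float]
    side: float


@dataclass(frozen=True)
class DopplerTraces:
    """The four velocity traces extracted from a field, on one time base."""

    dop_env: Waveform
    dop_mean: Waveform
    peak_u: Waveform
    true_mean: Waveform
    sample_volume: SampleVolume


def place_sample_volume(vf: VelocityField, coverage: float = 0.5) -> SampleVolume:
    """Place a square sample volume at the time-averaged lumen centroid.

    The square's side is ``coverage`` times the minimum (over time)
    effective diameter D(t) = 2*sqrt(A(t)/pi).
    """
    if not 0 < coverage <= 1:
        raise InvalidInputError("coverage must lie in (0, 1]")
    areas = vf.lumen_area()
    d_eff = 2.0 * np.sqrt(areas / np.pi)
    side = coverage * float(np.min(d_eff))
    xx, yy = np.meshgrid(vf.x, vf.y)
    cxs = np.empty(vf.n_frames)
    cys = np.empty(vf.n_frames)
    for k in range(vf.n_frames):
        m = vf.mask[k]
        cxs[k] = xx[m].mean()
        cys[k] = yy[m].mean()
    return SampleVolume((float(cxs.mean()), float(cys.mean())), side)


def extract_traces(vf: VelocityField, sv: SampleVolume) -> DopplerTraces:
    """Extract raw DopEnv/DopMean/PeakU/true-mean traces.

    Percentiles use linear interpolation between order statistics; a pixel
    belongs to the sample volume when its centre falls inside the square.
    """
    cx, cy = sv.center
    h = sv.side / 2.0
    xx, yy = np.meshgrid(vf.x, vf.y)
    in_square = (np.abs(xx - cx) <= h) & (np.abs(yy - cy) <= h)
    env = np.empty(vf.n_frames)
    mean_sv = np.empty(vf.n_frames)
    peak = np.empty(vf.n_frames)
    tmean = np.empty(vf.n_frames)
    for k in range(vf.n_frames):
        lum = vf.mask[k]
        inter = lum & in_square
        if not inter.any():
            raise InvalidInputError(
                f"sample volume does not intersect the lumen at frame {k}"
            )
        usv = vf.u[k][inter]
        ulum = vf.u[k][lum]
        env[k] = np.percentile(usv, 95)
        mean_sv[k] = usv.mean()
        peak[k] = np.percentile(ulum, 95)
        tmean[k] = ulum.mean()

    def _wf(v):
        return Waveform(vf.frames.copy(), v, "velocity", vf.cycle_length)

    return DopplerTraces(_wf(env), _wf(mean_sv), _wf(peak), _wf(tmean), sv)


def postprocess_trace(
    w: Waveform,
    lm: Optional[BeatLandmarks] = None,
) -> Waveform:
    """Offset a trace to zero at beat onset, then zero it during diastole.

    Landmarks are detected from the trace itself when not supplied.  The
    end-diastolic value at beat onset (the first sample: beats start at
    end-diastole) is subtracted, then every sample from the trace's
    post-systolic zero return (``t_zero``; end-systole when the offset
    trace never crosses zero) to beat end is set to 0.  Subtracting the
    first sample, rather than the value at the threshold-detected onset,
    makes the operation idempotent on already-clean traces.
    """
    if lm is None:
        lm = detect_landmarks(w)
    v = w.v - w.v[0]
    # zero-return of the offset trace at/after end-systole (from either
    # sign: a captured backflow lobe ends at an upward return to zero)
    t_cut = None
    i0 = min(int(np.searchsorted(w.t, lm.t_es)), w.n - 1)
    if v[i0] == 0.0:
        t_cut = float(w.t[i0])
    else:
        sign = np.sign(v[i0])
        for i in range(i0, w.n - 1):
            if v[i + 1] == 0.0 or np.sign(v[i + 1]) != sign:
                frac = v[i] / (v[i] - v[i + 1]) if v[i] != v[i + 1] else 0.0
                t_cut = float(w.t[i] + frac * (w.t[i + 1] - w.t[i]))
                break
    if t_cut is None:
        t_cut = lm.t_es  # trace never crosses zero after systole
    v = np.where(w.t >= t_cut, 0.0, v)
    return w.with_values(v)


# ---------------------------------------------------------------------------
# disk format: JSON header + whitespace-delimited dense text arrays
# ---------------------------------------------------------------------------

def write_velocity_field(vf: VelocityField, stem: str | Path) -> None:
    """Write a field as ``<stem>.json`` (header) + ``<stem>.dat`` (arrays).

    The .dat file holds, per frame, one row of velocities followed by one
    row of 0/1 mask flags, each of length ny*nx.
    """
    stem = Path(stem)
    header = {
        "frames_ms": vf.frames.tolist(),
        "x_mm": vf.x.tolist(),
        "y_mm": vf.y.tolist(),
        "pixel_area_mm2": vf.pixel_area,
        "cycle_length_ms": vf.cycle_length,
    }
    stem.with_suffix(".json").write_text(json.dumps(header))
    nf = vf.n_frames
    flat = np.empty((2 * nf, vf.u.shape[1] * vf.u.shape[2]))
    flat[0::2] = vf.u.reshape(nf, -1)
    flat[1::2] = vf.mask.reshape(nf, -1).astype(float)
    np.savetxt(stem.with_suffix(".dat"), flat)


def read_velocity_field(stem: str | Path) -> VelocityField:
    """Read a field written by :func:`write_velocity_field`."""
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    frames = np.asarray(header["frames_ms"], dtype=float)
    x = np.asarray(header["x_mm"], dtype=float)
    y = np.asarray(header["y_mm"], dtype=float)
    flat = np.loadtxt(stem.with_suffix(".dat"))
    nf = frames.size
    u = flat[0::2].reshape(nf, y.size, x.size)
    mask = flat[1::2].reshape(nf, y.size, x.size) > 0.5
    return VelocityField(
        frames, x, y, float(header["pixel_area_mm2"]), mask, u,
        float(header["cycle_length_ms"]),
    )
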