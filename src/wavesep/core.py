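"""Waveform container, resampling and beat-landmark detection.

A :class:`Waveform` is a single cardiac beat sampled on a (possibly
non-uniform) time grid in milliseconds.  Values are arbitrary units for
uncalibrated flow/velocity/area signals and mmHg for calibrated pressure.
:func:`detect_landmarks` locates the fiducial points used throughout the
package: the foot of the systolic upstroke, the 50 %-of-peak upstroke
crossing, the flow peak, end-systole (the local minimum following the
peak, i.e. the valve-closure notch) and the post-systolic return to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

from .errors import FormatError, InvalidInputError, InvalidParameterError, LandmarkError

VALID_KINDS = ("flow", "velocity", "pressure", "area")

MIN_SAMPLES = 16


@dataclass(frozen=True)
class Waveform:
    """A single-beat sampled signal.

    Parameters
    ----------
    t : ndarray
        Sample times in ms, strictly increasing.
    v : ndarray
        Sample values; arbitrary units unless ``kind == "pressure"`` and the
        signal has been calibrated to mmHg.
    kind : str
        One of ``flow``, ``velocity``, ``pressure``, ``area``.
    cycle_length : float
        Length of the full cardiac cycle in ms; at least the sampled span.
    """

    t: np.ndarray
    v: np.ndarray
    kind: str
    cycle_length: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if self.kind not in VALID_KINDS:
            raise InvalidInputError(
                f"kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidInputError("t and v must be 1-D arrays of equal length")
        if t.size < MIN_SAMPLES:
            raise InvalidInputError(
                f"waveform needs at least {MIN_SAMPLES} samples, got {t.size}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InvalidInputError("waveform contains non-finite samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time vector must be strictly increasing")
        if self.cycle_length < t[-1] - t[0] - 1e-9:
            raise InvalidInputError(
                "cycle_length must cover the sampled span "
                f"({self.cycle_length} < {t[-1] - t[0]})"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Sampled span in ms."""
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        """Mean sample interval in ms."""
        return self.duration / (self.n - 1)

    def with_values(self, v: np.ndarray, kind: Optional[str] = None) -> "Waveform":
        """Return a copy carrying new values on the same grid."""
        return replace(self, v=np.asarray(v, dtype=float), kind=kind or self.kind)

    def same_grid(self, other: "Waveform", atol: float = 1e-9) -> bool:
        return self.n == other.n and bool(np.allclose(self.t, other.t, atol=atol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t, "value": self.v})


@dataclass(frozen=True)
class BeatLandmarks:
    """Fiducial times of a single ejection beat, all in ms (sub-sample).

    ``t_onset`` is the foot of the upstroke (threshold crossing),
    ``t_50up`` the 50 %-of-peak upstroke crossing, ``t_peak`` the systolic
    peak, ``t_es`` end-systole (first local minimum after the peak) and
    ``t_zero`` the first return of the signal to zero at or after
    end-systole (``None`` if the signal never returns to zero).
    """

    t_onset: float
    t_50up: float
    t_peak: float
    t_es: float
    t_zero: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.t_onset <= self.t_50up < self.t_peak < self.t_es):
            raise LandmarkError(
                "landmark ordering violated: require t_onset <= t_50up < "
                f"t_peak < t_es, got {self}"
            )
        if self.t_zero is not None and self.t_zero < self.t_es - 1e-9:
            raise LandmarkError("t_zero precedes t_es")
        if self.ejection_time <= 0:
            raise LandmarkError("non-positive ejection time")

    @property
    def ejection_time(self) -> float:
        """Systolic ejection duration t_es − t_onset in ms."""
        return self.t_es - self.t_onset


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _interpolator(t: np.ndarray, v: np.ndarray, method: str):
    if method == "pchip":
        return PchipInterpolator(t, v)
    if method == "cubic":
        return CubicSpline(t, v)
    if method == "linear":
        return lambda x: np.interp(x, t, v)
    raise InvalidParameterError(f"unknown interpolation method {method!r}")


def resample_uniform(w: Waveform, n_points: int, method: str = "cubic") -> Waveform:
    """Resample a waveform onto a uniform grid spanning its time range.

    Piecewise-cubic interpolation through the input samples (a C^2 cubic
    spline by default; pass ``method="pchip"`` for shape-preserving
    interpolation that cannot overshoot at the dicrotic notch); endpoints
    are reproduced exactly.
    """
    if n_points < MIN_SAMPLES:
        raise InvalidParameterError(f"n_points must be >= {MIN_SAMPLES}")
    grid = np.linspace(w.t[0], w.t[-1], int(n_points))
    v = _interpolator(w.t, w.v, method)(grid)
    v = np.asarray(v, dtype=float)
    v[0], v[-1] = w.v[0], w.v[-1]
    return Waveform(grid, v, w.kind, w.cycle_length, dict(w.meta))


def interp_at(w: Waveform, times: np.ndarray, method: str = "pchip") -> np.ndarray:
    """Evaluate the waveform at arbitrary times inside its support."""
    return np.asarray(_interpolator(w.t, w.v, method)(np.asarray(times)), dtype=float)


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------

def _crossing_time(t0, t1, v0, v1, level):
    """Linear-interpolated time at which the segment crosses `level`."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_landmarks(
    w: Waveform,
    onset_fraction: float = 0.05,
    es_window_fraction: float = 0.6,
) -> BeatLandmarks:
    """Detect beat landmarks on a flow or velocity waveform.

    The waveform must carry a single dominant systolic ejection lobe with a
    positive peak.  End-systole is taken as the first local minimum after the
    peak within ``es_window_fraction * cycle_length``; a sample is a local
    minimum when it is lower than its left neighbour and no higher than its
    right neighbour (ties resolved to the earliest time).  Crossing landmarks
    (onset, 50 % upstroke, zero return) are linearly interpolated to
    sub-sample precision.
    """
    t, v = w.t, w.v
    if w.kind in ("pressure", "area"):
        # pulsatile signals ride on a diastolic baseline; thresholds are
        # fractions of the pulse, not of the absolute value
        v = v - np.min(v)
    vmax = float(np.max(v))
    if vmax <= 0:
        raise LandmarkError("missing landmark t_peak: no positive systolic peak")
    i_peak = int(np.argmax(v))
    t_peak = float(t[i_peak])

    # 50%-of-peak upward crossing before the peak
    half = 0.5 * vmax
    t_50up = None
    for i in range(i_peak, 0, -1):
        if v[i - 1] < half <= v[i]:
            t_50up = _crossing_time(t[i - 1], t[i], v[i - 1], v[i], half)
            break
    if t_50up is None:
        raise LandmarkError("missing landmark t_50up: no upward 50%-of-peak crossing")

    # onset: last time before t_50up at which v <= onset_fraction * vmax
    thresh = onset_fraction * vmax
    t_onset = float(t[0])
    for i in range(i_peak, 0, -1):
        if t[i] > t_50up:
            continue
        if v[i - 1] <= thresh < v[i]:
            t_onset = _crossing_time(t[i - 1], t[i], v[i - 1], v[i], thresh)
            break
    t_onset = min(t_onset, t_50up)

    # end-systole: first local minimum after the peak within the search window
    window_end = t_peak + es_window_fraction * w.cycle_length
    i_es = None
    for i in range(i_peak + 1, len(t) - 1):
        if t[i] > window_end:
            break
        if v[i] < v[i - 1] and v[i] <= v[i + 1]:
            i_es = i
            break
    if i_es is None and len(t) >= 2 and t[-1] <= window_end and v[-1] < v[-2]:
        i_es = len(t) - 1  # monotone fall to the end of the record
    if i_es is None:
        raise LandmarkError(
            "missing landmark t_es: no local minimum after the peak within "
            f"{es_window_fraction:.2f} of the cycle"
        )
    t_es = float(t[i_es])

    # first return to zero at or after end-systole (either direction)
    t_zero = None
    if v[i_es] == 0.0:
        t_zero = t_es
    else:
        sign = np.sign(v[i_es])
        for i in range(i_es, len(t) - 1):
            if v[i + 1] == 0.0 or np.sign(v[i + 1]) != sign:
                t_zero = _crossing_time(t[i], t[i + 1], v[i], v[i + 1], 0.0)
                break

    return BeatLandmarks(t_onset, float(t_50up), t_peak, t_es, t_zero)


# ---------------------------------------------------------------------------
# disk I/O — CSV (`time_ms,value`) and JSON ({t, v, kind, cycle_length_ms})
# ---------------------------------------------------------------------------

def read_waveform(
    path: str | Path,
    kind: Optional[str] = None,
    cycle_length: Optional[float] = None,
) -> Waveform:
    """Read a waveform from a two-column CSV or a JSON file.

    CSV files need a ``time_ms,value`` header; ``kind`` and ``cycle_length``
    must then be supplied (``cycle_length`` defaults to the sampled span).
    JSON files carry ``t``, ``v``, ``kind`` and ``cycle_length_ms`` fields.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        try:
            return Waveform(
                np.asarray(payload["t"], dtype=float),
                np.asarray(payload["v"], dtype=float),
                kind or payload["kind"],
                float(cycle_length or payload["cycle_length_ms"]),
            )
        except KeyError as exc:
            raise FormatError(f"JSON waveform missing field {exc}") from exc
    df = pd.read_csv(path)
    if not {"time_ms", "value"}.issubset(df.columns):
        raise FormatError(
            f"{path} must have a 'time_ms,value' header, got {list(df.columns)}"
        )
    t = df["time_ms"].to_numpy(dtype=float)
    if kind is None:
        raise FormatError("CSV waveforms require an explicit kind")
    if cycle_length is None:
        cycle_length = float(t[-1] - t[0])
    return Waveform(t, df["value"].to_numpy(dtype=float), kind, float(cycle_length))


def write_waveform(w: Waveform, path: str | Path) -> None:
    """Write a waveform as CSV (``time_ms,value``) or JSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(
                {
                    "t": w.t.tolist(),
                    "v": w.v.tolist(),
                    "kind": w.kind,
                    "cycle_length_ms": w.cycle_length,
                }
            )
        )
    else:
        w.to_frame().to_csv(path, index=False)
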