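"""Arterial wave separation: the :class:`WaveSeparation` model.

Measured (or surrogate) central pressure P and aortic flow Q are decomposed
into forward- and backward-travelling components

    Pf = (P - Pud + Zc*Q) / 2
    Pb = (P - Pud - Zc*Q) / 2

where Pud is the undisturbed pressure (zero by default) and Zc the
characteristic impedance, estimated as the least-squares slope of the
early-systolic P-Q relation (the segment of the beat least contaminated by
reflections).  Derived indices are the reflection magnitude RM = dPb/dPf
(ratio of component amplitudes) and the reflected-wave return time Tr,
computed by the centroid method as the delay between the time-axis centroids
of Pb and the input pressure Pf_in = Zc*Q, each offset to a zero minimum.

Pressure may be any linear surrogate (e.g. cross-sectional area): RM and Tr
are invariant to affine recalibration of P and to amplitude scaling of Q,
because Zc absorbs both scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import BeatLandmarks, Waveform, detect_landmarks
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "WaveSeparation",
    "WaveSeparationResults",
    "estimate_zc",
    "separate",
    "reflection_magnitude",
    "return_time_centroid",
    "calibrate_area_to_pressure",
]


# ---------------------------------------------------------------------------
# free-function building blocks
# ---------------------------------------------------------------------------

def estimate_zc(
    p: Waveform,
    q: Waveform,
    upstroke_fraction: float = 0.95,
    landmarks: Optional[BeatLandmarks] = None,
) -> float:
    """Characteristic impedance from the early-systolic P-Q loop.

    Least-squares slope of p versus q over the samples from q's upstroke
    onset until q first reaches ``upstroke_fraction`` of its peak.  Any
    intercept (diastolic pressure offset) is absorbed by the fit.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 samples fall inside the upstroke window.
    DegenerateInputError
        The fitted slope is not positive.
    """
    if not p.same_grid(q):
        raise InvalidInputError("pressure and flow must share one time grid")
    lm = landmarks if landmarks is not None else detect_landmarks(q)
    level = upstroke_fraction * float(np.max(q.v))
    # first time q reaches the level at/after the peak's upstroke
    idx_hit = None
    for i in range(q.n):
        if q.t[i] >= lm.t_onset and q.v[i] >= level:
            idx_hit = i
            break
    if idx_hit is None:
        raise InsufficientDataError("flow never reaches the upstroke fraction")
    sel = (q.t >= lm.t_onset) & (np.arange(q.n) <= idx_hit)
    if int(np.count_nonzero(sel)) < 4:
        raise InsufficientDataError(
            f"only {int(np.count_nonzero(sel))} samples in the Zc window (need >= 4)"
        )
    qv, pv = q.v[sel], p.v[sel]
    if np.ptp(qv) == 0:
        raise DegenerateInputError("flat flow upstroke; cannot fit a P-Q slope")
    slope = float(stats.linregress(qv, pv).slope)
    if not slope > 0:
        raise DegenerateInputError(f"non-positive P-Q loop slope ({slope:.3g})")
    return slope


def _amplitude(v: np.ndarray) -> float:
    return float(np.max(v) - np.min(v))


def _centroid(t: np.ndarray, s: np.ndarray) -> float:
    """Time-axis centroid of a nonnegative signal via trapezoidal quadrature."""
    denom = float(np.trapezoid(s, t))
    if denom <= 0:
        raise DegenerateInputError("zero-integral signal has no centroid")
    return float(np.trapezoid(t * s, t)) / denom


def separate(
    p: Waveform,
    q: Waveform,
    zc: float,
    p_ud: float = 0.0,
) -> "WaveSeparationResults":
    """Decompose pressure into forward/backward components at a given Zc."""
    if not p.same_grid(q):
        raise InvalidInputError("pressure and flow must share one time grid")
    if not zc > 0:
        raise DegenerateInputError("Zc must be positive")
    pf_v = 0.5 * (p.v - p_ud + zc * q.v)
    pb_v = 0.5 * (p.v - p_ud - zc * q.v)
    pf = p.with_values(pf_v, kind="pressure")
    pb = p.with_values(pb_v, kind="pressure")
    pf_in = p.with_values(zc * q.v, kind="pressure")
    return WaveSeparationResults(
        zc=zc, p_ud=p_ud, pressure=p, flow=q, pf=pf, pb=pb, pf_in=pf_in
    )


def reflection_magnitude(res: "WaveSeparationResults") -> float:
    """RM = amplitude of Pb over amplitude of Pf (max minus min over the beat)."""
    if res.dpf == 0:
        raise DegenerateInputError("zero forward-wave amplitude")
    return res.dpb / res.dpf


def return_time_centroid(res: "WaveSeparationResults") -> float:
    """Reflected-wave return time by the centroid method, in ms.

    Both Pb and the input pressure Pf_in = Zc*Q are offset so their minimum
    over the beat is zero; the return time is the difference of their
    time-axis centroids, integrated over the full beat.
    """
    pb = res.pb.v - np.min(res.pb.v)
    pf_in = res.pf_in.v - np.min(res.pf_in.v)
    return _centroid(res.pb.t, pb) - _centroid(res.pf_in.t, pf_in)


def calibrate_area_to_pressure(
    a: Waveform,
    map_mmHg: float,
    dbp_mmHg: float,
) -> Waveform:
    """Linearly calibrate an area waveform to brachial mean/diastolic pressure.

    The affine map v -> alpha*v + beta is chosen so the output's mean equals
    ``map_mmHg`` and its minimum equals ``dbp_mmHg``.
    """
    if not map_mmHg > dbp_mmHg:
        raise InvalidInputError("mean pressure must exceed diastolic pressure")
    mean_a = float(np.mean(a.v))
    min_a = float(np.min(a.v))
    if mean_a <= min_a:
        raise DegenerateInputError("flat area waveform cannot be calibrated")
    alpha = (map_mmHg - dbp_mmHg) / (mean_a - min_a)
    beta = map_mmHg - alpha * mean_a
    return a.with_values(alpha * a.v + beta, kind="pressure")


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class WaveSeparation:
    """Wave-separation model for one beat of paired pressure and flow.

    Parameters
    ----------
    pressure : Waveform
        Central pressure or an uncalibrated linear surrogate (area).
    flow : Waveform
        Aortic flow or velocity on the same time grid; only its shape
        matters for RM and Tr.
    zc : float, optional
        Characteristic impedance.  Estimated from the early-systolic P-Q
        loop when omitted.
    p_ud : float
        Undisturbed pressure subtracted before separation (default 0).
    upstroke_fraction : float
        Upper end of the Zc fitting window, as a fraction of peak flow.
    landmarks : BeatLandmarks, optional
        Pre-computed flow landmarks (detected from ``flow`` when omitted).

    Examples
    --------
    >>> res = WaveSeparation(p, q).fit()
    >>> res.rm, res.tr
    """

    def __init__(
        self,
        pressure: Waveform,
        flow: Waveform,
        zc: Optional[float] = None,
        p_ud: float = 0.0,
        upstroke_fraction: float = 0.95,
        landmarks: Optional[BeatLandmarks] = None,
    ) -> None:
        if not pressure.same_grid(flow):
            raise InvalidInputError("pressure and flow must share one time grid")
        self.pressure = pressure
        self.flow = flow
        self.zc = zc
        self.p_ud = p_ud
        self.upstroke_fraction = upstroke_fraction
        self.landmarks = landmarks

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pressure_col: str = "pressure",
        flow_col: str = "flow",
        time_col: str = "time_ms",
        cycle_length: Optional[float] = None,
        **kwargs,
    ) -> "WaveSeparation":
        """Build the model from a tidy per-sample DataFrame."""
        t = df[time_col].to_numpy(dtype=float)
        if cycle_length is None:
            cycle_length = float(t[-1] - t[0])
        p = Waveform(t, df[pressure_col].to_numpy(float), "pressure", cycle_length)
        q = Waveform(t, df[flow_col].to_numpy(float), "flow", cycle_length)
        return cls(p, q, **kwargs)

    def fit(self) -> "WaveSeparationResults":
        """Estimate Zc (unless given) and separate the beat."""
        zc = self.zc
        if zc is None:
            zc = estimate_zc(
                self.pressure,
                self.flow,
                upstroke_fraction=self.upstroke_fraction,
                landmarks=self.landmarks,
            )
        res = separate(self.pressure, self.flow, zc, self.p_ud)
        res.model = self
        return res


@dataclass
class WaveSeparationResults:
    """Separated components and reflection indices for one beat.

    Attributes
    ----------
    zc : float
        Characteristic impedance used (pressure-unit per flow-unit).
    pf, pb : Waveform
        Forward and backward pressure components; ``pf.v + pb.v``
        reconstructs ``pressure.v - p_ud`` to machine precision.
    pf_in : Waveform
        Input pressure Zc*Q (the pressure in the absence of reflections).
    dpf, dpb : float
        Component amplitudes (max minus min over the beat).
    rm : float
        Reflection magnitude dPb/dPf.
    tr : float
        Centroid-method return time in ms.
    """

    zc: float
    p_ud: float
    pressure: Waveform
    flow: Waveform
    pf: Waveform
    pb: Waveform
    pf_in: Waveform
    model: Optional[WaveSeparation] = field(default=None, repr=False, compare=False)

    @property
    def dpf(self) -> float:
        return _amplitude(self.pf.v)

    @property
    def dpb(self) -> float:
        return _amplitude(self.pb.v)

    @property
    def rm(self) -> float:
        return reflection_magnitude(self)

    @property
    def tr(self) -> float:
        return return_time_centroid(self)

    def reconstruction_error(self) -> float:
        """Max |Pf + Pb − (P − Pud)| relative to the pressure amplitude."""
        resid = self.pf.v + self.pb.v - (self.pressure.v - self.p_ud)
        scale = _amplitude(self.pressure.v) or 1.0
        return float(np.max(np.abs(resid))) / scale

    def summary(self) -> str:
        """Plain-text summary table of the fitted indices."""
        rows = [
            ("Characteristic impedance Zc", f"{self.zc:.6g}"),
            ("Undisturbed pressure Pud", f"{self.p_ud:.6g}"),
            ("Forward amplitude dPf", f"{self.dpf:.6g}"),
            ("Backward amplitude dPb", f"{self.dpb:.6g}"),
            ("Reflection magnitude RM", f"{self.rm:.4f}"),
            ("Return time Tr (ms)", f"{self.tr:.2f}"),
            ("Samples per beat", f"{self.pressure.n:d}"),
            ("Beat span (ms)", f"{self.pressure.duration:.1f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Wave Separation Results", "=" * (width + 14)]
        lines += [f"{k:<{width}}  {val:>12}" for k, val in rows]
        lines.append("=" * (width + 14))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "zc": self.zc,
            "p_ud": self.p_ud,
            "dpf": self.dpf,
            "dpb": self.dpb,
            "rm": self.rm,
            "tr_ms": self.tr,
            "t_ms": self.pressure.t.tolist(),
            "pf": self.pf.v.tolist(),
            "pb": self.pb.v.tolist(),
            "pf_in": self.pf_in.v.tolist(),
        }
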