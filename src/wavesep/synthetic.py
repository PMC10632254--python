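"""Ground-truthed synthetic hemodynamics.

A single-reflection tube-load (transmission-line) model generates paired
pressure/flow/area beats with known reflection coefficient, delay and
characteristic impedance:

    Pf(t) = F(t)                      forward wave (skewed half-sine)
    Pb(t) = gamma * F(t - delay)      single reflected copy
    P(t)  = Pf + Pb + baseline
    Q(t)  = (Pf - Pb) / Zc
    A(t)  = affine map of P           (linear pressure-area relation)

Re-reflections are deliberately excluded so the ground truth for the
reflection magnitude (RM = gamma when the reflected wave fits inside the
beat) and the component waveforms is exact and closed-form.  The same
module synthesises cross-sectional velocity fields with a displaced
power-law profile, for exercising the virtual Doppler simulator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Waveform
from .doppler import VelocityField
from .errors import InvalidParameterError

__all__ = [
    "SimulationGroundTruth",
    "CohortSubject",
    "DEFAULT_COHORT_JITTER",
    "forward_wave",
    "simulate_beat",
    "simulate_cohort",
    "simulate_velocity_field",
    "truths_to_frame",
]


@dataclass(frozen=True)
class SimulationGroundTruth:
    """True parameters of one simulated beat.

    Parameters
    ----------
    gamma : float
        Reflection coefficient in [0, 0.8] (dimensionless).
    delay_ms : float
        Round-trip delay of the reflected wave (ms); must be shorter than
        the cardiac cycle.
    zc_true : float
        Characteristic impedance (pressure-unit per flow-unit), default
        0.1 mmHg*s/mL.
    hr_bpm : float
        Heart rate; cycle length is 60000/hr_bpm ms.
    systole_ms : float, optional
        Ejection duration.  Defaults to 35 % of the cycle (about 300 ms at
        70 bpm).
    peak_time_fraction : float
        Position of the forward-wave peak within systole (default 0.25,
        matching the typical aortic flow peak near a quarter of ejection).
    amplitude : float
        Peak of the forward wave (pressure units).
    baseline : float
        Diastolic pressure baseline added to P.
    noise_sd : float
        SD of additive Gaussian noise as a fraction of the forward-wave
        peak (applied to both P and Q).
    skew : float
        Velocity-profile displacement as a fraction of the lumen radius,
        in [0, 1).
    profile_exponent : float
        Bluntness exponent n of the power-law profile (2 = parabolic;
        larger = blunter).
    area_slope, area_offset : float
        Linear pressure-to-area map: A = area_offset + area_slope * P (mm^2).
    lumen_radius_mm : float
        Lumen radius for the velocity-field synthesis.
    """

    gamma: float = 0.4
    delay_ms: float = 120.0
    zc_true: float = 0.1
    hr_bpm: float = 70.0
    systole_ms: Optional[float] = None
    peak_time_fraction: float = 0.25
    amplitude: float = 40.0
    baseline: float = 80.0
    noise_sd: float = 0.0
    skew: float = 0.0
    profile_exponent: float = 2.0
    area_slope: float = 2.0
    area_offset: float = 300.0
    lumen_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 0.8:
            raise InvalidParameterError(f"gamma must lie in [0, 0.8], got {self.gamma}")
        if not self.zc_true > 0:
            raise InvalidParameterError("zc_true must be positive")
        if not self.hr_bpm > 0:
            raise InvalidParameterError("hr_bpm must be positive")
        if self.delay_ms >= self.cycle_ms:
            raise InvalidParameterError(
                f"delay ({self.delay_ms} ms) must be shorter than the cycle "
                f"({self.cycle_ms:.1f} ms)"
            )
        if not 0.0 <= self.skew < 1.0:
            raise InvalidParameterError("skew must lie in [0, 1)")
        if not 0.0 < self.peak_time_fraction < 1.0:
            raise InvalidParameterError("peak_time_fraction must lie in (0, 1)")

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.hr_bpm

    @property
    def t_sys(self) -> float:
        """Ejection duration in ms."""
        return self.systole_ms if self.systole_ms is not None else 0.35 * self.cycle_ms


def forward_wave(gt: SimulationGroundTruth, t: np.ndarray) -> np.ndarray:
    """Evaluate the forward wave F(t): a half-sine with adjustable rise skew.

    Normalized time x = t / t_sys is warped piecewise-linearly so the peak
    falls at ``peak_time_fraction`` of systole; outside [0, t_sys] the wave
    is zero.  Peak value is ``gt.amplitude``.
    """
    t = np.asarray(t, dtype=float)
    x = t / gt.t_sys
    s = gt.peak_time_fraction
    phi = np.where(x <= s, x / (2.0 * s), 0.5 + (x - s) / (2.0 * (1.0 - s)))
    out = np.where((x >= 0.0) & (x <= 1.0), np.sin(np.pi * phi), 0.0)
    return gt.amplitude * out


def simulate_beat(
    gt: SimulationGroundTruth,
    n_samples: int = 128,
    seed: Optional[int] = None,
) -> tuple[Waveform, Waveform, Waveform]:
    """Simulate one beat; returns (pressure, flow, area) on a uniform grid.

    The grid emulates ``n_samples`` frames per cardiac cycle (default 128,
    typical of segmented phase-contrast MRI).  Noise, when requested, is
    drawn from a generator seeded with ``seed`` so identical seeds give
    bit-identical beats.
    """
    if n_samples < 16:
        raise InvalidParameterError("n_samples must be at least 16")
    cycle = gt.cycle_ms
    t = np.arange(n_samples) * (cycle / n_samples)
    pf = forward_wave(gt, t)
    pb = gt.gamma * forward_wave(gt, t - gt.delay_ms)
    p = pf + pb + gt.baseline
    q = (pf - pb) / gt.zc_true
    if gt.noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = gt.noise_sd * gt.amplitude
        p = p + rng.normal(0.0, scale, n_samples)
        q = q + rng.normal(0.0, scale / gt.zc_true, n_samples)
    a = gt.area_offset + gt.area_slope * p
    meta = {"ground_truth": asdict(gt)}
    return (
        Waveform(t, p, "pressure", cycle, dict(meta)),
        Waveform(t, q, "flow", cycle, dict(meta)),
        Waveform(t, a, "area", cycle, dict(meta)),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Per-subject uniform jitter ranges used for synthetic cohorts: heart rate,
#: reflection coefficient, delay, rise skew and amplitude.
DEFAULT_COHORT_JITTER: dict[str, tuple[float, float]] = {
    "hr_bpm": (55.0, 90.0),
    "gamma": (0.3, 0.6),
    "delay_ms": (80.0, 160.0),
    "peak_time_fraction": (0.20, 0.30),
    "amplitude": (30.0, 50.0),
}


@dataclass(frozen=True)
class CohortSubject:
    """One simulated subject: waveform triple plus its ground truth."""

    pressure: Waveform
    flow: Waveform
    area: Waveform
    truth: SimulationGroundTruth
    subject_id: int = 0


def simulate_cohort(
    base: SimulationGroundTruth,
    n: int,
    jitter: Optional[dict[str, tuple[float, float]]] = None,
    seed: Optional[int] = None,
    n_samples: int = 128,
) -> list[CohortSubject]:
    """Draw a cohort of ``n`` subjects around ``base``.

    Each parameter named in ``jitter`` is drawn uniformly from its
    ``(lo, hi)`` range per subject (``lo == hi`` pins the value; pass an
    empty dict for ``n`` identical beats).  ``jitter=None`` uses
    :data:`DEFAULT_COHORT_JITTER`.  Fully deterministic under ``seed``.
    """
    if n < 3:
        raise InvalidParameterError("cohort size must be at least 3")
    if jitter is None:
        jitter = DEFAULT_COHORT_JITTER
    for name, (lo, hi) in jitter.items():
        if not hasattr(base, name):
            raise InvalidParameterError(f"unknown jitter parameter {name!r}")
        if hi < lo:
            raise InvalidParameterError(f"empty jitter range for {name!r}")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in jitter.items()}
        gt = replace(base, **draws)
        beat_seed = int(rng.integers(0, 2**31 - 1))
        p, q, a = simulate_beat(gt, n_samples=n_samples, seed=beat_seed)
        subjects.append(CohortSubject(p, q, a, gt, subject_id=i))
    return subjects


def truths_to_frame(subjects: Sequence[CohortSubject]) -> pd.DataFrame:
    """Tabulate the cohort's ground-truth parameters (CSV round-trippable)."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update(asdict(s.truth))
        rows.append(row)
    df = pd.DataFrame(rows)
    # systole_ms may be None (auto from heart rate): keep the column numeric
    df["systole_ms"] = df["systole_ms"].astype(float)
    return df


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

def simulate_velocity_field(
    gt: SimulationGroundTruth,
    q: Waveform,
    pixel_mm: float = 0.5,
    margin_mm: float = 2.0,
) -> VelocityField:
    """Synthesise a cross-sectional velocity-field time series driven by q.

    The lumen is a circle of radius R; the through-plane velocity follows a
    power-law profile u(r') = ((n+2)/n) * (1 - (r'/R)^n) with r' measured
    from a displaced profile centre.  Skewing is flow-dependent, as it is in
    a curved vessel where the velocity peak migrates off-centre as flow
    accelerates: the per-frame displacement is
    ``skew * R * |q(t)| / max|q|`` along +x, reaching the full ``skew * R``
    at peak flow and vanishing when flow is zero.  (A time-constant
    displacement would make the field separable, u = g(x, y) * U(t), so
    every sample-volume trace would share one shape and the skew could
    never distort a Doppler-derived waveform.)  Each frame is rescaled so
    the lumen-mean velocity equals q(t)/A exactly, with A the discrete
    lumen area (pixel count times pixel area).
    """
    if not 0.0 <= gt.skew < 1.0:
        raise InvalidParameterError("skew must lie in [0, 1)")
    if gt.profile_exponent < 2:
        raise InvalidParameterError("profile_exponent must be at least 2")
    r = gt.lumen_radius_mm
    half = r + margin_mm
    x = np.arange(-half + pixel_mm / 2, half, pixel_mm)
    y = x.copy()
    xx, yy = np.meshgrid(x, y)
    mask2d = xx**2 + yy**2 <= r**2
    n = gt.profile_exponent
    area = float(mask2d.sum()) * pixel_mm**2
    qmax = float(np.max(np.abs(q.v))) or 1.0
    u = np.empty((q.n,) + mask2d.shape)
    for k in range(q.n):
        cx = gt.skew * r * abs(q.v[k]) / qmax
        rprime = np.sqrt((xx - cx) ** 2 + yy**2)
        base = ((n + 2.0) / n) * (1.0 - (rprime / r) ** n)
        base = np.where(mask2d, base, 0.0)
        # per-frame renormalization: lumen-mean equals q(t)/A exactly
        u[k] = base * ((q.v[k] / area) / float(base[mask2d].mean()))
    mask = np.broadcast_to(mask2d, (q.n,) + mask2d.shape).copy()
    return VelocityField(
        frames=q.t.copy(),
        x=x,
        y=y,
        pixel_area=pixel_mm**2,
        mask=mask,
        u=u,
        cycle_length=q.cycle_length,
    )
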