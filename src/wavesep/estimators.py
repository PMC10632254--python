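"""Non-representative flow surrogates.

The triangular flow waveform replaces the measured beat with a triangle
whose base spans from the onset of the flow upstroke to the end-systolic
minimum and whose unit-height apex sits at a fixed fraction of ejection
time (25 % by default, close to the typical time of peak aortic flow; 30 %
and the subject's true peak time are the classic alternatives).  An
external-waveform loader de-normalizes any user-supplied normalized
waveform (same anchor convention as the representative waveform: tau = 0
at the 50 % upstroke, tau = 1 at end-systole), e.g. a digitized adult
ultrasound-derived average.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import BeatLandmarks, Waveform
from .errors import FormatError, InvalidParameterError
from .repflow import NormalizedWaveform, denormalize

__all__ = ["triangular_flow", "load_external_normalized"]


def triangular_flow(
    lm: BeatLandmarks,
    grid: np.ndarray,
    apex_fraction: Union[float, str] = 0.25,
    t_peak_true: Optional[float] = None,
    cycle_length: Optional[float] = None,
) -> Waveform:
    """Synthesize a unit-peak triangular flow waveform on ``grid``.

    Zero before ``lm.t_onset``, linear rise to 1.0 at
    ``t_onset + apex_fraction * ejection_time`` (or at ``t_peak_true``
    when ``apex_fraction == "peak"``), linear fall to zero at ``lm.t_es``,
    zero after.
    """
    if apex_fraction == "peak":
        if t_peak_true is None:
            raise InvalidParameterError('apex_fraction="peak" needs t_peak_true')
        t_apex = float(t_peak_true)
    else:
        f = float(apex_fraction)
        if not 0.0 < f < 1.0:
            raise InvalidParameterError("apex_fraction must lie in (0, 1)")
        t_apex = lm.t_onset + f * lm.ejection_time
    if not lm.t_onset < t_apex < lm.t_es:
        raise InvalidParameterError(
            f"apex time {t_apex:.1f} ms outside (onset, end-systole) "
            f"({lm.t_onset:.1f}, {lm.t_es:.1f})"
        )
    grid = np.asarray(grid, dtype=float)
    v = np.interp(grid, [lm.t_onset, t_apex, lm.t_es], [0.0, 1.0, 0.0])
    v[(grid < lm.t_onset) | (grid > lm.t_es)] = 0.0
    if cycle_length is None:
        cycle_length = float(grid[-1] - grid[0])
    return Waveform(grid, v, "flow", cycle_length, {"apex_ms": t_apex})


def load_external_normalized(
    path: str | Path,
    lm: BeatLandmarks,
    grid: np.ndarray,
    cycle_length: Optional[float] = None,
) -> Waveform:
    """De-normalize an externally supplied normalized waveform onto a beat.

    The file must be a two-column CSV with a ``tau,value`` header and the
    standard anchor convention (tau = 0 at the 50 % upstroke, tau = 1 at
    end-systole).  De-normalization follows the same code path as the
    representative waveform.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"tau", "value"}.issubset(df.columns):
        raise FormatError(
            f"{path} must have a 'tau,value' header, got {list(df.columns)}"
        )
    tau = df["tau"].to_numpy(dtype=float)
    if tau.size < 2 or np.any(np.diff(tau) <= 0):
        raise FormatError(f"{path}: tau column must be strictly increasing")
    if not (tau[0] <= 0.0 <= tau[-1] and tau[0] <= 1.0 <= tau[-1]):
        raise FormatError(
            f"{path}: tau range [{tau[0]:.3g}, {tau[-1]:.3g}] must cover the "
            "anchors tau=0 and tau=1"
        )
    nw = NormalizedWaveform(
        tau, df["value"].to_numpy(dtype=float), meta={"source": str(path)}
    )
    w = denormalize(nw, lm, grid, cycle_length=cycle_length)
    w.meta["source"] = str(path)
    return w
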