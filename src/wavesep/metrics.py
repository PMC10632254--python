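"""Error metrics and the method-evaluation harness.

Flow-surrogate separations are compared against the reference separation
obtained with the measured flow on the same pressure waveform: signed and
absolute percent errors in reflection magnitude and return time, and the
RMSE of the separated component waveforms.  Because both separations share
P, the forward and backward residuals are equal and opposite, so
RMSE(Pf) == RMSE(Pb) identically and a single RMSE describes both
components.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import Waveform, detect_landmarks, read_waveform
from .errors import InvalidInputError, InvalidParameterError
from .estimators import load_external_normalized, triangular_flow
from .separation import WaveSeparation, WaveSeparationResults

if TYPE_CHECKING:
    from .repflow import NormalizedWaveform, RepresentativeWaveform

__all__ = [
    "compare_separations",
    "deviation_profile",
    "subject_deviation",
    "evaluate_methods",
]


def compare_separations(
    ref: WaveSeparationResults,
    est: WaveSeparationResults,
) -> dict:
    """Error record for a surrogate separation against a reference.

    Both results must share the pressure waveform and time grid.  Percent
    errors are relative to the reference; RMSE is over the beat's samples.
    """
    if not ref.pressure.same_grid(est.pressure) or not np.allclose(
        ref.pressure.v, est.pressure.v
    ):
        raise InvalidInputError("separations must share the pressure waveform")
    rm_err = 100.0 * (est.rm - ref.rm) / ref.rm
    tr_err_ms = est.tr - ref.tr
    tr_err = 100.0 * tr_err_ms / ref.tr
    rmse_pf = float(np.sqrt(np.mean((est.pf.v - ref.pf.v) ** 2)))
    rmse_pb = float(np.sqrt(np.mean((est.pb.v - ref.pb.v) ** 2)))
    return {
        "rm_error_pct": rm_err,
        "abs_rm_error_pct": abs(rm_err),
        "tr_error_pct": tr_err,
        "abs_tr_error_pct": abs(tr_err),
        "tr_error_ms": tr_err_ms,
        "rmse_pf": rmse_pf,
        "rmse_pb": rmse_pb,
        "rmse_equal": bool(abs(rmse_pf - rmse_pb) < 1e-12 * max(rmse_pf, 1.0)),
    }


def deviation_profile(
    cohort_norm: Sequence["NormalizedWaveform"],
    rep: "RepresentativeWaveform",
) -> pd.DataFrame:
    """Pointwise 5-95 percentile width of the cohort around the average.

    Returns a table over the normalized-time grid; the width quantifies
    where beats disagree (typically the systolic downstroke, not the
    upstroke).
    """
    grid = rep.tau
    for w in cohort_norm:
        if w.tau.shape != grid.shape or not np.allclose(w.tau, grid):
            raise InvalidInputError("cohort and representative grids differ")
    stack = np.vstack([w.v for w in cohort_norm])
    width = np.percentile(stack, 95, axis=0) - np.percentile(stack, 5, axis=0)
    return pd.DataFrame({"tau": grid, "width": width})


def subject_deviation(
    cohort_norm: Sequence["NormalizedWaveform"],
    rep: "RepresentativeWaveform",
    tau: float,
) -> np.ndarray:
    """Per-subject deviation from the representative waveform at one tau."""
    return np.array([w.value_at(tau) - rep.value_at(tau) for w in cohort_norm])


# ---------------------------------------------------------------------------
# method evaluation harness
# ---------------------------------------------------------------------------

_KNOWN_METHODS = ("measured", "repflow", "triangle", "triangle30", "tripeak")


def _load_cohort_dir(path: Path, use: str) -> list[tuple[Waveform, Waveform]]:
    pairs = []
    for qfile in sorted(path.glob("*_flow.csv")):
        stem = qfile.name[: -len("_flow.csv")]
        pfile = path / f"{stem}_{use}.csv"
        if not pfile.exists():
            raise InvalidInputError(f"missing paired {use} file for {stem}")
        q = read_waveform(qfile, kind="flow")
        p = read_waveform(pfile, kind=use)
        pairs.append((p, q))
    if not pairs:
        raise InvalidInputError(f"no '*_flow.csv' files found in {path}")
    return pairs


def evaluate_methods(
    cohort: Union[str, Path, Sequence[tuple[Waveform, Waveform]]],
    methods: Sequence[str] = ("repflow", "triangle"),
    use: str = "pressure",
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Evaluate flow-surrogate methods against measured-flow separation.

    ``cohort`` is either a directory of paired ``<id>_flow.csv`` and
    ``<id>_<use>.csv`` waveform files or an in-memory sequence of
    (pressure-or-area, flow) pairs.  Supported methods: ``measured``,
    ``repflow`` (leave-one-out representative waveform), ``triangle``
    (apex at 25 % of ejection), ``triangle30``, ``tripeak``, and
    ``external:<path>``.  Returns the per-method mean and SD of the error
    metrics; per-subject records (and the summary) are also written as CSV
    when ``out_dir`` is given.  The computation is deterministic for a
    given cohort.
    """
    from .repflow import build_representative, denormalize, normalize

    if isinstance(cohort, (str, Path)):
        pairs = _load_cohort_dir(Path(cohort), use)
    else:
        pairs = list(cohort)
    for m in methods:
        if not (m in _KNOWN_METHODS or m.startswith("external:")):
            raise InvalidParameterError(
                f"unknown method {m!r}; choose from {_KNOWN_METHODS} or 'external:<path>'"
            )

    landmarks = [detect_landmarks(q) for _, q in pairs]
    refs = [
        WaveSeparation(p, q, landmarks=lm).fit()
        for (p, q), lm in zip(pairs, landmarks)
    ]
    normed = None
    if "repflow" in methods:
        normed = [normalize(q, lm) for (_, q), lm in zip(pairs, landmarks)]

    records = []
    for method in methods:
        for i, ((p, q), lm, ref) in enumerate(zip(pairs, landmarks, refs)):
            if method == "measured":
                q_est = q
            elif method == "repflow":
                rep = build_representative(
                    [nw for j, nw in enumerate(normed) if j != i]
                )
                q_est = denormalize(rep, lm, p.t, cycle_length=p.cycle_length)
            elif method == "triangle":
                q_est = triangular_flow(lm, p.t, 0.25, cycle_length=p.cycle_length)
            elif method == "triangle30":
                q_est = triangular_flow(lm, p.t, 0.30, cycle_length=p.cycle_length)
            elif method == "tripeak":
                q_est = triangular_flow(
                    lm, p.t, "peak", t_peak_true=lm.t_peak,
                    cycle_length=p.cycle_length,
                )
            else:  # external:<path>
                q_est = load_external_normalized(
                    method.split(":", 1)[1], lm, p.t, cycle_length=p.cycle_length
                )
            est = WaveSeparation(p, q_est).fit() if method != "measured" else ref
            rec = compare_separations(ref, est)
            rec["method"] = method
            rec["subject"] = i
            records.append(rec)

    per_subject = pd.DataFrame(records)
    value_cols = [
        "rm_error_pct", "abs_rm_error_pct",
        "tr_error_pct", "abs_tr_error_pct", "tr_error_ms",
        "rmse_pf",
    ]
    summary = per_subject.groupby("method")[value_cols].agg(["mean", "std"])
    summary = summary.reindex([m for m in methods])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_subject.to_csv(out_dir / "per_subject.csv", index=False)
        summary.to_csv(out_dir / "summary.csv")
    return summary
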