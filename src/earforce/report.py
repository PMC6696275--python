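"""Table-shaped reports for correlation and cross-validation results.

Produces the four standard report tables as DataFrames and writes them
as CSV plus aligned plain text:

* pearson:  per subject, (mean, sd) for ear–force, ear–emg, emg–force;
* partial:  per subject, (mean, sd) for ear–force|emg and emg–force|ear;
* slopes:   per subject, mean fold slope ā̄ and its n−1 standard deviation;
* accuracy: per subject, mean RMSE, f̃MAX, f̃MIN, estimated width and
  NRMSE over folds, optionally with Newton-scale columns from the
  affine calibration.

AD-scale statistics are rendered with 4 decimal places; Newton columns
as integers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Sequence

import pandas as pd

from .correlation_analysis import PARTIAL_PAIRS, PEARSON_PAIRS, SessionCorrelations
from .force_estimation import SubjectEvaluation
from .signal_model import CalibrationModel, DEFAULT_CALIBRATION

__all__ = [
    "pearson_frame",
    "partial_frame",
    "slope_frame",
    "accuracy_frame",
    "render_text",
    "write_reports",
]

_PAIR_LABELS = {
    "ear_force": "ear-force",
    "ear_emg": "ear-emg",
    "emg_force": "emg-force",
    "ear_force_given_emg": "ear-force|emg",
    "emg_force_given_ear": "emg-force|ear",
}


def _corr_frame(
    results: Iterable[SessionCorrelations], pairs: Sequence[str], which: str
) -> pd.DataFrame:
    rows = {}
    for res in results:
        summaries = getattr(res, which)
        row = {}
        for pair in pairs:
            s = summaries[pair]
            row[(_PAIR_LABELS[pair], "mean")] = s.mean_r
            row[(_PAIR_LABELS[pair], "sd")] = s.sd_r
        rows[res.subject_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame.index.name = "subject"
    return frame


def pearson_frame(results: Iterable[SessionCorrelations]) -> pd.DataFrame:
    """Pairwise-correlation summary table (rows = subjects)."""
    return _corr_frame(results, PEARSON_PAIRS, "pearson")


def partial_frame(results: Iterable[SessionCorrelations]) -> pd.DataFrame:
    """Partial-correlation summary table (rows = subjects)."""
    return _corr_frame(results, PARTIAL_PAIRS, "partial")


def slope_frame(evals: Iterable[SubjectEvaluation]) -> pd.DataFrame:
    """Mean fold slope ā̄ and its unbiased-variance square root."""
    rows = {
        ev.subject_id: {"a_bar_mean": ev.a_bar_mean, "a_bar_sd": ev.a_bar_sd}
        for ev in evals
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject"
    return frame


def accuracy_frame(
    evals: Iterable[SubjectEvaluation],
    newtons: bool = False,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
) -> pd.DataFrame:
    """Cross-validation accuracy table, fold-averaged per subject.

    With ``newtons=True``, adds the calibrated f̃MAX/f̃MIN in Newtons and
    the width in Newtons (gain × AD width; the calibration offset
    cancels in the difference).
    """
    rows = {}
    for ev in evals:
        row = {
            "rmse": ev.rmse_mean,
            "f_tilde_max": ev.f_tilde_max_mean,
            "f_tilde_min": ev.f_tilde_min_mean,
            "width": ev.width_mean,
            "nrmse": ev.nrmse_mean,
        }
        if newtons:
            # estimates are not clamped to [0, 1] AD, so apply the
            # affine map directly instead of the range-checked converter
            row["f_tilde_max_N"] = round(
                calibration.gain * ev.f_tilde_max_mean + calibration.offset
            )
            row["f_tilde_min_N"] = round(
                calibration.gain * ev.f_tilde_min_mean + calibration.offset
            )
            row["width_N"] = round(calibration.gain * ev.width_mean)
        rows[ev.subject_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject"
    return frame


def render_text(frame: pd.DataFrame, title: str = "") -> str:
    """Aligned plain-text rendering; 4 decimals for AD-scale columns."""

    def fmt(x):
        if isinstance(x, float):
            return f"{x:.4f}"
        return str(x)

    body = frame.to_string(float_format=lambda x: f"{x:.4f}")
    if title:
        return f"{title}\n{'=' * len(title)}\n{body}\n"
    return body + "\n"


def write_reports(
    out_dir: str | Path,
    correlations: Sequence[SessionCorrelations] = (),
    evaluations: Sequence[SubjectEvaluation] = (),
    newtons: bool = False,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
) -> Dict[str, Path]:
    """Write all applicable report tables as CSV + text; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, title: str) -> None:
        csv_path = out_dir / f"{name}.csv"
        frame.to_csv(csv_path, float_format="%.6g")
        txt_path = out_dir / f"{name}.txt"
        txt_path.write_text(render_text(frame, title))
        written[name] = csv_path

    if correlations:
        emit("correlation_pearson", pearson_frame(correlations),
             "Pairwise correlation coefficients (mean, sd over runs)")
        emit("correlation_partial", partial_frame(correlations),
             "Partial correlation coefficients (mean, sd over runs)")
    if evaluations:
        emit("slopes", slope_frame(evaluations),
             "Fold-averaged regression slopes")
        emit("accuracy", accuracy_frame(evaluations, newtons, calibration),
             "Cross-validation accuracy (fold averages)")
    return written
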