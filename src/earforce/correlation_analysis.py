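"""Per-run correlation structure of the three channels.

For each run the three pairwise Pearson coefficients are computed
(ear–force, ear–emg, emg–force), together with the two first-order
partial correlations of interest: ear–force with the EMG envelope's
linear influence removed, and emg–force with the ear sensor's influence
removed. Each of the five per-run series is then summarized across a
subject's runs by its mean and the square root of its unbiased variance
(the n−1 sample standard deviation), the dispersion measure used for
this protocol.

The partial coefficient uses the standard first-order recursion

    r_xy.z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),

equivalent to correlating the residuals of x and y after regressing each
on z; the residual form is kept as an independent cross-check in the
test suite. Partials are computed per run from that run's own pairwise
coefficients and only then averaged across runs — not from run-averaged
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError
from .signal_model import Run, Session

__all__ = [
    "PEARSON_PAIRS",
    "PARTIAL_PAIRS",
    "PairCorrelation",
    "CorrelationSummary",
    "SessionCorrelations",
    "pearson",
    "partial_correlation",
    "summarize",
    "run_correlations",
    "correlation_table",
]

PEARSON_PAIRS = ("ear_force", "ear_emg", "emg_force")
PARTIAL_PAIRS = ("ear_force_given_emg", "emg_force_given_ear")


@dataclass(frozen=True)
class PairCorrelation:
    pair: str
    r: float
    run_index: int


@dataclass(frozen=True)
class CorrelationSummary:
    """Mean and n−1 standard deviation of per-run coefficients."""

    pair: str
    mean_r: float
    sd_r: float
    n_runs: int


@dataclass(frozen=True)
class SessionCorrelations:
    """All five per-pair summaries for one subject."""

    subject_id: str
    pearson: Dict[str, CorrelationSummary]
    partial: Dict[str, CorrelationSummary]
    per_run: Tuple[Dict[str, float], ...]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for pair, summ in {**self.pearson, **self.partial}.items():
            cols[(pair, "mean")] = summ.mean_r
            cols[(pair, "sd")] = summ.sd_r
        frame = pd.DataFrame(cols, index=[self.subject_id])
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError(
            f"series must be 1-D with equal length, got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise InsufficientDataError("need at least 2 samples for a correlation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError(
            "constant series: correlation is undefined for zero-variance input"
        )
    return float(stats.pearsonr(x, y).statistic)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z from three pairwise r's."""
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= r <= 1.0:
            raise DegenerateInputError(f"{name}={r} outside [-1, 1]")
    if abs(r_xz) == 1.0 or abs(r_yz) == 1.0:
        raise DegenerateInputError(
            "control variable perfectly correlated with x or y; "
            "partial correlation is undefined"
        )
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def summarize(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and square root of unbiased variance of per-run coefficients."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 values to summarize, got {arr.size}"
        )
    if np.all(arr == arr[0]):  # sd exactly 0 iff all values equal
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def run_correlations(run: Run, include_partials: bool = True) -> Dict[str, float]:
    """The three Pearson and (optionally) two partial coefficients.

    ``include_partials=False`` skips the partial step, which is
    undefined when a control channel is perfectly correlated with
    another (|r| = 1, as happens on exactly affine noise-free data).
    """
    try:
        r_ef = pearson(run.ear, run.force)
        r_em = pearson(run.ear, run.emg)
        r_mf = pearson(run.emg, run.force)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"run {run.run_index}: {exc}") from exc
    out = {"ear_force": r_ef, "ear_emg": r_em, "emg_force": r_mf}
    if include_partials:
        try:
            out["ear_force_given_emg"] = partial_correlation(r_ef, r_em, r_mf)
            out["emg_force_given_ear"] = partial_correlation(r_mf, r_em, r_ef)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"run {run.run_index}: {exc}") from exc
    return out


def correlation_table(
    session: Session, include_partials: bool = True
) -> SessionCorrelations:
    """Per-subject summary of all five correlation series over runs."""
    per_run = []
    for run in session.runs:
        try:
            per_run.append(run_correlations(run, include_partials))
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"subject {session.subject_id}: {exc}"
            ) from exc
    if len(per_run) < 2:
        raise InsufficientDataError(
            f"subject {session.subject_id}: cannot summarize a single run"
        )

    def summ(pair: str) -> CorrelationSummary:
        mean_r, sd_r = summarize([d[pair] for d in per_run])
        return CorrelationSummary(pair, mean_r, sd_r, len(per_run))

    return SessionCorrelations(
        subject_id=session.subject_id,
        pearson={p: summ(p) for p in PEARSON_PAIRS},
        partial=(
            {p: summ(p) for p in PARTIAL_PAIRS} if include_partials else {}
        ),
        per_run=tuple(per_run),
    )
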