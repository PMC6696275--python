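"""Anchored single-regression force estimation with leave-one-run-out CV.

The estimator predicts the occlusal-force AD series of a held-out run
from its ear-sensor AD series alone. For fold k of a K-fold
leave-one-run-out split:

1. each training run i contributes an ordinary least-squares slope

       a_ki = (n Σ e f − Σe Σf) / (n Σ e² − (Σe)²),

   the regression coefficient of force on ear over that run's n = 200
   samples (the fitted intercept is discarded);

2. the K−1 slopes are averaged into ā_k;

3. the held-out run is predicted anchored at its own first sample
   (e_k0, f_k0):

       f̃_kj = ā_k (e_kj − e_k0) + f_k0,  j = 1..200.

Anchoring replaces the regression intercept because the per-run ear
offset drifts between runs while the slope stays stable; pinning the
line to the test run's initial sample absorbs that run's offset.

Accuracy per fold is RMSE_k between measured and estimated force (AD
units) and NRMSE_k = RMSE_k / (f̃_kMAX − f̃_kMIN), the RMSE normalized by
the fold's estimated width. Per-subject figures average each per-fold
column independently across folds — so the reported mean NRMSE is the
mean of ratios, not the ratio of means — and the mean slope ā̄ is
reported with the square root of its unbiased variance over folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError, RangeError
from .signal_model import Session

__all__ = [
    "TrainingSet",
    "FoldResult",
    "SubjectEvaluation",
    "slope",
    "fold_mean_slope",
    "predict",
    "rmse",
    "nrmse",
    "estimated_width",
    "cross_validate",
]


def slope(e, f) -> float:
    """OLS slope of force on ear for one run's paired series.

    Computed by the closed-form sum formula
    ``(n Σef − Σe Σf) / (n Σe² − (Σe)²)``; the intercept is never formed.
    """
    e = np.asarray(e, dtype=float)
    f = np.asarray(f, dtype=float)
    if e.shape != f.shape or e.ndim != 1 or e.size < 2:
        raise DegenerateInputError(
            f"paired 1-D series of equal length >= 2 required, "
            f"got shapes {e.shape} and {f.shape}"
        )
    if np.ptp(e) == 0.0:
        raise DegenerateInputError(
            "ear series is constant: regression slope is undefined"
        )
    n = e.size
    num = n * np.dot(e, f) - e.sum() * f.sum()
    den = n * np.dot(e, e) - e.sum() ** 2
    return float(num / den)


@dataclass(frozen=True)
class TrainingSet:
    """The K−1 training runs for fold k, as paired (ear, force) series."""

    fold_index: int
    members: Tuple[Tuple[np.ndarray, np.ndarray], ...]
    member_indices: Tuple[int, ...] = ()

    @classmethod
    def from_session(cls, session: Session, k: int) -> "TrainingSet":
        """Training set excluding the run with 1-based position ``k``."""
        if not 1 <= k <= session.K:
            raise RangeError(f"fold index {k} outside 1..{session.K}")
        members = []
        indices = []
        for pos, run in enumerate(session.runs, start=1):
            if pos != k:
                members.append((run.ear, run.force))
                indices.append(run.run_index)
        return cls(fold_index=k, members=tuple(members),
                   member_indices=tuple(indices))


def fold_mean_slope(training: TrainingSet) -> float:
    """Arithmetic mean of the per-run slopes over the training set."""
    slopes = []
    for idx, (e, f) in zip(
        training.member_indices or range(1, len(training.members) + 1),
        training.members,
    ):
        try:
            slopes.append(slope(e, f))
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"fold {training.fold_index}, training run {idx}: {exc}"
            ) from exc
    if not slopes:
        raise DegenerateInputError(
            f"fold {training.fold_index}: empty training set"
        )
    return float(np.mean(slopes))


def predict(e_series, a_bar: float, e0: float, f0: float) -> np.ndarray:
    """Anchored estimate ``f̃_j = ā (e_j − e0) + f0`` elementwise."""
    e_series = np.asarray(e_series, dtype=float)
    if e_series.size == 0:
        raise DegenerateInputError("empty ear series")
    return a_bar * (e_series - e0) + f0


def rmse(f, f_tilde) -> float:
    """Root-mean-square error between measured and estimated series."""
    f = np.asarray(f, dtype=float)
    f_tilde = np.asarray(f_tilde, dtype=float)
    if f.shape != f_tilde.shape:
        raise RangeError(
            f"length mismatch: {f.shape} measured vs {f_tilde.shape} estimated"
        )
    return float(np.sqrt(np.mean((f - f_tilde) ** 2)))


def nrmse(rmse_k: float, f_tilde_max: float, f_tilde_min: float) -> float:
    """RMSE normalized by the estimated width of the fold."""
    width = estimated_width(f_tilde_max, f_tilde_min)
    if width == 0.0:
        raise DegenerateInputError(
            "estimated width is zero: NRMSE is undefined"
        )
    return rmse_k / width


def estimated_width(f_tilde_max: float, f_tilde_min: float) -> float:
    """Range f̃MAX − f̃MIN of the estimates within a fold."""
    if f_tilde_max < f_tilde_min:
        raise RangeError(
            f"maximum {f_tilde_max} smaller than minimum {f_tilde_min}"
        )
    return f_tilde_max - f_tilde_min


@dataclass(frozen=True)
class FoldResult:
    """All per-fold quantities for held-out run k."""

    k: int
    a_bar_k: float
    e0: float
    f0: float
    f_tilde: np.ndarray
    rmse_k: float
    f_tilde_max: float
    f_tilde_min: float
    estimated_width: float
    nrmse_k: float


@dataclass(frozen=True)
class SubjectEvaluation:
    """Cross-validation results for one subject.

    Each mean is the arithmetic average of its per-fold column taken
    independently; ``a_bar_sd`` is the square root of the unbiased
    variance of the K fold slopes ā_k.
    """

    subject_id: str
    folds: Tuple[FoldResult, ...]
    a_bar_mean: float
    a_bar_sd: float
    rmse_mean: float
    f_tilde_max_mean: float
    f_tilde_min_mean: float
    width_mean: float
    nrmse_mean: float


def cross_validate(session: Session) -> SubjectEvaluation:
    """Leave-one-run-out evaluation of the anchored estimator.

    For each fold: slope-average over the remaining runs, anchor on the
    held-out run's first sample, predict its force series, and score it.
    A degenerate fold (constant ear channel in any training run) aborts
    the whole evaluation with the fold identity rather than being
    silently skipped.
    """
    folds: List[FoldResult] = []
    for k in range(1, session.K + 1):
        training = TrainingSet.from_session(session, k)
        try:
            a_bar_k = fold_mean_slope(training)
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"subject {session.subject_id}: {exc}"
            ) from exc
        test = session.runs[k - 1]
        e0 = float(test.ear[0])
        f0 = float(test.force[0])
        f_tilde = predict(test.ear, a_bar_k, e0, f0)
        rmse_k = rmse(test.force, f_tilde)
        f_max = float(f_tilde.max())
        f_min = float(f_tilde.min())
        width = estimated_width(f_max, f_min)
        try:
            nrmse_k = nrmse(rmse_k, f_max, f_min)
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"subject {session.subject_id}, fold {k}: {exc}"
            ) from exc
        folds.append(
            FoldResult(
                k=k, a_bar_k=a_bar_k, e0=e0, f0=f0, f_tilde=f_tilde,
                rmse_k=rmse_k, f_tilde_max=f_max, f_tilde_min=f_min,
                estimated_width=width, nrmse_k=nrmse_k,
            )
        )
    a_bars = np.array([fr.a_bar_k for fr in folds])
    return SubjectEvaluation(
        subject_id=session.subject_id,
        folds=tuple(folds),
        a_bar_mean=float(a_bars.mean()),
        a_bar_sd=float(a_bars.std(ddof=1)),
        rmse_mean=float(np.mean([fr.rmse_k for fr in folds])),
        f_tilde_max_mean=float(np.mean([fr.f_tilde_max for fr in folds])),
        f_tilde_min_mean=float(np.mean([fr.f_tilde_min for fr in folds])),
        width_mean=float(np.mean([fr.estimated_width for fr in folds])),
        nrmse_mean=float(np.mean([fr.nrmse_k for fr in folds])),
    )
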