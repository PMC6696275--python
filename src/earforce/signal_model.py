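"""Domain types and signal conventions for multi-channel chew recordings.

A recording *run* is one 2 s press-and-hold chew trial sampled at 100 Hz:
200 simultaneous triples of (ear-canal sensor, masseter-EMG envelope,
occlusal-force meter) readings. Each analog channel (0–3.3 V) is digitized
at 12-bit resolution and normalized to the unit interval — the "AD value".
A *session* is one subject's ordered set of K such runs (K = 6 in the
protocol this package models).

Force AD values convert to Newtons through an affine calibration
``F = gain * ad + offset`` with device constants ``gain = 1985.6`` N per
AD unit and ``offset = -75.066`` N, determined experimentally for the
occlusal-force meter. The conversion is deliberately not clamped at zero:
AD values below offset/gain ≈ 0.0378 map to (small) negative Newtons.

This module also provides plain-text persistence: one CSV per run plus a
YAML manifest per session.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ExtractionError, ParseError, RangeError

__all__ = [
    "AD_LEVELS",
    "V_REF",
    "RUN_LENGTH",
    "SAMPLING_HZ",
    "Sample",
    "Run",
    "Session",
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "quantize_ad",
    "calibrate_force",
    "extract_window",
    "read_session",
    "write_session",
]

#: Number of quantization steps of the 12-bit AD converter (2**12 - 1).
AD_LEVELS = 4095
#: Full-scale input voltage of the AD converter, in volts.
V_REF = 3.3
#: Samples per run: 2 s at 100 Hz.
RUN_LENGTH = 200
SAMPLING_HZ = 100

RUN_CSV_COLUMNS = ("t_s", "ear_ad", "emg_ad", "force_ad")

_TIME_ATOL = 1e-9


def _as_channel(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ParseError(f"channel {name!r} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise RangeError(f"channel {name!r} contains non-finite values")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        bad = int(np.argmax((arr < 0.0) | (arr > 1.0)))
        raise RangeError(
            f"channel {name!r} has AD value {arr[bad]:.6g} outside [0, 1] "
            f"at sample {bad}"
        )
    return arr


@dataclass(frozen=True)
class Sample:
    """One simultaneous reading of the three channels.

    ``t`` is seconds since run start (a non-negative multiple of the
    10 ms sampling interval); the channel values are AD units in [0, 1].
    """

    t: float
    ear: float
    emg: float
    force: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise RangeError(f"sample time {self.t} is negative")
        step = 1.0 / SAMPLING_HZ
        if abs(self.t / step - round(self.t / step)) > 1e-6:
            raise RangeError(
                f"sample time {self.t} is not a multiple of {step} s"
            )
        for name in ("ear", "emg", "force"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise RangeError(f"{name} AD value {v} outside [0, 1]")


@dataclass
class Run:
    """One 200-sample, 100 Hz window of (ear, emg, force) AD triples."""

    t: np.ndarray
    ear: np.ndarray
    emg: np.ndarray
    force: np.ndarray
    run_index: int = 1
    sampling_hz: int = SAMPLING_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ear = _as_channel(self.ear, "ear")
        self.emg = _as_channel(self.emg, "emg")
        self.force = _as_channel(self.force, "force")
        n = self.t.size
        if not (self.ear.size == self.emg.size == self.force.size == n):
            raise ParseError(
                f"run {self.run_index}: channel lengths differ "
                f"({n}, {self.ear.size}, {self.emg.size}, {self.force.size})"
            )
        if n != RUN_LENGTH:
            raise ParseError(
                f"run {self.run_index}: expected {RUN_LENGTH} samples, got {n}"
            )
        step = 1.0 / self.sampling_hz
        expected = self.t[0] + step * np.arange(n)
        if self.t[0] < -_TIME_ATOL or not np.allclose(
            self.t, expected, atol=_TIME_ATOL, rtol=0.0
        ):
            raise ParseError(
                f"run {self.run_index}: timestamps are not a strictly "
                f"increasing grid with step {step} s"
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def samples(self) -> Iterator[Sample]:
        for t, e, m, f in zip(self.t, self.ear, self.emg, self.force):
            yield Sample(float(t), float(e), float(m), float(f))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "ear_ad": self.ear,
                "emg_ad": self.emg,
                "force_ad": self.force,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, run_index: int = 1, sampling_hz: int = SAMPLING_HZ
    ) -> "Run":
        return cls(
            t=frame["t_s"].to_numpy(),
            ear=frame["ear_ad"].to_numpy(),
            emg=frame["emg_ad"].to_numpy(),
            force=frame["force_ad"].to_numpy(),
            run_index=run_index,
            sampling_hz=sampling_hz,
        )


@dataclass
class Session:
    """An ordered collection of K runs from one subject."""

    subject_id: str
    runs: Sequence[Run] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.runs = list(self.runs)
        if len(self.runs) < 2:
            raise ParseError(
                f"session {self.subject_id!r}: needs at least 2 runs "
                f"(got {len(self.runs)}) so each cross-validation fold "
                "has a non-empty training set"
            )

    @property
    def K(self) -> int:
        return len(self.runs)

    def __iter__(self) -> Iterator[Run]:
        return iter(self.runs)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine AD-to-Newton calibration ``F = gain * ad + offset``."""

    gain: float = 1985.6   # N per AD unit
    offset: float = -75.066  # N

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise RangeError(f"calibration gain must be positive, got {self.gain}")

    def __call__(self, ad_value):
        return calibrate_force(ad_value, self)


DEFAULT_CALIBRATION = CalibrationModel()


def quantize_ad(voltage):
    """Convert an analog voltage in [0, 3.3] V to a 12-bit AD unit value.

    Round-to-nearest over 4095 steps, so 0 V → 0.0000 and 3.3 V → 1.0000
    exactly and the quantization error never exceeds half a step
    (1/8190 in AD units). Accepts scalars or arrays.
    """
    v = np.asarray(voltage, dtype=float)
    if np.any(v < 0.0) or np.any(v > V_REF):
        raise RangeError(f"voltage outside [0, {V_REF}] V: {voltage!r}")
    q = np.clip(np.round(v / V_REF * AD_LEVELS) / AD_LEVELS, 0.0, 1.0)
    if np.isscalar(voltage) or isinstance(voltage, numbers.Number):
        return float(q)
    return q


def quantize_unit(values):
    """Snap AD unit values in [0, 1] onto the 12-bit grid k/4095."""
    return np.round(np.asarray(values, dtype=float) * AD_LEVELS) / AD_LEVELS


def calibrate_force(ad_value, model: CalibrationModel = DEFAULT_CALIBRATION):
    """Convert force AD unit values to Newtons via the affine calibration.

    Values near zero AD calibrate to slightly negative Newtons; no
    clamping is applied. Accepts scalars or arrays.
    """
    v = np.asarray(ad_value, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise RangeError(f"AD value outside [0, 1]: {ad_value!r}")
    out = model.gain * v + model.offset
    if np.isscalar(ad_value) or isinstance(ad_value, numbers.Number):
        return float(out)
    return out


def extract_window(
    long_run: Run | pd.DataFrame | Sequence[Sample],
    onset_threshold: float = 0.05,
    run_index: int = 1,
    sampling_hz: int = SAMPLING_HZ,
) -> Run:
    """Cut the 2 s press window out of a longer recording.

    The window starts at the first sample whose force AD value reaches
    ``onset_threshold`` and spans the following 200 samples; timestamps
    are re-zeroed to the window start.
    """
    if isinstance(long_run, Run):
        frame = long_run.to_frame()
    elif isinstance(long_run, pd.DataFrame):
        frame = long_run
    else:
        frame = pd.DataFrame(
            {
                "t_s": [s.t for s in long_run],
                "ear_ad": [s.ear for s in long_run],
                "emg_ad": [s.emg for s in long_run],
                "force_ad": [s.force for s in long_run],
            }
        )
    force = frame["force_ad"].to_numpy(dtype=float)
    crossings = np.nonzero(force >= onset_threshold)[0]
    if crossings.size == 0:
        raise ExtractionError(
            f"force never reaches onset threshold {onset_threshold}"
        )
    start = int(crossings[0])
    if start + RUN_LENGTH > force.size:
        raise ExtractionError(
            f"only {force.size - start} samples follow the onset at index "
            f"{start}; {RUN_LENGTH} are required"
        )
    window = frame.iloc[start : start + RUN_LENGTH]
    return Run(
        t=np.arange(RUN_LENGTH) / sampling_hz,
        ear=window["ear_ad"].to_numpy(),
        emg=window["emg_ad"].to_numpy(),
        force=window["force_ad"].to_numpy(),
        run_index=run_index,
        sampling_hz=sampling_hz,
    )


def _read_run_csv(path: Path, run_index: int, sampling_hz: int,
                  extract: bool, onset_threshold: float) -> Run:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse run CSV: {exc}") from exc
    missing = [c for c in RUN_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in RUN_CSV_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(
                f"{path}, line {bad[0] + 2}: non-numeric value in {col!r}"
            )
        frame[col] = vals
    for col in RUN_CSV_COLUMNS[1:]:
        out = frame.index[(frame[col] < 0) | (frame[col] > 1)]
        if len(out):
            raise ParseError(
                f"{path}, line {out[0] + 2}: {col!r} value "
                f"{frame.loc[out[0], col]:.6g} outside [0, 1]"
            )
    dt = np.diff(frame["t_s"].to_numpy())
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise ParseError(f"{path}, line {line}: timestamps not increasing")
    try:
        if extract and len(frame) != RUN_LENGTH:
            return extract_window(
                frame, onset_threshold, run_index=run_index,
                sampling_hz=sampling_hz,
            )
        return Run.from_frame(frame, run_index=run_index, sampling_hz=sampling_hz)
    except (ParseError, ExtractionError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def read_session(
    manifest: str | Path,
    *,
    extract_windows: bool = False,
    onset_threshold: float = 0.05,
) -> Session:
    """Load a session from a YAML manifest listing its run CSV files.

    Run paths in the manifest are resolved relative to the manifest's
    directory. With ``extract_windows=True``, run files longer than 200
    samples are windowed by force onset instead of rejected.
    """
    manifest = Path(manifest)
    try:
        meta = yaml.safe_load(manifest.read_text())
    except Exception as exc:
        raise ParseError(f"{manifest}: cannot parse manifest: {exc}") from exc
    if not isinstance(meta, dict) or "subject_id" not in meta or "runs" not in meta:
        raise ParseError(
            f"{manifest}: manifest must define 'subject_id' and 'runs'"
        )
    sampling_hz = int(meta.get("sampling_hz", SAMPLING_HZ))
    runs = []
    for i, rel in enumerate(meta["runs"], start=1):
        path = manifest.parent / rel
        if not path.exists():
            raise ParseError(f"{manifest}: run file not found: {path}")
        runs.append(
            _read_run_csv(path, i, sampling_hz, extract_windows, onset_threshold)
        )
    return Session(subject_id=str(meta["subject_id"]), runs=runs)


def write_session(session: Session, directory: str | Path) -> Path:
    """Write one CSV per run plus a YAML manifest; returns the manifest path.

    ``read_session(write_session(s, d))`` reproduces ``s`` field-for-field
    (floats are written at full round-trip precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    run_files = []
    for run in session.runs:
        name = f"{session.subject_id}_run{run.run_index}.csv"
        run.to_frame().to_csv(directory / name, index=False)
        run_files.append(name)
    manifest = directory / f"{session.subject_id}_session.yaml"
    manifest.write_text(
        yaml.safe_dump(
            {
                "subject_id": session.subject_id,
                "sampling_hz": session.runs[0].sampling_hz,
                "runs": run_files,
            },
            sort_keys=False,
        )
    )
    return manifest
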