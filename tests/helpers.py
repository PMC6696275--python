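"""Shared construction helpers for the test suite."""

import numpy as np

from earforce import Run, Session
from earforce.signal_model import RUN_LENGTH, SAMPLING_HZ

T = np.arange(RUN_LENGTH) / SAMPLING_HZ


def make_run(ear, force, emg=None, run_index=1):
    """Build a valid Run from channel arrays (default EMG: flat 0.5 ramp)."""
    ear = np.asarray(ear, dtype=float)
    force = np.asarray(force, dtype=float)
    if emg is None:
        emg = np.linspace(0.1, 0.6, RUN_LENGTH)
    return Run(t=T, ear=ear, emg=np.asarray(emg, dtype=float),
               force=force, run_index=run_index)


def affine_session(a_s, e_base=0.5, f_base=0.1, f_peak=0.7, K=6,
                   subject_id="affine"):
    """Noise-free session with exact affine ear/force/EMG coupling.

    Force ramps linearly from f_base to f_peak; ear and EMG are exact
    affine functions of force, so every correlation is ±1 and every
    per-run slope equals ``a_s`` exactly.
    """
    runs = []
    for k in range(1, K + 1):
        force = np.linspace(f_base, f_peak, RUN_LENGTH)
        ear = e_base + (force - f_base) / a_s
        emg = 0.1 + 0.8 * (force - f_base) / (f_peak - f_base)
        runs.append(make_run(ear, force, emg, run_index=k))
    return Session(subject_id=subject_id, runs=runs)
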