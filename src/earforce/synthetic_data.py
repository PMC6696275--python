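"""Seeded generator for synthetic chew-trial sessions.

The real recordings this pipeline was designed around are access
restricted, so the generator emulates their statistical structure well
enough to exercise every stage of the analysis:

* a ~2 s monotone press-and-hold force ramp per run (smoothstep from a
  baseline to a per-run jittered peak);
* a subject-specific affine ear↔force coupling ``e = e_base + (f −
  f_base)/a_s`` whose sign differs between subjects (positive for some
  ear canals, negative for others);
* run-to-run ear-sensor offset drift: a per-run offset δ_r drawn once
  per run, so the six ear–force scatter lines share a slope but not an
  intercept;
* an EMG envelope that is a noisy linear function of force.

A single latent (noise-free) force ramp drives all three channels;
independent Gaussian measurement noise is then added per channel.
Keeping the latent shared means force-channel noise does not leak into
the ear channel: slope recovery stays unbiased under force noise, while
ear noise produces the classical errors-in-variables attenuation. After
noise, channels are clamped to [0, 1] and (by default) snapped to the
12-bit AD grid, matching the physical acquisition path.

Determinism contract: ``generate_session(params, K)`` is a pure function
of ``(params, K)``; identical inputs give bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from .errors import RangeError
from .signal_model import RUN_LENGTH, SAMPLING_HZ, Run, Session, quantize_unit

__all__ = [
    "SubjectParams",
    "generate_force_profile",
    "generate_run",
    "generate_session",
    "preset_subjects",
    "read_params",
    "write_params",
]

logger = logging.getLogger(__name__)

#: Standard deviation of the smoothstep ramp relative to its range,
#: used by the presets to convert relative SNR choices into absolute
#: AD-unit noise scales.  Var(3u^2 - 2u^3) for u uniform on [0, 1].
SMOOTHSTEP_REL_SD = 0.34845


@dataclass(frozen=True)
class SubjectParams:
    """Generation parameters for one synthetic subject.

    ``slope`` is the true coupling a_s = df/de in AD-force units per
    AD-ear unit (signed; its reciprocal sets how far the ear channel
    moves for a given force excursion). Noise scales are per-sample
    Gaussian standard deviations in AD units; ``drift_sd`` is the
    standard deviation of the once-per-run ear offset.
    """

    slope: float = -16.1064
    e_base: float = 0.5
    f_base: float = 0.0614
    f_peak: float = 0.6004
    drift_sd: float = 0.004
    noise_ear_sd: float = 0.0012
    noise_emg_sd: float = 0.047
    noise_force_sd: float = 0.01
    emg_gain: float = 1.0
    emg_base: float = 0.12
    peak_jitter: float = 0.03
    seed: int = 0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.slope == 0.0:
            raise RangeError("coupling slope must be nonzero")
        if not 0.0 <= self.f_base < self.f_peak <= 1.0:
            raise RangeError(
                f"need 0 <= f_base < f_peak <= 1, got "
                f"({self.f_base}, {self.f_peak})"
            )
        if not 0.0 <= self.e_base <= 1.0:
            raise RangeError(f"e_base {self.e_base} outside [0, 1]")
        if not 0.0 <= self.emg_base <= 1.0:
            raise RangeError(f"emg_base {self.emg_base} outside [0, 1]")
        for name in ("drift_sd", "noise_ear_sd", "noise_emg_sd",
                     "noise_force_sd", "emg_gain", "peak_jitter"):
            if getattr(self, name) < 0:
                raise RangeError(f"{name} must be >= 0")


def _latent_profile(params: SubjectParams, rng: np.random.Generator) -> np.ndarray:
    """Noise-free smoothstep ramp with a per-run jittered peak."""
    peak = params.f_peak * (1.0 + params.peak_jitter * rng.standard_normal())
    peak = float(np.clip(peak, params.f_base + 1e-6, 1.0))
    u = np.arange(RUN_LENGTH) / (RUN_LENGTH - 1)
    s = 3.0 * u**2 - 2.0 * u**3  # smoothstep: C1, monotone on [0, 1]
    return params.f_base + (peak - params.f_base) * s


def generate_force_profile(
    params: SubjectParams, run_rng: np.random.Generator
) -> np.ndarray:
    """One run's measured force AD series: latent ramp plus sensor noise."""
    latent = _latent_profile(params, run_rng)
    noisy = latent + run_rng.normal(0.0, params.noise_force_sd, RUN_LENGTH)
    return np.clip(noisy, 0.0, 1.0)


def generate_run(
    params: SubjectParams, run_index: int, run_rng: np.random.Generator
) -> Run:
    """Generate one 200-sample run of coupled (ear, emg, force) channels.

    All three channels derive from the same latent ramp; each then gets
    its own independent measurement noise. The ear channel additionally
    gets the per-run offset δ_r. If systematic clamping occurs (> 5% of
    samples in any channel) a warning is logged: the parameters push the
    signal outside the AD range.
    """
    latent = _latent_profile(params, run_rng)
    delta_r = run_rng.normal(0.0, params.drift_sd)
    force = latent + run_rng.normal(0.0, params.noise_force_sd, RUN_LENGTH)
    ear = (
        params.e_base
        + delta_r
        + (latent - params.f_base) / params.slope
        + run_rng.normal(0.0, params.noise_ear_sd, RUN_LENGTH)
    )
    # resting envelope level emg_base keeps the noise floor above the
    # clamp at 0 AD, as a rectified-envelope output sits above 0 V
    emg = (
        params.emg_base
        + params.emg_gain * (latent - params.f_base)
        + run_rng.normal(0.0, params.noise_emg_sd, RUN_LENGTH)
    )
    channels = {}
    for name, raw in (("ear", ear), ("emg", emg), ("force", force)):
        clipped = np.clip(raw, 0.0, 1.0)
        frac = float(np.mean(clipped != raw))
        if frac > 0.05:
            logger.warning(
                "run %d: %.0f%% of %s samples clamped to [0, 1]; "
                "parameters drive the signal outside the AD range",
                run_index, 100 * frac, name,
            )
        channels[name] = quantize_unit(clipped) if params.quantize else clipped
    return Run(
        t=np.arange(RUN_LENGTH) / SAMPLING_HZ,
        ear=channels["ear"],
        emg=channels["emg"],
        force=channels["force"],
        run_index=run_index,
        sampling_hz=SAMPLING_HZ,
    )


def generate_session(
    params: SubjectParams, K: int = 6, subject_id: str = "synthetic"
) -> Session:
    """Generate a K-run session; deterministic given ``(params, K)``.

    Each run gets an independent child stream spawned from
    ``params.seed`` so runs are statistically independent but jointly
    reproducible.
    """
    if K < 2:
        raise RangeError(f"K must be >= 2, got {K}")
    children = np.random.SeedSequence(params.seed).spawn(K)
    runs = [
        generate_run(params, k + 1, np.random.default_rng(children[k]))
        for k in range(K)
    ]
    return Session(subject_id=subject_id, runs=runs)


def preset_subjects(base_seed: int = 0) -> Dict[str, SubjectParams]:
    """Five synthetic subject profiles mirroring the study's structure.

    Three have negative ear↔force coupling and two positive, with
    per-subject slopes and force AD ranges of realistic magnitude. Noise
    scales are set *relative* to each subject's channel excursion: ear
    noise at 10% of the ear-signal standard deviation and EMG noise at
    25% of the EMG-signal standard deviation, making the ear channel the
    cleaner force proxy for every subject (this is the documented regime
    under which the ear–force partial correlation dominates the
    EMG–force partial correlation).
    """
    profiles = {
        "A": (-16.1064, 0.0614, 0.6004, 0.50),
        "B": (-22.8559, 0.0448, 0.4411, 0.45),
        "C": (12.0029, 0.0544, 0.2584, 0.55),
        "D": (-8.9634, 0.0536, 0.2699, 0.48),
        "E": (18.7544, 0.0176, 0.4466, 0.52),
    }
    out = {}
    for i, (sid, (a_s, f_lo, f_hi, e0)) in enumerate(profiles.items()):
        width = f_hi - f_lo
        ear_sd = SMOOTHSTEP_REL_SD * width / abs(a_s)
        emg_sd = SMOOTHSTEP_REL_SD * width  # emg_gain = 1
        out[sid] = SubjectParams(
            slope=a_s,
            e_base=e0,
            f_base=f_lo,
            f_peak=f_hi,
            drift_sd=0.10 * width / abs(a_s),
            noise_ear_sd=0.10 * ear_sd,
            noise_emg_sd=0.25 * emg_sd,
            noise_force_sd=0.05 * SMOOTHSTEP_REL_SD * width,
            emg_gain=1.0,
            emg_base=2.5 * 0.25 * emg_sd,  # keeps EMG clamping below ~1%
            peak_jitter=0.03,
            seed=base_seed + i,
        )
    return out


def write_params(params: SubjectParams, path: str | Path) -> Path:
    """Write SubjectParams as a key-value YAML file."""
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))
    return path


def read_params(path: str | Path) -> SubjectParams:
    """Read SubjectParams from a key-value YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise RangeError(f"{path}: parameter file must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(SubjectParams)}
    unknown = set(data) - known
    if unknown:
        raise RangeError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return SubjectParams(**data)
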