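"""Generate a synthetic chew-trial session and save it as CSV + manifest.

A session is six 2 s runs (200 samples at 100 Hz) of simultaneous
(ear sensor, EMG envelope, occlusal force) AD triples. The preset
subject-A profile has a negative ear↔force coupling of about −16 AD
force units per AD ear unit.
"""

from pathlib import Path

from earforce import generate_session, preset_subjects, write_session

params = preset_subjects()["A"]
session = generate_session(params, K=6, subject_id="A")
manifest = write_session(session, Path("scratch/session_A"))

print(f"subject {session.subject_id}: {session.K} runs -> {manifest}")
for run in session.runs:
    print(
        f"  run {run.run_index}: force {run.force.min():.4f}..{run.force.max():.4f} AD, "
        f"ear {run.ear.min():.4f}..{run.ear.max():.4f} AD"
    )
print(
    "Force ramps from the light-bite baseline to the per-run peak; the ear "
    "channel mirrors it through the subject's (negative) coupling, so ear "
    "values fall as force rises."
)
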