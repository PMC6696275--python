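"""Correlation structure of the three channels for five synthetic subjects.

Prints the pairwise Pearson table and the partial-correlation table
(mean and n−1 standard deviation over the six runs). Three subjects
have negative ear couplings and two positive; the EMG–force correlation
is positive for everyone. Because the ear channel is the cleaner force
proxy, the ear–force partial correlation (EMG influence removed) is
much larger in magnitude than the EMG–force partial correlation (ear
influence removed).
"""

from earforce import correlation_table, generate_session, preset_subjects
from earforce.report import partial_frame, pearson_frame, render_text

tables = [
    correlation_table(generate_session(p, subject_id=sid))
    for sid, p in preset_subjects().items()
]

print(render_text(pearson_frame(tables),
                  "Pairwise correlations (mean, sd over 6 runs)"))
print(render_text(partial_frame(tables),
                  "Partial correlations (mean, sd over 6 runs)"))
print(
    "Each coefficient is computed per run and summarized over runs. The "
    "sign of the ear columns is the subject's coupling sign; the ear-force "
    "partial staying near +/-0.9 while emg-force|ear drops to ~0.3 shows "
    "the ear channel carries force information beyond what EMG explains."
)
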