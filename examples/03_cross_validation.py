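"""Leave-one-run-out evaluation of the anchored single-regression estimator.

For each fold the training runs contribute per-run OLS slopes whose mean
ā_k, anchored at the held-out run's first sample (e_k0, f_k0), predicts
that run's force series: f̃_kj = ā_k (e_kj − e_k0) + f_k0. Accuracy is
RMSE in AD units and NRMSE (RMSE over the fold's estimated width).
"""

from earforce import DEFAULT_CALIBRATION, cross_validate, generate_session, preset_subjects

session = generate_session(preset_subjects()["A"], subject_id="A")
ev = cross_validate(session)

print("fold   a_bar_k    RMSE_k   f~max    f~min    width    NRMSE_k")
for fr in ev.folds:
    print(
        f"  {fr.k}   {fr.a_bar_k:8.4f}   {fr.rmse_k:.4f}   {fr.f_tilde_max:.4f}"
        f"   {fr.f_tilde_min:.4f}   {fr.estimated_width:.4f}   {fr.nrmse_k:.4f}"
    )
print(
    f"\nfold averages: slope {ev.a_bar_mean:.4f} (sd {ev.a_bar_sd:.4f}), "
    f"RMSE {ev.rmse_mean:.4f}, width {ev.width_mean:.4f}, NRMSE {ev.nrmse_mean:.4f}"
)
# estimates are unclamped AD values, so apply the affine map directly
to_newtons = lambda ad: DEFAULT_CALIBRATION.gain * ad + DEFAULT_CALIBRATION.offset
print(
    f"calibrated estimate range: "
    f"{to_newtons(ev.f_tilde_max_mean):.0f} N down to "
    f"{to_newtons(ev.f_tilde_min_mean):.0f} N"
)
print(
    "The recovered slope sits near the generating coupling (-16.1); NRMSE "
    "of a few percent means the anchored line tracks the held-out press "
    "ramp closely despite run-to-run ear-offset drift."
)
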