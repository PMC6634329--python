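"""Decode the dominant percept from per-cycle pupil phase, end to end.

Simulates a small multi-subject study (counterphase, 90-degree and
in-phase control conditions), cleans every block, chunks it into 588 ms
presentation cycles, extracts the complex F1 component Z per cycle and
runs the group statistics: paired t-tests on Im(Z) and single-cycle
ROC/AUC decoding with the optimal complex-plane rotation.
"""

from pupiltag import RunConfig, StimulusSchedule, run_synthetic_study

cfg = RunConfig(seed=1, n_subjects=6)
cfg.schedule = StimulusSchedule(block_duration_s=120.0)  # short demo blocks

per_subject, per_condition = run_synthetic_study(
    cfg, conditions=["mod180_naive", "mod90_naive", "mod0_control"]
)

cols = ["condition", "mean_auc_im", "mean_auc_opt", "im_t", "im_p", "auc_p"]
print(per_condition[cols].round(4).to_string(index=False))
print()
print("mean_auc_im: group-mean area under the ROC using Im(Z) per cycle")
print("  (0.5 = chance).  The phase-shifted conditions decode the percept")
print("  far above chance; the in-phase control cannot, because both")
print("  percepts see the same luminance signal.")
print("im_t / im_p: two-sided paired t-test on Im(mean Z) between")
print("  left-eye-reported and right-eye-reported cycles across subjects.")
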