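"""Run a small repeated train/test benchmark and summarize performance.

Mirrors the full evaluation protocol (fresh phantoms per repeat, retraining,
per-repeat means, mean ± SD across repeats) at desk scale: 3 repeats of
15 training / 5 test samples.  The full protocol (10 repeats of 80/40) is
what scripts/acceptance.py runs.
"""

from dceseg import RunConfig, run_experiment

summary = run_experiment(RunConfig(n_train=15, n_test=5, n_repeats=3, seed=7))

for key, label in (("aom", "AOM (Jaccard overlap)"),
                   ("cr", "CR  (% overlap, FP-penalized)"),
                   ("pm", "PM  (% of tumor recovered)")):
    entry = summary[key]
    per = ", ".join(f"{v:.3f}" for v in entry["per_repeat"])
    print(f"{label:32s} {entry['formatted']}   per repeat: {per}")
# Each repeat simulates an independent cohort; the SD shows run-to-run
# spread caused by phantom variability and hyperparameter selection.
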