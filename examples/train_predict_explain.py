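"""Train a model, predict held-out peptides, and explain the predictions.

The Shapley channel ranking should surface charge- and aromaticity-
related channels (isoelectric point, pKa, the charge block, aromatic
indicator), mirroring the compositional signal the generator plants.
"""

import numpy as np

import acpkit as a

bench = a.make_benchmark(a.GeneratorSpec(n_pos=80, n_neg=80, seed=7))
train_set, test_set = a.holdout_split(bench, 0.2, seed=7)

config = a.ModelConfig(
    scheme="mix", architecture="basic", n_units=16, dense_units=24,
    epochs=12, batch_size=16, seed=7,
)
model = a.train(config, train_set)

X_test = a.encode_dataset(test_set, "mix", model.standardization)
record = a.evaluate_predictions(model.forward(X_test), test_set.labels)
print(f"held-out: ACC {record.acc:.2f}%  Sen {record.sen:.2f}%  "
      f"Spc {record.spc:.2f}%  MCC {record.mcc:.3f}  AUC {record.auc:.3f}")

X_train = a.encode_dataset(train_set, "mix", model.standardization)
y = test_set.labels
idx = np.concatenate([np.flatnonzero(y == 1)[:4], np.flatnonzero(y == 0)[:4]])
report = a.shapley_attributions(
    model, X_test[idx], X_train[:80], n_perm=2, seed=7,
    sample_ids=[test_set.ids[i] for i in idx],
)
print(f"\nadditivity: worst |phi0 + sum(phi) - P(ACP)| = "
      f"{report.additivity_errors().max():.2e}")
print("top 5 channels by mean |phi|:")
for name, imp in report.ranking[:5]:
    print(f"  {name:28s} {imp:.4f}")
print("\nHigh-importance charge/aromaticity channels indicate the model")
print("decides from the planted compositional signal, not from noise.")
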