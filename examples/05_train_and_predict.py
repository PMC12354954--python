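"""Train one model and score new windows.

Fits the human-benchmark configuration on a training set, saves the model
archive, reloads it, and prints the Ψ-site probability of a few held-out
windows. Probabilities above 0.5 call the central uridine a Ψ site.
"""

import tempfile
from pathlib import Path

import numpy as np

from pseucnn import (GeneratorConfig, HUMAN_CONFIG, TrainedModel, build_model,
                     extract_features, feature_arrays, generate_dataset,
                     predict_site_probability, train)

train_set = generate_dataset(GeneratorConfig(n_pos=100, n_neg=100, seed=0))
test_set = generate_dataset(GeneratorConfig(n_pos=5, n_neg=5, seed=99))

X, y, _ = feature_arrays(extract_features(train_set))
spec = build_model(HUMAN_CONFIG, input_dim=X.shape[1])
model = train(spec, X, y, epochs=30, seed=0)
print(f"final training loss: {model.final_loss:.4f}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "model.npz"
    model.save(path)
    model = TrainedModel.load(path)

Xt, yt, ids = feature_arrays(extract_features(test_set))
probs = predict_site_probability(model, Xt)
for sid, label, p in zip(ids, yt, probs):
    print(f"{sid}: P(site) = {p:.3f}  true label = {label}")
acc = np.mean((probs >= 0.5) == yt)
print(f"held-out accuracy: {acc:.2f} (small n; see cross-validation for "
      "a proper estimate)")
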