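"""Tune the six architecture knobs by two-phase random search.

Each drawn configuration is screened with 5-fold cross-validation at
15 epochs (ACC primary, MCC tie-break); the winner is then fine-evaluated
with 10-fold cross-validation at 30 epochs. n_iter is kept small here so
the example runs in under a minute.
"""

from pseucnn import (GeneratorConfig, SearchSpace, extract_features,
                     feature_arrays, generate_dataset, random_search)

cfg = GeneratorConfig(n_pos=100, n_neg=100, window_length=21,
                      signal_strength=1.0, seed=0)
X, y, _ = feature_arrays(extract_features(generate_dataset(cfg)))

space = SearchSpace(n_iter=5, seed=0)  # the full space holds 648 combinations
trace = random_search(space, X, y)

print("screening leaderboard (ACC desc, MCC tie-break):")
print(trace.leaderboard()[["draw", "reshape_dim", "conv_kernel", "conv_stride",
                           "dense_layers", "dense_units", "activation",
                           "acc", "mcc"]].to_string(index=False))
print("\nwinner:", trace.best_hp)
print("final 10-fold evaluation:", trace.final.summary())
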