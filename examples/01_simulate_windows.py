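"""Generate a synthetic Ψ-site window dataset and sanity-check it.

Builds 100 positive + 100 negative 21-nt windows, all with a central U;
positives carry U-enriched flanks near the center, negatives A-enriched
flanks. Prints the class sizes and the central-uridine check.
"""

from pseucnn import GeneratorConfig, check_center_uridine, generate_dataset

cfg = GeneratorConfig(n_pos=100, n_neg=100, window_length=21,
                      signal_strength=1.0, seed=0)
sset = generate_dataset(cfg)
report = check_center_uridine(sset)

print(f"sequences: {len(sset)} (positives {int(sset.labels.sum())}, "
      f"negatives {int((1 - sset.labels).sum())}), window length {sset.max_length}")
print(f"central-U violations: {len(report.violations)}  "
      f"(0 means every window is a candidate uridine site)")
print("first positive:", sset.sequences[0].residues)
print("first negative:", sset.sequences[100].residues)
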