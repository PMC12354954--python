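"""Turn RNA windows into DFT amplitude features.

A 21-nt window has 20 overlapping dinucleotides; encoding it with the
free-energy and hydrophilicity tables and taking the modulus of each DFT
coefficient yields 2 x 20 = 40 features. The first amplitude of each block
is the DC component: the absolute sum of the physicochemical profile.
"""

from pseucnn import GeneratorConfig, extract_features, generate_dataset

sset = generate_dataset(GeneratorConfig(n_pos=5, n_neg=5, window_length=21, seed=0))
features = extract_features(sset)

n_feat = features.shape[1] - 2
print(f"feature matrix: {len(features)} rows x {n_feat} feature columns "
      "(40 expected for 21-nt windows; a 31-nt set would give 60)")
print("column order:", ", ".join(features.columns[2:5]), "...",
      ", ".join(features.columns[-3:]))
row = features.iloc[0]
print(f"{row['id']}: FreeEnergy_Amp_1 = {row['FreeEnergy_Amp_1']:.3f} "
      "(|sum of the 20 stacking free energies|, the DC term)")
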