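"""Simulate a wheat-like multi-environment trial and inspect its structure.

Generates a family-structured inbred panel with six environments whose
genetic correlations span from negative to 0.84, then prints per-environment
repeatability targets, the realised BLUE-level environment correlations, and
the across-environment heritability.
"""

import numpy as np

import sparsemet as sm

spec = sm.wheat_like_spec(n_lines=189, n_markers=2000, seed=1)
geno, truth, blues = sm.simulate_dataset(spec)

print(f"panel: {geno.n_lines} lines x {geno.n_markers} SNPs, "
      f"{spec.n_families} families, environments: {', '.join(spec.env_names)}")

corr = sm.env_correlations(blues)
off = corr.to_numpy()[np.triu_indices(6, 1)]
print(f"BLUE-level environment correlations: {off.min():.2f} .. {off.max():.2f}")
print("(these are attenuated relative to the genetic correlations by the "
      "square root of the product of the two repeatabilities)")

h2 = sm.cullis_heritability(blues)
print(f"across-environment heritability (Cullis): {h2:.2f}")
print("h2 reflects how strongly line differences persist across these "
      "partly discordant environments.")
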