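"""SNP QC and relationship matrices: VanRaden G and Rogers' distance.

Filters markers by minor allele frequency, builds the genomic relationship
matrix used by the prediction model, and summarises genetic diversity with
Rogers' distances.
"""

import numpy as np

import sparsemet as sm

spec = sm.wheat_like_spec(n_lines=120, n_markers=3000, seed=2, missing_rate=0.03)
geno = sm.simulate_genotypes(spec)

kept = sm.filter_snps(geno, maf_min=0.05, callrate_min=0.9)
print(f"QC: {geno.n_markers} -> {kept.n_markers} SNPs "
      f"(MAF >= 0.05, call rate >= 0.9)")

G = sm.vanraden_grm(kept)
d = np.diag(G.values)
print(f"G diagonal mean {d.mean():.2f} (near 2 for fully inbred lines, "
      "near 1 for an outbred equilibrium panel)")

D = sm.rogers_distance(kept)
off = D.values[np.triu_indices(kept.n_lines, 1)]
print(f"Rogers' distance between lines: {off.min():.3f} .. {off.max():.3f}")
print("small distances flag near-duplicate lines; family structure shows up "
      "as a bimodal distance distribution.")
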