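"""Enumerate sparse-phenotyping designs and draw CV2 masks.

Every 3-environment base combination can be extended by 1-3 of the remaining
environments; masking keeps exactly 3 observations per line so phenotyping
intensity (75/60/50% retention for 4/5/6 environments) matches the complete
3-environment trial.
"""

import sparsemet as sm

envs = [f"Y{y}_TOS{t}" for y in (1, 2, 3) for t in (1, 2)]
bases = sm.enumerate_base_combinations(envs, 3)
print(f"{len(bases)} base combinations of 3 environments out of {len(envs)}")

base = bases[0]
for size in (1, 2, 3):
    exts = sm.enumerate_extensions(base, envs, sizes=(size,))
    print(f"  {len(exts)} extensions of size {size} for {base.scenario_id}")

lines = [f"L{i:03d}" for i in range(100)]
for n_ext in (1, 2, 3):
    plan = sm.enumerate_extensions(base, envs, sizes=(n_ext,))[0]
    sc = sm.generate_mask(plan, lines, replicate_index=1, seed=7)
    print(f"{plan.n_envs}-environment scenario: {sc.retained.sum()} of "
          f"{sc.retained.size} cells retained "
          f"({100 * sc.retained_fraction():.0f}%), "
          f"{sm.masks_per_line(plan.n_envs, 3)} masked per line")
print("equal retained counts across scenarios = equal phenotyping budget.")
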