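"""Simulate a biparental F5 population with known cis-regulatory effects.

Two inbred parents are crossed and taken to the F5 by single seed descent
(four selfing generations), so each locus is heterozygous with probability
(1/2)^4 = 6.25%. A fifth of the triads carry a 2-fold cis effect on exactly
one homoeolog, linked to the parent-2 allele.
"""

import hebkit as hk

cfg = hk.SimConfig(n_triads=200, n_lines=50, seed=1)
sim = hk.simulate_population(cfg)

calls = sim.genotypes.calls.drop(columns=["P1_line", "P2_line"])
het = (calls == "HET").sum().sum() / (calls != "MISSING").sum().sum()
n_cis = (sim.truth["effect_type"] == "cis").sum()

print(f"simulated {cfg.n_triads} triads x {cfg.n_lines} F5 lines "
      f"x {cfg.n_replicates} replicates")
print(f"counts matrix: {sim.counts.values.shape[0]} genes "
      f"x {sim.counts.values.shape[1]} samples")
print(f"observed F5 heterozygosity: {het:.4f} (expected 0.0625 after four "
      f"selfing generations)")
print(f"{n_cis} triads carry a cis effect "
      f"(fold-change {cfg.cis_effect_size} on one homoeolog)")
# The truth table records which homoeolog is causal per triad -- the ground
# truth every downstream analysis is scored against.
print(sim.truth[sim.truth["effect_type"] == "cis"].head(3)
      [["causal_homoeolog", "effect_size"]])
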