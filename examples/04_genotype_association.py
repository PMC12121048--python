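"""Associate homoeolog expression with the inherited parental genotype.

SNP calls inside each gene are consolidated to one genotype per line
(conflicts -> missing), overly heterozygous lines are dropped, and each
expressed homoeolog with calls for > 80% of lines is tested by one-way
ANOVA of per-line mean expression on genotype class.
"""

import hebkit as hk
from hebkit import assoc

sim = hk.simulate_population(hk.SimConfig(n_triads=400, seed=1))
gm = hk.map_snps_to_genes(sim.genotypes, sim.triads)
gm = assoc.filter_snps_basic(gm, "P1_line", "P2_line")
print("SNP filter log:", gm.filter_log)

gene_calls = assoc.consolidate_gene_genotype(gm)
het = assoc.flag_heterozygous_lines(gene_calls)
print(f"line heterozygosity: median {het.median():.3f}, "
      f"{len(het.attrs['excluded'])} lines excluded (> 15%)")

cpm = hk.tmm_cpm(sim.counts)
table = assoc.homoeolog_genotype_anova(cpm, gene_calls, sim.triads)
tested = table[table["flag"] == ""]
print(f"\n{len(tested)} homoeologs tested, "
      f"{int(tested['significant'].sum())} associated at q < 0.05")

merged = table.reset_index().merge(sim.truth[["causal_homoeolog"]],
                                   left_on="triad_id", right_index=True)
causal = merged[merged["subgenome"] == merged["causal_homoeolog"]]
causal_tested = causal[causal["flag"] == ""]
print(f"of {len(causal_tested)} testable causal homoeologs, "
      f"{int(causal_tested['significant'].sum())} recovered — the ANOVA "
      "pinpoints which homoeolog of the triad the inherited variant acts on")

sd = assoc.sd_rank_analysis(table.reset_index())
print(f"associated homoeolog is the most variable one in "
      f"{100 * sd['frac_assoc_max_sd']:.0f}% of triads "
      f"(Wilcoxon on log SD: p = {sd['wilcoxon_p']:.2e})")
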