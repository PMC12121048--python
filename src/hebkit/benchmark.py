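"""Parameter-recovery evaluation on synthetic populations with known truth.

These routines run the full analysis on a simulated population and score it
against the generator's truth table: line-effect power and null rate, causal
homoeolog identification, divergent-triad combination structure, DFO
segregation balance, and cis-eQTL precision/recall. They are the package's
own benchmark of itself and are reused by the acceptance machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, eqtl, inheritance, quant
from .io import ExpressionMatrix, map_snps_to_genes, tmm_cpm
from .simulate import PARENT1, PARENT2, SimConfig, SimResult, simulate_population


def causal_gene_ids(truth: pd.DataFrame, triads) -> set[str]:
    """Gene IDs of the causal homoeolog of every cis triad."""
    out = set()
    cis = truth[truth["effect_type"] == "cis"]
    for tid, row in cis.iterrows():
        out.add(triads.triads.at[tid, f"gene_{row['causal_homoeolog']}"])
    return out


def recovery_suite(seed: int, config: SimConfig | None = None,
                   line_fdr: float = 1e-4, assoc_fdr: float = 0.05,
                   min_parental_distance: float = 0.2) -> dict:
    """Simulate one population at the canonical design and score recovery.

    Returns a flat dict of metrics; see the keys for what is measured. The
    expression filter is applied before the line-effect scan; the
    replicate-variability filter is not (its threshold is stringent enough
    to dominate retention and is evaluated separately).
    """
    cfg = config or SimConfig(seed=seed)
    sim = simulate_population(cfg)
    truth = sim.truth
    heb = quant.heb_table(sim.tpm, sim.triads)
    expressed = quant.filter_expressed_triads(sim.tpm, sim.triads)
    heb_e = heb[heb["triad_id"].isin(set(expressed))]
    f5 = heb_e[~heb_e["line"].isin([PARENT1, PARENT2])]
    effects = inheritance.line_effect_scan(f5, fdr=line_fdr)
    cis = (truth["effect_type"] == "cis").reindex(effects.index).fillna(False)
    sig = effects["significant"]
    metrics = {
        "n_triads_tested": int(len(effects)),
        "line_effect_power": float(sig[cis].mean()),
        "null_sig_rate": float(sig[~cis].mean()),
    }

    # inheritance patterns on significant triads
    bias = inheritance.bias_distance_table(heb_e, PARENT1, PARENT2)
    sig_ids = set(effects.index[sig])
    calls = inheritance.call_triad_pattern(bias[bias["triad_id"].isin(sig_ids)])
    seg = inheritance.segregation_summary(calls)
    metrics["n_dual_dfo_triads"] = int(seg["n_triads"])
    metrics["dfo_split_mean_frac"] = float(seg.get("mean_frac_a", np.nan))

    # genotype association
    gm = map_snps_to_genes(sim.genotypes, sim.triads)
    gm = assoc.filter_snps_basic(gm, PARENT1, PARENT2)
    gene_calls = assoc.consolidate_gene_genotype(gm)
    het = assoc.flag_heterozygous_lines(gene_calls)
    keep = [l for l in gene_calls.columns if l not in het.attrs["excluded"]]
    cpm = tmm_cpm(sim.counts)
    anova = assoc.homoeolog_genotype_anova(
        cpm, gene_calls[keep], sim.triads, expressed_triads=expressed,
        fdr=assoc_fdr).reset_index()
    by_key = anova.set_index(["triad_id", "subgenome"])
    detected_cis = [t for t in sig_ids
                    if truth.at[t, "effect_type"] == "cis"]
    ident = testable = 0
    for t in detected_cis:
        key = (t, truth.at[t, "causal_homoeolog"])
        if key in by_key.index and by_key.loc[key, "flag"] == "":
            testable += 1
            ident += int(bool(by_key.loc[key, "significant"]))
    metrics["n_detected_cis_triads"] = len(detected_cis)
    metrics["causal_testable_frac"] = (testable / len(detected_cis)
                                       if detected_cis else np.nan)
    metrics["causal_id_rate_testable"] = (ident / testable if testable
                                          else np.nan)
    metrics["causal_id_rate_all_detected"] = (ident / len(detected_cis)
                                              if detected_cis else np.nan)

    # combination table over divergent triads
    pdist = bias.groupby("triad_id")["parental_distance"].first()
    combo = assoc.count_associated_homoeologs(
        anova[anova["triad_id"].isin(sig_ids)],
        pdist.reindex(list(sig_ids)).dropna(),
        min_parental_distance=min_parental_distance)
    total = combo.loc["total", "n_triads"]
    metrics["n_divergent_assoc_triads"] = int(total)
    metrics["one_homoeolog_frac"] = (
        float(combo.loc["one_homoeolog_total", "n_triads"] / total)
        if total else np.nan)
    return metrics


def eqtl_suite(seed: int, config: SimConfig | None = None,
               fdr: float = 1e-3) -> dict:
    """cis-eQTL precision/recall on a cis population plus a null scan."""
    cfg = config or SimConfig(seed=seed)
    sim = simulate_population(cfg)

    def scan(s: SimResult) -> pd.DataFrame:
        gm = eqtl.filter_snps_eqtl(s.genotypes, PARENT1, PARENT2)
        cpm = tmm_cpm(s.counts)
        log_cpm = ExpressionMatrix(np.log2(cpm.values + 1.0), "CPM",
                                   cpm.samples, cpm.lengths)
        resid = eqtl.residualize_expression(log_cpm)
        return eqtl.eqtl_scan(resid, gm, s.triads, fdr=fdr)

    records = scan(sim)
    causal = causal_gene_ids(sim.truth, sim.triads)
    cis_rec = records[records["class"] == "cis"]
    metrics = {
        "n_eqtl_records": int(len(records)),
        "n_cis_records": int(len(cis_rec)),
        "cis_precision": (float(cis_rec["gene_id"].isin(causal).mean())
                          if len(cis_rec) else np.nan),
        "cis_recall_triads": (len(set(cis_rec["gene_id"]) & causal)
                              / len(causal) if causal else np.nan),
        "slope_sign_correct_frac": (
            float((records.loc[records["gene_id"].isin(causal)
                               & (records["class"] == "cis"),
                               "slope"] > 0).mean())
            if len(cis_rec) else np.nan),
    }

    null_cfg = SimConfig(n_triads=min(cfg.n_triads, 300),
                         prop_cis_triads=0.0,
                         seed=(seed + 1_000_003) % 2**31)
    null_records = scan(simulate_population(null_cfg))
    metrics["null_scan_false_discoveries"] = int(len(null_records))
    return metrics
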