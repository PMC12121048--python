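"""End-to-end orchestration: simulate -> quant -> inherit -> genoassoc -> eqtl.

Every threshold lives in :class:`RunConfig` (defaults are the canonical
analysis settings) and is echoed into a YAML run manifest along with package
versions, the seed and every filter count, so a run is reproducible and
auditable from its output directory alone. All outputs are plain TSV.
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, eqtl, inheritance, quant, simulate as sim
from .io import (ExpressionMatrix, GenotypeMatrix, TriadTable, counts_to_tpm,
                 map_snps_to_genes, read_expression, read_triads, read_vcf,
                 tmm_cpm)


@dataclass
class RunConfig:
    """All thresholds of the pipeline, with the canonical defaults."""

    tpm_min: float = 0.5          # triad expression filter (mean TPM per line)
    rep_dist_max: float = 0.01    # replicate ternary-distance filter
    rep_dist_method: str = "mean_pairwise"
    line_fdr: float = 1e-4        # line-effect LRT, BH q threshold
    dfo_hi: float = 0.2           # divergent-from-parent distance
    dfo_lo: float = 0.1           # similar-to-parent distance
    min_lines: int = 15           # lines required to support a triad pattern
    assoc_fdr: float = 0.05       # homoeolog-genotype ANOVA, BH q threshold
    call_rate: float = 0.8        # genotype call-rate gate for the ANOVA
    het_max_line: float = 0.15    # line-level heterozygosity exclusion
    eqtl_fdr: float = 1e-3        # eQTL scan, BH q threshold
    cis_window: int = 1_000_000   # cis distance (bp)
    maf_min: float = 0.05         # eQTL SNP minor allele frequency
    het_max_snp: float = 0.03     # eQTL SNP heterozygosity
    miss_max: float = 0.5         # eQTL SNP missingness
    depth_min: int = 3            # eQTL depth mask
    assoc_depth_min: int = 10     # genotype-association depth filter
    assoc_depth_min_samples: int = 5
    assoc_miss_max: float = 0.10
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimConfig overrides


@dataclass
class RunData:
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    genotypes: GenotypeMatrix
    triads: TriadTable
    parent1: str
    parent2: str
    truth: pd.DataFrame | None = None


def load_inputs(counts_tsv, metadata_tsv, lengths_tsv, triads_tsv, bed,
                vcf, parent1: str, parent2: str) -> RunData:
    counts = read_expression(counts_tsv, metadata_tsv, units="counts",
                             lengths_tsv=lengths_tsv)
    tt = read_triads(triads_tsv, bed)
    gm = read_vcf(vcf, parent1, parent2)
    return RunData(counts, counts_to_tpm(counts), gm, tt, parent1, parent2)


def run_all(cfg: RunConfig, out_dir: str | Path,
            data: RunData | None = None) -> dict:
    """Execute every stage, writing TSV outputs and a manifest.

    With ``data=None`` a population is simulated first (SimConfig overrides
    from ``cfg.simulation``, seeded by ``cfg.seed``). Identical config and
    seed give identical outputs. Returns the in-memory stage results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hebkit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": cfg.seed,
        "thresholds": {k: v for k, v in asdict(cfg).items()
                       if k not in ("simulation", "seed")},
        "filter_counts": {},
    }
    if data is None:
        sim_cfg = sim.SimConfig(seed=cfg.seed, **cfg.simulation)
        manifest["simulation"] = asdict(sim_cfg)
        population = sim.simulate_population(sim_cfg)
        sim.write_population(population, out / "simulated")
        data = RunData(population.counts, population.tpm, population.genotypes,
                       population.triads, sim.PARENT1, sim.PARENT2,
                       population.truth)

    # ---- quant ------------------------------------------------------------
    heb = quant.heb_table(data.tpm, data.triads)
    expressed = quant.filter_expressed_triads(data.tpm, data.triads,
                                              min_tpm=cfg.tpm_min)
    heb_expr = heb[heb["triad_id"].isin(set(expressed))]
    stable = quant.filter_replicate_variability(
        heb_expr, max_distance=cfg.rep_dist_max, method=cfg.rep_dist_method)
    manifest["filter_counts"]["triads_total"] = int(len(data.triads.triad_ids))
    manifest["filter_counts"]["triads_expressed"] = int(len(expressed))
    manifest["filter_counts"]["triads_replicate_stable"] = int(len(stable))
    heb_kept = heb_expr[heb_expr["triad_id"].isin(set(stable))]
    heb_kept.to_csv(out / "heb_table.tsv", sep="\t", index=False,
                    float_format="%.6g")

    results: dict = {"heb": heb_kept, "expressed": expressed, "stable": stable}

    # ---- inherit ------------------------------------------------------------
    roles = data.tpm.samples["role"]
    f5_lines = set(data.tpm.samples.loc[roles == "F5", "line"])
    heb_f5 = heb_kept[heb_kept["line"].isin(f5_lines)]
    if len(heb_f5):
        effects = inheritance.line_effect_scan(heb_f5, fdr=cfg.line_fdr)
        bias = inheritance.bias_distance_table(
            heb_kept, data.parent1, data.parent2, hi=cfg.dfo_hi, lo=cfg.dfo_lo)
        sig = set(effects.index[effects["significant"] == True])  # noqa: E712
        bias_sig = bias[bias["triad_id"].isin(sig)]
        calls = inheritance.call_triad_pattern(bias_sig, min_lines=cfg.min_lines) \
            if len(bias_sig) else pd.DataFrame()
        effects.to_csv(out / "line_effects.tsv", sep="\t", float_format="%.6g")
        bias.to_csv(out / "bias_distances.tsv", sep="\t", index=False,
                    float_format="%.6g")
        if len(calls):
            calls.to_csv(out / "triad_patterns.tsv", sep="\t",
                         float_format="%.6g")
        results.update(effects=effects, bias=bias, patterns=calls)
        manifest["filter_counts"]["triads_line_significant"] = int(len(sig))

    # ---- genoassoc ----------------------------------------------------------
    gm = map_snps_to_genes(data.genotypes, data.triads)
    gm_basic = assoc.filter_snps_basic(
        gm, data.parent1, data.parent2, max_missing=cfg.assoc_miss_max,
        depth_min=cfg.assoc_depth_min,
        depth_min_samples=cfg.assoc_depth_min_samples)
    gene_calls = assoc.consolidate_gene_genotype(gm_basic)
    het = assoc.flag_heterozygous_lines(gene_calls, max_het=cfg.het_max_line)
    keep_lines = [l for l in gene_calls.columns
                  if l not in het.attrs["excluded"]]
    cpm = tmm_cpm(data.counts)
    anova = assoc.homoeolog_genotype_anova(
        cpm, gene_calls[keep_lines], data.triads, expressed_triads=stable,
        call_rate=cfg.call_rate, fdr=cfg.assoc_fdr)
    anova.to_csv(out / "homoeolog_assoc.tsv", sep="\t", float_format="%.6g")
    gene_calls.to_csv(out / "gene_genotypes.tsv", sep="\t",
                      index_label="gene_id")
    manifest["filter_counts"]["snp_basic"] = gm_basic.filter_log
    manifest["filter_counts"]["heterozygous_lines_excluded"] = \
        het.attrs["excluded"]
    results.update(gene_calls=gene_calls, anova=anova, het_fraction=het)
    if "bias" in results and len(results["bias"]):
        pdist = results["bias"].groupby("triad_id")["parental_distance"].first()
        table1 = assoc.count_associated_homoeologs(anova.reset_index(), pdist)
        table1.to_csv(out / "assoc_combo_table.tsv", sep="\t",
                      float_format="%.6g")
        results["combo_table"] = table1

    # ---- eqtl ---------------------------------------------------------------
    gm_eqtl = eqtl.filter_snps_eqtl(
        data.genotypes, data.parent1, data.parent2, depth_min=cfg.depth_min,
        max_missing=cfg.miss_max, max_het=cfg.het_max_snp,
        maf_min=cfg.maf_min)
    log_cpm = ExpressionMatrix(np.log2(cpm.values + 1.0), "CPM", cpm.samples,
                               cpm.lengths)
    resid = eqtl.residualize_expression(log_cpm)
    records = eqtl.eqtl_scan(resid, gm_eqtl, data.triads, fdr=cfg.eqtl_fdr,
                             cis_window=cfg.cis_window)
    tally = eqtl.tally_by_subgenome(records)
    records.to_csv(out / "eqtl_records.tsv", sep="\t", index=False,
                   float_format="%.6g")
    tally.to_csv(out / "eqtl_tally.tsv", sep="\t", index=False)
    manifest["filter_counts"]["snp_eqtl"] = gm_eqtl.filter_log
    manifest["filter_counts"]["eqtl_records"] = int(len(records))
    results.update(eqtl_records=records, eqtl_tally=tally)

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results
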