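"""Synthetic biparental F5 populations with known regulatory ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a hexaploid with A/B/D subgenomes:

* two inbred parents plus ``n_lines`` F5 lines derived by single-seed descent
  (four selfing generations from a fully heterozygous F1, so residual
  heterozygosity (1/2)^4 per locus);
* ``n_triads`` expressed triads, a fraction of which carry a *cis* effect —
  a multiplicative fold-change on exactly one homoeolog tied to the parent-2
  allele at that gene's own locus (heterozygotes at the geometric midpoint);
* negative-binomial counts around line/batch-specific means, TPM derived from
  counts and gene lengths;
* RNA-seq-style genotype observation: per-SNP read depth is Poisson with mean
  proportional to the gene's expression, and calls below a depth cutoff are
  MISSING — lowly expressed homoeologs lose genotype information, as happens
  with genotyping from transcripts.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenotypeMatrix, TriadTable, counts_to_tpm
from . import io as _io

PARENT1 = "P1_line"
PARENT2 = "P2_line"


@dataclass
class SimConfig:
    """Parameters of the simulated population.

    Defaults describe the population the analysis was designed around:
    50 F5 lines in 3 replicated batches after 4 selfing generations, with a
    fifth of triads carrying a 2-fold single-homoeolog cis effect.
    """

    n_triads: int = 1000
    n_lines: int = 50
    n_replicates: int = 3
    selfing_generations: int = 4
    prop_cis_triads: float = 0.20
    cis_effect_size: float = 2.0
    #: log-normal baseline of per-homoeolog mean TPM: (mean of log, sd of log)
    baseline_log_tpm: tuple[float, float] = (3.0, 1.0)
    #: negative-binomial dispersion phi (variance = mu + phi mu^2); 0.01 is
    #: the canonical biological CV ~0.1 for genetically identical replicates
    dispersion: float = 0.01
    #: per-batch global library factors; batches coincide with replicates
    batch_effects: tuple[float, ...] = (1.0, 1.1, 0.9)
    #: sd of gene-specific log-normal batch wobble
    batch_gene_sigma: float = 0.05
    library_size: int = 2_000_000
    #: SNPs per gene are drawn uniformly from this inclusive range
    snps_per_gene: tuple[int, int] = (1, 2)
    #: genotype read depth mean = depth_per_tpm * line-mean TPM of the gene;
    #: 0.05 puts a median-expression gene around 10x per-SNP coverage
    depth_per_tpm: float = 0.05
    min_call_depth: int = 3
    #: share one genotype per (line, chromosome) instead of per gene; creates
    #: long-range within-chromosome structure (trans-s) for eQTL tests
    chromosome_blocks: bool = False
    n_tray_columns: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_triads", "n_lines", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if not 0.0 <= self.prop_cis_triads <= 1.0:
            raise ValueError("prop_cis_triads must be in [0, 1]")
        if self.cis_effect_size <= 0:
            raise ValueError("cis_effect_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if len(self.batch_effects) < self.n_replicates:
            raise ValueError("need a batch factor per replicate")


@dataclass
class SimResult:
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    genotypes: GenotypeMatrix
    triads: TriadTable
    samples: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def ssd_genotype_probs(selfing_generations: int) -> tuple[float, float, float]:
    """Genotype probabilities at one locus after single-seed descent.

    Starting from a fully heterozygous F1, each selfing generation halves the
    heterozygote probability: h_g = (1/2)^g, and the two homozygote classes
    share the remainder equally.
    """
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    p_het = 0.5 ** selfing_generations
    p_hom = (1.0 - p_het) / 2.0
    return (p_hom, p_het, p_hom)


def _make_triad_table(cfg: SimConfig, rng: np.random.Generator) -> TriadTable:
    triad_ids = [f"triad{i:05d}" for i in range(cfg.n_triads)]
    rows, gene_rows = {}, []
    lengths = np.clip(
        rng.lognormal(np.log(1500), 0.35, size=3 * cfg.n_triads), 300, None
    ).astype(int)
    k = 0
    for i, tid in enumerate(triad_ids):
        group = i % 7 + 1
        slot = i // 7
        genes = {}
        for sub in "ABD":
            gid = f"g{i:05d}{sub}"
            chrom = f"chr{group}{sub}"
            start = 1_000_000 + slot * 200_000
            end = start + int(lengths[k]) - 1
            gene_rows.append((gid, chrom, start, end, sub))
            genes[sub] = gid
            k += 1
        rows[tid] = genes
    triads = pd.DataFrame(
        {"gene_A": [rows[t]["A"] for t in triad_ids],
         "gene_B": [rows[t]["B"] for t in triad_ids],
         "gene_D": [rows[t]["D"] for t in triad_ids]},
        index=pd.Index(triad_ids, name="triad_id"),
    )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "subgenome"]
    ).set_index("gene_id")
    return TriadTable(triads, genes)


def simulate_population(cfg: SimConfig) -> SimResult:
    """Simulate expression, genotypes and ground truth for one population."""
    rng = np.random.default_rng(cfg.seed)
    tt = _make_triad_table(cfg, rng)
    genes = tt.genes
    gene_ids = list(genes.index)
    n_genes = len(gene_ids)
    lengths = genes["end"] - genes["start"] + 1

    # --- ground truth ------------------------------------------------------
    base_tpm = rng.lognormal(*cfg.baseline_log_tpm, size=n_genes)
    n_cis = int(round(cfg.prop_cis_triads * cfg.n_triads))
    cis_triads = rng.choice(cfg.n_triads, size=n_cis, replace=False)
    causal = np.array(["none"] * cfg.n_triads, dtype=object)
    causal[cis_triads] = rng.choice(list("ABD"), size=n_cis)
    # effect multiplier on the causal gene when the parent-2 allele is carried
    effect_mult = np.ones(n_genes)
    causal_gene_idx = {}
    for t_i in cis_triads:
        sub = causal[t_i]
        g_i = 3 * t_i + "ABD".index(sub)
        effect_mult[g_i] = cfg.cis_effect_size
        causal_gene_idx[t_i] = g_i

    # --- samples -----------------------------------------------------------
    lines = [PARENT1, PARENT2] + [f"F5_{i:03d}" for i in range(cfg.n_lines)]
    roles = ["parent1", "parent2"] + ["F5"] * cfg.n_lines
    sample_rows = []
    for line, role in zip(lines, roles):
        for r in range(cfg.n_replicates):
            sample_rows.append({
                "sample": f"{line}_r{r + 1}", "line": line,
                "replicate": f"rep{r + 1}", "batch": f"batch{r + 1}",
                "column": f"col{rng.integers(1, cfg.n_tray_columns + 1)}",
                "role": role,
            })
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # --- genotypes per line and gene locus ---------------------------------
    p_hom1, p_het, p_hom2 = ssd_genotype_probs(cfg.selfing_generations)
    n_f5 = cfg.n_lines
    if cfg.chromosome_blocks:
        chrom_names = sorted(genes["chrom"].unique())
        block = rng.choice(3, size=(len(chrom_names), n_f5), p=[p_hom1, p_het, p_hom2])
        chrom_idx = {c: i for i, c in enumerate(chrom_names)}
        geno = np.stack([block[chrom_idx[genes.at[g, "chrom"]]] for g in gene_ids])
    else:
        geno = rng.choice(3, size=(n_genes, n_f5), p=[p_hom1, p_het, p_hom2])
    # columns: parent1 (all 0), parent2 (all 2), then F5 lines
    geno_full = np.concatenate(
        [np.zeros((n_genes, 1), int), np.full((n_genes, 1), 2), geno], axis=1
    )

    # --- expected expression per line --------------------------------------
    # multiplicative effect: dose 0 -> 1, dose 1 -> sqrt(mult), dose 2 -> mult
    log_mult = np.log(effect_mult)[:, None] * (geno_full / 2.0)
    line_tpm = base_tpm[:, None] * np.exp(log_mult)  # genes x lines

    # --- counts per sample --------------------------------------------------
    batch_wobble = np.exp(
        rng.normal(0.0, cfg.batch_gene_sigma, size=(n_genes, cfg.n_replicates))
    )
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    lengths_arr = lengths.to_numpy()
    phi = cfg.dispersion
    for j, (sname, srow) in enumerate(samples.iterrows()):
        li = lines.index(srow["line"])
        r = int(srow["replicate"][3:]) - 1
        rel = line_tpm[:, li] * lengths_arr * batch_wobble[:, r]
        mu = rel / rel.sum() * cfg.library_size * cfg.batch_effects[r]
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples.index)
    em_counts = ExpressionMatrix(counts_df.astype(float), "counts", samples,
                                 lengths.astype(float))
    em_tpm = counts_to_tpm(em_counts)

    # --- genotype observation (SNPs with expression-driven depth) ----------
    line_mean_tpm = em_tpm.line_means()[lines]  # genes x lines, sim order
    snp_rows, snp_calls, snp_depth = [], [], []
    lo, hi = cfg.snps_per_gene
    n_snps = rng.integers(lo, hi + 1, size=n_genes)
    call_name = np.array(["P1", "HET", "P2"], dtype=object)
    for g_i, gid in enumerate(gene_ids):
        g = genes.loc[gid]
        for s_i in range(n_snps[g_i]):
            pos = int(rng.integers(g["start"], g["end"] + 1))
            snp_id = f"snp_{gid}_{s_i}"
            mean_depth = cfg.depth_per_tpm * line_mean_tpm.loc[gid].to_numpy()
            depth = rng.poisson(np.clip(mean_depth, 0, None))
            calls = call_name[geno_full[g_i]].copy()
            # heterozygotes are observed through binomial allele sampling of
            # the reads: with few reads a het is miscalled homozygous
            het = geno_full[g_i] == 1
            if het.any():
                ref_reads = rng.binomial(depth[het], 0.5)
                obs = np.where(ref_reads == depth[het], "P1",
                               np.where(ref_reads == 0, "P2", "HET"))
                calls[het] = obs
            calls[depth < cfg.min_call_depth] = "MISSING"
            snp_rows.append((snp_id, g["chrom"], pos, gid))
            snp_calls.append(calls)
            snp_depth.append(depth)
    idx = pd.Index([r[0] for r in snp_rows], name="snp_id")
    snps = pd.DataFrame(
        {"chrom": [r[1] for r in snp_rows], "pos": [r[2] for r in snp_rows],
         "gene": pd.array([r[3] for r in snp_rows], dtype="object")},
        index=idx,
    )
    line_cols = list(line_mean_tpm.columns)
    gm = GenotypeMatrix(
        snps,
        pd.DataFrame(snp_calls, index=idx, columns=line_cols),
        pd.DataFrame(snp_depth, index=idx, columns=line_cols),
    )

    # --- truth table --------------------------------------------------------
    truth_rows = []
    for t_i, tid in enumerate(tt.triad_ids):
        g_slice = slice(3 * t_i, 3 * t_i + 3)
        p1 = base_tpm[g_slice].copy()
        p2 = base_tpm[g_slice] * effect_mult[g_slice]
        truth_rows.append({
            "triad_id": tid,
            "causal_homoeolog": causal[t_i],
            "effect_type": "cis" if causal[t_i] != "none" else "none",
            "effect_size": cfg.cis_effect_size if causal[t_i] != "none" else 1.0,
            "p1_f_A": p1[0] / p1.sum(), "p1_f_B": p1[1] / p1.sum(),
            "p1_f_D": p1[2] / p1.sum(),
            "p2_f_A": p2[0] / p2.sum(), "p2_f_B": p2[1] / p2.sum(),
            "p2_f_D": p2[2] / p2.sum(),
        })
    truth = pd.DataFrame(truth_rows).set_index("triad_id")
    assert ((truth["causal_homoeolog"] == "none")
            == (truth["effect_type"] == "none")).all()
    return SimResult(em_counts, em_tpm, gm, tt, samples, truth, cfg)


def write_population(sim: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write all simulated tables as plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv", "tpm": out / "tpm.tsv",
        "metadata": out / "samples.tsv", "lengths": out / "gene_lengths.tsv",
        "triads": out / "triads.tsv", "bed": out / "genes.bed",
        "vcf": out / "genotypes.vcf", "calls": out / "genotype_calls.tsv",
        "depth": out / "genotype_depth.tsv", "snps": out / "snps.tsv",
        "truth": out / "truth.tsv",
    }
    _io.write_expression(sim.counts, paths["counts"], paths["metadata"])
    _io.write_expression(sim.tpm, paths["tpm"])
    sim.counts.lengths.rename("length").to_csv(
        paths["lengths"], sep="\t", index_label="gene_id"
    )
    _io.write_triads(sim.triads, paths["triads"], paths["bed"])
    _io.write_vcf(sim.genotypes, paths["vcf"], PARENT1, PARENT2)
    _io.write_genotype_tsv(sim.genotypes, paths["calls"], paths["depth"],
                           paths["snps"])
    sim.truth.to_csv(paths["truth"], sep="\t", float_format="%.10g")
    return paths
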