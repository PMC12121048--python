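"""Gene-level genotyping from transcript SNPs and expression-genotype tests.

SNP calls derived from RNA-seq are consolidated to one call per gene and
line (conflicting SNPs within a gene make that line MISSING for the gene),
suspiciously heterozygous lines are excluded, and each expressed homoeolog
with sufficient call rate is tested for association between its per-line
mean expression and the inherited genotype class by one-way ANOVA
(heterozygotes form their own class). Summaries mirror the standard
questions: in triads with divergent parental HEB, how many homoeologs per
triad carry an association, and is the associated homoeolog the most
variable one?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GenotypeMatrix, TriadTable

COMBOS = ("A", "B", "D", "A&B", "A&D", "B&D", "A&B&D")


# ---------------------------------------------------------------------------
# SNP and line filtering


def filter_snps_basic(gm: GenotypeMatrix, parent1: str, parent2: str,
                      f5_lines: list[str] | None = None,
                      max_missing: float = 0.10, depth_min: int = 10,
                      depth_min_samples: int = 5) -> GenotypeMatrix:
    """Quality filters for genotype-association SNPs.

    Keeps SNPs with < ``max_missing`` missing calls among the F5 lines, read
    depth >= ``depth_min`` in at least ``depth_min_samples`` samples, and
    parents homozygous for different alleles (polarized calls: parent1 = P1,
    parent2 = P2). Removal counts per rule go to ``filter_log``.
    """
    if f5_lines is None:
        f5_lines = [c for c in gm.calls.columns if c not in (parent1, parent2)]
    calls_f5 = gm.calls[f5_lines]
    missing_frac = (calls_f5 == "MISSING").mean(axis=1)
    ok_missing = missing_frac < max_missing
    ok_depth = (gm.depth >= depth_min).sum(axis=1) >= depth_min_samples
    ok_parents = (gm.calls[parent1] == "P1") & (gm.calls[parent2] == "P2")
    keep = ok_missing & ok_depth & ok_parents
    out = gm.subset(gm.snps.index[keep])
    out.filter_log.update({
        "removed_missingness": int((~ok_missing).sum()),
        "removed_depth": int((~ok_depth).sum()),
        "removed_parents_not_informative": int((~ok_parents).sum()),
        "kept": int(keep.sum()),
    })
    return out


def consolidate_gene_genotype(gm: GenotypeMatrix) -> pd.DataFrame:
    """One genotype call per (gene, line) from the gene's SNPs.

    If every non-missing SNP call in the gene agrees for a line, that call is
    used; conflicting calls yield MISSING for that line (the line, not the
    gene, is disqualified). Genes with no mapped SNP produce no record.
    The result is order-invariant in the SNP input order.
    """
    has_gene = gm.snps["gene"].notna()
    rows, genes = [], []
    for gene, snp_ids in gm.snps.index[has_gene].groupby(
            gm.snps.loc[has_gene, "gene"]).items():
        sub = gm.calls.loc[snp_ids]
        consolidated = []
        for s in sub.columns:
            vals = set(sub[s]) - {"MISSING"}
            consolidated.append(vals.pop() if len(vals) == 1 else "MISSING")
        rows.append(consolidated)
        genes.append(gene)
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                       columns=gm.calls.columns)
    return out.sort_index()


def flag_heterozygous_lines(gene_calls: pd.DataFrame,
                            max_het: float = 0.15) -> pd.Series:
    """HET fraction per line (of non-missing gene calls); excluded if above
    ``max_het``. Returns the fraction with an ``excluded`` attribute list.

    The default cutoff 0.15 sits well above the single-seed-descent
    expectation at F5 ((1/2)^4 = 0.0625) but below grossly contaminated or
    outcrossed lines.
    """
    non_missing = (gene_calls != "MISSING").sum(axis=0)
    het = (gene_calls == "HET").sum(axis=0)
    frac = (het / non_missing.replace(0, np.nan)).fillna(0.0).rename("het_fraction")
    frac.attrs["excluded"] = list(frac.index[frac > max_het])
    frac.attrs["max_het"] = max_het
    return frac


# ---------------------------------------------------------------------------
# association tests


def homoeolog_genotype_anova(expr: ExpressionMatrix, gene_calls: pd.DataFrame,
                             tt: TriadTable, expressed_triads=None,
                             lines: list[str] | None = None,
                             call_rate: float = 0.8,
                             fdr: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of per-line mean expression on inherited genotype.

    A homoeolog is testable when its triad passed the expression filter and
    genotype calls cover > ``call_rate`` of the lines. HET is its own class;
    classes need >= 2 lines to count. Untestable or constant-expression
    homoeologs are kept in the output with a flag. BH correction runs across
    all tested homoeologs; ``significant`` marks q < ``fdr``.
    """
    long = tt.genes_long()
    if expressed_triads is not None:
        long = long[long["triad_id"].isin(set(expressed_triads))]
    line_expr = expr.line_means(roles=("F5",))
    if lines is not None:
        line_expr = line_expr[[l for l in line_expr.columns if l in set(lines)]]
    test_lines = [l for l in line_expr.columns if l in gene_calls.columns]
    rows = []
    for _, rec in long.iterrows():
        gene = rec["gene_id"]
        row = {"gene_id": gene, "triad_id": rec["triad_id"],
               "subgenome": rec["subgenome"], "p": np.nan, "stat": np.nan,
               "flag": "", "n_lines": 0, "sd_expression": np.nan}
        if gene not in gene_calls.index or gene not in line_expr.index:
            row["flag"] = "no_genotype"
            rows.append(row)
            continue
        calls = gene_calls.loc[gene, test_lines]
        expr_vals = line_expr.loc[gene, test_lines]
        called = calls != "MISSING"
        row["sd_expression"] = float(expr_vals.std(ddof=1))
        if called.mean() <= call_rate:
            row["flag"] = "low_call_rate"
            rows.append(row)
            continue
        groups = [expr_vals[called & (calls == g)].to_numpy()
                  for g in ("P1", "P2", "HET")]
        groups = [g for g in groups if len(g) >= 2]
        row["n_lines"] = int(called.sum())
        for g, name in zip(("P1", "P2", "HET"), ("P1", "P2", "HET")):
            vals = expr_vals[called & (calls == g)]
            row[f"mean_{name}"] = float(vals.mean()) if len(vals) else np.nan
        if len(groups) < 2:
            row["flag"] = "single_class"
        elif all(np.ptp(g) == 0 for g in groups) and \
                np.ptp(np.concatenate(groups)) == 0:
            row["p"], row["stat"], row["flag"] = 1.0, 0.0, "constant"
        else:
            f, p = stats.f_oneway(*groups)
            if np.isnan(p):  # zero within-group variance etc.
                row["p"], row["stat"], row["flag"] = 1.0, 0.0, "degenerate"
            else:
                row["stat"], row["p"] = float(f), float(p)
        rows.append(row)
    if not rows:
        out = pd.DataFrame(columns=["triad_id", "subgenome", "p", "stat",
                                    "flag", "n_lines", "sd_expression", "q",
                                    "significant"],
                           index=pd.Index([], name="gene_id"))
        out.attrs["fdr_threshold"] = fdr
        return out
    out = pd.DataFrame(rows).set_index("gene_id")
    tested = out["p"].notna() & (out["flag"] == "")
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"],
                                             method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    out.attrs["fdr_threshold"] = fdr
    return out


def summarize_homoeolog_combos(combo_counts: dict[str, int]) -> pd.DataFrame:
    """Totals and percentages for per-triad associated-homoeolog combinations.

    ``combo_counts`` maps each combination (``"A"``...``"A&B&D"``) to its
    triad count. Returns the counts plus one-/two-/three-homoeolog subtotals
    and percentages of the grand total.
    """
    counts = {c: int(combo_counts.get(c, 0)) for c in COMBOS}
    total = sum(counts.values())
    one = counts["A"] + counts["B"] + counts["D"]
    two = counts["A&B"] + counts["A&D"] + counts["B&D"]
    three = counts["A&B&D"]
    rows = [{"combo": c, "n_triads": counts[c]} for c in COMBOS]
    rows += [
        {"combo": "one_homoeolog_total", "n_triads": one},
        {"combo": "two_homoeolog_total", "n_triads": two},
        {"combo": "three_homoeolog_total", "n_triads": three},
        {"combo": "total", "n_triads": total},
    ]
    out = pd.DataFrame(rows).set_index("combo")
    out["percent"] = (out["n_triads"] / total * 100) if total else 0.0
    return out


def count_associated_homoeologs(assoc: pd.DataFrame,
                                parental_distance: pd.Series,
                                min_parental_distance: float = 0.2
                                ) -> pd.DataFrame:
    """Combination table of significant homoeologs per divergent triad.

    Restricts to triads whose parents differ in HEB (bias distance >
    ``min_parental_distance``), counts which of A/B/D are significantly
    associated per triad, and tabulates the combinations with subtotals and
    percentages. Triads with no significant homoeolog are excluded from the
    table (the grand total counts triads with >= 1 association).
    """
    divergent = set(parental_distance.index[
        parental_distance > min_parental_distance])
    sub = assoc[assoc["triad_id"].isin(divergent) & assoc["significant"]]
    combos: dict[str, int] = {}
    for tid, grp in sub.groupby("triad_id"):
        key = "&".join(sorted(grp["subgenome"].unique()))
        combos[key] = combos.get(key, 0) + 1
    out = summarize_homoeolog_combos(combos)
    out.attrs["n_divergent_triads"] = len(divergent)
    return out


def sd_rank_analysis(assoc: pd.DataFrame) -> dict:
    """Is the genotype-associated homoeolog the most variable of its triad?

    Uses the across-line SD of normalized expression computed during the
    ANOVA. For each triad with >= 1 significant homoeolog, flags whether a
    significant homoeolog attains the maximal SD; reports the population
    fraction and a two-sided Wilcoxon rank-sum test on log SD of associated
    vs non-associated homoeologs.
    """
    per_triad = []
    for tid, grp in assoc.groupby("triad_id"):
        if not grp["significant"].any() or grp["sd_expression"].isna().any():
            continue
        max_sub = grp["sd_expression"].idxmax()
        per_triad.append({
            "triad_id": tid,
            "assoc_has_max_sd": bool(grp.loc[max_sub, "significant"]),
        })
    flags = pd.DataFrame(per_triad)
    sd_assoc = assoc.loc[assoc["significant"] == True, "sd_expression"].dropna()  # noqa: E712
    sd_other = assoc.loc[assoc["significant"] == False, "sd_expression"].dropna()  # noqa: E712
    sd_assoc = sd_assoc[sd_assoc > 0]
    sd_other = sd_other[sd_other > 0]
    result = {"n_triads": len(flags),
              "frac_assoc_max_sd": float(flags["assoc_has_max_sd"].mean())
              if len(flags) else np.nan}
    if len(sd_assoc) >= 1 and len(sd_other) >= 1:
        w = stats.ranksums(np.log(sd_assoc), np.log(sd_other))
        result["wilcoxon_stat"] = float(w.statistic)
        result["wilcoxon_p"] = float(w.pvalue)
    result["per_triad"] = flags
    return result
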