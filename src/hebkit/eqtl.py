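"""eQTL scan: strict SNP filters, covariate residualization, per-pair
regression and cis / trans-s / trans-d classification.

The scan regresses per-line residual expression on additive genotype dose
(P1 = 0, HET = 1, P2 = 2) for every SNP-gene pair, BH-corrects across all
tested pairs and keeps records below the FDR threshold (default 1e-3).
Classification is purely positional: a SNP on a different chromosome than
the gene is trans-d; on the same chromosome it is cis when within 1 Mb of
the gene body (distance 0 inside the gene) and trans-s beyond that.

Residualization removes the fixed nuisance covariates (batch, tray column,
replicate) by OLS and averages the adjusted values per line. The line term
itself is deliberately *not* removed: conditional residuals of a model with
line as a random effect would strip the genetic signal the scan is meant to
find; marginal residuals keep it while still correcting the batch structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GenotypeMatrix, TriadTable, subgenome_of

DOSE = {"P1": 0.0, "HET": 1.0, "P2": 2.0, "MISSING": np.nan}


def filter_snps_eqtl(gm: GenotypeMatrix, parent1: str, parent2: str,
                     f5_lines: list[str] | None = None, depth_min: int = 3,
                     max_missing: float = 0.5, max_het: float = 0.03,
                     maf_min: float = 0.05) -> GenotypeMatrix:
    """Stringent SNP filters for the eQTL scan, applied in order:

    1. calls with depth < ``depth_min`` become MISSING;
    2. (multiallelic sites are already dropped at VCF read);
    3. SNPs with > ``max_missing`` missing calls removed;
    4. SNPs with > ``max_het`` heterozygous calls removed;
    5. SNPs with minor allele frequency < ``maf_min`` removed (computed on
       non-missing calls, HET contributing one allele of each kind);
    6. parents must be homozygous and different (P1 / P2 after polarization).

    Because the surviving set is the conjunction of all rules, permuting the
    order changes only the per-rule attribution in the log, never the set.
    """
    if f5_lines is None:
        f5_lines = [c for c in gm.calls.columns if c not in (parent1, parent2)]
    calls = gm.calls.copy()
    low_depth = gm.depth < depth_min
    n_masked = int((low_depth & (calls != "MISSING")).to_numpy().sum())
    calls = calls.mask(low_depth, "MISSING")
    f5 = calls[f5_lines]
    missing_frac = (f5 == "MISSING").mean(axis=1)
    ok_missing = missing_frac <= max_missing
    non_missing = (f5 != "MISSING").sum(axis=1)
    het_frac = ((f5 == "HET").sum(axis=1)
                / non_missing.replace(0, np.nan)).fillna(1.0)
    ok_het = het_frac <= max_het
    n_p2_alleles = 2 * (f5 == "P2").sum(axis=1) + (f5 == "HET").sum(axis=1)
    with np.errstate(invalid="ignore"):
        p2_freq = n_p2_alleles / (2 * non_missing).replace(0, np.nan)
    maf = pd.concat([p2_freq, 1 - p2_freq], axis=1).min(axis=1).fillna(0.0)
    ok_maf = maf >= maf_min
    ok_parents = (calls[parent1] == "P1") & (calls[parent2] == "P2")
    keep = ok_missing & ok_het & ok_maf & ok_parents
    out = GenotypeMatrix(gm.snps.loc[keep], calls.loc[keep],
                         gm.depth.loc[keep], dict(gm.filter_log))
    out.filter_log.update({
        "calls_masked_low_depth": n_masked,
        "removed_missingness": int((~ok_missing).sum()),
        "removed_heterozygosity": int((~ok_het).sum()),
        "removed_maf": int((~ok_maf).sum()),
        "removed_parents_not_informative": int((~ok_parents).sum()),
        "kept": int(keep.sum()),
    })
    return out


def residualize_expression(expr: ExpressionMatrix,
                           covariates: tuple[str, ...] = ("batch", "column",
                                                          "replicate"),
                           roles: tuple[str, ...] = ("F5",)) -> pd.DataFrame:
    """Remove fixed covariate effects and average per line (genes x lines).

    Covariates are dummy-encoded and removed by a single shared OLS
    projection; the grand mean is added back so values stay on the input
    scale. Raises when the covariates are confounded with line (adding line
    indicators to the design would not increase its rank), since
    residualizing would then erase all between-line signal.
    """
    meta = expr.samples[expr.samples["role"].isin(roles)]
    Y = expr.values[meta.index].to_numpy()
    parts = [np.ones((len(meta), 1))]
    used = []
    for cov in covariates:
        if cov not in meta.columns:
            continue
        levels = pd.unique(meta[cov])
        if len(levels) > 1:
            parts.append((meta[cov].to_numpy()[:, None]
                          == levels[None, 1:]).astype(float))
            used.append(cov)
    X = np.hstack(parts)
    line_dummies = (meta["line"].to_numpy()[:, None]
                    == pd.unique(meta["line"])[None, :]).astype(float)
    if np.linalg.matrix_rank(np.hstack([X, line_dummies])) \
            <= np.linalg.matrix_rank(X):
        raise ValueError(
            f"covariates {used} are confounded with line; residualization "
            "would remove all genetic signal"
        )
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T + Y.mean(axis=1, keepdims=True)
    resid_df = pd.DataFrame(resid, index=expr.values.index, columns=meta.index)
    out = resid_df.T.groupby(meta["line"]).mean().T
    out.attrs["covariates_removed"] = used
    return out


def eqtl_scan(resid: pd.DataFrame, gm: GenotypeMatrix, tt: TriadTable,
              fdr: float = 1e-3, min_lines: int = 20,
              cis_window: int = 1_000_000) -> pd.DataFrame:
    """Per SNP-gene linear regression on additive genotype dose.

    ``resid`` is genes x lines (from :func:`residualize_expression`). Every
    SNP is tested against every gene with coordinates; the slope t-test
    p-values are BH-corrected over all tested pairs and records with
    q < ``fdr`` are returned, classified by position. Monomorphic SNPs and
    SNPs with fewer than ``min_lines`` informative lines are skipped and
    counted in ``attrs['skipped']``.
    """
    genes = [g for g in resid.index if g in tt.genes.index]
    Y_all = resid.loc[genes]
    gene_info = tt.genes.loc[genes]
    lines = [l for l in resid.columns if l in gm.calls.columns]
    skipped = {"monomorphic": 0, "too_few_lines": 0}
    recs: list[dict] = []
    pvals: list[np.ndarray] = []
    for snp in gm.snps.index:
        dose = gm.calls.loc[snp, lines].map(DOSE).to_numpy(dtype=float)
        ok = ~np.isnan(dose)
        if ok.sum() < min_lines:
            skipped["too_few_lines"] += 1
            continue
        x = dose[ok]
        if np.ptp(x) == 0:
            skipped["monomorphic"] += 1
            continue
        Y = Y_all.loc[:, np.asarray(lines)[ok]].to_numpy()
        xc = x - x.mean()
        yc = Y - Y.mean(axis=1, keepdims=True)
        sxx = float(xc @ xc)
        slope = yc @ xc / sxx
        n = len(x)
        rss = (yc**2).sum(axis=1) - slope**2 * sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
            t = slope / se
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        p[~np.isfinite(t)] = 0.0  # perfect fit
        pvals.append(p)
        srow = gm.snps.loc[snp]
        recs.append({"snp_id": snp, "snp_chrom": srow["chrom"],
                     "snp_pos": int(srow["pos"]), "slope": slope, "n": n})
    if not recs:
        out = _empty_records()
        out.attrs.update(skipped=skipped, n_pairs_tested=0,
                         fdr_threshold=fdr)
        return out
    all_p = np.concatenate(pvals)
    all_q = multipletests(all_p, method="fdr_bh")[1]
    rows = []
    offset = 0
    g_chrom = gene_info["chrom"].to_numpy()
    g_start = gene_info["start"].to_numpy()
    g_end = gene_info["end"].to_numpy()
    g_sub = gene_info["subgenome"].to_numpy()
    for rec, p in zip(recs, pvals):
        q = all_q[offset:offset + len(p)]
        offset += len(p)
        hit = np.flatnonzero(q < fdr)
        for j in hit:
            cls = classify_eqtl(rec["snp_chrom"], rec["snp_pos"], g_chrom[j],
                                int(g_start[j]), int(g_end[j]), cis_window)
            rows.append({
                "snp_id": rec["snp_id"], "snp_chrom": rec["snp_chrom"],
                "snp_pos": rec["snp_pos"], "gene_id": genes[j],
                "gene_chrom": g_chrom[j], "gene_start": int(g_start[j]),
                "gene_end": int(g_end[j]), "slope": float(rec["slope"][j]),
                "p": float(p[j]), "q": float(q[j]), "class": cls,
                "snp_subgenome": subgenome_of(rec["snp_chrom"]),
                "gene_subgenome": g_sub[j],
            })
    out = pd.DataFrame(rows) if rows else _empty_records()
    out.attrs["skipped"] = skipped
    out.attrs["n_pairs_tested"] = len(all_p)
    out.attrs["fdr_threshold"] = fdr
    return out


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "snp_id", "snp_chrom", "snp_pos", "gene_id", "gene_chrom",
        "gene_start", "gene_end", "slope", "p", "q", "class",
        "snp_subgenome", "gene_subgenome",
    ])


def classify_eqtl(snp_chrom: str, snp_pos: int, gene_chrom: str,
                  gene_start: int, gene_end: int,
                  cis_window: int = 1_000_000) -> str:
    """cis / trans_s / trans_d from SNP and gene coordinates.

    Different chromosome: trans_d. Same chromosome: cis when the distance
    from the SNP to the nearest gene-body boundary is <= ``cis_window``
    (0 inside the gene; the exact 1 Mb boundary counts as cis), else trans_s.
    """
    if snp_pos <= 0 or gene_start <= 0 or gene_end < gene_start:
        raise ValueError("invalid coordinates")
    if snp_chrom != gene_chrom:
        return "trans_d"
    if gene_start <= snp_pos <= gene_end:
        dist = 0
    else:
        dist = min(abs(snp_pos - gene_start), abs(snp_pos - gene_end))
    return "cis" if dist <= cis_window else "trans_s"


def tally_by_subgenome(records: pd.DataFrame) -> pd.DataFrame:
    """Counts per (class, snp_subgenome, gene_subgenome), with a flag for
    within- vs cross-subgenome associations. Tallies sum to the record count.
    """
    if records.empty:
        return pd.DataFrame(columns=["class", "snp_subgenome",
                                     "gene_subgenome", "n", "within_subgenome"])
    tally = (records.groupby(["class", "snp_subgenome", "gene_subgenome"])
             .size().rename("n").reset_index())
    tally["within_subgenome"] = tally["snp_subgenome"] == tally["gene_subgenome"]
    return tally
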