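"""Data model, readers/writers and expression normalization.

Containers are thin wrappers around pandas objects:

* :class:`TriadTable` — triad -> (gene_A, gene_B, gene_D) plus gene coordinates.
* :class:`ExpressionMatrix` — genes x samples with per-sample metadata
  (line, replicate, batch, tray column, role) and the unit of the values.
* :class:`GenotypeMatrix` — SNP x sample calls polarized to the two parents
  ({P1, P2, HET, MISSING}) with per-call read depths.

Coordinate conventions: BED input is 0-based half-open, VCF is 1-based;
internally everything is 1-based inclusive (converted at the boundary).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CALLS = ("P1", "P2", "HET", "MISSING")

#: chromosome names like "chr1A", "chr5D"; group 1 is the subgenome letter
SUBGENOME_REGEX = r"^chr\d+([ABD])$"

SAMPLE_COLUMNS = ("line", "replicate", "batch", "column", "role")


class FormatError(ValueError):
    """Malformed input file (bad header, duplicate IDs, missing cells...)."""


def subgenome_of(chrom: str, regex: str = SUBGENOME_REGEX) -> str:
    m = re.match(regex, chrom)
    if m is None:
        raise FormatError(
            f"cannot parse subgenome from chromosome name {chrom!r} "
            f"with pattern {regex!r}"
        )
    return m.group(1)


# ---------------------------------------------------------------------------
# containers


@dataclass
class TriadTable:
    """Triad membership plus gene coordinates.

    ``triads``: index triad_id, columns gene_A, gene_B, gene_D.
    ``genes``: index gene_id, columns chrom, start, end (1-based inclusive),
    subgenome.
    """

    triads: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_A", "gene_B", "gene_D") if c not in self.triads]
        if missing:
            raise FormatError(f"triad table lacks columns {missing}")
        stacked = self.triads[["gene_A", "gene_B", "gene_D"]].to_numpy().ravel()
        if len(stacked) != len(set(stacked)):
            raise FormatError("a gene appears in more than one triad slot")
        for sub in "ABD":
            for g in self.triads[f"gene_{sub}"]:
                if g in self.genes.index and self.genes.at[g, "subgenome"] != sub:
                    raise FormatError(
                        f"gene {g} listed as the {sub} homoeolog but located on "
                        f"subgenome {self.genes.at[g, 'subgenome']}"
                    )

    @property
    def triad_ids(self) -> pd.Index:
        return self.triads.index

    def genes_long(self) -> pd.DataFrame:
        """One row per homoeolog: triad_id, subgenome, gene_id."""
        long = self.triads[["gene_A", "gene_B", "gene_D"]].copy()
        long.columns = ["A", "B", "D"]
        out = long.stack().rename("gene_id").reset_index()
        out.columns = ["triad_id", "subgenome", "gene_id"]
        return out


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with attached sample metadata."""

    values: pd.DataFrame
    units: str  # "counts" | "TPM" | "CPM"
    samples: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.units not in ("counts", "TPM", "CPM"):
            raise ValueError(f"unknown expression unit {self.units!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        absent = self.values.columns.difference(self.samples.index)
        if len(absent):
            raise FormatError(f"samples without metadata: {list(absent)[:5]}")
        self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, names) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(names)], self.units, self.samples.loc[list(names)],
            self.lengths,
        )

    def line_means(self, roles: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Average expression per line over its replicates (genes x lines)."""
        meta = self.samples
        if roles is not None:
            meta = meta[meta["role"].isin(roles)]
        groups = meta.groupby("line").groups
        return pd.DataFrame(
            {line: self.values[list(cols)].mean(axis=1) for line, cols in groups.items()}
        )


@dataclass
class GenotypeMatrix:
    """SNP x sample genotype calls polarized to the parents.

    ``snps``: index snp_id, columns chrom, pos (1-based), gene (or NA).
    ``calls``: snp_id x sample strings from :data:`CALLS`.
    ``depth``: snp_id x sample integer read depths.
    """

    snps: pd.DataFrame
    calls: pd.DataFrame
    depth: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"unknown genotype calls {sorted(bad)}")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")

    def subset(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(
            self.snps.loc[snp_ids], self.calls.loc[snp_ids],
            self.depth.loc[snp_ids], dict(self.filter_log),
        )


# ---------------------------------------------------------------------------
# expression I/O and normalization


def read_expression(
    tsv: str | Path, metadata_tsv: str | Path, units: str = "counts",
    lengths_tsv: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV.

    The metadata file must have a ``sample`` column and the columns in
    :data:`SAMPLE_COLUMNS`. Duplicate gene IDs and cells without values are
    rejected rather than silently collapsed.
    """
    values = pd.read_csv(tsv, sep="\t", index_col=0)
    values.columns.name = "sample"
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique()
        raise FormatError(f"duplicate gene IDs in expression file: {list(dupes)[:5]}")
    if values.isna().any().any():
        raise FormatError("expression matrix contains missing cells")
    meta = pd.read_csv(metadata_tsv, sep="\t")
    if "sample" not in meta.columns:
        raise FormatError("metadata file lacks a 'sample' column")
    meta = meta.set_index("sample")
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata lacks columns {missing_cols}")
    lengths = None
    if lengths_tsv is not None:
        ltab = pd.read_csv(lengths_tsv, sep="\t", index_col=0)
        lengths = ltab.iloc[:, 0].reindex(values.index)
        if lengths.isna().any():
            raise FormatError("gene lengths missing for some genes")
    return ExpressionMatrix(values, units, meta, lengths)


def write_expression(em: ExpressionMatrix, tsv: str | Path,
                     metadata_tsv: str | Path | None = None) -> None:
    em.values.to_csv(tsv, sep="\t", index_label="gene_id", float_format="%.6g")
    if metadata_tsv is not None:
        em.samples.to_csv(metadata_tsv, sep="\t", index_label="sample")


def counts_to_tpm(em: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Length-normalize counts to transcripts per million.

    tpm_g = (c_g / L_g) / sum_j (c_j / L_j) * 1e6, per sample. Columns sum to
    1e6; an all-zero sample stays all-zero and triggers a warning.
    """
    if em.units != "counts":
        raise ValueError("counts_to_tpm expects a counts matrix")
    lengths = em.lengths if lengths is None else lengths.reindex(em.genes)
    if lengths is None:
        raise ValueError("gene lengths are required for TPM")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = em.values.div(lengths, axis=0)
    total = rate.sum(axis=0)
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample(s) left as zeros in TPM", stacklevel=2
        )
        total = total.replace(0, np.nan)
    tpm = rate.div(total, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(tpm, "TPM", em.samples, em.lengths)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
                ) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples. For each sample, M (log2 ratio to the
    reference) and A (average log2 abundance) are computed over genes positive
    in both; the most extreme 30% of M and 5% of A (each tail) are discarded
    and the factor is 2**mean(M) over the survivors, normalized so the factors
    multiply to 1. Identical libraries therefore get factor 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample; TMM undefined")
    frac = counts.div(lib, axis=1)
    q75 = frac.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
    ref = (q75 - q75.mean()).abs().idxmin()
    fr = frac[ref].to_numpy()
    log_factors = {}
    for s in counts.columns:
        fs = frac[s].to_numpy()
        ok = (fs > 0) & (fr > 0)
        if s == ref or not ok.any():
            log_factors[s] = 0.0
            continue
        m = np.log2(fs[ok] / fr[ok])
        a = 0.5 * np.log2(fs[ok] * fr[ok])
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        log_factors[s] = float(m[keep].mean()) if keep.any() else 0.0
    f = pd.Series(log_factors).reindex(counts.columns)
    f -= f.mean()  # geometric mean 1
    return np.exp2(f)


def tmm_cpm(em: ExpressionMatrix) -> ExpressionMatrix:
    """TMM-normalized counts per million."""
    if em.units != "counts":
        raise ValueError("tmm_cpm expects a counts matrix")
    factors = tmm_factors(em.values)
    eff_lib = em.values.sum(axis=0) * factors
    cpm = em.values.div(eff_lib, axis=1) * 1e6
    return ExpressionMatrix(cpm, "CPM", em.samples, em.lengths)


# ---------------------------------------------------------------------------
# triad table / BED


def read_triads(triads_tsv: str | Path, bed: str | Path,
                regex: str = SUBGENOME_REGEX) -> TriadTable:
    """Read triad membership (triad_id, gene_A, gene_B, gene_D) and a BED file
    of gene coordinates (0-based half-open, converted to 1-based inclusive)."""
    tri = pd.read_csv(triads_tsv, sep="\t")
    if "triad_id" not in tri.columns:
        raise FormatError("triad table lacks 'triad_id' column")
    tri = tri.set_index("triad_id")
    bed_df = pd.read_csv(bed, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id"])
    if bed_df["gene_id"].isna().any():
        raise FormatError("BED file must carry gene IDs in column 4")
    genes = pd.DataFrame({
        "chrom": bed_df["chrom"].to_numpy(),
        "start": bed_df["start"].to_numpy() + 1,  # 0-based -> 1-based
        "end": bed_df["end"].to_numpy(),
        "subgenome": [subgenome_of(c, regex) for c in bed_df["chrom"]],
    }, index=pd.Index(bed_df["gene_id"], name="gene_id"))
    return TriadTable(tri, genes)


def write_triads(tt: TriadTable, triads_tsv: str | Path, bed: str | Path) -> None:
    tt.triads.to_csv(triads_tsv, sep="\t", index_label="triad_id")
    out = tt.genes.reset_index()
    out["start0"] = out["start"] - 1
    out[["chrom", "start0", "end", "gene_id"]].to_csv(
        bed, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# genotypes


def read_vcf(path: str | Path, parent1: str, parent2: str) -> GenotypeMatrix:
    """Read a VCF with GT and DP and polarize calls to the parents.

    Samples matching ``parent1``/``parent2`` anchor the polarization: the
    allele carried homozygously by parent1 maps to P1, by parent2 to P2.
    Multiallelic records are dropped (count kept in ``filter_log``); records
    where either parent is heterozygous or missing are dropped too, since they
    cannot be polarized.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in (parent1, parent2):
        if p not in samples:
            raise FormatError(f"parental sample {p!r} absent from VCF")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    rows, call_rows, depth_rows = [], [], []
    n_multi = n_unpolarized = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()[:, :2]
        g1, g2 = gts[i1], gts[i2]
        if (g1 < 0).any() or (g2 < 0).any() or g1[0] != g1[1] or g2[0] != g2[1] \
                or g1[0] == g2[0]:
            n_unpolarized += 1
            continue
        p1_allele = g1[0]
        dp = rec.format("DP")
        dp = np.zeros(len(samples), int) if dp is None else dp[:, 0].astype(int)
        calls = []
        for g in gts:
            if (g < 0).any():
                calls.append("MISSING")
            elif g[0] != g[1]:
                calls.append("HET")
            else:
                calls.append("P1" if g[0] == p1_allele else "P2")
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((snp_id, rec.CHROM, rec.POS))
        call_rows.append(calls)
        depth_rows.append(np.clip(dp, 0, None))
    idx = pd.Index([r[0] for r in rows], name="snp_id")
    snps = pd.DataFrame(
        {"chrom": [r[1] for r in rows], "pos": [r[2] for r in rows],
         "gene": pd.Series([pd.NA] * len(rows), index=idx, dtype="object")},
        index=idx,
    )
    calls = pd.DataFrame(call_rows, index=idx, columns=samples)
    depth = pd.DataFrame(depth_rows, index=idx, columns=samples)
    return GenotypeMatrix(
        snps, calls, depth,
        {"multiallelic_dropped": n_multi, "unpolarizable_dropped": n_unpolarized},
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path, parent1: str, parent2: str) -> None:
    """Write a minimal biallelic VCF (GT:DP); P1 allele is REF, P2 is ALT."""
    code = {"P1": "0/0", "P2": "1/1", "HET": "0/1", "MISSING": "./."}
    samples = list(gm.calls.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = gm.snps.sort_values(["chrom", "pos"]).index
        for snp in order:
            row = gm.snps.loc[snp]
            cells = [
                f"{code[gm.calls.at[snp, s]]}:{int(gm.depth.at[snp, s])}"
                for s in samples
            ]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tG\t.\tPASS\t."
                     f"\tGT:DP\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(calls_tsv: str | Path, depth_tsv: str | Path,
                      snps_tsv: str | Path) -> GenotypeMatrix:
    snps = pd.read_csv(snps_tsv, sep="\t", index_col=0)
    calls = pd.read_csv(calls_tsv, sep="\t", index_col=0)
    depth = pd.read_csv(depth_tsv, sep="\t", index_col=0)
    if "gene" not in snps.columns:
        snps["gene"] = pd.NA
    snps["gene"] = snps["gene"].astype("object")
    return GenotypeMatrix(snps, calls, depth)


def write_genotype_tsv(gm: GenotypeMatrix, calls_tsv: str | Path,
                       depth_tsv: str | Path, snps_tsv: str | Path) -> None:
    gm.calls.to_csv(calls_tsv, sep="\t", index_label="snp_id")
    gm.depth.to_csv(depth_tsv, sep="\t", index_label="snp_id")
    gm.snps.to_csv(snps_tsv, sep="\t", index_label="snp_id")


def map_snps_to_genes(gm: GenotypeMatrix, tt: TriadTable) -> GenotypeMatrix:
    """Annotate each SNP with the unique gene whose body contains it.

    SNPs inside no gene keep ``gene = NA`` (still usable for eQTL scans);
    SNPs inside two or more genes are removed, matching the rule that only
    uniquely gene-mapped SNPs are genotyped.
    """
    genes = tt.genes
    assigned: dict[str, object] = {}
    ambiguous: list[str] = []
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for snp, row in gm.snps.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            assigned[snp] = pd.NA
            continue
        hit = sub[(sub["start"] <= row["pos"]) & (row["pos"] <= sub["end"])]
        if len(hit) == 0:
            assigned[snp] = pd.NA
        elif len(hit) == 1:
            assigned[snp] = hit.index[0]
        else:
            ambiguous.append(snp)
    keep = [s for s in gm.snps.index if s not in set(ambiguous)]
    out = gm.subset(keep)
    out.snps = out.snps.copy()
    out.snps["gene"] = pd.Series({s: assigned[s] for s in keep}, dtype="object")
    out.filter_log["ambiguous_gene_overlap_removed"] = len(ambiguous)
    return out
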