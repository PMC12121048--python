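"""eQTL SNP filters, residualization, the regression scan and positional
classification."""

import numpy as np
import pandas as pd
import pytest

import hebkit as hk
from hebkit import eqtl
from conftest import make_genotype_matrix

P = {"p1": "P1", "p2": "P2"}


class TestFilterSnpsEqtl:
    def _gm(self, f5_calls, depth=30):
        calls = {snp: {**P, **per_line} for snp, per_line in f5_calls.items()}
        return make_genotype_matrix(calls, depth=depth)

    def test_low_maf_removed(self):
        lines = {f"L{i}": ("P2" if i < 1 else "P1") for i in range(25)}  # 4%
        gm = self._gm({"rare": lines})
        out = eqtl.filter_snps_eqtl(gm, "p1", "p2")
        assert len(out.snps) == 0
        assert out.filter_log["removed_maf"] == 1

    def test_depth_masking_then_missingness(self):
        lines = {f"L{i}": ("P1" if i < 10 else "P2") for i in range(20)}
        depth = {"snp": {**{"p1": 30, "p2": 30},
                         **{f"L{i}": (2 if i < 11 else 30)
                            for i in range(20)}}}
        gm = make_genotype_matrix({"snp": {**P, **lines}}, depth=depth)
        out = eqtl.filter_snps_eqtl(gm, "p1", "p2")
        # 11 of 20 calls masked -> 55% missing -> SNP removed
        assert len(out.snps) == 0
        assert out.filter_log["calls_masked_low_depth"] == 11
        assert out.filter_log["removed_missingness"] == 1

    def test_depth_mask_keeps_snp_when_other_filters_pass(self):
        lines = {f"L{i}": ("P1" if i < 10 else "P2") for i in range(20)}
        depth = {"snp": {**{"p1": 30, "p2": 30},
                         **{f"L{i}": (2 if i == 0 else 30)
                            for i in range(20)}}}
        gm = make_genotype_matrix({"snp": {**P, **lines}}, depth=depth)
        out = eqtl.filter_snps_eqtl(gm, "p1", "p2")
        assert list(out.snps.index) == ["snp"]
        assert out.calls.at["snp", "L0"] == "MISSING"

    def test_high_heterozygosity_removed(self):
        lines = {f"L{i}": ("HET" if i < 2 else ("P1" if i % 2 else "P2"))
                 for i in range(30)}
        gm = self._gm({"hetty": lines})
        out = eqtl.filter_snps_eqtl(gm, "p1", "p2")
        assert out.filter_log["removed_heterozygosity"] == 1

    def test_surviving_set_is_filter_conjunction(self, population):
        gm = population.genotypes
        out = eqtl.filter_snps_eqtl(gm, "P1_line", "P2_line")
        # independent brute-force recheck of every surviving SNP
        f5 = [c for c in gm.calls.columns if c not in ("P1_line", "P2_line")]
        for snp in out.snps.index[:200]:
            calls = gm.calls.loc[snp].copy()
            calls[gm.depth.loc[snp] < 3] = "MISSING"
            sub = calls[f5]
            non_missing = (sub != "MISSING").sum()
            assert (sub == "MISSING").mean() <= 0.5
            assert (sub == "HET").sum() / non_missing <= 0.03
            alt = 2 * (sub == "P2").sum() + (sub == "HET").sum()
            maf = min(alt, 2 * non_missing - alt) / (2 * non_missing)
            assert maf >= 0.05
            assert calls["P1_line"] == "P1" and calls["P2_line"] == "P2"


class TestResidualizeExpression:
    def _em(self, values, batch, n_lines, reps=1):
        samples = []
        for i in range(len(batch)):
            samples.append({"sample": f"s{i}", "line": f"L{i % n_lines}",
                            "replicate": f"rep{i // n_lines + 1}",
                            "batch": batch[i], "column": "col1", "role": "F5"})
        meta = pd.DataFrame(samples).set_index("sample")
        vals = pd.DataFrame(values, index=["g1"], columns=meta.index,
                            dtype=float)
        return hk.ExpressionMatrix(vals, "CPM", meta)

    def test_no_nuisance_effects_is_identity_up_to_constant(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, 12)
        em = self._em([y], ["b1"] * 12, n_lines=12)
        out = eqtl.residualize_expression(em)
        line_means = pd.Series(y, index=[f"L{i}" for i in range(12)])
        diff = out.loc["g1"] - line_means.reindex(out.columns)
        assert np.allclose(diff, diff.iloc[0])

    def test_additive_batch_shift_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, 8)
        y = np.r_[base, base + 5.0]  # second replicate in a shifted batch
        em = self._em([y], ["b1"] * 8 + ["b2"] * 8, n_lines=8)
        out = eqtl.residualize_expression(em)
        # after adjustment the two batches agree, so per-line means equal
        # the batch-free values up to a constant
        diff = out.loc["g1"] - pd.Series(base,
                                         index=[f"L{i}" for i in range(8)])
        assert np.allclose(diff, diff.iloc[0], atol=1e-9)

    def test_confounded_design_rejected(self):
        y = np.arange(6, dtype=float)
        em = self._em([y], [f"b{i}" for i in range(6)], n_lines=6)
        with pytest.raises(ValueError, match="confounded"):
            eqtl.residualize_expression(em)

    def test_single_batch_single_replicate_passthrough(self):
        y = np.arange(6, dtype=float)
        em = self._em([y], ["b1"] * 6, n_lines=6)
        out = eqtl.residualize_expression(em)
        assert out.attrs["covariates_removed"] == []
        np.testing.assert_allclose(
            out.loc["g1"].to_numpy(),
            pd.Series(y, index=[f"L{i}" for i in range(6)])
            .reindex(out.columns).to_numpy(), atol=1e-12)


class TestClassifyEqtl:
    @pytest.mark.parametrize(
        "snp, gene, expected",
        [
            (("chr1A", 1_000_000), ("chr1A", 1_500_000, 1_502_000), "cis"),
            (("chr1A", 1_000_000), ("chr1A", 5_000_000, 5_002_000), "trans_s"),
            (("chr1A", 1_000_000), ("chr2B", 1_500_000, 1_502_000), "trans_d"),
            (("chr1A", 1_500_500), ("chr1A", 1_500_000, 1_502_000), "cis"),
            (("chr1A", 500_000), ("chr1A", 1_500_000, 1_502_000), "cis"),
            # exactly 1 Mb from the gene boundary counts as cis
            (("chr1A", 2_502_000), ("chr1A", 1_500_000, 1_502_000), "cis"),
            (("chr1A", 2_502_001), ("chr1A", 1_500_000, 1_502_000), "trans_s"),
        ],
    )
    def test_positional_rules(self, snp, gene, expected):
        assert hk.classify_eqtl(snp[0], snp[1], *gene) == expected

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            hk.classify_eqtl("chr1A", 0, "chr1A", 10, 20)
        with pytest.raises(ValueError):
            hk.classify_eqtl("chr1A", 5, "chr1A", 30, 20)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        chroms = [f"chr{i}{s}" for i in range(1, 8) for s in "ABD"]
        for _ in range(10_000):
            sc, gc = rng.choice(chroms, 2)
            pos = int(rng.integers(1, 10_000_000))
            start = int(rng.integers(1, 10_000_000))
            end = start + int(rng.integers(100, 5000))
            ours = hk.classify_eqtl(sc, pos, gc, start, end)
            if sc != gc:
                expected = "trans_d"
            else:
                d = 0 if start <= pos <= end else min(abs(pos - start),
                                                      abs(pos - end))
                expected = "cis" if d <= 1_000_000 else "trans_s"
            assert ours == expected


@pytest.fixture(scope="module")
def eqtl_run(population):
    gm = eqtl.filter_snps_eqtl(population.genotypes, "P1_line", "P2_line")
    cpm = hk.tmm_cpm(population.counts)
    log_cpm = hk.ExpressionMatrix(np.log2(cpm.values + 1.0), "CPM",
                                  cpm.samples, cpm.lengths)
    resid = eqtl.residualize_expression(log_cpm)
    records = eqtl.eqtl_scan(resid, gm, population.triads)
    return records, population.truth


class TestEqtlScan:
    def test_cis_records_hit_causal_genes(self, eqtl_run):
        records, truth = eqtl_run
        causal_genes = {
            f"g{int(t[5:]):05d}{truth.at[t, 'causal_homoeolog']}"
            for t in truth.index if truth.at[t, "effect_type"] == "cis"}
        cis = records[records["class"] == "cis"]
        assert len(cis) >= 5
        assert cis["gene_id"].isin(causal_genes).mean() >= 0.9

    def test_slope_sign_matches_simulated_direction(self, eqtl_run):
        records, truth = eqtl_run
        causal_genes = {
            f"g{int(t[5:]):05d}{truth.at[t, 'causal_homoeolog']}"
            for t in truth.index if truth.at[t, "effect_type"] == "cis"}
        hits = records[records["gene_id"].isin(causal_genes)
                       & (records["class"] == "cis")]
        # the parent-2 allele increases expression, coded dose 2
        assert (hits["slope"] > 0).mean() >= 0.95

    def test_noise_scan_has_few_discoveries(self):
        sim = hk.simulate_population(
            hk.SimConfig(n_triads=80, prop_cis_triads=0.0, seed=13))
        gm = eqtl.filter_snps_eqtl(sim.genotypes, "P1_line", "P2_line")
        cpm = hk.tmm_cpm(sim.counts)
        log_cpm = hk.ExpressionMatrix(np.log2(cpm.values + 1.0), "CPM",
                                      cpm.samples, cpm.lengths)
        resid = eqtl.residualize_expression(log_cpm)
        records = eqtl.eqtl_scan(resid, gm, sim.triads)
        assert len(records) <= 2

    def test_monomorphic_snps_skipped(self, population):
        gm = population.genotypes
        mono = gm.subset(gm.snps.index[:1])
        mono.calls.iloc[0, :] = "P1"
        cpm = hk.tmm_cpm(population.counts)
        resid = eqtl.residualize_expression(cpm)
        records = eqtl.eqtl_scan(resid, mono, population.triads)
        assert len(records) == 0
        assert records.attrs["skipped"]["monomorphic"] == 1


class TestTally:
    def test_empty_records(self):
        out = hk.tally_by_subgenome(eqtl._empty_records())
        assert len(out) == 0

    def test_three_records(self):
        records = pd.DataFrame({
            "class": ["cis", "trans_s", "trans_d"],
            "snp_subgenome": ["A", "B", "D"],
            "gene_subgenome": ["A", "B", "A"],
        })
        out = hk.tally_by_subgenome(records)
        assert out["n"].sum() == 3
        by_class = out.set_index("class")["within_subgenome"].to_dict()
        assert by_class == {"cis": True, "trans_s": True, "trans_d": False}

    def test_matches_brute_force_recount(self, eqtl_run):
        records, _ = eqtl_run
        if records.empty:
            pytest.skip("no records")
        out = hk.tally_by_subgenome(records)
        from collections import Counter
        counter = Counter(
            (r["class"], r["snp_subgenome"], r["gene_subgenome"])
            for _, r in records.iterrows())
        assert out["n"].sum() == len(records)
        for _, row in out.iterrows():
            assert counter[(row["class"], row["snp_subgenome"],
                            row["gene_subgenome"])] == row["n"]
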