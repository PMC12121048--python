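"""Line-effect testing, bias distances, pattern classification and
segregation summaries.

The profiled-ML mixed-model fitter is validated against ML log-likelihoods
obtained from R's lme4 on a frozen, reproducibly generated dataset.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hebkit as hk
from hebkit.inheritance import (ProfiledLMM, _design_matrices,
                                line_effect_test)


def _lmm_fixture():
    """8 lines x 3 replicates with line, replicate and residual effects."""
    rng = np.random.default_rng(42)
    n_lines, n_rep = 8, 3
    lines = np.repeat([f"L{i}" for i in range(n_lines)], n_rep)
    reps = np.tile([f"r{j}" for j in range(n_rep)], n_lines)
    line_eff = rng.normal(0, 0.2, n_lines)
    rep_eff = rng.normal(0, 0.1, n_rep)
    y = (0.5 + line_eff[np.repeat(np.arange(n_lines), n_rep)]
         + rep_eff[np.tile(np.arange(n_rep), n_lines)]
         + rng.normal(0, 0.05, n_lines * n_rep))
    return np.round(y, 10), lines, reps


class TestProfiledLMM:
    def test_ml_loglik_matches_lme4(self):
        # lme4 ML fits of cv ~ line + (1|rep) and cv ~ 1 + (1|rep)
        y, lines, reps = _lmm_fixture()
        X_full, X_red = _design_matrices(lines)
        full = ProfiledLMM(X_full, reps).fit(y)
        red = ProfiledLMM(X_red, reps).fit(y)
        assert full["loglik"] == pytest.approx(41.8870889359, abs=1e-6)
        assert red["loglik"] == pytest.approx(2.6831796274, abs=1e-6)

    def test_lrt_matches_lme4(self):
        y, lines, reps = _lmm_fixture()
        r = line_effect_test(y, lines, reps, method="lrt")
        assert r.stat == pytest.approx(78.4078186169, abs=1e-5)
        assert r.p == pytest.approx(2.9077739040e-14, rel=1e-4)

    def test_boundary_null_variance_handled(self):
        # pure noise with no replicate effect: lambda sits at the boundary
        rng = np.random.default_rng(0)
        y = rng.normal(size=24)
        lines = np.repeat([f"L{i}" for i in range(8)], 3)
        reps = np.tile(["r1", "r2", "r3"], 8)
        r = line_effect_test(y, lines, reps, method="lrt")
        assert 0.0 <= r.p <= 1.0 and r.flag == ""


class TestLineEffectTest:
    def test_zero_variance_degenerate(self):
        r = line_effect_test(np.full(12, 0.3), np.repeat(list("ABCD"), 3),
                             np.tile(["r1", "r2", "r3"], 4))
        assert r.p == 1.0 and r.flag == "degenerate"

    def test_missing_cv_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            line_effect_test(np.array([1.0, np.nan, 2.0, 1.0]),
                             np.array(["A", "A", "B", "B"]),
                             np.array(["r1", "r2", "r1", "r2"]))

    def test_f_default_matches_blocked_anova(self):
        y, lines, reps = _lmm_fixture()
        r = line_effect_test(y, lines, reps)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        tab = anova_lm(smf.ols(
            "cv ~ C(line) + C(rep)",
            pd.DataFrame({"cv": y, "line": lines, "rep": reps})).fit(), typ=2)
        assert r.stat == pytest.approx(tab.loc["C(line)", "F"])
        assert r.p == pytest.approx(tab.loc["C(line)", "PR(>F)"])


@pytest.fixture(scope="module")
def scan(population):
    heb = hk.heb_table(population.tpm, population.triads)
    f5 = heb[heb["line"].str.startswith("F5")]
    return hk.line_effect_scan(f5), population.truth


class TestLineEffectScan:

    def test_power_and_null_rate_on_known_truth(self, scan):
        eff, truth = scan
        cis = (truth["effect_type"] == "cis").reindex(eff.index)
        assert eff.loc[cis, "significant"].mean() >= 0.8
        assert eff.loc[~cis, "significant"].mean() <= 0.005

    def test_q_not_smaller_than_p(self, scan):
        eff, _ = scan
        ok = eff["p"].notna()
        assert (eff.loc[ok, "q"] >= eff.loc[ok, "p"] - 1e-12).all()

    def test_vectorized_path_matches_per_triad_tests(self, population):
        heb = hk.heb_table(population.tpm, population.triads)
        f5 = heb[heb["line"].str.startswith("F5")]
        eff = hk.line_effect_scan(f5)
        for tid in list(eff.index[:3]):
            grp = f5[f5["triad_id"] == tid]
            r = line_effect_test(grp["cv"].to_numpy(),
                                 grp["line"].to_numpy(),
                                 grp["replicate"].to_numpy())
            assert eff.loc[tid, "p"] == pytest.approx(r.p, rel=1e-9, abs=1e-12)

    def test_permuting_lines_destroys_significance(self, population):
        heb = hk.heb_table(population.tpm, population.triads)
        f5 = heb[heb["line"].str.startswith("F5")].copy()
        truth = population.truth
        effect_triads = truth.index[truth["effect_type"] == "cis"]
        sub = f5[f5["triad_id"].isin(effect_triads)].copy()
        rng = np.random.default_rng(1)
        # permute line labels within replicate, per triad
        for (tid, rep), idx in sub.groupby(["triad_id", "replicate"]).groups.items():
            sub.loc[idx, "line"] = rng.permutation(sub.loc[idx, "line"].to_numpy())
        eff = hk.line_effect_scan(sub)
        assert eff["q"].median() > 0.5
        assert eff["significant"].sum() == 0


class TestBiasDistance:
    def test_identical_points_zero(self):
        assert hk.bias_distance((0.2, 0.3, 0.5), (0.2, 0.3, 0.5)) == 0.0

    def test_vertex_to_vertex_maximum(self):
        assert hk.bias_distance((1, 0, 0), (0, 1, 0)) == pytest.approx(
            np.sqrt(2.0))

    def test_closed_form_example(self):
        d = hk.bias_distance((0.5, 0.25, 0.25), (1 / 3, 1 / 3, 1 / 3))
        assert d == pytest.approx(np.sqrt(1 / 24), abs=1e-9)
        assert d == pytest.approx(0.2041, abs=1e-4)

    def test_undefined_point_rejected(self):
        with pytest.raises(ValueError):
            hk.bias_distance(None, (1, 0, 0))

    @given(st.lists(st.floats(0.01, 1), min_size=9, max_size=9))
    @settings(deadline=None, max_examples=30)
    def test_metric_properties(self, raw):
        p = np.array(raw[0:3]); q = np.array(raw[3:6]); r = np.array(raw[6:9])
        p, q, r = p / p.sum(), q / q.sum(), r / r.sum()
        assert hk.bias_distance(p, q) == pytest.approx(hk.bias_distance(q, p))
        assert hk.bias_distance(p, r) <= hk.bias_distance(p, q) \
            + hk.bias_distance(q, r) + 1e-12


class TestClassifyLinePattern:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [
            (0.05, 0.05, "Con"),
            (0.25, 0.05, "DFO_a"),
            (0.05, 0.25, "DFO_b"),
            (0.25, 0.25, "DFB"),
            (0.25, 0.15, "uncategorized"),
            (0.15, 0.25, "uncategorized"),
            (0.2, 0.2, "uncategorized"),   # strict inequalities as printed
        ],
    )
    def test_rules(self, d1, d2, expected):
        assert hk.classify_line_pattern(d1, d2) == expected

    def test_partitions_the_distance_plane(self):
        grid = np.linspace(0, np.sqrt(2), 60)
        labels = {hk.classify_line_pattern(a, b) for a in grid for b in grid}
        # every point got exactly one label (function is total) and only
        # known labels occur
        assert labels <= {"Con", "DFO_a", "DFO_b", "DFB", "uncategorized"}


def _bias_frame(pattern_counts, triad="t1"):
    rows = []
    i = 0
    coords = {"Con": (0.05, 0.05), "DFO_a": (0.3, 0.05), "DFO_b": (0.05, 0.3),
              "DFB": (0.3, 0.3), "uncategorized": (0.25, 0.15)}
    for pattern, n in pattern_counts.items():
        for _ in range(n):
            d1, d2 = coords[pattern]
            rows.append({"triad_id": triad, "line": f"L{i}", "d_p1": d1,
                         "d_p2": d2, "pattern": pattern,
                         "parental_distance": 0.25})
            i += 1
    return pd.DataFrame(rows)


class TestCallTriadPattern:
    def test_single_dominant_pattern(self):
        calls = hk.call_triad_pattern(_bias_frame({"Con": 40, "DFB": 10}))
        assert calls.loc["t1", "patterns"] == "Con"

    def test_dual_dfo_pattern(self):
        calls = hk.call_triad_pattern(
            _bias_frame({"DFO_a": 20, "DFO_b": 22, "Con": 8}))
        assert set(calls.loc["t1", "patterns"].split(",")) == {"DFO_a",
                                                               "DFO_b"}

    def test_below_threshold_unclassified(self):
        calls = hk.call_triad_pattern(
            _bias_frame({"DFO_a": 14, "uncategorized": 36}))
        assert calls.loc["t1", "patterns"] == ""
        assert bool(calls.loc["t1", "unclassified"])

    def test_min_lines_threshold_respected(self):
        calls = hk.call_triad_pattern(_bias_frame({"DFO_a": 14}), min_lines=14)
        assert calls.loc["t1", "patterns"] == "DFO_a"


class TestParentalDivergenceComparison:
    def _effects(self, sig_ids, nonsig_ids):
        idx = list(sig_ids) + list(nonsig_ids)
        return pd.DataFrame(
            {"significant": [True] * len(sig_ids) + [False] * len(nonsig_ids)},
            index=pd.Index(idx, name="triad_id"))

    def test_identical_distributions(self):
        ids_a = [f"s{i}" for i in range(10)]
        ids_b = [f"n{i}" for i in range(10)]
        d = pd.Series(np.tile(np.linspace(0, 1, 10), 2), index=ids_a + ids_b)
        out = hk.parental_divergence_comparison(
            self._effects(ids_a, ids_b), d)
        assert out["ks_stat"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        ids_a = [f"s{i}" for i in range(10)]
        ids_b = [f"n{i}" for i in range(10)]
        d = pd.Series(np.r_[np.linspace(2, 3, 10), np.linspace(0, 1, 10)],
                      index=ids_a + ids_b)
        out = hk.parental_divergence_comparison(self._effects(ids_a, ids_b), d)
        assert out["ks_stat"] == pytest.approx(1.0)

    def test_shifted_uniforms_detected(self):
        rng = np.random.default_rng(4)
        ids_a = [f"s{i}" for i in range(500)]
        ids_b = [f"n{i}" for i in range(500)]
        d = pd.Series(np.r_[rng.uniform(0.5, 1.5, 500),
                            rng.uniform(0, 1, 500)], index=ids_a + ids_b)
        out = hk.parental_divergence_comparison(self._effects(ids_a, ids_b), d)
        assert out["p"] < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="each group"):
            hk.parental_divergence_comparison(
                self._effects(["a"], []), pd.Series({"a": 0.1}))


class TestSegregationSummary:
    def test_split_counts_reported(self):
        bias = pd.concat([
            _bias_frame({"DFO_a": 20, "DFO_b": 22, "Con": 8}, triad="t1"),
            _bias_frame({"Con": 50}, triad="t2"),
        ])
        calls = hk.call_triad_pattern(bias)
        seg = hk.segregation_summary(calls)
        assert seg["n_triads"] == 1
        assert seg["per_triad"].loc["t1"].tolist() == [20, 22]
        assert seg["mean_frac_a"] == pytest.approx(20 / 42)

    def test_no_dual_pattern_triads(self):
        calls = hk.call_triad_pattern(_bias_frame({"Con": 50}))
        seg = hk.segregation_summary(calls)
        assert seg["n_triads"] == 0 and len(seg["per_triad"]) == 0


def test_line_ternary_points_orderings_differ(heb):
    a = hk.inheritance.line_ternary_points(heb, "mean_tpm")
    b = hk.inheritance.line_ternary_points(heb, "mean_ternary")
    # both are valid simplex points but are not the same transform
    assert np.allclose(a[["f_A", "f_B", "f_D"]].sum(axis=1), 1.0)
    assert np.allclose(b[["f_A", "f_B", "f_D"]].sum(axis=1), 1.0)
    assert not np.allclose(a["f_A"], b["f_A"])


def test_dfo_recovery_on_simulated_cis_triads(population):
    """Cis triads detected as significant should mostly support the two
    divergent-from-one-parent patterns when parents differ strongly."""
    heb = hk.heb_table(population.tpm, population.triads)
    f5 = heb[heb["line"].str.startswith("F5")]
    eff = hk.line_effect_scan(f5)
    bias = hk.bias_distance_table(heb, "P1_line", "P2_line")
    truth = population.truth
    sig = set(eff.index[eff["significant"]])
    calls = hk.call_triad_pattern(bias[bias["triad_id"].isin(sig)])
    strong = calls[(calls["parental_distance"] > 0.25)
                   & calls.index.isin(truth.index[truth["effect_type"] == "cis"])]
    if len(strong) >= 5:
        dual = strong["patterns"].str.contains("DFO_a") \
            & strong["patterns"].str.contains("DFO_b")
        assert dual.mean() >= 0.7
    null_sig = calls.index.difference(
        truth.index[truth["effect_type"] == "cis"])
    con = calls.loc[null_sig, "patterns"].eq("Con")
    if len(con):
        assert con.mean() >= 0.9
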