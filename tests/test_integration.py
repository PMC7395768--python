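"""DEMG selection, regional aggregation, correlation models, block concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import photomics as pm
from photomics.cohort import CpGManifest, GenomicBlock
from photomics.integration import DemgCriteria, regional_cpg_counts


def make_manifest(links, n_cpgs=None, island="OpenSea"):
    cpgs = sorted({c for c, _, _ in links})
    if n_cpgs is not None:
        cpgs = sorted(set(cpgs) | {f"cg{i:03d}" for i in range(n_cpgs)})
    sites = pd.DataFrame(
        {
            "chromosome": ["chr1"] * len(cpgs),
            "position": np.arange(1, len(cpgs) + 1) * 100,
            "island_relation": [island] * len(cpgs),
        },
        index=pd.Index(cpgs, name="cpg_id"),
    )
    return CpGManifest(
        sites=sites,
        links=pd.DataFrame(links, columns=["cpg_id", "gene_id", "region_class"]),
    )


def diff_table(effects, qs):
    ids = list(effects.keys())
    return pd.DataFrame(
        {"effect": [effects[i] for i in ids], "q_value": [qs[i] for i in ids]},
        index=pd.Index(ids, name="feature_id"),
    )


class TestSelectDemgs:
    def _meth(self, cpgs, effect=0.5, q=0.01):
        return diff_table({c: effect for c in cpgs}, {c: q for c in cpgs})

    def test_gene_with_three_qualifying_cpgs_is_demg(self):
        links = [(f"cg{i:03d}", "G1", "Enhancer") for i in range(3)]
        table, _ = pm.select_demgs(
            diff_table({"G1": 0.6}, {"G1": 0.01}),
            self._meth([c for c, _, _ in links]),
            make_manifest(links),
        )
        assert bool(table.loc["G1", "demg"])

    def test_two_qualifying_cpgs_is_not_demg(self):
        links = [(f"cg{i:03d}", "G1", "Enhancer") for i in range(2)]
        table, _ = pm.select_demgs(
            diff_table({"G1": 0.6}, {"G1": 0.01}),
            self._meth([c for c, _, _ in links]),
            make_manifest(links),
        )
        assert not bool(table.loc["G1", "demg"])

    def test_intergenic_links_never_qualify(self):
        links = [(f"cg{i:03d}", "G1", "Intergenic") for i in range(5)]
        table, _ = pm.select_demgs(
            diff_table({"G1": 0.6}, {"G1": 0.01}),
            self._meth([c for c, _, _ in links]),
            make_manifest(links),
        )
        assert table.loc["G1", "n_qualifying_cpgs"] == 0

    def test_summary_fractions_up_down(self):
        # 10 up-genes of which 3 DEMG, 10 down of which 4 -> 0.30 / 0.40
        genes = [f"G{i:02d}" for i in range(20)]
        effects = {g: (0.8 if i < 10 else -0.8) for i, g in enumerate(genes)}
        qs = {g: 0.001 for g in genes}
        demg_genes = genes[:3] + genes[10:14]
        links = [(f"cg{gi}{i}", g, "TSS200")
                 for gi, g in enumerate(demg_genes) for i in range(3)]
        meth = self._meth([c for c, _, _ in links])
        table, summary = pm.select_demgs(diff_table(effects, qs), meth,
                                         make_manifest(links))
        assert summary["fraction_up"] == pytest.approx(0.30)
        assert summary["fraction_down"] == pytest.approx(0.40)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i:02d}" for i in range(30)]
        cpgs = [f"cg{i:03d}" for i in range(80)]
        classes = ["TSS200", "TSS1500", "Exon", "Enhancer", "Intergenic"]
        links = [(c, genes[rng.integers(30)], classes[rng.integers(5)])
                 for c in cpgs for _ in range(rng.integers(0, 3))]
        expr = diff_table({g: rng.normal() for g in genes},
                          {g: rng.random() for g in genes})
        meth = diff_table({c: rng.normal(scale=0.3) for c in cpgs},
                          {c: rng.random() for c in cpgs})
        crit = DemgCriteria()
        table, _ = pm.select_demgs(expr, meth, make_manifest(links), crit)
        for g in genes:
            qual = {
                c for c, gg, cls in links
                if gg == g and cls != "Intergenic"
                and meth.loc[c, "q_value"] < crit.cpg_q
                and abs(meth.loc[c, "effect"]) > crit.cpg_abs_effect
            }
            expected = (
                expr.loc[g, "q_value"] < crit.expr_q
                and abs(expr.loc[g, "effect"]) > crit.expr_abs_effect
                and len(qual) >= crit.min_cpgs
            )
            assert bool(table.loc[g, "demg"]) == expected
            assert table.loc[g, "n_qualifying_cpgs"] == len(qual)

    def test_planted_demgs_recovered(self, default_cohort, default_differential):
        truth = default_cohort["truth"]
        table, _ = pm.select_demgs(
            default_differential["expression"],
            default_differential["methylation"],
            default_cohort["manifest"],
        )
        called = set(table.index[table["demg"]])
        tp = len(called & truth.demg_genes)
        sensitivity = tp / len(truth.demg_genes)
        fdr = 1 - tp / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdr <= 0.2


class TestRegionalAggregation:
    def test_single_cpg_gene_row_equals_cpg_values(self):
        links = [("cg000", "G1", "Enhancer")]
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["cg000"],
                         columns=["a", "b", "c"])
        out = pm.aggregate_regional_methylation(m, make_manifest(links),
                                                "Enhancer")
        np.testing.assert_allclose(out.loc["G1"], [1.0, 2.0, 3.0])

    def test_mean_of_two_cpgs(self):
        links = [("cg000", "G1", "TSS200"), ("cg001", "G1", "TSS200")]
        m = pd.DataFrame([[1.0], [3.0]], index=["cg000", "cg001"], columns=["a"])
        out = pm.aggregate_regional_methylation(m, make_manifest(links), "TSS200")
        assert out.loc["G1", "a"] == pytest.approx(2.0)

    def test_shared_cpg_contributes_to_both_genes(self):
        links = [("cg000", "G1", "Exon"), ("cg000", "G2", "Exon"),
                 ("cg001", "G2", "Exon")]
        m = pd.DataFrame([[2.0], [4.0]], index=["cg000", "cg001"], columns=["a"])
        out = pm.aggregate_regional_methylation(m, make_manifest(links), "Exon")
        assert out.loc["G1", "a"] == pytest.approx(2.0)
        assert out.loc["G2", "a"] == pytest.approx(3.0)

    def test_empty_class_warns_and_returns_empty(self):
        links = [("cg000", "G1", "Exon")]
        m = pd.DataFrame([[2.0]], index=["cg000"], columns=["a"])
        with pytest.warns(UserWarning):
            out = pm.aggregate_regional_methylation(m, make_manifest(links),
                                                    "Enhancer")
        assert out.empty


class TestCorrelation:
    def test_perfect_line(self):
        samples = list("abcdefgh")
        meth = pd.DataFrame([np.arange(8.0)], index=["G1"], columns=samples)
        expr = 2.0 * meth
        out = pm.correlate_expression_methylation(expr, {"Enhancer": meth})
        rec = out.iloc[0]
        assert rec["pearson_r"] == pytest.approx(1.0)
        assert rec["slope"] == pytest.approx(2.0)
        assert rec["p_value"] < 1e-10

    def test_zero_variance_skipped(self):
        samples = list("abcde")
        meth = pd.DataFrame([np.arange(5.0)], index=["G1"], columns=samples)
        expr = pd.DataFrame([[3.0] * 5], index=["G1"], columns=samples)
        out = pm.correlate_expression_methylation(expr, {"Exon": meth})
        assert len(out) == 0

    def test_matches_least_squares_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.9, 3.2, 3.9, 5.1])
        samples = list("abcde")
        meth = pd.DataFrame([x], index=["G1"], columns=samples)
        expr = pd.DataFrame([y], index=["G1"], columns=samples)
        out = pm.correlate_expression_methylation(expr, {"TSS200": meth})
        ref = stats.linregress(x, y)
        rec = out.iloc[0]
        assert rec["slope"] == pytest.approx(ref.slope, abs=1e-10)
        assert rec["pearson_r"] == pytest.approx(ref.rvalue, abs=1e-10)
        assert rec["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_random_records_match_linregress(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(12)]
        genes = [f"G{i}" for i in range(15)]
        regional = {}
        for cls in ("Enhancer", "TSS1500"):
            regional[cls] = pd.DataFrame(rng.normal(size=(15, 12)),
                                         index=genes, columns=samples)
        expr = pd.DataFrame(rng.normal(size=(15, 12)), index=genes,
                            columns=samples)
        out = pm.correlate_expression_methylation(expr, regional)
        for rec in out.itertuples():
            ref = stats.linregress(
                regional[rec.region_class].loc[rec.gene_id],
                expr.loc[rec.gene_id],
            )
            assert rec.slope == pytest.approx(ref.slope, abs=1e-10)
            assert rec.pearson_r == pytest.approx(ref.rvalue, abs=1e-10)
            assert rec.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        # joint BH over the pooled p vector
        np.testing.assert_allclose(
            out["q_value"], pm.bh_adjust(out["p_value"].to_numpy()), atol=1e-12
        )

    def test_n_cpgs_reported_from_manifest(self):
        links = [("cg000", "G1", "Enhancer"), ("cg001", "G1", "Enhancer")]
        manifest = make_manifest(links)
        samples = list("abcde")
        rng = np.random.default_rng(0)
        meth = pd.DataFrame([rng.normal(size=5)], index=["G1"], columns=samples)
        expr = pd.DataFrame([rng.normal(size=5)], index=["G1"], columns=samples)
        out = pm.correlate_expression_methylation(expr, {"Enhancer": meth},
                                                  manifest=manifest)
        assert out.iloc[0]["n_cpgs"] == 2
        assert regional_cpg_counts(manifest, "Enhancer")["G1"] == 2


class TestBlockConcordance:
    def test_block_mean_and_sign_match(self):
        links = []
        sites = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "position": [150, 180],
             "island_relation": ["OpenSea", "OpenSea"]},
            index=pd.Index(["cg000", "cg001"], name="cpg_id"),
        )
        manifest = CpGManifest(sites=sites)
        diff = pd.DataFrame({"effect": [-0.4, -0.2], "q_value": [0.01, 0.01]},
                            index=["cg000", "cg001"])
        blocks = [GenomicBlock("b0", "chr1", 100, 200, -0.8)]
        res = pm.block_concordance(diff, manifest, blocks)
        row = res["table"].loc["b0"]
        assert row["mean_effect"] == pytest.approx(-0.3)
        assert bool(row["sign_match"])

    def test_block_without_significant_cpgs_excluded_from_r(self):
        sites = pd.DataFrame(
            {"chromosome": ["chr1"], "position": [150],
             "island_relation": ["OpenSea"]},
            index=pd.Index(["cg000"], name="cpg_id"),
        )
        manifest = CpGManifest(sites=sites)
        diff = pd.DataFrame({"effect": [-0.4], "q_value": [0.5]}, index=["cg000"])
        blocks = [GenomicBlock("b0", "chr1", 100, 200, -0.8)]
        res = pm.block_concordance(diff, manifest, blocks)
        assert res["n_evaluable"] == 0
        assert res["table"].loc["b0", "n_sig_cpgs"] == 0

    def test_block_on_unknown_chromosome_warns(self):
        sites = pd.DataFrame(
            {"chromosome": ["chr1"], "position": [150],
             "island_relation": ["OpenSea"]},
            index=pd.Index(["cg000"], name="cpg_id"),
        )
        manifest = CpGManifest(sites=sites)
        diff = pd.DataFrame({"effect": [-0.4], "q_value": [0.01]}, index=["cg000"])
        blocks = [GenomicBlock("b0", "chrX", 100, 200, -0.8)]
        with pytest.warns(UserWarning, match="chrX"):
            res = pm.block_concordance(diff, manifest, blocks)
        assert "b0" not in res["table"].index

    def test_planted_concordant_blocks_recovered(self, default_cohort,
                                                 default_differential):
        truth = default_cohort["truth"]
        res = pm.block_concordance(
            default_differential["methylation"], default_cohort["manifest"],
            default_cohort["blocks"],
        )
        info = truth.block_info.set_index("block_id")
        conc_ids = info.index[info["concordant"]]
        sub = res["table"].loc[conc_ids]
        assert bool(sub["sign_match"].all())
        r = stats.pearsonr(sub["mean_effect"], sub["reference_delta"])[0]
        assert r >= 0.9
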