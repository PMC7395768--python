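"""MED prefilter, affinity kernels, SNF cross-diffusion, spectral subtyping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import photomics as pm
from photomics.cohort import IRRADIATED
from photomics.differential import beta_to_m
from photomics.fusion import FusedNetwork, FusionParams

from conftest import tiny_config


def naive_affinity(points, k, alpha):
    """Loop-based oracle for the scaled-exponential kernel on 1-D data."""
    x = np.asarray(points, dtype=float)
    sd = x.std(ddof=0)
    z = (x - x.mean()) / (sd if sd else 1.0)
    n = len(z)
    d = np.abs(z[:, None] - z[None, :])
    W = np.zeros((n, n))
    mu = np.empty(n)
    for i in range(n):
        mu[i] = np.mean(sorted(d[i])[1: k + 1])
    for i in range(n):
        for j in range(n):
            eps = max((mu[i] + mu[j] + d[i, j]) / 3.0, 1e-12)
            W[i, j] = np.exp(-d[i, j] ** 2 / (alpha * eps))
    return (W + W.T) / 2.0


def irradiated_views(bundle):
    cohort = bundle["cohort"]
    irr = cohort.sample_table.index[cohort.sample_table["condition"] == IRRADIATED]
    expr = cohort.expression_log2()[irr]
    meth = pd.DataFrame(beta_to_m(cohort.methylation_beta.to_numpy()),
                        index=cohort.methylation_beta.index,
                        columns=cohort.methylation_beta.columns)[irr]
    med = cohort.med_per_sample().loc[irr]
    return expr, meth, med


class TestPrefilter:
    def test_fraction_one_is_identity(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(10, 8)),
                           index=[f"F{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(8)])
        med = pd.Series(rng.normal(size=8), index=mat.columns)
        pd.testing.assert_frame_equal(
            pm.prefilter_by_med_correlation(mat, med, 1.0), mat
        )

    def test_keeps_single_most_correlated_feature(self):
        rng = np.random.default_rng(1)
        med = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        mat = pd.DataFrame(rng.normal(size=(10, 8)),
                           index=[f"F{i}" for i in range(10)], columns=med.index)
        mat.loc["F7"] = med.to_numpy() * 2.0 + 0.01 * rng.normal(size=8)
        out = pm.prefilter_by_med_correlation(mat, med, 0.1)
        assert list(out.index) == ["F7"]

    def test_degenerate_input_rejected(self):
        med = pd.Series(np.arange(4.0), index=list("abcd"))
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(1, 4)),
                           columns=list("abcd"))
        with pytest.raises(ValueError, match=">= 2 input features"):
            pm.prefilter_by_med_correlation(mat, med, 0.5)

    def test_planted_med_features_retained(self, default_cohort):
        truth = default_cohort["truth"]
        expr, meth, med = irradiated_views(default_cohort)
        cfg = default_cohort["config"]
        for mat, level in ((expr, "expression"), (meth, "methylation")):
            kept = pm.prefilter_by_med_correlation(mat, med, 0.10)
            planted = set(truth.med_predictive[level].index)
            frac = len(planted & set(kept.index)) / len(planted)
            assert frac >= 0.9


class TestAffinity:
    def test_identical_samples_have_unit_affinity(self):
        data = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0], [7.0, 1.0]],
                            index=list("abcd"))
        W = pm.build_affinity(data, FusionParams(k=2))
        assert W.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(W), 1.0)

    def test_symmetry_on_random_data(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(20, 50)))
        W = pm.build_affinity(data, FusionParams(k=5)).to_numpy()
        assert np.abs(W - W.T).max() < 1e-12
        assert (W > 0).all() and (W <= 1.0 + 1e-12).all()

    def test_matches_hand_oracle_on_1d_fixture(self):
        points = [0.0, 1.0, 2.0, 10.0]
        data = pd.DataFrame({"x": points}, index=list("abcd"))
        W = pm.build_affinity(data, FusionParams(k=2, alpha=0.5)).to_numpy()
        np.testing.assert_allclose(W, naive_affinity(points, 2, 0.5), atol=1e-10)

    def test_k_too_large_rejected(self):
        data = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="k"):
            pm.build_affinity(data, FusionParams(k=4))


def random_affinities(n_levels=2, n=20, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    out = []
    for _ in range(n_levels):
        data = pd.DataFrame(rng.normal(size=(n, 30)), index=ids)
        out.append(pm.build_affinity(data, FusionParams(k=5)))
    return out


class TestSNF:
    def test_identical_levels_are_order_invariant(self):
        W = random_affinities(1)[0]
        params = FusionParams(k=5, t=10)
        f1 = pm.snf_fuse([W, W.copy()], params)
        f2 = pm.snf_fuse([W.copy(), W], params)
        np.testing.assert_allclose(f1.matrix, f2.matrix, atol=1e-12)

    def test_level_order_invariance(self):
        Ws = random_affinities(3)
        params = FusionParams(k=5, t=10)
        f1 = pm.snf_fuse(Ws, params)
        f2 = pm.snf_fuse([Ws[2], Ws[0], Ws[1]], params)
        np.testing.assert_allclose(f1.matrix, f2.matrix, atol=1e-8)

    def test_permutation_equivariance(self):
        Ws = random_affinities(2)
        params = FusionParams(k=5, t=10)
        base = pm.snf_fuse(Ws, params)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(base.sample_ids))
        permuted = [W.iloc[perm, perm] for W in Ws]
        fused_p = pm.snf_fuse(permuted, params)
        np.testing.assert_allclose(
            fused_p.matrix, base.matrix[np.ix_(perm, perm)], atol=1e-10
        )

    def test_output_symmetric_and_nonnegative(self):
        fused = pm.snf_fuse(random_affinities(2), FusionParams(k=5))
        assert np.abs(fused.matrix - fused.matrix.T).max() <= 1e-10
        assert (fused.matrix >= 0).all()

    def test_block_structure_preserved(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(18)]
        blocks = np.repeat([0, 1, 2], 6)
        levels = []
        for _ in range(2):
            centers = rng.normal(scale=4.0, size=(3, 10))
            data = pd.DataFrame(centers[blocks] + rng.normal(size=(18, 10)),
                                index=ids)
            levels.append(pm.build_affinity(data, FusionParams(k=4)))
        fused = pm.snf_fuse(levels, FusionParams(k=4)).matrix
        within, between = [], []
        for i in range(18):
            for j in range(i + 1, 18):
                (within if blocks[i] == blocks[j] else between).append(fused[i, j])
        assert np.mean(within) > np.mean(between)

    def test_iterates_contract(self, default_cohort):
        """The change between consecutive fused outputs shrinks as t grows."""
        expr, meth, med = irradiated_views(default_cohort)
        levels = []
        for mat in (expr, meth):
            kept = pm.prefilter_by_med_correlation(mat, med, 0.10)
            levels.append(pm.build_affinity(kept.T, FusionParams()))
        outs = {}
        for t in range(14, 21):
            outs[t] = pm.snf_fuse(levels, FusionParams(t=t)).matrix
        deltas = [np.abs(outs[t] - outs[t - 1]).max() for t in range(15, 21)]
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(deltas, deltas[1:]))

    def test_mismatched_sample_ids_rejected(self):
        Ws = random_affinities(2)
        bad = Ws[1].copy()
        bad.index = [f"x{i}" for i in range(len(bad))]
        bad.columns = bad.index
        with pytest.raises(ValueError, match="mismatched"):
            pm.snf_fuse([Ws[0], bad], FusionParams(k=5))


def block_diag_network(sizes, off=0.0):
    n = sum(sizes)
    W = np.full((n, n), off)
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = 1.0
        start += s
    ids = [f"s{i}" for i in range(n)]
    return FusedNetwork(matrix=W, sample_ids=ids), np.repeat(
        np.arange(len(sizes)), sizes)


class TestSpectral:
    def test_exact_on_disconnected_components(self):
        net, truth = block_diag_network([5, 6, 7])
        labels = pm.spectral_cluster(net, 3, seed=0)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_k_one_rejected(self):
        net, _ = block_diag_network([5, 5])
        with pytest.raises(ValueError, match="n_clusters"):
            pm.spectral_cluster(net, 1)

    def test_isolated_sample_named(self):
        W = np.eye(5)
        W[4, 4] = 0.0
        net = FusedNetwork(matrix=W, sample_ids=list("abcde"))
        with pytest.raises(ValueError, match="e"):
            pm.spectral_cluster(net, 2)

    def test_labels_canonicalized_by_first_occurrence(self):
        net, _ = block_diag_network([4, 4])
        labels = pm.spectral_cluster(net, 2, seed=1)
        assert labels.iloc[0] == 0
        assert labels.iloc[-1] == 1


class TestEigengap:
    def test_three_components_give_best_k_three(self):
        net, _ = block_diag_network([5, 6, 7])
        best, gaps = pm.estimate_cluster_number(net)
        assert best == 3
        assert gaps.loc[3] == max(gaps)

    def test_uniform_network_ties_resolve_to_k_min(self):
        n = 10
        net = FusedNetwork(matrix=np.ones((n, n)),
                           sample_ids=[f"s{i}" for i in range(n)])
        best, gaps = pm.estimate_cluster_number(net, k_min=2, k_max=5)
        # complete graph: lambda = (0, 1, ..., 1) so all gaps in [2,5] tie at 0
        assert best == 2
        np.testing.assert_allclose(gaps.to_numpy(), 0.0, atol=1e-10)


class TestEndToEnd:
    def test_subtype_recovery_at_default_conditions(self, default_cohort):
        expr, meth, med = irradiated_views(default_cohort)
        cohort = default_cohort["cohort"]
        res = pm.subtype_cohort(expr, meth, med, n_clusters=3, seed=1)
        subj = cohort.sample_table.loc[res["labels"].index, "subject"]
        truth = cohort.subject_table.loc[subj, "true_subtype"].to_numpy()
        assert res["best_k"] == 3
        assert adjusted_rand_score(truth, res["labels"].to_numpy()) >= 0.8

    def test_recovery_degrades_as_subtype_effect_vanishes(self):
        aris = []
        for shift in (2.0, 0.8, 0.1):
            cfg = tiny_config(n_subjects=24, n_genes=300, n_cpgs=800,
                              n_med_predictive_features=10,
                              n_subtype_signature_genes=30,
                              n_subtype_signature_cpgs=80, seed=9)
            cfg.effect_sizes.subtype_shift = shift
            cohort, _ = pm.generate_cohort(cfg)
            bundle = {"cohort": cohort}
            expr, meth, med = irradiated_views(bundle)
            res = pm.subtype_cohort(expr, meth, med, n_clusters=3, seed=2)
            subj = cohort.sample_table.loc[res["labels"].index, "subject"]
            truth = cohort.subject_table.loc[subj, "true_subtype"].to_numpy()
            aris.append(adjusted_rand_score(truth, res["labels"].to_numpy()))
        assert aris[0] >= aris[1] >= aris[2]
        assert aris[0] >= 0.8
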