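import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from neutropipe.io import SampleTable
from neutropipe.network import (
    GREY,
    ModuleDecomposition,
    adjacency_matrix,
    assign_membership,
    compute_eigengenes,
    cut_modules,
    detect_sample_outliers,
    mcc_hub_genes,
    merge_similar_modules,
    module_eigengene,
    module_trait_stats,
    run_wgcna,
    soft_threshold_scan,
    tom_similarity,
    variance_filter,
)


def planted_block_adjacency(rng, sizes=(60, 60, 60), within=0.9, between=0.05):
    n = sum(sizes)
    a = np.full((n, n), between)
    start = 0
    truth = np.empty(n, dtype=int)
    for b, s in enumerate(sizes):
        a[start:start + s, start:start + s] = within
        truth[start:start + s] = b
        start += s
    a += rng.uniform(-0.02, 0.02, size=(n, n))
    a = np.clip((a + a.T) / 2, 0, 1)
    np.fill_diagonal(a, 0.0)
    return a, truth


def planted_factor_expr(rng, sizes=(60, 60), loading=0.9, n_samples=60, n_noise=30):
    rows = []
    truth = []
    for b, s in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(s):
            rows.append(loading * f + np.sqrt(1 - loading ** 2) * rng.standard_normal(n_samples))
            truth.append(b)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        truth.append(-1)
    genes = [f"g{i:04d}" for i in range(len(rows))]
    expr = pd.DataFrame(rows, index=genes,
                        columns=[f"s{i:03d}" for i in range(n_samples)])
    return expr, np.array(truth)


class TestVarianceFilter:
    def test_fraction_one_is_identity(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 5)),
                            index=[f"g{i}" for i in range(10)])
        assert set(variance_filter(expr, 1.0)) == set(expr.index)

    def test_ten_percent_of_ten_is_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            index=[f"g{i}" for i in range(10)])
        kept = variance_filter(expr, 0.10)
        assert len(kept) == 1
        assert kept[0] == expr.var(axis=1).idxmax()

    def test_tie_broken_lexicographically(self):
        expr = pd.DataFrame([[0, 1.0], [0, 1.0], [0, 0.0]],
                            index=["b_gene", "a_gene", "c_gene"])
        kept = variance_filter(expr, 0.3)
        assert kept == ["a_gene"]


class TestOutliers:
    def test_planted_outlier_flagged(self):
        r = np.random.default_rng(5)
        expr = pd.DataFrame(r.normal(size=(200, 30)),
                            columns=[f"s{i}" for i in range(30)])
        expr["s7"] += 10.0
        assert detect_sample_outliers(expr) == ["s7"]

    def test_null_rarely_flags(self):
        clean = 0
        for s in range(20):
            r = np.random.default_rng(100 + s)
            expr = pd.DataFrame(r.normal(size=(150, 40)),
                                columns=[f"s{i}" for i in range(40)])
            clean += len(detect_sample_outliers(expr)) == 0
        assert clean >= 18

    def test_deterministic(self, rng):
        expr = pd.DataFrame(rng.normal(size=(100, 20)),
                            columns=[f"s{i}" for i in range(20)])
        assert detect_sample_outliers(expr) == detect_sample_outliers(expr)


class TestSoftThreshold:
    def test_connectivity_matches_brute_force_at_beta_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 25)),
                            index=[f"g{i}" for i in range(40)])
        adj = adjacency_matrix(expr, beta=1)
        cor = np.corrcoef(expr.to_numpy())
        brute = np.array([
            sum(abs(cor[i, j]) for j in range(40) if j != i) for i in range(40)
        ])
        assert adj.sum(axis=1) == pytest.approx(brute, abs=1e-10)

    def test_mean_connectivity_decreases_with_beta(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 20)),
                            index=[f"g{i}" for i in range(60)])
        scan = soft_threshold_scan(expr)
        k = dict(zip(scan.betas, scan.mean_connectivity))
        assert k[6] < k[2]
        assert np.all(np.diff(scan.mean_connectivity) < 0)

    def test_planted_modules_reach_scale_free_fit(self):
        # graded loadings plus a noise background give the heavy-tailed
        # connectivity a soft threshold is meant to expose
        r = np.random.default_rng(0)
        rows = []
        for _ in range(3):
            f = r.standard_normal(80)
            for _ in range(60):
                load = r.uniform(0.4, 0.95)
                rows.append(load * f + np.sqrt(1 - load ** 2) * r.standard_normal(80))
        for _ in range(300):
            rows.append(r.standard_normal(80))
        expr = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))],
                            columns=[f"s{i}" for i in range(80)])
        scan = soft_threshold_scan(expr)
        chosen = scan.signed_r2[np.flatnonzero(scan.betas == scan.chosen_beta)[0]]
        assert chosen >= 0.8

    def test_constant_gene_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(35, 10)))
        expr.iloc[0] = 3.0
        with pytest.raises(ValueError, match="constant"):
            adjacency_matrix(expr, beta=2)


class TestTOM:
    def test_perfect_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(a)
        assert tom == pytest.approx(np.ones((3, 3)))

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        assert tom == pytest.approx(np.eye(4))

    def test_matches_cubic_oracle(self, rng):
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        k = a.sum(axis=1)
        for i in range(20):
            for j in range(20):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(20))
                expected = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_fuzz_symmetry_and_bounds(self):
        for s in range(5):
            r = np.random.default_rng(s)
            a = r.uniform(0, 1, size=(30, 30))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(a)
            assert np.allclose(tom, tom.T)
            assert np.all((tom >= 0) & (tom <= 1))
            assert np.all(np.diag(tom) == 1.0)

    def test_invalid_adjacency_rejected(self):
        a = np.ones((3, 3)) * 1.5
        np.fill_diagonal(a, 0.0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            tom_similarity(a)


class TestCutModules:
    def test_planted_blocks_recovered_exactly(self):
        r = np.random.default_rng(1)
        a, truth = planted_block_adjacency(r)
        tom = tom_similarity(a)
        genes = [f"g{i:03d}" for i in range(len(truth))]
        d = cut_modules(tom, genes, min_size=40)
        labels = d.labels.to_numpy()
        assert GREY not in labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_uniform_random_tom_mostly_grey(self):
        grey_fracs = []
        for s in range(10):
            r = np.random.default_rng(50 + s)
            a = r.uniform(0, 0.5, size=(120, 120))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(a)
            d = cut_modules(tom, [f"g{i:03d}" for i in range(120)], min_size=40)
            grey_fracs.append((d.labels == GREY).mean())
        assert np.mean(grey_fracs) >= 0.95

    def test_block_below_min_size_goes_grey(self):
        r = np.random.default_rng(2)
        a, truth = planted_block_adjacency(r, sizes=(39, 80))
        tom = tom_similarity(a)
        genes = [f"g{i:03d}" for i in range(len(truth))]
        d = cut_modules(tom, genes, min_size=40)
        small_block = d.labels.iloc[:39]
        assert (small_block == GREY).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        a = np.ones((5, 5)) - np.eye(5)
        d = cut_modules(tom_similarity(a), list("abcde"), min_size=40)
        assert (d.labels == GREY).all()


class TestEigengene:
    def test_identical_genes_rank_one(self, rng):
        base = rng.normal(size=20)
        expr = pd.DataFrame([base, base, base], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(20)])
        me, ve = module_eigengene(expr, ["a", "b", "c"])
        assert abs(np.corrcoef(me, base)[0, 1]) == pytest.approx(1.0)
        assert ve == pytest.approx(1.0)

    def test_orientation_positive_with_module_mean(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=list("abcde"), columns=[f"s{i}" for i in range(30)])
        me, _ = module_eigengene(expr, list("abcde"))
        zs = (expr - expr.mean(axis=1).to_numpy()[:, None]).div(
            expr.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(me, zs.mean(axis=0))[0, 1] >= 0
        flipped, _ = module_eigengene(-expr, list("abcde"))
        assert np.corrcoef(flipped, (-zs).mean(axis=0))[0, 1] >= 0

    def test_matches_covariance_eigendecomposition(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 40)),
                            index=list("abcde"), columns=[f"s{i}" for i in range(40)])
        me, ve = module_eigengene(expr, list("abcde"))
        zs = ((expr - expr.mean(axis=1).to_numpy()[:, None])
              .div(expr.std(axis=1, ddof=1), axis=0)).to_numpy()
        cov = zs @ zs.T
        w, v = np.linalg.eigh(cov)
        pc = v[:, -1] @ zs
        pc = pc / pc.std(ddof=1)
        if np.corrcoef(pc, zs.mean(axis=0))[0, 1] < 0:
            pc = -pc
        assert me.to_numpy() == pytest.approx(pc, abs=1e-10)
        assert ve == pytest.approx(w[-1] / w.sum(), abs=1e-10)

    def test_orientation_stable_under_gene_reordering(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 25)),
                            index=list("abcdef"), columns=[f"s{i}" for i in range(25)])
        me1, _ = module_eigengene(expr, list("abcdef"))
        me2, _ = module_eigengene(expr.loc[list("fedcba")], list("fedcba"))
        assert me1.to_numpy() == pytest.approx(me2.to_numpy(), abs=1e-10)


class TestMergeAndMembership:
    def make_two_correlated_modules(self, rho, rng, n=80):
        shared = rng.standard_normal(n)
        f1 = shared
        f2 = rho * shared + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        rows, labels = [], []
        for f, name, size in ((f1, "m1", 20), (f2, "m2", 20)):
            for _ in range(size):
                rows.append(0.95 * f + 0.3 * rng.standard_normal(n))
                labels.append(name)
        genes = [f"g{i:03d}" for i in range(len(rows))]
        expr = pd.DataFrame(rows, index=genes, columns=[f"s{i}" for i in range(n)])
        decomp = ModuleDecomposition(pd.Series(labels, index=genes))
        return expr, compute_eigengenes(expr, decomp)

    def test_highly_correlated_modules_merge(self, rng):
        expr, decomp = self.make_two_correlated_modules(0.97, rng)
        merged = merge_similar_modules(expr, decomp, threshold=0.75)
        assert len(merged.modules()) == 1

    def test_weakly_correlated_modules_kept(self, rng):
        expr, decomp = self.make_two_correlated_modules(0.1, rng)
        merged = merge_similar_modules(expr, decomp, threshold=0.75)
        assert len(merged.modules()) == 2

    def test_merge_idempotent(self, rng):
        expr, decomp = self.make_two_correlated_modules(0.9, rng)
        once = merge_similar_modules(expr, decomp, threshold=0.75)
        twice = merge_similar_modules(expr, once, threshold=0.75)
        pd.testing.assert_series_equal(once.labels, twice.labels)

    def test_gene_equal_to_eigengene_assigned(self, rng):
        expr, decomp = self.make_two_correlated_modules(0.1, rng)
        me = decomp.eigengenes.loc["m1"]
        expr.loc["g000"] = me.to_numpy()
        out = assign_membership(expr, decomp, mm_cutoff=0.7)
        assert out.labels["g000"] == "m1"
        assert out.mm.loc["g000", "m1"] == pytest.approx(1.0)

    def test_pure_noise_gene_goes_grey(self, rng):
        grey = 0
        n_reps = 40
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            expr, decomp = self.make_two_correlated_modules(0.1, r, n=60)
            expr.loc["noise"] = r.standard_normal(60)
            out = assign_membership(expr, decomp, mm_cutoff=0.7)
            grey += out.labels["noise"] == GREY
        assert grey / n_reps >= 0.95

    def test_membership_below_cutoff_goes_grey(self, rng):
        expr, decomp = self.make_two_correlated_modules(0.1, rng)
        me = decomp.eigengenes.loc["m1"].to_numpy()
        # construct a gene with |cor| to every eigengene just below 0.7
        noise = rng.standard_normal(me.size)
        me2 = decomp.eigengenes.loc["m2"].to_numpy()
        resid = noise - np.polyval(np.polyfit(me, noise, 1), me)
        target = 0.69
        g = target * (me - me.mean()) / me.std() + np.sqrt(1 - target ** 2) * (
            resid - resid.mean()) / resid.std()
        if abs(np.corrcoef(g, me2)[0, 1]) < 0.7:
            expr.loc["edge"] = g
            out = assign_membership(expr, decomp, mm_cutoff=0.7)
            assert out.labels["edge"] == GREY


class TestTraitStats:
    def build(self, rng, shift):
        n = 60
        groups = ["control"] * 30 + ["cap_admission"] * 30
        t = np.array([0.0] * 30 + [1.0] * 30)
        f_hit = rng.standard_normal(n) + shift * t
        f_null = rng.standard_normal(n)
        rows, labels = [], []
        for f, name in ((f_hit, "hit"), (f_null, "null")):
            for _ in range(25):
                rows.append(0.9 * f + 0.4 * rng.standard_normal(n))
                labels.append(name)
        genes = [f"g{i:03d}" for i in range(len(rows))]
        sample_ids = [f"s{i:03d}" for i in range(n)]
        expr = pd.DataFrame(rows, index=genes, columns=sample_ids)
        samples = SampleTable(pd.DataFrame({"sample_id": sample_ids, "group": groups}))
        decomp = compute_eigengenes(expr, ModuleDecomposition(pd.Series(labels, index=genes)))
        return expr, samples, decomp

    def test_planted_trait_module_has_max_correlation(self, rng):
        expr, samples, decomp = self.build(rng, shift=2.0)
        out = module_trait_stats(expr, decomp, samples)
        best = out.loc[out["cor_trait"].abs().idxmax(), "module"]
        assert best == "hit"
        assert out.set_index("module").loc["hit", "wilcoxon_p"] < 0.001

    def test_trait_flip_negates_correlation(self, rng):
        expr, samples, decomp = self.build(rng, shift=1.0)
        t = pd.Series([0.0] * 30 + [1.0] * 30, index=expr.columns)
        a = module_trait_stats(expr, decomp, samples, trait=t)
        b = module_trait_stats(expr, decomp, samples, trait=1.0 - t)
        assert a["cor_trait"].to_numpy() == pytest.approx(-b["cor_trait"].to_numpy())
        assert a["wilcoxon_p"].to_numpy() == pytest.approx(b["wilcoxon_p"].to_numpy())

    def test_single_class_trait_errors(self, rng):
        expr, samples, decomp = self.build(rng, shift=0.0)
        with pytest.raises(ValueError, match="single class"):
            module_trait_stats(expr, decomp, samples,
                               trait=pd.Series(1.0, index=expr.columns))


class TestMCC:
    def via_graph(self, edges, genes):
        n = len(genes)
        tom = np.zeros((n, n))
        for a, b in edges:
            i, j = genes.index(a), genes.index(b)
            tom[i, j] = tom[j, i] = 1.0
        np.fill_diagonal(tom, 1.0)
        decomp = ModuleDecomposition(pd.Series("m", index=genes))
        # edge_quantile 0 keeps exactly the unit-weight edges
        return mcc_hub_genes(tom, genes, decomp, "m", top_n=10, edge_quantile=1.0)

    def test_triangle_scores_two_each(self):
        out = self.via_graph([("a", "b"), ("b", "c"), ("a", "c")], ["a", "b", "c"])
        assert list(out["mcc_score"]) == [2.0, 2.0, 2.0]

    def test_path_graph_scores(self):
        out = self.via_graph([("a", "b"), ("b", "c")], ["a", "b", "c"])
        scores = dict(zip(out["gene_id"], out["mcc_score"]))
        assert scores == {"a": 1.0, "b": 2.0, "c": 1.0}

    def test_isolated_vertices_score_one_lexicographic(self):
        out = self.via_graph([], ["c", "a", "b"])
        assert list(out["mcc_score"]) == [1.0, 1.0, 1.0]
        assert list(out["gene_id"]) == ["a", "b", "c"]

    def test_tiny_module_errors(self):
        genes = ["a", "b"]
        decomp = ModuleDecomposition(pd.Series("m", index=genes))
        with pytest.raises(ValueError, match="at least 3"):
            mcc_hub_genes(np.eye(2), genes, decomp, "m")


class TestEndToEnd:
    def test_planted_module_recovery_ari(self):
        from neutropipe.diffexpr import log_norm_expression
        from neutropipe.simulate import ModuleSpec, null_config, simulate_cohort

        aris = []
        for seed in range(3):
            cfg = null_config(seed=900 + seed, n_genes=900)
            cfg.planted_modules = [
                ModuleSpec("m1", size=80, loading=1.0, group_shift=0.0),
                ModuleSpec("m2", size=70, loading=1.0, group_shift=0.0),
                ModuleSpec("m3", size=60, loading=1.0, group_shift=0.0),
            ]
            co = simulate_cohort(cfg)
            expr = log_norm_expression(co.counts)
            res = run_wgcna(expr, co.samples, variance_fraction=0.30, min_size=40)
            truth = co.truth.module_labels.loc[res.decomposition.labels.index]
            mask = truth != "none"
            aris.append(adjusted_rand_score(truth[mask], res.decomposition.labels[mask]))
        assert np.mean(aris) >= 0.9

    def test_pipeline_determinism(self):
        from neutropipe.diffexpr import log_norm_expression
        from neutropipe.simulate import SimulationConfig, simulate_cohort

        co = simulate_cohort(SimulationConfig(seed=77, n_genes=600))
        expr = log_norm_expression(co.counts)
        r1 = run_wgcna(expr, co.samples, variance_fraction=0.4)
        r2 = run_wgcna(expr, co.samples, variance_fraction=0.4)
        pd.testing.assert_series_equal(r1.decomposition.labels, r2.decomposition.labels)
        pd.testing.assert_frame_equal(r1.hubs, r2.hubs)
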