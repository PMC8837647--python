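import numpy as np
import pandas as pd
import pytest

from spiralst.enrichment import (
    GeneSetCollection,
    coexpression_clusters,
    gsea_factors,
    gsea_preranked,
    risk_module_score,
    shared_signature,
)
from spiralst.factorize import FactorModel
from spiralst.io_core import NormalizedMatrix


def make_norm(values, genes=None):
    n, g = values.shape
    genes = genes or [f"g{i}" for i in range(g)]
    return NormalizedMatrix(
        values=np.asarray(values, dtype=float),
        gene_ids=genes,
        spot_ids=[f"s{i}" for i in range(n)],
        sample=["d0"] * n,
        variable_genes=list(genes),
        residual_variance=np.ones(g),
    )


# ---------------------------------------------------------------------------
# independent oracles


def ward_d2_oracle(dist, k):
    """Greedy Ward agglomeration via the Lance-Williams ward.D2 update,
    written independently of scipy.  Returns cluster labels at cut k."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(clusters) > k:
        (a, b), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = sizes[a], sizes[b]
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for c in clusters:
            nc = sizes[c]
            dac = d[(min(a, c), max(a, c))]
            dbc = d[(min(b, c), max(b, c))]
            dab = d[(a, b)]
            val = np.sqrt(
                ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dab**2)
                / (na + nb + nc)
            )
            new_d[(c, next_id)] = val
        d = {
            key: v
            for key, v in d.items()
            if a not in key and b not in key
        }
        for (c, nid), v in new_d.items():
            d[(min(c, nid), max(c, nid))] = v
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        next_id += 1
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters.values()):
        labels[members] = lab
    return labels


def es_oracle(ranked_in_set, stats_sorted, weight):
    """Brute-force cumulative running sum for GSEA."""
    inc = np.abs(stats_sorted) ** weight if weight != 0 else np.ones_like(stats_sorted)
    total_in = sum(v for v, m in zip(inc, ranked_in_set) if m)
    n_out = len(ranked_in_set) - sum(ranked_in_set)
    running, out = 0.0, []
    for v, m in zip(inc, ranked_in_set):
        running += (v / total_in) if m else (-1.0 / n_out)
        out.append(running)
    return np.array(out)


# ---------------------------------------------------------------------------


class TestCoexpressionClusters:
    def _block_norm(self, seed=0, n=400, block=10):
        rng = np.random.default_rng(seed)
        latents = rng.normal(size=(n, 3))
        cols, names = [], []
        for b in range(3):
            for g in range(block):
                cols.append(latents[:, b] * 2 + rng.normal(size=n) * 0.5)
                names.append(f"b{b}_g{g}")
        return make_norm(np.column_stack(cols), genes=names), names

    def test_block_recovery_ari_one(self):
        from sklearn.metrics import adjusted_rand_score

        norm, names = self._block_norm()
        assign, corr, best = coexpression_clusters(norm, names, k=3)
        truth = [int(n[1]) for n in names]
        assert adjusted_rand_score(truth, [assign[g] for g in names]) == 1.0
        assert np.all(np.diag(corr.to_numpy()) == 0)

    def test_scipy_matches_ward_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            x = rng.normal(size=(50, 8))
            norm = make_norm(x)
            genes = list(norm.gene_ids)
            assign, corr, _ = coexpression_clusters(norm, genes, k=3)
            dist = 1.0 - corr.to_numpy()
            np.fill_diagonal(dist, 0.0)
            oracle = ward_d2_oracle(dist, k=3)
            # compare partitions up to label permutation
            from sklearn.metrics import adjusted_rand_score

            mine = [assign[g] for g in genes]
            assert adjusted_rand_score(mine, oracle) == 1.0

    def test_k_equals_n_singletons(self):
        norm, names = self._block_norm()
        sub = names[:5]
        assign, _, _ = coexpression_clusters(norm, sub, k=5)
        assert len(set(assign.values())) == 5

    def test_absent_genes_dropped_with_warning(self, caplog):
        norm, names = self._block_norm()
        with caplog.at_level("WARNING", logger="spiralst.enrichment"):
            assign, _, _ = coexpression_clusters(norm, names[:6] + ["nope"], k=2)
        assert "nope" not in assign

    def test_too_few_genes(self):
        norm, names = self._block_norm()
        with pytest.raises(ValueError, match="need >= k"):
            coexpression_clusters(norm, names[:2], k=3)

    def test_best_cluster_is_most_coexpressed(self):
        norm, names = self._block_norm()
        # add uncorrelated noise genes; the planted blocks should outrank them
        assign, corr, best = coexpression_clusters(norm, names, k=3)
        members = [g for g, lab in assign.items() if lab == best]
        sub = corr.loc[members, members].to_numpy()
        mean_r = sub[np.triu_indices(len(members), 1)].mean()
        assert mean_r > 0.5


class TestRiskModuleScore:
    def test_follicle_hotspot_enrichment(self, bundle, norm):
        t = bundle.truth
        table = risk_module_score(norm, t.planted_sets["follicle"], seed=0)
        v = table.scores.iloc[:, 0].to_numpy()
        hot = t.true_W[:, t.factor_names.index("follicle")] > 0.5
        null_sd = v[~hot].std()
        assert v[hot].mean() - v[~hot].mean() >= 3 * null_sd

    def test_empty_cluster_error(self, norm):
        with pytest.raises(ValueError, match="empty"):
            risk_module_score(norm, [], seed=0)

    def test_deterministic(self, bundle, norm):
        genes = bundle.truth.planted_sets["follicle"]
        a = risk_module_score(norm, genes, seed=7)
        b = risk_module_score(norm, genes, seed=7)
        np.testing.assert_array_equal(a.scores.to_numpy(), b.scores.to_numpy())


class TestGseaPreranked:
    def test_top20_maximal_enrichment(self):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.normal(size=1000))[::-1]
        genes = [f"g{i}" for i in range(1000)]
        res = gsea_preranked(dict(zip(genes, stats)), genes[:20], n_perm=1000, seed=0)
        assert res.es >= 0.95
        assert res.p == pytest.approx(1.0 / 1001.0)
        assert set(res.leading_edge) == set(genes[:20])

    def test_running_sum_matches_oracle(self):
        rng = np.random.default_rng(1)
        from spiralst.enrichment import _running_sum

        for _ in range(100):
            n = int(rng.integers(50, 300))
            stats = np.sort(rng.normal(size=n))[::-1]
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, size=int(rng.integers(5, 30)), replace=False)] = True
            mine = _running_sum(in_set, stats, 1.0)
            oracle = es_oracle(in_set.tolist(), stats, 1.0)
            np.testing.assert_allclose(mine, oracle, atol=1e-12)

    def test_es_antisymmetric_under_reversal_weight0(self):
        rng = np.random.default_rng(2)
        stats = np.sort(rng.normal(size=200))[::-1]
        genes = [f"g{i}" for i in range(200)]
        gene_set = [genes[i] for i in rng.choice(200, 40, replace=False)]
        fwd = gsea_preranked(
            dict(zip(genes, stats)), gene_set, n_perm=10, seed=0, gsea_weight=0.0
        )
        rev = gsea_preranked(
            dict(zip(genes, -stats)), gene_set, n_perm=10, seed=0, gsea_weight=0.0
        )
        assert fwd.es == pytest.approx(-rev.es, abs=1e-12)

    def test_pvalue_monotone_transform_invariant_weight0(self):
        rng = np.random.default_rng(3)
        stats = np.sort(rng.normal(size=150))[::-1]
        genes = [f"g{i}" for i in range(150)]
        gene_set = [genes[i] for i in rng.choice(150, 25, replace=False)]
        a = gsea_preranked(
            dict(zip(genes, stats)), gene_set, n_perm=200, seed=5, gsea_weight=0.0
        )
        b = gsea_preranked(
            dict(zip(genes, np.exp(stats))), gene_set, n_perm=200, seed=5,
            gsea_weight=0.0,
        )
        assert a.p == b.p and a.es == pytest.approx(b.es, abs=1e-12)

    def test_size_bounds_skip(self):
        stats = dict(zip([f"g{i}" for i in range(100)], np.arange(100.0)[::-1]))
        res = gsea_preranked(stats, ["g0", "g1"], min_size=15, max_size=500)
        assert res.skipped is not None and np.isnan(res.es)

    def test_empty_intersection_error(self):
        stats = dict(zip([f"g{i}" for i in range(50)], np.arange(50.0)))
        with pytest.raises(ValueError, match="no genes"):
            gsea_preranked(stats, ["absent"])

    def test_planted_sets_hit_only_own_factor(self):
        # a constructed 20-factor loading matrix with exclusive marker sets:
        # each set must be significant only for its own factor
        rng = np.random.default_rng(4)
        n_genes, K, m = 1000, 20, 15
        genes = [f"g{i}" for i in range(n_genes)]
        H = rng.uniform(0.0, 0.3, size=(K, n_genes))
        sets = {}
        for k in range(K):
            idx = np.arange(k * m, (k + 1) * m)
            H[k, idx] = rng.uniform(5.0, 8.0, size=m)
            sets[f"set{k}"] = [genes[i] for i in idx]
        model = FactorModel(
            W=np.ones((2, K)), H=H, gene_ids=genes, spot_ids=["a", "b"],
            K=K, seed=0,
        )
        results = gsea_factors(
            model, GeneSetCollection(sets), n_perm=500, seed=0
        )
        for r in results:
            own = r.target == f"factor_{r.set_name[3:]}"
            if own:
                assert r.padj < 0.05, f"{r.set_name} missed its own factor"
            else:
                assert r.padj >= 0.05, f"{r.set_name} hit {r.target}"


class TestSharedSignature:
    def _model(self):
        rng = np.random.default_rng(0)
        H = rng.uniform(size=(2, 300))
        genes = [f"g{i}" for i in range(300)]
        return FactorModel(
            W=np.ones((2, 2)), H=H, gene_ids=genes, spot_ids=["a", "b"],
            K=2, seed=0,
        )

    def test_disjoint_empty(self):
        model = self._model()
        assert shared_signature(["absent1", "absent2"], model, 0) == []

    def test_planted_overlap_exact(self):
        model = self._model()
        top100 = model.top_genes(0, 100)
        overlap = top100[10:40]  # 30 genes inside the top 100
        outside = [g for g in model.gene_ids if g not in set(top100)][:5]
        result = shared_signature(overlap + outside, model, 0, top_k=100)
        assert sorted(result) == sorted(overlap)

    def test_superset_returns_top_intersection(self):
        model = self._model()
        result = shared_signature(list(model.gene_ids), model, 1, top_k=100)
        assert result == model.top_genes(1, 100)
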