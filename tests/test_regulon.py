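from math import comb

import numpy as np
import pandas as pd
import pytest

from mmra import regulon as reg
from mmra.types import ClassificationRecord, ExpressionMatrix, NullModelSpec, Regulon


def _expr(values, genes=None, samples=None):
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestQuantileNormalize:
    def test_column_permutations_become_identical_sorted(self, rng):
        col = rng.normal(size=50)
        values = np.column_stack([col, rng.permutation(col), rng.permutation(col)])
        qn = reg.quantile_normalize(values)
        ref = np.sort(qn[:, 0])
        for j in range(3):
            assert np.allclose(np.sort(qn[:, j]), ref)

    def test_preserves_within_column_ranks(self, rng):
        values = rng.normal(size=(30, 4))
        qn = reg.quantile_normalize(values)
        for j in range(4):
            assert np.array_equal(np.argsort(values[:, j]), np.argsort(qn[:, j]))


class TestPreprocess:
    def test_sd_filter_matches_brute_force(self, rng):
        mrna = _expr(rng.normal(5, 1, size=(500, 60))
                     * rng.uniform(0.5, 2.5, size=(500, 1)))
        hub_row = rng.normal(5, 1.5, size=60)
        pre = reg.preprocess_for_network(mrna, hub_row, "HUB", sd_min=1.2)
        # brute-force recount of the rule on the same processed scale
        stacked = np.vstack([mrna.values.to_numpy(), hub_row[None, :]])
        relog = np.log2(reg.quantile_normalize(2.0 ** stacked))
        expected = int((relog[:-1].std(axis=1) >= 1.2).sum()) + 1  # + hub
        assert pre.matrix.shape[0] == expected
        assert "HUB" in pre.matrix.index
        assert len(pre.removed) == 501 - expected

    def test_constant_gene_removed_hub_exempt(self, rng):
        vals = rng.normal(5, 2, size=(5, 40))
        vals[0] = 7.0  # constant gene: s.d. 0
        mrna = _expr(vals)
        pre = reg.preprocess_for_network(mrna, rng.normal(5, 0.1, size=40), "HUB")
        assert "G0" in pre.removed
        assert "HUB" in pre.matrix.index  # hub s.d. << 1.2 but retained

    def test_constant_hub_rejected(self, rng):
        mrna = _expr(rng.normal(size=(3, 20)))
        with pytest.raises(ValueError, match="constant"):
            reg.preprocess_for_network(mrna, np.full(20, 3.0), "HUB")


class TestMutualInformation:
    def test_exactly_symmetric(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert reg.mutual_information(x, y) == reg.mutual_information(y, x)

    def test_invariant_under_monotone_transforms(self, rng):
        x, y = rng.normal(size=80), rng.normal(size=80)
        a = reg.mutual_information(x, y)
        assert reg.mutual_information(np.exp(x), y) == a
        # decreasing transforms reverse the ranks: identical up to float
        # summation order
        assert reg.mutual_information(x, -1.0 / (1 + np.exp(-y))) == \
            pytest.approx(a, rel=1e-12)

    def test_self_dependence_is_maximal(self, rng):
        x = rng.normal(size=300)
        others = [rng.normal(size=300) for _ in range(5)]
        mi_self = reg.mutual_information(x, x)
        assert all(reg.mutual_information(x, o) < mi_self for o in others)

    def test_independent_permutation_below_significance(self, rng):
        x = rng.normal(size=500)
        y = rng.permutation(x)
        thr = reg.mi_significance_threshold(500, p_target=0.05, n_null=2000, seed=0)
        assert reg.mutual_information(x, y) < thr

    def test_gaussian_closed_form(self, rng):
        rho = 0.5
        cov = [[1, rho], [rho, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=2000)
        mi = reg.mutual_information(z[:, 0], z[:, 1])
        assert mi == pytest.approx(-0.5 * np.log(1 - rho ** 2), abs=0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            reg.mutual_information(np.ones(20), np.arange(20.0))


class TestMiSignificanceThreshold:
    def test_p_target_one_gives_zero(self):
        assert reg.mi_significance_threshold(100, p_target=1.0) == 0.0

    def test_monotone_in_p_target(self):
        t3 = reg.mi_significance_threshold(150, p_target=1e-3, n_null=5000, seed=1)
        t7 = reg.mi_significance_threshold(150, p_target=1e-7, n_null=5000, seed=1)
        assert t7 > t3

    def test_monotone_decreasing_in_n_samples(self):
        a = reg.mi_significance_threshold(80, p_target=1e-7, n_null=5000, seed=1)
        b = reg.mi_significance_threshold(320, p_target=1e-7, n_null=5000, seed=1)
        assert b < a

    def test_extrapolation_tracks_direct_percentile(self, rng):
        # at a reachable tail probability the extrapolated threshold should
        # sit close to the direct empirical quantile of the same null
        n = 200
        thr = reg.mi_significance_threshold(n, p_target=1e-3, n_null=20_000, seed=3)
        h = reg.mi_bandwidth(n)
        grid = (np.arange(1, n + 1) - 0.5) / n
        null = np.array([reg._mi_from_copula(grid, rng.permutation(grid), h)
                         for _ in range(20_000)])
        assert thr == pytest.approx(np.quantile(null, 0.999), rel=0.10)


def _driver_system(rng, n=150, n_targets=20, n_noise=80, slope=-0.8, noise=0.4):
    # the hub must share the genes' expression range: quantile normalization
    # works on within-sample ranks, and a hub far below every gene would be
    # pinned to the reference minimum
    hub = rng.normal(5, 1.5, size=n)
    targets = (5 + slope * (hub[None, :] - 5)
               + rng.normal(0, noise, size=(n_targets, n)))
    noise_genes = rng.normal(5, 1.5, size=(n_noise, n))
    genes = [f"T{i}" for i in range(n_targets)] + [f"N{i}" for i in range(n_noise)]
    mrna = _expr(np.vstack([targets, noise_genes]), genes=genes)
    return mrna, hub


class TestBuildRegulon:
    def test_planted_targets_recovered_with_full_support(self, rng):
        mrna, hub = _driver_system(rng)
        pre = reg.preprocess_for_network(mrna, hub, "HUB", sd_min=0.0)
        thr = reg.mi_significance_threshold(150, p_target=1e-7, n_null=5000, seed=0)
        r = reg.build_regulon(pre, "HUB", thr, n_boot=30, consensus_p=1e-12, seed=0)
        target_edges = {g for g in r.genes if g.startswith("T")}
        assert len(target_edges) == 20
        assert all(r.edges[g][1] == 30 for g in target_edges)
        assert len(r.genes - target_edges) <= 2  # at most stray noise genes

    def test_noise_hub_gives_empty_regulon(self, rng):
        mrna, _ = _driver_system(rng, n_targets=1, n_noise=60)
        hub = rng.normal(0, 1.5, size=150)  # independent of everything
        pre = reg.preprocess_for_network(mrna, hub, "HUB", sd_min=0.0)
        thr = reg.mi_significance_threshold(150, p_target=1e-7, n_null=5000, seed=0)
        r = reg.build_regulon(pre, "HUB", thr, n_boot=20, seed=0)
        assert len(r) <= 1

    def test_edges_shrink_as_threshold_rises(self, rng):
        # raising the MI threshold can only lower each edge's bootstrap
        # support; with a non-saturated edge-keeping rate the consensus
        # regulon shrinks accordingly (with the same bootstrap seed)
        mrna, hub = _driver_system(rng, slope=-0.4, noise=1.0)
        pre = reg.preprocess_for_network(mrna, hub, "HUB", sd_min=0.0)
        supports, sizes = [], []
        for thr in [0.12, 0.14, 0.16, 0.20]:
            r = reg.build_regulon(pre, "HUB", thr, n_boot=15,
                                  consensus_p=1e-6, seed=123)
            sizes.append(len(r))
            supports.append({g: r.edges[g][1] for g in r.genes})
        assert sizes == sorted(sizes, reverse=True)
        for tighter, looser in zip(supports[1:], supports):
            for g, s in tighter.items():
                assert s <= looser.get(g, 15)


class TestMraTest:
    def test_identical_sets_extreme_p(self):
        genes = [f"G{i}" for i in range(1000)]
        r = Regulon("M", {g: (0.3, 10, 1e-15) for g in genes[:50]}, n_boot=10)
        res = reg.mra_test(r, set(genes[:50]), genes)
        assert res.fisher_p < 1e-40

    def test_disjoint_sets_p_near_one(self):
        genes = [f"G{i}" for i in range(200)]
        r = Regulon("M", {g: (0.3, 10, 1e-15) for g in genes[:50]}, n_boot=10)
        res = reg.mra_test(r, set(genes[100:150]), genes)
        assert res.fisher_p > 0.95

    def test_empty_regulon_p_one(self):
        res = reg.mra_test(Regulon("M", {}), {"G1"}, {"G1", "G2"})
        assert res.fisher_p == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # 2x2 table (10, 40; 15, 935): universe 1000, regulon 50, signature 25
        from tests.test_enrich import brute_force_hypergeom_tail
        genes = [f"G{i}" for i in range(1000)]
        regulon_genes = genes[:50]
        signature = set(genes[:10]) | set(genes[50:65])
        r = Regulon("M", {g: (0.3, 10, 1e-15) for g in regulon_genes}, n_boot=10)
        res = reg.mra_test(r, signature, genes)
        assert res.overlap == 10
        assert res.fisher_p == pytest.approx(
            brute_force_hypergeom_tail(1000, 25, 50, 10), rel=1e-9)

    def test_small_tables_match_enumeration(self, rng):
        from tests.test_enrich import brute_force_hypergeom_tail
        for _ in range(25):
            n_u = int(rng.integers(10, 51))
            genes = [f"G{i}" for i in range(n_u)]
            n_r = int(rng.integers(1, n_u))
            n_s = int(rng.integers(1, n_u))
            regulon_genes = list(rng.choice(genes, n_r, replace=False))
            signature = set(rng.choice(genes, n_s, replace=False))
            r = Regulon("M", {g: (0.3, 1, 0.0) for g in regulon_genes})
            res = reg.mra_test(r, signature, genes)
            assert res.fisher_p == pytest.approx(
                brute_force_hypergeom_tail(n_u, n_s, n_r, res.overlap), rel=1e-9)


class TestNullModel:
    def test_threshold_is_order_statistic(self):
        from mmra.types import MraResult
        ps = [0.5, 0.9, 0.01, 0.3, 0.7]
        results = [MraResult("M", "C", "A", "UP", 0, p) for p in ps]
        thr = reg.mra_threshold_from_null(results, percentile=95)
        assert thr == pytest.approx(np.percentile(ps, 5))

    def test_empty_null_falls_back(self):
        assert reg.mra_threshold_from_null([], fallback=1e-4) == 1e-4

    def test_detection_and_snr_rules(self, default_dataset, default_truth):
        from mmra.diffexp import select_core_samples
        mrna, mirna, records, _, _, _ = default_dataset
        cores = select_core_samples(records, "SIM")
        drivers = set(default_truth["drivers"])
        values = mirna.values.to_numpy()
        spec = NullModelSpec()
        # qualification logic only: use empty candidate list and skip regulons
        from mmra.regulon import _snr
        from mmra.diffexp import _contrast_columns
        qualified = []
        for i, mid in enumerate(mirna.feature_ids):
            snrs = []
            for subtype in cores.cores:
                x_idx, y_idx = _contrast_columns(mirna, cores, subtype)
                snrs.append(abs(_snr(values[i, x_idx], values[i, y_idx])))
            if max(snrs) < spec.snr_bound:
                qualified.append(mid)
        assert not set(qualified) & drivers      # drivers are differential
        assert len(qualified) >= 3               # some decoys qualify

    def test_low_detection_mirna_excluded(self, rng):
        # microRNA "detected" in 30 of 450 samples fails the >10% rule
        vals = np.full((2, 450), -1.0)
        vals[0, :30] = 5.0
        vals[1] = rng.normal(5, 0.1, size=450)
        mirna = _expr(vals, genes=["MLOW", "MOK"])
        records = [ClassificationRecord(f"S{i}", "C", "A" if i < 225 else "B",
                                        0.01, 0.1) for i in range(450)]
        from mmra.diffexp import select_core_samples
        cores = select_core_samples(records, "C", delta_percentile=100)
        mrna = _expr(rng.normal(5, 2, size=(30, 450)))
        out = reg.build_null_model(mirna, [cores], [], NullModelSpec(),
                                   mrna, mi_threshold=0.5, n_boot=2, seed=0)
        assert all(r.hub != "MLOW" for r in out)


class TestMiRankEnrichment:
    def _regulon(self, mis):
        # zero-padded names so lexicographic tie-breaks follow the index
        return Regulon("M", {f"G{i:02d}": (mi, 10, 1e-15)
                             for i, mi in enumerate(mis)})

    def test_top_ranked_signature_maximal_es(self):
        mis = sorted(np.linspace(0.1, 1.0, 20), reverse=True)
        r = self._regulon(mis)
        top = {g for g in r.genes if r.mi(g) >= sorted(mis, reverse=True)[4]}
        res = reg.mi_rank_enrichment(r, top, n_perm=200, seed=0)
        assert res.es == pytest.approx(1.0)      # hits exhaust before any miss
        assert res.perm_p < 0.05
        assert set(res.leading_edge) == top

    def test_uniform_placement_not_significant(self):
        r = self._regulon([1.0] * 20)
        hits = {f"G{i:02d}" for i in range(0, 20, 4)}  # evenly spaced
        res = reg.mi_rank_enrichment(r, hits, n_perm=300, seed=0)
        assert res.perm_p > 0.3
        assert abs(res.nes) < 1.5

    def test_equal_weight_running_sum_matches_hand_computation(self):
        # 20 genes, 5 hits at ranks 1-3, 10, 15 (1-based), unit weights:
        # steps +1/5 at hits, -1/15 at misses; peak after rank 3 = 3/5
        r = self._regulon([1.0] * 20)
        hits = {"G00", "G01", "G02", "G09", "G14"}
        res = reg.mi_rank_enrichment(r, hits, n_perm=100, seed=0)
        assert res.es == pytest.approx(3 / 5)

    def test_no_signature_genes_rejected(self):
        r = self._regulon([0.5, 0.4])
        with pytest.raises(ValueError):
            reg.mi_rank_enrichment(r, {"ZZZ"}, n_perm=10, seed=0)
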