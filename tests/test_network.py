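import numpy as np
import pytest

from otuwas import (
    OtuCountTable,
    SimulationConfig,
    block_correlation,
    build_network,
    cag_phenotype_assoc,
    cluster_cags,
    permanova,
    simulate,
    sparcc,
    sparcc_bootstrap_p,
    to_relative,
)
from conftest import make_pheno, rel_from_matrix


def two_block_panel(seed, n=200, m=24, block=8, rho=0.8, depth=20_000):
    C = block_correlation(m, [(0, block, rho), (block, block, rho)])
    cfg = SimulationConfig(
        n_samples=n, n_otus=m, library_depth=depth, n_cages=1, cage_sd=0.0,
        sex_effect=0.0, zero_inflation=1.0, log_mean=np.zeros(m), log_sd=1.0,
        basis_correlation=C, seed=seed,
    )
    table, _, _ = simulate(cfg)
    return table


class TestSparcc:
    def test_symmetry_and_unit_diagonal(self, rng):
        counts = OtuCountTable(
            [f"s{i}" for i in range(30)],
            [f"o{j}" for j in range(6)],
            rng.integers(0, 500, size=(30, 6)),
        )
        r = sparcc(counts, n_inner=5, seed=1)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1).all()

    def test_requires_four_otus(self, rng):
        counts = OtuCountTable(["s1", "s2"], ["a", "b", "c"], rng.integers(1, 9, (2, 3)))
        with pytest.raises(ValueError, match="4 OTU"):
            sparcc(counts)

    def test_deterministic_given_seed(self, rng):
        counts = OtuCountTable(
            [f"s{i}" for i in range(20)], [f"o{j}" for j in range(5)],
            rng.integers(0, 300, size=(20, 5)),
        )
        np.testing.assert_array_equal(
            sparcc(counts, n_inner=5, seed=4), sparcc(counts, n_inner=5, seed=4)
        )

    def test_recovers_planted_blocks(self):
        """Within-block correlations near the planted 0.8, cross-block near 0."""
        table = two_block_panel(seed=7)
        r = sparcc(table, n_exclude_iter=60, seed=1)
        iu = np.triu_indices(8, 1)
        within = (r[:8, :8][iu].mean() + r[8:16, 8:16][iu].mean()) / 2
        cross = np.abs(r[:8, 8:16]).mean()
        assert abs(within - 0.8) < 0.1
        assert cross < 0.15

    def test_null_correlations_shrink_with_n(self):
        """Mean off-diagonal |r| on independent OTUs is small at n=500."""
        cfg = SimulationConfig(
            n_samples=500, n_otus=12, library_depth=20_000, n_cages=1, cage_sd=0.0,
            sex_effect=0.0, zero_inflation=1.0, log_mean=np.zeros(12), seed=3,
        )
        table, _, _ = simulate(cfg)
        r = sparcc(table, seed=2)
        off = np.abs(r[np.triu_indices(12, 1)])
        assert off.mean() < 0.1


class TestBootstrapP:
    def test_minimum_attainable_p(self, rng):
        counts = OtuCountTable(
            [f"s{i}" for i in range(25)], [f"o{j}" for j in range(5)],
            rng.integers(0, 200, size=(25, 5)),
        )
        r = sparcc(counts, n_inner=5, seed=0)
        p = sparcc_bootstrap_p(counts, r, n_boot=50, seed=1, n_inner=3)
        assert p.min() >= 1 / 51 - 1e-12

    def test_requires_50_bootstraps(self, rng):
        counts = OtuCountTable(
            [f"s{i}" for i in range(10)], [f"o{j}" for j in range(4)],
            rng.integers(1, 50, size=(10, 4)),
        )
        with pytest.raises(ValueError):
            sparcc_bootstrap_p(counts, np.eye(4), n_boot=10)

    def test_planted_pair_reaches_min_p_null_pair_does_not(self):
        table = two_block_panel(seed=11, m=12, block=4, rho=0.9)
        r = sparcc(table, n_exclude_iter=30, seed=5)
        p = sparcc_bootstrap_p(table, r, n_boot=60, seed=6, n_inner=5, n_exclude_iter=30)
        iu = np.triu_indices(4, 1)
        assert (p[:4, :4][iu] <= 1 / 61 + 1e-12).all()
        assert p[8:, 8:][np.triu_indices(4, 1)].mean() > 0.2


class TestBuildNetwork:
    def test_strict_thresholds(self):
        ids = ["a", "b", "c"]
        r = np.array([[1.0, 0.4, -0.41], [0.4, 1.0, 0.2], [-0.41, 0.2, 1.0]])
        p = np.full((3, 3), 0.01)
        edges = build_network(r, p, ids)
        assert edges == [("a", "c", -0.41, 0.01)]

    def test_matches_brute_force(self, rng):
        m = 15
        ids = [f"o{j}" for j in range(m)]
        r = rng.uniform(-1, 1, (m, m))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        p = rng.random((m, m))
        p = (p + p.T) / 2
        edges = build_network(r, p, ids, 0.3, 0.1)
        expected = set()
        for i in range(m):
            for j in range(m):
                if i < j and p[i, j] < 0.1 and abs(r[i, j]) > 0.3:
                    expected.add((ids[i], ids[j]))
        assert {(a, b) for a, b, *_ in edges} == expected

    def test_invariant_to_otu_ordering(self, rng):
        m = 10
        ids = [f"o{j}" for j in range(m)]
        r = rng.uniform(-1, 1, (m, m)); r = (r + r.T) / 2; np.fill_diagonal(r, 1.0)
        p = rng.random((m, m)); p = (p + p.T) / 2
        edges = {frozenset((a, b)) for a, b, *_ in build_network(r, p, ids)}
        perm = rng.permutation(m)
        edges2 = {
            frozenset((a, b))
            for a, b, *_ in build_network(
                r[np.ix_(perm, perm)], p[np.ix_(perm, perm)], [ids[i] for i in perm]
            )
        }
        assert edges == edges2


class TestClusterCags:
    def test_perfect_blocks_exact_recovery(self):
        r = np.block(
            [[np.ones((3, 3)), -np.ones((3, 2))], [-np.ones((2, 3)), np.ones((2, 2))]]
        )
        labels = cluster_cags(r, ["a", "b", "c", "d", "e"], k=2)
        assert labels == {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2}

    def test_k_equals_n(self):
        labels = cluster_cags(np.eye(4), ["a", "b", "c", "d"], k=4)
        assert sorted(labels.values()) == [1, 2, 3, 4]

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_cags(np.eye(3), ["a", "b", "c"], k=4)

    def test_noisy_blocks_recovered(self, rng):
        from sklearn.metrics import rand_score

        scores = []
        for _ in range(20):
            m = 12
            r = np.full((m, m), -0.3) + rng.normal(0, 0.1, (m, m))
            r[:6, :6] = 0.6 + rng.normal(0, 0.1, (6, 6))
            r[6:, 6:] = 0.6 + rng.normal(0, 0.1, (6, 6))
            r = np.clip((r + r.T) / 2, -1, 1)
            np.fill_diagonal(r, 1.0)
            labels = cluster_cags(r, [f"o{j:02d}" for j in range(m)], k=2)
            truth = [1] * 6 + [2] * 6
            scores.append(rand_score(truth, [labels[f"o{j:02d}"] for j in range(m)]))
        assert np.mean(scores) >= 0.9


class TestPermanova:
    def test_separated_blocks_min_p(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        f, p = permanova(d, [1] * 10 + [2] * 10, n_perm=999, seed=0)
        # label swaps reproduce the same partition, so ties with F_obs can
        # lift p one notch above the 1/1000 minimum
        assert p <= 0.005
        assert f > 100

    def test_matches_scikit_bio(self, rng):
        """Pseudo-F agrees with the independent PERMANOVA implementation."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(0, 1, (18, 3))
        pts[9:] += 0.8
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [1] * 9 + [2] * 9
        f, _ = permanova(d, labels, n_perm=99, seed=1)
        res = skbio_permanova(DistanceMatrix(d), [str(l) for l in labels], permutations=99)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_degenerate_all_identical(self):
        with pytest.raises(ValueError, match="identical"):
            permanova(np.zeros((6, 6)), [1, 1, 1, 2, 2, 2])

    def test_singleton_group_rejected(self, rng):
        d = np.abs(rng.normal(0, 1, (5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, [1, 1, 1, 1, 2])

    def test_null_p_values_approximately_uniform(self, rng):
        """Kolmogorov-Smirnov does not reject uniformity of null p-values."""
        from scipy import stats

        pvals = []
        pts = rng.standard_normal((24, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for i in range(200):
            labels = rng.permutation([1] * 12 + [2] * 12)
            _, p = permanova(d, labels, n_perm=99, seed=i)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCagAssociation:
    def test_monotone_phenotype_gives_rho_one(self, rng):
        ab = rng.dirichlet(np.ones(4), size=20)
        rel = rel_from_matrix(ab)
        cag = {"otu0": 1, "otu1": 1}
        group_ab = ab[:, :2].sum(axis=1)
        pheno = make_pheno(np.exp(group_ab), adjusted=True)
        pheno.data["phenotype_adj"] = np.exp(group_ab)
        out = cag_phenotype_assoc(rel, cag, pheno)
        assert out[0].spearman_rho == pytest.approx(1.0)
        assert out[0].q == out[0].p  # single CAG: BH leaves p unchanged

    def test_sum_vs_mean_abundance_same_rho(self, rng):
        """Group abundance as mean instead of sum leaves Spearman unchanged."""
        from scipy import stats

        ab = rng.dirichlet(np.ones(6), size=30)
        y = rng.normal(0, 1, 30)
        s = ab[:, :3].sum(axis=1)
        assert stats.spearmanr(s, y)[0] == pytest.approx(stats.spearmanr(s / 3, y)[0])

    def test_null_association_rarely_significant(self, rng):
        hits = 0
        for i in range(50):
            ab = rng.dirichlet(np.ones(6), size=40)
            rel = rel_from_matrix(ab)
            pheno = make_pheno(rng.normal(0, 1, 40), adjusted=True)
            out = cag_phenotype_assoc(rel, {"otu0": 1, "otu1": 1, "otu2": 2, "otu3": 2}, pheno)
            hits += any(c.p < 0.05 for c in out)
        assert hits <= 10
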