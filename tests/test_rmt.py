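import numpy as np
import pytest

from otunet import (
    build_network,
    edge_sign_proportions,
    generate_block_matrix,
    generate_goe_matrix,
    nnsd_chi2,
    pearson_similarity,
    scan_thresholds,
    select_threshold,
    unfold_spectrum,
)
from otunet.rmt import NetworkConstructionError, SimilarityMatrix, _threshold_matrix


def planted_block_similarity(
    n_blocks=4, block_size=50, r_within=0.8, noise=0.16, seed=0
):
    """Symmetric matrix: strong within-block entries, weak noise elsewhere.

    Noise sd 0.16 mimics null sample correlations at ~40 samples: its tail
    crosses low thresholds, so the scan only turns Poisson-consistent once
    the threshold clears the noise level.
    """
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    r = rng.normal(0, noise * np.sqrt(2), size=(n, n))
    r = (r + r.T) / 2
    for b in range(n_blocks):
        blk = slice(b * block_size, (b + 1) * block_size)
        r[blk, blk] = r_within + rng.normal(0, 0.02, size=(block_size, block_size))
        r[blk, blk] = (r[blk, blk] + r[blk, blk].T) / 2
    np.clip(r, -0.99, 0.99, out=r)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r=r, otu_ids=[f"O{i}" for i in range(n)], n_samples=50)


class TestPearsonSimilarity:
    def test_identical_and_negated_profiles(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        mat = np.vstack([x, x, -x])
        sim = pearson_similarity(mat)
        assert sim.r[0, 1] == pytest.approx(1.0)
        assert sim.r[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_sum_formula(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(3, 4))
        sim = pearson_similarity(mat)
        for i in range(3):
            for j in range(3):
                x, y = mat[i], mat[j]
                n = len(x)
                num = n * (x * y).sum() - x.sum() * y.sum()
                den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
                    n * (y**2).sum() - y.sum() ** 2
                )
                assert sim.r[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_profile_gets_zero(self):
        mat = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        sim = pearson_similarity(mat)
        assert sim.r[0, 1] == 0.0
        assert sim.r[0, 0] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_similarity(np.ones((4, 2)))


class TestUnfoldSpectrum:
    def test_uniform_spectrum_unit_spacings(self):
        d = unfold_spectrum(np.arange(1.0, 101.0))
        np.testing.assert_allclose(d, 1.0, atol=0.05)

    def test_mean_spacing_is_one(self):
        lam = np.linalg.eigvalsh(generate_goe_matrix(300, seed=1))
        d = unfold_spectrum(lam)
        assert np.mean(d) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_eigenvalues_removed(self):
        lam = np.repeat(np.arange(30.0), 3)  # 90 values, 30 distinct
        with pytest.raises(NetworkConstructionError, match="distinct"):
            unfold_spectrum(lam)

    def test_goe_prefers_wigner(self):
        lam = np.linalg.eigvalsh(generate_goe_matrix(500, seed=2))
        d = unfold_spectrum(lam)
        chi_p, _ = nnsd_chi2(d, "poisson")
        chi_g, p_g = nnsd_chi2(d, "goe")
        assert chi_g < chi_p
        assert p_g > 0.01

    def test_block_diagonal_prefers_poisson(self):
        lam = np.linalg.eigvalsh(generate_block_matrix(10, 50, seed=3))
        d = unfold_spectrum(lam)
        chi_p, p_p = nnsd_chi2(d, "poisson")
        chi_g, _ = nnsd_chi2(d, "goe")
        assert chi_p < chi_g
        assert p_p > 0.01

    def test_polynomial_unfolding_agrees_on_goe(self):
        lam = np.linalg.eigvalsh(generate_goe_matrix(400, seed=4))
        d = unfold_spectrum(lam, method="polynomial")
        chi_p, _ = nnsd_chi2(d, "poisson")
        chi_g, _ = nnsd_chi2(d, "goe")
        assert chi_g < chi_p


class TestNnsdChi2:
    def test_exponential_spacings_fit_poisson_at_nominal_rate(self):
        rng = np.random.default_rng(6)
        rejections = 0
        goe_rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            d = rng.exponential(1.0, size=10_000)
            _, p = nnsd_chi2(d, "poisson")
            rejections += p < 0.05
            _, p_g = nnsd_chi2(d, "goe")
            goe_rejections += p_g < 0.001
        assert rejections <= 0.12 * n_rep  # ~5% nominal
        assert goe_rejections >= 0.99 * n_rep

    def test_degenerate_histogram_is_finite(self):
        chi2, p = nnsd_chi2(np.full(100, 1.05), "poisson")
        assert np.isfinite(chi2) and 0 <= p <= 1

    def test_too_few_spacings_rejected(self):
        with pytest.raises(ValueError):
            nnsd_chi2(np.ones(10), "poisson")


class TestThresholdScan:
    def test_planted_blocks_recovered_in_range(self):
        sim = planted_block_similarity(seed=7)
        scan = scan_thresholds(sim)
        s_t = select_threshold(scan)
        assert 0.35 < s_t < 0.80
        # Poisson-consistent points exist between noise and signal levels
        usable = [p for p in scan.points if p.usable and 0.4 < p.threshold < 0.8]
        assert any(p.p_poisson > 0.05 for p in usable)

    def test_pure_noise_scan_completes(self):
        rng = np.random.default_rng(8)
        sim = pearson_similarity(rng.normal(size=(80, 30)))
        scan = scan_thresholds(sim)
        assert len(scan.points) == 70
        assert any(not p.usable for p in scan.points)  # high s_t degenerate

    def test_coarse_scan_is_subset_of_fine(self):
        sim = planted_block_similarity(seed=9)
        fine = {p.threshold: p for p in scan_thresholds(sim, step=0.01).points}
        for p in scan_thresholds(sim, step=0.05).points:
            q = fine[p.threshold]
            assert (p.chi2_poisson == q.chi2_poisson) or (
                np.isnan(p.chi2_poisson) and np.isnan(q.chi2_poisson)
            )

    def test_goe_similarity_never_selected_as_goe_fitting(self):
        # wherever selection succeeds, the chosen point must fit Poisson
        # better than GOE (on GOE-like input the rule only fires at high
        # thresholds where the matrix has fragmented)
        g = generate_goe_matrix(200, seed=10)
        r = g / (np.abs(g).max() + 1e-9)
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix(
            r=r, otu_ids=[f"O{i}" for i in range(200)], n_samples=50
        )
        scan = scan_thresholds(sim)
        s_t = select_threshold(scan)
        chosen = next(p for p in scan.points if p.threshold == s_t)
        if chosen.p_poisson > 0.05:  # selection rule (not the fallback)
            assert chosen.chi2_poisson < chosen.chi2_goe

    def test_last_point_poisson_consistent_is_returned(self):
        sim = planted_block_similarity(seed=11)
        scan = scan_thresholds(sim)
        usable = [p for p in scan.points if p.usable]
        qualifying = [
            p for p in usable
            if p.p_poisson > 0.05 and p.chi2_poisson < p.chi2_goe
        ]
        assert select_threshold(scan) == qualifying[0].threshold

    def test_no_usable_points_is_error(self):
        scan = scan_thresholds(
            SimilarityMatrix(
                r=np.eye(70), otu_ids=[f"O{i}" for i in range(70)], n_samples=10
            )
        )
        with pytest.raises(NetworkConstructionError):
            select_threshold(scan)


class TestBuildNetwork:
    def three_otu_sim(self):
        r = np.array(
            [[1.0, 0.9, 0.2], [0.9, 1.0, -0.95], [0.2, -0.95, 1.0]]
        )
        return SimilarityMatrix(r=r, otu_ids=["A", "B", "C"], n_samples=10)

    def test_threshold_example(self):
        net = build_network(self.three_otu_sim(), 0.86)
        assert set(net.graph.nodes) == {"A", "B", "C"}
        assert net.n_edges == 2
        assert net.graph.edges["A", "B"]["sign"] == 1
        assert net.graph.edges["B", "C"]["sign"] == -1

    def test_empty_network_is_error(self):
        with pytest.raises(NetworkConstructionError, match="empty"):
            build_network(self.three_otu_sim(), 0.99)

    def test_edge_monotonicity_in_threshold(self):
        sim = planted_block_similarity(2, 20, seed=12)
        edges = {}
        for s_t in (0.3, 0.5, 0.7):
            edges[s_t] = set(build_network(sim, s_t).graph.edges)
        assert edges[0.7] <= edges[0.5] <= edges[0.3]

    def test_relabeling_equivariance(self):
        sim = planted_block_similarity(2, 30, seed=13)
        net = build_network(sim, 0.5)
        perm = np.random.default_rng(14).permutation(sim.n_otus)
        sim2 = SimilarityMatrix(
            r=sim.r[np.ix_(perm, perm)],
            otu_ids=[sim.otu_ids[i] for i in perm],
            n_samples=sim.n_samples,
        )
        net2 = build_network(sim2, 0.5)
        assert set(net.graph.nodes) == set(net2.graph.nodes)
        assert set(map(frozenset, net.graph.edges)) == set(
            map(frozenset, net2.graph.edges)
        )

    def test_isolated_rows_dropped_by_threshold_matrix(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        assert _threshold_matrix(r, 0.5).shape == (2, 2)


class TestEdgeSigns:
    @pytest.mark.parametrize(
        "signs, expected",
        [([1, 1, -1], (200 / 3, 100 / 3)), ([1, 1, 1], (100.0, 0.0))],
    )
    def test_proportions(self, signs, expected, two_triangles):
        for (u, v), s in zip(two_triangles.graph.edges, signs * 2):
            two_triangles.graph.edges[u, v]["sign"] = s
        pos, neg = edge_sign_proportions(two_triangles)
        assert pos == pytest.approx(expected[0])
        assert neg == pytest.approx(expected[1])
        assert pos + neg == pytest.approx(100.0)
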