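"""Eigenstructure, constraint angles, random skewers, Flury hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import ortho_group

import evoquant as eq
from evoquant.gcompare import (
    _empirical_tails,
    _fg_objective,
    eigen_summary,
    flury_cpc,
    flury_significance,
    posterior_theta,
    random_skewers,
    rs_significance,
    vector_angle,
)


def random_psd(rng, t, extra=3):
    x = rng.standard_normal((t + extra, t))
    return x.T @ x / (t + extra)


class TestEigenSummary:
    def test_diagonal_two_by_two(self):
        es = eigen_summary(np.diag([3.0, 1.0]), ["height", "scent"])
        assert np.allclose(es.values, [3.0, 1.0])
        assert np.allclose(np.abs(es.g_max), [1.0, 0.0])
        assert es.relative[0] == pytest.approx(0.75)
        assert es.axis_angles("height")[0] == pytest.approx(0.0)
        assert es.axis_angles("height")[1] == pytest.approx(90.0)

    def test_identity_degenerate(self):
        es = eigen_summary(np.eye(4))
        assert es.relative[0] == pytest.approx(0.25)
        # deterministic tie-break: repeated calls agree exactly
        es2 = eigen_summary(np.eye(4))
        assert np.array_equal(es.vectors, es2.vectors)

    def test_reconstruction(self, rng):
        g = random_psd(rng, 4)
        es = eigen_summary(g)
        rebuilt = es.vectors @ np.diag(es.values) @ es.vectors.T
        assert np.max(np.abs(rebuilt - g)) < 1e-10

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigen_summary(np.array([[1.0, 1.0], [0.0, 1.0]]))

    def test_relative_sizes_sum_to_one(self, rng):
        es = eigen_summary(random_psd(rng, 5))
        assert es.relative.sum() == pytest.approx(1.0)


class TestVectorAngle:
    def test_closed_forms(self):
        assert vector_angle([1, 0], [1, 0]) == pytest.approx(0.0)
        assert vector_angle([1, 0], [0, 1]) == pytest.approx(90.0)
        assert vector_angle([1, 1], [1, 0]) == pytest.approx(45.0)

    def test_folding_sign_invariance(self):
        a = np.array([0.3, -0.7, 0.2])
        assert vector_angle(a, -a, fold=True) == pytest.approx(0.0, abs=1e-5)
        assert vector_angle(a, -a, fold=False) == pytest.approx(180.0)

    def test_gamma_scale_invariance(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4)
        assert vector_angle(a, b) == pytest.approx(
            vector_angle(3.0 * a, 0.5 * b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_angle([0, 0], [1, 0])


class TestPosteriorTheta:
    def test_parallel_gmax_zero_theta(self):
        g = np.diag([5.0, 1.0, 1.0])
        draws = np.repeat(g[None], 150, axis=0)
        rep = posterior_theta(draws, [1.0, 0.0, 0.0], beta=[2.0, 0.0, 0.0])
        assert rep.theta_mean == pytest.approx(0.0)
        assert rep.theta_hpd == (0.0, 0.0)
        assert rep.gamma == pytest.approx(0.0)

    def test_isotropic_draws_match_random_angle(self, rng):
        """Against near-isotropic G draws, theta behaves like the folded
        angle between a fixed vector and a random direction in R^t."""
        t, m = 4, 800
        draws = np.stack([
            np.eye(t) + 0.05 * random_psd(rng, t) for _ in range(m)
        ])
        rep = posterior_theta(draws, np.r_[1.0, np.zeros(t - 1)])
        # Monte-Carlo oracle for folded random angles in dimension t
        v = rng.standard_normal((20_000, t))
        cos = np.abs(v[:, 0]) / np.linalg.norm(v, axis=1)
        oracle = np.degrees(np.arccos(cos))
        assert abs(np.median(rep.theta_draws) - np.median(oracle)) < 8.0

    def test_minimum_draws(self):
        with pytest.raises(ValueError):
            posterior_theta(np.repeat(np.eye(2)[None], 10, axis=0), [1, 0])


class TestRandomSkewers:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_self_comparison_exactly_one(self, seed):
        rng = np.random.default_rng(seed)
        g = random_psd(rng, 4)
        mean, per = random_skewers(g, g, 200, seed=seed)
        assert mean == 1.0
        assert np.all(per == 1.0)

    def test_proportional_matrices(self, rng):
        g = random_psd(rng, 3)
        mean, _ = random_skewers(g, 4.2 * g, 500, seed=0)
        assert mean == pytest.approx(1.0)

    def test_symmetry_and_rotation_invariance(self, rng):
        g1, g2 = random_psd(rng, 4), random_psd(rng, 4)
        m12, _ = random_skewers(g1, g2, 40_000, seed=5)
        m21, _ = random_skewers(g2, g1, 40_000, seed=5)
        assert m12 == pytest.approx(m21, abs=1e-12)
        q = ortho_group.rvs(4, random_state=3)
        mrot, _ = random_skewers(q @ g1 @ q.T, q @ g2 @ q.T, 40_000, seed=5)
        assert mrot == pytest.approx(m12, abs=0.02)

    def test_quadrature_oracle_two_by_two(self):
        """MC mean correlation vs dense quadrature over the unit circle for
        G1 = diag(1, 10), G2 = diag(10, 1)."""
        g1, g2 = np.diag([1.0, 10.0]), np.diag([10.0, 1.0])
        mc, _ = random_skewers(g1, g2, 100_000, seed=2)

        def integrand(phi):
            s = np.array([np.cos(phi), np.sin(phi)])
            r1, r2 = g1 @ s, g2 @ s
            return (r1 @ r2) / (np.linalg.norm(r1) * np.linalg.norm(r2))

        oracle = quad(integrand, 0, 2 * np.pi)[0] / (2 * np.pi)
        assert mc == pytest.approx(oracle, abs=0.01)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            random_skewers(np.eye(2), np.eye(3))


class TestRSSignificance:
    def test_observed_below_all_nulls(self, rng):
        nulls = [np.eye(2) for _ in range(60)]
        out = rs_significance(nulls, nulls, observed_rs=-0.5, seed=0)
        assert out["p_left"] <= 1.0 / 60
        assert out["tail"] == "left"

    def test_observed_at_median(self, rng):
        null1 = [random_psd(rng, 3) for _ in range(80)]
        null2 = [random_psd(rng, 3) for _ in range(80)]
        probe = rs_significance(null1, null2, observed_rs=0.0,
                                n_skewers=300, seed=1)
        med = float(np.median(probe["null_stats"]))
        out = rs_significance(null1, null2, observed_rs=med,
                              n_skewers=300, seed=1)
        assert 0.3 < out["p_left"] < 0.7

    def test_few_replicates_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            rs_significance([np.eye(2)] * 10, [np.eye(2)] * 10, 0.5,
                            n_skewers=50, seed=0)


class TestFlury:
    def test_identical_matrices_all_zero(self, rng):
        g = random_psd(rng, 3)
        res = flury_cpc([g, g], [20, 20])
        for stat in res.stats.values():
            assert abs(stat) < 1e-8

    def test_proportional_matrices(self, rng):
        g = random_psd(rng, 3)
        res = flury_cpc([g, 3.0 * g], [20, 20])
        assert res.stats["proportionality"] == pytest.approx(0.0, abs=1e-6)
        assert res.stats["cpc"] == pytest.approx(0.0, abs=1e-6)
        assert res.stats["equality"] > 1.0

    def test_codiagonalizable_matrices(self, rng):
        q = ortho_group.rvs(4, random_state=1)
        g1 = q @ np.diag([4.0, 3.0, 2.0, 1.0]) @ q.T
        g2 = q @ np.diag([1.0, 5.0, 2.5, 0.5]) @ q.T
        res = flury_cpc([g1, g2], [30, 30])
        assert res.stats["cpc"] == pytest.approx(0.0, abs=1e-6)
        assert res.stats["equality"] > 1.0
        assert res.stats["proportionality"] > 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_two_by_two_grid_oracle(self, seed):
        """FG objective at the returned basis matches a brute-force grid
        search over the single rotation angle."""
        rng = np.random.default_rng(seed)
        mats = [random_psd(rng, 2), random_psd(rng, 2)]
        ns = [7.0, 9.0]
        res = flury_cpc(mats, ns)

        def objective(theta):
            c, s = np.cos(theta), np.sin(theta)
            return _fg_objective(np.array([[c, -s], [s, c]]), mats, ns)

        grid = min(objective(th) for th in np.linspace(0, np.pi, 20_001))
        assert res.objective == pytest.approx(grid, abs=1e-4)

    def test_basis_orthonormal(self, rng):
        mats = [random_psd(rng, 5), random_psd(rng, 5), random_psd(rng, 5)]
        res = flury_cpc(mats, [10, 12, 14])
        assert np.max(np.abs(res.basis.T @ res.basis - np.eye(5))) < 1e-10

    def test_significance_extreme_rank(self, rng):
        nulls1 = [np.eye(2) + 0.01 * random_psd(rng, 2) for _ in range(40)]
        nulls2 = [np.eye(2) + 0.01 * random_psd(rng, 2) for _ in range(40)]
        obs = {"equality": 100.0, "proportionality": 100.0, "cpc": 100.0}
        table = flury_significance(obs, nulls1, nulls2, seed=0)
        assert (table["p_right"] <= 1.0 / 40).all()
        assert (table["tail"] == "right").all()


def test_empirical_tails_median_case():
    out = _empirical_tails(np.arange(100, dtype=float), 49.5)
    assert out["p_left"] == pytest.approx(0.5)
    assert out["p_right"] == pytest.approx(0.5)
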