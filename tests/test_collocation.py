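import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import TRUE_COV12, TRUE_ECC, TRUE_ERR_VAR, make_triplet, series_from_values
from tvegfuse import collocation as col
from tvegfuse.collocation import (
    CollocatedSeries,
    CollocationError,
    ec_quadruplet_estimate,
    eivd_estimate,
    lag1_autocovariance,
    pairwise_covariances,
    tc_error_variances,
    tc_rescale,
)


class TestPairwiseCovariances:
    def test_identical_series_covariance_equals_variance(self):
        x = np.array([1.0, 4.0, 2.0, 5.0])
        s = series_from_values([x, x], valid=np.ones((2, 4)))
        cov, means, n = pairwise_covariances(s, min_samples=2)
        assert cov[0, 1] == pytest.approx(cov[0, 0])
        assert n == 4

    def test_population_denominator_hand_value(self):
        # cov((1,2,3),(2,4,6)) with denominator n: mean-centered products
        # (-1)(-2)+(0)(0)+(1)(2) = 4, / 3
        s = series_from_values([[1, 2, 3], [2, 4, 6]])
        cov, _, _ = pairwise_covariances(s, min_samples=2)
        assert cov[0, 1] == pytest.approx(4.0 / 3.0)
        # sample (ddof=1) convention also available
        cov1, _, _ = pairwise_covariances(s, min_samples=2, ddof=1)
        assert cov1[0, 1] == pytest.approx(2.0)

    def test_masked_step_equals_reduced_series(self):
        vals = np.array([[1.0, 2.0, 3.0, 9.0], [2.0, 4.0, 6.0, -5.0]])
        valid = np.array([[1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool)
        s = series_from_values(vals, valid)
        cov, _, n = pairwise_covariances(s, min_samples=2)
        ref, _, _ = pairwise_covariances(
            series_from_values(vals[:, :3]), min_samples=2
        )
        assert n == 3
        np.testing.assert_allclose(cov, ref)

    def test_too_few_samples_flagged(self):
        s = series_from_values([[1, 2], [3, 4]])
        with pytest.raises(CollocationError, match="complete steps"):
            pairwise_covariances(s, min_samples=100)


class TestTcRescale:
    def test_construction_recovers_inverse_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 1, 5000)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.01, x.size)
        z = x + rng.normal(0, 0.01, x.size)
        s = series_from_values([x, y, z])
        _, factors = tc_rescale(s, "p0", min_samples=2)
        assert factors["p1"] == pytest.approx(0.5, rel=0.02)

    def test_reference_unchanged_and_means_match(self, triplet):
        _, s, _ = triplet
        scaled, factors = tc_rescale(s, s.product_ids[0])
        np.testing.assert_array_equal(scaled.values[0], s.values[0])
        assert factors[s.product_ids[0]] == 1.0
        ref_mean = s.values[0].mean()
        for row in scaled.values:
            assert row.mean() == pytest.approx(ref_mean, abs=1e-9)


class TestTcErrorVariances:
    def test_noiseless_triplet_zero_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        s = series_from_values([x, 2 * x + 1, 0.5 * x])
        em = tc_error_variances(s, min_samples=2)
        np.testing.assert_allclose(em.error_variance, 0.0, atol=1e-12)

    def test_closed_form_hand_substitution(self):
        # direct substitution: var_eX = sigma2_X - s_XY s_XZ / s_YZ = 2 - 1 = 1
        cov = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]])

        def closed(i, covm):
            j, k = [m for m in range(3) if m != i]
            return covm[i, i] - covm[i, j] * covm[i, k] / covm[j, k]

        assert closed(0, cov) == pytest.approx(1.0)

    def test_monte_carlo_recovery_zero_ecc(self):
        _, s, _ = make_triplet(n_steps=20000, seed=7, cov12=0.0)
        em = tc_error_variances(s)
        np.testing.assert_allclose(em.error_variance, TRUE_ERR_VAR, rtol=0.10)
        assert em.variance_valid.all()

    def test_closed_form_equals_cross_multiplied_differences(self):
        """The covariance closed forms equal the averaged cross-multiplied
        differences of the rescaled series — an exact algebraic identity."""
        _, s, _ = make_triplet(n_steps=500, seed=3)
        em = tc_error_variances(s, min_samples=2)
        scaled, factors = tc_rescale(s, s.product_ids[0], min_samples=2)
        x, y, z = scaled.values
        bY, bZ = factors[s.product_ids[1]], factors[s.product_ids[2]]
        cross = np.array(
            [
                np.mean((x - y) * (x - z)),
                np.mean((y - x) * (y - z)) / bY**2,
                np.mean((z - x) * (z - y)) / bZ**2,
            ]
        )
        np.testing.assert_allclose(em.error_variance, cross, rtol=1e-10)


class TestLag1Autocovariance:
    def test_constant_series_zero(self):
        assert lag1_autocovariance(np.full(300, 5.0), min_pairs=2) == 0.0

    def test_ar1_ratio_recovers_phi(self):
        from tvegfuse.synthetic import TruthConfig, simulate_truth

        x = simulate_truth(
            TruthConfig(n_steps=20000, ar1_coeff=0.7, seasonal_amplitude=0.0, seed=8)
        )
        l1 = lag1_autocovariance(x)
        var = np.mean((x - x.mean()) ** 2)
        assert l1 / var == pytest.approx(0.7, abs=0.05)

    def test_alternating_series_minus_variance(self):
        x = np.tile([1.0, -1.0], 100)
        assert lag1_autocovariance(x, min_pairs=2) == pytest.approx(-1.0)

    def test_gap_excludes_non_adjacent_pairs(self):
        x = np.array([1.0, 2.0, np.nan, 3.0, 4.0])
        # pairs (0,1) and (3,4) only
        mean = np.nanmean(x)
        a = x - mean
        expected = np.mean([a[0] * a[1], a[3] * a[4]])
        assert lag1_autocovariance(x, min_pairs=2) == pytest.approx(expected)


class TestEIVD:
    def test_recovers_error_structure(self, triplet):
        _, s, _ = triplet
        em = eivd_estimate(s, ("prod1", "prod2"))
        assert em.valid
        order = [em.product_ids.index(f"prod{i+1}") for i in range(3)]
        np.testing.assert_allclose(
            em.error_variance[order], TRUE_ERR_VAR, rtol=0.10
        )
        rho = em.ecc[("prod1", "prod2")]
        assert rho == pytest.approx(TRUE_ECC, abs=0.05)

    def test_zero_ecc_data_yields_near_zero_rho(self):
        _, s, _ = make_triplet(n_steps=20000, seed=13, cov12=0.0)
        em = eivd_estimate(s, ("prod1", "prod2"))
        assert abs(em.ecc[("prod1", "prod2")]) < 0.05

    def test_white_noise_truth_rejected(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(2, 1, 5000)  # no autocorrelation, no seasonality
        from tvegfuse.synthetic import ProductConfig, simulate_products

        s = simulate_products(truth, ProductConfig(seed=6))
        em = eivd_estimate(s, ("prod1", "prod2"))
        assert not em.valid
        assert "autocovariance" in em.reason

    def test_scale_equivariance(self, triplet):
        """Scaling one product by c multiplies its error variance by c^2 and
        leaves the ECC estimate unchanged."""
        _, s, _ = triplet
        em0 = eivd_estimate(s, ("prod1", "prod2"))
        c = 3.0
        scaled = CollocatedSeries(
            product_ids=s.product_ids,
            times=s.times,
            values=np.vstack([c * s.values[0], s.values[1:]]),
            valid_mask=s.valid_mask,
        )
        em1 = eivd_estimate(scaled, ("prod1", "prod2"))
        i = em0.product_ids.index("prod1")
        assert em1.error_variance[i] == pytest.approx(
            c**2 * em0.error_variance[i], rel=1e-8
        )
        assert em1.ecc[("prod1", "prod2")] == pytest.approx(
            em0.ecc[("prod1", "prod2")], rel=1e-8
        )

    def test_permutation_equivariance(self, triplet):
        _, s, _ = triplet
        em0 = eivd_estimate(s, ("prod1", "prod2"))
        perm = s.subset(["prod3", "prod1", "prod2"])
        em1 = eivd_estimate(perm, ("prod1", "prod2"))
        for pid in s.product_ids:
            a = em0.error_variance[em0.product_ids.index(pid)]
            b = em1.error_variance[em1.product_ids.index(pid)]
            assert a == pytest.approx(b, rel=1e-9)

    def test_tc_biased_under_ecc_but_eivd_not(self, triplet):
        """Ignoring a true error cross-correlation corrupts zero-ECC TC
        estimates for the correlated pair, while EIVD stays unbiased."""
        _, s, _ = triplet
        em_tc = tc_error_variances(s)
        em_iv = eivd_estimate(s, ("prod1", "prod2"))
        for k, pid in enumerate(["prod1", "prod2"]):
            tc_rel = abs(em_tc.error_variance[k] - TRUE_ERR_VAR[k]) / TRUE_ERR_VAR[k]
            iv = em_iv.error_variance[em_iv.product_ids.index(pid)]
            iv_rel = abs(iv - TRUE_ERR_VAR[k]) / TRUE_ERR_VAR[k]
            assert tc_rel > 0.10
            assert iv_rel < 0.10


class TestECQuadruplet:
    @staticmethod
    def _quadruplet(n=20000, seed=21, cov12=0.10):
        from tvegfuse.synthetic import ProductConfig, TruthConfig, simulate_products, simulate_truth

        truth = simulate_truth(TruthConfig(n_steps=n, seed=seed))
        cov = np.diag([0.36, 0.29, 0.13, 0.20]).astype(float)
        cov[0, 1] = cov[1, 0] = cov12
        cfg = ProductConfig(
            alphas=(0.0,) * 4, betas=(1.0, 0.8, 1.2, 0.9), error_cov=cov,
            seed=seed + 1,
        )
        return simulate_products(truth, cfg)

    def test_recovers_declared_pair_covariance(self):
        s = self._quadruplet()
        em = ec_quadruplet_estimate(s, [("prod1", "prod2")])
        assert em.error_covariance[("prod1", "prod2")] == pytest.approx(0.10, rel=0.10)
        np.testing.assert_allclose(
            em.error_variance, [0.36, 0.29, 0.13, 0.20], rtol=0.10
        )

    def test_zero_declared_pairs_matches_tc_on_triplets(self):
        s = self._quadruplet(cov12=0.0)
        em = ec_quadruplet_estimate(s, [])
        tri = tc_error_variances(s.subset(["prod1", "prod2", "prod3"]))
        for pid in ["prod1", "prod2", "prod3"]:
            a = em.error_variance[em.product_ids.index(pid)]
            b = tri.error_variance[tri.product_ids.index(pid)]
            assert a == pytest.approx(b, abs=0.05)

    def test_unsolvable_pair_set_rejected(self):
        s = self._quadruplet(n=500)
        with pytest.raises(CollocationError, match="unsolvable"):
            ec_quadruplet_estimate(
                s,
                [("prod1", "prod2"), ("prod3", "prod4"), ("prod1", "prod3")],
            )


class TestGridEstimation:
    def test_recovery_and_masking_on_small_grid(self):
        from tvegfuse.synthetic import ProductConfig, TruthConfig, simulate_grid

        tcfg = TruthConfig(n_steps=2000, seed=2)
        pcfg = ProductConfig(seed=3)
        cubes, _ = simulate_grid((3, 3), tcfg, pcfg)
        # blank out one pixel entirely
        for pid in cubes:
            cubes[pid].values[:, 0, 0] = np.nan
        ds = col.grid_error_estimation(cubes, method="eivd", ecc_pair=("prod1", "prod2"))
        assert not bool(ds["valid"].values[0, 0])
        valid = ds["valid"].values
        assert valid.sum() == 8
        for k, pid in enumerate(["prod1", "prod2", "prod3"]):
            vals = ds[f"error_variance_{pid}"].values[valid]
            assert np.nanmean(vals) == pytest.approx(TRUE_ERR_VAR[k], rel=0.25)

    def test_grid_mismatch_rejected(self):
        from tvegfuse.synthetic import ProductConfig, TruthConfig, simulate_grid

        tcfg = TruthConfig(n_steps=200, seed=2)
        pcfg = ProductConfig(seed=3)
        cubes, _ = simulate_grid((2, 2), tcfg, pcfg)
        other, _ = simulate_grid((2, 3), tcfg, pcfg)
        cubes["prod3"] = other["prod3"]
        with pytest.raises(CollocationError, match="grid mismatch"):
            col.grid_error_estimation(cubes, method="tc")


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_tc_closed_form_identity_property(seed):
    """Eq-style identity between covariance closed forms and cross-multiplied
    rescaled differences holds on any random triplet (exact algebra)."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1, (3, 60)) + rng.normal(0, 1, 60) * rng.uniform(
        0.5, 2.0, (3, 1)
    )
    s = series_from_values(vals)
    em = tc_error_variances(s, min_samples=2)
    scaled, factors = tc_rescale(s, "p0", min_samples=2)
    x, y, z = scaled.values
    cross = np.array(
        [
            np.mean((x - y) * (x - z)),
            np.mean((y - x) * (y - z)) / factors["p1"] ** 2,
            np.mean((z - x) * (z - y)) / factors["p2"] ** 2,
        ]
    )
    np.testing.assert_allclose(em.error_variance, cross, rtol=1e-8, atol=1e-10)
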