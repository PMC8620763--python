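"""Causal-effect estimators against independent closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from mrkit.estimators import (cochran_q, ivw, mr_egger, mr_raps, wald_ratio,
                              weighted_median, weighted_mode, wglr, Z_95)
from mrkit.sumstats import LdMatrix

from conftest import make_harmonized

SEED = 73


class TestWaldRatio:
    def test_forced_arithmetic(self):
        est = wald_ratio(0.5, 0.05, 0.2, 0.1)
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert est.beta == 0.0
        assert est.or_ == pytest.approx(1.0)

    @pytest.mark.parametrize("x", [-0.7, 0.0, 0.3, 2.0])
    def test_unit_exposure_identity(self, x):
        assert wald_ratio(1.0, 0.1, x, 0.1).beta == pytest.approx(x)

    def test_zero_gamma_is_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.2, 0.1)

    def test_ci_and_or_consistency(self):
        est = wald_ratio(0.5, 0.05, 0.2, 0.1)
        assert est.ci_low == pytest.approx(est.beta - Z_95 * est.se)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.or_high == pytest.approx(np.exp(est.ci_high))


class TestIvw:
    def test_identical_ratios(self):
        h = make_harmonized([0.5, 0.25], [0.05, 0.05], [0.1, 0.05],
                            [0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.2)

    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.5], [0.05], [0.2], [0.1])
        est = ivw(h)
        ref = wald_ratio(0.5, 0.05, 0.2, 0.1)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_weighted_mean_oracle(self):
        # ratios 0.1 and 0.3 with first-order ratio SE 0.1 each -> equal
        # weights 100, mean 0.2
        h = make_harmonized([1.0, 1.0], [0.0, 0.0], [0.1, 0.3], [0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.2)

    def test_matches_ratio_level_weighted_mean(self, rng):
        gamma = rng.uniform(0.1, 0.5, 8)
        sG = rng.uniform(0.02, 0.1, 8)
        Gamma = 0.3 * gamma + rng.normal(0, 0.02, 8)
        h = make_harmonized(gamma, np.full(8, 0.01), Gamma, sG)
        ratios = Gamma / gamma
        w = gamma ** 2 / sG ** 2
        assert ivw(h).beta == pytest.approx(np.sum(w * ratios) / np.sum(w),
                                            rel=1e-12)

    def test_se_floor_fixed_effect(self):
        # perfectly homogeneous ratios: residual scale ~ 0, SE floored at
        # the fixed-effect value rather than shrunk below it
        gamma = np.array([0.2, 0.4, 0.6])
        sG = np.array([0.05, 0.05, 0.05])
        h = make_harmonized(gamma, np.zeros(3), 0.3 * gamma, sG)
        expect = np.sum(gamma ** 2 / sG ** 2) ** -0.5
        assert ivw(h).se == pytest.approx(expect, rel=1e-10)


class TestEgger:
    def test_perfect_linear_fit(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        Gamma = 0.01 + 0.3 * gamma
        h = make_harmonized(gamma, np.full(5, 0.01), Gamma, np.full(5, 0.05))
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.intercept == pytest.approx(0.01, abs=1e-10)

    def test_no_pleiotropy_zero_intercept(self):
        gamma = np.array([0.1, 0.25, 0.4])
        h = make_harmonized(gamma, np.full(3, 0.01), 0.5 * gamma,
                            np.full(3, 0.05))
        assert mr_egger(h).intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_wls_oracle(self, rng):
        """Closed-form weighted least squares, coded independently."""
        J = 5
        gamma = rng.uniform(0.1, 0.6, J)
        sG = rng.uniform(0.02, 0.1, J)
        Gamma = 0.02 + 0.4 * gamma + rng.normal(0, 0.03, J)
        h = make_harmonized(gamma, np.full(J, 0.01), Gamma, sG)
        est = mr_egger(h)
        # oracle: sqrt-weight transform + ordinary lstsq
        sw = 1.0 / sG
        X = np.column_stack([sw, sw * gamma])
        coef, *_ = np.linalg.lstsq(X, sw * Gamma, rcond=None)
        assert est.intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_too_few_snps_fatal(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(ValueError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_definition(self):
        h = make_harmonized([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.9],
                            [0.1] * 3)
        est = weighted_median(h, n_boot=100, seed=SEED)
        assert est.beta == pytest.approx(0.2)

    def test_degenerate_equal_ratios(self):
        gamma = np.array([0.2, 0.3, 0.4])
        h = make_harmonized(gamma, np.full(3, 1e-4), 0.7 * gamma,
                            np.full(3, 0.05))
        est = weighted_median(h, n_boot=200, seed=SEED)
        assert est.beta == pytest.approx(0.7)
        assert est.se < 0.5

    def test_matches_interpolation_oracle(self):
        # 4-SNP weighted instance recomputed by hand:
        # ratios (.05,.2,.35,.6), weights (1,3,2,1) ->
        # s = (1/14, 5/14, 10/14, 13/14), interp at 0.5 -> 0.26
        gamma = np.array([1.0, 1.0, 1.0, 1.0])
        sG = 1.0 / np.sqrt(np.array([1.0, 3.0, 2.0, 1.0]))
        Gamma = np.array([0.05, 0.2, 0.35, 0.6])
        h = make_harmonized(gamma, np.full(4, 0.01), Gamma, sG)
        est = weighted_median(h, n_boot=100, seed=SEED)
        assert est.beta == pytest.approx(0.26, abs=1e-12)

    def test_seed_reproducible(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.02] * 3, [0.06, 0.1, 0.11],
                            [0.05] * 3)
        a = weighted_median(h, n_boot=150, seed=5)
        b = weighted_median(h, n_boot=150, seed=5)
        assert a.se == b.se

    def test_missing_seed_fatal(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.02] * 3, [0.1] * 3,
                            [0.05] * 3)
        with pytest.raises(ValueError):
            weighted_median(h, n_boot=100)


class TestWeightedMode:
    def test_degenerate_all_equal(self):
        gamma = np.array([0.2, 0.3, 0.4])
        h = make_harmonized(gamma, np.full(3, 1e-4), 0.4 * gamma,
                            np.full(3, 0.05))
        est = weighted_mode(h, n_boot=100, seed=SEED)
        assert est.beta == pytest.approx(0.4, abs=1e-9)

    def test_majority_cluster_wins(self, rng):
        # 7 ratios near 0.2, 3 near 1.0 with equal weights -> mode ~ 0.2
        ratios = np.concatenate([rng.normal(0.2, 0.01, 7),
                                 rng.normal(1.0, 0.01, 3)])
        gamma = np.ones(10)
        h = make_harmonized(gamma, np.full(10, 0.01), ratios,
                            np.full(10, 0.1))
        est = weighted_mode(h, n_boot=100, seed=SEED)
        assert abs(est.beta - 0.2) < 0.1

    def test_bandwidth_scales_with_phi(self):
        from mrkit.estimators import _mode_bandwidth
        ratios = np.array([0.1, 0.2, 0.4, 0.45, 0.9])
        assert _mode_bandwidth(ratios, 2.0) == pytest.approx(
            2.0 * _mode_bandwidth(ratios, 1.0))


class TestRaps:
    def test_single_snp_equals_wald(self):
        h = make_harmonized([0.5], [0.05], [0.2], [0.1])
        est = mr_raps(h)
        assert est.beta == pytest.approx(0.4, abs=1e-8)

    def test_zero_exposure_noise_equals_fixed_ivw(self, rng):
        gamma = rng.uniform(0.1, 0.5, 10)
        sG = rng.uniform(0.05, 0.2, 10)
        Gamma = 0.3 * gamma + rng.normal(0, 0.01, 10)
        h = make_harmonized(gamma, np.zeros(10), Gamma, sG)
        est = mr_raps(h)
        w = gamma ** 2 / sG ** 2
        beta_ivw = np.sum(w * (Gamma / gamma)) / np.sum(w)
        assert est.beta == pytest.approx(beta_ivw, abs=1e-8)
        assert est.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-6)

    @pytest.mark.parametrize("loss", ["l2", "huber"])
    def test_matches_grid_oracle(self, loss, rng):
        """Dense grid search over the profile objective."""
        J = 20
        gamma = rng.normal(0.15, 0.05, J)
        sg = np.full(J, 0.03)
        sG = rng.uniform(0.03, 0.08, J)
        Gamma = 0.3 * gamma + rng.normal(0, sG)
        h = make_harmonized(gamma, sg, Gamma, sG)
        est = mr_raps(h, loss=loss)

        grid = np.arange(-2.0, 2.0, 1e-4)
        t = (Gamma[None, :] - grid[:, None] * gamma[None, :]) / np.sqrt(
            sG[None, :] ** 2 + grid[:, None] ** 2 * sg[None, :] ** 2)
        if loss == "l2":
            obj = 0.5 * np.sum(t ** 2, axis=1)
        else:
            k = 1.345
            a = np.abs(t)
            obj = np.sum(np.where(a <= k, 0.5 * t ** 2,
                                  k * a - 0.5 * k ** 2), axis=1)
        assert est.beta == pytest.approx(grid[np.argmin(obj)], abs=1e-3)

    def test_bracket_boundary_fatal(self):
        h = make_harmonized([0.01], [0.0], [0.9], [0.01])
        with pytest.raises(RuntimeError, match="bracket"):
            mr_raps(h, bracket=(-1.0, 1.0))


class TestWglr:
    def test_identity_ld_equals_ivw(self, rng):
        J = 6
        gamma = rng.uniform(0.1, 0.5, J)
        sG = rng.uniform(0.03, 0.1, J)
        Gamma = 0.25 * gamma + rng.normal(0, 0.02, J)
        h = make_harmonized(gamma, np.full(J, 0.01), Gamma, sG)
        ld = LdMatrix([f"rs{i}" for i in range(J)], np.eye(J))
        est = wglr(h, ld)
        w = gamma ** 2 / sG ** 2
        beta_ivw = np.sum(w * (Gamma / gamma)) / np.sum(w)
        assert est.beta == pytest.approx(beta_ivw, rel=1e-12)
        assert est.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-12)

    def test_duplicated_snp_singular(self):
        h = make_harmonized([0.2, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LdMatrix(["rs0", "rs1"], rho)
        with pytest.raises(np.linalg.LinAlgError):
            wglr(h, ld)

    def test_matches_hand_solved_3x3(self):
        gamma = np.array([0.2, 0.3, 0.4])
        sG = np.array([0.05, 0.06, 0.07])
        Gamma = np.array([0.08, 0.1, 0.13])
        h = make_harmonized(gamma, np.full(3, 0.01), Gamma, sG)
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        est = wglr(h, LdMatrix(["rs0", "rs1", "rs2"], rho))
        # frozen from an explicit matrix-inversion oracle
        assert est.beta == pytest.approx(0.33275847051650553, rel=1e-10)
        assert est.se == pytest.approx(0.16002351538719187, rel=1e-10)


class TestCochranQ:
    def test_homogeneous_ratios(self):
        gamma = np.array([0.2, 0.3, 0.4])
        h = make_harmonized(gamma, np.full(3, 0.01), 0.5 * gamma,
                            np.full(3, 0.05))
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        # ratios (0, 1) with unit ratio-SEs: IVW 0.5, Q = 0.5
        h = make_harmonized([1.0, 1.0], [0.0, 0.0], [0.0, 1.0], [1.0, 1.0])
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_null_distribution_is_chisquare(self, rng):
        """Homogeneous simulated sets give Q ~ chi-square(J-1)."""
        J, reps = 6, 1000
        qs = np.empty(reps)
        gamma = rng.uniform(0.3, 0.6, J)
        sG = np.full(J, 0.05)
        for i in range(reps):
            Gamma = 0.2 * gamma + rng.normal(0, sG)
            h = (gamma, np.zeros(J), Gamma, sG)
            qs[i], _, _ = cochran_q(h)
        ks = stats.kstest(qs, stats.chi2(J - 1).cdf)
        assert ks.pvalue > 0.01


class TestEquivariance:
    def test_relabeling_and_joint_sign_flip(self, rng):
        J = 8
        gamma = rng.uniform(0.1, 0.5, J)
        sg = np.full(J, 0.02)
        sG = rng.uniform(0.03, 0.1, J)
        Gamma = 0.3 * gamma + rng.normal(0, 0.02, J)

        perm = rng.permutation(J)
        flip = np.ones(J)
        flip[:3] = -1.0  # joint sign flip of (gamma, Gamma) for 3 SNPs

        base = (gamma, sg, Gamma, sG)
        variant = ((gamma * flip)[perm], sg[perm], (Gamma * flip)[perm],
                   sG[perm])
        # note: estimators that assume the gamma >= 0 orientation (Egger)
        # are excluded; sign-flip equivariance applies to ratio-based ones
        for fn in (ivw, mr_raps):
            assert fn(base).beta == pytest.approx(fn(variant).beta,
                                                  rel=1e-7)
        q0, _, _ = cochran_q(base)
        q1, _, _ = cochran_q(variant)
        assert q0 == pytest.approx(q1, rel=1e-9)
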