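"""Causal-mixture likelihoods, fitting, derived estimands and AIC checks."""

import numpy as np
import pytest
from scipy import stats

import pleioscan as ps
from pleioscan.mixture import (
    BivariateParams,
    UnivariateParams,
    bivariate_loglik,
    univariate_loglik,
)


def simulate_univariate(pi, s2b, n, M, seed):
    cfg = ps.ArchitectureConfig(
        M=M,
        traits=[ps.TraitSpec("t", "disorder", n)],
        pi={"t": pi},
        sigma_beta2={"t": s2b},
        seed=seed,
    )
    panel, truth = ps.simulate_panel(cfg)
    return panel.Z[:, 0], truth


class TestUnivariateLoglik:
    def test_zero_pi_collapses_to_pure_normal(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500)
        p = UnivariateParams(pi=0.0, sigma_beta2=1e-4, sigma0=1.2)
        assert univariate_loglik(p, z, 1e4) == pytest.approx(
            stats.norm.logpdf(z, scale=1.2).sum()
        )

    def test_single_point_closed_form(self):
        # z=0, sigma0=1, pi=0.5, n*sigma_beta2=1
        p = UnivariateParams(pi=0.5, sigma_beta2=1e-4, sigma0=1.0)
        expected = np.log(
            0.5 * stats.norm.pdf(0, scale=1.0) + 0.5 * stats.norm.pdf(0, scale=np.sqrt(2))
        )
        assert univariate_loglik(p, np.array([0.0]), 1e4) == pytest.approx(expected)

    def test_matches_direct_mixture_oracle(self):
        """Likelihood equals a direct two-component density evaluation."""
        rng = np.random.default_rng(1)
        z = rng.normal(0, 2, 1000)
        p = UnivariateParams(pi=0.01, sigma_beta2=5e-5, sigma0=1.05)
        n = 1e5
        direct = np.log(
            (1 - p.pi) * stats.norm.pdf(z, scale=p.sigma0)
            + p.pi * stats.norm.pdf(z, scale=np.sqrt(p.sigma0**2 + n * p.sigma_beta2))
        ).sum()
        assert univariate_loglik(p, z, n) == pytest.approx(direct, abs=1e-10 * abs(direct))

    def test_ld_mode_with_unit_scores_equals_no_ld(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(300)
        p = UnivariateParams(pi=0.05, sigma_beta2=2e-5, sigma0=1.0)
        assert univariate_loglik(p, z, 1e4, ld_scores=np.ones(300)) == pytest.approx(
            univariate_loglik(p, z, 1e4)
        )

    def test_ld_mode_binomial_weights(self):
        """Two tagged causals double the causal variance contribution."""
        z = np.array([3.0])
        pi, s2b, n = 0.3, 1e-4, 1e4
        p = UnivariateParams(pi, s2b, 1.0)
        ell = np.array([2.0])
        w = stats.binom.pmf(np.arange(3), 2, pi)
        direct = np.log(
            sum(
                w[c] * stats.norm.pdf(3.0, scale=np.sqrt(1 + c * n * s2b))
                for c in range(3)
            )
        )
        assert univariate_loglik(p, z, n, ld_scores=ell) == pytest.approx(direct)

    def test_truth_beats_perturbations(self):
        wins = 0
        for seed in range(10):
            z, _ = simulate_univariate(0.003, 5e-5, 1e5, 50_000, seed + 30)
            truth = UnivariateParams(0.003, 5e-5, 1.0)
            ll_truth = univariate_loglik(truth, z, 1e5)
            worse = [
                UnivariateParams(0.003 * f, 5e-5, 1.0) for f in (0.5, 1.5)
            ] + [UnivariateParams(0.003, 5e-5 * f, 1.0) for f in (0.5, 1.5)]
            if all(univariate_loglik(w, z, 1e5) <= ll_truth for w in worse):
                wins += 1
        assert wins >= 6


class TestFitUnivariate:
    def test_null_recovery(self):
        z, _ = simulate_univariate(0.0, 0.0, 1e5, 20_000, 40)
        fit = ps.fit_univariate(z, 1e5, seed=0)
        assert fit.derived["h2_obs"] < 0.01

    def test_deterministic_refit(self):
        z, _ = simulate_univariate(0.005, 5e-5, 1e5, 20_000, 41)
        f1 = ps.fit_univariate(z, 1e5, seed=2)
        f2 = ps.fit_univariate(z, 1e5, seed=2)
        assert f1.params == f2.params

    def test_fixed_pi_constrained_model(self):
        z, _ = simulate_univariate(0.005, 5e-5, 1e5, 20_000, 42)
        fit = ps.fit_univariate(z, 1e5, seed=0, fix_pi=1.0)
        assert fit.params.pi == 1.0 and fit.n_params == 2


class TestPolygenicity90:
    def test_full_fraction_limit(self):
        assert ps.polygenicity90(0.01, 100_000, fraction=1.0) == pytest.approx(1000)

    def test_reference_value(self):
        assert ps.polygenicity90(0.01, 100_000) == pytest.approx(445, abs=1)

    def test_scale_free_in_sigma_beta2(self):
        a = ps.polygenicity90(0.01, 100_000, sigma_beta2=1e-5)
        b = ps.polygenicity90(0.01, 100_000, sigma_beta2=1e-3)
        assert a == b

    def test_small_count_rejected(self):
        with pytest.raises(ValueError):
            ps.polygenicity90(1e-9, 1000)


class TestConcordance:
    @pytest.mark.parametrize("rho,expected", [(0.0, 0.5), (1.0, 1.0), (0.5, 2 / 3)])
    def test_orthant_closed_forms(self, rho, expected):
        assert ps.concordance_from_rho(rho) == pytest.approx(expected, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            ps.concordance_from_rho(1.5)


class TestBivariateLoglik:
    @staticmethod
    def _null_params(rho0=0.4):
        return BivariateParams(
            pi0=1.0, pi1=0.0, pi2=0.0, pi12=0.0, rho12=0.0, rho0=rho0,
            sigma_beta2_1=1e-5, sigma_beta2_2=1e-5, sigma0_1=1.0, sigma0_2=1.0,
        )

    def test_null_collapse_to_bivariate_normal(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((400, 2))
        p = self._null_params(rho0=0.4)
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        direct = stats.multivariate_normal(mean=[0, 0], cov=C).logpdf(z).sum()
        assert bivariate_loglik(p, z[:, 0], z[:, 1], 1e4, 1e4) == pytest.approx(direct)

    def test_independent_traits_factorize(self):
        """With independent causal statuses and no correlations the joint
        likelihood is the product of the marginals."""
        rng = np.random.default_rng(4)
        z1, z2 = rng.standard_normal(500), rng.standard_normal(500)
        a, b = 0.01, 0.02
        p = BivariateParams(
            pi0=(1 - a) * (1 - b), pi1=a * (1 - b), pi2=(1 - a) * b, pi12=a * b,
            rho12=0.0, rho0=0.0,
            sigma_beta2_1=5e-5, sigma_beta2_2=8e-5, sigma0_1=1.0, sigma0_2=1.1,
        )
        n1, n2 = 1e5, 5e4
        joint = bivariate_loglik(p, z1, z2, n1, n2)
        u1 = univariate_loglik(UnivariateParams(a, 5e-5, 1.0), z1, n1)
        u2 = univariate_loglik(UnivariateParams(b, 8e-5, 1.1), z2, n2)
        assert joint == pytest.approx(u1 + u2)

    def test_truth_beats_perturbations_bivariate(self):
        wins = 0
        for seed in range(6):
            cfg = ps.ArchitectureConfig(
                M=30_000,
                traits=[ps.TraitSpec("a", "disorder", 1e5), ps.TraitSpec("b", "disorder", 1e5)],
                pi={"a": 0.004, "b": 0.004},
                sigma_beta2={"a": 2e-4, "b": 2e-4},
                overlap={("a", "b"): ps.OverlapSpec(0.002, 0.6)},
                seed=seed + 50,
            )
            panel, _ = ps.simulate_panel(cfg)
            truth = BivariateParams(
                pi0=1 - 0.006, pi1=0.002, pi2=0.002, pi12=0.002,
                rho12=0.6, rho0=0.0,
                sigma_beta2_1=2e-4, sigma_beta2_2=2e-4, sigma0_1=1.0, sigma0_2=1.0,
            )
            args = (panel.Z[:, 0], panel.Z[:, 1], 1e5, 1e5)
            ll_t = bivariate_loglik(truth, *args)
            perturbed = []
            for f in (0.5, 1.5):
                perturbed.append(
                    BivariateParams(**{**vars(truth), "rho12": min(0.6 * f, 0.99)})
                )
                pi12 = 0.002 * f
                perturbed.append(
                    BivariateParams(**{
                        **vars(truth),
                        "pi12": pi12,
                        "pi1": 0.004 - pi12,
                        "pi2": 0.004 - pi12,
                        "pi0": 1 - 0.008 + pi12,
                    })
                )
            if all(bivariate_loglik(q, *args) <= ll_t for q in perturbed):
                wins += 1
        assert wins >= 4

    def test_ld_scores_unsupported(self):
        with pytest.raises(NotImplementedError):
            bivariate_loglik(
                self._null_params(), np.zeros(3), np.zeros(3), 1e4, 1e4,
                ld_scores=np.ones(3),
            )


@pytest.fixture(scope="module")
def overlapping_pair():
    cfg = ps.ArchitectureConfig(
        M=50_000,
        traits=[ps.TraitSpec("a", "disorder", 1e5), ps.TraitSpec("b", "disorder", 1e5)],
        pi={"a": 0.003, "b": 0.003},
        sigma_beta2={"a": 2e-4, "b": 2e-4},
        overlap={("a", "b"): ps.OverlapSpec(0.0015, 0.6)},
        seed=60,
    )
    panel, truth = ps.simulate_panel(cfg)
    u1 = ps.fit_univariate(panel.Z[:, 0], 1e5, seed=0, n_starts=3)
    u2 = ps.fit_univariate(panel.Z[:, 1], 1e5, seed=0, n_starts=3)
    return panel, truth, u1, u2


class TestFitBivariate:
    def test_swapping_traits_swaps_overlaps(self, overlapping_pair):
        panel, _, u1, u2 = overlapping_pair
        z1, z2 = panel.Z[:, 0], panel.Z[:, 1]
        f12 = ps.fit_bivariate(z1, z2, 1e5, 1e5, u1, u2, seed=1, n_starts=1)
        f21 = ps.fit_bivariate(z2, z1, 1e5, 1e5, u2, u1, seed=1, n_starts=1)
        assert f12.derived["overlap_frac_1"] == pytest.approx(
            f21.derived["overlap_frac_2"], abs=0.05
        )
        assert f12.derived["concordance"] == pytest.approx(
            f21.derived["concordance"], abs=0.05
        )

    def test_zero_overlap_recovered(self):
        cfg = ps.ArchitectureConfig(
            M=50_000,
            traits=[ps.TraitSpec("a", "disorder", 1e5), ps.TraitSpec("b", "disorder", 1e5)],
            pi={"a": 0.003, "b": 0.003},
            sigma_beta2={"a": 2e-4, "b": 2e-4},
            seed=61,
        )
        panel, _ = ps.simulate_panel(cfg)
        u1 = ps.fit_univariate(panel.Z[:, 0], 1e5, seed=0, n_starts=3)
        u2 = ps.fit_univariate(panel.Z[:, 1], 1e5, seed=0, n_starts=3)
        fb = ps.fit_bivariate(panel.Z[:, 0], panel.Z[:, 1], 1e5, 1e5, u1, u2, seed=0, n_starts=2)
        assert fb.derived["overlap_frac_1"] <= 0.1

    def test_posterior_counting_cross_check(self, overlapping_pair):
        panel, _, u1, u2 = overlapping_pair
        fb = ps.fit_bivariate(
            panel.Z[:, 0], panel.Z[:, 1], 1e5, 1e5, u1, u2, seed=1, n_starts=1
        )
        orthant = fb.derived["concordance"]
        counted = ps.concordance_posterior(
            fb.params, panel.Z[:, 0], panel.Z[:, 1], 1e5, 1e5, seed=0
        )
        assert counted == pytest.approx(orthant, abs=0.15)


class TestAic:
    def test_identical_fits_zero_difference(self, overlapping_pair):
        _, _, u1, _ = overlapping_pair
        assert ps.aic_compare(u1, {"same": u1}) == {"same": 0.0}

    def test_sparse_architecture_beats_infinitesimal(self):
        z, _ = simulate_univariate(0.001, 5e-4, 1e5, 30_000, 70)
        full = ps.fit_univariate(z, 1e5, seed=0, n_starts=3)
        inf = ps.fit_univariate(z, 1e5, seed=0, fix_pi=1.0, n_starts=2)
        diff = ps.aic_compare(full, {"infinitesimal": inf})["infinitesimal"]
        assert diff > 0

    def test_infinitesimal_architecture_not_rejected(self):
        z, _ = simulate_univariate(1.0, 3e-6, 1e5, 30_000, 71)
        full = ps.fit_univariate(z, 1e5, seed=0, n_starts=3)
        inf = ps.fit_univariate(z, 1e5, seed=0, fix_pi=1.0, n_starts=2)
        diff = ps.aic_compare(full, {"infinitesimal": inf})["infinitesimal"]
        assert diff < 6.0

    def test_mismatched_data_rejected(self, overlapping_pair):
        _, _, u1, _ = overlapping_pair
        other = ps.MixtureFit("univariate", u1.params, -1.0, 3, M=u1.M + 1)
        with pytest.raises(ValueError):
            ps.aic_compare(u1, {"bad": other})

    def test_bivariate_overlap_baselines(self, overlapping_pair):
        """Data simulated with genuine partial overlap: both the no-overlap
        and max-overlap baselines should fit worse (positive AIC gap)."""
        panel, _, u1, u2 = overlapping_pair
        args = (panel.Z[:, 0], panel.Z[:, 1], 1e5, 1e5, u1, u2)
        full = ps.fit_bivariate(*args, seed=1, n_starts=1)
        lo = ps.fit_bivariate(*args, seed=1, n_starts=1, constraint="no_overlap")
        hi = ps.fit_bivariate(*args, seed=1, n_starts=1, constraint="max_overlap")
        diffs = ps.aic_compare(full, {"min": lo, "max": hi})
        assert diffs["min"] > 0


class TestSubsampleAverage:
    def _fit_fn(self, z, n):
        def fn(idx):
            return ps.fit_univariate(z[idx], n, seed=0, n_starts=2)

        return fn

    def test_single_full_subset_equals_single_fit(self):
        z, _ = simulate_univariate(0.005, 1e-4, 1e5, 8000, 80)
        mean, se, fits = ps.subsample_average(self._fit_fn(z, 1e5), len(z), k_subsets=1)
        single = ps.fit_univariate(z, 1e5, seed=0, n_starts=2)
        assert mean["pi"] == pytest.approx(single.params.pi)
        assert se["pi"] == 0.0

    def test_deterministic_given_seed(self):
        z, _ = simulate_univariate(0.005, 1e-4, 1e5, 8000, 81)
        m1, _, _ = ps.subsample_average(self._fit_fn(z, 1e5), len(z), 3, 4000, seed=5)
        m2, _, _ = ps.subsample_average(self._fit_fn(z, 1e5), len(z), 3, 4000, seed=5)
        assert m1 == m2

    def test_se_shrinks_with_subset_size(self):
        # causal fraction pi is scale-free across subset sizes, unlike h2
        z, _ = simulate_univariate(0.005, 1e-4, 1e5, 8000, 82)
        _, se_small, _ = ps.subsample_average(self._fit_fn(z, 1e5), len(z), 8, 1000, seed=1)
        _, se_large, _ = ps.subsample_average(self._fit_fn(z, 1e5), len(z), 8, 6000, seed=1)
        assert se_large["pi"] < se_small["pi"]

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            ps.subsample_average(lambda i: None, 10, 2, 20)
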