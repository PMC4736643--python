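"""The five fitting methods: hand oracles, grid-search oracles, recovery."""

import numpy as np
import pytest

from retfit import (CensoredSample, RetentionDistribution, bin_times,
                    censored_nll, empirical_cumulative, expand_to_points,
                    fit, fit_bound_ml, fit_cd_ml, fit_cd_nls, regular_scheme,
                    simulate_censored, tail_varied_scheme)


class TestExpandToPoints:
    def test_upper(self, small_sample):
        assert list(expand_to_points(small_sample, "upper")) == [1.0, 1.0, 2.0]

    def test_mid(self, small_sample):
        assert list(expand_to_points(small_sample, "mid")) == [0.5, 0.5, 1.5]

    def test_lower_zero_floor(self, small_sample):
        assert list(expand_to_points(small_sample, "lower")) == [0.01, 0.01, 1.0]

    def test_right_censored_excluded(self):
        sample = CensoredSample([0.0, 1.0], [1.0, 2.0], [2, 1], right_censored=4)
        assert len(expand_to_points(sample, "upper")) == 3


class TestBoundML:
    def test_lognormal_matches_closed_form(self, typical_sample):
        # ML for lognormal point data: mean and population sd of log times
        for bound in ("lower", "mid", "upper"):
            points = expand_to_points(typical_sample, bound)
            result = fit_bound_ml(typical_sample, "lognormal", bound)
            assert result.converged
            assert result.mu_hat == pytest.approx(np.mean(np.log(points)), abs=1e-6)
            assert result.sigma_hat == pytest.approx(np.std(np.log(points)), abs=1e-6)
            expected_nll = -np.sum(
                RetentionDistribution("lognormal", result.mu_hat, result.sigma_hat)
                .frozen.logpdf(points))
            assert result.objective == pytest.approx(expected_nll, rel=1e-9)

    def test_weibull_fine_bin_recovery(self):
        true = RetentionDistribution("weibull", 2.0, 10.0)
        scheme = regular_scheme(0.1, 52.0)
        sample = simulate_censored(true, 10**5, scheme, seed=8)
        result = fit_bound_ml(sample, "weibull", "mid")
        assert result.converged
        assert result.mu_hat == pytest.approx(2.0, rel=0.02)
        assert result.sigma_hat == pytest.approx(10.0, rel=0.02)

    def test_upper_bound_mu_exceeds_lower_bound_mu(self, lognormal_default):
        sample = simulate_censored(lognormal_default, 500, regular_scheme(4.0), seed=4)
        up = fit_bound_ml(sample, "lognormal", "upper")
        lo = fit_bound_ml(sample, "lognormal", "lower")
        assert up.mu_hat > lo.mu_hat

    def test_degenerate_points_not_converged(self):
        sample = CensoredSample([0.0], [4.0], [10])
        result = fit_bound_ml(sample, "lognormal", "mid")
        assert not result.converged
        assert np.isnan(result.mu_hat)


class TestCensoredNLL:
    def test_exponential_hand_value(self):
        # gamma(shape 1, rate 1): one propagule in (0,1], one censored past 1
        sample = CensoredSample([0.0], [1.0], [1], right_censored=1)
        expected = -(np.log(1 - np.exp(-1)) - 1.0)
        assert censored_nll((1.0, 1.0), sample, "gamma") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.45868, abs=5e-6)

    def test_total_probability_interval_gives_zero(self):
        sample = CensoredSample([0.0], [np.inf], [7])
        for family, params in [("lognormal", (1.0, 1.0)), ("gamma", (2.0, 0.5)),
                               ("weibull", (1.5, 8.0))]:
            assert censored_nll(params, sample, family) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_counts(self, typical_sample):
        doubled = CensoredSample(typical_sample.lower, typical_sample.upper,
                                 2 * typical_sample.counts,
                                 2 * typical_sample.right_censored)
        a = censored_nll((1.8, 0.6), typical_sample, "lognormal")
        b = censored_nll((1.8, 0.6), doubled, "lognormal")
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_infinite_for_impossible_cell(self):
        sample = CensoredSample([0.0, 1.0], [1.0, 2.0], [0, 5], right_censored=0)
        # Weibull with tiny scale puts ~all mass below 1 h: cell (1,2] empty
        assert censored_nll((2.0, 1e-4), sample, "weibull") == np.inf

    def test_matches_multinomial_up_to_constant(self, typical_sample):
        from scipy.stats import multinomial
        bp = typical_sample.breakpoints

        def multinomial_ll(mu, sigma):
            dist = RetentionDistribution("lognormal", mu, sigma)
            cdf = dist.cdf(bp)
            p = np.concatenate([np.diff(cdf), [1 - cdf[-1]]])
            x = np.concatenate([typical_sample.counts, [typical_sample.right_censored]])
            return multinomial.logpmf(x, n=x.sum(), p=p / p.sum())

        pairs = [(1.8, 0.6), (2.0, 0.5), (1.5, 0.9)]
        nlls = [censored_nll(p, typical_sample, "lognormal") for p in pairs]
        mlls = [multinomial_ll(*p) for p in pairs]
        # same function up to an additive constant independent of parameters
        diffs_nll = np.diff(nlls)
        diffs_mll = -np.diff(mlls)
        assert np.allclose(diffs_nll, diffs_mll, atol=1e-8)


def _grid_minimum(objective, center, half_width=0.5, step=0.005):
    """Brute-force grid search oracle around a moment-style center."""
    mus = np.arange(center[0] - half_width, center[0] + half_width + step / 2, step)
    sigmas = np.arange(max(center[1] - half_width, step), center[1] + half_width + step / 2, step)
    best, best_val = None, np.inf
    for mu in mus:
        for sigma in sigmas:
            val = objective(mu, sigma)
            if val < best_val:
                best, best_val = (mu, sigma), val
    return best


GRID_FIXTURES = [
    ("lognormal", RetentionDistribution("lognormal", 1.8, 0.6), 4.0, 80, 21),
    ("lognormal", RetentionDistribution("lognormal", 1.3, 0.4), 2.0, 60, 22),
    ("gamma", RetentionDistribution("gamma", 2.5, 0.5), 4.0, 80, 23),
    ("weibull", RetentionDistribution("weibull", 1.8, 9.0), 2.0, 100, 24),
    ("lognormal", RetentionDistribution("lognormal", 2.2, 0.8), 4.0, 120, 25),
]


class TestCDML:
    @pytest.mark.parametrize("family,true,width,n,seed", GRID_FIXTURES)
    def test_matches_grid_search_oracle(self, family, true, width, n, seed):
        sample = simulate_censored(true, n, regular_scheme(width), seed=seed)
        result = fit_cd_ml(sample, family)
        assert result.converged
        grid_mu, grid_sigma = _grid_minimum(
            lambda mu, sg: censored_nll((mu, sg), sample, family),
            center=(result.mu_hat, result.sigma_hat))
        assert abs(result.mu_hat - grid_mu) <= 0.005 + 1e-9
        assert abs(result.sigma_hat - grid_sigma) <= 0.005 + 1e-9

    def test_estimate_beats_truth_in_likelihood(self, typical_sample, lognormal_default):
        result = fit_cd_ml(typical_sample, "lognormal")
        assert result.converged
        assert result.objective <= censored_nll(
            (lognormal_default.mu, lognormal_default.sigma), typical_sample, "lognormal") + 1e-9

    def test_fine_bin_recovery_within_1pct(self, lognormal_default):
        sample = simulate_censored(lognormal_default, 10**5, regular_scheme(0.5), seed=2)
        result = fit_cd_ml(sample, "lognormal")
        assert result.mu_hat == pytest.approx(1.8, rel=0.01)
        assert result.sigma_hat == pytest.approx(0.6, rel=0.01)

    def test_single_interval_unidentifiable(self):
        sample = CensoredSample([0.0], [52.0], [500])
        result = fit_cd_ml(sample, "lognormal")
        assert not result.converged

    def test_deterministic(self, typical_sample):
        a = fit_cd_ml(typical_sample, "gamma")
        b = fit_cd_ml(typical_sample, "gamma")
        assert (a.mu_hat, a.sigma_hat, a.objective) == (b.mu_hat, b.sigma_hat, b.objective)


class TestEmpiricalCumulative:
    def test_hand_cumsum(self):
        sample = CensoredSample([0.0, 1.0, 2.0], [1.0, 2.0, 4.0], [5, 3, 2])
        uppers, props = empirical_cumulative(sample)
        assert list(uppers) == [1.0, 2.0, 4.0]
        assert list(props) == [0.5, 0.8, 1.0]

    def test_censored_mass_keeps_last_point_below_one(self):
        sample = CensoredSample([0.0, 1.0], [1.0, 2.0], [5, 3], right_censored=2)
        _, props = empirical_cumulative(sample)
        assert list(props) == [0.5, 0.8]

    def test_empty_interval_keeps_cumulative_value(self):
        sample = CensoredSample([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [4, 0, 4])
        _, props = empirical_cumulative(sample)
        assert list(props) == [0.5, 0.5, 1.0]


class TestCDNLS:
    def test_noiseless_zero_residual_fixed_point(self, lognormal_default):
        n = 10**8
        uppers = np.arange(1.0, 53.0)
        cum = np.round(lognormal_default.cdf(uppers) * n)
        counts = np.diff(np.concatenate([[0.0], cum])).astype(np.int64)
        sample = CensoredSample(np.arange(0.0, 52.0), uppers, counts,
                                right_censored=int(n - counts.sum()))
        result = fit_cd_nls(sample, "lognormal")
        assert result.converged
        assert result.mu_hat == pytest.approx(1.8, abs=1e-4)
        assert result.sigma_hat == pytest.approx(0.6, abs=1e-4)
        assert result.objective < 1e-9

    @pytest.mark.parametrize("family,true,width,n,seed", GRID_FIXTURES[:3])
    def test_matches_grid_search_rss_oracle(self, family, true, width, n, seed):
        sample = simulate_censored(true, n, regular_scheme(width), seed=seed)
        result = fit_cd_nls(sample, family)
        assert result.converged
        uppers, props = empirical_cumulative(sample)

        def rss(mu, sigma):
            f = RetentionDistribution(family, mu, sigma).cdf(uppers)
            return float(np.sum((props - f) ** 2))

        grid_mu, grid_sigma = _grid_minimum(rss, center=(result.mu_hat, result.sigma_hat))
        # the optimizer must do at least as well as the grid oracle, and sit
        # in the same valley (correlated parameters allow the discrete grid
        # argmin to wander a couple of steps along it)
        assert result.objective <= rss(grid_mu, grid_sigma) + 1e-12
        assert abs(result.mu_hat - grid_mu) <= 3 * 0.005 + 1e-9
        assert abs(result.sigma_hat - grid_sigma) <= 3 * 0.005 + 1e-9

    def test_two_points_under_determined(self):
        sample = CensoredSample([0.0, 4.0], [4.0, 8.0], [300, 200])
        result = fit_cd_nls(sample, "lognormal")
        assert not result.converged


class TestCrossMethodProperties:
    def test_fine_bins_all_methods_agree(self, lognormal_default):
        """As bin width -> 0 the five methods see the same information and
        their estimates converge pairwise."""
        sample = simulate_censored(lognormal_default, 10**5, regular_scheme(0.05), seed=6)
        estimates = []
        for method in ("lower", "mid", "upper", "cd_ml", "cd_nls"):
            r = fit(sample, "lognormal", method)
            assert r.converged
            estimates.append((r.mu_hat, r.sigma_hat))
        est = np.array(estimates)
        for j, truth in enumerate([1.8, 0.6]):
            spread = est[:, j].max() - est[:, j].min()
            assert spread / truth < 0.01

    def test_all_methods_recover_parameters_with_fine_bins(self, probe_dist):
        sample = simulate_censored(probe_dist, 10**5, regular_scheme(0.05), seed=13)
        for method in ("lower", "mid", "upper", "cd_ml", "cd_nls"):
            r = fit(sample, probe_dist.family, method)
            assert r.converged, method
            assert r.mu_hat == pytest.approx(probe_dist.mu, rel=0.02), method
            assert r.sigma_hat == pytest.approx(probe_dist.sigma, rel=0.02), method

    def test_coarse_bins_overestimate_lognormal_sigma_for_midpoints(self, lognormal_default):
        """With 4 h bins at N=500, mid-interval fits inflate the variance
        parameter on average: the first-interval midpoint (2 h) stretches
        the low end of the log scale.  (The upper-bound fit compresses it
        instead, so the inflation is specific to mid-points.)"""
        sigma_hats = []
        scheme = regular_scheme(4.0)
        for rep in range(100):
            sample = simulate_censored(lognormal_default, 500, scheme, seed=1000 + rep)
            sigma_hats.append(fit_bound_ml(sample, "lognormal", "mid").sigma_hat)
        assert np.mean(sigma_hats) > 0.6


@pytest.mark.parametrize("family,r_name", [("lognormal", "lnorm"), ("weibull", "weibull")])
def test_cd_ml_matches_r_fitdistcens(tmp_path, family, r_name, typical_sample):
    """Independent oracle: R's fitdistrplus::fitdistcens on the same sample."""
    import shutil, subprocess
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rows = ["left,right"]
    for lo, hi, c in zip(typical_sample.lower, typical_sample.upper, typical_sample.counts):
        rows.extend([f"{lo},{hi}"] * int(c))
    data = tmp_path / "cens.csv"
    data.write_text("\n".join(rows) + "\n")
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(fitdistrplus))\n"
        f"d <- read.csv('{data}')\n"
        f"f <- fitdistcens(d, '{r_name}')\n"
        "cat(sprintf('%.10f %.10f', f$estimate[1], f$estimate[2]))\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    r_mu, r_sigma = map(float, out.stdout.split())
    ours = fit_cd_ml(typical_sample, family)
    assert ours.converged
    assert ours.mu_hat == pytest.approx(r_mu, rel=5e-3)
    assert ours.sigma_hat == pytest.approx(r_sigma, rel=5e-3)
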