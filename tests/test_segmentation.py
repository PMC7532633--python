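import itertools
import math

import numpy as np
import pytest
from scipy.stats import betabinom as sp_betabinom

from pmdscan import (
    BetaBinomParams,
    ConsistencyError,
    DataError,
    HmmParams,
    baum_welch,
    betabinom_logpmf,
    call_domains,
    default_init,
    fit_betabinom,
    posterior_decode,
    simulate_binned_sequence,
)
from pmdscan.binning import BinnedChrom, BinnedMethylome


def make_binned(m, n, bin_size=1000, chrom="chr1"):
    m = np.asarray(m, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    length = bin_size * len(m)
    bc = BinnedChrom(chrom, length, bin_size, m, n, np.ones(len(m), dtype=np.int64))
    return BinnedMethylome(bin_size, {chrom: bc}, 1.0)


class TestBetaBinomLogpmf:
    def test_uniform_beta_gives_uniform_outcomes(self):
        assert betabinom_logpmf(0, 1, BetaBinomParams(1, 1)) == pytest.approx(math.log(0.5))

    def test_empty_observation_has_probability_one(self):
        assert betabinom_logpmf(0, 0, BetaBinomParams(2.3, 0.7)) == 0.0

    def test_closed_form_value(self):
        # C(3,2) * B(4, 2) / B(2, 1) = 3 * (1/20) / (1/2) = 0.3
        assert betabinom_logpmf(2, 3, BetaBinomParams(2, 1)) == pytest.approx(
            math.log(0.3), abs=1e-12)

    @pytest.mark.parametrize("a,b", [(0.5, 0.5), (2, 6), (40, 4), (9999, 1)])
    def test_matches_scipy_within_1e10(self, a, b):
        n = 25
        m = np.arange(n + 1)
        ours = betabinom_logpmf(m, np.full(n + 1, n), BetaBinomParams(a, b))
        ref = sp_betabinom.logpmf(m, n, a, b)
        assert np.allclose(ours, ref, atol=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            betabinom_logpmf(4, 3, BetaBinomParams(1, 1))


class TestFitBetaBinom:
    def test_recovers_simulated_mean(self):
        rng = np.random.default_rng(42)
        p = rng.beta(2, 6, size=5000)
        n = np.full(5000, 30)
        m = rng.binomial(n, p)
        fit = fit_betabinom(m, n)
        assert fit.mean == pytest.approx(0.25, abs=0.02)

    def test_beats_or_matches_grid_search(self):
        """The refined MLE likelihood is at least as good as a coarse
        grid-search over (mean, precision)."""
        rng = np.random.default_rng(7)
        p = rng.beta(4, 2, size=800)
        n = rng.integers(5, 50, size=800)
        m = rng.binomial(n, p)
        fit = fit_betabinom(m, n)

        def ll(params):
            return float(np.sum(betabinom_logpmf(m, n, params)))

        grid_best = max(
            (BetaBinomParams(mu * s, (1 - mu) * s)
             for mu in np.linspace(0.05, 0.95, 19)
             for s in np.geomspace(0.5, 500, 25)),
            key=ll,
        )
        assert ll(fit) >= ll(grid_best) - 1e-6

    def test_point_mass_weights_fit_the_weighted_mean(self):
        m = np.array([0, 50, 100])
        n = np.array([100, 100, 100])
        w = np.array([0.0, 1.0, 0.0])
        fit = fit_betabinom(m, n, weights=w)
        assert fit.mean == pytest.approx(0.5, abs=0.01)

    def test_single_observation_falls_back_to_smoothed_mean(self):
        fit = fit_betabinom([3], [4])
        assert fit.mean == pytest.approx((3 + 0.5) / (4 + 1), rel=1e-3)
        assert fit.precision == pytest.approx(1e4, rel=0.01)

    def test_all_uncovered_raises(self):
        with pytest.raises(DataError):
            fit_betabinom([0, 0], [0, 0])


def enumerate_posteriors(m, n, params: HmmParams):
    """Exact forward-backward oracle: marginalise over all 2^L state paths."""
    L = len(m)
    post = np.zeros((L, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=L):
        logp = math.log(params.pi[path[0]])
        logp += betabinom_logpmf(int(m[0]), int(n[0]), params.emis[path[0]])
        for t in range(1, L):
            logp += math.log(params.A[path[t - 1], path[t]])
            logp += betabinom_logpmf(int(m[t]), int(n[t]), params.emis[path[t]])
        p = math.exp(logp)
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total


class TestPosteriorDecode:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.integers(3, 12)
        n = rng.integers(0, 6, size=L)
        m = rng.binomial(n, 0.6)
        params = HmmParams(
            np.array([0.3, 0.7]),
            np.array([[0.8, 0.2], [0.35, 0.65]]),
            (BetaBinomParams(2, 3), BetaBinomParams(6, 1.5)),
        )
        track = posterior_decode(make_binned(m, n), params)
        expected = enumerate_posteriors(m, n, params)
        assert np.allclose(track.posterior["chr1"], expected[:, 0], atol=1e-9)

    def test_posteriors_normalised(self):
        rng = np.random.default_rng(0)
        n = rng.integers(0, 40, size=500)
        m = rng.binomial(n, 0.5)
        track = posterior_decode(make_binned(m, n), default_init())
        assert np.all((track.posterior["chr1"] >= 0) & (track.posterior["chr1"] <= 1))

    def test_interior_of_long_run_has_confident_posterior(self):
        m = np.r_[np.full(5, 34), np.full(20, 18), np.full(5, 34)]
        n = np.full(30, 40)
        params = default_init()
        track = posterior_decode(make_binned(m, n), params)
        assert np.all(track.posterior["chr1"][8:22] > 0.99)

    def test_uninformative_emissions_give_pi_driven_posterior(self):
        params = HmmParams(
            np.array([0.25, 0.75]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
            (BetaBinomParams(2, 3), BetaBinomParams(2, 3)),
        )
        n = np.full(10, 20)
        m = np.full(10, 10)
        track = posterior_decode(make_binned(m, n), params)
        post = track.posterior["chr1"]
        assert post[0] == pytest.approx(0.25, abs=1e-12)
        assert np.allclose(post[1:], 0.5, atol=1e-12)


class TestBaumWelch:
    def test_parameter_recovery_single_instance(self):
        m, n, _ = simulate_binned_sequence(
            10_000, 40, means=(0.45, 0.85), precisions=(10, 10), diag=0.99, seed=3)
        params, track = baum_welch(make_binned(m, n))
        assert params.pmd_mean == pytest.approx(0.45, abs=0.03)
        assert params.background_mean == pytest.approx(0.85, abs=0.03)
        assert params.A[0, 0] == pytest.approx(0.99, abs=0.01)
        assert params.A[1, 1] == pytest.approx(0.99, abs=0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_log_likelihood_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(50, 400))
        n = rng.poisson(rng.uniform(1, 40), size=L)
        m = rng.binomial(n, rng.beta(2, 2))
        params, track = baum_welch(make_binned(m, n), max_iter=40)
        h = np.array(track.ll_history)
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[:-1]))

    def test_single_regime_data_is_all_background(self):
        m = np.full(200, 34)
        n = np.full(200, 40)
        params, track = baum_welch(make_binned(m, n))
        assert np.all(track.posterior["chr1"] < 0.5)

    def test_two_informative_bins_is_minimal_valid_input(self):
        params, track = baum_welch(make_binned([1, 30], [40, 40]))
        assert track.n_iter >= 1

    def test_fewer_than_two_informative_bins_raises(self):
        with pytest.raises(DataError):
            baum_welch(make_binned([0, 0], [0, 0]))

    def test_label_permutation_invariance(self):
        """Starting with swapped state labels yields the same domains."""
        m, n, _ = simulate_binned_sequence(
            2000, 40, means=(0.45, 0.85), precisions=(10, 10), diag=0.98, seed=9)
        binned = make_binned(m, n)
        init = default_init()
        swapped = HmmParams(init.pi[[1, 0]], init.A[np.ix_([1, 0], [1, 0])],
                            (init.emis[1], init.emis[0]))
        p1, t1 = baum_welch(binned, init=init)
        p2, t2 = baum_welch(binned, init=swapped)
        d1 = call_domains(t1, binned)
        d2 = call_domains(t2, binned)
        assert d1.df[["chrom", "start", "end"]].equals(d2.df[["chrom", "start", "end"]])


class TestCallDomains:
    def _track(self, post, binned):
        track = posterior_decode(binned, default_init())
        track.posterior["chr1"] = np.asarray(post, dtype=float)
        return track

    def test_simple_run_extraction(self):
        binned = make_binned([0, 0, 0], [0, 0, 0])
        pmds = call_domains(self._track([0.9, 0.9, 0.1], binned), binned)
        assert pmds.df[["start", "end"]].values.tolist() == [[0, 2000]]

    def test_no_domains_when_all_below_cutoff(self):
        binned = make_binned([0, 0, 0], [0, 0, 0])
        assert len(call_domains(self._track([0.1, 0.1, 0.1], binned), binned)) == 0

    def test_strict_cutoff_splits_runs(self):
        binned = make_binned([0, 0, 0], [0, 0, 0])
        pmds = call_domains(self._track([0.9, 0.4, 0.9], binned), binned)
        assert len(pmds) == 2

    def test_tie_at_cutoff_goes_to_background(self):
        binned = make_binned([0, 0], [0, 0])
        assert len(call_domains(self._track([0.5, 0.5], binned), binned)) == 0

    def test_misaligned_track_rejected(self):
        binned = make_binned([0, 0, 0], [0, 0, 0])
        other = make_binned([0, 0], [0, 0])
        track = posterior_decode(other, default_init())
        with pytest.raises(ConsistencyError):
            call_domains(track, binned)
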