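import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from vertemech import (BimodalFit, GreyscaleVolume, Histogram, average_histogram,
                       compute_histogram, fit_bimodal, global_threshold,
                       select_species_threshold, threshold_clear_minimum,
                       threshold_equal_misclassification)


def mixture_histogram(mu1, mu2, s1, s2, a1, a2, n_bins=200, lo=None, hi=None):
    """Histogram of the exact model curve (no sampling noise)."""
    lo = mu1 - 5 * s1 if lo is None else lo
    hi = mu2 + 5 * s2 if hi is None else hi
    edges = np.linspace(lo, hi, n_bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    counts = w * (a1 * norm.pdf(c, mu1, s1) + a2 * norm.pdf(c, mu2, s2))
    return Histogram(edges=edges, counts=counts)


def sampled_histogram(mu1, mu2, s1, s2, w1, n, seed, n_bins=256):
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < w1
    x = np.where(comp, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
    counts, edges = np.histogram(x, bins=n_bins)
    return Histogram(edges=edges, counts=counts.astype(float))


class TestComputeHistogram:
    def test_constant_volume_single_bin(self):
        vol = GreyscaleVolume(data=np.full((4, 4, 4), 3.0), spacing=(1, 1, 1))
        h = compute_histogram(vol, n_bins=8)
        assert np.count_nonzero(h.counts) == 1
        assert h.total == 64

    def test_full_volume_conserves_count(self):
        rng = np.random.default_rng(0)
        vol = GreyscaleVolume(data=rng.random((5, 6, 7)), spacing=(0.5, 0.5, 0.5))
        h = compute_histogram(vol, n_bins=32)
        assert h.total == 5 * 6 * 7

    def test_roi_matches_bruteforce_centre_enumeration(self):
        rng = np.random.default_rng(1)
        vol = GreyscaleVolume(data=rng.random((40, 40, 50)), spacing=(0.074,) * 3)
        roi = ((0.30, 1.91), (0.11, 2.57), (0.52, 3.03))
        h = compute_histogram(vol, roi=roi, n_bins=16)
        count = 0
        for i in range(40):
            for j in range(40):
                for k in range(50):
                    x, y, z = ((np.array([i, j, k]) + 0.5) * 0.074)
                    if (roi[0][0] <= x <= roi[0][1] and roi[1][0] <= y <= roi[1][1]
                            and roi[2][0] <= z <= roi[2][1]):
                        count += 1
        assert h.total == count

    def test_roi_errors(self):
        vol = GreyscaleVolume(data=np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            compute_histogram(vol, roi=((0, 1), (0, 1), (2, 2)))  # degenerate
        with pytest.raises(ValueError):
            compute_histogram(vol, roi=((10, 12), (0, 1), (0, 1)))  # outside


class TestAverageHistogram:
    def test_identity_and_mean(self):
        h1 = Histogram(edges=[0, 1, 2], counts=[2, 0])
        h2 = Histogram(edges=[0, 1, 2], counts=[0, 2])
        assert np.array_equal(average_histogram([h1]).counts, [2, 0])
        assert np.array_equal(average_histogram([h1, h2]).counts, [1, 1])

    def test_random_set_matches_direct_mean(self):
        rng = np.random.default_rng(3)
        edges = np.linspace(0, 10, 21)
        hs = [Histogram(edges=edges, counts=rng.integers(0, 50, 20))
              for _ in range(5)]
        avg = average_histogram(hs)
        np.testing.assert_allclose(avg.counts,
                                   np.mean([h.counts for h in hs], axis=0))

    def test_mismatched_edges_rejected(self):
        h1 = Histogram(edges=[0, 1, 2], counts=[1, 1])
        h2 = Histogram(edges=[0, 1, 3], counts=[1, 1])
        with pytest.raises(ValueError):
            average_histogram([h1, h2])


class TestFitBimodal:
    def test_parameter_recovery_from_large_sample(self):
        # 1e6 draws from 0.5 N(100, 10^2) + 0.5 N(200, 30^2)
        h = sampled_histogram(100, 200, 10, 30, 0.5, 10 ** 6, seed=42)
        fit = fit_bimodal(h)
        assert fit.converged
        assert abs(fit.mu1 - 100) / 100 < 0.01
        assert abs(fit.mu2 - 200) / 200 < 0.01
        assert abs(fit.sigma1 - 10) / 10 < 0.02
        assert abs(fit.sigma2 - 30) / 30 < 0.02

    def test_exact_model_curve_is_fixed_point(self):
        h = mixture_histogram(100, 200, 12, 25, 6e5, 4e5)
        fit = fit_bimodal(h)
        assert fit.residual < 1e-4 * float(h.counts.max()) ** 2
        assert abs(fit.mu1 - 100) < 0.5 and abs(fit.mu2 - 200) < 0.5

    def test_objective_no_worse_than_truth_start(self):
        h = mixture_histogram(100, 180, 15, 20, 5e5, 5e5)
        truth = (100, 180, 15, 20, 5e5, 5e5)
        from vertemech.threshold_select import _objective
        fit = fit_bimodal(h, init=truth)
        assert fit.residual <= _objective(np.array(truth), h.centres, h.widths,
                                          h.counts) + 1e-9

    def test_two_spikes_do_not_crash(self):
        edges = np.linspace(0, 100, 101)
        counts = np.zeros(100)
        counts[[20, 21, 22, 70, 71, 72]] = [1, 1000, 1, 1, 1000, 1]
        fit = fit_bimodal(Histogram(edges=edges, counts=counts))
        assert 18 < fit.mu1 < 26 and 68 < fit.mu2 < 76
        assert fit.sigma1 >= 1.0  # bounded below by the bin width

    def test_insufficient_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_bimodal(Histogram(edges=np.arange(7.0),
                                  counts=[5, 0, 3, 0, 2, 0]))
        with pytest.raises(ValueError):
            fit_bimodal(Histogram(edges=np.arange(11.0),
                                  counts=[0, 0, 9, 0, 0, 0, 0, 0, 0, 0]))


class TestEqualMisclassification:
    def test_symmetric_mixture_gives_midpoint(self):
        fit = BimodalFit(mu1=100, mu2=200, sigma1=20, sigma2=20, A1=1e5, A2=1e5,
                         residual=0, converged=True)
        assert abs(threshold_equal_misclassification(fit) - 150.0) < 1e-6

    def test_matches_bisection_oracle_on_randomized_fits(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mu1 = rng.uniform(50, 150)
            mu2 = mu1 + rng.uniform(30, 150)
            s1, s2 = rng.uniform(5, 30, 2)
            a1, a2 = rng.uniform(1e4, 1e6, 2)
            fit = BimodalFit(mu1=mu1, mu2=mu2, sigma1=s1, sigma2=s2,
                             A1=a1, A2=a2, residual=0, converged=True)

            def g(t):
                return a1 * (1 - norm.cdf((t - mu1) / s1)) \
                    - a2 * norm.cdf((t - mu2) / s2)

            lo, hi = mu1, mu2
            if np.sign(g(lo)) == np.sign(g(hi)):
                continue  # pathological draw: the operation raises, oracle too
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.sign(g(mid)) == np.sign(g(lo)):
                    lo = mid
                else:
                    hi = mid
            assert abs(threshold_equal_misclassification(fit)
                       - 0.5 * (lo + hi)) < 1e-6

    def test_increasing_background_mass_raises_threshold(self):
        base = dict(mu1=100, mu2=200, sigma1=10, sigma2=30, residual=0,
                    converged=True)
        t1 = threshold_equal_misclassification(BimodalFit(A1=1e5, A2=1e5, **base))
        t2 = threshold_equal_misclassification(BimodalFit(A1=2e5, A2=1e5, **base))
        assert t2 > t1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(mu1=st.floats(0, 100), gap=st.floats(10, 200),
           s1=st.floats(2, 40), s2=st.floats(2, 40),
           la1=st.floats(3, 6), la2=st.floats(3, 6))
    def test_threshold_strictly_interior(self, mu1, gap, s1, s2, la1, la2):
        fit = BimodalFit(mu1=mu1, mu2=mu1 + gap, sigma1=s1, sigma2=s2,
                         A1=10 ** la1, A2=10 ** la2, residual=0, converged=True)
        try:
            t = threshold_equal_misclassification(fit)
        except ValueError:
            return  # no crossing: valid refusal for pathological mass ratios
        assert fit.mu1 < t < fit.mu2


class TestClearMinimum:
    def test_symmetric_separated_minimum_at_midpoint(self):
        fit = BimodalFit(mu1=100, mu2=200, sigma1=15, sigma2=15, A1=1e5, A2=1e5,
                         residual=0, converged=True)
        t = threshold_clear_minimum(fit)
        assert t is not None and abs(t - 150) < 1e-3

    def test_overlapping_unimodal_returns_none(self):
        fit = BimodalFit(mu1=100, mu2=120, sigma1=25, sigma2=35, A1=1e5, A2=1e5,
                         residual=0, converged=True)
        assert threshold_clear_minimum(fit) is None

    def test_asymmetric_matches_dense_grid_argmin(self):
        fit = BimodalFit(mu1=90, mu2=210, sigma1=12, sigma2=28, A1=3e5, A2=1e5,
                         residual=0, converged=True)
        t = threshold_clear_minimum(fit)
        grid = np.linspace(fit.mu1, fit.mu2, 10 ** 5)
        t_grid = grid[np.argmin(fit.density(grid))]
        assert t is not None and abs(t - t_grid) < (fit.mu2 - fit.mu1) / 10 ** 4


class TestSelectAndGlobal:
    def test_rule_dispatch_by_separation(self):
        sep = BimodalFit(mu1=100, mu2=220, sigma1=15, sigma2=25, A1=8e5, A2=2e5,
                         residual=0, converged=True)
        ovl = BimodalFit(mu1=100, mu2=150, sigma1=20, sigma2=35, A1=5e5, A2=5e5,
                         residual=0, converged=True)
        assert select_species_threshold(sep).rule == "clear_minimum"
        assert select_species_threshold(ovl).rule == "equal_misclassification"

    def test_symmetric_mixture_rules_agree(self):
        fit = BimodalFit(mu1=100, mu2=200, sigma1=15, sigma2=15, A1=1e5, A2=1e5,
                         residual=0, converged=True)
        t_min = threshold_clear_minimum(fit)
        t_eq = threshold_equal_misclassification(fit)
        assert abs(t_min - t_eq) < 1e-3
        assert select_species_threshold(fit).rule == "clear_minimum"

    def test_selection_is_deterministic(self):
        fit = BimodalFit(mu1=100, mu2=220, sigma1=15, sigma2=25, A1=8e5, A2=2e5,
                         residual=0, converged=True)
        r1 = select_species_threshold(fit)
        r2 = select_species_threshold(fit)
        assert r1.threshold == r2.threshold and r1.rule == r2.rule

    def test_global_threshold_arithmetic(self):
        assert global_threshold(100, 200) == 150
        assert global_threshold(137.5, 137.5) == 137.5
        assert global_threshold(110, 140) == global_threshold(140, 110)
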