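import numpy as np
import pytest

from telandscape import dfe
from telandscape.sfs import FoldedSFS
from telandscape.simulate import simulate_sfs_pair


def fine_grid_expected(S, n, m=200_001):
    """Independent oracle: trapezoid integration of the sampled PRF density
    on a fine uniform grid.  The integrand is written with the 1/(x(1-x))
    factor cancelled analytically so its endpoint limits are finite
    (ratio(0) = 1, ratio(1) = 0)."""
    from scipy.special import comb

    x = np.linspace(0, 1, m)
    inner = x[1:-1]
    ratio = np.empty(m)
    if S == 0:
        ratio[1:-1] = 1.0 - inner
    else:
        with np.errstate(over="ignore"):
            ratio[1:-1] = np.expm1(-S * (1 - inner)) / np.expm1(-S)
    ratio[0], ratio[-1] = 1.0, 0.0
    out = []
    for i in range(1, n):
        y = comb(n, i) * x ** (i - 1) * (1 - x) ** (n - i - 1) * ratio
        y[0] = comb(n, i) if i == 1 else 0.0
        y[-1] = 0.0
        out.append(np.trapezoid(y, x))
    return np.array(out)


class TestExpectedSFS:
    def test_neutral_closed_form_n4(self):
        folded = dfe.expected_folded_sfs(0.0, 4)
        expect = np.array([1 + 1 / 3, 1 / 2])
        assert np.allclose(folded, expect, rtol=1e-6)

    def test_matches_fine_grid_oracle_moderate_selection(self):
        for S in (-1.0, -10.0, -50.0):
            mine = dfe.expected_unfolded_sfs(S, 10)
            oracle = fine_grid_expected(S, 10)
            assert np.allclose(mine, oracle, rtol=1e-4)

    def test_strong_selection_concentrates_on_singletons(self):
        e = dfe.expected_folded_sfs(-100.0, 20)
        oracle = dfe.fold(fine_grid_expected(-100.0, 20))
        assert np.allclose(e, oracle, rtol=1e-3)
        assert e[0] / e.sum() > 0.9

    def test_converges_to_neutral_form_as_selection_vanishes(self):
        neutral = dfe.expected_folded_sfs(0.0, 6)
        err = []
        for S in (-1e-2, -1e-4, -1e-6):
            e = dfe.expected_folded_sfs(S, 6)
            err.append(np.max(np.abs(e - neutral) / neutral))
        # error scales ~ O(|S|): first-order sensitivity of the model
        assert err[0] > err[1] > err[2]
        assert err[1] < 5e-5
        assert err[2] < 1e-6

    def test_nonnegative_and_finite_over_selection_range(self):
        for S in (0.0, -1.0, -100.0, -1e4):
            e = dfe.expected_folded_sfs(S, 12)
            assert np.all(np.isfinite(e)) and np.all(e >= 0)

    def test_beyond_stability_bound_flagged(self):
        with pytest.warns(RuntimeWarning):
            dfe.expected_folded_sfs(-1e7, 6)

    def test_monotone_singleton_fraction_in_selection_strength(self):
        """Stronger mean selection inflates the nonsyn singleton fraction."""
        fracs = []
        for sm in (1.0, 10.0, 100.0, 1000.0):
            b = dfe.gamma_expected_folded(0.5, sm, 20)
            fracs.append(b[0] / b.sum())
        assert np.all(np.diff(fracs) > 0)


class TestGammaMixture:
    def test_grid_mixture_matches_direct_quadrature(self):
        """The cached |S|-grid integration agrees with direct per-class
        integration of the gamma density."""
        from scipy.integrate import quad
        from scipy.special import gammainc
        from scipy.stats import gamma as gamma_dist

        beta, sm, n = 0.4, 300.0, 8
        scale = sm / beta
        s_lo, s_hi = 1e-5, 5e4
        mine = dfe.gamma_expected_folded(beta, sm, n)
        neutral = dfe.expected_unfolded_sfs(0.0, n)
        direct_unfolded = []
        for i in range(n - 1):
            # log-s substitution tames the s^(beta-1) density singularity
            val, _ = quad(
                lambda t, i=i: dfe.expected_unfolded_sfs(-np.exp(t), n)[i]
                * gamma_dist.pdf(np.exp(t), beta, scale=scale) * np.exp(t),
                np.log(s_lo), np.log(s_hi), limit=300,
            )
            # mass below the cutoff behaves neutrally
            direct_unfolded.append(val + gammainc(beta, s_lo / scale) * neutral[i])
        from telandscape.sfs import fold

        direct = fold(np.array(direct_unfolded))
        assert np.allclose(mine, direct, rtol=1e-2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dfe.gamma_expected_folded(-1.0, 100.0, 10)


class TestFit:
    def _pair(self, s, d, n=20, L=1e6):
        return (FoldedSFS(n, np.asarray(s, float), L, "synonymous"),
                FoldedSFS(n, np.asarray(d, float), L, "nonsynonymous"))

    def test_nuisance_factors_unity_on_exact_neutral_data(self):
        """Feeding the exact neutral expectations recovers r_i = 1."""
        n, L, theta = 20, 1e6, 0.005
        neutral = dfe._grid_tables(n)[3]
        b = dfe.gamma_expected_folded(0.3, 500.0, n)
        syn, nonsyn = self._pair(theta * L * neutral, theta * L * b, n, L)
        fit = dfe.fit_gamma_dfe(syn, nonsyn)
        assert np.allclose(fit.r, 1.0, atol=0.02)
        assert fit.beta == pytest.approx(0.3, rel=0.05)
        assert fit.s_mean == pytest.approx(-500.0, rel=0.1)

    def test_identical_spectra_hit_neutral_boundary(self):
        n, L = 20, 1e6
        neutral = dfe._grid_tables(n)[3]
        syn, nonsyn = self._pair(0.005 * L * neutral, 0.005 * L * neutral, n, L)
        fit = dfe.fit_gamma_dfe(syn, nonsyn)
        assert fit.neutral_boundary

    def test_likelihood_peaks_near_generating_parameters(self):
        syn, nonsyn = simulate_sfs_pair(0.3, 500.0, 20, 1e7, 1e7, 0.008, seed=5)
        s = syn.counts
        d = nonsyn.counts
        A = syn.L * dfe._grid_tables(20)[3]

        def nll(beta, sm):
            B = nonsyn.L * dfe.gamma_expected_folded(beta, sm, 20)
            return dfe._profile_nuisance(s, d, A, B)[2]

        at_truth = nll(0.3, 500.0)
        for beta, sm in [(0.6, 500.0), (0.3, 5000.0), (0.15, 100.0), (1.0, 50.0)]:
            assert nll(beta, sm) > at_truth

    def test_parameter_recovery_small_batch(self):
        betas, sms = [], []
        for seed in range(6):
            syn, nonsyn = simulate_sfs_pair(0.3, 500.0, 20, 1e6, 1e6, 0.008, seed)
            fit = dfe.fit_gamma_dfe(syn, nonsyn)
            betas.append(fit.beta)
            sms.append(-fit.s_mean)
        assert 0.2 < np.median(betas) < 0.4
        assert 250 < np.median(sms) < 1000

    def test_mismatched_sample_sizes_rejected(self):
        syn = FoldedSFS(20, np.ones(10), 1e6, "synonymous")
        nonsyn = FoldedSFS(18, np.ones(9), 1e6, "nonsynonymous")
        with pytest.raises(ValueError):
            dfe.fit_gamma_dfe(syn, nonsyn)

    def test_too_few_classes_rejected(self):
        syn = FoldedSFS(4, np.ones(2), 1e4, "synonymous")
        nonsyn = FoldedSFS(4, np.ones(2), 1e4, "nonsynonymous")
        with pytest.raises(ValueError, match="unidentifiable"):
            dfe.fit_gamma_dfe(syn, nonsyn)

    def test_scaled_coefficient_conversion(self):
        fit = dfe.DFEFit(beta=0.3, s_mean=-400.0, theta=0.01, r=np.ones(10),
                         log_likelihood=0.0, n=20)
        assert fit.mean_s(100.0) == pytest.approx(-1.0)
        assert fit.es == -400.0
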