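import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterflim.decayfit import (
    estimate_background,
    fit_multiexp,
    mean_lifetimes,
    moment_mean_lifetime,
    select_n_components,
)
from clusterflim.synthetic import SpeciesDef, delta_irf, expected_curve, gaussian_irf

DT = 19.97
N_CHANNELS = 512
IRF = gaussian_irf(N_CHANNELS, DT, t0=300.0, fwhm=100.0)


class TestEstimateBackground:
    def test_flat_histogram(self):
        assert estimate_background(np.full(100, 4.0)) == 4.0

    def test_all_zero_window(self):
        assert estimate_background(np.zeros(100)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.ones(10), prepulse_window=(5, 5))

    def test_poisson_window_accuracy(self, rng):
        # Monte-Carlo oracle: mean of a 30-channel Poisson(2) window
        lam, width = 2.0, 30
        errs = [
            estimate_background(rng.poisson(lam, 100), (0, width)) - lam
            for _ in range(200)
        ]
        assert abs(np.mean(errs)) < 3 * np.sqrt(lam / width) / np.sqrt(len(errs))


class TestMeanLifetimes:
    def test_worked_two_component_case(self):
        tau_m_a, betas, tau_m = mean_lifetimes([0.5, 0.5], [1.0, 3.0])
        assert tau_m_a == pytest.approx(2.0)
        assert betas.tolist() == pytest.approx([0.25, 0.75])
        assert tau_m == pytest.approx(2.5)

    def test_single_component_identity(self):
        tau_m_a, betas, tau_m = mean_lifetimes([1.0], [1.7])
        assert tau_m_a == tau_m == pytest.approx(1.7)
        assert betas.tolist() == [1.0]

    def test_non_positive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            mean_lifetimes([1.0], [0.0])

    @settings(deadline=None, max_examples=50)
    @given(
        alphas=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4),
        taus=st.lists(st.floats(0.05, 10.0), min_size=4, max_size=4),
    )
    def test_betas_normalized_and_ordering(self, alphas, taus):
        taus = taus[: len(alphas)]
        tau_m_a, betas, tau_m = mean_lifetimes(alphas, taus)
        assert betas.sum() == pytest.approx(1.0, abs=1e-9)
        # component-weighted mean never falls below the amplitude-weighted
        # one (Cauchy-Schwarz); equality only for effectively one component
        assert tau_m >= tau_m_a - 1e-12


class TestFitMultiexp:
    def test_noiseless_monoexponential_recovery(self):
        sp = SpeciesDef("m", (1.0,), (1.0,))
        curve = expected_curve(sp, IRF, DT, N_CHANNELS, 1e6, background=2.0)
        fit = fit_multiexp(curve, 1, IRF, DT)
        assert fit.lifetimes[0] == pytest.approx(1.0, abs=1e-3)
        assert fit.background == pytest.approx(2.0, rel=0.05)

    def test_biexponential_recovery_with_poisson_noise(self, rng):
        sp = SpeciesDef("b", (0.5, 0.5), (0.5, 3.0))
        curve = expected_curve(sp, IRF, DT, N_CHANNELS, 1e6, background=2.0)
        fit = fit_multiexp(rng.poisson(curve), 2, IRF, DT)
        assert fit.lifetimes[0] == pytest.approx(0.5, rel=0.05)
        assert fit.lifetimes[1] == pytest.approx(3.0, rel=0.05)
        assert fit.tau_m_a == pytest.approx(1.75, rel=0.05)
        assert 0.5 < fit.goodness < 2.0

    def test_overfitting_monoexp_with_two_components_keeps_tau_ma(self):
        # degeneracy: n=2 on truly monoexponential data must still give
        # the correct amplitude-weighted mean lifetime
        sp = SpeciesDef("m", (1.0,), (1.2,))
        curve = expected_curve(sp, IRF, DT, N_CHANNELS, 1e6, background=1.0)
        fit = fit_multiexp(curve, 2, IRF, DT)
        assert fit.tau_m_a == pytest.approx(1.2, abs=1e-2)

    def test_amplitude_scale_invariance(self, rng):
        sp = SpeciesDef("b", (0.4, 0.6), (0.6, 2.5))
        curve = expected_curve(sp, IRF, DT, N_CHANNELS, 2e5)
        y = rng.poisson(curve)
        f1 = fit_multiexp(y, 2, IRF, DT)
        f2 = fit_multiexp(y * 10, 2, IRF, DT)
        assert np.allclose(f1.lifetimes, f2.lifetimes, rtol=1e-2)
        assert np.allclose(f1.betas, f2.betas, atol=1e-2)

    def test_invariant_tau_ma_le_tau_m(self, rng):
        sp = SpeciesDef("b", (0.5, 0.5), (0.4, 2.0))
        curve = expected_curve(sp, IRF, DT, N_CHANNELS, 1e6)
        fit = fit_multiexp(rng.poisson(curve), 2, IRF, DT)
        assert fit.tau_m_a <= fit.tau_m

    def test_empty_fls_rejected(self):
        with pytest.raises(ValueError):
            fit_multiexp(np.zeros(N_CHANNELS), 1, IRF, DT)

    def test_unbiased_recovery_over_replicates(self, rng):
        # bias of the lifetime estimator on repeated noisy monoexponential
        # signatures stays below 1%
        sp = SpeciesDef("m", (1.0,), (1.5,))
        curve = expected_curve(sp, IRF, DT, 256, 1e5)
        taus = [
            fit_multiexp(rng.poisson(curve), 1, IRF, DT, max_starts=2).lifetimes[0]
            for _ in range(25)
        ]
        assert abs(np.mean(taus) - 1.5) / 1.5 < 0.01


def test_moment_lifetime_orders_species():
    fast = expected_curve(SpeciesDef("f", (1.0,), (0.3,)), IRF, DT, N_CHANNELS, 1e5)
    slow = expected_curve(SpeciesDef("s", (1.0,), (2.0,)), IRF, DT, N_CHANNELS, 1e5)
    assert moment_mean_lifetime(fast, DT) < moment_mean_lifetime(slow, DT)


def test_component_selection_prefers_true_model(rng):
    sp = SpeciesDef("b", (0.5, 0.5), (0.3, 2.5))
    curve = expected_curve(sp, IRF, DT, 256, 1e6)
    scores = select_n_components(rng.poisson(curve), IRF, DT, n_range=(1, 2))
    by_n = {s["n"]: s["bic"] for s in scores}
    assert by_n[2] < by_n[1]
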