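import numpy as np
import pytest

from clusterflim.synthetic import (
    SceneLayout,
    SpeciesDef,
    block_layout,
    delta_irf,
    expected_curve,
    fig2_species_panel,
    gaussian_irf,
    simulate_image,
    simulate_pixel,
)


class TestGaussianIrf:
    def test_normalized_to_unit_sum(self):
        irf = gaussian_irf(256, 19.97, t0=500.0, fwhm=100.0)
        assert irf.vector.sum() == pytest.approx(1.0, abs=1e-9)

    def test_narrow_irf_peaks_in_t0_bin(self):
        irf = gaussian_irf(64, 20.0, t0=210.0, fwhm=1.0)
        assert int(np.argmax(irf.vector)) == 10

    def test_measured_fwhm_on_oversampled_grid(self):
        # independent numeric check: sample the IRF at 10x finer channels
        # and measure the width at half maximum directly
        fwhm = 100.0
        irf = gaussian_irf(2560, 1.997, t0=2000.0, fwhm=fwhm)
        v = irf.vector
        half = v.max() / 2
        above = np.nonzero(v >= half)[0]
        measured = (above[-1] - above[0] + 1) * 1.997
        assert measured == pytest.approx(fwhm, rel=0.02)

    def test_rejects_bad_fwhm(self):
        with pytest.raises(ValueError):
            gaussian_irf(64, 20.0, t0=100.0, fwhm=0.0)


class TestExpectedCurve:
    def test_delta_irf_monoexp_has_constant_channel_ratio(self):
        # tau = 1 ns sampled at dt = 0.02 ns: successive channels decay
        # by exactly exp(-0.02)
        sp = SpeciesDef("m", (1.0,), (1.0,))
        irf = delta_irf(100, 20.0, t0=0.0)
        curve = expected_curve(sp, irf, 20.0, 100, total=1e5)
        ratios = curve[1:] / curve[:-1]
        assert np.allclose(ratios, np.exp(-0.02), rtol=1e-12)

    def test_zero_total_gives_flat_background(self):
        sp = SpeciesDef("m", (1.0,), (1.0,))
        irf = delta_irf(100, 20.0)
        curve = expected_curve(sp, irf, 20.0, 100, total=0.0, background=0.5)
        assert np.allclose(curve, 0.5)

    def test_biexponential_lies_in_span_of_monoexponentials(self):
        # linearity: the normalized biexponential curve is a convex
        # combination of the two normalized single-component curves
        irf = gaussian_irf(256, 20.0, t0=300.0, fwhm=100.0)
        mix = expected_curve(
            SpeciesDef("mix", (0.3, 0.7), (0.4, 2.0)), irf, 20.0, 256, 1.0
        )
        c1 = expected_curve(SpeciesDef("a", (1.0,), (0.4,)), irf, 20.0, 256, 1.0)
        c2 = expected_curve(SpeciesDef("b", (1.0,), (2.0,)), irf, 20.0, 256, 1.0)
        basis = np.column_stack([c1, c2])
        w, residual, *_ = np.linalg.lstsq(basis, mix, rcond=None)
        assert np.allclose(basis @ w, mix, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w > 0)


class TestSimulatePixel:
    def test_zero_curve_gives_zero_histogram(self):
        assert simulate_pixel(np.zeros(32), 0).sum() == 0

    def test_seed_determinism(self):
        curve = np.linspace(0, 5, 64)
        assert np.array_equal(simulate_pixel(curve, 42), simulate_pixel(curve, 42))

    def test_rejects_negative_curve(self):
        with pytest.raises(ValueError):
            simulate_pixel(np.array([1.0, -0.1]), 0)

    def test_mean_total_matches_curve_sum(self):
        # Monte-Carlo oracle: over many draws the mean total photon count
        # approaches the sum of the expected curve
        curve = 3.0 * np.exp(-np.arange(64) / 10.0)
        rng = np.random.default_rng(1)
        totals = [simulate_pixel(curve, rng).sum() for _ in range(10_000)]
        mu = curve.sum()
        se = np.sqrt(mu / len(totals))
        assert abs(np.mean(totals) - mu) < 3 * se


class TestSimulateImage:
    def test_truth_map_equals_layout(self, panel5):
        layout = block_layout(5, shape=(10, 10), mean_counts=50.0)
        _, truth = simulate_image(panel5, layout, n_channels=64, seed=0)
        assert np.array_equal(truth, layout.label_map)

    def test_seed_determinism(self, panel4):
        layout = block_layout(4, shape=(8, 8), mean_counts=100.0)
        c1, _ = simulate_image(panel4, layout, n_channels=64, seed=9)
        c2, _ = simulate_image(panel4, layout, n_channels=64, seed=9)
        assert np.array_equal(c1.counts, c2.counts)

    def test_out_of_range_species_index_rejected(self, panel4):
        layout = SceneLayout(np.full((4, 4), 7), mean_counts=10.0)
        with pytest.raises(ValueError, match="out of range"):
            simulate_image(panel4, layout, n_channels=64, seed=0)

    def test_grand_mean_counts_matches_request(self, panel5):
        # Monte-Carlo oracle on the per-pixel total:
        # mean_counts + background * n_channels
        n_channels, bg, mean_counts = 128, 0.05, 200.0
        layout = SceneLayout(
            np.zeros((40, 40), dtype=int), mean_counts, background_rate=bg
        )
        cube, _ = simulate_image(
            panel5[:1], layout, n_channels=n_channels, seed=3
        )
        expected = mean_counts + bg * n_channels
        se = np.sqrt(expected / cube.n_pixels)
        assert abs(cube.pixel_totals().mean() - expected) < 3 * se


class TestSpeciesPanel:
    def test_five_species_span_printed_range(self, panel5):
        taus = [s.mean_lifetime_amplitude for s in panel5]
        assert len(panel5) == 5
        assert taus[0] == pytest.approx(0.20)
        assert taus[-1] == pytest.approx(1.53)

    def test_four_species_evenly_spaced_same_endpoints(self, panel4):
        taus = [s.mean_lifetime_amplitude for s in panel4]
        assert taus[0] == pytest.approx(0.20)
        assert taus[-1] == pytest.approx(1.53)
        spacing = np.diff(taus)
        assert np.allclose(spacing, (1.53 - 0.20) / 3)

    def test_amplitudes_normalized(self, panel5):
        for sp in panel5:
            assert sum(sp.amplitudes) == pytest.approx(1.0, abs=1e-9)

    def test_other_k_rejected(self):
        with pytest.raises(ValueError):
            fig2_species_panel(3)
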