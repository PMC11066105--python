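"""Autocorrelation core: padding, FFT correlation vs spatial-domain oracle,
Gaussian peak fitting, and the degree-of-aggregation identity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from _oracles import circular_acf_oracle, masked_acf_oracle
from aggscreen.ics import (
    AcfSurface,
    compute_acf,
    degree_of_aggregation,
    extract_masked_padded,
    fit_gaussian_peak,
    measure_nucleus,
)
from aggscreen.synthetic import SimulationSpec, simulate_field


def _random_mask(rng, shape):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = rng.uniform(8, shape[0] - 8), rng.uniform(8, shape[1] - 8)
    a, b = rng.uniform(5, 10, 2)
    mask[((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1] = True
    return mask


class TestPadding:
    def test_uniform_interior_pads_to_uniform_output(self):
        img = np.full((40, 40), 7.0)
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[10:30, 10:30] = 1
        padded, _, mean_i = extract_masked_padded(img, mask, 1, margin=5)
        assert mean_i == 7.0
        assert np.all(padded == 7.0)

    def test_padded_mean_equals_nuclear_mean_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            img = rng.uniform(10, 200, size=(48, 48))
            mask = _random_mask(rng, (48, 48)).astype(np.int32)
            padded, mask_crop, mean_i = extract_masked_padded(img, mask, 1, 6)
            assert mean_i == pytest.approx(img[mask == 1].mean(), rel=1e-12)
            # direct-computation oracle: only mask pixels may differ
            assert padded[~mask_crop] == pytest.approx(mean_i)
            assert padded.mean() == pytest.approx(mean_i, rel=1e-9)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            extract_masked_padded(np.ones((10, 10)), np.zeros((10, 10), int), 3)


class TestAcf:
    def test_constant_image_has_zero_correlation_everywhere(self):
        acf = compute_acf(np.full((32, 32), 5.0))
        assert np.allclose(acf.values, 0.0, atol=1e-12)

    def test_zero_mean_image_rejected(self):
        with pytest.raises(ValueError):
            compute_acf(np.zeros((16, 16)))

    def test_checkerboard_hand_computed_lags(self):
        v = 3.0
        img = np.indices((32, 32)).sum(axis=0) % 2 * 2 * v
        acf = compute_acf(img)
        r0, c0 = acf.center
        assert acf.values[r0, c0] == pytest.approx(1.0)
        assert acf.values[r0 + 1, c0] == pytest.approx(-1.0)
        assert acf.values[r0, c0 + 1] == pytest.approx(-1.0)

    def test_fft_matches_spatial_domain_oracle_on_random_images(self):
        rng = np.random.default_rng(1)
        for shape in [(16, 16), (17, 23), (32, 32), (64, 64)]:
            img = rng.uniform(1, 100, size=shape)
            ours = compute_acf(img).values
            assert np.max(np.abs(ours - circular_acf_oracle(img))) < 1e-8

    def test_mask_normalized_acf_matches_its_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(10, 100, size=(32, 32))
        mask = _random_mask(rng, (32, 32))
        ours = compute_acf(img, mask=mask).values
        ref = masked_acf_oracle(img, mask)
        both = np.isfinite(ours) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(ours), np.isfinite(ref))
        assert np.max(np.abs(ours[both] - ref[both])) < 1e-8

    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(6, 14), st.integers(6, 14)),
            elements=st.floats(1.0, 100.0),
        )
    )
    def test_symmetry_and_nonnegative_zero_lag(self, img):
        acf = compute_acf(img)
        r0, c0 = acf.center
        assert acf.values[r0, c0] >= -1e-12
        # r(xi, eta) == r(-xi, -eta); for even axes the extreme negative lag
        # has no positive counterpart and is dropped before mirroring
        sub = acf.values
        if sub.shape[0] % 2 == 0:
            sub = sub[1:, :]
        if sub.shape[1] % 2 == 0:
            sub = sub[:, 1:]
        assert np.allclose(sub, sub[::-1, ::-1], atol=1e-10)


def _surface(a=0.05, b=0.001, c=3.0, x0=0.0, y0=0.0, half=16, noise=0.0, rng=None):
    eta, xi = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    vals = a * np.exp(-(((xi - x0) ** 2 + (eta - y0) ** 2) / c**2)) + b
    if noise:
        vals = vals + rng.normal(0, noise, vals.shape)
    return AcfSurface(values=vals, center=(half, half))


class TestGaussianFit:
    def test_recovers_its_own_model_exactly(self):
        fit = fit_gaussian_peak(_surface(), fit_radius=16)
        assert fit.converged
        assert fit.a == pytest.approx(0.05, rel=1e-6)
        assert fit.b == pytest.approx(0.001, rel=1e-4)
        assert fit.c == pytest.approx(3.0, rel=1e-6)
        assert abs(fit.x0) < 1e-4 and abs(fit.y0) < 1e-4

    def test_amplitude_recovered_within_5pct_under_noise(self):
        rng = np.random.default_rng(0)
        errs = [
            abs(fit_gaussian_peak(_surface(noise=0.001, rng=rng), 16).a - 0.05)
            / 0.05
            for _ in range(100)
        ]
        assert np.mean(errs) < 0.05

    def test_flat_surface_flagged_degenerate(self):
        flat = AcfSurface(values=np.zeros((33, 33)), center=(16, 16))
        fit = fit_gaussian_peak(flat, fit_radius=16)
        da = degree_of_aggregation(100.0, fit, fit_radius=16)
        assert not da.qc_pass

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_peak(_surface(), fit_radius=2)


class TestDegreeOfAggregation:
    def test_defining_arithmetic(self):
        fit = fit_gaussian_peak(_surface(a=0.05), fit_radius=16)
        da = degree_of_aggregation(200.0, fit, fit_radius=16)
        assert da.qc_pass
        assert da.n_psf == pytest.approx(20.0, rel=1e-6)
        assert da.da == pytest.approx(10.0, rel=1e-6)

    def test_da_times_n_psf_equals_mean_intensity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(0.01, 0.5)
            mean_i = rng.uniform(10, 1000)
            fit = fit_gaussian_peak(_surface(a=a), fit_radius=16)
            da = degree_of_aggregation(mean_i, fit, fit_radius=16)
            assert da.da * da.n_psf == pytest.approx(mean_i, rel=1e-9)


@pytest.fixture(scope="module")
def clean_field():
    spec = SimulationSpec(
        seed=8, monomer_density=0.5, background_offset=0.0,
        read_noise_sigma=0.0, nucleus_radius_range=(16.0, 20.0),
        n_nuclei=8,
    )
    return spec, *simulate_field(spec)


class TestOnSimulatedNuclei:
    def test_padding_margin_changes_amplitude_below_5pct(self, clean_field):
        _, _, protein, truth = clean_field
        nt = truth.nuclei[0]
        mask = nt.render_mask(protein.shape)
        a = {m: measure_nucleus(protein, mask, 1, margin=m).fit.a for m in (0, 8)}
        assert abs(a[0] - a[8]) / a[8] < 0.05

    def test_brightness_rescaling_moves_da_not_n_psf(self, clean_field):
        spec, _, protein, truth = clean_field
        bright_spec = dataclasses.replace(spec, monomer_brightness=2 * spec.monomer_brightness)
        _, protein2, truth2 = simulate_field(bright_spec)
        ratios_n, ratios_da = [], []
        for nt, nt2 in zip(truth.nuclei, truth2.nuclei):
            m = nt.render_mask(protein.shape)
            r1 = measure_nucleus(protein, m, 1)
            r2 = measure_nucleus(protein2, m, 1)
            if r1.qc_pass and r2.qc_pass:
                ratios_n.append(r2.n_psf / r1.n_psf)
                ratios_da.append(r2.da / r1.da)
        assert np.mean(ratios_n) == pytest.approx(1.0, abs=0.02)
        assert np.mean(ratios_da) == pytest.approx(2.0, rel=0.02)
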