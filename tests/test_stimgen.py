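"""Butterworth filtering, contrast normalization and noise synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfscene.stimgen import (
    DEFAULT_FOV_DEG,
    FrequencyFilter,
    GrayImage,
    NoiseSpec,
    StimulusError,
    apply_frequency_filter,
    butterworth_gain,
    cpd_to_cpi,
    joint_contrast_normalize,
    make_triplet,
    radial_frequency_grid,
    synthesize_noise,
)

RNG = np.random.default_rng(42)


def _random_image(shape=(64, 64), fov=(4.0, 4.0)):
    return GrayImage(RNG.random(shape), fov)


class TestButterworthGain:
    @pytest.mark.parametrize(
        "kind,f,fc,order,expected",
        [
            ("lowpass", 2.0, 2.0, 1, 2**-0.5),  # half-power at cutoff
            ("lowpass", 2.0, 2.0, 5, 2**-0.5),
            ("highpass", 3.0, 3.0, 2, 2**-0.5),
            ("lowpass", 0.0, 1.0, 2, 1.0),  # DC passes a low-pass
            ("highpass", 0.0, 1.0, 2, 0.0),  # DC blocked by a high-pass
            ("lowpass", 4.0, 1.0, 2, 1.0 / np.sqrt(1.0 + 4.0**4)),
        ],
    )
    def test_closed_form(self, kind, f, fc, order, expected):
        assert butterworth_gain(f, FrequencyFilter(kind, fc, order)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_half_power_at_cutoffs(self):
        """Gain at the cutoff is exactly 1/sqrt(2) for any order."""
        for order in (1, 2, 3, 6):
            for kind in ("lowpass", "highpass"):
                g = butterworth_gain(1.7, FrequencyFilter(kind, 1.7, order))
                assert abs(g - 2**-0.5) < 1e-12

    def test_bandpass_is_edge_product(self):
        """Band-pass gain factorizes into high-pass × low-pass edge gains."""
        bp = FrequencyFilter("bandpass", (1.0, 4.0), 2)
        hp = FrequencyFilter("highpass", 1.0, 2)
        lp = FrequencyFilter("lowpass", 4.0, 2)
        f = np.linspace(0.0, 10.0, 101)
        np.testing.assert_allclose(
            butterworth_gain(f, bp),
            butterworth_gain(f, hp) * butterworth_gain(f, lp),
            atol=1e-14,
        )
        # at each edge: 1/sqrt(2) times the other edge's gain, exactly
        for edge, other in ((1.0, lp), (4.0, hp)):
            assert butterworth_gain(edge, bp) == pytest.approx(
                2**-0.5 * butterworth_gain(edge, other), abs=1e-14
            )

    @given(
        f=st.floats(0.0, 50.0),
        fc=st.floats(0.01, 20.0),
        order=st.integers(1, 6),
        kind=st.sampled_from(["lowpass", "highpass"]),
    )
    @settings(deadline=None, max_examples=200)
    def test_gain_bounded(self, f, fc, order, kind):
        g = butterworth_gain(f, FrequencyFilter(kind, fc, order))
        assert 0.0 <= g <= 1.0

    def test_invalid_parameters(self):
        with pytest.raises(StimulusError):
            FrequencyFilter("lowpass", -1.0)
        with pytest.raises(StimulusError):
            FrequencyFilter("bandpass", (4.0, 1.0))
        with pytest.raises(StimulusError):
            butterworth_gain(-1.0, FrequencyFilter("lowpass", 1.0))


class TestFrequencyGrid:
    def test_reference_values(self):
        g = radial_frequency_grid((600, 800), DEFAULT_FOV_DEG)
        assert g[0, 0] == 0.0
        assert g[0, 17] == pytest.approx(17 / 22.7, abs=1e-9)
        assert g[17, 0] == pytest.approx(17 / 17.0, abs=1e-9)

    def test_negation_symmetry(self):
        g = radial_frequency_grid((32, 48), (4.0, 3.0))
        neg_u = (-np.arange(32)) % 32
        neg_v = (-np.arange(48)) % 48
        np.testing.assert_allclose(g, g[np.ix_(neg_u, neg_v)])

    def test_rejects_degenerate_shape(self):
        with pytest.raises(StimulusError):
            radial_frequency_grid((1, 8))


class TestApplyFilter:
    def test_constant_image_loses_all_highpass_energy(self):
        img = GrayImage(np.full((32, 32), 0.5), (4.0, 4.0))
        out = apply_frequency_filter(img, FrequencyFilter("highpass", 1.0, 2))
        assert out.pixels.var() < 1e-20

    def test_sinusoid_is_eigenfunction(self):
        """A pure grating comes back scaled by the closed-form gain."""
        shape, fov = (64, 64), (4.0, 4.0)
        k = 8  # cycles per image width -> 2 cpd
        x = np.arange(shape[1])
        grating = np.cos(2 * np.pi * k * x / shape[1])[None, :] * np.ones((shape[0], 1))
        filt = FrequencyFilter("lowpass", 1.5, 2)
        out = apply_frequency_filter(GrayImage(grating, fov), filt)
        gain = butterworth_gain(k / fov[0], filt)
        np.testing.assert_allclose(out.pixels, gain * grating, atol=1e-6)

    def test_phase_preserved(self):
        img = _random_image()
        filt = FrequencyFilter("lowpass", 1.0, 2)
        before = np.fft.fft2(img.pixels)
        after = np.fft.fft2(apply_frequency_filter(img, filt).pixels)
        keep = np.abs(after) > 1e-9
        dphi = np.angle(after[keep] * np.conj(before[keep]))
        assert np.abs(dphi).max() < 1e-6

    def test_energy_never_amplified(self):
        img = _random_image()
        for filt in (
            FrequencyFilter("lowpass", 1.0, 2),
            FrequencyFilter("highpass", 2.0, 3),
            FrequencyFilter("bandpass", (0.5, 2.0), 2),
        ):
            before = np.abs(np.fft.fft2(img.pixels))
            after = np.abs(np.fft.fft2(apply_frequency_filter(img, filt).pixels))
            assert np.all(after <= before + 1e-9)

    def test_complementary_highpass_sums_to_original(self):
        """Low-pass plus the auxiliary (1 - lowpass-gain) variant restores
        the image exactly, by linearity."""
        img = _random_image()
        filt = FrequencyFilter("lowpass", 1.0, 2)
        low = apply_frequency_filter(img, filt).pixels
        grid = radial_frequency_grid(img.shape, img.fov_deg)
        spec = np.fft.fft2(img.pixels)
        complement = np.fft.ifft2(spec * (1.0 - butterworth_gain(grid, filt))).real
        np.testing.assert_allclose(low + complement, img.pixels, atol=1e-10)


class TestJointNormalization:
    def test_hand_computed_single_image(self):
        out = joint_contrast_normalize([GrayImage(np.array([[0.0, 1.0, 2.0]]), (3.0, 1.0))])
        np.testing.assert_allclose(out[0].pixels, [[0.0, 0.5, 1.0]], atol=1e-12)

    def test_equal_moments_and_pooled_range(self):
        imgs = [_random_image(), _random_image(), _random_image()]
        out = joint_contrast_normalize(imgs)
        means = [o.pixels.mean() for o in out]
        sds = [o.pixels.std() for o in out]
        assert max(means) - min(means) < 1e-6
        assert max(sds) - min(sds) < 1e-6
        pooled = np.concatenate([o.pixels.ravel() for o in out])
        assert pooled.min() == pytest.approx(0.0, abs=1e-12)
        assert pooled.max() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        out1 = joint_contrast_normalize([_random_image(), _random_image()])
        out2 = joint_contrast_normalize(out1)
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(StimulusError, match="zero variance"):
            joint_contrast_normalize([GrayImage(np.ones((4, 4)), (1.0, 1.0))])


@pytest.fixture(scope="module")
def triplet():
    """Triplet of a synthetic scene stand-in with a natural 1/f spectrum."""
    rng = np.random.default_rng(3)
    shape = (150, 200)
    grid = radial_frequency_grid(shape, DEFAULT_FOV_DEG)
    amp = np.where(grid > 0, 1.0 / np.maximum(grid, 1e-6), 0.0)
    phase = np.angle(np.fft.fft2(rng.standard_normal(shape)))
    img = np.fft.ifft2(amp * np.exp(1j * phase)).real
    img = (img - img.min()) / (img.max() - img.min())
    return make_triplet(GrayImage(img, DEFAULT_FOV_DEG))


class TestMakeTriplet:

    def test_invariants(self, triplet):
        means = [im.pixels.mean() for im in triplet]
        sds = [im.pixels.std() for im in triplet]
        assert max(means) - min(means) < 1e-6
        assert max(sds) - min(sds) < 1e-6
        pooled = np.concatenate([im.pixels.ravel() for im in triplet])
        assert pooled.min() == pytest.approx(0.0, abs=1e-12)
        assert pooled.max() == pytest.approx(1.0, abs=1e-12)

    def test_lsf_energy_concentrated_below_cutoff(self, triplet):
        grid = radial_frequency_grid(triplet.lsf.shape, triplet.lsf.fov_deg)
        spec = np.abs(np.fft.fft2(triplet.lsf.pixels - triplet.lsf.pixels.mean())) ** 2
        spec[0, 0] = 0.0
        above = spec[grid > 2 * 0.75].sum()
        assert above / spec.sum() < 0.01

    def test_hsf_dark_edge_polarity(self, triplet):
        from scipy.stats import skew

        # extremes on the dark side: non-positive skew of the HSF image
        assert skew(triplet.hsf.pixels, axis=None) <= 0

    def test_cutoff_ordering_enforced(self):
        with pytest.raises(StimulusError):
            make_triplet(_random_image(), lsf_cutoff_cpd=6.0, hsf_cutoff_cpd=0.75)


@pytest.mark.parametrize(
    "cpd,expected",
    [(0.75, 17), (1.5, 34), (3.0, 68), (6.0, 136)],
)
def test_cpd_to_cpi(cpd, expected):
    """0.75 cpd over 22.7 degrees is 17 cycles per image, 6 cpd is 136."""
    assert cpd_to_cpi(cpd, 22.7) == expected


class TestNoise:
    def test_seeded_determinism(self):
        a = synthesize_noise(NoiseSpec(3.0, seed=5), (64, 64), (4.0, 4.0))
        b = synthesize_noise(NoiseSpec(3.0, seed=5), (64, 64), (4.0, 4.0))
        c = synthesize_noise(NoiseSpec(3.0, seed=6), (64, 64), (4.0, 4.0))
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    @pytest.mark.parametrize("center", [0.75, 1.5, 3.0, 6.0])
    def test_energy_within_one_octave(self, center):
        img = synthesize_noise(NoiseSpec(center, seed=1), (300, 400), DEFAULT_FOV_DEG)
        grid = radial_frequency_grid(img.shape, img.fov_deg)
        spec = np.abs(np.fft.fft2(img.pixels)) ** 2
        spec[0, 0] = 0.0
        inband = spec[(grid >= center / 2) & (grid <= 2 * center)].sum()
        assert inband / spec.sum() >= 0.90

    def test_luminance_contrast_match(self):
        img = synthesize_noise(
            NoiseSpec(1.5, seed=2), (64, 64), (4.0, 4.0), target_mean=0.43, target_sd=0.11
        )
        assert img.pixels.mean() == pytest.approx(0.43, abs=1e-6)
        assert img.pixels.std() == pytest.approx(0.11, abs=1e-6)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(StimulusError, match="Nyquist"):
            synthesize_noise(NoiseSpec(20.0, seed=0), (64, 64), (4.0, 4.0))
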