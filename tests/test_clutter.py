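"""Clutter-filter and ASAP tests, including a brute-force
eigendecomposition oracle for the SVD filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bubbleflow import (
    FrameStack,
    InvalidConfigurationError,
    InvalidInputError,
    SceneConfig,
    SVDClutterFilter,
    asap_correlation,
    casorati,
    contrast_ratio,
    generate_ceus_scene,
    power_doppler,
    stack_from_casorati,
    svd_clutter_filter,
)


def _random_stack(rng, shape=(10, 5, 5), complex_data=False):
    data = rng.normal(size=shape)
    if complex_data:
        data = data + 1j * rng.normal(size=shape)
    return FrameStack(data, frame_rate=2.0)


class TestCasorati:
    def test_shape_and_round_trip(self, rng):
        stack = _random_stack(rng, (3, 2, 2))
        M = casorati(stack)
        assert M.shape == (4, 3)
        back = stack_from_casorati(M, stack)
        assert np.array_equal(back.data, stack.data)

    def test_constant_stack_is_rank_one(self):
        stack = FrameStack(np.full((6, 3, 3), 2.0), 1.0)
        s = np.linalg.svd(casorati(stack), compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_zero_stack(self):
        stack = FrameStack(np.zeros((4, 2, 2)), 1.0)
        assert not casorati(stack).any()

    @given(arrays(np.float64, (6, 3, 4), elements=st.floats(-10, 10)))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, data):
        stack = FrameStack(data, 1.0)
        assert np.array_equal(
            stack_from_casorati(casorati(stack), stack).data, data)


class TestSVDClutterFilter:
    def test_rank_one_clutter_removed_exactly(self):
        pattern = np.outer(np.arange(1, 5.0), np.ones(4)).reshape(4, 4)
        env = np.linspace(1.0, 1.2, 8)
        data = env[:, None, None] * pattern[None, :, :]
        out = svd_clutter_filter(FrameStack(data, 1.0), low_cutoff=1)
        assert np.sum(out.data**2) < 1e-6 * np.sum(data**2)

    def test_zero_cutoffs_identity(self, rng):
        stack = _random_stack(rng)
        out = svd_clutter_filter(stack, low_cutoff=0)
        assert np.allclose(out.data, stack.data, atol=1e-10)

    def test_energy_never_increases_and_orders_with_cutoff(self, rng):
        stack = _random_stack(rng, (12, 6, 6))
        energies = []
        for k in range(0, 6):
            out = svd_clutter_filter(stack, low_cutoff=k)
            energies.append(np.sum(np.abs(out.data) ** 2))
        assert energies[0] <= np.sum(np.abs(stack.data) ** 2) + 1e-9
        assert np.all(np.diff(energies) <= 1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        # independent route: project out the leading eigenvectors of the
        # pixel-space covariance C = M M^H
        stack = _random_stack(rng, (10, 5, 5), complex_data=True)
        M = casorati(stack)
        C = M @ M.conj().T
        w, U = np.linalg.eigh(C)
        for k in (1, 2, 3):
            lead = U[:, ::-1][:, :k]
            expected = (np.eye(25) - lead @ lead.conj().T) @ M
            got = casorati(svd_clutter_filter(stack, low_cutoff=k))
            assert np.allclose(got, expected, atol=1e-8)

    def test_high_cutoff_removes_trailing_components(self, rng):
        stack = _random_stack(rng, (8, 4, 4))
        out = svd_clutter_filter(stack, low_cutoff=0, high_cutoff=7)
        # only the leading component survives
        s = np.linalg.svd(casorati(out), compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_invalid_cutoffs_rejected(self, rng):
        stack = _random_stack(rng, (6, 3, 3))
        with pytest.raises(InvalidConfigurationError):
            svd_clutter_filter(stack, low_cutoff=6)
        with pytest.raises(InvalidConfigurationError):
            svd_clutter_filter(stack, low_cutoff=3, high_cutoff=3)

    def test_energy_mode_selects_dominant_components(self):
        rng = np.random.default_rng(0)
        data = 100.0 * np.ones((10, 4, 4)) + 0.1 * rng.normal(size=(10, 4, 4))
        filt = SVDClutterFilter(mode="energy", energy_threshold=0.95)
        out = filt.transform(FrameStack(data, 1.0))
        assert filt.low_cutoff_ >= 1
        assert np.sum(out.data**2) < 0.01 * np.sum(data**2)

    def test_transformer_accepts_plain_arrays(self, rng):
        data = rng.normal(size=(6, 3, 3))
        out = SVDClutterFilter(low_cutoff=1).transform(data)
        assert isinstance(out, np.ndarray)
        assert out.shape == data.shape

    def test_scene_power_localizes_to_vessels(self):
        from scipy.stats import pointbiserialr

        cfg = SceneConfig(seed=11)
        a, _, truth = generate_ceus_scene(cfg)
        out = svd_clutter_filter(a, low_cutoff=cfg.clutter_rank)
        power = np.mean(np.abs(out.data) ** 2, axis=0)
        r = pointbiserialr(truth["vessel_mask"].ravel(), power.ravel())
        assert r.statistic > 0.9


class TestPowerDoppler:
    def test_zero_and_constant_stacks(self):
        assert not power_doppler(FrameStack(np.zeros((3, 2, 2)), 1.0)).data.any()
        img = power_doppler(FrameStack(np.full((5, 2, 2), 3.0), 1.0))
        assert np.allclose(img.data, 9.0)

    def test_vessel_contrast_on_filtered_scene(self):
        cfg = SceneConfig(seed=4)
        a, _, truth = generate_ceus_scene(cfg)
        filtered = svd_clutter_filter(a, low_cutoff=cfg.clutter_rank)
        img = power_doppler(filtered)
        assert contrast_ratio(img, truth["vessel_mask"], db=True) > 10.0


class TestAsapCorrelation:
    def test_self_correlation_is_unity(self, rng):
        stack = _random_stack(rng, (20, 4, 4), complex_data=True)
        img = asap_correlation(stack, stack, normalized=True)
        assert np.allclose(np.abs(img.data), 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(5)
        a = _random_stack(rng, (360, 8, 8))
        b = _random_stack(rng, (360, 8, 8))
        img = asap_correlation(a, b, normalized=True)
        assert np.mean(np.abs(img.data)) < 3.0 / np.sqrt(360)

    def test_conjugate_symmetry(self, rng):
        a = _random_stack(rng, (12, 3, 3), complex_data=True)
        b = _random_stack(rng, (12, 3, 3), complex_data=True)
        ab = asap_correlation(a, b).data
        ba = asap_correlation(b, a).data
        assert np.allclose(ab, np.conj(ba), atol=1e-12)

    def test_background_level_shrinks_with_frames(self):
        # independent noise averages out as ~1/sqrt(N)
        rng = np.random.default_rng(6)
        levels = {}
        for n in (40, 160, 360):
            a = _random_stack(rng, (n, 12, 12))
            b = _random_stack(rng, (n, 12, 12))
            levels[n] = np.mean(np.abs(asap_correlation(a, b).data))
        for n1, n2 in [(40, 160), (160, 360)]:
            expected = np.sqrt(n2 / n1)
            assert levels[n1] / levels[n2] == pytest.approx(expected, rel=0.2)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            asap_correlation(_random_stack(rng, (5, 3, 3)),
                             _random_stack(rng, (5, 4, 4)))

    def test_asap_beats_power_doppler_contrast(self):
        cfg = SceneConfig(seed=21)
        a, b, truth = generate_ceus_scene(cfg)
        fa = svd_clutter_filter(a, low_cutoff=cfg.clutter_rank)
        fb = svd_clutter_filter(b, low_cutoff=cfg.clutter_rank)
        mask = truth["vessel_mask"]
        asap_c = contrast_ratio(asap_correlation(fa, fb), mask)
        pd_c = contrast_ratio(power_doppler(fa), mask)
        assert asap_c > pd_c
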