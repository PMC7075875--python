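"""Rigid transforms, coil simulation, and the multishot corruption model."""

import numpy as np
import pytest

from mrimotion.metrics import artifact_power
from mrimotion.motion import (apply_rigid_transform, cfft2, encode,
                              encode_adjoint, forward_corrupt, icfft2,
                              make_motion, simulate_coil_maps, KSpaceData)
from mrimotion.phantom import generate_phantom
from mrimotion.trajectories import make_scheme


class TestMakeMotion:
    def test_constant_increment_two_shots(self):
        """S=2 with a 5-degree maximum is one 5-degree inter-shot rotation."""
        m = make_motion("constant_increment", 2, 5.0)
        assert np.allclose(m.angles, [0.0, 5.0])
        assert m.angles[0] == 0.0

    def test_zero_amplitude_gives_zero_trajectory(self):
        for name in ("constant_increment", "random_uniform"):
            m = make_motion(name, 6, 0.0, seed=3)
            assert m.is_zero()

    def test_random_uniform_bounds_and_reference_shot(self):
        m = make_motion("random_uniform", 8, 10.0, seed=3)
        assert len(m.angles) == 8
        assert np.all(np.abs(m.angles) <= 10.0)
        assert m.angles[0] == 0.0
        assert np.all(m.translations[0] == 0.0)

    def test_negative_rotation_rejected(self):
        with pytest.raises(ValueError):
            make_motion("constant_increment", 2, -1.0)


class TestRigidTransform:
    def test_identity(self):
        img = generate_phantom(32, seed=0)
        assert np.array_equal(apply_rigid_transform(img, 0.0, 0.0, 0.0), img)

    def test_quarter_turn_is_index_permutation(self):
        """On an odd grid a 90-degree turn hits grid points exactly."""
        img = np.random.default_rng(0).random((33, 33))
        rot = apply_rigid_transform(img, 90.0)
        oracle = np.rot90(img)  # out[i, j] = in[j, N-1-i]
        assert np.allclose(rot, oracle, atol=1e-9)

    def test_integer_translation_is_shift(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = apply_rigid_transform(img, 0.0, t_x=2.0, t_y=-3.0)
        assert out[5, 10] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_inverse_composition(self):
        """Rotate/unrotate returns the smooth phantom within the
        interpolation-error budget on interior pixels."""
        img = generate_phantom(64, seed=2)
        back = apply_rigid_transform(
            apply_rigid_transform(img, 7.0), -7.0)
        interior = np.s_[8:-8, 8:-8]
        mae = np.mean(np.abs(back[interior] - img[interior]))
        assert mae <= 0.02


class TestCoilMaps:
    def test_single_coil_is_uniform(self):
        coils = simulate_coil_maps(1, 64)
        assert np.allclose(coils.maps, 1.0, atol=1e-12)

    def test_sos_normalisation(self):
        coils = simulate_coil_maps(8, 128)
        assert np.max(np.abs(coils.sos() - 1.0)) < 1e-9

    def test_maps_are_smooth(self):
        coils = simulate_coil_maps(4, 32)
        for m in coils.maps:
            gy = np.abs(np.diff(m, axis=0)).max()
            gx = np.abs(np.diff(m, axis=1)).max()
            assert max(gy, gx) < 0.5

    def test_invalid_coil_count(self):
        with pytest.raises(ValueError):
            simulate_coil_maps(0, 32)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestEncodeAdjoint:
    def test_uniform_coil_full_mask_is_dft(self):
        img = generate_phantom(32, seed=1)
        coils = simulate_coil_maps(1, 32)
        k = encode(img, coils, np.ones((32, 32), bool))
        assert np.allclose(k.samples[0], cfft2(img), atol=1e-12)

    def test_zero_image_zero_kspace(self):
        coils = simulate_coil_maps(4, 16)
        k = encode(np.zeros((16, 16)), coils, np.ones((16, 16), bool))
        assert np.all(k.samples == 0)

    def test_adjoint_identity_brute_force(self):
        """<E x, y> must equal <x, E^H y> for random vectors (N=16)."""
        rng = np.random.default_rng(0)
        coils = simulate_coil_maps(4, 16)
        mask = rng.random((16, 16)) < 0.7
        for _ in range(5):
            x = random_complex(rng, (16, 16))
            y = random_complex(rng, (4, 16, 16)) * mask
            lhs = np.vdot(encode(x, coils, mask).samples, y)
            rhs = np.vdot(x, encode_adjoint(KSpaceData(y, mask), coils))
            assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_round_trip_full_mask(self):
        img = generate_phantom(32, seed=3)
        coils = simulate_coil_maps(1, 32)
        k = encode(img, coils, np.ones((32, 32), bool))
        back = encode_adjoint(k, coils)
        assert np.allclose(back, img, atol=1e-10)

    def test_shape_mismatch(self):
        coils = simulate_coil_maps(2, 16)
        with pytest.raises(ValueError):
            encode(np.zeros((8, 8)), coils, np.ones((16, 16), bool))


class TestForwardCorrupt:
    def test_zero_motion_equals_clean_encoding(self):
        img = generate_phantom(32, seed=4)
        coils = simulate_coil_maps(4, 32)
        full = np.ones((32, 32), bool)
        clean_k = encode(img, coils, full).samples
        for name in ("cartesian_sequential", "cartesian_parallel_1d",
                     "cartesian_parallel_2d", "random"):
            scheme = make_scheme(name, 4, 32, seed=1)
            motion = make_motion("constant_increment", 4, 0.0)
            y = forward_corrupt(img, motion, scheme, coils)
            assert np.array_equal(y.samples, clean_k)

    def test_linearity_in_image(self):
        img = generate_phantom(16, seed=5)
        coils = simulate_coil_maps(2, 16)
        scheme = make_scheme("random", 2, 16, seed=0)
        motion = make_motion("constant_increment", 2, 0.0)
        y1 = forward_corrupt(img, motion, scheme, coils).samples
        y2 = forward_corrupt(3.0 * img, motion, scheme, coils).samples
        assert np.allclose(y2, 3.0 * y1, atol=1e-10)

    def test_motion_produces_measurable_artifacts(self):
        img = generate_phantom(64, seed=6)
        coils = simulate_coil_maps(4, 64)
        scheme = make_scheme("cartesian_sequential", 2, 64)
        motion = make_motion("constant_increment", 2, 5.0)
        y = forward_corrupt(img, motion, scheme, coils)
        recon = np.abs(encode_adjoint(y, coils))
        assert artifact_power(img, recon / recon.max()) > 1e-4

    def test_shot_count_mismatch_rejected(self):
        img = generate_phantom(16, seed=0)
        coils = simulate_coil_maps(2, 16)
        scheme = make_scheme("random", 4, 16, seed=0)
        motion = make_motion("constant_increment", 2, 5.0)
        with pytest.raises(ValueError):
            forward_corrupt(img, motion, scheme, coils)


def test_centered_fft_round_trip():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    assert np.allclose(icfft2(cfft2(x)), x, atol=1e-12)
    # orthonormal scaling preserves energy
    assert np.isclose(np.linalg.norm(cfft2(x)), np.linalg.norm(x))
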