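"""Forward model for rigid inter-shot motion in multishot MRI.

A multishot acquisition samples k-space in S excitations.  If the subject
moves between shots, each shot sees a differently posed object: shot s
acquires the k-space segment u_s of the rigidly transformed image M_s(x).
The corrupted measurement is the union of the per-shot segments

    y = sum_s  U_s F C M_s(x)

with C the per-coil sensitivity weighting, F the centred orthonormal 2D
DFT, and U_s the binary segment mask.  Shot 1 is the reference pose and
always carries zero motion.

The encoding operator E (coil weighting + DFT + sampling) and its exact
adjoint are exposed separately; they are the building blocks of the
CG-SENSE reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trajectories import SamplingScheme

__all__ = [
    "MotionTrajectory",
    "CoilSensitivities",
    "KSpaceData",
    "make_motion",
    "apply_rigid_transform",
    "simulate_coil_maps",
    "encode",
    "encode_adjoint",
    "forward_corrupt",
    "cfft2",
    "icfft2",
]

MOTION_SCHEDULES = ("constant_increment", "random_uniform", "custom")


@dataclass
class MotionTrajectory:
    """Per-shot rigid parameters: rotation (degrees) and translation (pixels)."""

    angles: np.ndarray           # (S,) degrees
    translations: np.ndarray     # (S, 2) pixels, (row shift, col shift)
    schedule_name: str = "custom"
    max_rotation: float = 0.0
    max_translation: float = 0.0
    seed: int | None = None

    @property
    def n_shots(self) -> int:
        return len(self.angles)

    def is_zero(self) -> bool:
        return not (np.any(self.angles) or np.any(self.translations))


@dataclass
class CoilSensitivities:
    """Complex receiver sensitivity maps, sum-of-squares normalised."""

    maps: np.ndarray  # (n_c, N, N) complex

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_size(self) -> int:
        return self.maps.shape[1]

    def sos(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass
class KSpaceData:
    """Acquired multi-coil k-space; entries outside the sampling mask are zero."""

    samples: np.ndarray       # (n_c, N, N) complex
    mask: np.ndarray          # (N, N) bool, union of sampled positions
    scheme: SamplingScheme | None = None

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def grid_size(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# Motion schedules


def make_motion(schedule_name: str, n_shots: int, max_rotation: float,
                max_translation: float = 0.0, seed: int = 0) -> MotionTrajectory:
    """Build a per-shot rigid-motion schedule.

    ``constant_increment`` ramps linearly from 0 to the maximum over the
    shots (for S=2 this is the single relative rotation between the two
    shots).  ``random_uniform`` draws each shot independently from
    U(-max, +max).  Shot 1 is always the motion-free reference pose.
    """
    if schedule_name not in MOTION_SCHEDULES:
        raise ValueError(
            f"unknown schedule {schedule_name!r}; choose from {MOTION_SCHEDULES}")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    if max_rotation < 0:
        raise ValueError(f"max_rotation must be >= 0, got {max_rotation}")
    if max_translation < 0:
        raise ValueError(f"max_translation must be >= 0, got {max_translation}")

    s = int(n_shots)
    if schedule_name == "constant_increment":
        ramp = np.linspace(0.0, 1.0, s) if s > 1 else np.zeros(1)
        angles = ramp * max_rotation
        translations = np.stack([ramp * max_translation] * 2, axis=1)
    elif schedule_name == "random_uniform":
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-max_rotation, max_rotation, size=s)
        translations = rng.uniform(-max_translation, max_translation, size=(s, 2))
        angles[0] = 0.0
        translations[0] = 0.0
    else:  # custom: zero schedule; callers fill in their own parameters
        angles = np.zeros(s)
        translations = np.zeros((s, 2))

    return MotionTrajectory(angles=angles, translations=translations,
                            schedule_name=schedule_name,
                            max_rotation=float(max_rotation),
                            max_translation=float(max_translation), seed=seed)


def apply_rigid_transform(image: np.ndarray, theta: float,
                          t_x: float = 0.0, t_y: float = 0.0) -> np.ndarray:
    """Rotate by ``theta`` degrees about the image centre, then translate.

    Bilinear interpolation, zero fill outside the frame.  ``t_x`` shifts
    along columns, ``t_y`` along rows, both in pixels.  The rotation centre
    is the geometric centre (N-1)/2, so for odd N a 90-degree rotation is an
    exact index permutation.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2D image, got shape {image.shape}")
    if theta == 0.0 and t_x == 0.0 and t_y == 0.0:
        return image.copy()
    n = image.shape[0]
    c = (n - 1) / 2.0
    th = np.deg2rad(theta)
    # Inverse map in (row, col) coordinates: out(p) = in(R^-1 (p - c - t) + c).
    r_inv = np.array([[np.cos(th), np.sin(th)],
                      [-np.sin(th), np.cos(th)]])
    centre = np.array([c, c])
    t = np.array([t_y, t_x])
    offset = centre - r_inv @ (centre + t)
    return ndimage.affine_transform(image, r_inv, offset=offset, order=1,
                                    mode="constant", cval=0.0, prefilter=False)


def simulate_coil_maps(n_coils: int, grid_size: int) -> CoilSensitivities:
    """Smooth Gaussian-profile receiver maps, sum-of-squares normalised.

    Coil centres sit on a circle just outside the field of view; each map is
    a broad Gaussian of the distance to its coil centre with a constant
    per-coil phase.  After normalisation the sum of squared magnitudes is 1
    at every pixel, so E^H E equals identity under full sampling.
    """
    if n_coils < 1:
        raise ValueError(f"n_coils must be >= 1, got {n_coils}")
    n = int(grid_size)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    radius = 0.6 * n
    sigma = 0.55 * n
    maps = np.empty((n_coils, n, n), dtype=np.complex128)
    for k in range(n_coils):
        ang = 2.0 * np.pi * k / n_coils
        cy = c + radius * np.sin(ang)
        cx = c + radius * np.cos(ang)
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
        maps[k] = g * np.exp(1j * ang)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos
    return CoilSensitivities(maps=maps)


# ---------------------------------------------------------------------------
# Encoding operator


def cfft2(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2D DFT (DC at the array centre)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def icfft2(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


def encode(image: np.ndarray, coils: CoilSensitivities,
           mask: np.ndarray) -> KSpaceData:
    """Apply the SENSE encoding operator E: coil weighting, DFT, sampling."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    n = coils.grid_size
    if image.shape != (n, n) or mask.shape != (n, n):
        raise ValueError(
            f"shape mismatch: image {image.shape}, mask {mask.shape}, coils {n}x{n}")
    k = cfft2(coils.maps * image[None])
    k *= mask[None]
    return KSpaceData(samples=k, mask=mask)


def encode_adjoint(kspace: KSpaceData, coils: CoilSensitivities) -> np.ndarray:
    """Apply E^H: zero-filled inverse DFT per coil, conjugate coil sum."""
    if kspace.samples.shape != coils.maps.shape:
        raise ValueError(
            f"shape mismatch: k-space {kspace.samples.shape}, "
            f"coils {coils.maps.shape}")
    imgs = icfft2(kspace.samples * kspace.mask[None])
    return np.sum(np.conj(coils.maps) * imgs, axis=0)


def forward_corrupt(image: np.ndarray, motion: MotionTrajectory,
                    scheme: SamplingScheme,
                    coils: CoilSensitivities) -> KSpaceData:
    """Simulate motion-corrupted multishot k-space.

    For every shot s the image is rigidly transformed by that shot's
    parameters, encoded with the coil maps, and restricted to the shot's
    segment mask; the segments are summed into the full measurement.  With
    zero motion the segments recombine into the clean encoding exactly,
    because the masks partition k-space.
    """
    if motion.n_shots != scheme.n_shots:
        raise ValueError(
            f"motion has {motion.n_shots} shots but scheme has {scheme.n_shots}")
    n = scheme.grid_size
    image = np.asarray(image)
    if image.shape != (n, n):
        raise ValueError(f"image shape {image.shape} does not match grid {n}")
    if coils.grid_size != n:
        raise ValueError(f"coil grid {coils.grid_size} does not match {n}")

    y = np.zeros((coils.n_coils, n, n), dtype=np.complex128)
    for s in range(motion.n_shots):
        th = motion.angles[s]
        ty, tx = motion.translations[s]
        if th == 0.0 and tx == 0.0 and ty == 0.0:
            moved = image
        else:
            moved = apply_rigid_transform(image, th, t_x=tx, t_y=ty)
        shot_k = cfft2(coils.maps * np.asarray(moved)[None])
        y += shot_k * scheme.masks[s][None]
    return KSpaceData(samples=y, mask=scheme.union, scheme=scheme)
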