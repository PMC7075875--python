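"""Synthetic brain-like phantom slices and slice preprocessing.

Downstream stages (motion simulation, CG-SENSE, the adversarial corrector)
operate on real-valued square magnitude images normalised to [0, 1].  This
module provides such images without any external download: randomised
composites of soft-edged ellipses inside a skull-like ring, loosely in the
spirit of the Shepp-Logan phantom but intentionally asymmetric under
rotation so that rigid-motion corruption is always observable.

Real T2-FLAIR-style volumes can optionally be read from NIfTI files and put
through the same preprocessing (centre crop to a square, resample to the
target grid, rescale to [0, 1], discard blank slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

__all__ = [
    "generate_phantom",
    "preprocess_slice",
    "load_volume",
    "split_scans",
    "DatasetSplit",
]


@dataclass
class DatasetSplit:
    """Scan-level train/validation/test partition."""

    train: list
    validation: list
    test: list
    split_seed: int = 0

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def _soft_ellipse(yy, xx, cy, cx, ry, rx, angle, softness):
    """Soft-edged ellipse indicator in [0, 1] (sigmoid-smoothed boundary)."""
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    d = (u / ry) ** 2 + (v / rx) ** 2
    z = np.clip((d - 1.0) / softness, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(z))


def generate_phantom(size: int = 128, seed: int = 0, n_ellipses: int = 8) -> np.ndarray:
    """Generate a brain-like magnitude slice of overlapping soft ellipses.

    The image always contains a bright skull-like outer ring plus an interior
    brain region with ``n_ellipses`` randomly placed soft-edged elliptical
    structures of varying intensity, so the result is piecewise smooth,
    asymmetric under rotation, and normalised to [0, 1].

    Parameters
    ----------
    size : side length N of the square image (N >= 16).
    seed : RNG seed; output is bit-identical for equal arguments.
    n_ellipses : number of interior structures (>= 1).
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    if n_ellipses < 1:
        raise ValueError(f"n_ellipses must be >= 1, got {n_ellipses}")

    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    # Skull: bright ring = difference of two soft ellipses, slightly eccentric.
    outer_ry = 0.46 * size
    outer_rx = 0.40 * size
    skull_outer = _soft_ellipse(yy, xx, c, c, outer_ry, outer_rx, 0.0, 0.05)
    skull_inner = _soft_ellipse(yy, xx, c, c, 0.92 * outer_ry, 0.91 * outer_rx, 0.0, 0.05)
    img = 0.9 * (skull_outer - skull_inner)

    # Brain background inside the skull.
    img += 0.35 * skull_inner

    # Interior soft-tissue structures; offset centres break rotational symmetry.
    for _ in range(n_ellipses):
        cy = c + rng.uniform(-0.22, 0.22) * size
        cx = c + rng.uniform(-0.20, 0.20) * size
        ry = rng.uniform(0.03, 0.14) * size
        rx = rng.uniform(0.03, 0.14) * size
        angle = rng.uniform(0.0, np.pi)
        amp = rng.uniform(-0.25, 0.45)
        img += amp * _soft_ellipse(yy, xx, cy, cx, ry, rx, angle, 0.08) * skull_inner

    # One guaranteed off-centre bright blob so even n_ellipses=1 with an
    # unlucky draw cannot produce a rotationally symmetric image.
    img += 0.3 * _soft_ellipse(yy, xx, c - 0.15 * size, c + 0.12 * size,
                               0.08 * size, 0.05 * size, 0.4, 0.08) * skull_inner

    img = np.clip(img, 0.0, None)
    img /= img.max()
    return img


def preprocess_slice(slice_: np.ndarray, target_size: int = 128):
    """Centre-crop a slice to a square, resample it, rescale to [0, 1].

    Mirrors the standard preparation of axial brain slices for a fixed-size
    reconstruction grid: crop the central square, resize (bilinear) to
    ``target_size`` x ``target_size``, and divide by the slice maximum.
    Blank slices (all-zero before normalisation) are flagged for discarding
    rather than divided by zero.

    Returns
    -------
    (image, blank) : the preprocessed image and a bool flag; when ``blank``
    is True the image is all-zero and should be discarded.
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    if slice_.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={slice_.ndim}")
    h, w = slice_.shape
    side = min(h, w)
    if side < target_size:
        raise ValueError(
            f"slice {h}x{w} smaller than target {target_size} after centre crop"
        )
    top = (h - side) // 2
    left = (w - side) // 2
    cropped = slice_[top:top + side, left:left + side]

    if cropped.max() == 0.0:
        return np.zeros((target_size, target_size)), True

    if side == target_size:
        out = cropped.copy()
    else:
        # order=1 -> bilinear; anti-aliasing for downsampling.
        out = resize(cropped, (target_size, target_size), order=1,
                     anti_aliasing=side > target_size, preserve_range=True)
    out = np.clip(out, 0.0, None)
    out /= out.max()
    return out, False


def load_volume(path) -> list[np.ndarray]:
    """Load a NIfTI volume and return its axial slices in acquisition order."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read NIfTI file: {path}")
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim != 3:
        raise IOError(f"expected a 3D volume in {path}, got ndim={vol.ndim}")
    return [vol[:, :, k] for k in range(vol.shape[2])]


def split_scans(scans: list, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> DatasetSplit:
    """Randomly partition scans into train/validation/test at the scan level.

    All slices of one scan end up in exactly one split, so no subject leaks
    across splits.  Sizes are ``round(len * f)`` for the first two fractions
    with the remainder in test; deterministic per seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 values summing to 1, got {fractions}")
    scans = list(scans)
    n = len(scans)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return DatasetSplit(
        train=[scans[i] for i in idx_train],
        validation=[scans[i] for i in idx_val],
        test=[scans[i] for i in idx_test],
        split_seed=seed,
    )
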