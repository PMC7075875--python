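"""Per-shot k-space sampling masks for multishot encoding strategies.

A multishot acquisition covers the N x N Cartesian k-space grid in S shots;
each shot s owns a binary mask u_s, and the masks partition the grid (they
are pairwise disjoint and their union is full coverage).  Four strategies
are provided:

``cartesian_sequential``
    shot s owns a contiguous block of phase-encode rows;
``cartesian_parallel_1d``
    rows interleaved: shot s owns every S-th row starting at row s;
``cartesian_parallel_2d``
    interleaving on a 2D lattice: S is factored a x b (a = b = sqrt(S) for
    perfect squares) and shot s owns the (row mod a, col mod b) coset;
``random``
    a uniformly random disjoint assignment of individual grid points.

The row index is the phase-encode direction; the column index is the
frequency-encode direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplingScheme", "make_scheme", "scheme_coverage_report", "SCHEME_NAMES"]

SCHEME_NAMES = (
    "cartesian_sequential",
    "cartesian_parallel_1d",
    "cartesian_parallel_2d",
    "random",
)


@dataclass
class SamplingScheme:
    """S disjoint binary masks covering the full N x N k-space grid."""

    masks: np.ndarray  # (S, N, N) bool
    scheme_name: str
    n_shots: int
    grid_size: int
    seed: int | None = None

    @property
    def union(self) -> np.ndarray:
        return self.masks.any(axis=0)

    def validate(self) -> None:
        counts = self.masks.sum(axis=0)
        if not np.all(counts == 1):
            raise ValueError("masks do not partition the k-space grid")


def _factor_2d(s: int) -> tuple[int, int]:
    """Factor S = a*b with a <= b and a as close to sqrt(S) as possible."""
    a = int(np.floor(np.sqrt(s)))
    while s % a:
        a -= 1
    return a, s // a


def _row_groups(n_rows: int, n_shots: int, interleaved: bool) -> list[np.ndarray]:
    if interleaved:
        return [np.arange(s, n_rows, n_shots) for s in range(n_shots)]
    # Contiguous blocks; remainder rows go to the earliest shots.
    base, extra = divmod(n_rows, n_shots)
    sizes = [base + (1 if s < extra else 0) for s in range(n_shots)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[s], edges[s + 1]) for s in range(n_shots)]


def make_scheme(scheme_name: str, n_shots: int, grid_size: int,
                seed: int = 0) -> SamplingScheme:
    """Build the per-shot sampling masks for one encoding strategy.

    Raises ``ValueError`` for unknown strategy names or when there are more
    shots than k-space points.
    """
    if scheme_name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme {scheme_name!r}; choose from {SCHEME_NAMES}")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    n, s = int(grid_size), int(n_shots)
    if s > n * n:
        raise ValueError(f"n_shots={s} exceeds the number of k-space points {n * n}")

    masks = np.zeros((s, n, n), dtype=bool)

    if scheme_name == "cartesian_sequential":
        if s > n:
            raise ValueError(f"cartesian schemes need n_shots <= grid_size ({s} > {n})")
        for sh, rows in enumerate(_row_groups(n, s, interleaved=False)):
            masks[sh, rows, :] = True
    elif scheme_name == "cartesian_parallel_1d":
        if s > n:
            raise ValueError(f"cartesian schemes need n_shots <= grid_size ({s} > {n})")
        for sh, rows in enumerate(_row_groups(n, s, interleaved=True)):
            masks[sh, rows, :] = True
    elif scheme_name == "cartesian_parallel_2d":
        a, b = _factor_2d(s)
        if a > n or b > n:
            raise ValueError(f"2D lattice {a}x{b} does not fit a {n}x{n} grid")
        rows = np.arange(n)[:, None]
        cols = np.arange(n)[None, :]
        for sh in range(s):
            i, j = divmod(sh, b)
            masks[sh] = (rows % a == i) & (cols % b == j)
    else:  # random
        rng = np.random.default_rng(seed)
        assign = np.empty(n * n, dtype=np.int64)
        # Guarantee every shot is non-empty, then assign the rest uniformly.
        perm = rng.permutation(n * n)
        assign[perm[:s]] = np.arange(s)
        assign[perm[s:]] = rng.integers(0, s, size=n * n - s)
        assign = assign.reshape(n, n)
        for sh in range(s):
            masks[sh] = assign == sh

    scheme = SamplingScheme(masks=masks, scheme_name=scheme_name, n_shots=s,
                            grid_size=n, seed=seed if scheme_name == "random" else None)
    scheme.validate()
    return scheme


def scheme_coverage_report(scheme: SamplingScheme) -> dict:
    """Per-shot sample counts; the counts always sum to N^2."""
    counts = scheme.masks.reshape(scheme.n_shots, -1).sum(axis=1)
    return {
        "scheme": scheme.scheme_name,
        "n_shots": scheme.n_shots,
        "grid_size": scheme.grid_size,
        "counts": counts.tolist(),
        "total": int(counts.sum()),
    }
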