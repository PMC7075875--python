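"""HDF5 container for paired clean / motion-corrupted datasets.

One file holds one experiment cell (a fixed motion level, shot count and
encoding trajectory):

    /clean                (n, N, N)        float64, motion-free images
    /corrupted_kspace     (n, n_c, N, N)   complex128, simulated acquisitions
    /masks                (S, N, N)        bool, per-shot segment masks
    /motion/angles        (n, S)           degrees
    /motion/translations  (n, S, 2)        pixels
    /reconstructed        (n, N, N)        added by the CG-SENSE stage
    /corrected            (n, N, N)        added by the corrector stage

File attributes record full provenance (motion level, shots, trajectory,
seeds, coil count) so every stage is independently reproducible.  Datasets
are written with ``track_times=False`` so identical runs produce
bit-identical files.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np


class MissingStageError(KeyError):
    """A pipeline stage's output group is absent from the dataset file."""


def _write(group, name, data):
    if name in group:
        del group[name]
    group.create_dataset(name, data=data, track_times=False)


def save_paired_dataset(path, clean, kspace, masks, angles, translations,
                        attrs: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "clean", np.asarray(clean))
        _write(f, "corrupted_kspace", np.asarray(kspace))
        _write(f, "masks", np.asarray(masks, dtype=bool))
        mg = f.create_group("motion", track_order=True)
        _write(mg, "angles", np.asarray(angles))
        _write(mg, "translations", np.asarray(translations))
        for k, v in sorted(attrs.items()):
            f.attrs[k] = v


def require_group(path, name: str, stage: str):
    """Check that a stage output exists, naming the missing stage otherwise."""
    with h5py.File(path, "r") as f:
        if name not in f:
            raise MissingStageError(
                f"dataset {path} has no '{name}' group; run the '{stage}' "
                f"stage first")


def load_arrays(path, names) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name in names:
            if name not in f:
                raise MissingStageError(f"dataset {path} has no '{name}' group")
            out[name] = f[name][()]
        out["attrs"] = dict(f.attrs)
    return out


def append_array(path, name: str, data, attrs: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        _write(f, name, np.asarray(data))
        for k, v in sorted((attrs or {}).items()):
            f[name].attrs[k] = v
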