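"""Experiment orchestration: simulate -> reconstruct -> train -> correct -> evaluate.

Runs the full grid of study conditions (motion levels x shot counts x
encoding trajectories) over synthetic phantoms.  Each grid cell gets its
own HDF5 dataset file and its own deterministic seed derived from the
master seed by stable hashing, so cells are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as h5io
from .cgsense import CGConfig, cg_sense_reconstruct
from .gan import GANCorrector, TrainedCorrector
from .metrics import evaluate_set
from .motion import (KSpaceData, forward_corrupt, make_motion,
                     simulate_coil_maps)
from .phantom import generate_phantom
from .trajectories import make_scheme

logger = logging.getLogger("mrimotion")

__all__ = ["ExperimentConfig", "cell_seed", "cell_name", "run_simulate",
           "run_reconstruct", "run_train", "run_correct", "run_evaluate"]


@dataclass
class ExperimentConfig:
    """Grid of study conditions plus per-stage settings."""

    motion_levels: list = field(default_factory=lambda: [5.0])
    shot_counts: list = field(default_factory=lambda: [4])
    trajectories: list = field(default_factory=lambda: ["random"])
    n_images: int = 10
    image_size: int = 64
    n_coils: int = 8
    n_ellipses: int = 8
    motion_schedule: str = "constant_increment"
    max_translation: float = 0.0
    cg_max_iterations: int = 50
    cg_tolerance: float = 1e-6
    gan: dict = field(default_factory=dict)   # GANCorrector keyword overrides
    output_dir: str = "experiments"
    master_seed: int = 0

    def __post_init__(self):
        if any(m < 0 for m in self.motion_levels):
            raise ValueError("motion levels must be non-negative")
        if any(s < 1 for s in self.shot_counts):
            raise ValueError("shot counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)


def cell_seed(master_seed: int, dtheta: float, n_shots: int, scheme: str,
              salt: str = "") -> int:
    """Stable per-cell seed below 2^31 derived from the master seed."""
    key = f"{master_seed}|{dtheta}|{n_shots}|{scheme}|{salt}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def cell_name(dtheta: float, n_shots: int, scheme: str) -> str:
    return f"dtheta{dtheta:g}_S{n_shots}_{scheme}"


def _cells(config: ExperimentConfig):
    for dtheta in config.motion_levels:
        for s in config.shot_counts:
            for scheme in config.trajectories:
                yield dtheta, s, scheme


def simulate_pairs(n_images: int, image_size: int, dtheta: float, n_shots: int,
                   scheme_name: str, n_coils: int = 8, seed: int = 0,
                   schedule: str = "constant_increment",
                   max_translation: float = 0.0, n_ellipses: int = 8):
    """Simulate paired clean images / corrupted k-space for one condition.

    Returns (clean (n,N,N), kspace (n,n_c,N,N), scheme, coils, angles,
    translations).  Each image gets its own phantom seed; under the random
    motion schedule each image also gets its own motion draw.
    """
    coils = simulate_coil_maps(n_coils, image_size)
    scheme = make_scheme(scheme_name, n_shots, image_size, seed=seed)
    clean = np.empty((n_images, image_size, image_size))
    kspace = np.empty((n_images, n_coils, image_size, image_size),
                      dtype=np.complex128)
    angles = np.empty((n_images, n_shots))
    translations = np.empty((n_images, n_shots, 2))
    rng = np.random.default_rng(seed)
    for i in range(n_images):
        clean[i] = generate_phantom(image_size, seed=int(rng.integers(2 ** 31)),
                                    n_ellipses=n_ellipses)
        motion = make_motion(schedule, n_shots, dtheta, max_translation,
                             seed=int(rng.integers(2 ** 31)))
        angles[i] = motion.angles
        translations[i] = motion.translations
        kspace[i] = forward_corrupt(clean[i], motion, scheme, coils).samples
    return clean, kspace, scheme, coils, angles, translations


def run_simulate(config: ExperimentConfig) -> list[Path]:
    """Write one paired HDF5 dataset per grid cell; returns the file paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for dtheta, s, scheme_name in _cells(config):
        seed = cell_seed(config.master_seed, dtheta, s, scheme_name)
        clean, kspace, scheme, _, angles, trans = simulate_pairs(
            config.n_images, config.image_size, dtheta, s, scheme_name,
            n_coils=config.n_coils, seed=seed,
            schedule=config.motion_schedule,
            max_translation=config.max_translation,
            n_ellipses=config.n_ellipses)
        path = outdir / f"sim_{cell_name(dtheta, s, scheme_name)}.h5"
        h5io.save_paired_dataset(
            path, clean, kspace, scheme.masks, angles, trans,
            attrs={"delta_theta": dtheta, "n_shots": s,
                   "trajectory": scheme_name, "seed": seed,
                   "master_seed": config.master_seed,
                   "n_coils": config.n_coils,
                   "image_size": config.image_size,
                   "motion_schedule": config.motion_schedule,
                   # provenance: the scientific conditions, not disk layout
                   "config_json": json.dumps(
                       {k: v for k, v in asdict(config).items()
                        if k != "output_dir"}, sort_keys=True)})
        logger.info("simulated %d pairs -> %s", config.n_images, path)
        paths.append(path)
    return paths


def run_reconstruct(path, cg_config: CGConfig | None = None) -> np.ndarray:
    """CG-SENSE reconstruct every corrupted acquisition in a dataset file."""
    h5io.require_group(path, "corrupted_kspace", stage="simulate")
    data = h5io.load_arrays(path, ["clean", "corrupted_kspace", "masks"])
    attrs = data["attrs"]
    coils = simulate_coil_maps(int(attrs["n_coils"]), int(attrs["image_size"]))
    union = data["masks"].any(axis=0)
    cfg = cg_config or CGConfig()
    recon = np.empty_like(data["clean"])
    iters, residuals = [], []
    for i, y in enumerate(data["corrupted_kspace"]):
        res = cg_sense_reconstruct(KSpaceData(samples=y, mask=union), coils, cfg)
        recon[i] = res.image
        iters.append(res.iterations_used)
        residuals.append(res.residual_history[-1])
    h5io.append_array(path, "reconstructed", recon,
                      attrs={"cg_iterations": iters,
                             "cg_final_residual": residuals,
                             "cg_tolerance": cfg.tolerance,
                             "cg_max_iterations": cfg.max_iterations})
    logger.info("reconstructed %d images in %s", len(recon), path)
    return recon


def run_train(path, checkpoint_path, **gan_kwargs) -> GANCorrector:
    """Fit the adversarial corrector on a dataset's (reconstructed, clean) pairs."""
    h5io.require_group(path, "reconstructed", stage="reconstruct")
    data = h5io.load_arrays(path, ["clean", "reconstructed"])
    est = GANCorrector(**gan_kwargs)
    est.fit(data["reconstructed"], data["clean"])
    est.model_.save(checkpoint_path)
    logger.info("trained corrector on %s -> %s", path, checkpoint_path)
    return est


def run_correct(path, checkpoint_path) -> np.ndarray:
    """Apply a trained corrector to the reconstructed images of a dataset."""
    h5io.require_group(path, "reconstructed", stage="reconstruct")
    data = h5io.load_arrays(path, ["reconstructed"])
    model = TrainedCorrector.load(checkpoint_path)
    corrected = model.correct(data["reconstructed"])
    h5io.append_array(path, "corrected", corrected,
                      attrs={"checkpoint": str(checkpoint_path)})
    logger.info("corrected %d images in %s", len(corrected), path)
    return corrected


def run_evaluate(path, out_prefix=None) -> dict:
    """Score reconstructed (and corrected, if present) images against clean.

    Returns a dict of metric tables (mean +/- sd per metric) and optionally
    writes them as CSV and JSON next to ``out_prefix``.
    """
    h5io.require_group(path, "reconstructed", stage="reconstruct")
    names = ["clean", "reconstructed"]
    import h5py

    with h5py.File(path, "r") as f:
        has_corrected = "corrected" in f
    if has_corrected:
        names.append("corrected")
    data = h5io.load_arrays(path, names)

    tables = {}
    for key in names[1:]:
        report = evaluate_set(data["clean"], data[key])
        tables[key] = report.to_dict()
        logger.info("%s vs clean: PSNR %.2f +/- %.2f dB, SSIM %.3f, AP %.2e",
                    key, *report.psnr_mean_sd, report.ssim_mean_sd[0],
                    report.ap_mean_sd[0])
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{out_prefix}.json", "w") as f:
            json.dump(tables, f, indent=2)
        import pandas as pd

        rows = []
        for key, t in tables.items():
            rows.append({"stage": key,
                         "psnr_mean": t["psnr_mean"], "psnr_sd": t["psnr_sd"],
                         "ssim_mean": t["ssim_mean"], "ssim_sd": t["ssim_sd"],
                         "ap_mean": t["ap_mean"], "ap_sd": t["ap_sd"],
                         "n_images": t["n_images"]})
        pd.DataFrame(rows).to_csv(f"{out_prefix}.csv", index=False)
    return tables
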