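"""Shared fixtures.

The heavy fixtures (smoke-scale adversarial training, the fine-tuning
transfer experiment) are session-scoped and lazy, so they are built once
and shared by every test that needs them.
"""

import numpy as np
import pytest

from mrimotion.cgsense import cg_sense_reconstruct
from mrimotion.motion import KSpaceData
from mrimotion.pipeline import simulate_pairs

# Fixed study conditions for the desk-scale smoke task: 32x32 phantoms,
# 5 degrees of inter-shot rotation, random trajectory, 8 coils.
SMOKE_SEED = 202
SMOKE_SIZE = 32
SMOKE_DTHETA = 5.0
TRAIN_SEEDS = (0, 1, 2)


def make_corrupted_task(n_images, size, dtheta, n_shots, scheme_name, seed,
                        n_train, schedule="random_uniform"):
    """Simulate pairs, CG-SENSE reconstruct, split into train/held-out."""
    clean, ksp, scheme, coils, _, _ = simulate_pairs(
        n_images, size, dtheta, n_shots, scheme_name, n_coils=8, seed=seed,
        schedule=schedule)
    recon = np.array([
        cg_sense_reconstruct(KSpaceData(k, scheme.union), coils).image
        for k in ksp])
    return {"Xtr": recon[:n_train], "ytr": clean[:n_train],
            "Xte": recon[n_train:], "yte": clean[n_train:]}


@pytest.fixture(scope="session")
def smoke_task_s4():
    """128 training + 32 held-out pairs at S=4 shots."""
    return make_corrupted_task(160, SMOKE_SIZE, SMOKE_DTHETA, 4, "random",
                               seed=SMOKE_SEED, n_train=128,
                               schedule="constant_increment")


@pytest.fixture(scope="session")
def smoke_task_s16():
    """Training pairs at S=16 shots for the transfer experiment."""
    return make_corrupted_task(144, SMOKE_SIZE, SMOKE_DTHETA, 16, "random",
                               seed=SMOKE_SEED + 1, n_train=128,
                               schedule="constant_increment")


@pytest.fixture(scope="session")
def smoke_models(smoke_task_s4):
    """Adversarially trained correctors for three seeds on the S=4 task."""
    from mrimotion.gan import GANCorrector

    models = {}
    for seed in TRAIN_SEEDS:
        est = GANCorrector(n_blocks=2, base_features=16, pretrain_steps=200,
                           max_steps=300, random_state=seed)
        est.fit(smoke_task_s4["Xtr"], smoke_task_s4["ytr"])
        models[seed] = est
    return models


@pytest.fixture(scope="session")
def transfer_results(smoke_task_s4, smoke_task_s16):
    """Fine-tuning transfer: S=16-trained warm start vs from-scratch at S=4.

    For each seed, trains the generator (data term only, Adam) from scratch
    on the S=4 task recording held-out data loss every 10 steps, then warm
    starts from a model trained on the S=16 task and fine-tunes on S=4 with
    the same budget.  Returns per-seed step counts at which the warm start
    reaches the from-scratch final validation loss.
    """
    from mrimotion.gan import TrainConfig, finetune, pretrain_generator

    s4 = (smoke_task_s4["Xtr"], smoke_task_s4["ytr"])
    s16 = (smoke_task_s16["Xtr"], smoke_task_s16["ytr"])
    val = (smoke_task_s4["Xte"], smoke_task_s4["yte"])
    total_steps = 200
    results = []
    for seed in TRAIN_SEEDS:
        cfg = TrainConfig(seed=seed, pretrain_steps=total_steps,
                          max_steps=total_steps)
        scratch = pretrain_generator(s4, cfg, validation=val)
        scratch_curve = [e["val_loss"] for e in scratch.log if "val_loss" in e]
        warm_base = pretrain_generator(s16, cfg)
        warm = finetune(warm_base, s4,
                        TrainConfig(seed=seed, max_steps=total_steps),
                        validation=val)
        warm_curve = [e["val_loss"] for e in warm.log
                      if e["phase"] == "finetune" and "val_loss" in e]
        target = scratch_curve[-1]
        steps_to_reach = total_steps
        for i, v in enumerate(warm_curve):
            if v <= target:
                steps_to_reach = (i + 1) * 10
                break
        results.append({"seed": seed, "scratch_final": target,
                        "warm_curve": warm_curve,
                        "scratch_curve": scratch_curve,
                        "steps_to_reach": steps_to_reach,
                        "total_steps": total_steps})
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
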