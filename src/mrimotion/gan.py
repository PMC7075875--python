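"""Conditional adversarial correction of motion-artifact images.

The corrector is a conditional GAN: the generator G is a U-Net that maps a
CG-SENSE reconstruction x_m bearing motion artifacts to a corrected image,
and the discriminator D (the encoder half of the same architecture plus a
scalar head) scores images as clean/generated.  Training minimises

    L_G = ||x_c - G(x_m)||_2  +  lambda * log(1 - D(G(x_m)))

(the per-image L2 data-mismatch norm plus the adversarial term, batch
averaged) against the standard discriminator objective

    L_D = -[ log D(x_c) + log(1 - D(G(x_m))) ].

Following common practice the generator's adversarial gradient uses the
non-saturating form (ascend log D(G(x_m))) while the reported loss value is
the saturating expression above; with a fresh discriminator the saturating
form has near-zero gradient and stalls training.

The schedule mirrors the reference training recipe: RMSProp at learning
rate 1e-4 for both networks, batch size 16, two discriminator updates per
generator update, adversarial weight lambda = 0.6 (the winning region of a
0.1-1.0 grid search is lambda > 0.5), and an optional Adam warm start of
the generator on the data term alone.

:class:`GANCorrector` wraps all of this as a scikit-learn style estimator:
``fit(X_corrupted, y_clean)`` / ``predict(X_corrupted)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn

__all__ = [
    "UNetConfig", "TrainConfig", "TrainedCorrector", "GANCorrector",
    "build_generator", "build_discriminator",
    "generator_loss", "discriminator_loss",
    "pretrain_generator", "train", "correct", "finetune",
    "data_loss",
]

_CLAMP = 1e-7


@dataclass
class UNetConfig:
    """Architecture of the hourglass generator (and discriminator encoder).

    Each encoder/decoder block has 5 convolutional layers with ``n`` feature
    maps except the middle layer with ``n/2``; the first encoder-layer /
    last decoder-layer of each block changes resolution with stride 2.
    """

    n_blocks: int = 4
    base_features: int = 64
    input_size: int = 128
    layers_per_block: int = 5  # fixed by the block design

    def __post_init__(self):
        if self.layers_per_block != 5:
            raise ValueError("blocks are built from exactly 5 convolution layers")
        if self.input_size % (2 ** self.n_blocks) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^{self.n_blocks}")


@dataclass
class TrainConfig:
    """Optimisation schedule for the adversarial corrector."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    adversarial_weight: float = 0.6   # lambda of the composite generator loss
    d_updates_per_g: int = 2
    pretrain: bool = True
    pretrain_steps: int = 200
    max_steps: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.d_updates_per_g < 1:
            raise ValueError("d_updates_per_g must be >= 1")


def build_generator(config: UNetConfig, rng=None) -> nn.UNetGenerator:
    """Instantiate the U-Net generator for the given architecture config."""
    rng = np.random.default_rng(rng)
    return nn.UNetGenerator(config.n_blocks, config.base_features,
                            config.input_size, rng)


def build_discriminator(config: UNetConfig, rng=None) -> nn.Discriminator:
    """Instantiate the encoder-shaped discriminator with a scalar P(real) head."""
    rng = np.random.default_rng(rng)
    return nn.Discriminator(config.n_blocks, config.base_features,
                            config.input_size, rng, clamp_eps=_CLAMP)


# ---------------------------------------------------------------------------
# Losses


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError(f"expected (B, N, N) or (B, 1, N, N) images, "
                         f"got shape {x.shape}")
    return x


def _data_term(clean: np.ndarray, generated: np.ndarray):
    """Batch-mean per-image L2 norm of the residual and its gradient."""
    diff = (generated - clean).astype(np.float64)
    b = diff.shape[0]
    norms = np.sqrt(np.sum(diff.reshape(b, -1) ** 2, axis=1))
    loss = float(norms.mean())
    safe = np.maximum(norms, 1e-12)
    grad = diff / safe[:, None, None, None] / b
    return loss, grad


def data_loss(clean, generated) -> float:
    """Batch-mean per-image L2 residual norm ||x_c - G(x_m)||_2."""
    clean = _as_batch(clean)
    generated = _as_batch(generated)
    if clean.shape != generated.shape:
        raise ValueError(f"shape mismatch: {clean.shape} vs {generated.shape}")
    return _data_term(clean, generated)[0]


def generator_loss(clean, corrupted, generator, discriminator,
                   adversarial_weight: float) -> float:
    """Composite generator objective: data mismatch + weighted adversarial term.

    ``generator`` and ``discriminator`` may be networks or plain callables;
    the value returned is the batch average of
    ``||x_c - G(x_m)||_2 + lambda * log(1 - D(G(x_m)))``.
    """
    if adversarial_weight < 0:
        raise ValueError("adversarial_weight must be >= 0")
    clean = _as_batch(clean)
    corrupted = _as_batch(corrupted)
    if clean.shape != corrupted.shape:
        raise ValueError(f"shape mismatch: {clean.shape} vs {corrupted.shape}")
    generated = np.asarray(generator(corrupted))
    generated = _as_batch(generated)
    loss = _data_term(clean, generated)[0]
    if adversarial_weight > 0:
        p = np.clip(np.asarray(discriminator(generated), dtype=np.float64),
                    _CLAMP, 1.0 - _CLAMP)
        loss += adversarial_weight * float(np.mean(np.log(1.0 - p)))
    return loss


def discriminator_loss(clean, generated, discriminator) -> float:
    """Standard GAN discriminator objective -[log D(real) + log(1 - D(fake))]."""
    clean = _as_batch(clean)
    generated = _as_batch(generated)
    p_real = np.clip(np.asarray(discriminator(clean), dtype=np.float64),
                     _CLAMP, 1.0 - _CLAMP)
    p_fake = np.clip(np.asarray(discriminator(generated), dtype=np.float64),
                     _CLAMP, 1.0 - _CLAMP)
    return float(-(np.mean(np.log(p_real)) + np.mean(np.log(1.0 - p_fake))))


# ---------------------------------------------------------------------------
# Trained model container


@dataclass
class TrainedCorrector:
    """A trained generator with its configs and training log."""

    generator: nn.UNetGenerator
    unet_config: UNetConfig
    train_config: TrainConfig
    discriminator: nn.Discriminator | None = None
    log: list = field(default_factory=list)

    def correct(self, x_m: np.ndarray) -> np.ndarray:
        return correct(self, x_m)

    def save(self, path) -> None:
        """Single-file checkpoint: parameters + configs + log (npz archive)."""
        path = Path(path)
        arrays = {f"g_{i}": a for i, a in enumerate(self.generator.state_list())}
        if self.discriminator is not None:
            arrays.update(
                {f"d_{i}": a for i, a in enumerate(self.discriminator.state_list())})
        meta = {
            "unet_config": asdict(self.unet_config),
            "train_config": asdict(self.train_config),
            "log": self.log,
            "has_discriminator": self.discriminator is not None,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedCorrector":
        path = Path(path)
        if not path.exists():
            alt = path.with_suffix(path.suffix + ".npz")
            if alt.exists():
                path = alt
            else:
                raise IOError(f"checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            ucfg = UNetConfig(**meta["unet_config"])
            tcfg = TrainConfig(**meta["train_config"])
            gen = build_generator(ucfg, rng=0)
            n_g = sum(1 for k in data.files if k.startswith("g_"))
            gen.load_state_list([data[f"g_{i}"] for i in range(n_g)])
            disc = None
            if meta["has_discriminator"]:
                disc = build_discriminator(ucfg, rng=0)
                n_d = sum(1 for k in data.files if k.startswith("d_"))
                disc.load_state_list([data[f"d_{i}"] for i in range(n_d)])
        return cls(generator=gen, unet_config=ucfg, train_config=tcfg,
                   discriminator=disc, log=meta["log"])


def _check_dataset(dataset):
    corrupted, clean = dataset
    corrupted = _as_batch(corrupted).astype(nn.F32)
    clean = _as_batch(clean).astype(nn.F32)
    if corrupted.shape != clean.shape:
        raise ValueError(
            f"paired dataset shapes differ: {corrupted.shape} vs {clean.shape}")
    if corrupted.shape[0] == 0:
        raise ValueError("paired dataset is empty")
    return corrupted, clean


def _val_loss(gen, validation):
    vx, vy = validation
    return _data_term(vy, gen.forward(vx))[0]


def _pretrain_loop(model: TrainedCorrector, corrupted, clean, steps, rng,
                   tag="pretrain", validation=None, val_every=10):
    cfg = model.train_config
    gen = model.generator
    opt = nn.Adam(gen, lr=cfg.learning_rate)
    n = corrupted.shape[0]
    for step in range(steps):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        xb, yb = corrupted[idx], clean[idx]
        out = gen.forward(xb)
        loss, grad = _data_term(yb, out)
        gen.backward(grad.astype(nn.F32))
        opt.step()
        entry = {"phase": tag, "step": len(model.log), "data_loss": loss,
                 "g_loss": loss, "d_loss": None, "adv_loss": 0.0}
        if validation is not None and (step + 1) % val_every == 0:
            entry["val_loss"] = _val_loss(gen, validation)
        model.log.append(entry)
    return model


def pretrain_generator(dataset, config: TrainConfig,
                       unet_config: UNetConfig | None = None,
                       validation=None) -> TrainedCorrector:
    """Warm-start the generator alone on the data-mismatch term with Adam."""
    corrupted, clean = _check_dataset(dataset)
    if unet_config is None:
        unet_config = UNetConfig(n_blocks=2, base_features=16,
                                 input_size=corrupted.shape[-1])
    if validation is not None:
        validation = _check_dataset(validation)
    rng = np.random.default_rng(config.seed)
    gen = build_generator(unet_config, rng=rng)
    model = TrainedCorrector(generator=gen, unet_config=unet_config,
                             train_config=config)
    steps = config.pretrain_steps if config.pretrain_steps else config.max_steps
    return _pretrain_loop(model, corrupted, clean, steps, rng,
                          validation=validation)


def _adversarial_loop(model: TrainedCorrector, corrupted, clean, steps, rng,
                      tag="gan", validation=None, val_every=10):
    cfg = model.train_config
    gen, disc = model.generator, model.discriminator
    opt_g = nn.RMSProp(gen, lr=cfg.learning_rate)
    opt_d = nn.RMSProp(disc, lr=cfg.learning_rate)
    lam = cfg.adversarial_weight
    n = corrupted.shape[0]
    bs = min(cfg.batch_size, n)

    for step in range(steps):
        # One generator forward per step: the fake batch serves both
        # discriminator updates (G's parameters do not change in between)
        # and the generator update itself, and G's layer caches stay valid
        # because the discriminator passes never touch them.
        idx = rng.integers(0, n, size=bs)
        xb, yb = corrupted[idx], clean[idx]
        out = gen.forward(xb)

        # --- discriminator updates (twice per generator update) ---
        d_loss_val = None
        for _ in range(cfg.d_updates_per_g):
            idx_r = rng.integers(0, n, size=bs)
            p_real = disc.forward(clean[idx_r])
            g_real = (-1.0 / np.maximum(p_real, _CLAMP) / bs).astype(nn.F32)
            disc.backward(g_real)
            real_grads = [(l, nm, getattr(l, "g" + nm).copy())
                          for l, nm in disc.parameters()]
            p_fake = disc.forward(out)
            g_fake = (1.0 / np.maximum(1.0 - p_fake, _CLAMP) / bs).astype(nn.F32)
            disc.backward(g_fake)
            for l, nm, g_prev in real_grads:
                setattr(l, "g" + nm, getattr(l, "g" + nm) + g_prev)
            opt_d.step()
            d_loss_val = float(
                -(np.mean(np.log(np.clip(p_real, _CLAMP, None)))
                  + np.mean(np.log(np.clip(1.0 - p_fake, _CLAMP, None)))))

        # --- generator update ---
        dloss, grad = _data_term(yb, out)
        adv_val = 0.0
        if lam > 0:
            p = disc.forward(out)
            adv_val = float(np.mean(np.log(np.clip(1.0 - p, _CLAMP, None))))
            # Non-saturating gradient: ascend log D(G(x_m)).
            g_head = (-lam / np.maximum(p, _CLAMP) / bs).astype(nn.F32)
            grad_adv = disc.backward(g_head)
            grad = grad.astype(nn.F32) + grad_adv
        gen.backward(grad.astype(nn.F32))
        opt_g.step()
        entry = {"phase": tag, "step": len(model.log), "data_loss": dloss,
                 "adv_loss": adv_val, "g_loss": dloss + lam * adv_val,
                 "d_loss": d_loss_val}
        if validation is not None and (step + 1) % val_every == 0:
            entry["val_loss"] = _val_loss(gen, validation)
        model.log.append(entry)
    return model


def train(dataset, config: TrainConfig,
          unet_config: UNetConfig | None = None) -> TrainedCorrector:
    """Full adversarial training, optionally warm-started on the data term.

    Runs ``pretrain_steps`` Adam steps on the generator alone (if
    ``config.pretrain``), then ``max_steps`` alternating updates with
    RMSProp, updating the discriminator ``d_updates_per_g`` times per
    generator step.
    """
    corrupted, clean = _check_dataset(dataset)
    if unet_config is None:
        unet_config = UNetConfig(n_blocks=2, base_features=16,
                                 input_size=corrupted.shape[-1])
    rng = np.random.default_rng(config.seed)
    gen = build_generator(unet_config, rng=rng)
    disc = build_discriminator(unet_config, rng=rng)
    model = TrainedCorrector(generator=gen, unet_config=unet_config,
                             train_config=config, discriminator=disc)
    if config.pretrain and config.pretrain_steps > 0:
        _pretrain_loop(model, corrupted, clean, config.pretrain_steps, rng)
    return _adversarial_loop(model, corrupted, clean, config.max_steps, rng)


def finetune(model: TrainedCorrector, dataset, config: TrainConfig,
             validation=None) -> TrainedCorrector:
    """Continue training an existing corrector on a new paired dataset."""
    corrupted, clean = _check_dataset(dataset)
    if corrupted.shape[-1] != model.unet_config.input_size:
        raise ValueError(
            f"dataset image size {corrupted.shape[-1]} does not match the "
            f"model input size {model.unet_config.input_size}")
    model = TrainedCorrector(generator=model.generator,
                             unet_config=model.unet_config,
                             train_config=config,
                             discriminator=model.discriminator,
                             log=list(model.log))
    rng = np.random.default_rng(config.seed)
    if config.max_steps <= 0:
        return model
    if validation is not None:
        validation = _check_dataset(validation)
    if model.discriminator is None:
        return _pretrain_loop(model, corrupted, clean, config.max_steps, rng,
                              tag="finetune", validation=validation)
    return _adversarial_loop(model, corrupted, clean, config.max_steps, rng,
                             tag="finetune", validation=validation)


def correct(model: TrainedCorrector, x_m: np.ndarray) -> np.ndarray:
    """Apply the trained generator to one image or a stack; clips to [0, 1]."""
    x = np.asarray(x_m)
    single = x.ndim == 2
    xb = _as_batch(x)
    n = model.unet_config.input_size
    if xb.shape[-2:] != (n, n):
        raise ValueError(f"input size {xb.shape[-2:]} does not match the "
                         f"trained model ({n}x{n})")
    out = np.clip(model.generator.forward(xb.astype(nn.F32)), 0.0, 1.0)
    out = out[:, 0].astype(np.float64)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


class GANCorrector(BaseEstimator):
    """Adversarial motion-artifact corrector with a scikit-learn interface.

    Parameters mirror :class:`UNetConfig` and :class:`TrainConfig`.  ``fit``
    takes corrupted reconstructions ``X`` of shape (n_samples, N, N) and the
    matching clean images ``y``; ``predict`` maps corrupted images to
    corrected ones.  ``score`` returns the mean PSNR of the corrections.
    """

    def __init__(self, n_blocks=2, base_features=16, learning_rate=1e-4,
                 batch_size=16, adversarial_weight=0.6, d_updates_per_g=2,
                 pretrain=True, pretrain_steps=200, max_steps=300,
                 random_state=0):
        self.n_blocks = n_blocks
        self.base_features = base_features
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.adversarial_weight = adversarial_weight
        self.d_updates_per_g = d_updates_per_g
        self.pretrain = pretrain
        self.pretrain_steps = pretrain_steps
        self.max_steps = max_steps
        self.random_state = random_state

    def _configs(self, input_size):
        ucfg = UNetConfig(n_blocks=self.n_blocks,
                          base_features=self.base_features,
                          input_size=input_size)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           adversarial_weight=self.adversarial_weight,
                           d_updates_per_g=self.d_updates_per_g,
                           pretrain=self.pretrain,
                           pretrain_steps=self.pretrain_steps,
                           max_steps=self.max_steps,
                           seed=self.random_state)
        return ucfg, tcfg

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError(
                f"expected matching (n, N, N) stacks, got {X.shape} / {y.shape}")
        ucfg, tcfg = self._configs(X.shape[-1])
        model = train((X, y), tcfg, unet_config=ucfg)
        self.model_ = model
        self.generator_ = model.generator
        self.discriminator_ = model.discriminator
        self.history_ = model.log
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X):
        self._check_fitted()
        return correct(self.model_, np.asarray(X, dtype=np.float64))

    def score(self, X, y):
        from .metrics import psnr

        self._check_fitted()
        pred = self.predict(X)
        y = np.asarray(y, dtype=np.float64)
        return float(np.mean([psnr(r, p) for r, p in zip(y, pred)]))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("GANCorrector is not fitted yet; call fit first")
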