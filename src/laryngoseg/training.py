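"""Alternating generator/critic training with weight clipping.

One optimization cycle processes a batch with ``disc_frequency`` critic
substeps followed by ``gen_frequency`` generator substeps (defaults 1:1).
The critic substep updates only the encoder-side parameters — validity
(real→1, noise-mixed→0), label-smoothed auxiliary classification with a
dedicated dummy class for lesion-free frames, latent consistency under
random affine distortion, and an adversarial real-vs-synthesized term — and
clamps them to [−c, c] afterward.  The generator substep updates only the
decoder-side parameters with the blended MSE/SSIM reconstruction loss plus
the adversarial term; it is never clipped.

Validation MSE on the held-out split is the checkpoint metric: ``last.ckpt``
is always overwritten, and the three best epochs are kept separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .losses import (
    LossWeights,
    clip_weights,
    cross_entropy,
    latent_consistency_loss,
    reconstruction_loss,
    validity_loss,
)
from .model import ModelConfig, SegModel, save_checkpoint
from .nn import Tensor, make_optimizer, no_grad
from .color_codec import classify_image
from .synthetic_data import (
    DatasetManifest,
    SceneConfig,
    apply_random_affine,
    mix_gaussian_noise,
)

__all__ = ["TrainConfig", "CheckpointPolicy", "History", "Trainer", "fit", "toy_configs"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 10
    lr_gen: float = 5e-5
    lr_disc: float = 5e-5
    optimizer: str = "rmsprop"
    gen_frequency: int = 1
    disc_frequency: int = 1
    seed: int = 0
    noise_sigma: float = 255.0
    affine_rotation: float = 15.0
    affine_translate: float = 0.10
    affine_shear: float = 5.0
    wasserstein_adversarial: bool = False  # ablation: raw critic scores, no sigmoid
    checkpoint_dir: str = "checkpoints"
    log_dir: str = "logs"
    loss: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.gen_frequency < 1 or self.disc_frequency < 1:
            raise ValueError("frequencies must be >= 1")


@dataclass
class CheckpointPolicy:
    """Keep ``last.ckpt`` (always overwritten) plus the k best by metric."""

    directory: Path
    keep_best_k: int = 3
    best: list[tuple[float, Path]] = field(default_factory=list)

    def update(self, model: SegModel, epoch: int, metric: float) -> None:
        self.directory.mkdir(parents=True, exist_ok=True)
        save_checkpoint(self.directory / "last.ckpt", model, epoch=epoch, metric=metric)
        path = self.directory / f"best-epoch{epoch:03d}-mse{metric:.6f}.ckpt"
        self.best.append((metric, path))
        self.best.sort(key=lambda item: item[0])
        if len(self.best) <= self.keep_best_k or path in {p for _, p in self.best[: self.keep_best_k]}:
            save_checkpoint(path, model, epoch=epoch, metric=metric)
        for _, stale in self.best[self.keep_best_k :]:
            stale.unlink(missing_ok=True)
        self.best = self.best[: self.keep_best_k]


@dataclass
class History:
    """One record per epoch plus per-step loss events."""

    epochs: list[dict] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)


def _load_split(manifest: DatasetManifest, split: str) -> dict[str, np.ndarray]:
    rows = manifest.rows(split)
    images, masks, aux_targets = [], [], []
    num_classes = 7
    for _, row in rows.iterrows():
        img = np.asarray(Image.open(manifest.root / row["image_path"]).convert("RGB"))
        msk = np.asarray(Image.open(manifest.root / row["mask_path"]).convert("RGB"))
        images.append(img)
        masks.append(msk)
        labels = classify_image(msk)
        counts = np.bincount(labels[labels >= 0].ravel(), minlength=num_classes)
        # dominant lesion class, or the dedicated dummy class for clean frames
        aux_targets.append(int(np.argmax(counts)) if counts.sum() > 0 else num_classes)
    return {
        "images": np.stack(images),
        "masks": np.stack(masks),
        "aux_targets": np.asarray(aux_targets, dtype=np.int64),
    }


def _to_nchw(batch_u8: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(batch_u8.transpose(0, 3, 1, 2)).astype(np.float32) / 255.0


class Trainer:
    def __init__(self, model: SegModel, cfg: TrainConfig):
        self.model = model
        self.cfg = cfg
        self.opt_gen = make_optimizer(cfg.optimizer, model.generator_parameters(), cfg.lr_gen)
        self.opt_disc = make_optimizer(cfg.optimizer, model.discriminator_parameters(), cfg.lr_disc)
        self.rng = np.random.default_rng(cfg.seed)
        self._last_synth: np.ndarray | None = None

    # -- single optimization steps ----------------------------------------
    def discriminator_step(self, batch: dict[str, np.ndarray], epoch: int = 0) -> dict[str, float]:
        """One critic update (validity + auxiliary + consistency + adversarial)."""
        if len(batch["images"]) == 0:
            raise ValueError("empty batch")
        cfg, w = self.cfg, self.cfg.loss
        images = batch["images"]
        x = Tensor(_to_nchw(images))
        latent, _, validity, aux_logits, adv = self.model.encode(x)

        real_target = 1.0 - w.smoothing_eps
        fake_target = w.smoothing_eps
        loss_valid_real = validity_loss(validity, real_target)
        loss_aux = cross_entropy(aux_logits, batch["aux_targets"], eps=w.smoothing_eps)

        noisy = np.stack(
            [mix_gaussian_noise(img, cfg.noise_sigma, self.rng) for img in images]
        )
        _, _, validity_noise, _, _ = self.model.encode(Tensor(_to_nchw(noisy)))
        loss_valid_noise = validity_loss(validity_noise, fake_target)

        distorted = np.stack(
            [
                apply_random_affine(
                    img, cfg.affine_rotation, cfg.affine_translate, cfg.affine_shear, self.rng
                )
                for img in images
            ]
        )
        latent_dist, _, _, _, _ = self.model.encode(Tensor(_to_nchw(distorted)))
        loss_consistency = latent_consistency_loss(latent, latent_dist)

        # real vs synthesized: the generator output is a constant here; the
        # synthesis cached by the previous generator substep is reused when
        # its shape matches, saving one decoder pass per critic step
        synth = self._last_synth
        if synth is None or synth.shape != x.shape:
            with no_grad():
                synth = self.model.generate(x).data
        _, _, _, _, adv_fake = self.model.encode(Tensor(synth))
        if cfg.wasserstein_adversarial:
            loss_adv = adv_fake.mean() - adv.mean()
        else:
            loss_adv = validity_loss(adv, real_target) + validity_loss(adv_fake, fake_target)

        total = (
            w.validity_weight * (loss_valid_real + loss_valid_noise)
            + w.auxiliary_weight * loss_aux
            + w.consistency_weight * loss_consistency
            + w.adversarial_weight * loss_adv
        )
        self.model.zero_grad()
        total.backward()
        self.opt_disc.step()
        clip_weights(self.model.discriminator_parameters(), w.clip_value)
        self.model.zero_grad()
        return {
            "disc_total": total.item(),
            "validity_real": loss_valid_real.item(),
            "validity_noise": loss_valid_noise.item(),
            "auxiliary": loss_aux.item(),
            "consistency": loss_consistency.item(),
            "disc_adversarial": loss_adv.item(),
        }

    def generator_step(
        self,
        batch: dict[str, np.ndarray],
        epoch: int = 0,
        pred_override: np.ndarray | None = None,
    ) -> dict[str, float]:
        """One generator update (reconstruction + adversarial; no clipping).

        ``pred_override`` replaces the predicted segmentation in the loss —
        a test hook for verifying the loss plumbing.
        """
        if len(batch["images"]) == 0:
            raise ValueError("empty batch")
        cfg, w = self.cfg, self.cfg.loss
        x = Tensor(_to_nchw(batch["images"]))
        gt = Tensor(_to_nchw(batch["masks"]))
        seg = self.model.generate(x) if pred_override is None else Tensor(pred_override)
        self._last_synth = seg.data.copy()

        diff = seg - gt
        mse = (diff * diff).mean()
        recon = reconstruction_loss(seg, gt, epoch, w)

        # fool the critic: the synthesized image should score as real
        _, _, _, _, adv_fake = self.model.encode(seg)
        if cfg.wasserstein_adversarial:
            loss_adv = -adv_fake.mean()
        else:
            loss_adv = validity_loss(adv_fake, 1.0 - w.smoothing_eps)

        total = recon + w.adversarial_weight * loss_adv
        self.model.zero_grad()
        total.backward()
        self.opt_gen.step()
        self.model.zero_grad()
        alpha = w.mse_ssim_blend(epoch)
        ssim_part = 0.0 if alpha >= 1.0 else (1.0 - (recon.item() - alpha * mse.item()) / (1.0 - alpha))
        return {
            "gen_total": total.item(),
            "reconstruction": recon.item(),
            "mse": mse.item(),
            "ssim": ssim_part,
            "gen_adversarial": loss_adv.item(),
        }

    # -- evaluation helpers ------------------------------------------------
    def validation_metrics(self, data: dict[str, np.ndarray]) -> dict[str, float]:
        cfg = self.cfg
        n = len(data["images"])
        mse_sum = 0.0
        validity_clean: list[float] = []
        validity_noise: list[float] = []
        for start in range(0, n, cfg.batch_size):
            imgs = data["images"][start : start + cfg.batch_size]
            msks = data["masks"][start : start + cfg.batch_size]
            x = Tensor(_to_nchw(imgs))
            with no_grad():
                out = self.model.forward(x)
                seg = out.seg_image.data
                validity_clean.extend(_sigmoid(out.validity_logit.data[:, 0]))
                noisy = np.stack(
                    [mix_gaussian_noise(img, cfg.noise_sigma, self.rng) for img in imgs]
                )
                _, _, v_noise, _, _ = self.model.encode(Tensor(_to_nchw(noisy)))
                validity_noise.extend(_sigmoid(v_noise.data[:, 0]))
            mse_sum += float(np.sum((seg - _to_nchw(msks)) ** 2)) / seg[0].size
        return {
            "mse_loss": mse_sum / n,
            "validity": float(np.mean(validity_clean)),
            "validity_std": float(np.std(validity_clean)),
            "validity_noise": float(np.mean(validity_noise)),
        }

    def _sample_grid(self, data: dict[str, np.ndarray], path: Path, max_rows: int = 4) -> None:
        """Per-epoch progress sheet: [ground truth | segmentation | overlay | input]."""
        rows = []
        take = min(max_rows, len(data["images"]))
        imgs = data["images"][:take]
        msks = data["masks"][:take]
        with no_grad():
            seg = self.model.forward(Tensor(_to_nchw(imgs))).seg_image.data
        seg_u8 = np.clip(seg * 255.0, 0, 255).astype(np.uint8).transpose(0, 2, 3, 1)
        for img, msk, pred in zip(imgs, msks, seg_u8):
            overlay = np.clip(0.5 * img + 0.5 * pred, 0, 255).astype(np.uint8)
            rows.append(np.concatenate([msk, pred, overlay, img], axis=1))
        Image.fromarray(np.concatenate(rows, axis=0)).save(path)

    # -- the main loop ------------------------------------------------------
    def fit(self, manifest: DatasetManifest) -> History:
        cfg = self.cfg
        train = _load_split(manifest, "train")
        val = _load_split(manifest, "test")
        if len(train["images"]) == 0 or len(val["images"]) == 0:
            raise ValueError("manifest must contain non-empty train and test splits")

        ckpt_dir = Path(cfg.checkpoint_dir)
        log_dir = Path(cfg.log_dir)
        log_dir.mkdir(parents=True, exist_ok=True)
        policy = CheckpointPolicy(ckpt_dir)
        history = History()
        events = open(log_dir / "events.jsonl", "w")

        n_train = len(train["images"])
        try:
            for epoch in range(cfg.epochs):
                order = np.random.default_rng([cfg.seed, 1000 + epoch]).permutation(n_train)
                n_disc = n_gen = 0
                for start in range(0, n_train, cfg.batch_size):
                    idx = order[start : start + cfg.batch_size]
                    batch = {key: arr[idx] for key, arr in train.items()}
                    for _ in range(cfg.disc_frequency):
                        record = self.discriminator_step(batch, epoch)
                        record.update(epoch=epoch, phase="disc")
                        history.steps.append(record)
                        events.write(json.dumps(record) + "\n")
                        n_disc += 1
                    for _ in range(cfg.gen_frequency):
                        record = self.generator_step(batch, epoch)
                        record.update(epoch=epoch, phase="gen")
                        history.steps.append(record)
                        events.write(json.dumps(record) + "\n")
                        n_gen += 1
                metrics = self.validation_metrics(val)
                metrics.update(epoch=epoch, disc_steps=n_disc, gen_steps=n_gen)
                history.epochs.append(metrics)
                events.write(json.dumps(metrics) + "\n")
                events.flush()
                policy.update(self.model, epoch, metrics["mse_loss"])
                self._sample_grid(val, log_dir / f"epoch{epoch:03d}.png")
        except Exception:
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(ckpt_dir / "last.ckpt", self.model, epoch=-1, metric=math.nan)
            raise
        finally:
            events.close()
        pd.DataFrame(history.epochs).to_csv(log_dir / "epochs.csv", index=False)
        return history


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def fit(model: SegModel, cfg: TrainConfig, manifest: DatasetManifest) -> History:
    """Convenience wrapper: train ``model`` on a generated dataset manifest."""
    return Trainer(model, cfg).fit(manifest)


def toy_configs(seed: int = 0, out_root: str | Path = "runs/toy") -> tuple[SceneConfig, ModelConfig, TrainConfig]:
    """The desk-scale study conditions: 200 synthetic 96×96 scenes (160/40),
    a slim network, 15 epochs on one CPU.

    Used by the worked example, the test suite, and the acceptance script so
    they all describe the same experiment.
    """
    out_root = Path(out_root)
    scene = SceneConfig(image_size=(96, 96), seed=seed)
    model_cfg = ModelConfig(
        encoder_channels=(8, 12, 16, 24, 32),
        d6_channels=48,
        d7_channels=32,
        residual_units_per_skip=1,
    )
    train_cfg = TrainConfig(
        epochs=15,
        batch_size=10,
        lr_gen=1e-3,
        lr_disc=5e-4,
        optimizer="rmsprop",
        gen_frequency=2,
        seed=seed,
        checkpoint_dir=str(out_root / "checkpoints"),
        log_dir=str(out_root / "logs"),
        loss=LossWeights(total_epochs=15, clip_value=0.05, alpha_floor=0.85),
    )
    return scene, model_cfg, train_cfg
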