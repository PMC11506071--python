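"""The modified U-Net: a segmentation generator that is its own critic.

The network is a five-level U-Net whose encoder doubles as the adversarial
discriminator.  Each encoder stage is a strided convolution followed by a
residual unit and halves the spatial dimensions (five stages → /32).  The
bottleneck branches three ways:

* into the decoder (five attention-gated upsampling stages, each doubling
  the spatial dimensions, with every skip connection routed through a
  configurable number of residual units F(x) + x);
* through two channel-only 1×1 convolutions (d6, d7) into the encoder
  output unit, where global average pooling produces two one-dimensional
  vectors: the latent vector l7 (default 32-dim) and the auxiliary vector
  l8;
* from those vectors, purely affine heads (no activation inside the heads;
  sigmoid/softmax is applied only in the losses): a validity scalar — a
  learned dimension reduction of l7 —, auxiliary class logits with more
  nodes than there are classes (spare nodes absorb the dummy/unknown
  categories), and a single adversarial logit from l8.

The segmentation output is bounded to [0,1] by a sigmoid so it can be
compared to color-coded masks with MSE and SSIM.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (Conv2d, InstanceNorm, Linear, Module, ResidualUnit, Tensor, concat,
                 no_grad, upsample2x)

__all__ = ["ModelConfig", "ModelOutputs", "SegModel", "build", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    latent_dim: int = 32
    latent_aux_dim: int = 32
    num_lesion_classes: int = 7
    aux_output_nodes: int = 9  # 7 lesion classes + dummy + spare
    residual_units_per_skip: int = 2
    encoder_channels: tuple[int, ...] = (64, 64, 128, 256, 512)
    d6_channels: int = 256
    d7_channels: int = 128

    def __post_init__(self) -> None:
        if self.aux_output_nodes <= self.num_lesion_classes:
            raise ValueError("aux_output_nodes must exceed num_lesion_classes")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be at least 2")
        if len(self.encoder_channels) != 5:
            raise ValueError("encoder_channels must have exactly 5 entries")


@dataclass
class ModelOutputs:
    """All network outputs for one batch (autograd tensors)."""

    seg_image: Tensor  # (N, 3, H, W) in [0, 1]
    latent: Tensor  # (N, latent_dim)       — l7
    latent_aux: Tensor  # (N, latent_aux_dim)   — l8
    validity_logit: Tensor  # (N, 1)
    aux_logits: Tensor  # (N, aux_output_nodes)
    adv_logit: Tensor  # (N, 1)


class _EncoderStage(Module):
    """Strided conv + norm + residual unit; halves H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.down = Conv2d(in_ch, out_ch, 3, stride=2, rng=rng)
        self.norm = InstanceNorm(out_ch)
        self.res = ResidualUnit(out_ch, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.res(self.norm(self.down(x)).relu())


class _AttentionGate(Module):
    """Additive attention on a skip feature, gated by the decoder feature.

    The psi bias starts positive so gates begin nearly open and training
    can close them selectively.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        inter = max(channels // 2, 4)
        self.w_gate = Conv2d(channels, inter, 1, rng=rng)
        self.w_skip = Conv2d(channels, inter, 1, rng=rng)
        self.psi = Conv2d(inter, 1, 1, rng=rng)
        self.psi.bias.data[:] = 2.0

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        att = self.psi((self.w_gate(gate) + self.w_skip(skip)).relu()).sigmoid()
        return skip * att


class _SkipBlock(Module):
    """residual_units_per_skip chained residual units on a skip connection."""

    def __init__(self, channels: int, n_units: int, rng: np.random.Generator):
        self.units = [ResidualUnit(channels, rng=rng) for _ in range(n_units)]

    def __call__(self, x: Tensor) -> Tensor:
        for unit in self.units:
            x = unit(x)
        return x


class _DecoderStage(Module):
    """Upsample ×2, refine, attend to the skip, fuse; doubles H and W."""

    def __init__(self, in_ch: int, out_ch: int, skip_ch: int | None, n_skip_units: int,
                 rng: np.random.Generator):
        self.conv_up = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.norm_up = InstanceNorm(out_ch)
        if skip_ch is not None:
            self.attention = _AttentionGate(out_ch, rng=rng)
            self.skip_block = _SkipBlock(skip_ch, n_skip_units, rng=rng)
            self.fuse = Conv2d(out_ch + skip_ch, out_ch, 3, rng=rng)
            self.norm_fuse = InstanceNorm(out_ch)
        else:
            self.attention = None
            self.skip_block = None
            self.fuse = None

    def __call__(self, x: Tensor, skip: Tensor | None) -> Tensor:
        up = self.norm_up(self.conv_up(upsample2x(x))).relu()
        if skip is None or self.attention is None:
            return up
        gated = self.attention(self.skip_block(skip), up)
        return self.norm_fuse(self.fuse(concat([up, gated], axis=1))).relu()


class SegModel(Module):
    """Generator + inner discriminator in one module."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        chans = cfg.encoder_channels

        # ---- encoder / discriminator side --------------------------------
        self.enc_stages = [
            _EncoderStage(3 if i == 0 else chans[i - 1], chans[i], rng) for i in range(5)
        ]
        self.d6 = Conv2d(chans[4], cfg.d6_channels, 1, rng=rng)
        self.d7 = Conv2d(cfg.d6_channels, cfg.d7_channels, 1, rng=rng)
        self.proj_latent = Linear(cfg.d6_channels, cfg.latent_dim, rng=rng)
        self.proj_latent_aux = Linear(cfg.d7_channels, cfg.latent_aux_dim, rng=rng)
        self.head_validity = Linear(cfg.latent_dim, 1, rng=rng)
        self.head_aux = Linear(cfg.latent_dim, cfg.aux_output_nodes, rng=rng)
        self.head_adv = Linear(cfg.latent_aux_dim, 1, rng=rng)

        # ---- decoder / generator side ------------------------------------
        # the fifth upsampling stage pairs with the full-resolution input
        # level: a stem convolution provides its skip features, mirroring the
        # original U-Net's pre-pooling feature path (generator-owned, so it
        # is never weight-clipped)
        self.stem = Conv2d(3, chans[0], 3, rng=rng)
        dec_in = [chans[4], chans[3], chans[2], chans[1], chans[0]]
        dec_out = [chans[3], chans[2], chans[1], chans[0], chans[0]]
        skips = [chans[3], chans[2], chans[1], chans[0], chans[0]]
        self.dec_stages = [
            _DecoderStage(dec_in[i], dec_out[i], skips[i], cfg.residual_units_per_skip, rng)
            for i in range(5)
        ]
        self.out_conv = Conv2d(chans[0], 3, 3, rng=rng)
        # masks are mostly black: start the sigmoid output dark so early
        # training refines lesions instead of first crushing the background
        self.out_conv.bias.data[:] = -2.0

    # ---- parameter groups ------------------------------------------------
    _DISC_ATTRS = ("enc_stages", "d6", "d7", "proj_latent", "proj_latent_aux",
                   "head_validity", "head_aux", "head_adv")
    _GEN_ATTRS = ("stem", "dec_stages", "out_conv")

    def _group(self, attrs: tuple[str, ...]) -> list[tuple[str, Tensor]]:
        found: list[tuple[str, Tensor]] = []
        for name in attrs:
            value = getattr(self, name)
            if isinstance(value, Module):
                found.extend(value.named_parameters(prefix=f"{name}."))
            else:
                for i, item in enumerate(value):
                    found.extend(item.named_parameters(prefix=f"{name}.{i}."))
        return found

    def discriminator_parameters(self) -> list[Tensor]:
        """Encoder stages, d6/d7, and all heads — the clipped critic set."""
        return [t for _, t in self._group(self._DISC_ATTRS)]

    def generator_parameters(self) -> list[Tensor]:
        """Decoder stages (incl. skip residual units, attention) + output conv."""
        return [t for _, t in self._group(self._GEN_ATTRS)]

    # ---- forward paths ---------------------------------------------------
    @staticmethod
    def _check_dims(x: Tensor) -> None:
        _, _, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {h}×{w}")

    def _encode_features(self, x: Tensor) -> tuple[list[Tensor], Tensor, Tensor]:
        feats = []
        cur = x
        for stage in self.enc_stages:
            cur = stage(cur)
            feats.append(cur)
        e6 = self.d6(feats[-1])
        e7 = self.d7(e6)
        return feats, e6, e7

    def _heads(self, e6: Tensor, e7: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
        pooled6 = e6.mean(axis=(2, 3))
        pooled7 = e7.mean(axis=(2, 3))
        latent = self.proj_latent(pooled6)
        latent_aux = self.proj_latent_aux(pooled7)
        return (
            latent,
            latent_aux,
            self.head_validity(latent),
            self.head_aux(latent),
            self.head_adv(latent_aux),
        )

    def forward(self, x: Tensor) -> ModelOutputs:
        """Full pass: segmentation plus all encoder outputs.

        ``x`` is NCHW float32 in [0, 1].
        """
        self._check_dims(x)
        feats, e6, e7 = self._encode_features(x)
        latent, latent_aux, validity, aux, adv = self._heads(e6, e7)
        seg = self._decode(x, feats)
        return ModelOutputs(seg, latent, latent_aux, validity, aux, adv)

    def _decode(self, x: Tensor, feats: list[Tensor]) -> Tensor:
        cur = feats[4]
        skips = [feats[3], feats[2], feats[1], feats[0], self.stem(x).relu()]
        for stage, skip in zip(self.dec_stages, skips):
            cur = stage(cur, skip)
        return self.out_conv(cur).sigmoid()

    def generate(self, x: Tensor, detach_encoder: bool = True) -> Tensor:
        """Decoder-only training path: segmentation with encoder features
        treated as constants, so backward touches generator parameters only."""
        self._check_dims(x)
        if detach_encoder:
            with no_grad():
                feats, _, _ = self._encode_features(x)
            feats = [Tensor(f.data) for f in feats]
        else:
            feats, _, _ = self._encode_features(x)
        return self._decode(x, feats)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
        """Encoder-only pass: (latent, latent_aux, validity, aux, adv)."""
        self._check_dims(x)
        _, e6, e7 = self._encode_features(x)
        return self._heads(e6, e7)

    def encoder_feature_map(self, x: Tensor) -> Tensor:
        """Bottleneck feature map (pre-pooling d7 output) for Gram analysis."""
        self._check_dims(x)
        _, _, e7 = self._encode_features(x)
        return e7

    def reduce_latent(self, latent: Tensor | np.ndarray) -> Tensor:
        """Affine dimension reduction of a latent vector to one raw logit."""
        t = latent if isinstance(latent, Tensor) else Tensor(np.atleast_2d(latent))
        if t.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent length {t.shape[-1]} != configured {self.config.latent_dim}"
            )
        return self.head_validity(t)

    def predict(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Inference on a uint8 (N,H,W,3) batch; returns numpy outputs."""
        x = Tensor(np.ascontiguousarray(images.transpose(0, 3, 1, 2)) / 255.0)
        with no_grad():
            out = self.forward(x)
        return {
            "seg_image": out.seg_image.data.transpose(0, 2, 3, 1),
            "latent": out.latent.data,
            "latent_aux": out.latent_aux.data,
            "validity_logit": out.validity_logit.data[:, 0],
            "aux_logits": out.aux_logits.data,
            "adv_logit": out.adv_logit.data[:, 0],
        }


def build(config: ModelConfig | None = None, seed: int = 0) -> SegModel:
    return SegModel(config, seed=seed)


def save_checkpoint(path: str | Path, model: SegModel, epoch: int = 0,
                    metric: float | None = None) -> None:
    state = model.state_dict()
    meta = json.dumps({"config": asdict(model.config), "epoch": epoch, "metric": metric})
    with open(path, "wb") as f:  # file handle keeps the exact name (e.g. last.ckpt)
        np.savez(f, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[SegModel, dict]:
    with np.load(Path(path), allow_pickle=False) as blob:
        meta = json.loads(bytes(blob["__meta__"].tobytes()).decode())
        state = {k: blob[k] for k in blob.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
    model = SegModel(ModelConfig(**cfg))
    model.load_state_dict(state)
    return model, meta
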