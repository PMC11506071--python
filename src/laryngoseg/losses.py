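"""Training objectives for the adversarial segmentation scheme.

The generator learns the color-coded ground-truth mask with a blended
MSE + (1−SSIM) reconstruction loss whose blend weight α drifts from pure
MSE toward structural similarity as training progresses.  The
encoder/critic learns three things at once: a validity scalar pushed toward
1.0 for informative inputs and 0.0 for Gaussian-noise inputs (binary
cross-entropy with logits, so the raw head stays affine), label-smoothed
auxiliary classification (with a dedicated dummy class for lesion-free
frames), and latent consistency between an image and its affine-distorted
copy.  Stability comes from WGAN-style weight clipping of the critic
parameters; the generator is never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, box_filter

__all__ = [
    "LossWeights",
    "ssim",
    "reconstruction_loss",
    "smooth_labels",
    "cross_entropy",
    "validity_loss",
    "latent_consistency_loss",
    "clip_weights",
]


@dataclass(frozen=True)
class LossWeights:
    """Loss-term weights and schedules.

    ``mse_ssim_blend(epoch)`` gives α for reconstruction = α·MSE +
    (1−α)·(1−SSIM): linear from 1.0 at epoch 0 down to ``alpha_floor`` at
    ``total_epochs − 1``, i.e. structure matters more the longer training
    runs.  ``clip_value`` is the WGAN clipping constant c.
    """

    smoothing_eps: float = 0.1
    clip_value: float = 0.01
    alpha_floor: float = 0.5
    total_epochs: int = 15
    adversarial_weight: float = 0.1
    auxiliary_weight: float = 1.0
    consistency_weight: float = 1.0
    validity_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.clip_value <= 0:
            raise ValueError("clip_value must be positive")
        if not (0.0 <= self.smoothing_eps < 1.0):
            raise ValueError("smoothing_eps must be in [0, 1)")

    def mse_ssim_blend(self, epoch: int) -> float:
        if epoch < 0:
            raise ValueError("epoch must be non-negative")
        span = max(self.total_epochs - 1, 1)
        frac = min(epoch / span, 1.0)
        return 1.0 - (1.0 - self.alpha_floor) * frac


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def ssim(a, b, window: int = 7, k1: float = 0.01, k2: float = 0.03,
         data_range: float = 1.0) -> Tensor:
    """Mean windowed structural similarity; differentiable.

    Uses a uniform ``window``×``window`` mean filter with zero padding over
    the trailing two spatial axes of NCHW inputs.  Returns a scalar tensor
    (``.item()`` for the float); identical inputs give exactly 1.
    """
    ta, tb = _as_tensor(a), _as_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a = box_filter(ta, window)
    mu_b = box_filter(tb, window)
    var_a = box_filter(ta * ta, window) - mu_a * mu_a
    var_b = box_filter(tb * tb, window) - mu_b * mu_b
    cov = box_filter(ta * tb, window) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return (num / den).mean()


def reconstruction_loss(pred_seg, gt_mask, epoch: int, weights: LossWeights | None = None) -> Tensor:
    """α(epoch)·MSE + (1−α(epoch))·(1−SSIM) on [0,1]-range images."""
    weights = weights or LossWeights()
    alpha = weights.mse_ssim_blend(epoch)  # raises on epoch < 0
    pred, gt = _as_tensor(pred_seg), _as_tensor(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    diff = pred - gt
    mse = (diff * diff).mean()
    if alpha >= 1.0:
        return mse
    return alpha * mse + (1.0 - alpha) * (1.0 - ssim(pred, gt))


def smooth_labels(one_hot: np.ndarray, eps: float) -> np.ndarray:
    """(1−eps)·one_hot + eps/K per component; rows sum to 1."""
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must be in [0, 1)")
    arr = np.asarray(one_hot, dtype=np.float64)
    k = arr.shape[-1]
    return (1.0 - eps) * arr + eps / k


def cross_entropy(logits: Tensor, class_ids: np.ndarray, eps: float = 0.0) -> Tensor:
    """Mean cross-entropy of logits against label-smoothed one-hot targets."""
    n, k = logits.shape
    one_hot = np.eye(k)[np.asarray(class_ids, dtype=np.int64)]
    targets = smooth_labels(one_hot, eps).astype(np.float32)
    zmax = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    lse = (logits - zmax).exp().sum(axis=1, keepdims=True).log() + zmax
    log_probs = logits - lse
    return -(Tensor(targets) * log_probs).sum() * (1.0 / n)


def validity_loss(validity_logit, target) -> Tensor:
    """Numerically stable binary cross-entropy with logits.

    ``loss = softplus(z) − z·t`` averaged over the batch; target may be a
    scalar (possibly smoothed) or an array matching the logit shape.
    """
    z = _as_tensor(validity_logit)
    if not np.all(np.isfinite(z.data)):
        raise ValueError("validity logit must be finite")
    t = np.broadcast_to(np.asarray(target, dtype=np.float32), z.shape)
    return (z.softplus() - z * Tensor(t.copy())).mean()


def latent_consistency_loss(z_original, z_distorted) -> Tensor:
    """Mean squared difference between two latent vectors (symmetric)."""
    a, b = _as_tensor(z_original), _as_tensor(z_distorted)
    if a.shape != b.shape:
        raise ValueError(f"latent length mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    return (diff * diff).mean()


def clip_weights(params, c: float) -> None:
    """Clamp every parameter in ``params`` to [−c, c] in place (idempotent)."""
    if c <= 0:
        raise ValueError("clip value c must be positive")
    for p in params:
        np.clip(p.data, -c, c, out=p.data)
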