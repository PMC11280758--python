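"""Gradient-weighted class-activation mapping for the segmentation network.

The map answers "which regions drive the coating prediction": the coating
class score (sum of coating logits) is backpropagated to the activations of
the last convolutional block, the per-channel gradients are global-average-
pooled into channel weights, and the weighted activation sum is rectified,
upsampled to the input size and min-max normalized into [0, 1].
"""

from __future__ import annotations

import numpy as np

from .backbone import ConfigurationError
from .model import CoatSegNet
from .nn import autodiff as ad
from .nn.autodiff import Tensor

CAM_LAYERS = ("last_conv",)


def gradcam(
    net: CoatSegNet, image: np.ndarray, layer: str = "last_conv"
) -> np.ndarray:
    """Heat map in [0, 1] with the input's spatial size.

    ``image`` is a normalized (3, H, W) array (see ``normalize_image``).
    """
    if layer not in CAM_LAYERS:
        raise ConfigurationError(
            f"unknown CAM layer {layer!r}; available: {CAM_LAYERS}"
        )
    was_training = net.training
    net.eval()
    try:
        logits = net.forward_tensor(Tensor(image[None].astype(np.float32)))
        act = net._cam_activation
        act.retain_grad = True
        score = logits[:, 1].sum()  # total evidence for the coating class
        score.backward()
    finally:
        net.train(was_training)
    grads = act.grad[0]          # (C, h, w)
    acts = act.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    h, w = image.shape[1:]
    cam_t = ad.upsample_bilinear(Tensor(cam[None, None]), h, w).data[0, 0]
    lo, hi = cam_t.min(), cam_t.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam_t)
    return ((cam_t - lo) / (hi - lo)).astype(np.float64)


def heat_overlay(image: np.ndarray, heat: np.ndarray,
                 alpha: float = 0.5) -> np.ndarray:
    """Blend a blue->red heat colormap over an RGB uint8 image."""
    if image.shape[:2] != heat.shape:
        raise ValueError("image and heat map sizes differ")
    r = np.clip(1.5 * heat - 0.25, 0, 1)
    g = np.clip(1.0 - np.abs(2.0 * heat - 1.0), 0, 1)
    b = np.clip(1.25 - 1.5 * heat, 0, 1)
    cmap = (np.stack([r, g, b], axis=-1) * 255).astype(np.float64)
    out = (1 - alpha) * image.astype(np.float64) + alpha * cmap
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
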