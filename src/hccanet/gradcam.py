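"""Gradient-weighted class-activation maps and heatmap overlays.

For a chosen convolutional feature map A ∈ R^{h×w×c} and target class k,
the channel weights are the spatial means of ∂(pre-softmax logit k)/∂A;
the map is the rectified weighted channel sum, bilinearly upsampled to
the input size and min-max normalised to [0, 1].  The pre-softmax logit
is used as the score because softmax gradients saturate; this also makes
the map invariant to adding a constant to all logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from ._engine import Tensor
from .model import HCCANet
from .preprocessing import resize_image

__all__ = ["GradCAMMap", "gradcam", "overlay"]


@dataclass
class GradCAMMap:
    heatmap: np.ndarray        # (H, W) in [0, 1], input resolution
    target_class: int
    target_layer: str
    all_zero: bool = False     # set when gradients vanish identically


def gradcam(model: HCCANet, image: np.ndarray, target_class: int,
            target_layer: str | None = None) -> GradCAMMap:
    """Class-activation heatmap for one (H, W, 3) image.

    ``target_layer`` must name a convolutional feature map of the model
    (a backbone conv, "mccbam", or "fused"); the default is the fused
    map, the network's final convolutional representation.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {image.shape}")
    if target_layer is None:
        target_layer = "fused"
    if target_layer not in model.cam_layers:
        raise ValueError(
            f"{target_layer!r} is not a convolutional feature map; "
            f"choose one of {model.cam_layers}"
        )
    record: dict[str, Tensor] = {}
    x = Tensor(image[None])
    x.requires_grad = True  # keep the graph alive through frozen layers
    logits = model.forward(x, record=record)
    k = int(target_class)
    if not (0 <= k < logits.shape[1]):
        raise ValueError(f"class index {k} out of range for {logits.shape[1]} classes")
    seed = np.zeros(logits.shape)
    seed[0, k] = 1.0
    logits.backward(seed)

    act = record[target_layer]
    grads = act.grad
    a = act.data[0]
    if grads is None or not np.any(grads):
        h, w = image.shape[:2]
        return GradCAMMap(heatmap=np.zeros((h, w)), target_class=k,
                          target_layer=target_layer, all_zero=True)
    weights = grads[0].mean(axis=(0, 1))                 # (c,)
    cam = np.maximum((a * weights).sum(axis=2), 0.0)      # rectified weighted sum
    cam = resize_image(cam, image.shape[:2])
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
        all_zero = False
    else:
        cam = np.zeros_like(cam)
        all_zero = True
    return GradCAMMap(heatmap=cam, target_class=k, target_layer=target_layer,
                      all_zero=all_zero)


def overlay(cam: GradCAMMap, img: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Blend a blue-to-red rendering of the heatmap onto the image.

    Blue marks unimportant regions, red the critical ones.  alpha = 0
    returns the image unchanged; alpha = 1 the pure colormap render.
    """
    img = np.asarray(img)
    if img.shape[:2] != cam.heatmap.shape:
        raise ValueError(
            f"heatmap {cam.heatmap.shape} does not match image {img.shape[:2]}"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return img.copy()
    # 'bwr' runs blue -> white -> red with redness monotone in the heat
    # value, so the heat peak is always the reddest rendered pixel
    colored = colormaps["bwr"](cam.heatmap)[..., :3] * 255.0
    blended = (1.0 - alpha) * img.astype(np.float64) + alpha * colored
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
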