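"""HCCANet architecture.

A VGG16-topology convolutional backbone (optionally width-shrunk for
desk-scale runs) feeds its final feature map both to an identity path and
to a parallel MCCBAM attention branch; the two are fused by channel
concatenation (C + 3C = 4C) and classified by global average pooling
followed by a single affine layer and softmax over the three
differentiation grades.

Fine-tuning mimics transfer-learning practice: layers before a named
freeze boundary (default the third convolutional block, ``Block_Conv3``)
are non-trainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _engine as eg
from ._engine import Tensor
from .attention import MCCBAMConfig, MCCBAMLayer

__all__ = [
    "VGG16_STAGES",
    "BackboneConfig",
    "HCCANetConfig",
    "VGG16Backbone",
    "HCCANet",
    "build_backbone",
    "build_hccanet",
    "save_checkpoint",
    "load_checkpoint",
]

# (channels, number of convs) per stage; a 2x2 max-pool follows each stage
VGG16_STAGES: tuple[tuple[int, int], ...] = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

# canonical alias of the fine-tuning boundary: train from the third
# convolutional block onward, freeze everything before it
_FREEZE_ALIAS = {"block_conv3": "block3_conv1"}


@dataclass(frozen=True)
class BackboneConfig:
    """VGG16 convolutional stack configuration.

    width_multiplier scales every stage's channel count (min 1 channel),
    allowing the full topology to run at desk scale on CPU.
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    freeze_until: str = "Block_Conv3"
    pretrained: bool = False
    weights_path: str | None = None
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")

    def stage_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_multiplier)) for c, _ in VGG16_STAGES)


@dataclass(frozen=True)
class HCCANetConfig:
    backbone: BackboneConfig = BackboneConfig()
    attention: MCCBAMConfig = MCCBAMConfig()
    use_attention: bool = True   # False drops the MCCBAM branch (ablation)
    n_classes: int = 3
    seed: int = 0


class VGG16Backbone(eg.Module):
    """The thirteen-conv VGG16 stack with named layers and a freeze boundary."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.stage_widths()
        names: list[str] = []
        for bi, (_, n_convs) in enumerate(VGG16_STAGES, start=1):
            names.extend(f"block{bi}_conv{ci}" for ci in range(1, n_convs + 1))
        boundary = self._resolve_freeze(cfg.freeze_until, names)

        self.layers: list[tuple[str, eg.Module]] = []
        cin = cfg.input_size[2]
        frozen = True
        for bi, (_, n_convs) in enumerate(VGG16_STAGES, start=1):
            cout = widths[bi - 1]
            for ci in range(1, n_convs + 1):
                name = f"block{bi}_conv{ci}"
                if name == boundary:
                    frozen = False
                self.layers.append(
                    (name, eg.Conv2D(cin, cout, 3, rng, trainable=not frozen, name=name))
                )
                cin = cout
            self.layers.append((f"block{bi}_pool", eg.MaxPool2(name=f"block{bi}_pool")))
        self.out_channels = cin
        if cfg.pretrained:
            self._load_pretrained(cfg.weights_path)

    @staticmethod
    def _resolve_freeze(freeze_until: str, names: list[str]) -> str:
        key = freeze_until.lower()
        key = _FREEZE_ALIAS.get(key, key)
        if key not in names:
            raise ValueError(
                f"unknown freeze layer {freeze_until!r}; known layers: {names}"
            )
        return key

    def _load_pretrained(self, path: str | None) -> None:
        if path is None:
            raise ValueError("pretrained=True requires weights_path")
        with np.load(path) as npz:
            arrays = [npz[k] for k in sorted(npz.files)]
        self.load_state_arrays(arrays)

    @property
    def conv_layer_names(self) -> list[str]:
        return [n for n, l in self.layers if isinstance(l, eg.Conv2D)]

    def __call__(self, x: Tensor | np.ndarray, record: dict | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        for name, layer in self.layers:
            if isinstance(layer, eg.Conv2D):
                x = eg.relu(layer(x))
            else:
                x = layer(x)
            if record is not None:
                record[name] = x
        return x

    def output_spatial(self) -> tuple[int, int]:
        h, w = self.cfg.input_size[:2]
        for _ in VGG16_STAGES:
            h, w = h // 2, w // 2
        return h, w


class HCCANet(eg.Module):
    """Backbone + parallel MCCBAM + concat fusion + GAP/affine/softmax head."""

    def __init__(self, cfg: HCCANetConfig):
        self.cfg = cfg
        self.backbone = VGG16Backbone(cfg.backbone)
        rng = np.random.default_rng(cfg.seed + 1)
        c = self.backbone.out_channels
        self.attention = MCCBAMLayer(c, cfg.attention, rng=rng) if cfg.use_attention else None
        self.fused_channels = c + (self.attention.out_channels if self.attention else 0)
        self.head = eg.Dense(self.fused_channels, cfg.n_classes, rng, name="head")

    # -- forward passes --------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, record: dict | None = None) -> Tensor:
        """Logits for a batch (N, H, W, 3). ``record`` collects named activations."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        fm = self.backbone(t, record=record)
        if self.attention is not None:
            att = self.attention(fm)
            fused = eg.concat([fm, att], axis=3)
        else:
            fused = fm
        if record is not None:
            if self.attention is not None:
                record["mccbam"] = att
            record["fused"] = fused
        pooled = eg.mean_axes(fused, (1, 2))
        return self.head(pooled)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size])
            out.append(eg.softmax(logits.data))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    # -- interpretation hooks -------------------------------------------
    @property
    def cam_layers(self) -> list[str]:
        """Names of feature maps eligible as Grad-CAM targets."""
        extra = ["mccbam", "fused"] if self.attention is not None else ["fused"]
        return self.backbone.conv_layer_names + extra

    # -- introspection ---------------------------------------------------
    def summary(self) -> list[dict]:
        rows = []
        for name, layer in self.backbone.layers:
            if isinstance(layer, eg.Conv2D):
                rows.append({
                    "name": name,
                    "kind": "conv3x3",
                    "shape": list(layer.w.data.shape),
                    "trainable": layer.trainable,
                    "params": int(layer.w.data.size + (layer.b.data.size if layer.b is not None else 0)),
                })
            else:
                rows.append({"name": name, "kind": "maxpool2", "shape": [], "trainable": False, "params": 0})
        if self.attention is not None:
            rows.append({
                "name": "mccbam",
                "kind": "attention",
                "shape": [self.backbone.out_channels, self.attention.out_channels],
                "trainable": True,
                "params": int(sum(p.data.size for p in self.attention.parameters())),
            })
        rows.append({
            "name": "head",
            "kind": "gap+affine+softmax",
            "shape": [self.fused_channels, self.cfg.n_classes],
            "trainable": True,
            "params": int(sum(p.data.size for p in self.head.parameters())),
        })
        return rows

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def build_backbone(cfg: BackboneConfig) -> VGG16Backbone:
    return VGG16Backbone(cfg)


def build_hccanet(cfg: HCCANetConfig) -> HCCANet:
    return HCCANet(cfg)


def save_checkpoint(model: HCCANet, path: str) -> None:
    arrays = model.state_arrays()
    np.savez(path, **{f"p{i:04d}": a for i, a in enumerate(arrays)})


def load_checkpoint(model: HCCANet, path: str) -> HCCANet:
    with np.load(path) as npz:
        arrays = [npz[k] for k in sorted(npz.files)]
    model.load_state_arrays(arrays)
    return model
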