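"""Image preprocessing for model training.

Three stages, applied in order: (1) denoising with one of four filter
families — mean, median, gaussian, bilateral — swept over kernel sizes
3/5/7 to pick the best filter; (2) bilinear resize to the backbone's
224×224 input; (3) per-feature standardization (zero mean, unit variance)
fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_bilateral

__all__ = [
    "FilterSpec",
    "StandardizerState",
    "ImageStandardizer",
    "gaussian_kernel",
    "denoise",
    "resize_image",
    "fit_standardizer",
    "apply_standardizer",
    "save_standardizer",
    "load_standardizer",
]

FILTER_FAMILIES = ("mean", "median", "gaussian", "bilateral")
KERNEL_SWEEP = (3, 5, 7)


@dataclass(frozen=True)
class FilterSpec:
    """One denoising configuration.

    gaussian_sigma defaults to the kernel-to-sigma convention
    0.3*((k-1)/2 - 1) + 0.8 when not given.  Bilateral sigmas are on the
    0–255 intensity scale (color) and in pixels (space).
    """

    family: str = "gaussian"
    kernel: int = 5
    gaussian_sigma: float | None = None
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0

    def __post_init__(self):
        if self.family not in FILTER_FAMILIES:
            raise ValueError(f"unknown filter family {self.family!r}; one of {FILTER_FAMILIES}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        for s in (self.gaussian_sigma, self.bilateral_sigma_color, self.bilateral_sigma_space):
            if s is not None and s <= 0:
                raise ValueError("sigmas must be positive")

    @property
    def sigma(self) -> float:
        if self.gaussian_sigma is not None:
            return self.gaussian_sigma
        return 0.3 * ((self.kernel - 1) / 2 - 1) + 0.8


def gaussian_kernel(k: int, sigma: float) -> np.ndarray:
    """Discrete k×k gaussian kernel, normalised to sum exactly to 1."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {k}")
    ax = np.arange(k) - (k - 1) / 2
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k2 = np.outer(g, g)
    return k2 / k2.sum()


def _as_float(img: np.ndarray) -> tuple[np.ndarray, np.dtype]:
    img = np.asarray(img)
    return img.astype(np.float64), img.dtype


def _restore(out: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(dtype)
    return out.astype(dtype)


def denoise(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Denoise an H×W or H×W×C image; per channel, edge-replicated borders."""
    arr, dtype = _as_float(img)
    if arr.size == 0:
        raise ValueError("empty image")
    chan_last = arr.ndim == 3
    size = (spec.kernel, spec.kernel, 1) if chan_last else (spec.kernel, spec.kernel)
    if spec.family == "mean":
        out = ndimage.uniform_filter(arr, size=size, mode="nearest")
    elif spec.family == "median":
        out = ndimage.median_filter(arr, size=size, mode="nearest")
    elif spec.family == "gaussian":
        k2 = gaussian_kernel(spec.kernel, spec.sigma)
        if chan_last:
            out = np.stack(
                [ndimage.correlate(arr[..., c], k2, mode="nearest") for c in range(arr.shape[2])],
                axis=-1,
            )
        else:
            out = ndimage.correlate(arr, k2, mode="nearest")
    else:  # bilateral
        scale = 255.0 if np.issubdtype(dtype, np.integer) or arr.max() > 1.0 else 1.0
        out = denoise_bilateral(
            arr / scale,
            win_size=spec.kernel,
            sigma_color=spec.bilateral_sigma_color / 255.0,
            sigma_spatial=spec.bilateral_sigma_space,
            channel_axis=-1 if chan_last else None,
        ) * scale
    return _restore(out, dtype)


def resize_image(img: np.ndarray, target: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear resize (half-pixel-center sampling, edge-clamped)."""
    arr, dtype = _as_float(img)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError(f"expected H x W or H x W x C image, got shape {arr.shape}")
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target size must be positive")
    h, w = arr.shape[:2]
    r = (np.arange(th) + 0.5) * h / th - 0.5
    c = (np.arange(tw) + 0.5) * w / tw - 0.5
    r0f, c0f = np.floor(r), np.floor(c)
    tr, tc = r - r0f, c - c0f
    r0 = np.clip(r0f, 0, h - 1).astype(int)
    r1 = np.clip(r0f + 1, 0, h - 1).astype(int)
    c0 = np.clip(c0f, 0, w - 1).astype(int)
    c1 = np.clip(c0f + 1, 0, w - 1).astype(int)
    if arr.ndim == 3:
        tr = tr[:, None, None]
        tc = tc[None, :, None]
    else:
        tr = tr[:, None]
        tc = tc[None, :]
    top = (1 - tc) * arr[np.ix_(r0, c0)] + tc * arr[np.ix_(r0, c1)]
    bot = (1 - tc) * arr[np.ix_(r1, c0)] + tc * arr[np.ix_(r1, c1)]
    out = (1 - tr) * top + tr * bot
    return _restore(out, dtype)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizerState:
    """Per-feature scale state fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance_mask: np.ndarray
    shape: tuple[int, ...] = field(default_factory=tuple)


def _flatten_set(images) -> tuple[np.ndarray, tuple[int, ...]]:
    arrs = [np.asarray(im, dtype=np.float64) for im in images]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("all images must share one shape for standardization")
    return np.stack([a.ravel() for a in arrs]), shape


def fit_standardizer(train_images) -> StandardizerState:
    """Fit per-feature mean/std over a list of same-shape images."""
    train_images = list(train_images)
    if len(train_images) < 2:
        raise ValueError("standardizer needs at least 2 images to fit")
    x, shape = _flatten_set(train_images)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    mask = std <= 1e-12
    return StandardizerState(mean=mean, std=std, zero_variance_mask=mask, shape=shape)


def apply_standardizer(state: StandardizerState, img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.shape != state.shape:
        raise ValueError(f"image shape {arr.shape} != fitted shape {state.shape}")
    flat = arr.ravel()
    safe = np.where(state.zero_variance_mask, 1.0, state.std)
    out = (flat - state.mean) / safe
    out[state.zero_variance_mask] = 0.0
    return out.reshape(state.shape)


def save_standardizer(state: StandardizerState, path: str) -> None:
    """Arrays to <path>.npz, metadata to <path>.json."""
    np.savez(path + ".npz", mean=state.mean, std=state.std,
             mask=state.zero_variance_mask)
    with open(path + ".json", "w") as f:
        json.dump({"shape": list(state.shape),
                   "n_features": int(state.mean.size),
                   "n_zero_variance": int(state.zero_variance_mask.sum())}, f)


def load_standardizer(path: str) -> StandardizerState:
    with np.load(path + ".npz") as npz:
        mean, std, mask = npz["mean"], npz["std"], npz["mask"]
    with open(path + ".json") as f:
        meta = json.load(f)
    return StandardizerState(mean=mean, std=std, zero_variance_mask=mask,
                             shape=tuple(meta["shape"]))


class ImageStandardizer:
    """sklearn-style transformer over image stacks (N, H, W, C).

    Fit on the training split only; validation/test are transformed with
    the training statistics.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "ImageStandardizer":
        return self

    def fit(self, X, y=None) -> "ImageStandardizer":
        X = np.asarray(X, dtype=np.float64)
        self.state_ = fit_standardizer(list(X))
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.stack([apply_standardizer(self.state_, im) for im in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
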