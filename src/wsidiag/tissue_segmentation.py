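"""Valid-tissue segmentation on 8x-downsampled scan images.

Classifying every patch of a gigapixel scan is wasteful because most
of the slide is empty background.  A binary tissue mask computed on
the scan downsampled by a factor of 8 restricts classification to
patches that actually overlap tissue.

Two methods are provided.  The default is Otsu thresholding on the
grayscale image (H&E tissue is darker than the white scan
background), followed by a 3x3 morphological closing.  The
alternative is a small fully convolutional network predicting a
per-pixel tissue probability; it is implemented in plain numpy with
the stated defaults (10 convolutional layers of 64 3x3 filters,
trained on 21x21 patches for 600 epochs with Adam at learning rate
1e-4 and weight decay 1e-4) and trains at desk scale with a reduced,
logged configuration.

A patch is considered valid tissue when at least half of its
footprint (in mask pixels) is tissue; the 50% coupling is
configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle

from .patch_labeling import PatchGrid

logger = logging.getLogger(__name__)

DOWNSAMPLE_FACTOR = 8


@dataclass
class TissueMask:
    """Binary tissue mask at 1/8 of the 40x-level resolution."""

    scan_id: str
    mask: np.ndarray
    method: str  # "otsu" or "fcn"
    downsample_factor: int = DOWNSAMPLE_FACTOR

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.method not in ("otsu", "fcn"):
            raise ValueError(f"unknown mask method {self.method!r}")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def downsample_scan(image: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Block-average downsampling; output dims are ``ceil(in / factor)``.

    Edges of non-divisible images are padded by replication so border
    blocks average real pixels only.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    pad_h = (-h) % factor
    pad_w = (-w) % factor
    pad = ((0, pad_h), (0, pad_w)) + ((0, 0),) * (img.ndim - 2)
    padded = np.pad(img.astype(float), pad, mode="edge")
    oh, ow = padded.shape[0] // factor, padded.shape[1] // factor
    tail = padded.shape[2:]
    out = padded.reshape((oh, factor, ow, factor) + tail).mean(axis=(1, 3))
    if np.issubdtype(img.dtype, np.integer):
        out = np.round(out).astype(img.dtype)
    return out


def otsu_tissue_mask(image: np.ndarray, scan_id: str = "") -> TissueMask:
    """Otsu threshold on grayscale; tissue is the darker side.

    A zero-variance (blank) image yields an all-background mask with a
    warning.  Pinholes are filled by a 3x3 morphological closing.
    """
    gray = rgb2gray(np.asarray(image, dtype=np.uint8))
    if np.ptp(gray) == 0:
        warnings.warn("blank image: returning all-background tissue mask")
        return TissueMask(scan_id, np.zeros(gray.shape, bool), "otsu")
    thresh = threshold_otsu(gray)
    tissue = gray < thresh
    tissue = closing(tissue, footprint_rectangle((3, 3)))
    return TissueMask(scan_id, tissue, "otsu")


# ---------------------------------------------------------------------------
# Fully convolutional tissue segmenter (numpy)


@dataclass
class FCNConfig:
    n_layers: int = 10
    n_filters: int = 64
    kernel_size: int = 3
    epochs: int = 600
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def log_overrides(self) -> None:
        defaults = FCNConfig()
        for f in fields(self):
            if f.name == "seed":
                continue
            if getattr(self, f.name) != getattr(defaults, f.name):
                logger.info(
                    "FCN config override: %s=%r (default %r)",
                    f.name,
                    getattr(self, f.name),
                    getattr(defaults, f.name),
                )


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' zero-padded 2D convolution. x: (N,H,W,Ci), w: (k,k,Ci,Co)."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,Ci,k,k)
    return np.einsum("nhwcij,ijco->nhwo", win, w, optimize=True) + b


def _conv2d_backward(
    x: np.ndarray, w: np.ndarray, dz: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    dw = np.einsum("nhwcij,nhwo->ijco", win, dz, optimize=True)
    db = dz.sum(axis=(0, 1, 2))
    dzp = np.pad(dz, ((0, 0), (p, p), (p, p), (0, 0)))
    win_dz = sliding_window_view(dzp, (k, k), axis=(1, 2))  # (N,H,W,Co,k,k)
    w_rot = w[::-1, ::-1]
    dx = np.einsum("nhwoij,ijco->nhwc", win_dz, w_rot, optimize=True)
    return dx, dw, db


@dataclass
class FCNModel:
    """Stack of 'same' 3x3 convolutions with ReLU, sigmoid pixel output."""

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    config: FCNConfig
    history: List[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, config: FCNConfig) -> "FCNModel":
        rng = np.random.default_rng(config.seed)
        dims = [3] + [config.n_filters] * (config.n_layers - 1) + [1]
        weights, biases = [], []
        k = config.kernel_size
        for cin, cout in zip(dims[:-1], dims[1:]):
            std = np.sqrt(2.0 / (k * k * cin))
            weights.append(rng.normal(0.0, std, size=(k, k, cin, cout)))
            biases.append(np.zeros(cout))
        return cls(weights, biases, config)

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        a = x
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if cache is not None:
                cache.append(a)
            z = _conv2d(a, w, b)
            a = np.maximum(z, 0.0) if i < n - 1 else z
        return 1.0 / (1.0 + np.exp(-a[..., 0]))

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel tissue probability for one RGB image in [0, 255]."""
        x = np.asarray(image, dtype=float)[None] / 255.0
        return self.forward(x)[0]


def train_fcn(
    patches: np.ndarray,
    masks: np.ndarray,
    config: Optional[FCNConfig] = None,
) -> FCNModel:
    """Train the tissue FCN on 21x21 RGB patches with per-pixel labels.

    ``patches``: (N, 21, 21, 3) in [0, 255]; ``masks``: (N, 21, 21) in
    {0, 1}.  Optimized with Adam on per-pixel binary cross-entropy
    plus L2 weight decay.  Configuration deviating from the defaults
    is allowed but logged.
    """
    config = config or FCNConfig()
    config.log_overrides()
    model = FCNModel.initialize(config)
    x_all = np.asarray(patches, dtype=float) / 255.0
    y_all = np.asarray(masks, dtype=float)
    rng = np.random.default_rng(config.seed + 1)
    n = len(x_all)
    # Adam state
    mom = [np.zeros_like(w) for w in model.weights]
    vel = [np.zeros_like(w) for w in model.weights]
    mom_b = [np.zeros_like(b) for b in model.biases]
    vel_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            cache: list = []
            p = model.forward(x, cache)
            p = np.clip(p, 1e-7, 1 - 1e-7)
            epoch_loss += float(
                -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean() * len(idx)
            )
            # gradient of mean BCE wrt final pre-activation
            dz = ((p - y) / p.size)[..., None]
            grads_w, grads_b = [None] * len(model.weights), [None] * len(model.biases)
            da = dz
            for i in range(len(model.weights) - 1, -1, -1):
                a_in = cache[i]
                if i < len(model.weights) - 1:
                    z = _conv2d(a_in, model.weights[i], model.biases[i])
                    da = da * (z > 0)
                da, grads_w[i], grads_b[i] = _conv2d_backward(
                    a_in, model.weights[i], da
                )
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i in range(len(model.weights)):
                g = grads_w[i] + config.weight_decay * model.weights[i]
                mom[i] = beta1 * mom[i] + (1 - beta1) * g
                vel[i] = beta2 * vel[i] + (1 - beta2) * g * g
                model.weights[i] -= lr_t * mom[i] / (np.sqrt(vel[i]) + eps)
                gb = grads_b[i]
                mom_b[i] = beta1 * mom_b[i] + (1 - beta1) * gb
                vel_b[i] = beta2 * vel_b[i] + (1 - beta2) * gb * gb
                model.biases[i] -= lr_t * mom_b[i] / (np.sqrt(vel_b[i]) + eps)
        model.history.append(epoch_loss / n)
    return model


def fcn_tissue_mask(image: np.ndarray, model: FCNModel, scan_id: str = "") -> TissueMask:
    """Per-pixel tissue probability thresholded at 0.5."""
    prob = model.predict_mask(image)
    return TissueMask(scan_id, prob >= 0.5, "fcn")


# ---------------------------------------------------------------------------
# Mask-to-grid coupling


def patch_validity(
    mask: TissueMask,
    grid: PatchGrid,
    min_tissue_fraction: float = 0.5,
) -> np.ndarray:
    """Boolean (n_rows, n_cols): patch overlaps >= ``min_tissue_fraction`` tissue.

    The patch footprint at 40x level is projected into mask pixels
    (mask resolution is 1/8 of 40x).
    """
    scale = 40 // grid.magnification
    factor = mask.downsample_factor
    out = np.zeros(grid.shape, dtype=bool)
    mh, mw = mask.mask.shape
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            x, y = grid.position(row, col)
            x0 = int(np.floor(x * scale / factor))
            y0 = int(np.floor(y * scale / factor))
            x1 = int(np.ceil((x + grid.patch_size) * scale / factor))
            y1 = int(np.ceil((y + grid.patch_size) * scale / factor))
            window = mask.mask[y0 : min(y1, mh), x0 : min(x1, mw)]
            if window.size:
                out[row, col] = window.mean() >= min_tissue_fraction
    return out
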