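"""Patch preprocessing, pluggable classifiers and probability maps.

The preprocessing contract: 256x256 RGB patches are cropped to
224x224 (random crop plus random horizontal flip and rotation by a
multiple of 90 degrees in training; central crop in evaluation) and
normalized per model family.  The CNN family subtracts the RGB mean
(123.680, 116.779, 103.939); the ViT family scales to [0, 1] and
standardizes with mean (0.485, 0.456, 0.406) and std (0.229, 0.224,
0.225).

Backbones are pluggable behind a minimal fit / predict_proba
contract, so any deep architecture can be dropped in as
configuration.  The repository ships a deliberately small reference
backbone, a multinomial logistic model on per-channel color
statistics, sufficient for the color-separable synthetic textures the
test suite uses.

A trained classifier is swept over a scan's patch grid to produce a
:class:`~wsidiag.annotations_io.ProbabilityMap`; the central 224 crop
of each 256 grid patch is evaluated, keeping one map cell per stride
position, and cells outside the tissue mask carry a uniform vector
with ``valid_mask`` false.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Callable, Dict, List, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import log_loss
from sklearn.preprocessing import StandardScaler

from .annotations_io import PatchManifest, ProbabilityMap, uniform_vector
from .labels import ClassLabel, DEFAULT_SEVERITY_ORDER, severity_rank
from .patch_labeling import build_patch_grid
from .pyramid import ScanPyramid
from .tissue_segmentation import TissueMask, patch_validity

logger = logging.getLogger(__name__)

CNN_MEAN = (123.680, 116.779, 103.939)
VIT_MEAN = (0.485, 0.456, 0.406)
VIT_STD = (0.229, 0.224, 0.225)

CROP_SIZE = 224
INPUT_SIZE = 256
_EVAL_OFFSET = (INPUT_SIZE - CROP_SIZE) // 2  # (16, 16)


def preprocess(
    image: np.ndarray,
    mode: str = "eval",
    family: str = "cnn",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Crop, augment (train only) and normalize one 256x256 RGB patch."""
    img = np.asarray(image)
    if img.shape[:2] != (INPUT_SIZE, INPUT_SIZE):
        raise ValueError(f"expected {INPUT_SIZE}x{INPUT_SIZE} input, got {img.shape[:2]}")
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if family not in ("cnn", "vit"):
        raise ValueError(f"unknown model family {family!r}")
    if mode == "train":
        if rng is None:
            raise ValueError("train mode requires an rng for reproducible augmentation")
        max_off = INPUT_SIZE - CROP_SIZE
        ox = int(rng.integers(0, max_off + 1))
        oy = int(rng.integers(0, max_off + 1))
        out = img[oy : oy + CROP_SIZE, ox : ox + CROP_SIZE].astype(float)
        if rng.integers(0, 2):
            out = out[:, ::-1]
        out = np.rot90(out, k=int(rng.integers(0, 4)))
    else:
        out = img[
            _EVAL_OFFSET : _EVAL_OFFSET + CROP_SIZE,
            _EVAL_OFFSET : _EVAL_OFFSET + CROP_SIZE,
        ].astype(float)
    if family == "cnn":
        out = out - np.asarray(CNN_MEAN)
    else:
        out = (out / 255.0 - np.asarray(VIT_MEAN)) / np.asarray(VIT_STD)
    return np.ascontiguousarray(out)


@dataclass
class TrainConfig:
    """Training defaults for patch classifiers.

    SGD for 50 epochs at learning rate 1e-4 decayed by 0.1 every 20
    epochs, batch size 32, weight decay 5e-4; dropout 0.5 applies to
    backbones that have dropout layers.  Overrides are logged.
    """

    epochs: int = 50
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    batch_size: int = 32
    weight_decay: float = 5e-4
    dropout: float = 0.5
    seed: int = 0

    def log_overrides(self) -> None:
        defaults = TrainConfig()
        for f in fields(self):
            if f.name == "seed":
                continue
            if getattr(self, f.name) != getattr(defaults, f.name):
                logger.info(
                    "train config override: %s=%r (default %r)",
                    f.name,
                    getattr(self, f.name),
                    getattr(defaults, f.name),
                )

    def lr_at_epoch(self, epoch: int) -> float:
        return self.learning_rate * self.lr_decay_factor ** (epoch // self.lr_decay_every)


class Backbone(Protocol):
    """Minimal contract a patch backbone must implement."""

    def fit(
        self,
        images: np.ndarray,
        labels: Sequence[str],
        config: TrainConfig,
        class_list: Sequence[str],
    ) -> List[float]:
        """Train on preprocessed 224x224 inputs; return per-epoch losses."""

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """(N, C) probabilities in ``class_list`` order."""


class ColorStatBackbone:
    """Reference backbone: logistic model on per-channel mean and std.

    Six features per patch (RGB means and standard deviations over the
    224x224 crop), standardized, then a multinomial logistic model
    fitted by minibatch SGD honoring the epoch/learning-rate/batch
    fields of :class:`TrainConfig`.
    """

    def __init__(self) -> None:
        self.scaler: Optional[StandardScaler] = None
        self.clf: Optional[SGDClassifier] = None
        self.class_list: List[str] = []

    @staticmethod
    def features(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        means = x.mean(axis=(1, 2))
        stds = x.std(axis=(1, 2))
        return np.concatenate([means, stds], axis=1)

    def fit(self, images, labels, config, class_list):
        feats = self.features(images)
        y = np.asarray(labels)
        self.class_list = list(class_list)
        self.scaler = StandardScaler().fit(feats)
        feats = self.scaler.transform(feats)
        self.clf = SGDClassifier(
            loss="log_loss",
            learning_rate="constant",
            eta0=config.learning_rate,
            alpha=config.weight_decay,
            random_state=config.seed,
        )
        rng = np.random.default_rng(config.seed)
        classes = np.asarray(self.class_list)
        history: List[float] = []
        for epoch in range(config.epochs):
            self.clf.eta0 = config.lr_at_epoch(epoch)
            order = rng.permutation(len(feats))
            for start in range(0, len(feats), config.batch_size):
                idx = order[start : start + config.batch_size]
                self.clf.partial_fit(feats[idx], y[idx], classes=classes)
            history.append(
                float(
                    log_loss(y, self.clf.predict_proba(feats), labels=self.clf.classes_)
                )
            )
        return history

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(feats)
        # reorder sklearn's lexicographic classes_ to the declared class list
        order = [list(self.clf.classes_).index(c) for c in self.class_list]
        return proba[:, order]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba_features(self.scaler.transform(self.features(images)))


@dataclass
class PatchClassifier:
    """A trained backbone plus its class order, family and history."""

    backbone: Backbone
    class_list: List[str]
    family: str = "cnn"
    config: TrainConfig = field(default_factory=TrainConfig)
    history: List[float] = field(default_factory=list)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Probabilities for raw 256x256 patches (eval preprocessing)."""
        batch = np.stack([preprocess(p, "eval", self.family) for p in patches])
        proba = self.backbone.predict_proba(batch)
        proba = np.clip(proba, 0.0, None)
        return proba / proba.sum(axis=1, keepdims=True)


ImageLoader = Callable[[str, int, int, int], np.ndarray]


def train_classifier(
    manifest: PatchManifest,
    images: Mapping[Tuple[str, int, int, int], np.ndarray] | ImageLoader,
    config: Optional[TrainConfig] = None,
    backbone: Optional[Backbone] = None,
    family: str = "cnn",
    class_list: Optional[Sequence[str]] = None,
) -> PatchClassifier:
    """Fit a patch classifier on the manifest's labeled rows.

    ``images`` maps ``(scan_id, magnification, x, y)`` to a 256x256
    patch, or is a callable with those arguments.  The class list
    defaults to the labels present in the manifest in severity order;
    a requested class with no training rows is rejected by name.
    """
    config = config or TrainConfig()
    config.log_overrides()
    backbone = backbone if backbone is not None else ColorStatBackbone()
    rows = manifest.labeled()
    if not len(rows):
        raise ValueError("manifest has no labeled rows")
    present = set(rows["label"])
    if class_list is None:
        class_list = sorted(
            present, key=lambda code: severity_rank(ClassLabel(code))
        )
    for code in class_list:
        if code not in present:
            raise ValueError(f"class {code!r} has no training instances")
    rows = rows[rows["label"].isin(set(class_list))]
    loader: ImageLoader
    if callable(images):
        loader = images
    else:
        loader = lambda s, m, x, y: images[(s, m, x, y)]
    rng = np.random.default_rng(config.seed)
    batch = np.stack(
        [
            preprocess(
                loader(r.scan_id, r.magnification, r.x, r.y), "train", family, rng
            )
            for r in rows.itertuples()
        ]
    )
    history = backbone.fit(batch, list(rows["label"]), config, class_list)
    return PatchClassifier(backbone, list(class_list), family, config, history or [])


def predict_probability_map(
    scan: ScanPyramid,
    magnification: int,
    classifier: PatchClassifier,
    tissue_mask: Optional[TissueMask] = None,
    patch_size: int = 256,
    stride: int = 128,
    min_tissue_fraction: float = 0.5,
) -> ProbabilityMap:
    """Classify every valid-tissue grid patch of one pyramid level.

    Cells not overlapping valid tissue get a uniform vector and
    ``valid_mask`` false.  The output grid shape equals the patch-grid
    shape for this scan and magnification.
    """
    if not scan.has_level(magnification):
        raise ValueError(f"scan {scan.scan_id}: magnification {magnification}x absent")
    grid = build_patch_grid(scan.dims(magnification), magnification, patch_size, stride)
    if tissue_mask is not None:
        valid = patch_validity(tissue_mask, grid, min_tissue_fraction)
    else:
        valid = np.ones(grid.shape, dtype=bool)
    n_classes = len(classifier.class_list)
    out = np.tile(uniform_vector(n_classes), grid.shape + (1,))
    coords = [
        (row, col)
        for row in range(grid.n_rows)
        for col in range(grid.n_cols)
        if valid[row, col]
    ]
    if coords:
        patches = np.stack(
            [
                scan.crop(magnification, *grid.position(row, col), patch_size)
                for row, col in coords
            ]
        )
        proba = classifier.predict_proba(patches)
        for (row, col), vec in zip(coords, proba):
            out[row, col] = vec
    return ProbabilityMap(
        scan_id=scan.scan_id,
        magnification=magnification,
        class_list=list(classifier.class_list),
        grid=out,
        valid_mask=valid,
    )
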