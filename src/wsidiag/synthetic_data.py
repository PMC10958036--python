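"""Synthetic annotated scans, probability maps and diagnosis cohorts.

Every pipeline stage is exercised on generated data, so the package
is testable end to end without any external slide archive.  The
generator emulates the *structure* of annotated prostate scans, not
their appearance: a white slide background, one tissue sheet, and
axis-aligned class regions filled with class-specific color textures
separable by mean color (so the small reference classifier can
succeed).  Rectangular regions with integer corners make exact
coverage arithmetic available to the tests; realism is explicitly a
non-goal.

The default region-class mix follows the class shares observed in
annotated prostate cohorts (normal tissue dominating, Gleason 3-4
the most frequent grades, grades 1-2 rare).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, box

from .annotations_io import AnnotationSet, ProbabilityMap
from .labels import ClassLabel
from .pyramid import ScanPyramid
from .tissue_segmentation import DOWNSAMPLE_FACTOR, TissueMask, downsample_scan

#: per-class texture mean RGB; chosen mutually separable by mean color
CLASS_COLORS: Dict[ClassLabel, Tuple[int, int, int]] = {
    ClassLabel.BG: (250, 250, 250),
    ClassLabel.T: (200, 162, 182),
    ClassLabel.N: (188, 130, 164),
    ClassLabel.A: (150, 150, 150),
    ClassLabel.R1: (196, 134, 120),
    ClassLabel.R2: (170, 150, 90),
    ClassLabel.R3: (150, 100, 160),
    ClassLabel.R4: (120, 70, 130),
    ClassLabel.R5: (80, 45, 95),
}

#: default class mix of the generated regions (tissue classes only),
#: proportional to the shares seen in annotated prostate cohorts
DEFAULT_REGION_DISTRIBUTION: Dict[ClassLabel, float] = {
    ClassLabel.N: 0.507,
    ClassLabel.A: 0.119,
    ClassLabel.R1: 0.010,
    ClassLabel.R2: 0.010,
    ClassLabel.R3: 0.088,
    ClassLabel.R4: 0.222,
    ClassLabel.R5: 0.044,
}


@dataclass
class SynthConfig:
    """Parameters of one synthetic annotated scan.

    Dimensions are 40x-level pixels.  ``tissue_fraction`` is the area
    share of the tissue sheet; class regions are placed inside it
    without mutual overlap.  The seed is mandatory: generation is
    fully deterministic given the config.
    """

    seed: int
    width: int = 1280
    height: int = 1280
    tissue_fraction: float = 0.6
    n_regions: int = 5
    region_size: Tuple[int, int] = (256, 448)
    class_distribution: Dict[ClassLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_DISTRIBUTION)
    )
    noise_sd: float = 6.0
    background_value: int = 250
    #: minimum gap between placed regions, in px; a gap of >= 128 makes
    #: it impossible for two regions to label one 256px patch jointly
    margin: int = 0

    def __post_init__(self) -> None:
        if self.width < 256 or self.height < 256:
            raise ValueError("scan dims must be at least 256 px")
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class distribution must sum to 1")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue fraction must be in (0, 1]")


def _fill_texture(
    img: np.ndarray,
    rect: Tuple[int, int, int, int],
    label: ClassLabel,
    rng: np.random.Generator,
    noise_sd: float,
) -> None:
    x0, y0, x1, y1 = rect
    base = np.asarray(CLASS_COLORS[label], dtype=float)
    block = base + rng.normal(0.0, noise_sd, size=(y1 - y0, x1 - x0, 3))
    img[y0:y1, x0:x1] = np.clip(block, 0, 255)


def generate_scan(
    config: SynthConfig,
) -> Tuple[ScanPyramid, AnnotationSet, TissueMask]:
    """One synthetic annotated scan with its pyramid and truth mask.

    The tissue sheet is an axis-aligned rectangle of the configured
    area share, textured as tissue background (T); class regions are
    non-overlapping integer rectangles inside it.  Lower pyramid
    levels are rendered by block averaging.  Annotations carry the
    class rectangles plus the tissue sheet minus those rectangles as
    T, so region labels are unambiguous under the overlap rule.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.width, config.height
    img = np.clip(
        config.background_value + rng.normal(0, 2.0, size=(h, w, 3)), 0, 255
    )

    # tissue sheet with exact configured area share
    tw = int(round(w * np.sqrt(config.tissue_fraction)))
    th = int(round(h * np.sqrt(config.tissue_fraction)))
    tw, th = min(tw, w), min(th, h)
    tx = int(rng.integers(0, w - tw + 1))
    ty = int(rng.integers(0, h - th + 1))
    tissue_rect = (tx, ty, tx + tw, ty + th)
    _fill_texture(img, tissue_rect, ClassLabel.T, rng, config.noise_sd)

    labels = list(config.class_distribution.keys())
    probs = np.asarray([config.class_distribution[lab] for lab in labels])
    placed: List[Tuple[Tuple[int, int, int, int], ClassLabel]] = []
    lo, hi = config.region_size
    for _ in range(config.n_regions):
        label = labels[int(rng.choice(len(labels), p=probs))]
        ok = False
        for _attempt in range(200):
            rw = int(rng.integers(lo, hi + 1))
            rh = int(rng.integers(lo, hi + 1))
            if rw > tw or rh > th:
                continue
            rx = int(rng.integers(tx, tx + tw - rw + 1))
            ry = int(rng.integers(ty, ty + th - rh + 1))
            rect = (rx, ry, rx + rw, ry + rh)
            g = config.margin
            if all(
                rect[2] + g <= o[0]
                or o[2] + g <= rect[0]
                or rect[3] + g <= o[1]
                or o[3] + g <= rect[1]
                for o, _ in placed
            ):
                placed.append((rect, label))
                _fill_texture(img, rect, label, rng, config.noise_sd)
                ok = True
                break
        if not ok:
            warnings.warn(
                f"could not place all {config.n_regions} regions without overlap; "
                f"generated {len(placed)}"
            )
            break

    regions: List[Tuple[Polygon, ClassLabel]] = [
        (box(*rect), label) for rect, label in placed
    ]
    leftover = box(*tissue_rect)
    for rect, _ in placed:
        leftover = leftover.difference(box(*rect))
    if not leftover.is_empty:
        parts = (
            leftover.geoms if isinstance(leftover, MultiPolygon) else [leftover]
        )
        for part in parts:
            if part.area > 0:
                regions.append((part, ClassLabel.T))

    scan_id = f"synth-{config.seed:08d}"
    base = np.round(img).astype(np.uint8)
    levels = {40: base}
    for mag in (20, 10, 5):
        levels[mag] = downsample_scan(base, 40 // mag)
    pyramid = ScanPyramid(scan_id=scan_id, levels=levels)

    tissue_full = np.zeros((h, w), dtype=float)
    tissue_full[ty : ty + th, tx : tx + tw] = 1.0
    truth = downsample_scan(tissue_full, DOWNSAMPLE_FACTOR) >= 0.5
    mask = TissueMask(scan_id, truth, "otsu")
    return pyramid, AnnotationSet(scan_id=scan_id, regions=regions), mask


DEFAULT_CLASS_LIST = [lab.value for lab in ClassLabel]


def generate_probability_map(
    grid_shape: Tuple[int, int],
    cancer_fraction: float,
    sharpness: float = 5.0,
    seed: int = 0,
    class_list: Sequence[str] = DEFAULT_CLASS_LIST,
    cancer_class: str = "R4",
    normal_class: str = "N",
    scan_id: str = "synth-map",
    magnification: int = 10,
) -> Tuple[ProbabilityMap, np.ndarray]:
    """A probability map with a contiguous cancer blob of known size.

    ``cancer_fraction`` of the cells are cancerous (grown as a
    connected blob); each cell's vector is Dirichlet-distributed with
    concentration ``1 + sharpness**2`` on its true class, so the
    argmax recovers the truth with probability approaching 1 as
    sharpness grows (and exactly at ``sharpness = inf``).  Returns the
    map and the boolean truth layout.
    """
    if not 0 <= cancer_fraction <= 1:
        raise ValueError("cancer_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    n_cells = rows * cols
    n_cancer = int(round(cancer_fraction * n_cells))
    truth = np.zeros((rows, cols), dtype=bool)
    if n_cancer > 0:
        start = (int(rng.integers(rows)), int(rng.integers(cols)))
        blob = {start}
        frontier = [start]
        while len(blob) < n_cancer and frontier:
            r, c = frontier[int(rng.integers(len(frontier)))]
            neighbors = [
                (r + dr, c + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < rows and 0 <= c + dc < cols
            ]
            fresh = [p for p in neighbors if p not in blob]
            if not fresh:
                frontier.remove((r, c))
                continue
            pick = fresh[int(rng.integers(len(fresh)))]
            blob.add(pick)
            frontier.append(pick)
        for r, c in blob:
            truth[r, c] = True
    class_list = list(class_list)
    ci = class_list.index(cancer_class)
    ni = class_list.index(normal_class)
    n_classes = len(class_list)
    grid = np.empty((rows, cols, n_classes))
    for r in range(rows):
        for c in range(cols):
            true_idx = ci if truth[r, c] else ni
            if np.isinf(sharpness):
                vec = np.zeros(n_classes)
                vec[true_idx] = 1.0
            else:
                alpha = np.ones(n_classes)
                alpha[true_idx] += sharpness**2
                vec = rng.dirichlet(alpha)
            grid[r, c] = vec
    pmap = ProbabilityMap(
        scan_id=scan_id,
        magnification=magnification,
        class_list=class_list,
        grid=grid,
        valid_mask=np.ones((rows, cols), dtype=bool),
    )
    return pmap, truth


def generate_cohort(
    n_scans: int = 200,
    c_lognormal: Tuple[float, float] = (np.log(13.0), 0.7),
    nc_lognormal: Tuple[float, float] = (np.log(0.3), 1.0),
    prevalence: float = 0.5,
    seed: int = 0,
) -> "pd.DataFrame":
    """Scan-level cohort of (p_c, truth) pairs.

    Cancerous and non-cancerous scans draw their cancerous-tissue
    percentage from separate log-normal distributions (parameters on
    the log scale), mirroring the strongly bimodal percentages seen
    in real screening cohorts; values are clipped to [0, 100].
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    truth = np.where(rng.random(n_scans) < prevalence, "C", "NC")
    p_c = np.empty(n_scans)
    c_mask = truth == "C"
    p_c[c_mask] = rng.lognormal(*c_lognormal, size=int(c_mask.sum()))
    p_c[~c_mask] = rng.lognormal(*nc_lognormal, size=int((~c_mask).sum()))
    p_c = np.clip(p_c, 0.0, 100.0)
    return pd.DataFrame(
        {
            "scan_id": [f"scan-{i:04d}" for i in range(n_scans)],
            "p_c": p_c,
            "truth": truth,
        }
    )
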