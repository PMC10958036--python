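"""Patch-grid construction and hierarchical patch labeling.

Patches of 256 x 256 px are extracted with a stride of 128 at four
magnification levels (40x, 20x, 10x, 5x).  At the base level a patch
receives a class label iff exactly one class's annotated regions
cover at least 75% of its area.  At lower magnifications the patch's
physical footprint is subdivided into the 40x-level patches it spans
(4 at 20x, 16 at 10x, 64 at 5x), each sub-patch is labeled with the
base-level rule, and the most severe sub-label wins; a patch whose
sub-patches are all unlabeled stays unlabeled.

Coverage fractions are computed by exact polygon clipping (shapely);
pixel rasterization is used only as an independent test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import box

from .annotations_io import AnnotationSet, PatchManifest
from .labels import ClassLabel, DEFAULT_SEVERITY_ORDER, severity_rank
from .pyramid import MAGNIFICATIONS, ScanPyramid

OVERLAP_THRESHOLD = 0.75
#: tolerance for the inclusive >= 0.75 comparison under float area arithmetic
_COVER_EPS = 1e-9


def n_subpatches(magnification: int) -> int:
    """Number of 40x-level sub-patches tiling one patch's footprint."""
    if magnification not in MAGNIFICATIONS:
        raise ValueError(f"unknown magnification {magnification!r}")
    return (40 // magnification) ** 2


@dataclass(frozen=True)
class PatchGrid:
    """Row-major lattice of patch positions at one magnification."""

    magnification: int
    patch_size: int
    stride: int
    n_cols: int
    n_rows: int

    @property
    def shape(self) -> Tuple[int, int]:
        return self.n_rows, self.n_cols

    def position(self, row: int, col: int) -> Tuple[int, int]:
        return col * self.stride, row * self.stride

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield self.position(row, col)


def build_patch_grid(
    scan_dims: Tuple[int, int],
    magnification: int = 40,
    patch_size: int = 256,
    stride: int = 128,
) -> PatchGrid:
    """All positions ``(x, y)`` with ``x, y = 0 (mod stride)`` and the
    full patch inside the scan; partial edge patches are dropped."""
    width, height = scan_dims
    n_cols = (width - patch_size) // stride + 1
    n_rows = (height - patch_size) // stride + 1
    if n_cols < 1 or n_rows < 1:
        warnings.warn(
            f"scan of size {scan_dims} smaller than one {patch_size}px patch; empty grid"
        )
        n_cols = max(n_cols, 0)
        n_rows = max(n_rows, 0)
    return PatchGrid(magnification, patch_size, stride, n_cols, n_rows)


def class_coverage(
    patch_rect: Tuple[float, float, float, float],
    annotations: AnnotationSet,
) -> Dict[ClassLabel, float]:
    """Fraction of the patch covered by each class's region union.

    ``patch_rect`` is ``(x0, y0, x1, y1)`` in 40x-level coordinates.
    Degenerate (zero-area) regions contribute nothing.  Fractions of
    different classes may sum above 1 where regions overlap.
    """
    patch = box(*patch_rect)
    area = patch.area
    if area <= 0:
        raise ValueError(f"degenerate patch rectangle {patch_rect}")
    coverage: Dict[ClassLabel, float] = {}
    for label in annotations.labels_present:
        union = annotations.class_union(label)
        if union.is_empty or union.area == 0:
            continue
        frac = patch.intersection(union).area / area
        if frac > 0:
            coverage[label] = min(frac, 1.0)
    return coverage


def assign_label_40x(
    coverage: Mapping[ClassLabel, float],
    threshold: float = OVERLAP_THRESHOLD,
) -> Optional[ClassLabel]:
    """Unique class reaching the overlap threshold, else ``None``.

    The comparison is inclusive (a coverage of exactly 0.75 labels the
    patch).  Zero classes reaching the threshold, or two or more
    (possible only with overlapping annotations of different classes),
    leave the patch unlabeled.
    """
    hits = [lab for lab, frac in coverage.items() if frac >= threshold - _COVER_EPS]
    if len(hits) == 1:
        return hits[0]
    return None


def merge_sublabels(
    labels: Sequence[Optional[ClassLabel]],
    order: Sequence[ClassLabel] = DEFAULT_SEVERITY_ORDER,
) -> Optional[ClassLabel]:
    """Most severe of the 40x-level sub-labels; ``None`` if all are.

    The list length must be one of the subdivision counts 4, 16 or 64.
    Unlabeled sub-patches are ignored so a partially annotated patch
    still receives the most severe labeled value.
    """
    if len(labels) not in (4, 16, 64):
        raise ValueError(f"expected 4, 16 or 64 sub-labels, got {len(labels)}")
    present = [lab for lab in labels if lab is not None]
    if not present:
        return None
    return max(present, key=lambda lab: severity_rank(lab, order))


def label_patch(
    x: int,
    y: int,
    magnification: int,
    annotations: AnnotationSet,
    patch_size: int = 256,
    threshold: float = OVERLAP_THRESHOLD,
    order: Sequence[ClassLabel] = DEFAULT_SEVERITY_ORDER,
) -> Optional[ClassLabel]:
    """Label one patch given at its own magnification's coordinates.

    At 40x this is the single-patch overlap rule; at lower levels the
    patch's 40x footprint is tiled by non-overlapping 256px sub-patches
    which are labeled individually and merged by severity.
    """
    if magnification not in MAGNIFICATIONS:
        raise ValueError(f"unknown magnification {magnification!r}")
    scale = 40 // magnification
    bx, by = x * scale, y * scale
    if scale == 1:
        cov = class_coverage((bx, by, bx + patch_size, by + patch_size), annotations)
        return assign_label_40x(cov, threshold)
    sublabels: List[Optional[ClassLabel]] = []
    for sy in range(scale):
        for sx in range(scale):
            x0 = bx + sx * patch_size
            y0 = by + sy * patch_size
            cov = class_coverage((x0, y0, x0 + patch_size, y0 + patch_size), annotations)
            sublabels.append(assign_label_40x(cov, threshold))
    return merge_sublabels(sublabels, order)


def label_grid(
    grid: PatchGrid,
    annotations: AnnotationSet,
    threshold: float = OVERLAP_THRESHOLD,
) -> List[Optional[ClassLabel]]:
    """Labels for every grid position, row-major."""
    return [
        label_patch(x, y, grid.magnification, annotations, grid.patch_size, threshold)
        for x, y in grid
    ]


def extract_dataset(
    scans: Iterable[ScanPyramid],
    annotations: Mapping[str, AnnotationSet],
    partitions: Mapping[str, str],
    out_dir: Optional[str | Path] = None,
    magnifications: Sequence[int] = MAGNIFICATIONS,
    patch_size: int = 256,
    stride: int = 128,
    threshold: float = OVERLAP_THRESHOLD,
) -> PatchManifest:
    """Build the labeled patch manifest (and optionally patch images).

    Every grid patch at every available magnification becomes one
    manifest row; unlabeled patches are recorded with an empty label.
    With ``out_dir`` set, patch crops are saved as PNG under
    ``out_dir/<scan>/<mag>x/<x>_<y>.png``.
    """
    records = []
    for scan in scans:
        if scan.scan_id not in partitions:
            raise ValueError(f"scan {scan.scan_id!r} has no partition assignment")
        partition = partitions[scan.scan_id]
        ann = annotations.get(scan.scan_id, AnnotationSet(scan.scan_id))
        for mag in magnifications:
            if not scan.has_level(mag):
                warnings.warn(f"scan {scan.scan_id}: missing {mag}x level; skipped")
                continue
            grid = build_patch_grid(scan.dims(mag), mag, patch_size, stride)
            for x, y in grid:
                label = label_patch(x, y, mag, ann, patch_size, threshold)
                records.append(
                    {
                        "scan_id": scan.scan_id,
                        "magnification": mag,
                        "x": x,
                        "y": y,
                        "label": label.value if label is not None else "",
                        "partition": partition,
                    }
                )
                if out_dir is not None:
                    patch_dir = Path(out_dir) / scan.scan_id / f"{mag}x"
                    patch_dir.mkdir(parents=True, exist_ok=True)
                    Image.fromarray(scan.crop(mag, x, y, patch_size)).save(
                        patch_dir / f"{x}_{y}.png"
                    )
    df = pd.DataFrame.from_records(
        records, columns=["scan_id", "magnification", "x", "y", "label", "partition"]
    )
    return PatchManifest(df, patch_size=patch_size, stride=stride)
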