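"""Data model and serialization for annotations, patch manifests and
probability maps.

Annotations are GeoJSON FeatureCollections of polygons in base-level
(40x) pixel coordinates, each feature carrying a ``label`` property
with one of the nine class codes.  Patch manifests are CSV files, one
row per grid patch.  Probability maps are HDF5 files with a
``grid`` dataset (H x W x C), a ``valid_mask`` dataset and the scan
id / magnification / class order stored as attributes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping
from shapely.ops import unary_union

from .labels import ClassLabel

PARTITIONS = ("train", "validation", "test")

MANIFEST_COLUMNS = ("scan_id", "magnification", "x", "y", "label", "partition")


class AnnotationError(ValueError):
    """Malformed annotation input."""


def _normalize_ring(coords: Sequence[Sequence[float]]) -> List[Tuple[float, float]]:
    """Drop consecutive duplicate vertices and the closing repeat."""
    pts = [(float(x), float(y)) for x, y in coords]
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts = pts[:-1]
    out: List[Tuple[float, float]] = []
    for p in pts:
        if not out or p != out[-1]:
            out.append(p)
    return out


def _normalize_polygon(geom: dict, feature_index: int) -> Polygon:
    if geom.get("type") != "Polygon":
        raise AnnotationError(
            f"feature {feature_index}: geometry type {geom.get('type')!r} is not Polygon"
        )
    rings = geom.get("coordinates") or []
    if not rings:
        raise AnnotationError(f"feature {feature_index}: polygon has no rings")
    shell = _normalize_ring(rings[0])
    holes = [_normalize_ring(r) for r in rings[1:]]
    if len(shell) < 3:
        raise AnnotationError(f"feature {feature_index}: ring has fewer than 3 vertices")
    poly = Polygon(shell, holes)
    if not poly.is_valid:
        # self-touching rings etc.; buffer(0) produces the simple equivalent
        fixed = poly.buffer(0)
        if isinstance(fixed, Polygon) and fixed.is_valid:
            poly = fixed
        else:
            raise AnnotationError(
                f"feature {feature_index}: polygon is not simple after normalization"
            )
    return poly


@dataclass
class AnnotationSet:
    """Labeled regions of one scan, in 40x-level pixel coordinates."""

    scan_id: str
    regions: List[Tuple[Polygon, ClassLabel]] = field(default_factory=list)
    _unions: Dict[ClassLabel, object] = field(default_factory=dict, repr=False)

    @property
    def labels_present(self) -> List[ClassLabel]:
        seen: List[ClassLabel] = []
        for _, lab in self.regions:
            if lab not in seen:
                seen.append(lab)
        return seen

    def class_union(self, label: ClassLabel):
        """Union geometry of all regions of one class (cached)."""
        if label not in self._unions:
            geoms = [poly for poly, lab in self.regions if lab is label]
            self._unions[label] = unary_union(geoms) if geoms else Polygon()
        return self._unions[label]


def read_annotations(path: str | Path, scan_id: Optional[str] = None) -> AnnotationSet:
    """Parse a GeoJSON FeatureCollection into an :class:`AnnotationSet`.

    Each feature must be a simple polygon (coordinates are 40x-level
    pixels) with a ``label`` property naming one of the nine classes.
    Unknown labels and non-polygon geometries are rejected with the
    offending feature index.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: not a GeoJSON FeatureCollection")
    if scan_id is None:
        scan_id = data.get("properties", {}).get("scan_id") or path.stem
    regions: List[Tuple[Polygon, ClassLabel]] = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        code = props.get("label")
        try:
            label = ClassLabel(code)
        except ValueError:
            raise AnnotationError(
                f"feature {i}: unknown class label {code!r}"
            ) from None
        poly = _normalize_polygon(feat.get("geometry") or {}, i)
        regions.append((poly, label))
    return AnnotationSet(scan_id=scan_id, regions=regions)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    features = []
    for poly, label in annotations.regions:
        features.append(
            {
                "type": "Feature",
                "properties": {"label": label.value},
                "geometry": mapping(poly),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"scan_id": annotations.scan_id},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Patch manifest


@dataclass
class PatchManifest:
    """Table of grid patches: ``(scan_id, magnification, x, y, label, partition)``.

    ``label`` is a :class:`ClassLabel` code or the empty string for
    unlabeled patches.  Coordinates lie on the stride lattice at the
    patch's own magnification; partitions are disjoint at scan level.
    """

    rows: pd.DataFrame
    patch_size: int = 256
    stride: int = 128

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        self.rows = df = df[list(MANIFEST_COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.rows
        if ((df["x"] % self.stride != 0) | (df["y"] % self.stride != 0)).any():
            raise ValueError(f"patch coordinates not on the stride-{self.stride} lattice")
        key = ["scan_id", "magnification", "x", "y"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValueError(
                f"duplicate manifest key {tuple(dup[k] for k in key)}"
            )
        bad_part = set(df["partition"]) - set(PARTITIONS)
        if bad_part:
            raise ValueError(f"unknown partition value(s) {sorted(bad_part)}")
        labels = set(df["label"]) - {""}
        bad_lab = {lab for lab in labels if lab not in ClassLabel._value2member_map_}
        if bad_lab:
            raise ValueError(f"unknown class label(s) {sorted(bad_lab)}")
        per_scan = df.groupby("scan_id")["partition"].nunique()
        if (per_scan > 1).any():
            offender = per_scan[per_scan > 1].index[0]
            raise ValueError(f"scan {offender!r} appears in multiple partitions")

    def labeled(self) -> pd.DataFrame:
        return self.rows[self.rows["label"] != ""]

    def __len__(self) -> int:
        return len(self.rows)


def write_manifest(manifest: PatchManifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, index=False)


def read_manifest(path: str | Path, patch_size: int = 256, stride: int = 128) -> PatchManifest:
    df = pd.read_csv(
        path,
        dtype={"scan_id": str, "label": str, "partition": str},
        keep_default_na=False,
    )
    df["magnification"] = df["magnification"].astype(int)
    df["x"] = df["x"].astype(int)
    df["y"] = df["y"].astype(int)
    return PatchManifest(df, patch_size=patch_size, stride=stride)


# ---------------------------------------------------------------------------
# Probability maps


@dataclass
class ProbabilityMap:
    """Per-patch class-probability vectors on a scan's patch grid.

    ``grid`` has shape (H, W, C) aligned to the patch grid at one
    magnification; ``valid_mask`` flags cells overlapping valid
    tissue.  Vectors on valid cells are probability simplices.
    """

    scan_id: str
    magnification: int
    class_list: List[str]
    grid: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.ndim != 3 or self.grid.shape[2] != len(self.class_list):
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with "
                f"{len(self.class_list)} classes"
            )
        if self.valid_mask.shape != self.grid.shape[:2]:
            raise ValueError("valid_mask shape does not match grid")
        self.class_list = [str(c) for c in self.class_list]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape[:2]

    def check_normalized(self, atol: float = 1e-6) -> None:
        sums = self.grid[self.valid_mask].sum(axis=-1)
        if sums.size and (np.abs(sums - 1.0) > atol).any():
            raise ValueError("probability vectors on valid cells do not sum to 1")
        if (self.grid < -atol).any():
            raise ValueError("negative probabilities")

    def argmax_indices(self) -> np.ndarray:
        return np.argmax(self.grid, axis=-1)

    def class_index(self, code: str) -> int:
        return self.class_list.index(code)


def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=pmap.grid)
        f.create_dataset("valid_mask", data=pmap.valid_mask)
        f.attrs["scan_id"] = pmap.scan_id
        f.attrs["magnification"] = pmap.magnification
        f.attrs["class_list"] = np.asarray(pmap.class_list, dtype="S")


def read_probability_map(path: str | Path) -> ProbabilityMap:
    """Read a map; near-degenerate vectors are renormalized with a warning."""
    with h5py.File(path, "r") as f:
        if "class_list" not in f.attrs:
            raise KeyError(f"{path}: missing class order attribute")
        class_list = [c.decode() for c in f.attrs["class_list"]]
        grid = np.asarray(f["grid"], dtype=float)
        valid = np.asarray(f["valid_mask"], dtype=bool)
        pmap = ProbabilityMap(
            scan_id=str(f.attrs["scan_id"]),
            magnification=int(f.attrs["magnification"]),
            class_list=class_list,
            grid=grid,
            valid_mask=valid,
        )
    sums = pmap.grid[pmap.valid_mask].sum(axis=-1)
    if sums.size and (np.abs(sums - 1.0) > 1e-4).any():
        warnings.warn(f"{path}: probability vectors deviate from 1; renormalizing")
        total = pmap.grid.sum(axis=-1, keepdims=True)
        nonzero = total[..., 0] > 0
        pmap.grid[nonzero] = pmap.grid[nonzero] / total[nonzero]
        pmap.grid[~nonzero] = 1.0 / len(pmap.class_list)
    return pmap


def uniform_vector(n_classes: int) -> np.ndarray:
    return np.full(n_classes, 1.0 / n_classes)
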