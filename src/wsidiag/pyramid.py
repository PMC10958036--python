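"""Multi-resolution scan container.

A whole-slide scan is held as a four-level image pyramid at 40x, 20x,
10x and 5x magnification (40x is the base, ~0.25 um/pixel).  Levels
are plain RGB arrays; coordinates everywhere in the package are
0-based, half-open rectangles with the origin at the top-left, given
at the patch's own magnification level.  Conversion to base-level
coordinates is a multiplication by ``40 / magnification``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
from PIL import Image

MAGNIFICATIONS = (40, 20, 10, 5)


@dataclass
class ScanPyramid:
    scan_id: str
    levels: Dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mag in self.levels:
            if mag not in MAGNIFICATIONS:
                raise ValueError(f"unknown magnification {mag!r}")
        if 40 in self.levels:
            w40, h40 = self.dims(40)
            for mag in self.levels:
                w, h = self.dims(mag)
                ew, eh = w40 * mag / 40, h40 * mag / 40
                if abs(w - ew) > 1 or abs(h - eh) > 1:
                    warnings.warn(
                        f"scan {self.scan_id}: level {mag}x dims {(w, h)} deviate "
                        f"from base-level scaling {(ew, eh)}"
                    )

    def dims(self, magnification: int) -> Tuple[int, int]:
        """(width, height) in pixels of a pyramid level."""
        img = self.levels[magnification]
        return img.shape[1], img.shape[0]

    def has_level(self, magnification: int) -> bool:
        return magnification in self.levels

    def crop(self, magnification: int, x: int, y: int, size: int) -> np.ndarray:
        """Half-open crop ``[x, x+size) x [y, y+size)`` at one level."""
        img = self.levels[magnification]
        h, w = img.shape[:2]
        if x < 0 or y < 0 or x + size > w or y + size > h:
            raise ValueError(
                f"crop ({x},{y},{size}) outside level {magnification}x of size {(w, h)}"
            )
        return img[y : y + size, x : x + size]

    def save(self, directory: str | Path) -> None:
        out = Path(directory) / self.scan_id
        out.mkdir(parents=True, exist_ok=True)
        for mag, img in self.levels.items():
            Image.fromarray(img).save(out / f"{mag}x.png")

    @classmethod
    def load(cls, directory: str | Path, scan_id: str) -> "ScanPyramid":
        root = Path(directory) / scan_id
        levels: Dict[int, np.ndarray] = {}
        for mag in MAGNIFICATIONS:
            path = root / f"{mag}x.png"
            if path.exists():
                levels[mag] = np.asarray(Image.open(path).convert("RGB"))
        if not levels:
            raise FileNotFoundError(f"no pyramid levels found under {root}")
        return cls(scan_id=scan_id, levels=levels)
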