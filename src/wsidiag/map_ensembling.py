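"""Combining probability maps across models and magnifications.

Maps from models trained at different magnifications cover the same
physical region at different grid resolutions, so higher-resolution
maps are first rescaled (block-averaging the probability vectors) to
the grid of the lowest-magnification member, then all member maps are
averaged cell-wise.  Both operations are convex on the probability
simplex, so normalization is preserved exactly.

Class groups (e.g. cancerous = R1..R5) are merged by summing member
probabilities.  Binarized prediction maps can be smoothed with a
masked median filter (default kernel 3) that removes isolated
positives not forming larger clusters; borders are handled by
reflection padding and invalid cells are excluded from every
neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotations_io import ProbabilityMap
from .labels import CancerSetting, ClassLabel, binary_grouping


def rescale_map(pmap: ProbabilityMap, target_shape: Tuple[int, int]) -> ProbabilityMap:
    """Block-average a map down to ``target_shape``.

    Each output cell is the mean of the corresponding r x r block of
    probability vectors; the valid mask is the logical OR over the
    block.  The per-axis ratios must be integers.
    """
    h, w = pmap.shape
    th, tw = target_shape
    if th > h or tw > w:
        raise ValueError(f"target shape {target_shape} exceeds map shape {(h, w)}")
    if h % th or w % tw:
        raise ValueError(
            f"non-integer rescale ratio from {(h, w)} to {target_shape}"
        )
    ry, rx = h // th, w // tw
    grid = pmap.grid.reshape(th, ry, tw, rx, -1).mean(axis=(1, 3))
    valid = pmap.valid_mask.reshape(th, ry, tw, rx).any(axis=(1, 3))
    return ProbabilityMap(
        pmap.scan_id, pmap.magnification, list(pmap.class_list), grid, valid
    )


def average_maps(maps: Sequence[ProbabilityMap]) -> ProbabilityMap:
    """Cell-wise arithmetic mean of maps on one grid; valid mask is OR."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.shape != first.shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {first.shape}")
        if m.class_list != first.class_list:
            raise ValueError("class list mismatch between maps")
    grid = np.mean([m.grid for m in maps], axis=0)
    valid = np.logical_or.reduce([m.valid_mask for m in maps])
    return ProbabilityMap(
        first.scan_id, first.magnification, list(first.class_list), grid, valid
    )


def merge_class_groups(
    pmap: ProbabilityMap, grouping: Mapping[str, Set[ClassLabel] | Set[str]]
) -> ProbabilityMap:
    """Sum member-class probabilities into group probabilities.

    ``grouping`` must partition the map's class list.
    """
    codes = [{c.value if isinstance(c, ClassLabel) else str(c) for c in members}
             for members in grouping.values()]
    flat = [c for group in codes for c in group]
    if sorted(flat) != sorted(pmap.class_list) or len(flat) != len(set(flat)):
        raise ValueError("grouping is not a partition of the map's class list")
    group_names = list(grouping.keys())
    grid = np.stack(
        [
            pmap.grid[..., [pmap.class_index(c) for c in group]].sum(axis=-1)
            for group in codes
        ],
        axis=-1,
    )
    return ProbabilityMap(
        pmap.scan_id, pmap.magnification, group_names, grid, pmap.valid_mask.copy()
    )


def median_filter_map(
    binary_map: np.ndarray,
    k: int = 3,
    valid_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Masked k x k median filter of a binary prediction map.

    Each cell is replaced by the median (majority, for binary values)
    of the valid cells in its k x k neighborhood, with reflection
    padding at the borders.  Invalid cells are excluded from every
    neighborhood and keep their value; an exact tie also keeps the
    original value.
    """
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    arr = np.asarray(binary_map)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("median_filter_map expects a binary map")
    valid = (
        np.ones(arr.shape, bool) if valid_mask is None else np.asarray(valid_mask, bool)
    )
    p = k // 2
    ap = np.pad(arr.astype(float), p, mode="reflect")
    vp = np.pad(valid, p, mode="reflect")
    win_a = sliding_window_view(ap, (k, k))
    win_v = sliding_window_view(vp, (k, k))
    ones = (win_a * win_v).sum(axis=(-2, -1))
    total = win_v.sum(axis=(-2, -1))
    out = arr.copy()
    decided = valid & (total > 0) & (2 * ones != total)
    out[decided] = (2 * ones > total)[decided]
    return out.astype(arr.dtype)


@dataclass
class EnsembleSpec:
    """Which (model id, magnification) maps to combine.

    The target grid is the grid of the lowest-magnification member.
    """

    members: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")


@dataclass
class EnsembleResult:
    probability_map: ProbabilityMap
    cancer_map: Optional[np.ndarray] = None  # binarized (+ filtered) cancer calls


def binarize_cancer(
    pmap: ProbabilityMap, setting: CancerSetting = CancerSetting.S1
) -> np.ndarray:
    """1 where the argmax class (after group merging) is cancerous."""
    if set(pmap.class_list) == {"cancerous", "non_cancerous"}:
        merged = pmap
    else:
        grouping = binary_grouping(setting, [ClassLabel(c) for c in pmap.class_list])
        merged = merge_class_groups(pmap, grouping)
    cancer_idx = merged.class_list.index("cancerous")
    return (merged.argmax_indices() == cancer_idx).astype(np.uint8)


def run_ensemble(
    spec: EnsembleSpec,
    maps: Mapping[Tuple[str, int], ProbabilityMap],
    median_filter: bool = False,
    k: int = 3,
    setting: CancerSetting = CancerSetting.S1,
    filter_per_member: bool = False,
) -> EnsembleResult:
    """Rescale member maps to a common grid and average them.

    With ``median_filter`` the binarized cancer map is smoothed; the
    filter runs either on the ensembled map (default) or on each
    member's binarized map before majority voting
    (``filter_per_member``).
    """
    member_maps: List[ProbabilityMap] = []
    for member in spec.members:
        if member not in maps:
            raise KeyError(f"missing probability map for ensemble member {member}")
        member_maps.append(maps[member])
    target_shape = min((m.shape for m in member_maps), key=lambda s: s[0] * s[1])
    rescaled = [rescale_map(m, target_shape) for m in member_maps]
    averaged = average_maps(rescaled)
    cancer: Optional[np.ndarray] = None
    if median_filter:
        if filter_per_member:
            votes = np.mean(
                [
                    median_filter_map(binarize_cancer(m, setting), k, m.valid_mask)
                    for m in rescaled
                ],
                axis=0,
            )
            cancer = (votes > 0.5).astype(np.uint8)
            ties = votes == 0.5
            if ties.any():  # even member count: fall back to the ensembled call
                cancer[ties] = binarize_cancer(averaged, setting)[ties]
        else:
            cancer = median_filter_map(
                binarize_cancer(averaged, setting), k, averaged.valid_mask
            )
    return EnsembleResult(probability_map=averaged, cancer_map=cancer)
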