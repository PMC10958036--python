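"""Scan-level abstaining diagnosis from patch probability maps.

The scan statistic is the cancerous-tissue percentage p_c: the share
of valid tissue patches whose (argmax) class is cancerous, excluding
both patches removed by the tissue segmentation and patches whose
argmax class is scan background (BG).  The abstaining rule with lower
threshold T_L and upper threshold T_U (both percentages) outputs

    NC  (non-cancerous)  if p_c <= T_L,
    C   (cancerous)      if p_c >= T_U,
    IHC (abstain: needs further examination) otherwise.

Narrowing the abstention interval decides more scans at the price of
accuracy; :func:`threshold_sweep` maps that trade-off on a grid of
(T_L, T_U) pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score

from .annotations_io import ProbabilityMap
from .labels import CancerSetting, ClassLabel
from .map_ensembling import binarize_cancer

DIAGNOSES = ("NC", "IHC", "C")


@dataclass(frozen=True)
class DiagnosisRule:
    """Abstention thresholds in percent; 0 <= T_L < T_U <= 100."""

    t_lower: float = 0.5
    t_upper: float = 7.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_lower < self.t_upper <= 100):
            raise ValueError(
                f"invalid thresholds T_L={self.t_lower}, T_U={self.t_upper}"
            )


def cancer_ratio(
    pmap: ProbabilityMap,
    setting: CancerSetting = CancerSetting.S1,
    prob_threshold: Optional[float] = None,
) -> float:
    """Percentage of valid, non-background patches called cancerous.

    A patch is cancerous when its argmax class falls in the setting's
    cancer group (or, with ``prob_threshold``, when the summed cancer
    probability exceeds the threshold).  Valid patches whose argmax is
    BG are excluded from the denominator along with segmentation-
    excluded background.  With no valid tissue patches at all the
    ratio is undefined and NaN is returned with a warning.
    """
    valid = pmap.valid_mask
    argmax = pmap.argmax_indices()
    if "BG" in pmap.class_list:
        non_bg = argmax != pmap.class_index("BG")
    else:
        non_bg = np.ones(pmap.shape, dtype=bool)
    denom_mask = valid & non_bg
    n_denom = int(denom_mask.sum())
    if n_denom == 0:
        warnings.warn(
            f"scan {pmap.scan_id}: no valid tissue patches; cancer ratio undefined"
        )
        return float("nan")
    if prob_threshold is None:
        cancer = binarize_cancer(pmap, setting).astype(bool)
    else:
        if set(pmap.class_list) == {"cancerous", "non_cancerous"}:
            p_cancer = pmap.grid[..., pmap.class_list.index("cancerous")]
        else:
            idx = [
                i
                for i, c in enumerate(pmap.class_list)
                if ClassLabel(c) in setting.cancer_labels
            ]
            p_cancer = pmap.grid[..., idx].sum(axis=-1)
        cancer = p_cancer >= prob_threshold
    return 100.0 * int((cancer & denom_mask).sum()) / n_denom


def abstain_diagnose(p_c: float, rule: DiagnosisRule = DiagnosisRule()) -> str:
    """Apply the abstaining rule to one cancerous-tissue percentage.

    An undefined (NaN) p_c propagates as an abstention with a warning.
    """
    if math.isnan(p_c):
        warnings.warn("undefined cancer ratio: abstaining from the diagnosis")
        return "IHC"
    if p_c <= rule.t_lower:
        return "NC"
    if p_c >= rule.t_upper:
        return "C"
    return "IHC"


def diagnose_scan(
    pmap: ProbabilityMap,
    rule: DiagnosisRule = DiagnosisRule(),
    setting: CancerSetting = CancerSetting.S1,
) -> Tuple[str, float]:
    """Convenience: p_c then the rule; returns (diagnosis, p_c)."""
    p_c = cancer_ratio(pmap, setting)
    return abstain_diagnose(p_c, rule), p_c


@dataclass
class SweepResult:
    """Accuracy / coverage trade-off over a (T_L, T_U) grid.

    ``accuracy[i, j]`` is the accuracy over decided scans for
    ``(t_lower_grid[i], t_upper_grid[j])`` (NaN when nothing is
    decided or the pair is invalid); ``proportion[i, j]`` the decided
    fraction; ``valid[i, j]`` marks pairs with T_L < T_U.
    """

    t_lower_grid: np.ndarray
    t_upper_grid: np.ndarray
    accuracy: np.ndarray
    proportion: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tl in enumerate(self.t_lower_grid):
            for j, tu in enumerate(self.t_upper_grid):
                rows.append(
                    {
                        "t_lower": tl,
                        "t_upper": tu,
                        "valid": bool(self.valid[i, j]),
                        "accuracy": self.accuracy[i, j],
                        "proportion_decided": self.proportion[i, j],
                    }
                )
        return pd.DataFrame(rows)


DEFAULT_TL_GRID = np.round(np.arange(0.0, 2.01, 0.1), 10)
DEFAULT_TU_GRID = np.arange(2.0, 15.01, 1.0)


def threshold_sweep(
    p_c_values: Sequence[float],
    truths: Sequence[str],
    t_lower_grid: Sequence[float] = DEFAULT_TL_GRID,
    t_upper_grid: Sequence[float] = DEFAULT_TU_GRID,
) -> SweepResult:
    """Accuracy on decided scans and proportion decided per threshold pair.

    ``truths`` are binary scan diagnoses in {"C", "NC"}.
    """
    p_c = np.asarray(p_c_values, dtype=float)
    truth = np.asarray(truths)
    if p_c.shape != truth.shape:
        raise ValueError("p_c and truth lengths differ")
    if not set(truth) <= {"C", "NC"}:
        raise ValueError("truths must be binary C/NC")
    tl_grid = np.asarray(t_lower_grid, dtype=float)
    tu_grid = np.asarray(t_upper_grid, dtype=float)
    acc = np.full((len(tl_grid), len(tu_grid)), np.nan)
    prop = np.full_like(acc, np.nan)
    valid = np.zeros(acc.shape, dtype=bool)
    for i, tl in enumerate(tl_grid):
        for j, tu in enumerate(tu_grid):
            if not tl < tu:
                continue
            valid[i, j] = True
            decided_nc = p_c <= tl
            decided_c = p_c >= tu
            decided = decided_nc | decided_c
            prop[i, j] = decided.mean() if len(p_c) else np.nan
            if decided.any():
                pred = np.where(decided_nc, "NC", "C")[decided]
                acc[i, j] = float((pred == truth[decided]).mean())
    return SweepResult(tl_grid, tu_grid, acc, prop, valid)


def compute_metrics(predicted: Sequence[str], true: Sequence[str]) -> Tuple[float, float]:
    """Overall accuracy and average (macro) accuracy.

    AvAcc is the unweighted mean of per-class recalls over classes
    with at least one true instance, robust to class imbalance.
    """
    pred = np.asarray(predicted)
    truth = np.asarray(true)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    acc = float(accuracy_score(truth, pred))
    avacc = float(balanced_accuracy_score(truth, pred))
    return acc, avacc
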