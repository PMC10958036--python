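"""Tissue class labels and their severity order.

Annotated regions of a prostate whole-slide image carry one of nine
classes: scan background (``BG``), tissue background (``T``), normal
tissue (``N``), acquisition artifact (``A``), or a Gleason grade
``R1``–``R5``.  Gleason grades are ordinal (higher means more
malignant) and every grade ranks above every non-cancer class, which
is what makes the "most severe label wins" merge rule well defined.
The relative order of the non-cancer classes (BG < T < N < A) only
matters for merging unlabeled/ambiguous tissue and is configurable.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Optional, Sequence


class ClassLabel(str, enum.Enum):
    """One of the nine region/patch classes."""

    BG = "BG"
    T = "T"
    N = "N"
    A = "A"
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"
    R4 = "R4"
    R5 = "R5"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def gleason_grade(self) -> Optional[int]:
        """Numeric Gleason grade for R1..R5, ``None`` otherwise."""
        if self.value.startswith("R"):
            return int(self.value[1])
        return None


#: Default strict total severity order, least to most severe.
DEFAULT_SEVERITY_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.BG,
    ClassLabel.T,
    ClassLabel.N,
    ClassLabel.A,
    ClassLabel.R1,
    ClassLabel.R2,
    ClassLabel.R3,
    ClassLabel.R4,
    ClassLabel.R5,
)

GLEASON_LABELS: frozenset[ClassLabel] = frozenset(
    {ClassLabel.R1, ClassLabel.R2, ClassLabel.R3, ClassLabel.R4, ClassLabel.R5}
)


def severity_rank(
    label: ClassLabel, order: Sequence[ClassLabel] = DEFAULT_SEVERITY_ORDER
) -> int:
    """Position of ``label`` in the (configurable) severity order."""
    return order.index(label)


def most_severe(
    labels: Iterable[ClassLabel], order: Sequence[ClassLabel] = DEFAULT_SEVERITY_ORDER
) -> ClassLabel:
    return max(labels, key=lambda lab: severity_rank(lab, order))


class CancerSetting(str, enum.Enum):
    """Which Gleason grades count as cancerous.

    ``S1`` treats every grade (R1-R5) as cancerous; ``S2`` treats the
    clinically reported grades R3-R5 as cancerous and folds R1-R2
    (rarely used by practitioners) into the non-cancerous group.
    """

    S1 = "S1"
    S2 = "S2"

    @property
    def cancer_labels(self) -> frozenset[ClassLabel]:
        if self is CancerSetting.S1:
            return GLEASON_LABELS
        return frozenset({ClassLabel.R3, ClassLabel.R4, ClassLabel.R5})


def is_cancerous(label: ClassLabel, setting: CancerSetting) -> bool:
    return label in setting.cancer_labels


def binary_grouping(
    setting: CancerSetting, class_list: Optional[Sequence[ClassLabel]] = None
) -> Mapping[str, frozenset[ClassLabel]]:
    """Partition of ``class_list`` into cancerous / non-cancerous groups."""
    labels = tuple(class_list) if class_list is not None else tuple(ClassLabel)
    cancer = frozenset(lab for lab in labels if is_cancerous(lab, setting))
    other = frozenset(lab for lab in labels if not is_cancerous(lab, setting))
    return {"cancerous": cancer, "non_cancerous": other}
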