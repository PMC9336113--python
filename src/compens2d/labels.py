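"""Frame-level compensation labels.

Four compensation categories are coded 0-3 — trunk forward (TF, 0),
trunk rotation (TR, 1), shoulder elevation (SE, 2) and other trunk
patterns such as moving backward or tilting (O, 3). A frame with none of
them is Normal (code 4), which is exclusive with every compensation
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

TF, TR, SE, OTHER = 0, 1, 2, 3
NORMAL = 4
COMPENSATION_LABELS = (TF, TR, SE, OTHER)
N_LABEL_SLOTS = 5
LABEL_NAMES = {TF: "trunk_forward", TR: "trunk_rotation",
               SE: "shoulder_elevation", OTHER: "other", NORMAL: "normal"}


@dataclass(frozen=True)
class LabelSet:
    """The compensation labels active in one frame.

    ``labels`` is a subset of {0, 1, 2, 3}; the frame is Normal exactly
    when it is empty.
    """

    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        labs = frozenset(int(x) for x in self.labels)
        if not labs <= set(COMPENSATION_LABELS):
            raise ValueError(f"labels must be within {{0,1,2,3}}: {labs}")
        object.__setattr__(self, "labels", labs)

    @classmethod
    def of(cls, *labels: int) -> "LabelSet":
        return cls(frozenset(labels))

    @classmethod
    def normal_set(cls) -> "LabelSet":
        return cls(frozenset())

    @property
    def normal(self) -> bool:
        return not self.labels

    def __contains__(self, label: int) -> bool:
        return label in self.labels

    def __or__(self, other: "LabelSet") -> "LabelSet":
        return LabelSet(self.labels | other.labels)


def to_onehot(labelsets: Iterable[LabelSet]) -> np.ndarray:
    """(N, 5) binary indicator matrix; slot 4 marks Normal frames."""
    labelsets = list(labelsets)
    out = np.zeros((len(labelsets), N_LABEL_SLOTS), dtype=int)
    for i, ls in enumerate(labelsets):
        if ls.normal:
            out[i, NORMAL] = 1
        else:
            out[i, sorted(ls.labels)] = 1
    return out


def from_onehot(matrix: np.ndarray) -> list[LabelSet]:
    """Inverse of :func:`to_onehot` (Normal slot wins when set alone)."""
    out = []
    for row in np.asarray(matrix):
        active = frozenset(int(j) for j in np.nonzero(row[:NORMAL])[0])
        out.append(LabelSet(active))
    return out
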