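"""Segmentation agreement between automatic and manually revised masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskPair", "dice"]


@dataclass
class MaskPair:
    """An automatic segmentation paired with its revised reference."""

    auto_mask: np.ndarray
    ref_mask: np.ndarray

    def __post_init__(self) -> None:
        self.auto_mask = np.asarray(self.auto_mask).astype(bool)
        self.ref_mask = np.asarray(self.ref_mask).astype(bool)
        if self.auto_mask.shape != self.ref_mask.shape:
            raise ValueError("masks are on different grids")

    def dice(self) -> float:
        return dice(self.auto_mask, self.ref_mask)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient, 2|A∩B| / (|A|+|B|).

    Two empty masks are rejected rather than scored 1: an empty/empty
    comparison in this pipeline always indicates upstream failure.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"masks are on different grids: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)
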