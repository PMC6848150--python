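"""Somatic ROI sets: per-cell boolean masks with counterstain labels.

ROIs are inputs to the pipeline (drawn manually in the original workflow, or
derived from generator ground truth here).  Each cell carries exactly one
counterstain label (TxRed-positive or -negative) and an in-focus flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk of given radius (pixels) centred at (row, col)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@dataclass
class RoiSet:
    """Per-cell boolean masks plus labels.

    masks : (n_cells, H, W) boolean array
    txred_positive : (n_cells,) boolean
    in_focus : (n_cells,) boolean
    """

    masks: np.ndarray
    txred_positive: np.ndarray
    in_focus: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_cells, H, W) boolean array")
        n = self.masks.shape[0]
        self.txred_positive = np.asarray(self.txred_positive, dtype=bool)
        if self.in_focus is None:
            self.in_focus = np.ones(n, dtype=bool)
        self.in_focus = np.asarray(self.in_focus, dtype=bool)
        if self.txred_positive.shape != (n,) or self.in_focus.shape != (n,):
            raise ValueError("label arrays must have one entry per cell")
        if n == 0:
            raise ValueError("RoiSet must contain at least one cell")
        empties = np.flatnonzero(~self.masks.any(axis=(1, 2)))
        if empties.size:
            raise ValueError(f"empty ROI masks for cells {empties.tolist()}")

    @property
    def n_cells(self) -> int:
        return int(self.masks.shape[0])

    def label_image(self) -> np.ndarray:
        """Label image (0 = background, cell i -> i + 1; later cells win on overlap)."""
        lab = np.zeros(self.masks.shape[1:], dtype=np.int32)
        for i, m in enumerate(self.masks):
            lab[m] = i + 1
        return lab

    @classmethod
    def from_disks(
        cls,
        shape: tuple[int, int],
        centers: np.ndarray,
        radii: np.ndarray,
        txred_positive: np.ndarray,
        in_focus: np.ndarray | None = None,
    ) -> "RoiSet":
        masks = np.stack([disk_mask(shape, tuple(c), r) for c, r in zip(centers, radii)])
        return cls(masks=masks, txred_positive=txred_positive, in_focus=in_focus)
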