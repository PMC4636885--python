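"""Cell-detachment scoring from marker ("dot") images.

Detachment is measured by imaging the same culture areas shortly before and
two hours after treatment. Each cell is marked with a dot on a blank
background; counting the dots per field of view and comparing the mean
count before vs after gives the relative change in cell number, where a
negative value is cell loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .exceptions import DegenerateDataError

__all__ = ["DetachmentRecord", "count_markers", "cell_loss"]


def count_markers(dot_image: np.ndarray) -> int:
    """Number of connected dot components larger than one pixel.

    Accepts binary or near-binary rasters; anything above half the image
    maximum counts as a dot pixel. Single isolated pixels are ignored as
    noise. A blank image yields 0.
    """
    img = np.asarray(dot_image, dtype=float)
    if img.size == 0 or img.max() <= 0:
        return 0
    mask = img > 0.5 * img.max()
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes > 1).sum())


def cell_loss(before: Sequence[float], after: Sequence[float]) -> float:
    """Relative change in mean cell count, percent; negative = loss.

    ``100 * (mean(after) - mean(before)) / mean(before)``. Bounded below by
    -100 for nonnegative counts. Raises when the baseline mean is zero.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    mb = before.mean()
    if not mb > 0:
        raise DegenerateDataError("baseline mean count must be positive")
    return float(100.0 * (after.mean() - mb) / mb)


@dataclass
class DetachmentRecord:
    """Per-replicate spot counts before and after treatment.

    The standard acquisition is three random spots per exposure area over
    six areas, i.e. 18 counts per time point, but any nonempty structure is
    accepted.
    """

    counts_before: np.ndarray
    counts_after: np.ndarray

    def __post_init__(self) -> None:
        self.counts_before = np.asarray(self.counts_before, dtype=float)
        self.counts_after = np.asarray(self.counts_after, dtype=float)
        if np.any(self.counts_before < 0) or np.any(self.counts_after < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def relative_change(self) -> float:
        """Percent change in mean count; see :func:`cell_loss`."""
        return cell_loss(self.counts_before, self.counts_after)
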