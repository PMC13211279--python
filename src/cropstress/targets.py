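"""Edge and signed-distance auxiliary supervision targets.

The edge target is the union over classes of the morphological gradient
(3x3 dilation minus erosion) of each class's binary support, marking the
two-pixel transition band at class boundaries.  The signed distance
target measures exact Euclidean distance to the boundary of the combined
non-soil foreground: positive inside, negative outside, scaled by tau and
clipped to [-1, 1] so far-field distances do not dominate the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cropstress.masks import LabelMask, IGNORE_LABEL

DEFAULT_TAU = 20.0

_SE_3x3 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


@dataclass
class AuxTargets:
    edge: np.ndarray  # H x W {0, 1}
    sdt: np.ndarray  # H x W in [-1, 1]
    tau: float


def edge_target(mask: LabelMask | np.ndarray) -> np.ndarray:
    """Union of per-class morphological gradients, binarized."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    edge = np.zeros(labels.shape, dtype=bool)
    for k in np.unique(labels):
        if k == IGNORE_LABEL:
            continue
        support = labels == k
        grad = ndimage.binary_dilation(support, _SE_3x3) & ~ndimage.binary_erosion(
            support, _SE_3x3, border_value=1
        )
        edge |= grad
    return edge.astype(np.uint8)


def sdt_target(mask: LabelMask | np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Normalized signed distance to the combined non-soil boundary.

    Foreground is the union of the non-soil classes.  When the mask has no
    boundary (all foreground or all background) the map saturates at +1 or
    -1 respectively.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    fg = (labels != 0) & (labels != IGNORE_LABEL)
    if fg.all():
        return np.ones(labels.shape, dtype=np.float64)
    if not fg.any():
        return -np.ones(labels.shape, dtype=np.float64)
    # The boundary set is the inner pixel ring of the foreground (4-connected,
    # so the ring stays one pixel thin); pixels on it get distance exactly zero.
    cross = ndimage.generate_binary_structure(2, 1)
    boundary = fg & ~ndimage.binary_erosion(fg, cross, border_value=1)
    dist = ndimage.distance_transform_edt(~boundary)
    signed = np.where(fg, dist, -dist).astype(np.float64)
    return np.clip(signed / float(tau), -1.0, 1.0)


def make_aux_targets(mask: LabelMask | np.ndarray, tau: float = DEFAULT_TAU) -> AuxTargets:
    return AuxTargets(edge=edge_target(mask), sdt=sdt_target(mask, tau), tau=tau)
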