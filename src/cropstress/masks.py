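"""Label-mask container shared across the pipeline.

Three label spaces are used.  The water-stress task is four-class
(0 soil, 1 low stress, 2 high stress, 3 healthy), the rust task is
three-class (0 soil, 1 rust, 2 healthy), and combined training happens in
the harmonized five-class ``mix5`` space (0 soil, 1 low stress,
2 high stress, 3 healthy, 4 rust).  Invalid (NoData) pixels carry the
reserved ignore value 255 in every space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

IGNORE_LABEL = 255

WATER4 = "water4"
RUST3 = "rust3"
MIX5 = "mix5"

SPACE_LABELS = {
    WATER4: (0, 1, 2, 3),
    RUST3: (0, 1, 2),
    MIX5: (0, 1, 2, 3, 4),
}

MIX5_CLASS_NAMES = {
    0: "soil",
    1: "low_stress",
    2: "high_stress",
    3: "healthy",
    4: "rust",
}

# Overlay colors (RGB) for QC renderings, per mix5 class id.
MIX5_PALETTE = {
    0: (120, 92, 60),     # soil: brown
    1: (255, 210, 60),    # low stress: yellow
    2: (230, 90, 30),     # high stress: orange-red
    3: (40, 160, 60),     # healthy: green
    4: (170, 40, 170),    # rust: purple
    IGNORE_LABEL: (0, 0, 0),
}


@dataclass
class LabelMask:
    """Integer class raster tagged with its label space."""

    labels: np.ndarray  # H x W uint8
    space: str
    valid_mask: np.ndarray | None = None
    palette: dict = field(default_factory=lambda: dict(MIX5_PALETTE))

    def __post_init__(self) -> None:
        if self.space not in SPACE_LABELS:
            raise ValueError(f"unknown label space {self.space!r}")
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.valid_mask is None:
            self.valid_mask = self.labels != IGNORE_LABEL
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        allowed = set(SPACE_LABELS[self.space]) | {IGNORE_LABEL}
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(
                f"labels {sorted(present - allowed)} not allowed in space {self.space!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.space, self.valid_mask.copy(), dict(self.palette))

    def colored(self) -> np.ndarray:
        """Render the mask as an H x W x 3 uint8 image using the palette."""
        out = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for cid, rgb in self.palette.items():
            out[self.labels == cid] = rgb
        return out

    def save_png(self, path) -> None:
        Image.fromarray(self.labels, mode="L").save(path)

    @classmethod
    def load_png(cls, path, space: str) -> "LabelMask":
        arr = np.asarray(Image.open(path), dtype=np.uint8)
        return cls(arr, space)


def overlay_on_rgb(rgb: np.ndarray, mask: LabelMask, alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend a colored mask over an RGB rendering for QC."""
    base = np.asarray(rgb, dtype=np.float64)
    if base.max() <= 1.0:
        base = base * 255.0
    color = mask.colored().astype(np.float64)
    blend = (1.0 - alpha) * base + alpha * color
    return np.clip(blend, 0, 255).astype(np.uint8)
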