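"""Vegetation indices used by the rule-based labeling stage.

Five indices are computed from the six-band reflectance stack:

* SAVI  = (NIR - Red)(1 + L) / (NIR + Red + L + eps), soil-adjusted, L = 0.5
* NDRE  = (NIR - RedEdge) / (NIR + RedEdge + eps)
* NDVI  = (NIR - Red) / (NIR + Red + eps)
* GCI   = NIR / (Green + eps) - 1
* SR    = NIR / (Red + eps)

SAVI separates plants from soil, NDRE tracks vigor/stress, NDVI and GCI
feed the low/high-stress split, and SR joins NDRE/NDVI in the rust vote.
``eps`` is a small positive stabilizer against zero denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from cropstress.scene import MultispectralScene

DEFAULT_L = 0.5
DEFAULT_EPS = 1e-6


def compute_savi(nir, red, L: float = DEFAULT_L, eps: float = DEFAULT_EPS):
    if L < 0:
        raise ValueError("soil brightness factor L must be >= 0")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    return (nir - red) * (1.0 + L) / (nir + red + L + eps)


def compute_ndre(nir, rededge, eps: float = DEFAULT_EPS):
    nir = np.asarray(nir, dtype=np.float64)
    rededge = np.asarray(rededge, dtype=np.float64)
    return (nir - rededge) / (nir + rededge + eps)


def compute_ndvi(nir, red, eps: float = DEFAULT_EPS):
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    return (nir - red) / (nir + red + eps)


def compute_gci(nir, green, eps: float = DEFAULT_EPS):
    nir = np.asarray(nir, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    return nir / (green + eps) - 1.0


def compute_sr(nir, red, eps: float = DEFAULT_EPS):
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    return nir / (red + eps)


@dataclass
class IndexStack:
    """The five index maps over a scene; values are NaN off the valid mask."""

    savi: np.ndarray
    ndre: np.ndarray
    ndvi: np.ndarray
    gci: np.ndarray
    sr: np.ndarray
    valid_mask: np.ndarray
    L_soil: float = DEFAULT_L
    eps: float = DEFAULT_EPS

    @property
    def shape(self) -> tuple[int, int]:
        return self.savi.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"savi": self.savi, "ndre": self.ndre, "ndvi": self.ndvi,
                "gci": self.gci, "sr": self.sr}


def compute_index_stack(
    scene: MultispectralScene, L: float = DEFAULT_L, eps: float = DEFAULT_EPS
) -> IndexStack:
    """Compute all five indices on valid pixels; invalid pixels become NaN."""
    required = ("green", "red", "rededge", "nir")
    for name in required:
        if name not in scene.band_names:
            raise KeyError(f"scene is missing required band {name!r}")
    valid = scene.valid_mask
    green = np.where(valid, scene.band("green"), np.nan)
    red = np.where(valid, scene.band("red"), np.nan)
    rededge = np.where(valid, scene.band("rededge"), np.nan)
    nir = np.where(valid, scene.band("nir"), np.nan)
    return IndexStack(
        savi=compute_savi(nir, red, L, eps),
        ndre=compute_ndre(nir, rededge, eps),
        ndvi=compute_ndvi(nir, red, eps),
        gci=compute_gci(nir, green, eps),
        sr=compute_sr(nir, red, eps),
        valid_mask=valid.copy(),
        L_soil=L,
        eps=eps,
    )


def export_index(index_map: np.ndarray, path) -> None:
    """Write one index map as a single-band float32 TIFF (NaN off-mask)."""
    tifffile.imwrite(str(path), index_map.astype(np.float32))
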