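"""Percentile normalization, overlapping tiling, and patch dataset export.

Orthomosaics are normalized per band to [0, 1] over the 2nd-98th
percentile range of valid pixels, scanned with overlapping tile x tile
windows (default tile 224, stride 96), and filtered by foreground ratio:
patches whose source-specific foreground fraction (water: low+high
stress; rust: rust) falls below ``fg_min`` are kept only with probability
``keep_negative_ratio`` so background does not swamp the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from cropstress.masks import LabelMask, MIX5, IGNORE_LABEL
from cropstress.scene import MultispectralScene

DEFAULT_TILE = 224
DEFAULT_STRIDE = 96

#: mix5 foreground classes used for the foreground-ratio rule, per source
FOREGROUND_CLASSES = {"water": (1, 2), "rust": (4,)}


@dataclass
class PatchFilter:
    fg_min: float = 0.01
    keep_negative_ratio: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.keep_negative_ratio <= 1.0:
            raise ValueError("keep_negative_ratio must be in [0, 1]")


@dataclass
class PatchRecord:
    """One image/mask window pair cut from an orthomosaic."""

    image: np.ndarray  # tile x tile x C float32 in [0, 1]
    mask: np.ndarray  # tile x tile uint8 (mix5 + ignore)
    origin_rc: tuple[int, int]
    source: str
    fg_ratio: float
    split: str = ""


def percentile_normalize(
    scene: MultispectralScene, p_low: float = 2.0, p_high: float = 98.0
) -> MultispectralScene:
    """Per-band clip to the [P_low, P_high] range and affine map to [0, 1]."""
    valid = scene.valid_mask
    if not valid.any():
        raise ValueError("scene has no valid pixels")
    bands = scene.bands.astype(np.float64).copy()
    for b in range(bands.shape[-1]):
        vals = bands[:, :, b][valid]
        lo, hi = np.percentile(vals, [p_low, p_high])
        if hi == lo:
            raise ValueError(f"degenerate band {b}: P{p_low} == P{p_high}")
        bands[:, :, b] = np.clip((bands[:, :, b] - lo) / (hi - lo), 0.0, 1.0)
    bands = np.where(valid[..., None], bands, scene.nodata_value).astype(np.float32)
    return MultispectralScene(
        bands=bands,
        valid_mask=valid.copy(),
        geotransform=scene.geotransform,
        crs_label=scene.crs_label,
        nodata_value=scene.nodata_value,
        gsd_m=scene.gsd_m,
        band_names=scene.band_names,
    )


def window_origins(h: int, w: int, tile: int, stride: int, flush: bool = False) -> list[tuple[int, int]]:
    """Top-left corners of all fully-contained tile x tile windows.

    With ``flush`` a final boundary-flushed row/column of windows is added
    whenever the stride grid does not reach the raster edge, so inference
    covers every pixel.  Training extraction uses the plain grid.
    """
    if tile > h or tile > w:
        raise ValueError("tile larger than raster")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    def axis(n: int) -> list[int]:
        pos = list(range(0, n - tile + 1, stride))
        if flush and pos[-1] != n - tile:
            pos.append(n - tile)
        return pos

    return [(r, c) for r in axis(h) for c in axis(w)]


def extract_patches(
    scene: MultispectralScene,
    mask: LabelMask,
    source: str,
    tile: int = DEFAULT_TILE,
    stride: int = DEFAULT_STRIDE,
    patch_filter: PatchFilter | None = None,
) -> list[PatchRecord]:
    """Cut the stride grid into patch records, filtering near-empty negatives."""
    if mask.space != MIX5:
        raise ValueError("extract_patches expects a harmonized mix5 mask")
    if source not in FOREGROUND_CLASSES:
        raise ValueError(f"unknown source {source!r}")
    patch_filter = patch_filter or PatchFilter()
    rng = np.random.default_rng(patch_filter.seed)
    fg_classes = FOREGROUND_CLASSES[source]
    h, w = scene.shape
    records: list[PatchRecord] = []
    for (r, c) in window_origins(h, w, tile, stride, flush=False):
        img = scene.bands[r : r + tile, c : c + tile].astype(np.float32)
        m = mask.labels[r : r + tile, c : c + tile]
        valid = m != IGNORE_LABEL
        n_valid = int(valid.sum())
        fg = float(np.isin(m, fg_classes).sum() / n_valid) if n_valid else 0.0
        keep = True
        if fg < patch_filter.fg_min:
            keep = rng.random() < patch_filter.keep_negative_ratio
        if keep:
            img = np.where(valid[..., None], img, 0.0).astype(np.float32)
            records.append(PatchRecord(img, m.copy(), (r, c), source, fg))
    return records


def split_dataset(records: list[PatchRecord], val_fraction: float = 0.2, seed: int = 42) -> list[PatchRecord]:
    """Seeded patch-level train/val split, stratified by source."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sources = sorted({rec.source for rec in records})
    for src in sources:
        idx = [i for i, rec in enumerate(records) if rec.source == src]
        if len(idx) < 2:
            raise ValueError(f"source {src!r} has too few patches to split")
        idx = list(rng.permutation(idx))
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            n_val = len(idx) - 1
        for i in idx[:n_val]:
            records[i].split = "val"
        for i in idx[n_val:]:
            records[i].split = "train"
    return records


def export_patches(records: list[PatchRecord], out_dir, qc_every: int = 0) -> list[dict]:
    """Write patches (.npy float16 image + uint8 PNG mask) and a JSON manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if qc_every:
        (out_dir / "qc").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(records):
        stem = f"{rec.source}_{rec.origin_rc[0]:06d}_{rec.origin_rc[1]:06d}"
        img_path = out_dir / "images" / f"{stem}.npy"
        mask_path = out_dir / "masks" / f"{stem}.png"
        np.save(img_path, rec.image.astype(np.float16))
        Image.fromarray(rec.mask, mode="L").save(mask_path)
        if qc_every and i % qc_every == 0:
            lm = LabelMask(rec.mask, MIX5)
            Image.fromarray(lm.colored()).save(out_dir / "qc" / f"{stem}_mask.png")
        manifest.append(
            {
                "image": str(img_path.relative_to(out_dir)),
                "mask": str(mask_path.relative_to(out_dir)),
                "origin_rc": list(rec.origin_rc),
                "source": rec.source,
                "fg_ratio": rec.fg_ratio,
                "split": rec.split,
            }
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_patches(out_dir, manifest: list[dict] | None = None) -> list[PatchRecord]:
    from PIL import Image

    out_dir = Path(out_dir)
    if manifest is None:
        with open(out_dir / "manifest.json") as fh:
            manifest = json.load(fh)
    records = []
    for row in manifest:
        img = np.load(out_dir / row["image"]).astype(np.float32)
        mask = np.asarray(Image.open(out_dir / row["mask"]), dtype=np.uint8)
        records.append(
            PatchRecord(img, mask, tuple(row["origin_rc"]), row["source"], row["fg_ratio"], row["split"])
        )
    return records
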