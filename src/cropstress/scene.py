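"""Seeded synthetic six-band orthomosaic scenes with known class layouts.

Real crop-stress orthomosaics pair a bright-in-Red soil background with
vegetation that is bright in NIR; water stress depresses NIR/RedEdge
progressively with severity, and rust disease depresses NIR and the simple
ratio NIR/Red.  The generator plants class regions with those contrasts —
diffuse smoothed-random-field patches for water stress, compact clusters
snapped to row stripes for rust — adds i.i.d. Gaussian reflectance noise,
and masks a NoData border, so every downstream stage can be exercised
against a known reference layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
import tifffile

from cropstress.masks import LabelMask, WATER4, RUST3, IGNORE_LABEL

BAND_NAMES = ("blue", "green", "red", "rededge", "nir", "nir2")
NODATA_VALUE = -9999.0

#: Mean reflectance per mix5 class (rows) and band (cols, BAND_NAMES order).
#: Orderings encoded: NIR healthy > low > high > soil; rust NIR depressed with
#: SR = NIR/Red well below the healthy value; soil brightest in Red.
_SIGNATURES = np.array(
    [
        # blue  green red   rededge nir   nir2
        [0.10, 0.16, 0.22, 0.26, 0.30, 0.30],  # 0 soil
        [0.04, 0.09, 0.07, 0.26, 0.42, 0.42],  # 1 low stress
        [0.05, 0.10, 0.08, 0.24, 0.36, 0.36],  # 2 high stress
        [0.03, 0.08, 0.05, 0.30, 0.55, 0.55],  # 3 healthy
        [0.05, 0.09, 0.09, 0.22, 0.38, 0.38],  # 4 rust
    ]
)

# Default areal class fractions (of the valid area) per scenario.
DEFAULT_FRACTIONS = {
    "water": {1: 0.15, 2: 0.10, 3: 0.35},
    "rust": {4: 0.12, 3: 0.55},
}


def class_signature(class_id: int, band_index: int) -> float:
    """Mean reflectance of a mix5 class in one band (deterministic lookup)."""
    if not (isinstance(class_id, (int, np.integer)) and 0 <= class_id <= 4):
        raise ValueError(f"unknown class id {class_id!r}")
    if not (isinstance(band_index, (int, np.integer)) and 0 <= band_index <= 5):
        raise ValueError(f"unknown band index {band_index!r}")
    return float(_SIGNATURES[class_id, band_index])


@dataclass
class SceneConfig:
    """Configuration of one synthetic orthomosaic."""

    height_px: int = 512
    width_px: int = 512
    gsd_m: float = 0.05
    scenario: str = "water"
    class_fractions: dict = field(default_factory=dict)
    noise_sd: float = 0.02
    nodata_margin_px: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.gsd_m <= 0:
            raise ValueError("gsd_m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scenario not in ("water", "rust"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.class_fractions:
            self.class_fractions = dict(DEFAULT_FRACTIONS[self.scenario])
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("non-soil class fractions must sum to <= 1")


@dataclass
class MultispectralScene:
    """Georeferenced six-band reflectance raster with a validity mask.

    ``geotransform`` follows the GDAL convention
    (x0, dx, 0, y0, 0, -dy) mapping pixel (row, col) centers to world
    coordinates; here world units are degrees (lon, lat) while ``gsd_m``
    carries the metric pixel size.
    """

    bands: np.ndarray  # H x W x 6 float32, NODATA_VALUE on invalid pixels
    valid_mask: np.ndarray  # H x W bool
    geotransform: tuple
    crs_label: str = "EPSG:4326"
    nodata_value: float = NODATA_VALUE
    gsd_m: float = 0.05
    band_names: tuple = BAND_NAMES

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def band(self, name: str) -> np.ndarray:
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"scene has no band {name!r}") from None
        return self.bands[:, :, idx]

    def rgb(self) -> np.ndarray:
        """Quick true-color rendering (Red, Green, Blue bands) for overlays."""
        rgb = np.stack([self.band("red"), self.band("green"), self.band("blue")], axis=-1)
        rgb = np.where(self.valid_mask[..., None], rgb, 0.0)
        hi = max(rgb.max(), 1e-6)
        return np.clip(rgb / hi, 0.0, 1.0)


# metres per degree of latitude at mid-latitudes; used only to give the
# synthetic geotransform plausible degree steps.
_M_PER_DEG = 111_320.0
_ORIGIN_LONLAT = (33.9400, 39.3960)


def _default_geotransform(gsd_m: float) -> tuple:
    step = gsd_m / _M_PER_DEG
    x0, y0 = _ORIGIN_LONLAT
    return (x0, step, 0.0, y0, 0.0, -step)


def _row_stripe_mask(h: int, w: int, period: int = 12, veg_width: int = 8) -> np.ndarray:
    """Vertical crop-row stripes: True on vegetation rows."""
    cols = np.arange(w) % period
    return np.broadcast_to(cols < veg_width, (h, w)).copy()


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float = 24.0) -> np.ndarray:
    return ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=sigma)


def _plant_water_labels(rng, h, w, fractions) -> np.ndarray:
    """Diffuse stress patches: quantile-threshold a smoothed random field."""
    veg = _row_stripe_mask(h, w)
    labels = np.zeros((h, w), dtype=np.uint8)  # soil background
    field_ = _smooth_field(rng, h, w)
    veg_idx = np.flatnonzero(veg.ravel())
    n_total = h * w
    n_veg = veg_idx.size
    n_high = int(round(fractions.get(2, 0.0) * n_total))
    n_low = int(round(fractions.get(1, 0.0) * n_total))
    n_healthy = int(round(fractions.get(3, 0.0) * n_total))
    if n_high + n_low + n_healthy > n_veg:
        raise ValueError("requested vegetation fractions exceed the row-stripe area")
    order = veg_idx[np.argsort(field_.ravel()[veg_idx])]
    flat = labels.ravel()
    flat[order[:n_high]] = 2
    flat[order[n_high : n_high + n_low]] = 1
    flat[order[n_high + n_low :]] = 3  # remaining vegetation healthy
    return labels


def _plant_rust_labels(rng, h, w, fractions) -> np.ndarray:
    """Compact rust clusters snapped to the row stripes."""
    veg = _row_stripe_mask(h, w)
    labels = np.zeros((h, w), dtype=np.uint8)
    labels[veg] = 2  # rust3 healthy
    n_total = h * w
    n_rust_target = int(round(fractions.get(4, fractions.get(1, 0.0)) * n_total))
    if n_rust_target > int(veg.sum()):
        raise ValueError("requested rust fraction exceeds the row-stripe area")
    rust = np.zeros((h, w), dtype=bool)
    veg_rows, veg_cols = np.nonzero(veg)
    yy, xx = np.mgrid[0:h, 0:w]
    guard = 0
    while rust.sum() < n_rust_target and guard < 10_000:
        guard += 1
        i = rng.integers(veg_rows.size)
        cy, cx = veg_rows[i], veg_cols[i]
        r = rng.integers(4, 11)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        rust |= blob & veg
    labels[rust] = 1  # rust3 rust
    return labels


def generate_scene(config: SceneConfig) -> tuple[MultispectralScene, LabelMask]:
    """Generate a synthetic scene and its planted reference mask.

    The reference mask is in the scenario's native label space (water4 or
    rust3).  Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    if config.scenario == "water":
        native = _plant_water_labels(rng, h, w, config.class_fractions)
        space = WATER4
        to_mix5 = np.array([0, 1, 2, 3], dtype=np.uint8)
    else:
        native = _plant_rust_labels(rng, h, w, config.class_fractions)
        space = RUST3
        to_mix5 = np.array([0, 4, 3], dtype=np.uint8)

    mix5 = to_mix5[native]
    bands = _SIGNATURES[mix5].astype(np.float64)
    if config.noise_sd > 0:
        bands = bands + rng.normal(0.0, config.noise_sd, size=bands.shape)
    bands = np.clip(bands, 0.0, 1.0)

    valid = np.ones((h, w), dtype=bool)
    m = config.nodata_margin_px
    if m > 0:
        valid[:m, :] = valid[-m:, :] = False
        valid[:, :m] = valid[:, -m:] = False
    bands = np.where(valid[..., None], bands, NODATA_VALUE).astype(np.float32)

    labels = native.copy()
    labels[~valid] = IGNORE_LABEL
    scene = MultispectralScene(
        bands=bands,
        valid_mask=valid,
        geotransform=_default_geotransform(config.gsd_m),
        gsd_m=config.gsd_m,
    )
    return scene, LabelMask(labels, space, valid_mask=valid)


def write_scene(scene: MultispectralScene, tif_path, config: SceneConfig | None = None) -> None:
    """Write the scene as a six-band float32 TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) carries geotransform, CRS, NoData value,
    band names, GSD, and — when given — the generating SceneConfig.
    """
    tif_path = str(tif_path)
    tifffile.imwrite(tif_path, np.moveaxis(scene.bands, -1, 0))
    meta = {
        "geotransform": list(scene.geotransform),
        "crs_label": scene.crs_label,
        "nodata_value": scene.nodata_value,
        "gsd_m": scene.gsd_m,
        "band_names": list(scene.band_names),
    }
    if config is not None:
        meta["scene_config"] = asdict(config)
    with open(tif_path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_scene(tif_path) -> MultispectralScene:
    tif_path = str(tif_path)
    bands = np.moveaxis(tifffile.imread(tif_path), 0, -1).astype(np.float32)
    with open(tif_path + ".json") as fh:
        meta = json.load(fh)
    nodata = float(meta["nodata_value"])
    valid = np.all(np.isfinite(bands) & (bands != nodata), axis=-1)
    return MultispectralScene(
        bands=bands,
        valid_mask=valid,
        geotransform=tuple(meta["geotransform"]),
        crs_label=meta["crs_label"],
        nodata_value=nodata,
        gsd_m=float(meta["gsd_m"]),
        band_names=tuple(meta["band_names"]),
    )
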