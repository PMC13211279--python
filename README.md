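# cropstress

Crop-stress segmentation for six-band UAV multispectral orthomosaics:
rule-based ground-truth generation from vegetation indices, a multi-head
nested-skip segmentation network (WF-UNet++) with edge and signed-distance
auxiliary supervision, fractional-order anisotropic diffusion (FPDE)
refinement of the class probability maps, blended sliding-window inference,
and field-scale stress-zone summaries.

The package is written for precision-agriculture researchers who need a
reproducible pipeline from raw reflectance rasters to per-pixel stress maps
and actionable zone tables, without hand annotation: labels come from index
rules, and every stage is testable against a seeded synthetic-scene
generator with known class layouts.

## The method

Five classes are segmented: soil, low water stress, high water stress,
healthy vegetation, rust disease.

**Labeling.** SAVI = (NIR−Red)(1+L)/(NIR+Red+L+ε) separates plants from
soil (Otsu threshold for the water task, 1-D 2-means for the rust task).
Water stress: a second Otsu threshold on NDRE = (NIR−RedEdge)/(NIR+RedEdge+ε)
finds stressed candidates, which 2-means on (NDVI, GCI) splits into low and
high stress (higher mean NDVI → low). Rust: each of NDRE, NDVI and
SR = NIR/(Red+ε) votes where a plant pixel falls below that index's
plant-region median; ≥ 2 votes → rust, followed by morphological cleaning.

**Network.** A UNet++ lattice X(i,j) = block(concat(X(i,0..j−1),
up(X(i+1,j−1)))) of Conv–BN–ReLU blocks, optionally augmented with Haar
wavelet detail bands, with three heads on the full-resolution node:
softmax segmentation (K = 5), sigmoid edge probability, and tanh-bounded
signed-distance regression. The loss is
λ_seg(L_WCE + L_Dice) + λ_edge L_BCE + λ_sdt L_L1.

**FPDE refinement.** Probability channels are diffused by an edge-stopping
multi-scale Perona–Malik update u ← u + λ Σ_m w_m(α) ∇·(c(‖∇u‖)∇u)_m with
power-law scale weights w_m ∝ m^(−α) (α = 1.3, T = 2 iterations), clipped
and renormalized to the simplex each iteration. During training the
refinement is phased in by an epoch-linear curriculum gate; at inference it
runs per window before overlap-averaged blending. Everything — including
the refinement — is differentiable on the package's own numpy autograd
engine (`cropstress.nn`).

## Worked example

```python
from cropstress.experiments import run_synthetic_benchmark

res = run_synthetic_benchmark(seed=42)
print(f"water labeling recovery : {res['water_label_recovery']:.4f}")
print(f"rust  labeling recovery : {res['rust_label_recovery']:.4f}")
print(f"validation mIoU         : {res['val_miou']:.4f}")
print(f"validation mIoU + FPDE  : {res['val_miou_fpde']:.4f}")
print(f"fragmentation raw/FPDE  : {res['fragmentation_raw']}/{res['fragmentation_fpde']}")
```

prints (≈4 minutes on one CPU):

```
water labeling recovery : 1.0000
rust  labeling recovery : 0.9922
validation mIoU         : 0.9625
validation mIoU + FPDE  : 0.9631
fragmentation raw/FPDE  : 117/110
```

Reading the numbers: the index-rule labeling recovers the planted water
layout exactly and 99.2% of the rust layout on noise-free 512×512 scenes
(the deficit is cleaning of single-pixel cluster fringes). A reduced
WF-UNet++ (depth 3, 16 base filters) trained 15 epochs on the noisy scenes
reaches 0.96 validation mIoU; switching FPDE refinement on at inference
does not cost accuracy (+0.0006 mIoU) while reducing the number of
connected stress components from 117 to 110, i.e. spatially more coherent
maps.

The same pipeline is scriptable from the shell:

```
cropstress simulate --out-dir work/scene --scenario rust --seed 42
cropstress label    --scene work/scene/rust_scene.tif --scenario rust --out-dir work/labels
cropstress patchify --scene work/scene/rust_scene.tif --mask work/labels/rust_mask_mix5.png \
                    --scenario rust --out-dir work/patches --tile 64 --stride 64
cropstress train    --patch-dir work/patches --out-dir work/run --epochs 15 --depth 3 --base-filters 16
cropstress predict  --scene work/scene/rust_scene.tif --checkpoint work/run/checkpoint.npz --out-dir work/pred --tile 64 --stride 32
cropstress evaluate --pred work/pred/prediction_mix5.png --gt work/labels/rust_mask_mix5.png --out work/metrics.json
cropstress zones    --pred work/pred/prediction_mix5.png --scene work/scene/rust_scene.tif \
                    --target-class 4 --out-dir work/zones
```

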