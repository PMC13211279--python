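"""Multi-task losses, curriculum gating, balanced sampling, and training.

The total objective is

    L_total = lambda_seg (L_WCE + L_Dice) + lambda_edge L_edge + lambda_sdt L_sdt

with class-weighted cross-entropy and Dice on the (possibly FPDE-refined
and curriculum-blended) segmentation probabilities, binary cross-entropy
on the edge head, and L1 on the signed-distance head.  FPDE refinement is
phased in by the epoch gate g(e): off before ``e_start``, ramping
linearly over ``e_ramp`` epochs, then fully on; the refined and raw
probability maps are blended as (1-g) raw + g refined, which keeps the
output on the simplex and gradients flowing through the refinement.

Batch construction: PatchBalance draws half of the samples from the
above-median foreground-ratio pool so foreground-bearing patches make up
at least half the stream; BalancedMix alternates draws evenly between the
water and rust sources regardless of their dataset share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cropstress.fpde import FPDEConfig, fpde_refine
from cropstress.masks import IGNORE_LABEL
from cropstress.model import ModelConfig, WFUNetPP, NetworkOutputs
from cropstress.nn import Tensor, Adam, ReduceLROnPlateau
from cropstress.patches import PatchRecord
from cropstress.targets import make_aux_targets, DEFAULT_TAU

# Ablation variants: cumulative component toggles.
VARIANTS = {
    "A": set(),
    "B": {"wavelet"},
    "C": {"wavelet", "edge"},
    "D": {"wavelet", "edge", "sdt"},
    "E": {"wavelet", "edge", "sdt", "fpde"},
    "F": {"wavelet", "edge", "sdt", "fpde", "curriculum"},
    "G": {"wavelet", "edge", "sdt", "fpde", "curriculum", "patchbalance"},
    "H": {"wavelet", "edge", "sdt", "fpde", "curriculum", "patchbalance", "balancedmix"},
}


@dataclass
class LossWeights:
    lambda_seg: float = 1.0
    lambda_edge: float = 0.5
    lambda_sdt: float = 0.5
    class_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda_seg <= 0:
            raise ValueError("lambda_seg must be positive")
        if min(self.lambda_edge, self.lambda_sdt) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class CurriculumSchedule:
    e_start: int = 20
    e_ramp: int = 20

    def __post_init__(self) -> None:
        if self.e_start < 0 or self.e_ramp < 1:
            raise ValueError("e_start must be >= 0 and e_ramp >= 1")


@dataclass
class TrainConfig:
    lr: float = 0.002
    batch: int = 4
    epochs: int = 80
    seed: int = 42
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    lr_min: float = 1e-6
    variant: str = "H"
    fpde: FPDEConfig = field(default_factory=FPDEConfig)
    schedule: CurriculumSchedule = field(default_factory=CurriculumSchedule)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    sdt_tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


def model_config_for_variant(variant: str, in_channels: int = 6, depth: int = 4,
                             base_filters: int = 32, seed: int = 42) -> ModelConfig:
    toggles = VARIANTS[variant]
    return ModelConfig(
        in_channels=in_channels,
        depth=depth,
        base_filters=base_filters,
        wavelet_enabled="wavelet" in toggles,
        edge_head="edge" in toggles,
        sdt_head="sdt" in toggles,
        seed=seed,
    )


# -- curriculum --------------------------------------------------------------


def curriculum_gate(epoch: int, schedule: CurriculumSchedule) -> float:
    """Piecewise-linear gate: 0 before e_start, ramp to 1 over e_ramp epochs."""
    if epoch < schedule.e_start:
        return 0.0
    if epoch < schedule.e_start + schedule.e_ramp:
        return (epoch - schedule.e_start) / schedule.e_ramp
    return 1.0


def blend_refined(p_raw, p_refined, g: float):
    """Convex blend (1-g) raw + g refined; preserves the simplex."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("gate must be in [0, 1]")
    if p_raw.shape != p_refined.shape:
        raise ValueError("shape mismatch between raw and refined maps")
    if g == 0.0:
        return p_raw
    if g == 1.0:
        return p_refined
    return (1.0 - g) * p_raw + g * p_refined


# -- losses ------------------------------------------------------------------

_LOG_EPS = 1e-7


def _onehot(labels: np.ndarray, num_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """One-hot (N, K, H, W) plus valid-pixel mask; ignore pixels are all-zero."""
    valid = labels != IGNORE_LABEL
    safe = np.where(valid, labels, 0)
    onehot = np.eye(num_classes)[safe]  # N, H, W, K
    onehot = np.moveaxis(onehot, -1, 1) * valid[:, None, :, :]
    return onehot, valid


def weighted_ce(probs: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted cross-entropy, averaged over counted (valid) pixels."""
    K = probs.shape[1]
    w = np.ones(K) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    onehot, valid = _onehot(labels, K)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid pixels to average over")
    logp = probs.clip(_LOG_EPS, 1.0).log()
    weighted = Tensor(onehot * w[None, :, None, None])
    return -1.0 / n * (weighted * logp).sum()


def dice_loss(probs: Tensor, labels: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice with sums over pixels and classes jointly."""
    K = probs.shape[1]
    onehot, valid = _onehot(labels, K)
    vmask = Tensor(valid[:, None, :, :].astype(np.float64))
    p = probs * vmask
    target = Tensor(onehot)
    inter = (p * target).sum()
    denom = target.sum() + p.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def edge_bce(edge_probs: Tensor, edge_target: np.ndarray, valid: np.ndarray | None = None) -> Tensor:
    """Pixel-mean binary cross-entropy on the edge head."""
    t = np.asarray(edge_target, dtype=np.float64)
    if valid is None:
        valid = np.ones_like(t, dtype=bool)
    n = int(valid.sum())
    p = edge_probs.clip(_LOG_EPS, 1.0 - _LOG_EPS)
    vm = Tensor(valid.astype(np.float64))
    tt = Tensor(t)
    ll = tt * p.log() + (1.0 - tt) * (1.0 - p).log()
    return -1.0 / n * (ll * vm).sum()


def sdt_l1(sdt_pred: Tensor, sdt_target: np.ndarray, valid: np.ndarray | None = None) -> Tensor:
    """Pixel-mean absolute error on the signed-distance head."""
    t = Tensor(np.asarray(sdt_target, dtype=np.float64))
    if valid is None:
        valid = np.ones(sdt_target.shape, dtype=bool)
    n = int(valid.sum())
    vm = Tensor(valid.astype(np.float64))
    return 1.0 / n * (((sdt_pred - t).abs()) * vm).sum()


def total_loss(parts: dict, weights: LossWeights) -> Tensor:
    """lambda_seg (L_WCE + L_Dice) + lambda_edge L_edge + lambda_sdt L_sdt."""
    loss = weights.lambda_seg * (parts["wce"] + parts["dice"])
    if parts.get("edge") is not None and weights.lambda_edge > 0:
        loss = loss + weights.lambda_edge * parts["edge"]
    if parts.get("sdt") is not None and weights.lambda_sdt > 0:
        loss = loss + weights.lambda_sdt * parts["sdt"]
    return loss


def class_weight_estimate(masks, num_classes: int = 5) -> np.ndarray:
    """Inverse pixel-frequency weights, normalized to mean 1 over present classes."""
    counts = np.zeros(num_classes, dtype=np.float64)
    for m in masks:
        labels = m.mask if isinstance(m, PatchRecord) else np.asarray(m)
        valid = labels != IGNORE_LABEL
        counts += np.bincount(labels[valid].ravel(), minlength=num_classes)[:num_classes]
    present = counts > 0
    if not present.any():
        raise ValueError("no labeled pixels")
    raw = np.zeros(num_classes)
    raw[present] = 1.0 / counts[present]
    raw /= raw[present].mean()
    return raw


# -- balanced sampling -------------------------------------------------------


def balanced_batches(records: list[PatchRecord], batch_size: int, seed: int,
                     epoch: int = 0, patch_balance: bool = True,
                     balanced_mix: bool = True) -> list[list[int]]:
    """Seeded batch index stream with PatchBalance and BalancedMix applied."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng([seed, epoch])
    sources = sorted({r.source for r in records})
    if balanced_mix and len(sources) < 2:
        warnings.warn("only one source present; BalancedMix falls back to single-source")
        balanced_mix = False

    pools: dict[str, dict[str, np.ndarray]] = {}
    groups = {s: [i for i, r in enumerate(records) if r.source == s] for s in sources} \
        if balanced_mix else {"all": list(range(len(records)))}
    for key, idx in groups.items():
        fg = np.array([records[i].fg_ratio for i in idx])
        med = np.median(fg)
        high = [i for i, f in zip(idx, fg) if f > med]
        pools[key] = {"all": np.array(idx), "high": np.array(high if high else idx)}

    keys = list(pools)
    n_batches = max(1, len(records) // batch_size)
    batches = []
    for _ in range(n_batches):
        batch = []
        for _ in range(batch_size):
            pool = pools[keys[rng.integers(len(keys))]]
            use_high = patch_balance and rng.random() < 0.5
            group = pool["high"] if use_high else pool["all"]
            batch.append(int(group[rng.integers(group.size)]))
        batches.append(batch)
    return batches


# -- training loop -----------------------------------------------------------


def _stack_batch(records: list[PatchRecord], idx: list[int]):
    imgs = np.stack([np.moveaxis(records[i].image, -1, 0) for i in idx]).astype(np.float64)
    labels = np.stack([records[i].mask for i in idx])
    return imgs, labels


def forward_with_refinement(model: WFUNetPP, x, config: TrainConfig, epoch: int):
    """Forward pass with gated FPDE refinement of the probability maps."""
    toggles = VARIANTS[config.variant]
    out: NetworkOutputs = model(x)
    probs = out.probs
    if "fpde" in toggles and config.fpde.iters > 0:
        g = curriculum_gate(epoch, config.schedule) if "curriculum" in toggles else 1.0
        if g > 0:
            refined = fpde_refine(probs, config.fpde)
            probs = blend_refined(probs, refined, g)
    return out, probs


def _compute_losses(out: NetworkOutputs, probs, labels, config: TrainConfig,
                    class_w: np.ndarray) -> dict:
    valid = labels != IGNORE_LABEL
    parts = {
        "wce": weighted_ce(probs, labels, class_w),
        "dice": dice_loss(probs, labels),
        "edge": None,
        "sdt": None,
    }
    if out.edge_probs is not None:
        edge_t = np.stack([make_aux_targets(m, config.sdt_tau).edge for m in labels])
        parts["edge"] = edge_bce(out.edge_probs, edge_t, valid)
    if out.sdt_pred is not None:
        sdt_t = np.stack([make_aux_targets(m, config.sdt_tau).sdt for m in labels])
        parts["sdt"] = sdt_l1(out.sdt_pred, sdt_t, valid)
    return parts


def evaluate_patches(model: WFUNetPP, records: list[PatchRecord], config: TrainConfig,
                     epoch: int, class_w: np.ndarray, batch_size: int = 8):
    """Validation loss and mIoU over a patch list (eval mode, no gradients)."""
    from cropstress.inference import confusion_matrix_counts, metrics_from_confusion

    model.eval()
    total, n = 0.0, 0
    K = model.config.num_classes
    conf = np.zeros((K, K), dtype=np.int64)
    for start in range(0, len(records), batch_size):
        idx = list(range(start, min(start + batch_size, len(records))))
        x, labels = _stack_batch(records, idx)
        out, probs = forward_with_refinement(model, x, config, epoch)
        parts = _compute_losses(out, probs, labels, config, class_w)
        loss = total_loss(parts, config.loss_weights)
        total += float(loss.data) * len(idx)
        n += len(idx)
        pred = np.argmax(probs.data, axis=1).astype(np.uint8)
        for p, t in zip(pred, labels):
            conf += confusion_matrix_counts(p, t, K)
    model.train()
    report = metrics_from_confusion(conf)
    return total / max(n, 1), report


def train(model: WFUNetPP, records: list[PatchRecord], config: TrainConfig | None = None,
          verbose: bool = False):
    """Train on the 'train' split, validate per epoch, keep the best-mIoU weights.

    Returns (best, history): ``best`` holds the state dict, epoch, and
    validation mIoU of the checkpointed epoch; ``history`` is one row per
    epoch with losses, mIoU, learning rate, and gate value.
    """
    config = config or TrainConfig()
    toggles = VARIANTS[config.variant]
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "val"]
    if not train_recs or not val_recs:
        raise ValueError("need non-empty train and val splits")
    class_w = class_weight_estimate(train_recs, model.config.num_classes)

    optimizer = Adam(model.parameters(), lr=config.lr)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                  patience=config.plateau_patience, min_lr=config.lr_min)
    history: list[dict] = []
    best = {"state": model.state_dict(), "epoch": -1, "val_miou": -1.0}
    for epoch in range(config.epochs):
        model.train()
        batches = balanced_batches(
            train_recs, config.batch, config.seed, epoch,
            patch_balance="patchbalance" in toggles,
            balanced_mix="balancedmix" in toggles,
        )
        epoch_loss, n_seen = 0.0, 0
        for batch_idx in batches:
            x, labels = _stack_batch(train_recs, batch_idx)
            out, probs = forward_with_refinement(model, x, config, epoch)
            parts = _compute_losses(out, probs, labels, config, class_w)
            loss = total_loss(parts, config.loss_weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch_idx)
            n_seen += len(batch_idx)
        val_loss, val_report = evaluate_patches(model, val_recs, config, epoch, class_w)
        scheduler.step(val_loss)
        gate = curriculum_gate(epoch, config.schedule) if "curriculum" in toggles else (
            1.0 if "fpde" in toggles else 0.0
        )
        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_seen, 1),
            "val_loss": val_loss,
            "val_miou": val_report.miou,
            "val_fg_iou": val_report.fg_iou,
            "lr": optimizer.lr,
            "gate": gate,
        }
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d}  train {row['train_loss']:.4f}  "
                f"val {val_loss:.4f}  mIoU {val_report.miou:.4f}  lr {optimizer.lr:.2e}"
            )
        if val_report.miou > best["val_miou"]:
            best = {"state": model.state_dict(), "epoch": epoch, "val_miou": val_report.miou}
    model.load_state_dict(best["state"])
    return best, history
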