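"""Losses, curriculum gate, class weights, balanced sampling, training smoke."""

import numpy as np
import pytest

from cropstress.fpde import FPDEConfig
from cropstress.masks import IGNORE_LABEL
from cropstress.model import ModelConfig, build_model
from cropstress.nn import Tensor
from cropstress.patches import PatchRecord
from cropstress.training import (
    CurriculumSchedule,
    LossWeights,
    TrainConfig,
    balanced_batches,
    blend_refined,
    class_weight_estimate,
    curriculum_gate,
    dice_loss,
    edge_bce,
    sdt_l1,
    total_loss,
    train,
    weighted_ce,
)


# -- curriculum --------------------------------------------------------------


def test_curriculum_gate_piecewise_form_exhaustive():
    sched = CurriculumSchedule(e_start=20, e_ramp=20)
    for e in range(120):
        if e < 20:
            expect = 0.0
        elif e < 40:
            expect = (e - 20) / 20
        else:
            expect = 1.0
        assert curriculum_gate(e, sched) == pytest.approx(expect)
    gates = [curriculum_gate(e, sched) for e in range(120)]
    assert (np.diff(gates) >= 0).all()
    assert curriculum_gate(30, sched) == pytest.approx(0.5)
    assert curriculum_gate(40, sched) == 1.0


def test_blend_endpoints_and_midpoint(rng):
    a = rng.random((4, 4, 3))
    a /= a.sum(-1, keepdims=True)
    b = rng.random((4, 4, 3))
    b /= b.sum(-1, keepdims=True)
    assert blend_refined(a, b, 0.0) is a
    assert blend_refined(a, b, 1.0) is b
    mid = blend_refined(a, b, 0.5)
    assert np.allclose(mid, (a + b) / 2)
    assert np.allclose(mid.sum(-1), 1.0)
    with pytest.raises(ValueError):
        blend_refined(a, b[:2], 0.5)


# -- losses ------------------------------------------------------------------


def _probs_from(p):
    return Tensor(np.asarray(p, dtype=np.float64))


def test_weighted_ce_single_pixel_hand_case():
    probs = _probs_from(np.array([0.5, 0.25, 0.25]).reshape(1, 3, 1, 1))
    labels = np.zeros((1, 1, 1), dtype=np.uint8)
    w = np.array([2.0, 1.0, 1.0])
    loss = weighted_ce(probs, labels, w)
    assert float(loss.data) == pytest.approx(2 * np.log(2), abs=1e-9)


def test_weighted_ce_perfect_prediction_zero():
    probs = _probs_from(np.array([1.0, 0.0, 0.0]).reshape(1, 3, 1, 1))
    labels = np.zeros((1, 1, 1), dtype=np.uint8)
    assert float(weighted_ce(probs, labels).data) == pytest.approx(0.0, abs=1e-5)


def test_weighted_ce_linear_in_weights(rng):
    probs = Tensor(np.moveaxis(rng.dirichlet(np.ones(5), size=(2, 4, 4)), -1, 1))
    labels = rng.integers(0, 5, (2, 4, 4)).astype(np.uint8)
    w = rng.random(5) + 0.5
    l1 = float(weighted_ce(probs, labels, w).data)
    l2 = float(weighted_ce(probs, labels, w / 2).data)
    assert l2 == pytest.approx(l1 / 2)


def test_weighted_ce_ignores_invalid_pixels(rng):
    probs = Tensor(np.moveaxis(rng.dirichlet(np.ones(3), size=(1, 2, 2)), -1, 1))
    labels = np.array([[[0, IGNORE_LABEL], [1, IGNORE_LABEL]]], dtype=np.uint8)
    loss = weighted_ce(probs, labels)
    manual = -(np.log(probs.data[0, 0, 0, 0]) + np.log(probs.data[0, 1, 1, 0])) / 2
    assert float(loss.data) == pytest.approx(manual)


def test_dice_loss_full_and_zero_overlap():
    onehot = np.zeros((1, 2, 2, 2))
    onehot[0, 0] = 1.0
    labels = np.zeros((1, 2, 2), dtype=np.uint8)
    perfect = dice_loss(_probs_from(onehot), labels, eps=1e-3)
    assert float(perfect.data) == pytest.approx(0.0, abs=1e-3)
    wrong = np.zeros((1, 2, 2, 2))
    wrong[0, 1] = 1.0
    disjoint = dice_loss(_probs_from(wrong), labels, eps=1e-3)
    assert float(disjoint.data) == pytest.approx(1.0, abs=1e-3)


def test_dice_loss_hand_case():
    # two pixels, two classes: p = [0.8, 0.2] truth 0; p = [0.4, 0.6] truth 1
    probs = np.array([[0.8, 0.4], [0.2, 0.6]]).reshape(1, 2, 1, 2)
    labels = np.array([[[0, 1]]], dtype=np.uint8)
    eps = 1.0
    expect = 1 - (2 * (0.8 + 0.6) + eps) / (2 + 2 + eps)
    assert float(dice_loss(_probs_from(probs), labels, eps=eps).data) == pytest.approx(expect)


def test_edge_bce_values():
    t = np.array([[0.0, 1.0]])
    half = edge_bce(Tensor(np.full((1, 2), 0.5)), t)
    assert float(half.data) == pytest.approx(np.log(2))
    exact = edge_bce(Tensor(t.copy()), t)
    assert float(exact.data) == pytest.approx(0.0, abs=1e-5)
    # symmetry under complementing both prediction and target
    p = np.array([[0.3, 0.8]])
    a = float(edge_bce(Tensor(p), t).data)
    b = float(edge_bce(Tensor(1 - p), 1 - t).data)
    assert a == pytest.approx(b)


def test_sdt_l1_constant_offset(rng):
    target = rng.uniform(-1, 1, (2, 8, 8))
    pred = Tensor(target + 0.3)
    assert float(sdt_l1(pred, target).data) == pytest.approx(0.3)
    assert float(sdt_l1(Tensor(target.copy()), target).data) == 0.0
    # matches an explicit loop
    p = rng.uniform(-1, 1, (1, 3, 3))
    t = rng.uniform(-1, 1, (1, 3, 3))
    manual = np.mean([abs(p[0, i, j] - t[0, i, j]) for i in range(3) for j in range(3)])
    assert float(sdt_l1(Tensor(p), t).data) == pytest.approx(manual, abs=1e-12)


def test_total_loss_weighted_sum_and_linearity():
    parts = {"wce": Tensor(np.array(1.0)), "dice": Tensor(np.array(1.0)),
             "edge": Tensor(np.array(1.0)), "sdt": Tensor(np.array(1.0))}
    w = LossWeights(lambda_seg=1.0, lambda_edge=0.5, lambda_sdt=0.5)
    assert float(total_loss(parts, w).data) == pytest.approx(3.0)
    w2 = LossWeights(lambda_seg=2.0, lambda_edge=1.0, lambda_sdt=1.0)
    assert float(total_loss(parts, w2).data) == pytest.approx(6.0)
    parts_zero = {k: Tensor(np.array(0.0)) for k in parts}
    assert float(total_loss(parts_zero, w).data) == 0.0
    no_aux = {"wce": Tensor(np.array(0.7)), "dice": Tensor(np.array(0.3)),
              "edge": None, "sdt": None}
    assert float(total_loss(no_aux, w).data) == pytest.approx(1.0)


def test_class_weight_estimate_hand_case():
    labels = np.concatenate([np.zeros(100), np.ones(50), np.full(50, 2)]).astype(np.uint8)
    w = class_weight_estimate([labels.reshape(1, -1)], num_classes=3)
    assert np.allclose(w, [0.6, 1.2, 1.2])


def test_class_weight_balanced_gives_ones():
    labels = np.repeat(np.arange(5), 20).astype(np.uint8)
    w = class_weight_estimate([labels.reshape(1, -1)], num_classes=5)
    assert np.allclose(w, 1.0)


# -- sampling ----------------------------------------------------------------


def _fake_records(n_water, n_rust, rng):
    recs = []
    for i in range(n_water + n_rust):
        src = "water" if i < n_water else "rust"
        recs.append(PatchRecord(
            image=np.zeros((8, 8, 6), dtype=np.float32),
            mask=np.zeros((8, 8), dtype=np.uint8),
            origin_rc=(0, i), source=src, fg_ratio=float(rng.random()), split="train"))
    return recs


def test_balanced_batches_even_source_mix(rng):
    recs = _fake_records(90, 10, rng)
    counts = {"water": 0, "rust": 0}
    n_draws = 0
    for epoch in range(100):
        for batch in balanced_batches(recs, 4, seed=0, epoch=epoch):
            assert len(batch) == 4
            for i in batch:
                counts[recs[i].source] += 1
                n_draws += 1
    frac_rust = counts["rust"] / n_draws
    se = np.sqrt(0.25 / n_draws)
    assert abs(frac_rust - 0.5) < 4 * se


def test_balanced_batches_oversample_foreground(rng):
    recs = _fake_records(50, 50, rng)
    med = np.median([r.fg_ratio for r in recs])
    high = 0
    total = 0
    for epoch in range(50):
        for batch in balanced_batches(recs, 4, seed=1, epoch=epoch):
            for i in batch:
                high += recs[i].fg_ratio > med
                total += 1
    assert high / total >= 0.5 - 3 * np.sqrt(0.25 / total)


def test_balanced_batches_deterministic(rng):
    recs = _fake_records(10, 10, rng)
    b1 = balanced_batches(recs, 4, seed=9, epoch=2)
    b2 = balanced_batches(recs, 4, seed=9, epoch=2)
    assert b1 == b2
    assert b1 != balanced_batches(recs, 4, seed=9, epoch=3)


def test_balanced_batches_single_source_warns(rng):
    recs = _fake_records(8, 0, rng)
    with pytest.warns(UserWarning):
        batches = balanced_batches(recs, 4, seed=0)
    assert all(len(b) == 4 for b in batches)


# -- training loop smoke -----------------------------------------------------


def _toy_records(rng, n=10, size=16):
    """Trivially separable patches: class = f(one informative channel)."""
    recs = []
    for i in range(n):
        labels = rng.integers(0, 5, (size, size)).astype(np.uint8)
        img = np.zeros((size, size, 6), dtype=np.float32)
        for k in range(5):
            img[labels == k] = k / 4.0
        img += rng.normal(0, 0.01, img.shape).astype(np.float32)
        recs.append(PatchRecord(np.clip(img, 0, 1), labels, (0, 0),
                                "water" if i % 2 else "rust",
                                fg_ratio=0.5, split="train" if i >= 2 else "val"))
    return recs


def test_train_smoke_two_epochs(rng):
    recs = _toy_records(rng)
    model = build_model(ModelConfig(in_channels=6, depth=2, base_filters=4, seed=0))
    cfg = TrainConfig(epochs=2, batch=4, variant="H",
                      fpde=FPDEConfig(iters=1),
                      schedule=CurriculumSchedule(e_start=0, e_ramp=1))
    best, history = train(model, recs, cfg)
    assert len(history) == 2
    assert {"epoch", "train_loss", "val_loss", "val_miou", "lr", "gate"} <= set(history[0])
    assert history[0]["gate"] == 0.0 and history[1]["gate"] == 1.0
    assert 0 <= best["val_miou"] <= 1
    # training loss is finite and positive
    assert np.isfinite([h["train_loss"] for h in history]).all()


def test_train_requires_both_splits(rng):
    recs = _toy_records(rng)
    for r in recs:
        r.split = "train"
    model = build_model(ModelConfig(in_channels=6, depth=2, base_filters=4, seed=0))
    with pytest.raises(ValueError):
        train(model, recs, TrainConfig(epochs=1))
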