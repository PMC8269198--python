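"""Discriminative pull/push loss: closed forms, oracle, invariances."""

import numpy as np
import pytest

from tamseg.losses import (DiscriminativeLossParams, assemble_loss,
                           discriminative_loss)
from tamseg.models import NetworkOutput
from tamseg.nn import Tensor
from tamseg.weight_maps import WeightMap


def oracle_discriminative(emb, labels, p):
    """Direct per-pixel/per-pair evaluation (independent of autodiff path)."""
    emb = np.asarray(emb, dtype=np.float64)
    e = emb.shape[0]
    ids = sorted(set(labels.ravel()) - {0})
    mus = {}
    var_terms = []
    for k in ids:
        pts = emb[:, labels == k]  # (E, n)
        mu = pts.mean(axis=1)
        mus[k] = mu
        d = np.sqrt(((pts - mu[:, None]) ** 2).sum(axis=0))
        var_terms.append(np.mean(np.maximum(0.0, d - p.delta_v) ** 2))
    var = np.mean(var_terms)
    pair_terms = []
    for i, k1 in enumerate(ids):
        for k2 in ids[i + 1:]:
            d = np.linalg.norm(mus[k1] - mus[k2])
            pair_terms.append(max(0.0, 2 * p.delta_d - d) ** 2)
    dist = np.mean(pair_terms) if pair_terms else 0.0
    reg = np.mean([np.linalg.norm(mus[k]) for k in ids])
    return p.alpha * var + p.beta * dist + p.gamma * reg


def _two_instance_labels(h=10, w=10):
    labels = np.zeros((h, w), np.int32)
    labels[1:4, 1:4] = 1
    labels[6:9, 6:9] = 2
    return labels


def test_zero_loss_when_hinges_inactive():
    """Constant per-instance embeddings far apart: both hinges inactive."""
    p = DiscriminativeLossParams(gamma=0.0)
    labels = _two_instance_labels()
    emb = np.zeros((3, 10, 10), np.float32)
    emb[0][labels == 2] = 10 * p.delta_d
    loss = discriminative_loss(emb, labels, p)
    assert loss.item() == pytest.approx(0.0, abs=1e-9)


def test_collapsed_centroids_closed_form():
    """All instances at one point: each pair contributes (2·δd)²·β."""
    p = DiscriminativeLossParams(gamma=0.0)
    for n_inst, h in [(2, 10), (3, 15)]:
        labels = np.zeros((h, 10), np.int32)
        for k in range(n_inst):
            labels[k * 5:k * 5 + 3, 2:5] = k + 1
        emb = np.full((4, h, 10), 0.7, np.float32)
        loss = discriminative_loss(emb, labels, p)
        assert loss.item() == pytest.approx(p.beta * (2 * p.delta_d) ** 2,
                                            rel=1e-5)


def test_single_instance_at_pull_margin():
    """Pixels exactly δv from the centroid: variance hinge at its boundary."""
    p = DiscriminativeLossParams(gamma=0.0)
    labels = np.zeros((1, 4), np.int32)
    labels[0, :2] = 1
    emb = np.zeros((1, 1, 4), np.float32)
    emb[0, 0, 0] = -p.delta_v
    emb[0, 0, 1] = p.delta_v  # centroid 0, both pixels at distance δv
    loss = discriminative_loss(emb, labels, p)
    assert loss.item() == pytest.approx(0.0, abs=1e-6)


def test_zero_instances_is_error():
    with pytest.raises(ValueError):
        discriminative_loss(np.zeros((2, 4, 4), np.float32),
                            np.zeros((4, 4), np.int32))


def test_oracle_agreement_random_fields(rng):
    p = DiscriminativeLossParams(delta_v=0.4, delta_d=1.2, alpha=0.9,
                                 beta=1.1, gamma=0.01)
    for _ in range(10):
        h, w = 10, 12  # ≤ 200 pixels
        labels = rng.integers(0, 5, (h, w)).astype(np.int32)
        if not (labels > 0).any():
            labels[0, 0] = 1
        emb = rng.standard_normal((5, h, w)).astype(np.float32)
        got = discriminative_loss(emb, labels, p).item()
        want = oracle_discriminative(emb, labels, p)
        assert got == pytest.approx(want, abs=1e-6)


def test_invariant_under_relabel_and_pixel_order(rng):
    p = DiscriminativeLossParams()
    labels = _two_instance_labels()
    emb = rng.standard_normal((4, 10, 10)).astype(np.float32)
    base = discriminative_loss(emb, labels, p).item()
    swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, 0))
    assert discriminative_loss(emb, swapped, p).item() == pytest.approx(
        base, rel=1e-6)
    perm = rng.permutation(100)
    labels_p = labels.ravel()[perm].reshape(10, 10)
    emb_p = emb.reshape(4, -1)[:, perm].reshape(4, 10, 10)
    assert discriminative_loss(emb_p, labels_p, p).item() == pytest.approx(
        base, rel=1e-6)


def test_gradient_matches_numeric(rng):
    p = DiscriminativeLossParams(gamma=0.01)
    labels = _two_instance_labels(6, 6)
    emb = rng.standard_normal((3, 6, 6)).astype(np.float32)
    t = Tensor(emb.copy(), requires_grad=True)
    loss = discriminative_loss(t, labels, p)
    loss.backward()
    eps = 1e-3
    num = np.zeros_like(emb)
    for idx in np.ndindex(emb.shape):
        e2 = emb.copy()
        e2[idx] += eps
        fp = discriminative_loss(e2, labels, p).item()
        e2[idx] -= 2 * eps
        fm = discriminative_loss(e2, labels, p).item()
        num[idx] = (fp - fm) / (2 * eps)
    scale = max(np.abs(num).max(), 1e-3)
    assert np.abs(t.grad - num).max() / scale < 5e-2


# ---------------------------------------------------------------------------
# loss assembly per strategy


def _output(rng, labels, emb=False):
    n = 1
    h, w = labels.shape
    scores = Tensor(rng.standard_normal((n, 2, h, w)).astype(np.float32))
    embt = Tensor(rng.standard_normal((n, 4, h, w)).astype(np.float32)) \
        if emb else None
    return NetworkOutput(class_scores=scores, embeddings=embt)


def test_vanilla_perfect_prediction_zero(rng):
    labels = _two_instance_labels()
    target = (labels > 0)
    scores = np.stack([np.where(target, -40.0, 40.0),
                       np.where(target, 40.0, -40.0)])[None].astype(np.float32)
    out = NetworkOutput(class_scores=Tensor(scores))
    assert assemble_loss("vanilla", out, labels[None]).item() < 1e-9


def test_weighted_with_unit_map_equals_vanilla(rng):
    labels = _two_instance_labels()
    out = _output(rng, labels)
    wm = WeightMap(np.ones(labels.shape, np.float32))
    a = assemble_loss("vanilla", out, labels[None]).item()
    b = assemble_loss("weighted", out, labels[None], weight_maps=[wm]).item()
    assert a == pytest.approx(b, rel=1e-6)


def test_instance_loss_dominates_its_ce_component(rng):
    labels = _two_instance_labels()
    out = _output(rng, labels, emb=True)
    ce = assemble_loss("vanilla", out, labels[None]).item()
    full = assemble_loss("instance", out, labels[None]).item()
    assert full >= ce - 1e-9


def test_missing_inputs_named(rng):
    labels = _two_instance_labels()
    with pytest.raises(ValueError, match="weight_maps"):
        assemble_loss("weighted", _output(rng, labels), labels[None])
    with pytest.raises(ValueError, match="embedding"):
        assemble_loss("instance", _output(rng, labels), labels[None])
    with pytest.raises(ValueError, match="strategy"):
        assemble_loss("bogus", _output(rng, labels), labels[None])
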