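"""IoU/Dice/Best-Dice/SBD against hand computations and brute-force oracles."""

import json

import numpy as np
import pytest

from tamseg.masks import relabel_canonical
from tamseg.metrics import (MetricReport, best_dice, dice, evaluate_dataset,
                            iou, sbd)

from conftest import random_binary_mask, random_label_mask


# ---------------------------------------------------------------------------
# brute-force oracles (set-based, independent of the implementation)

def oracle_iou(p, t):
    p = {tuple(x) for x in np.argwhere(p)}
    t = {tuple(x) for x in np.argwhere(t)}
    if not p and not t:
        return 1.0
    return len(p & t) / len(p | t)


def oracle_dice(p, t):
    p = {tuple(x) for x in np.argwhere(p)}
    t = {tuple(x) for x in np.argwhere(t)}
    if not p and not t:
        return 1.0
    return 2 * len(p & t) / (len(p) + len(t))


def oracle_best_dice(a, b):
    ids_a = sorted(set(a.ravel()) - {0})
    ids_b = sorted(set(b.ravel()) - {0})
    vals = []
    for i in ids_a:
        pa = {tuple(x) for x in np.argwhere(a == i)}
        best = 0.0
        for j in ids_b:
            pb = {tuple(x) for x in np.argwhere(b == j)}
            best = max(best, 2 * len(pa & pb) / (len(pa) + len(pb)))
        vals.append(best)
    return float(np.mean(vals))


def _mask(coords, shape=(8, 8)):
    m = np.zeros(shape, dtype=np.int32)
    for k, pts in enumerate(coords, start=1):
        for r, c in pts:
            m[r, c] = k
    return m


# ---------------------------------------------------------------------------
# hand-computed examples


def test_iou_dice_hand_examples():
    # P covers 6 pixels, T covers 4, overlap 3 -> union 7
    p = np.zeros((4, 4), bool)
    t = np.zeros((4, 4), bool)
    p.ravel()[:6] = True
    t.ravel()[3:7] = True  # overlap = pixels 3,4,5
    assert iou(p, t) == pytest.approx(3 / 7)
    assert dice(p, t) == pytest.approx(0.6)
    assert iou(p, p) == 1.0
    assert dice(t, t) == 1.0
    disjoint = np.zeros((4, 4), bool)
    disjoint.ravel()[10:12] = True
    assert iou(p, disjoint) == 0.0
    assert dice(p, disjoint) == 0.0


def test_empty_mask_conventions():
    empty = np.zeros((5, 5), bool)
    full = np.ones((5, 5), bool)
    assert iou(empty, empty) == 1.0
    assert dice(empty, empty) == 1.0
    assert iou(empty, full) == 0.0
    lab_empty = np.zeros((5, 5), int)
    lab = np.zeros((5, 5), int)
    lab[0, 0] = 1
    assert sbd(lab_empty, lab_empty) == 1.0
    assert sbd(lab_empty, lab) == 0.0
    assert sbd(lab, lab_empty) == 0.0
    assert best_dice(lab, lab_empty) == 0.0
    with pytest.raises(ValueError):
        best_dice(lab_empty, lab)


def test_shape_mismatch_reports_both_shapes():
    with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
        iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def test_best_dice_non_commutative_example():
    """One shared instance plus a spurious extra: BD=1 one way, 0.5 back."""
    a = _mask([[(0, 0), (0, 1), (0, 2)]])
    b = _mask([[(0, 0), (0, 1), (0, 2)], [(5, 5), (5, 6)]])
    assert best_dice(a, b) == pytest.approx(1.0)
    assert best_dice(b, a) == pytest.approx(0.5)
    assert sbd(a, b) == pytest.approx(0.5)
    assert sbd(a, b) == sbd(b, a)


def test_best_dice_two_instance_example():
    """A1 (4px) vs B1 (3px inside); A2 (2px) vs B2 (3px, 2 shared)."""
    a = _mask([
        [(0, 0), (0, 1), (1, 0), (1, 1)],       # A1
        [(5, 5), (5, 6)],                        # A2
    ])
    b = _mask([
        [(0, 0), (0, 1), (1, 0)],                # B1 ⊂ A1
        [(5, 5), (5, 6), (5, 7)],                # B2, 2 px shared with A2
    ])
    expected = (6 / 7 + 4 / 5) / 2
    assert best_dice(a, b) == pytest.approx(expected)
    assert expected == pytest.approx(0.8286, abs=1e-4)
    assert sbd(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# properties on randomized masks


def test_metric_oracle_agreement_randomized(rng):
    for _ in range(60):
        p = random_binary_mask(rng)
        t = random_binary_mask(rng)
        assert iou(p, t) == pytest.approx(oracle_iou(p, t), abs=1e-12)
        assert dice(p, t) == pytest.approx(oracle_dice(p, t), abs=1e-12)
        a = random_label_mask(rng)
        b = random_label_mask(rng)
        assert best_dice(a, b) == pytest.approx(oracle_best_dice(a, b), abs=1e-9)
        assert sbd(a, b) == pytest.approx(
            min(oracle_best_dice(a, b), oracle_best_dice(b, a)), abs=1e-9)


def test_dice_iou_identity_and_ordering(rng):
    for _ in range(100):
        p = random_binary_mask(rng)
        t = random_binary_mask(rng)
        i, d = iou(p, t), dice(p, t)
        assert 0.0 <= i <= d <= 1.0
        assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)


def test_sbd_symmetry_and_identity(rng):
    for _ in range(30):
        a = random_label_mask(rng)
        b = random_label_mask(rng)
        assert sbd(a, b) == pytest.approx(sbd(b, a), abs=1e-12)
        if (a > 0).any():
            assert sbd(a, a) == pytest.approx(1.0)
            assert sbd(a, relabel_canonical(a)) == pytest.approx(1.0)


def test_metrics_invariant_under_joint_translation(rng):
    a = random_label_mask(rng)
    b = random_label_mask(rng)
    for shift in [(3, 0), (0, 5), (2, 2)]:
        a2 = np.roll(a, shift, axis=(0, 1))
        b2 = np.roll(b, shift, axis=(0, 1))
        assert sbd(a2, b2) == pytest.approx(sbd(a, b), abs=1e-12)
        assert iou(a2 > 0, b2 > 0) == pytest.approx(iou(a > 0, b > 0), abs=1e-12)


# ---------------------------------------------------------------------------
# relabeling


def test_relabel_canonical():
    m = np.zeros((4, 4), np.int32)
    m[0, 0] = 7
    m[2, 2] = 42
    out = relabel_canonical(m)
    assert sorted(set(out.ravel())) == [0, 1, 2]
    assert np.array_equal(relabel_canonical(out), out)
    with pytest.raises(ValueError):
        relabel_canonical(np.array([[-1, 0]]))


# ---------------------------------------------------------------------------
# dataset-level report


def test_evaluate_dataset_and_report(tmp_path, rng):
    a = random_label_mask(rng)
    rep = evaluate_dataset([(a, a)], image_ids=["x"])
    assert rep.iou_mean == pytest.approx(100.0)
    assert rep.sbd_mean == pytest.approx(100.0)
    assert rep.iou_stdev == 0.0

    # two pairs with per-image IoU {1.0, 0.5}
    full = np.ones((4, 4), np.int32)
    half = np.zeros((4, 4), np.int32)
    half[:2] = 1
    rep2 = evaluate_dataset([(full, full), (half, full)])
    assert rep2.iou_mean == pytest.approx(75.0)

    with pytest.raises(ValueError):
        evaluate_dataset([])

    # JSON round trip preserves the report
    path = tmp_path / "report.json"
    rep2.to_json(path)
    back = MetricReport.from_json(path)
    assert back.iou_mean == pytest.approx(rep2.iou_mean)
    assert back.per_image == rep2.per_image
    row = rep2.summary_row()
    assert set(row) == {"model", "strategy", "iou_mean", "iou_stdev",
                        "sbd_mean", "sbd_stdev"}
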