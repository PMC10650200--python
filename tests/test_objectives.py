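"""Loss and metric formulas against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhunet.exceptions import ValidationError
from dhunet.objectives import (ConfusionCounts, bce_loss, confusion_counts,
                               dice_index, dice_loss, segmentation_metrics)


def brute_force_bce(y, p, eps=1e-7):
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, eps), 1 - eps)
        total += yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
    return -total / len(y)


def brute_force_dice(y, p, smooth=1e-6):
    num = 2 * sum(yi * pi for yi, pi in zip(y, p)) + smooth
    den = sum(yi * yi for yi in y) + sum(pi * pi for pi in p) + smooth
    return num / den


def brute_force_counts(y, p, thr=0.5):
    tp = fp = fn = tn = 0
    for yi, pi in zip(y, p):
        pred = pi >= thr
        if pred and yi:
            tp += 1
        elif pred:
            fp += 1
        elif yi:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestBCE:
    def test_perfect_prediction_limit(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(y, y) <= 1.1e-7

    def test_single_pixel_closed_form(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_term_by_term_summation(self, rng):
        y = (rng.random(16) > 0.5).astype(float)
        p = rng.random(16)
        assert bce_loss(y, p) == pytest.approx(brute_force_bce(y, p), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            bce_loss([1, 0], [0.5])


class TestDice:
    def test_identical_masks(self):
        y = np.array([1, 1, 0, 1], float)
        assert dice_index(y, y) == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluation(self):
        assert dice_index([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(2 / 3, abs=1e-5)
        assert dice_loss([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(1 / 3, abs=1e-5)

    def test_empty_empty_is_one(self):
        z = np.zeros(8)
        assert dice_index(z, z) == 1.0

    def test_loss_complements_index(self, rng):
        y = (rng.random(32) > 0.6).astype(float)
        p = rng.random(32)
        assert dice_loss(y, p) + dice_index(y, p) == pytest.approx(1.0, abs=1e-12)


class TestConfusion:
    def test_enumeration_example(self):
        c = confusion_counts([1, 1, 0, 0], [1.0, 0.0, 1.0, 0.0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_binarized_truth_has_no_errors(self, rng):
        p = rng.random(64)
        y = (p >= 0.5).astype(float)
        c = confusion_counts(y, p)
        assert c.fp == 0 and c.fn == 0

    def test_counts_partition_pixels(self, rng):
        c = confusion_counts((rng.random(50) > 0.5).astype(float), rng.random(50))
        assert c.total == 50

    def test_threshold_ge_convention(self):
        c = confusion_counts([1.0], [0.5])
        assert c.tp == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            confusion_counts([1.0], [0.5], threshold=1.5)


class TestSegmentationMetrics:
    def test_direct_arithmetic(self):
        rep = segmentation_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=10))
        assert rep.precision == 0.75 and rep.recall == 0.75
        assert rep.f1 == pytest.approx(0.75)

    def test_zero_over_zero_convention(self):
        rep = segmentation_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert rep.precision == 0.0 and rep.f1 == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            y = (rng.random(64) > 0.5).astype(float)
            p = rng.random(64)
            c = confusion_counts(y, p)
            tp, fp, fn, tn = brute_force_counts(y, p)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            rep = segmentation_metrics(c, pair=(y, (p >= 0.5).astype(float)))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.precision == pytest.approx(prec, abs=1e-12)
            assert rep.recall == pytest.approx(rec, abs=1e-12)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)

    def test_f1_is_harmonic_mean_of_own_fields(self, rng):
        y = (rng.random(100) > 0.3).astype(float)
        p = rng.random(100)
        rep = segmentation_metrics(confusion_counts(y, p))
        if rep.precision + rep.recall > 0:
            hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(hm, abs=1e-12)


# -- property tests ----------------------------------------------------

binary_masks = st.lists(st.integers(0, 1), min_size=1, max_size=64)


@settings(deadline=None, derandomize=True)
@given(binary_masks, st.data())
def test_dice_symmetry_for_binary_pairs(y, data):
    p = data.draw(st.lists(st.integers(0, 1), min_size=len(y), max_size=len(y)))
    assert dice_index(y, p) == pytest.approx(dice_index(p, y), abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(binary_masks, st.data())
def test_binary_dice_equals_confusion_form(y, data):
    p = data.draw(st.lists(st.integers(0, 1), min_size=len(y), max_size=len(y)))
    c = confusion_counts(np.array(y, float), np.array(p, float))
    denom = 2 * c.tp + c.fp + c.fn
    expected = 2 * c.tp / denom if denom else 1.0
    assert dice_index(y, p) == pytest.approx(expected, abs=1e-4)


@settings(deadline=None, derandomize=True)
@given(binary_masks, st.data())
def test_metric_ranges(y, data):
    p = data.draw(st.lists(st.floats(0, 1), min_size=len(y), max_size=len(y)))
    assert bce_loss(y, p) >= 0
    rep = segmentation_metrics(confusion_counts(np.array(y, float), np.array(p)))
    for v in (rep.precision, rep.recall, rep.f1, rep.dice):
        assert 0.0 <= v <= 1.0


def test_monotonicity_of_precision_and_recall():
    base = ConfusionCounts(tp=4, fp=3, fn=2, tn=7)
    fp_fixed = ConfusionCounts(tp=4, fp=2, fn=2, tn=8)   # one FP -> TN
    fn_fixed = ConfusionCounts(tp=5, fp=3, fn=1, tn=7)   # one FN -> TP
    assert segmentation_metrics(fp_fixed).precision >= \
        segmentation_metrics(base).precision
    assert segmentation_metrics(fn_fixed).recall >= \
        segmentation_metrics(base).recall
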