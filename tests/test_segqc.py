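"""Mask metrics, the quality gate (with an independent flood-fill
oracle) and gate arithmetic."""

import numpy as np
import pytest

from synthmri import segqc
from synthmri.segqc import QCReport, area_fraction_pct, dice, pass_rate, \
    pixel_accuracy, qc_gate


# ---------------------------------------------------------------------
# dice / accuracy
# ---------------------------------------------------------------------

def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


def test_dice_formula_cases():
    a = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
    assert dice(a, a) == 1.0
    b = _mask((4, 4), [(3, 3)])
    assert dice(a, b) == 0.0
    # TP=3, FP=1, FN=1 -> 6/8
    pred = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (2, 2)])
    truth = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (3, 3)])
    assert dice(pred, truth) == 0.75
    assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0


def test_accuracy_formula_cases():
    a = _mask((10, 10), [(i, j) for i in range(3) for j in range(3)])
    assert pixel_accuracy(a, a) == 1.0
    assert pixel_accuracy(a, ~a) == 0.0
    b = a.copy()
    b[9, :] = ~b[9, :]
    assert pixel_accuracy(a, b) == 0.9


def test_metrics_are_symmetric_and_validated():
    rng = np.random.default_rng(0)
    a = rng.uniform(size=(8, 8)) > 0.5
    b = rng.uniform(size=(8, 8)) > 0.5
    assert dice(a, b) == dice(b, a)
    assert pixel_accuracy(a, b) == pixel_accuracy(b, a)
    with pytest.raises(ValueError):
        dice(a, np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        pixel_accuracy(a.astype(float) * 0.5, b)


# ---------------------------------------------------------------------
# gate
# ---------------------------------------------------------------------

def _disc(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def test_gate_passes_single_large_blob_on_500px_grid():
    mask = _disc((500, 500), 250, 250, 62)     # ~12,070 px
    rep = qc_gate(mask)
    assert rep.passed and rep.n_components == 1
    assert rep.predicted_area >= 10000
    assert rep.criterion == "min_area=10000"


def test_gate_fails_two_blobs_even_when_total_area_is_enough():
    mask = _disc((500, 500), 150, 150, 62) | _disc((500, 500), 380, 380, 62)
    rep = qc_gate(mask)
    assert not rep.passed and rep.n_components == 2
    assert rep.predicted_area >= 10000


def test_gate_minimum_training_contour_passes_with_printed_fraction():
    """A 10,932-px single region passes; truncation prints 4.3 and
    round-half-up prints 4.4 for its 4.3728% fraction."""
    mask = np.zeros((500, 500), dtype=bool)
    mask[100:200, 100:209] = True            # 100*109 = 10,900
    mask[200:201, 100:132] = True            # +32 -> 10,932, attached
    assert mask.sum() == 10932
    rep = qc_gate(mask)
    assert rep.passed and rep.n_components == 1
    assert area_fraction_pct(rep.predicted_area, 500, "truncate") == 4.3
    assert area_fraction_pct(rep.predicted_area, 500, "round") == 4.4


def test_gate_interior_holes_do_not_fail():
    mask = _disc((500, 500), 250, 250, 80)
    mask[240:260, 240:260] = False           # hole
    assert qc_gate(mask).passed


def test_gate_uses_fraction_threshold_off_500px():
    small = _disc((128, 128), 64, 64, 16)    # ~804 px > 4% of 16384 = 656
    rep = qc_gate(small)
    assert rep.passed and rep.criterion.startswith("min_fraction")
    tiny = _disc((128, 128), 64, 64, 10)     # ~314 px < 656
    assert not qc_gate(tiny).passed


def test_gate_monotone_under_growth():
    """Growing a passing component without splitting it never flips
    pass -> fail."""
    mask = _disc((500, 500), 250, 250, 62)
    assert qc_gate(mask).passed
    for r in (70, 90, 120, 180):
        grown = _disc((500, 500), 250, 250, r)
        assert (mask <= grown).all()
        assert qc_gate(grown).passed
        mask = grown


def test_gate_rejects_non_binary_masks():
    with pytest.raises(ValueError):
        qc_gate(np.full((8, 8), 0.5))


def _flood_fill_components(mask: np.ndarray) -> int:
    """Brute-force 8-connected component counter (stack flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                count += 1
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and mask[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
    return count


@pytest.mark.parametrize("density", [0.2, 0.5, 0.8])
def test_gate_component_count_matches_flood_fill_oracle(density):
    rng = np.random.default_rng(int(density * 100))
    for _ in range(120):
        mask = rng.uniform(size=(32, 32)) < density
        rep = qc_gate(mask, min_area=1)
        assert rep.n_components == _flood_fill_components(mask)
        assert rep.passed == (rep.n_components == 1)


# ---------------------------------------------------------------------
# percent arithmetic
# ---------------------------------------------------------------------

@pytest.mark.parametrize("area,side,mode,expected", [
    (10932, 500, "truncate", 4.3),
    (19481, 500, "truncate", 7.7),
    (19481, 500, "round", 7.8),
    (10000, 500, "truncate", 4.0),
    (10000, 500, "round", 4.0),
])
def test_area_fraction_printed_values(area, side, mode, expected):
    assert area_fraction_pct(area, side, mode) == expected


def test_area_fraction_rejects_impossible_area():
    with pytest.raises(ValueError):
        area_fraction_pct(500 * 500 + 1, 500)


def _reports(n_pass, n_fail):
    mk = lambda p: QCReport(None, 0, 1, 0.0, p, "")
    return [mk(True)] * n_pass + [mk(False)] * n_fail


def test_pass_rate_printed_value_and_edges():
    assert pass_rate(_reports(253, 654 - 253)) == 38.6
    assert pass_rate(_reports(5, 0)) == 100.0
    assert pass_rate(_reports(1, 2)) == 33.3
    with pytest.raises(ValueError):
        pass_rate([])


# ---------------------------------------------------------------------
# segmenter plumbing (training behaviour is covered by the acceptance
# suite on the shared fixture)
# ---------------------------------------------------------------------

def test_train_rejects_insufficient_or_misshapen_input():
    cfg = segqc.SegTrainConfig(batch_size=3)
    with pytest.raises(ValueError):
        segqc.train_segmenter([(np.zeros((16, 16)), np.zeros((16, 16), bool))],
                              cfg)
    with pytest.raises(ValueError):
        segqc.SegTrainConfig(learning_rate=0.0)


def test_predict_requires_training_shape(seg_model):
    with pytest.raises(ValueError):
        segqc.predict_mask(seg_model, np.zeros((16, 16)))


def test_predict_handles_blank_input_and_is_deterministic(seg_model):
    size = seg_model.image_size
    blank = np.zeros((size, size))
    m1 = segqc.predict_mask(seg_model, blank)
    m2 = segqc.predict_mask(seg_model, blank)
    assert m1.dtype == bool and (m1 == m2).all()
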