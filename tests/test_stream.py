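"""Strided video inference: scheduling, caching, and overlay rendering."""

import math

import numpy as np
import pytest

from surgmtl import StreamConfig, process_stream, render_overlay, schedule_predictions


class CountingModel:
    """Stub whose prediction depends on the frame brightness, so cache reuse
    is observable."""

    def __init__(self, input_size=(16, 16)):
        self.calls = 0
        self.input_size = input_size

    def predict(self, image):
        self.calls += 1
        img = np.asarray(image, dtype=np.float64)
        if img.max() > 1.5:  # uint8 passthrough
            img = img / 255.0
        mask = np.zeros(self.input_size, dtype=np.uint8)
        mask[: self.input_size[0] // 2] = img.mean() > 0.5
        return mask, float(img.mean())


def stream_config(**kwargs):
    kwargs.setdefault("input_size", (16, 16))
    return StreamConfig(**kwargs)


@pytest.mark.parametrize(
    "n,k,expected",
    [(30, 30, [0]), (30, 1, list(range(30))), (10, 3, [0, 3, 6, 9]), (0, 5, [])],
)
def test_schedule_examples(n, k, expected):
    assert schedule_predictions(n, k) == expected


def test_schedule_length_is_ceil_over_grid():
    for n in range(0, 121):
        for k in range(1, 31):
            assert len(schedule_predictions(n, k)) == math.ceil(n / k)


def test_schedule_rejects_bad_stride():
    with pytest.raises(ValueError):
        schedule_predictions(10, 0)


@pytest.mark.parametrize("stride", [0, 31])
def test_stream_config_stride_bounds(stride):
    with pytest.raises(ValueError, match="stride"):
        StreamConfig(prediction_stride=stride)


def frames_of(values, size=16):
    return [np.full((size, size, 3), v, dtype=np.uint8) for v in values]


@pytest.mark.parametrize("n,k", [(30, 2), (10, 3), (7, 7), (1, 1), (12, 30)])
def test_model_invocations_are_ceil_n_over_k(n, k):
    model = CountingModel()
    out = process_stream(frames_of([100] * n), model, stream_config(prediction_stride=k))
    assert model.calls == math.ceil(n / k)
    assert len(out) == n
    assert [af.frame_index for af in out] == list(range(n))
    for af in out:
        assert af.used_cached_prediction == (af.frame_index % k != 0)


def test_cache_reuse_on_alternating_stream():
    """With k=2, odd frames repeat the annotation of the preceding even frame."""
    vals = [230, 20, 230, 20, 230, 20, 230, 20]
    out = process_stream(
        frames_of(vals), CountingModel(), stream_config(prediction_stride=2)
    )
    for i in range(1, len(out), 2):
        assert out[i].used_cached_prediction
        assert out[i].blood_percentage == out[i - 1].blood_percentage
        assert out[i].banner_shown == out[i - 1].banner_shown


def test_constant_stream_annotations_independent_of_stride():
    frames = frames_of([200] * 12)
    out1 = process_stream(frames, CountingModel(), stream_config(prediction_stride=1))
    out2 = process_stream(frames, CountingModel(), stream_config(prediction_stride=12))
    for a, b in zip(out1, out2):
        assert a.blood_percentage == b.blood_percentage
        np.testing.assert_array_equal(a.image, b.image)


def test_empty_stream_yields_empty_output():
    assert process_stream([], CountingModel(), stream_config()) == []


def test_unreadable_frame_reports_index():
    frames = [np.zeros((16, 16, 3), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8)]
    with pytest.raises(ValueError, match="index 1"):
        process_stream(frames, CountingModel(), stream_config())


def test_banner_strictly_above_threshold():
    cfg = stream_config()
    # brightness 50% exactly -> percentage 50.0 -> no banner
    mid = frames_of([128], size=16)  # 128/255 = 0.502 > 0.5; use explicit floats
    out = process_stream(
        [np.full((16, 16, 3), 127, dtype=np.uint8)], CountingModel(), cfg
    )
    assert out[0].blood_percentage < 50
    assert not out[0].banner_shown
    out_hi = process_stream(
        [np.full((16, 16, 3), 200, dtype=np.uint8)], CountingModel(), cfg
    )
    assert out_hi[0].banner_shown


def test_render_overlay_threshold_semantics():
    cfg = stream_config()
    frame = np.full((16, 16, 3), 120, dtype=np.uint8)
    empty = np.zeros((16, 16), dtype=bool)
    at_threshold = render_overlay(frame, empty, 50.0, cfg)
    np.testing.assert_array_equal(at_threshold, frame)  # P = 50 exactly: no banner
    above = render_overlay(frame, empty, 62.0, cfg)
    assert not np.array_equal(above, frame)  # banner drawn


def test_empty_mask_low_percentage_is_bit_identical_passthrough():
    cfg = stream_config()
    frame = np.arange(16 * 16 * 3, dtype=np.uint8).reshape(16, 16, 3)
    out = render_overlay(frame, np.zeros((16, 16), dtype=bool), 10.0, cfg)
    np.testing.assert_array_equal(out, frame)


def test_overlay_tints_only_mask_pixels():
    cfg = stream_config()
    frame = np.full((16, 16, 3), 100, dtype=np.uint8)
    mask = np.zeros((16, 16), dtype=bool)
    mask[2:5, 3:9] = True
    out = render_overlay(frame, mask, 0.0, cfg)
    np.testing.assert_array_equal(out[~mask], frame[~mask])
    assert (out[mask] != frame[mask]).any()
    # alpha-blend toward blue: blue channel rises, red falls
    assert out[3, 4, 2] > frame[3, 4, 2]
    assert out[3, 4, 0] < frame[3, 4, 0]


def test_mask_upscaled_to_frame_resolution():
    model = CountingModel(input_size=(16, 16))
    frames = [np.full((32, 32, 3), 220, dtype=np.uint8)]
    out = process_stream(frames, model, stream_config(prediction_stride=1))
    assert out[0].image.shape == (32, 32, 3)
    # stub masks the top half at model resolution -> top half tinted at 32x32
    assert (out[0].image[4, :, 2] > 220).all()


def test_mask_size_mismatch_rejected():
    cfg = stream_config()
    with pytest.raises(ValueError, match="match"):
        render_overlay(
            np.zeros((16, 16, 3), dtype=np.uint8), np.zeros((8, 8), dtype=bool), 0.0, cfg
        )
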