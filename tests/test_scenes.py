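"""Synthetic scene generator: determinism, label consistency, augmentation."""

import numpy as np
import pytest

from surgmtl import (
    SceneConfig,
    apply_transform,
    augment,
    dice_coefficient,
    generate_dataset,
    generate_scene,
    load_dataset,
    save_dataset,
)
from surgmtl.scenes import FLIPS, ROTATION_RANGE, draw_augmentation


def test_identical_config_and_seed_give_bit_identical_samples(tiny_scene_config):
    s1 = generate_scene(tiny_scene_config, np.random.default_rng(3))
    s2 = generate_scene(tiny_scene_config, np.random.default_rng(3))
    np.testing.assert_array_equal(s1.image, s2.image)
    np.testing.assert_array_equal(s1.tool_mask, s2.tool_mask)
    assert s1.event_label == s2.event_label
    assert s1.blood_fraction == s2.blood_fraction
    s3 = generate_scene(tiny_scene_config, np.random.default_rng(4))
    assert not np.array_equal(s1.image, s3.image)


def test_no_pools_means_no_blood(tiny_scene_config):
    config = SceneConfig(height=64, width=96, blood_pool_count=(0, 0), seed=5)
    sample = generate_scene(config, np.random.default_rng(0))
    assert sample.blood_fraction == 0.0
    assert sample.event_label == 0


def test_event_label_matches_threshold_rule(scene_batch, tiny_scene_config):
    tau = tiny_scene_config.blood_area_threshold
    for s in scene_batch:
        assert s.event_label == int(s.blood_fraction >= tau)
        assert 0.0 <= s.blood_fraction < 1.0
        assert s.tool_mask.any()  # at least one tool always rendered


def test_tool_mask_is_exact_footprint_on_flat_scene():
    """With noise and illumination off the tool pixels are exactly the mask."""
    config = SceneConfig(
        height=64, width=96, noise_sigma=0.0, illumination=0.0,
        blood_pool_count=(0, 0), seed=9,
    )
    sample = generate_scene(config, np.random.default_rng(9))
    from surgmtl.scenes import TISSUE_BASE

    background = np.all(np.isclose(sample.image, TISSUE_BASE, atol=1e-6), axis=-1)
    np.testing.assert_array_equal(~background, sample.tool_mask)


def test_dataset_sizes_and_class_balance():
    config = SceneConfig(height=64, width=96, seed=21)
    splits = generate_dataset(config, sizes=(16, 8, 8), seed=21)
    for name, samples in splits:
        assert len(samples) == {"train": 16, "val": 8, "test": 8}[name]
        labels = [s.event_label for s in samples]
        assert sum(labels) >= len(labels) / 4  # >= 25% class 1
        assert len(labels) - sum(labels) >= len(labels) / 4  # >= 25% class 0


def test_empty_sizes_give_empty_splits(tiny_scene_config):
    splits = generate_dataset(tiny_scene_config, sizes=(0, 0, 0))
    assert splits.train == [] and splits.val == [] and splits.test == []


def test_dataset_reproducible_and_seed_sensitive(tiny_scene_config):
    a = generate_dataset(tiny_scene_config, sizes=(4, 0, 0), seed=8)
    b = generate_dataset(tiny_scene_config, sizes=(4, 0, 0), seed=8)
    c = generate_dataset(tiny_scene_config, sizes=(4, 0, 0), seed=9)
    for s1, s2 in zip(a.train, b.train):
        np.testing.assert_array_equal(s1.image, s2.image)
    assert not all(
        np.array_equal(s1.image, s2.image) for s1, s2 in zip(a.train, c.train)
    )


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(blood_area_threshold=0.0),
        dict(blood_area_threshold=1.0),
        dict(height=100),  # not divisible by 16
        dict(n_tools=(2, 1)),
    ],
)
def test_invalid_scene_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SceneConfig(**kwargs)


def test_augmentation_draws_stay_in_declared_ranges():
    rng = np.random.default_rng(17)
    angles = []
    flips = set()
    for _ in range(10_000):
        angle, flip = draw_augmentation(rng)
        angles.append(angle)
        flips.add(flip)
    angles = np.array(angles)
    assert np.all(np.abs(angles) <= ROTATION_RANGE)
    assert np.abs(angles).max() > 30  # the full range is actually exercised
    assert flips == set(FLIPS)


def test_double_flip_recovers_original_exactly(scene_batch):
    sample = scene_batch[0]
    once = apply_transform(sample, 0.0, "both")
    twice = apply_transform(once, 0.0, "both")
    np.testing.assert_array_equal(twice.image, sample.image)
    np.testing.assert_array_equal(twice.tool_mask, sample.tool_mask)
    assert twice.event_label == sample.event_label


def test_mask_transforms_identically_to_image(scene_batch):
    """Independently transforming a copy of the mask gives Dice 1.0."""
    sample = scene_batch[1]
    mask_only = type(sample)(
        image=np.repeat(sample.tool_mask[..., None].astype(np.float32), 3, axis=-1),
        tool_mask=sample.tool_mask.copy(),
        event_label=sample.event_label,
        blood_fraction=sample.blood_fraction,
    )
    angle, flip = 21.5, "horizontal"
    aug = apply_transform(sample, angle, flip)
    aug_mask_copy = apply_transform(mask_only, angle, flip)
    assert dice_coefficient(aug.tool_mask, aug_mask_copy.tool_mask) == 1.0


def test_augment_does_not_mutate_input(scene_batch):
    sample = scene_batch[2]
    img_before = sample.image.copy()
    augment(sample, np.random.default_rng(0))
    np.testing.assert_array_equal(sample.image, img_before)


def test_labels_preserved_under_augmentation(scene_batch):
    rng = np.random.default_rng(3)
    for s in scene_batch[:4]:
        a = augment(s, rng)
        assert a.event_label == s.event_label
        assert a.blood_fraction == s.blood_fraction
        assert a.image.shape == s.image.shape


def test_save_load_roundtrip(tmp_path, tiny_scene_config):
    splits = generate_dataset(tiny_scene_config, sizes=(3, 2, 1), seed=2)
    save_dataset(splits, tmp_path, config=tiny_scene_config)
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "scene_config.json").exists()
    loaded = load_dataset(tmp_path)
    assert len(loaded.train) == 3 and len(loaded.val) == 2 and len(loaded.test) == 1
    for orig, back in zip(splits.train, loaded.train):
        np.testing.assert_array_equal(orig.tool_mask, back.tool_mask)
        assert orig.event_label == back.event_label
        assert back.blood_fraction == pytest.approx(orig.blood_fraction)
        # images survive 8-bit quantization
        assert np.abs(orig.image - back.image).max() <= 1.0 / 255.0 + 1e-6
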