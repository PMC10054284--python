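"""Seeded generator of laparoscopic-like scenes with paired labels.

Real surgical video of robot-assisted prostatectomy cannot be redistributed,
so every other module is exercised against a parametric scene grammar that
reproduces the *structure* of such data: a tissue-coloured background with
smooth illumination variation and texture noise, zero or more dark-red blood
pools, and one or more elongated metallic-gray instruments drawn on top
(instruments occlude blood). The ground truth is self-consistent by
construction: the tool mask is exactly the rendered instrument footprint, the
blood fraction is the visible red-pool area divided by the image area, and
the binary event label ("blood accumulation") is 1 iff that fraction reaches
the configured area threshold tau.

The module also implements the train-time augmentation: a rotation drawn
uniformly from (-35, 35) degrees combined with one of {none, horizontal,
vertical, both} flips, applied identically to image and mask.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

__all__ = [
    "SceneConfig",
    "SceneSample",
    "DatasetSplits",
    "generate_scene",
    "generate_dataset",
    "augment",
    "apply_transform",
    "draw_augmentation",
    "save_dataset",
    "load_dataset",
    "TISSUE_BASE",
    "FLIPS",
]

# flat reference colours (RGB in [0,1])
TISSUE_BASE = (0.70, 0.42, 0.40)
BLOOD_COLOR = (0.42, 0.04, 0.06)
TOOL_GRAY = 0.62

FLIPS = ("none", "horizontal", "vertical", "both")

ROTATION_RANGE = 35.0  # degrees, augmentation draws from (-35, +35)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the scene grammar.

    Geometry ranges are fractions of image dimensions so the grammar scales
    with resolution; ``blood_area_threshold`` (tau) is the visible-blood area
    fraction at or above which the event label is 1.
    """

    height: int = 160
    width: int = 240
    n_tools: tuple[int, int] = (1, 2)
    tool_length: tuple[float, float] = (0.55, 1.0)  # fraction of the diagonal
    tool_width: tuple[float, float] = (0.04, 0.09)  # fraction of min(H, W)
    blood_pool_count: tuple[int, int] = (0, 3)
    pool_radius: tuple[float, float] = (0.06, 0.16)  # semi-axis fraction of min(H, W)
    blood_area_threshold: float = 0.08
    noise_sigma: float = 0.025
    illumination: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.blood_area_threshold < 1.0:
            raise ValueError("blood_area_threshold must lie strictly in (0, 1)")
        if self.height % 16 or self.width % 16:
            raise ValueError(
                f"image size {self.height}x{self.width} must be divisible by 16 "
                "for model compatibility"
            )
        for name in ("n_tools", "blood_pool_count"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} range {lo}..{hi} is invalid")
        if self.n_tools[1] < 1:
            raise ValueError("at least one tool must be possible (n_tools upper bound >= 1)")


@dataclass
class SceneSample:
    """One rendered scene with its paired ground truth."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    tool_mask: np.ndarray  # (H, W) bool
    event_label: int  # 0 = no blood accumulation, 1 = blood accumulation
    blood_fraction: float  # visible red-pool pixels / total pixels


@dataclass
class DatasetSplits:
    train: list[SceneSample] = field(default_factory=list)
    val: list[SceneSample] = field(default_factory=list)
    test: list[SceneSample] = field(default_factory=list)

    def __iter__(self):
        yield from (("train", self.train), ("val", self.val), ("test", self.test))


def _smooth_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency field in roughly [-1, 1] for illumination variation."""
    coarse = rng.normal(0.0, 1.0, size=(max(h // 16, 2), max(w // 16, 2)))
    field_ = sk_resize(coarse, (h, w), order=3, mode="reflect", anti_aliasing=False)
    peak = np.abs(field_).max()
    return field_ / peak if peak > 0 else field_


def _tool_footprint(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """Rasterize one elongated rotated rectangle; retries degenerate draws."""
    h, w = cfg.height, cfg.width
    diag = math.hypot(h, w)
    mind = min(h, w)
    for _ in range(50):
        length = rng.uniform(*cfg.tool_length) * diag
        half_w = rng.uniform(*cfg.tool_width) * mind / 2.0
        theta = rng.uniform(0.0, math.pi)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        dy, dx = math.sin(theta), math.cos(theta)
        ny, nx = -dx, dy  # unit normal
        half_l = length / 2.0
        rows = np.array(
            [
                cy - dy * half_l - ny * half_w,
                cy - dy * half_l + ny * half_w,
                cy + dy * half_l + ny * half_w,
                cy + dy * half_l - ny * half_w,
            ]
        )
        cols = np.array(
            [
                cx - dx * half_l - nx * half_w,
                cx - dx * half_l + nx * half_w,
                cx + dx * half_l + nx * half_w,
                cx + dx * half_l - nx * half_w,
            ]
        )
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        if rr.size > 0:
            fp = np.zeros((h, w), dtype=bool)
            fp[rr, cc] = True
            return fp
    raise RuntimeError("could not draw a non-degenerate tool after 50 attempts")


def generate_scene(config: SceneConfig, rng: np.random.Generator) -> SceneSample:
    """Render one scene; a pure function of (config, rng state).

    Drawing order is background, blood pools, then tools, so instruments
    occlude blood; the blood fraction counts only visible pool pixels.
    """
    h, w = config.height, config.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = TISSUE_BASE
    if config.illumination > 0:
        img *= (1.0 + config.illumination * _smooth_field(rng, h, w))[..., None]

    pool_mask = np.zeros((h, w), dtype=bool)
    n_pools = int(rng.integers(config.blood_pool_count[0], config.blood_pool_count[1] + 1))
    mind = min(h, w)
    for _ in range(n_pools):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(*config.pool_radius) * mind
        b = rng.uniform(*config.pool_radius) * mind
        rot = rng.uniform(0.0, math.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
        pool_mask[rr, cc] = True
    img[pool_mask] = BLOOD_COLOR

    tool_mask = np.zeros((h, w), dtype=bool)
    n_tools = int(rng.integers(config.n_tools[0], config.n_tools[1] + 1))
    for _ in range(n_tools):
        fp = _tool_footprint(rng, config)
        gray = TOOL_GRAY + rng.uniform(-0.08, 0.08)
        img[fp] = (gray, gray + 0.02, gray + 0.05)  # slightly bluish metal
        tool_mask |= fp

    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)

    visible_blood = pool_mask & ~tool_mask
    blood_fraction = float(np.count_nonzero(visible_blood)) / (h * w)
    event_label = int(blood_fraction >= config.blood_area_threshold)
    return SceneSample(
        image=np.clip(img, 0.0, 1.0).astype(np.float32),
        tool_mask=tool_mask,
        event_label=event_label,
        blood_fraction=blood_fraction,
    )


def _generate_split(
    config: SceneConfig, n: int, rng: np.random.Generator, balance: bool
) -> list[SceneSample]:
    """Draw n scenes; with balancing, rejection-resample so each event class
    fills at least a quarter of the split."""
    if n == 0:
        return []
    if not balance:
        return [generate_scene(config, rng) for _ in range(n)]
    quota = math.ceil(n / 4)
    counts = [0, 0]
    samples: list[SceneSample] = []
    attempts = 0
    while len(samples) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                "class balancing failed: the scene grammar produces one event "
                "class too rarely under this configuration"
            )
        s = generate_scene(config, rng)
        c = s.event_label
        other = 1 - c
        # accept only if room remains for the other class's unmet quota
        if len(samples) + 1 + max(0, quota - counts[other]) <= n:
            samples.append(s)
            counts[c] += 1
    return samples


def generate_dataset(
    config: SceneConfig,
    sizes: tuple[int, int, int] = (200, 32, 86),
    seed: int | None = None,
) -> DatasetSplits:
    """Generate disjoint train/val/test splits, reproducible from the seed.

    Splits of size >= 8 are rejection-resampled so each event class covers at
    least 25% of the split.
    """
    if len(sizes) != 3 or any(s < 0 for s in sizes):
        raise ValueError(f"sizes must be three nonnegative counts, got {sizes}")
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(3)
    out = []
    for n, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        out.append(_generate_split(config, n, rng, balance=n >= 8))
    return DatasetSplits(train=out[0], val=out[1], test=out[2])


# ----- augmentation --------------------------------------------------------------


def draw_augmentation(rng: np.random.Generator) -> tuple[float, str]:
    """Draw (angle in degrees, flip mode) for one augmentation."""
    angle = float(rng.uniform(-ROTATION_RANGE, ROTATION_RANGE))
    flip = FLIPS[int(rng.integers(len(FLIPS)))]
    return angle, flip


def apply_transform(
    sample: SceneSample, angle: float, flip: str, fill=TISSUE_BASE
) -> SceneSample:
    """Rotate then flip image and mask with the identical geometric transform.

    Image interpolation is bilinear with exposed corners filled with the
    tissue base colour; the mask uses nearest-neighbour and is re-binarized.
    Angle 0 skips the warp entirely so pure flips are exact involutions.
    Labels are carried over unchanged.
    """
    if flip not in FLIPS:
        raise ValueError(f"flip must be one of {FLIPS}, got {flip!r}")
    img = sample.image
    mask = sample.tool_mask
    if angle != 0.0:
        img = np.stack(
            [
                sk_rotate(
                    img[..., c], angle, order=1, mode="constant",
                    cval=fill[c], preserve_range=True,
                )
                for c in range(img.shape[2])
            ],
            axis=-1,
        )
        mask = (
            sk_rotate(
                mask.astype(np.float64), angle, order=0, mode="constant",
                cval=0.0, preserve_range=True,
            )
            > 0.5
        )
    if flip in ("horizontal", "both"):
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    if flip in ("vertical", "both"):
        img = img[::-1]
        mask = mask[::-1]
    return SceneSample(
        image=np.ascontiguousarray(img, dtype=np.float32),
        tool_mask=np.ascontiguousarray(mask),
        event_label=sample.event_label,
        blood_fraction=sample.blood_fraction,
    )


def augment(sample: SceneSample, rng: np.random.Generator) -> SceneSample:
    """One random train-time augmentation: rotation in (-35, 35) degrees plus
    one of the four flip modes, drawn uniformly."""
    angle, flip = draw_augmentation(rng)
    return apply_transform(sample, angle, flip)


# ----- on-disk layout ------------------------------------------------------------


def save_dataset(splits: DatasetSplits, outdir, config: SceneConfig | None = None) -> None:
    """Export splits as PNGs plus a manifest CSV.

    Layout: ``images/<split>_<i>.png`` (RGB), ``masks/<split>_<i>.png``
    (single channel, 0=background, 255=tool), ``manifest.csv`` with columns
    filename, split, event_label, blood_fraction, and ``scene_config.json``
    when a config is given.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for split_name, samples in splits:
        for i, s in enumerate(samples):
            fname = f"{split_name}_{i:04d}.png"
            iio.imwrite(
                outdir / "images" / fname,
                (s.image * 255.0).round().astype(np.uint8),
            )
            iio.imwrite(
                outdir / "masks" / fname,
                np.where(s.tool_mask, 255, 0).astype(np.uint8),
            )
            rows.append((fname, split_name, s.event_label, repr(s.blood_fraction)))
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "split", "event_label", "blood_fraction"])
        writer.writerows(rows)
    if config is not None:
        (outdir / "scene_config.json").write_text(json.dumps(asdict(config), indent=2))


def load_dataset(indir) -> DatasetSplits:
    """Load a directory written by :func:`save_dataset`."""
    import imageio.v3 as iio

    indir = Path(indir)
    splits = DatasetSplits()
    by_name = {"train": splits.train, "val": splits.val, "test": splits.test}
    with open(indir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            image = iio.imread(indir / "images" / row["filename"]).astype(np.float32) / 255.0
            mask = iio.imread(indir / "masks" / row["filename"]) > 127
            by_name[row["split"]].append(
                SceneSample(
                    image=image,
                    tool_mask=mask,
                    event_label=int(row["event_label"]),
                    blood_fraction=float(row["blood_fraction"]),
                )
            )
    return splits
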