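"""Multi-task U-Net: shared encoder, segmentation decoder, event-detection head.

The architecture is an encoder–decoder for binary tool segmentation whose
bottleneck also feeds a fully connected classifier deciding whether blood is
accumulating in the scene. The encoder repeats ``depth`` times the block
[3x3 conv, ReLU, 3x3 conv, ReLU, 2x2 max-pool], doubling the channel count at
every level; two 3x3 convolutions (with ReLU) form the bottleneck. The
segmentation branch mirrors the encoder: nearest-neighbour 2x upsampling, a
2x2 channel-halving convolution, concatenation with the symmetric encoder
feature map (skip connection), and two 3x3 convolutions with ReLU, closed by
a 1x1 convolution to the segmentation logits. The classification branch
flattens the bottleneck into [linear -> ReLU -> dropout] x 2 followed by a
final linear layer over the event classes. All 3x3 convolutions are padded so
the segmentation map has exactly the input's spatial size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Conv2d, Linear, ReLU, MaxPool2x2, Upsample2x, Dropout, Parameter
from .nn.layers import dtype as _dtype

__all__ = [
    "ModelConfig",
    "MultiTaskOutput",
    "EncoderState",
    "MultiTaskUNet",
    "build_model",
    "predict",
    "mask_and_probability",
    "sigmoid",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_height``/``input_width`` must be divisible by ``2**depth`` because
    the classification head flattens the bottleneck, which fixes its size.
    Channel count at encoder level k is ``base_channels * 2**k``.
    """

    input_height: int = 160
    input_width: int = 240
    in_channels: int = 3
    base_channels: int = 64
    depth: int = 4
    seg_out_channels: int = 1
    num_event_classes: int = 2
    hidden_width: int = 1024
    dropout_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "input_height",
            "input_width",
            "in_channels",
            "base_channels",
            "depth",
            "seg_out_channels",
            "hidden_width",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.num_event_classes < 2:
            raise ValueError("num_event_classes must be >= 2")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        div = 2**self.depth
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input size {self.input_height}x{self.input_width} must be "
                f"divisible by 2^depth = {div} (the flattened-bottleneck "
                "classification head requires a fixed bottleneck size)"
            )

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2**self.depth

    @property
    def bottleneck_size(self) -> tuple[int, int]:
        return (self.input_height // 2**self.depth, self.input_width // 2**self.depth)


@dataclass
class MultiTaskOutput:
    """Paired pre-activation outputs for one batch."""

    seg_logits: np.ndarray  # (B, seg_out_channels, H, W)
    event_logits: np.ndarray  # (B, num_event_classes)


@dataclass
class EncoderState:
    """Shared-trunk activations: bottleneck plus the per-level skip maps."""

    bottleneck: np.ndarray
    skips: list = field(default_factory=list)


def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z, axis=-1):
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiTaskUNet:
    """The shared-trunk multi-task network; see the module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2**k for k in range(config.depth + 1)]
        self.level_channels = ch

        self.enc_blocks = []
        in_c = config.in_channels
        for k in range(config.depth):
            self.enc_blocks.append(
                {
                    "conv1": Conv2d(in_c, ch[k], (3, 3), (1, 1, 1, 1), rng, f"enc{k}.conv1"),
                    "relu1": ReLU(),
                    "conv2": Conv2d(ch[k], ch[k], (3, 3), (1, 1, 1, 1), rng, f"enc{k}.conv2"),
                    "relu2": ReLU(),
                    "pool": MaxPool2x2(),
                }
            )
            in_c = ch[k]

        self.bott_conv1 = Conv2d(ch[-2], ch[-1], (3, 3), (1, 1, 1, 1), rng, "bott.conv1")
        self.bott_relu1 = ReLU()
        self.bott_conv2 = Conv2d(ch[-1], ch[-1], (3, 3), (1, 1, 1, 1), rng, "bott.conv2")
        self.bott_relu2 = ReLU()

        self.dec_blocks = []
        for k in reversed(range(config.depth)):
            self.dec_blocks.append(
                {
                    "level": k,
                    "up": Upsample2x(),
                    # even 2x2 kernel: asymmetric (0,1,0,1) padding keeps the size
                    "upconv": Conv2d(ch[k + 1], ch[k], (2, 2), (0, 1, 0, 1), rng, f"dec{k}.upconv"),
                    "conv1": Conv2d(2 * ch[k], ch[k], (3, 3), (1, 1, 1, 1), rng, f"dec{k}.conv1"),
                    "relu1": ReLU(),
                    "conv2": Conv2d(ch[k], ch[k], (3, 3), (1, 1, 1, 1), rng, f"dec{k}.conv2"),
                    "relu2": ReLU(),
                }
            )
        self.out_conv = Conv2d(ch[0], config.seg_out_channels, (1, 1), (0, 0, 0, 0), rng, "out_conv")

        bh, bw = config.bottleneck_size
        self._flat_features = ch[-1] * bh * bw
        self.fc1 = Linear(self._flat_features, config.hidden_width, rng, "head.fc1")
        self.fc_relu1 = ReLU()
        self.fc_drop1 = Dropout(config.dropout_p)
        self.fc2 = Linear(config.hidden_width, config.hidden_width, rng, "head.fc2")
        self.fc_relu2 = ReLU()
        self.fc_drop2 = Dropout(config.dropout_p)
        self.fc3 = Linear(config.hidden_width, config.num_event_classes, rng, "head.fc3")

        self._bott_shape = None

    # ----- parameter bookkeeping -------------------------------------------------

    def encoder_parameters(self) -> list[Parameter]:
        params = []
        for blk in self.enc_blocks:
            params += blk["conv1"].parameters() + blk["conv2"].parameters()
        params += self.bott_conv1.parameters() + self.bott_conv2.parameters()
        return params

    def decoder_parameters(self) -> list[Parameter]:
        params = []
        for blk in self.dec_blocks:
            params += (
                blk["upconv"].parameters()
                + blk["conv1"].parameters()
                + blk["conv2"].parameters()
            )
        return params + self.out_conv.parameters()

    def head_parameters(self) -> list[Parameter]:
        return self.fc1.parameters() + self.fc2.parameters() + self.fc3.parameters()

    def parameters(self) -> list[Parameter]:
        return self.encoder_parameters() + self.decoder_parameters() + self.head_parameters()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ----- forward / backward ----------------------------------------------------

    def encode(self, x, *, train=False) -> EncoderState:
        skips = []
        h = x
        for blk in self.enc_blocks:
            h = blk["relu1"](blk["conv1"](h))
            h = blk["relu2"](blk["conv2"](h))
            skips.append(h)
            h = blk["pool"](h)
        b = self.bott_relu1(self.bott_conv1(h))
        b = self.bott_relu2(self.bott_conv2(b))
        return EncoderState(bottleneck=b, skips=skips)

    def forward(self, images, *, train: bool = False, rng=None) -> MultiTaskOutput:
        """Run a (B, in_channels, H, W) batch; values expected in [0, 1].

        With ``train=False`` dropout is disabled and the mapping is
        deterministic.
        """
        x = np.ascontiguousarray(images, dtype=_dtype())
        cfg = self.config
        expected = (cfg.in_channels, cfg.input_height, cfg.input_width)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(
                f"expected input of shape (B, {expected[0]}, {expected[1]}, "
                f"{expected[2]}), received {x.shape}"
            )

        state = self.encode(x, train=train)
        b = state.bottleneck
        self._bott_shape = b.shape

        d = b
        for blk in self.dec_blocks:
            d = blk["upconv"](blk["up"](d))
            d = np.concatenate([state.skips[blk["level"]], d], axis=1)
            d = blk["relu1"](blk["conv1"](d))
            d = blk["relu2"](blk["conv2"](d))
        seg_logits = self.out_conv(d)

        flat = b.reshape(b.shape[0], -1)
        h = self.fc_drop1(self.fc_relu1(self.fc1(flat)), train=train, rng=rng)
        h = self.fc_drop2(self.fc_relu2(self.fc2(h)), train=train, rng=rng)
        event_logits = self.fc3(h)
        return MultiTaskOutput(seg_logits=seg_logits, event_logits=event_logits)

    def backward(self, dseg, devent) -> None:
        """Accumulate parameter gradients from output-side gradients.

        ``dseg``/``devent`` are d(loss)/d(seg_logits) and d(loss)/d(event_logits);
        either may be all-zero to probe one head alone.
        """
        d = self.out_conv.backward(np.asarray(dseg, dtype=_dtype()))
        dskips = {}
        for blk in reversed(self.dec_blocks):
            k = blk["level"]
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))))
            c = self.level_channels[k]
            dskips[k] = d[:, :c]
            d = blk["up"].backward(blk["upconv"].backward(d[:, c:]))
        db = d  # gradient at the bottleneck from the segmentation branch

        g = self.fc3.backward(np.asarray(devent, dtype=_dtype()))
        g = self.fc1.backward(self.fc_relu1.backward(self.fc_drop1.backward(
            self.fc2.backward(self.fc_relu2.backward(self.fc_drop2.backward(g))))))
        db = db + g.reshape(self._bott_shape)

        d = self.bott_conv1.backward(self.bott_relu1.backward(
            self.bott_conv2.backward(self.bott_relu2.backward(db))))
        for k in reversed(range(len(self.enc_blocks))):
            blk = self.enc_blocks[k]
            d = blk["pool"].backward(d) + dskips[k]
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))))

    # ----- inference -------------------------------------------------------------

    def predict(self, image) -> tuple[np.ndarray, float]:
        """Predict for a single (H, W, 3) image in [0, 1] (or uint8).

        Returns the binary tool mask (H, W) uint8 and the blood-accumulation
        probability (softmax component of class 1).
        """
        img = np.asarray(image)
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        if img.ndim != 3 or img.shape[2] != self.config.in_channels:
            raise ValueError(f"expected (H, W, {self.config.in_channels}) image, got {img.shape}")
        x = img.transpose(2, 0, 1)[None]
        out = self.forward(x, train=False)
        mask, prob = mask_and_probability(out.seg_logits[0, 0], out.event_logits[0])
        return mask, prob


def mask_and_probability(seg_logits, event_logits) -> tuple[np.ndarray, float]:
    """Apply the inference activations: sigmoid + 0.5 threshold on the
    segmentation logits, softmax class-1 component on the event logits."""
    mask = (sigmoid(seg_logits) >= 0.5).astype(np.uint8)
    prob = float(softmax(np.asarray(event_logits, dtype=np.float64))[1])
    return mask, prob


def build_model(config: ModelConfig) -> MultiTaskUNet:
    """Instantiate the multi-task network for a validated configuration."""
    return MultiTaskUNet(config)


def predict(model: MultiTaskUNet, image):
    return model.predict(image)


# ----- checkpointing -------------------------------------------------------------


def save_checkpoint(model: MultiTaskUNet, path) -> None:
    """Serialize config + weights into a single .npz file."""
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> MultiTaskUNet:
    """Rebuild a model from a checkpoint.

    Refuses to load when ``expected_config`` is given and disagrees with the
    stored one.
    """
    with np.load(path) as data:
        stored = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        if expected_config is not None and stored != expected_config:
            raise ValueError(
                f"checkpoint config {stored} disagrees with requested {expected_config}"
            )
        model = MultiTaskUNet(stored)
        params = model.parameters()
        for i, p in enumerate(params):
            arr = data[f"param_{i:04d}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} has shape {arr.shape}, expected {p.value.shape}")
            p.value[...] = arr
    return model
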