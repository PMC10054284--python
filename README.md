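# surgmtl

Joint **surgical-tool segmentation** and **blood-accumulation detection** for
laparoscopic video, as one multi-task convolutional network, plus everything
needed to exercise it end to end without access to clinical recordings: a
seeded synthetic scene generator, a training/evaluation loop, and a strided
real-time-style video annotator.

## Who this is for

Researchers and engineers prototyping intraoperative video-understanding
systems. Intraoperative bleeding is among the most problematic events in
minimally invasive surgery: blood pools quickly, obscures the surgical field,
and demands prompt aspiration. A system that simultaneously localizes the
instruments (per-pixel) and raises an alert when blood is accumulating
(per-frame) supports the operating team without any extra sensors — the input
is plain RGB video.

## The model

A U-Net-style encoder–decoder with a second head sharing the encoder
("shared trunk" multi-task learning):

- **Encoder** (shared): `depth` = 4 repetitions of [3×3 conv, ReLU, 3×3
  conv, ReLU, 2×2 max-pool], doubling channels each level
  (64 → 128 → 256 → 512), then two 3×3 convolutions forming a 1024-channel
  bottleneck.
- **Segmentation branch**: mirror decoder with nearest-neighbour 2×
  upsampling, 2×2 channel-halving convolution, skip concatenation with the
  symmetric encoder map, and two 3×3 conv + ReLU; a final 1×1 convolution
  maps the 64-component feature vectors to a one-channel logit map. All
  convolutions are padded, so the mask has exactly the input's size.
- **Event-detection branch**: the flattened bottleneck through
  [linear(1024) → ReLU → dropout] × 2 → linear(2), classifying
  *no blood accumulation* (0) vs *blood accumulation* (1).

Training minimizes the unweighted sum

```
loss = segloss + clsloss
```

with `segloss` a sigmoid + binary cross-entropy over pixels and `clsloss` a
softmax + cross-entropy over the two event classes (both computed in stable
logit form). Segmentation is scored by the Dice coefficient
`2·|P∩T| / (|P|+|T|)` and event detection by accuracy
`#correct / #samples`, overall and per class. The reference protocol is 30
epochs, batch 32, Adam with learning rate 1e-4, with training images randomly
rotated in (−35°, 35°) and flipped horizontally/vertically/both.

The network, including forward and backward passes and the Adam optimizer,
is implemented in NumPy (`surgmtl.nn`) — no deep-learning framework is
required. The hand-written gradients are verified against finite differences
in the test suite.

At inference the video annotator predicts every k-th frame (default k = 2),
reuses the cached prediction in between, tints tool pixels blue, and prints
the blood-accumulation percentage in the top-left corner only when it is
strictly above 50%.

## Worked example

```python
import numpy as np
import surgmtl as s

# a reproducible synthetic dataset (tissue background, gray tools, red pools)
scenes = s.SceneConfig(height=96, width=128, seed=23)
splits = s.generate_dataset(scenes, sizes=(200, 32, 0), seed=23)

model = s.build_model(s.ModelConfig(
    input_height=96, input_width=128, base_channels=16, depth=3,
    hidden_width=256, dropout_p=0.25, seed=23))
model, history = s.train(model, splits, s.TrainConfig(
    epochs=10, batch_size=16, learning_rate=1e-3, seed=23))

report = s.evaluate(model, splits.val)
print(round(report.dice, 4), round(report.accuracy, 4), report.per_class_accuracy)
```

Output:

```
0.9484 1.0 {0: 1.0, 1: 1.0}
```

i.e. after ten epochs on 200 synthetic scenes the held-out split is
segmented with a mean per-image Dice of 0.9484, and all 32 validation scenes
are classified correctly (per-class accuracies 1.0 / 1.0). The per-epoch
curves (total/seg/cls training loss, validation Dice and accuracy) are in
`history.rows`.

The same pipeline is available from the shell:

```bash
surgmtl generate-data --out data/ --seed 23 --sizes 200 32 0 --height 96 --width 128
surgmtl train --data data/ --out run/ --epochs 10 --batch-size 16 \
    --learning-rate 1e-3 --base-channels 16 --depth 3 --hidden-width 256 --dropout 0.25
surgmtl evaluate --checkpoint run/checkpoint.npz --data data/ --split val
surgmtl annotate-video --checkpoint run/checkpoint.npz --in frames_dir/ --out annotated/ --stride 2
```

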