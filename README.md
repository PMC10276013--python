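# ducknet

Encoder–decoder convolutional network for binary image segmentation built
around multi-scale "DUCK" blocks — six parallel convolutional branches
(dilated, residual-chained, and spatially factorized) that emulate kernel
spans of 5/7/9/13/15 pixels — plus a residual downsampling path that feeds
the raw input into every encoder resolution by addition.

The whole stack runs on a small pure-NumPy reverse-mode autodiff backend
(`ducknet.nn`), so it trains and evaluates on a single CPU with no deep
learning framework installed.

## Contents

| module                  | what it does |
|-------------------------|--------------|
| `ducknet.nn`            | tensors with autograd, conv/batch-norm/upsample primitives, RMSprop |
| `ducknet.blocks`        | residual / midscope / widescope / separated / DUCK / simple-conv blocks, strided downsample, receptive-field oracle |
| `ducknet.model`         | the full encoder–decoder (`build_ducknet`), prediction, checkpoints |
| `ducknet.metrics`       | confusion counts, Dice/Jaccard/Precision/Recall/Accuracy, soft Dice loss, CSV reports |
| `ducknet.augmentation`  | paired image/mask policy: flips, color jitter (image only), affine transforms |
| `ducknet.dataio`        | image/mask loading (Lanczos rescale, nearest-neighbour masks), 80:10:10 splits |
| `ducknet.synthetic`     | seeded generator of textured frames with 1–3 irregular bright blobs + exact masks |
| `ducknet.training`      | training loop (RMSprop, Dice loss, per-epoch augmentation), evaluation, cross-dataset evaluation |

## CLI

```bash
# make a synthetic dataset (images/ + masks/ PNG layout)
ducknet synth --n 200 --size 64 --seed 7 --out data/

# write train/val/test id manifests (80:10:10)
ducknet split --data data/ --seed 0 --out splits/

# train; config file keys mirror TrainConfig/ModelConfig/AugmentConfig
ducknet train --data data/ --config config.yaml --out runs/exp1/

# evaluate on one split, or a whole foreign dataset
ducknet eval --model runs/exp1/model.npz --data data/ --manifest splits/test_ids.txt
ducknet cross-eval --model runs/exp1/model.npz --data other_data/

# segment one image / report measured receptive fields
ducknet predict --model runs/exp1/model.npz --image img.png --out mask.png
ducknet rf
```

Example `config.yaml`:

```yaml
model: {filters: 17, input_size: 352, depth: 5, block_type: duck, seed: 0}
learning_rate: 1.0e-4
batch_size: 4
epochs: 600
```

Training defaults follow the reference protocol (RMSprop, lr 1e-4,
batch 4, 600 epochs, 352×352 Lanczos-rescaled inputs, best-validation-Dice
checkpointing); smoke-scale settings are overridden explicitly.

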