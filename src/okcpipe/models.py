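"""Classifier backbones and the transfer-learning contract.

Two backbone families are described structurally — layer census,
filter counts, shape propagation, dense-connectivity arithmetic — the
way the pipeline uses them:

* ``build_vgg16``: thirteen 3x3 convolutions (64, 64, 128, 128, 256,
  256, 256, 512x6) with ReLU, five 2x2/stride-2 max-pools, and a
  three-layer fully connected head (25088 -> 4096 -> 2, softmax).
  Under transfer learning the thirteen convolutional layers keep their
  pretrained weights and only the head is trained.
* ``build_densenet``: dense blocks in which layer *n* receives the
  channel-wise concatenation of all preceding feature maps and applies
  the composite batch-norm -> ReLU -> 3x3 convolution; a network of N
  layers therefore has N(N+1)/2 direct connections.  Blocks are
  separated by transition layers (1x1 convolution with compression
  0.5, then 2x2 average pooling).

The trainable desk-scale model is :class:`okcpipe.nn.SmallCNN`;
``train``/``predict`` here wrap it behind the pipeline's surface and
produce :class:`PredictionScore` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import SmallCNN, TrainingResults, bce_loss, softmax  # noqa: F401  (re-export)
from .synthdata import OKC, LabeledImage

VGG16_CONV_FILTERS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
#: Number of convolutions before each max-pool, matching the ordering
#: Conv1, Conv2, MP1, Conv3, Conv4, MP2, ..., plus the standard pool
#: after Conv13 that brings 224 x 224 down to 7 x 7.
VGG16_POOL_AFTER = (2, 4, 7, 10, 13)

DENSENET169_BLOCKS = (6, 12, 32, 32)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one classifier branch."""

    architecture: str = "smallcnn"  # {vgg16, densenet, smallcnn}
    input_shape: tuple[int, int, int] = (224, 224, 3)
    frozen_prefix: int = 0
    head_units: tuple[int, ...] = (4096, 2)
    batch_size: int = 12
    epochs: int = 15
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in {"vgg16", "densenet", "smallcnn"}:
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass(frozen=True)
class PredictionScore:
    """Per-image confidence scores; ``p_okc + p_nonokc == 1``."""

    id: str
    p_okc: float
    p_nonokc: float


@dataclass
class LayerDesc:
    """One layer of an architecture description."""

    kind: str  # conv / maxpool / avgpool / flatten / dense / bn_relu_conv / concat
    name: str
    filters: int | None = None
    kernel: tuple[int, int] | None = None
    stride: int = 1
    padding: int = 0
    units: int | None = None
    activation: str | None = None
    frozen: bool = False
    output_shape: tuple[int, ...] | None = None


@dataclass
class ModelDescription:
    """Structural description of a backbone plus its head."""

    name: str
    input_shape: tuple[int, int, int]
    layers: list[LayerDesc] = field(default_factory=list)

    @property
    def conv_layers(self) -> list[LayerDesc]:
        return [l for l in self.layers if l.kind == "conv"]

    @property
    def head_widths(self) -> tuple[int, ...]:
        return tuple(l.units for l in self.layers if l.kind == "dense")

    @property
    def flattened_features(self) -> int:
        for l in self.layers:
            if l.kind == "flatten":
                return int(np.prod(l.output_shape))
        raise ValueError("description has no flatten stage")


def build_vgg16(spec: ModelSpec | None = None) -> ModelDescription:
    """VGG16 description for transfer learning on 224 x 224 x 3 input.

    Thirteen 3x3/stride-1/pad-1 convolutions with ReLU, max-pools of
    2x2 stride 2 after convolutions 2, 4, 7, 10 and 13; head of three
    fully connected layers — 25088 (the flattened 7*7*512 features),
    4096, and a 2-unit softmax.  The convolutional layers are marked
    frozen (pretrained); only the head trains.
    """
    spec = spec or ModelSpec(architecture="vgg16")
    h, w, c = spec.input_shape
    if (h, w, c) != (224, 224, 3):
        raise ValueError(f"vgg16 requires input shape (224, 224, 3), got {spec.input_shape}")

    desc = ModelDescription(name="vgg16", input_shape=(h, w, c))
    pools = set(VGG16_POOL_AFTER)
    ch = c
    for i, f in enumerate(VGG16_CONV_FILTERS, start=1):
        desc.layers.append(
            LayerDesc(
                kind="conv",
                name=f"conv{i}",
                filters=f,
                kernel=(3, 3),
                stride=1,
                padding=1,
                activation="relu",
                frozen=True,
                output_shape=(h, w, f),
            )
        )
        ch = f
        if i in pools:
            h, w = h // 2, w // 2
            desc.layers.append(
                LayerDesc(
                    kind="maxpool",
                    name=f"maxpool{sorted(pools).index(i) + 1}",
                    kernel=(2, 2),
                    stride=2,
                    output_shape=(h, w, ch),
                )
            )

    flat = h * w * ch  # 7 * 7 * 512 = 25088
    desc.layers.append(LayerDesc(kind="flatten", name="flatten", output_shape=(flat,)))
    desc.layers.append(
        LayerDesc(kind="dense", name="fc1", units=flat, activation="relu", output_shape=(flat,))
    )
    desc.layers.append(
        LayerDesc(kind="dense", name="fc2", units=4096, activation="relu", output_shape=(4096,))
    )
    desc.layers.append(
        LayerDesc(kind="dense", name="output", units=2, activation="softmax", output_shape=(2,))
    )
    return desc


def build_densenet(
    block_config: tuple[int, ...] = DENSENET169_BLOCKS,
    growth_rate: int = 32,
    initial_channels: int = 64,
    compression: float = 0.5,
    input_shape: tuple[int, int, int] = (224, 224, 3),
) -> ModelDescription:
    """Densely connected backbone description.

    Each dense layer appends ``growth_rate`` channels to the running
    concatenation; transitions halve the channels (compression 0.5 via
    1x1 convolution) and the spatial size (2x2 average pooling).  The
    default block configuration (6, 12, 32, 32) is the 169-layer
    variant.
    """
    h, w, c = input_shape
    # conventional depth label counts bottleneck conv pairs plus the
    # stem, transitions and classifier: 2 * sum(blocks) + 5 = 169 for
    # the (6, 12, 32, 32) configuration
    depth = 2 * sum(block_config) + 5
    desc = ModelDescription(name=f"densenet{depth}", input_shape=input_shape)
    desc.layers.append(
        LayerDesc(kind="conv", name="conv0", filters=initial_channels, kernel=(7, 7),
                  stride=2, padding=3, output_shape=(h // 2, w // 2, initial_channels))
    )
    h, w = h // 4, w // 4  # initial conv stride 2, then 3x3/2 max pool
    desc.layers.append(
        LayerDesc(kind="maxpool", name="pool0", kernel=(3, 3), stride=2,
                  output_shape=(h, w, initial_channels))
    )
    ch = initial_channels
    for b, n_layers in enumerate(block_config, start=1):
        for l in range(1, n_layers + 1):
            desc.layers.append(
                LayerDesc(kind="bn_relu_conv", name=f"block{b}_layer{l}",
                          filters=growth_rate, kernel=(3, 3), padding=1,
                          output_shape=(h, w, ch + growth_rate))
            )
            ch += growth_rate
        if b < len(block_config):
            ch = int(np.floor(ch * compression))
            h, w = h // 2, w // 2
            desc.layers.append(
                LayerDesc(kind="avgpool", name=f"transition{b}", kernel=(2, 2), stride=2,
                          filters=ch, output_shape=(h, w, ch))
            )
    desc.layers.append(LayerDesc(kind="avgpool", name="global_pool", output_shape=(ch,)))
    desc.layers.append(LayerDesc(kind="flatten", name="flatten", output_shape=(ch,)))
    desc.layers.append(
        LayerDesc(kind="dense", name="output", units=2, activation="softmax", output_shape=(2,))
    )
    return desc


def dense_layer_input(feature_maps: list[np.ndarray]) -> np.ndarray:
    """Channel-wise concatenation of the feature maps y_0 ... y_{n-1}.

    This is the input the n-th dense layer sees before its composite
    (batch-norm, ReLU, 3x3 convolution) is applied.  All maps must
    share spatial dimensions (arrays are H x W x C).
    """
    if not feature_maps:
        raise ValueError("need at least one feature map")
    maps = [np.asarray(m) for m in feature_maps]
    spatial = maps[0].shape[:2]
    for m in maps[1:]:
        if m.shape[:2] != spatial:
            raise ValueError(
                f"spatial dimensions differ: {m.shape[:2]} vs {spatial}"
            )
    return np.concatenate(maps, axis=-1)


def dense_connection_count(n: int) -> int:
    """Direct connections in an N-layer densely connected network.

    Layer i feeds every later layer, giving the triangular number
    N(N+1)/2 (each of the N layers also receives the input).
    """
    if n < 1:
        raise ValueError(f"layer count must be >= 1, got {n}")
    return n * (n + 1) // 2


# ---------------------------------------------------------------------------
# training / prediction over the desk-scale network


def images_to_array(
    images: list[LabeledImage], input_shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack labelled images into (X in [0,1], y, ids); resizes if needed."""
    from .dataset import resize_image

    h, w, _ = input_shape
    xs, ys, ids = [], [], []
    for img in images:
        px = img.pixels
        if px.shape[:2] != (h, w):
            px = resize_image(px, (w, h))
        xs.append(px.astype(np.float64) / 255.0)
        ys.append(1 if img.label == OKC else 0)
        ids.append(img.source_id)
    return np.stack(xs), np.asarray(ys), ids


def build_model(spec: ModelSpec) -> SmallCNN:
    """Instantiate the trainable network for a spec.

    Only the ``smallcnn`` architecture is trainable here; the vgg16 and
    densenet builders produce structural descriptions for inspection.
    """
    if spec.architecture != "smallcnn":
        raise ValueError(
            f"architecture {spec.architecture!r} is structural-only; "
            "use 'smallcnn' for training"
        )
    return SmallCNN(input_shape=spec.input_shape, seed=spec.seed)


def train(
    model: SmallCNN,
    train_images: list[LabeledImage],
    spec: ModelSpec,
    val_images: list[LabeledImage] | None = None,
) -> TrainingResults:
    """Fit the network with Adam on binary cross-entropy."""
    x, y, _ = images_to_array(train_images, model.input_shape)
    validation = None
    if val_images:
        xv, yv, _ = images_to_array(val_images, model.input_shape)
        validation = (xv, yv)
    return model.fit(
        x,
        y,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        validation=validation,
    )


def predict(model: SmallCNN, images: list[LabeledImage]) -> list[PredictionScore]:
    """Confidence scores for a batch, order-stable."""
    x, _, ids = images_to_array(images, model.input_shape)
    probs = model.predict_proba(x)
    return [
        PredictionScore(id=i, p_okc=float(p[1]), p_nonokc=float(p[0]))
        for i, p in zip(ids, probs)
    ]
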