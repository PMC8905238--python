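"""Corn-seed-Net: a two-pathway CNN for 4-channel (RGB+NIR) seed chips.

The network runs a VGG16-style branch and a ResNet50-style branch in
parallel on the same 4-channel chip and concatenates their 512-dimensional
embeddings into a 1,024-vector, which a final fully connected layer maps to
the two classes ("good" / "bad") through a softmax.

The VGG branch keeps the 13-convolution 3x3 trunk of VGG16 but replaces its
enormous fully connected head: a 7x7 convolution with 512 channels collapses
the final 7x7 max-pooling map to 1x1, followed by two fully connected layers
of 512 units — far fewer parameters than the original 25088-4096-4096 head.
The ResNet branch is a standard bottleneck-block ResNet50 trunk (stages of
3, 4, 6, 3 blocks; 1 stem + 48 block convolutions + 1 FC = 50 weighted
layers) whose global-average-pooled features feed one fully connected layer
of 512 units.

``width_multiplier`` scales every channel/embedding count so desk-scale
experiments train on a CPU in minutes; 1.0 reproduces the printed
architecture.  Similarly, any input size divisible by 32 is accepted at
reduced width (the head convolution kernel tracks the final feature-map
size, input_size/32); at width 1.0 only the native 224 is accepted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn
from .segmentation import SeedChip

CLASSES = ("good", "bad")

# VGG16 convolutional trunk: 13 conv layers, 'M' = 2x2 max-pool.
VGG16_TRUNK = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
               512, 512, 512, "M", 512, 512, 512, "M"]
RESNET50_STAGES = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))  # (mid_ch, blocks, stride)


@dataclass
class ArchitectureSpec:
    input_channels: int = 4
    input_size: int = 224
    width_multiplier: float = 1.0
    n_classes: int = 2
    branch_embed_dim: int = 512
    fused_dim: int = 1024
    pretrained_init: str = "none"          # "none" | "imagenet-adapted"

    def __post_init__(self):
        if not (0.0 < self.width_multiplier <= 1.0):
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.fused_dim != 2 * self.branch_embed_dim:
            raise ValueError("fused_dim must equal 2 x branch_embed_dim")
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ValueError("input_size must be a positive multiple of 32")
        if self.width_multiplier == 1.0 and self.input_size != 224:
            raise ValueError("only input_size=224 is supported at width 1.0")
        if self.pretrained_init not in ("none", "imagenet-adapted"):
            raise ValueError("pretrained_init must be 'none' or 'imagenet-adapted'")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    @property
    def embed_dim(self) -> int:
        return self.scaled(self.branch_embed_dim)


@dataclass
class TrainingConfig:
    optimizer: str = "SGD"                 # "SGD" | "Adam"
    momentum: float = 0.9                  # SGD only
    learning_rate: float = 0.001
    epochs: int = 100
    plateau_patience: int = 3              # epochs without test-loss improvement
    lr_halving_factor: float = 0.5         # fixed: lr is reduced by half on plateau
    batch_size: int = 32
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("SGD", "Adam"):
            raise ValueError("optimizer must be 'SGD' or 'Adam'")


@dataclass
class ClassifierOutput:
    """Per-chip logits z_m, softmax probabilities y_m and the argmax class."""

    logits: np.ndarray
    probs: np.ndarray
    predicted_class: str


softmax = nn.softmax
cross_entropy = nn.cross_entropy


class VGGBranch(nn.Sequential):
    """13-conv VGG16 trunk + (m x m conv, 512ch) + two FC-512 layers."""

    def __init__(self, spec: ArchitectureSpec, rng):
        layers = []
        in_ch = spec.input_channels
        n_conv = 0
        for item in VGG16_TRUNK:
            if item == "M":
                layers.append(nn.MaxPool2d(2))
            else:
                out_ch = spec.scaled(item)
                layers += [nn.Conv2d(in_ch, out_ch, 3, pad=1, rng=rng), nn.ReLU()]
                in_ch = out_ch
                n_conv += 1
        final_map = spec.input_size // 32      # 7 at the native 224
        head_ch = spec.scaled(512)
        layers += [
            nn.Conv2d(in_ch, head_ch, final_map, rng=rng),   # valid -> 1x1
            nn.ReLU(),
            nn.Flatten(),
            nn.Linear(head_ch, spec.embed_dim, rng=rng),
            nn.ReLU(),
            nn.Linear(spec.embed_dim, spec.embed_dim, rng=rng),
            nn.ReLU(),
        ]
        super().__init__(layers)
        self.trunk_conv_count = n_conv
        self.head_conv_kernel = final_map
        self.embed_dim = spec.embed_dim


class ResNetBranch(nn.Sequential):
    """ResNet50 trunk (bottleneck stages 3-4-6-3) + GAP + one FC-512 layer."""

    def __init__(self, spec: ArchitectureSpec, rng):
        stem_ch = spec.scaled(64)
        layers = [
            nn.Conv2d(spec.input_channels, stem_ch, 7, stride=2, pad=3, bias=False, rng=rng),
            nn.BatchNorm2d(stem_ch),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, pad=1),
        ]
        in_ch = stem_ch
        n_block_convs = 0
        for mid, blocks, stride in RESNET50_STAGES:
            for b in range(blocks):
                block = nn.Bottleneck(in_ch, spec.scaled(mid),
                                      stride=stride if b == 0 else 1, rng=rng)
                layers.append(block)
                in_ch = block.out_ch
                n_block_convs += 3
        layers += [
            nn.GlobalAvgPool(),
            nn.Linear(in_ch, spec.embed_dim, rng=rng),
            nn.ReLU(),
        ]
        super().__init__(layers)
        # stem conv + main-path block convs + the embedding FC
        self.weighted_layer_count = 1 + n_block_convs + 1
        self.embed_dim = spec.embed_dim


class CornSeedNet(nn.Layer):
    """Two-pathway model: concat(VGG branch, ResNet branch) -> FC -> 2 logits."""

    def __init__(self, spec: ArchitectureSpec, rng_seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        self.vgg = VGGBranch(spec, rng)
        self.resnet = ResNetBranch(spec, rng)
        self.fused_dim = 2 * spec.embed_dim
        self.classifier = nn.Linear(self.fused_dim, spec.n_classes, rng=rng)

    def children(self):
        return [self.vgg, self.resnet, self.classifier]

    def forward(self, x, train=True):
        a = self.vgg.forward(x, train=train)
        b = self.resnet.forward(x, train=train)
        fused = np.concatenate([a, b], axis=1)
        return self.classifier.forward(fused, train=train)

    def backward(self, dout):
        dfused = self.classifier.backward(dout)
        da = dfused[:, :self.vgg.embed_dim]
        db = dfused[:, self.vgg.embed_dim:]
        dxa = self.vgg.backward(np.ascontiguousarray(da))
        dxb = self.resnet.backward(np.ascontiguousarray(db))
        return dxa + dxb

    def predict_proba(self, x):
        return nn.softmax(self.forward(x, train=False))


def build_vgg_branch(spec: ArchitectureSpec = None, rng_seed: int = 0) -> VGGBranch:
    spec = spec or ArchitectureSpec()
    return VGGBranch(spec, np.random.default_rng(rng_seed))


def build_resnet_branch(spec: ArchitectureSpec = None, rng_seed: int = 0) -> ResNetBranch:
    spec = spec or ArchitectureSpec()
    return ResNetBranch(spec, np.random.default_rng(rng_seed))


def build_corn_seed_net(spec: ArchitectureSpec = None, rng_seed: int = 0) -> CornSeedNet:
    spec = spec or ArchitectureSpec()
    return CornSeedNet(spec, rng_seed=rng_seed)


def vgg_head_parameter_counts(spec: ArchitectureSpec = None):
    """(modified head, original VGG16 FC head) parameter counts at width 1.

    The modified head is the (input_size/32)^2 conv with 512 channels plus two
    FC-512 layers; the original head is FC 25088->4096->4096.
    """
    spec = spec or ArchitectureSpec()
    m = spec.input_size // 32
    c512 = spec.scaled(512)
    modified = (c512 * c512 * m * m + c512) + 2 * (c512 * spec.embed_dim + spec.embed_dim)
    original = (25088 * 4096 + 4096) + (4096 * 4096 + 4096)
    return modified, original


def adapt_pretrained_first_layer(rgb_kernels: np.ndarray) -> np.ndarray:
    """Extend 3-channel first-layer kernels to 4 channels for RGB+NIR input.

    The R, G, B kernel slices are copied unchanged; the NIR slice is
    initialised as the mean of the three colour slices.
    """
    k = np.asarray(rgb_kernels)
    if k.ndim != 4 or k.shape[1] != 3:
        raise ValueError(f"expected (out_ch, 3, kh, kw) kernels, got shape {k.shape}")
    nir = k.mean(axis=1, keepdims=True)
    return np.concatenate([k, nir], axis=1)


def chips_to_arrays(chips):
    """Stack chips into (N, 4, S, S) float32 in [0,1] plus class indices."""
    x = np.stack([c.pixels for c in chips]).astype(np.float32) / 255.0
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    y = np.array([CLASSES.index(c.label) if c.label is not None else -1 for c in chips])
    return x, y


def _evaluate(model, x, y, batch_size):
    loss_fn = nn.SoftmaxCrossEntropy()
    total_loss, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.forward(xb, train=False)
        probs = nn.softmax(logits)
        picked = probs[np.arange(len(yb)), yb]
        total_loss += float(-np.log(np.clip(picked, 1e-12, 1.0)).sum())
        correct += int((probs.argmax(axis=1) == yb).sum())
    return total_loss / len(x), correct / len(x)


def train(model: CornSeedNet, train_chips, test_chips, config: TrainingConfig = None):
    """Train with the configured optimizer; halve the lr on test-loss plateau.

    After every epoch the test loss is evaluated; if it has not improved for
    ``plateau_patience`` consecutive epochs the learning rate is multiplied
    by ``lr_halving_factor``.  Returns (model, history DataFrame) with
    per-epoch train/test loss and accuracy and the lr in force.
    """
    config = config or TrainingConfig()
    if not train_chips or not test_chips:
        raise ValueError("train and test chip sets must both be non-empty")
    x_tr, y_tr = chips_to_arrays(train_chips)
    x_te, y_te = chips_to_arrays(test_chips)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")

    params = list(model.parameters())
    if config.optimizer == "SGD":
        opt = nn.SGD(params, lr=config.learning_rate, momentum=config.momentum)
    else:
        opt = nn.Adam(params, lr=config.learning_rate)
    loss_fn = nn.SoftmaxCrossEntropy()
    rng = np.random.default_rng(config.rng_seed)

    history = []
    best_test_loss = np.inf
    epochs_since_improve = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb, train=True)
            loss = loss_fn.forward(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={opt.lr:g}); reduce the learning rate"
                )
            ep_loss += loss * len(idx)
            ep_correct += int((loss_fn.probs.argmax(axis=1) == yb).sum())
            model.backward(loss_fn.backward())
            opt.step()
        test_loss, test_acc = _evaluate(model, x_te, y_te, config.batch_size)
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": ep_loss / len(x_tr),
            "train_accuracy": ep_correct / len(x_tr),
            "test_loss": test_loss,
            "test_accuracy": test_acc,
        })
        if test_loss < best_test_loss - 1e-9:
            best_test_loss = test_loss
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= config.plateau_patience:
                opt.lr *= config.lr_halving_factor
                epochs_since_improve = 0
    return model, pd.DataFrame(history)


def predict(model: CornSeedNet, chips, batch_size: int = 32):
    """Classify chips; one :class:`ClassifierOutput` per chip."""
    if isinstance(chips, SeedChip):
        chips = [chips]
    expected = (model.spec.input_size, model.spec.input_size, model.spec.input_channels)
    for c in chips:
        if c.pixels.shape != expected:
            raise ValueError(f"chip shape {c.pixels.shape} does not match model input {expected}")
    x, _ = chips_to_arrays(chips)
    outputs = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        probs = nn.softmax(logits)
        for z, p in zip(logits, probs):
            outputs.append(ClassifierOutput(np.asarray(z, dtype=np.float64), p,
                                            CLASSES[int(p.argmax())]))
    return outputs


def save_model(model: CornSeedNet, path) -> None:
    """Checkpoint the model (architecture spec + all parameters/buffers)."""
    arrays = {}
    for i, layer in enumerate(model.iter_layers()):
        for name in sorted(layer.params):
            arrays[f"p{i}_{name}"] = layer.params[name]
        for name in sorted(layer.buffers):
            arrays[f"b{i}_{name}"] = layer.buffers[name]
    np.savez_compressed(path, __spec__=json.dumps(asdict(model.spec)), **arrays)


def load_model(path) -> CornSeedNet:
    with np.load(path, allow_pickle=False) as data:
        spec = ArchitectureSpec(**json.loads(str(data["__spec__"])))
        model = CornSeedNet(spec)
        for i, layer in enumerate(model.iter_layers()):
            for name in sorted(layer.params):
                layer.params[name] = data[f"p{i}_{name}"]
            for name in sorted(layer.buffers):
                layer.buffers[name] = data[f"b{i}_{name}"]
    return model
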