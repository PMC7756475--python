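"""The dual-arm ("X-shaped") multiview heatmap-regression network.

Two arms take the sagittal and coronal intensity-projection images of one
scan.  Each arm encodes through four residual stages (5x5 kernels, PReLU,
batch norm, strided 2x2 down-convolutions instead of pooling), the two
arms' feature maps are concatenated into a shared dense feature space
(three 5x5 conv stages), and each arm decodes back through four stages
(2x2 transpose convolutions, skip concatenation with its own encoder).
Each arm emits an H x W x 27 sigmoid heatmap stack: 24 vertebral bodies,
2 sacral landmarks and 1 null/background channel.

Training minimizes, per arm, (1 - soft Dice) + mean binary cross-entropy,
summed over both arms, with Adam at learning rate 2e-4 and batch size 8.
The ``reduced`` preset is a desk-scale configuration for CPU tests.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .levels import N_CHANNELS


@dataclass
class XNetConfig:
    input_shape: tuple[int, int] = (608, 192)
    n_channels_out: int = N_CHANNELS
    encode_filters: tuple[int, ...] = (32, 64, 128, 256)
    shared_filters: tuple[int, ...] = (512, 1024, 512)
    kernel: int = 5
    batch_size: int = 8
    learning_rate: float = 2e-4
    seed: int = 0
    reduced: bool = False

    def __post_init__(self) -> None:
        if self.n_channels_out != N_CHANNELS:
            raise ValueError(f"n_channels_out must be {N_CHANNELS}")
        strides = 2 ** len(self.encode_filters)
        if any(s % strides for s in self.input_shape):
            raise ValueError(
                f"input dims {self.input_shape} must be divisible by {strides}"
            )

    @classmethod
    def reduced_preset(cls, seed: int = 0, **overrides) -> "XNetConfig":
        """Desk-scale preset: 96x32 input, filters (4,8,16,32)/(32,64,32)."""
        kw = dict(
            input_shape=(96, 32),
            encode_filters=(4, 8, 16, 32),
            shared_filters=(32, 64, 32),
            learning_rate=1e-3,  # the tiny preset tolerates a hotter schedule
            reduced=True,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


class _Arm:
    """Encoder + decoder of one view; the bottleneck is shared outside."""

    def __init__(self, cfg: XNetConfig, rng):
        k = cfg.kernel
        f = cfg.encode_filters
        # stage i works at f[i] channels; the down conv already maps to the
        # next stage's filter count
        self.enc = [nn.ResBlock(1, f[0], k, rng)]
        self.enc += [nn.ResBlock(c, c, k, rng) for c in f[1:]]
        self.down = [
            nn.DownConv2d(f[i], f[i + 1] if i + 1 < len(f) else 2 * f[-1], rng)
            for i in range(len(f))
        ]
        self.down_bn = [
            nn.BatchNorm2d(f[i + 1] if i + 1 < len(f) else 2 * f[-1])
            for i in range(len(f))
        ]
        self.down_act = [
            nn.PReLU(f[i + 1] if i + 1 < len(f) else 2 * f[-1])
            for i in range(len(f))
        ]
        shared_out = cfg.shared_filters[-1]
        self.up = []
        self.up_bn = []
        self.up_act = []
        self.dec = []
        cin = shared_out
        for c in reversed(f):
            self.up.append(nn.UpConv2d(cin, c, rng))
            self.up_bn.append(nn.BatchNorm2d(c))
            self.up_act.append(nn.PReLU(c))
            self.dec.append(nn.ResBlock(2 * c, c, k, rng))
            cin = c
        self.out_conv = nn.Conv2d(f[0], cfg.n_channels_out, k, rng)

    def encode(self, x, train):
        skips = []
        for block, down, bn, act in zip(self.enc, self.down, self.down_bn,
                                        self.down_act):
            x = block(x, train)
            skips.append(x)
            x = act(bn(down(x), train))
        return x, skips

    def decode(self, x, skips, train):
        for up, bn, act, block, skip in zip(self.up, self.up_bn, self.up_act,
                                            self.dec, reversed(skips)):
            x = act(bn(up(x), train))
            x = block(nn.concat([x, skip]), train)
        return nn.sigmoid(self.out_conv(x))

    def layers(self):
        return (
            self.enc + self.down + self.down_bn + self.down_act + self.up
            + self.up_bn + self.up_act + self.dec + [self.out_conv]
        )


class XNet:
    """Two-arm heatmap regressor; see the module docstring."""

    def __init__(self, config: XNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.sagittal = _Arm(config, rng)
        self.coronal = _Arm(config, rng)
        g = config.shared_filters
        cin = 2 * 2 * config.encode_filters[-1]  # both arms concatenated
        self.shared = []
        for c in g:
            self.shared.append(nn.ConvBNAct(cin, c, config.kernel, rng))
            cin = c

    # -- forward ------------------------------------------------------------
    def forward(self, sag: np.ndarray, cor: np.ndarray, train: bool = False):
        """Run both arms.

        ``sag``/``cor``: (N, H, W) or (H, W) float images in [0, 1].
        Returns per-arm (N, H, W, C) arrays in (0, 1) when ``train`` is
        False, else the graph Tensors (N, C, H, W) for loss building.
        """
        sag = np.asarray(sag, np.float32)
        cor = np.asarray(cor, np.float32)
        if sag.ndim == 2:
            sag, cor = sag[None], cor[None]
        if sag.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"input shape {sag.shape[1:]} != configured "
                f"{self.config.input_shape}"
            )
        xs = nn.Tensor(sag[:, None])
        xc = nn.Tensor(cor[:, None])

        def run():
            hs, skips_s = self.sagittal.encode(xs, train)
            hc, skips_c = self.coronal.encode(xc, train)
            h = nn.concat([hs, hc])
            for stage in self.shared:
                h = stage(h, train)
            ys = self.sagittal.decode(h, skips_s, train)
            yc = self.coronal.decode(h, skips_c, train)
            return ys, yc

        if train:
            return run()
        with nn.no_grad():
            ys, yc = run()
        return (
            ys.data.transpose(0, 2, 3, 1),
            yc.data.transpose(0, 2, 3, 1),
        )

    def predict(self, sag: np.ndarray, cor: np.ndarray):
        """Inference on a single image pair -> per-arm (H, W, C) heatmaps."""
        ys, yc = self.forward(sag, cor, train=False)
        return ys[0], yc[0]

    # -- bookkeeping --------------------------------------------------------
    def layers(self):
        return self.sagittal.layers() + self.coronal.layers() + list(self.shared)

    def parameters(self) -> list[nn.Tensor]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def save(self, path) -> None:
        state = {
            "config": self.config,
            "params": [p.data for p in self.parameters()],
            "running": [
                dict(l.running) for l in self.layers()
                if isinstance(l, nn.BatchNorm2d)
            ] + [
                dict(l.bn.running) for l in self._bn_owners()
            ],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    def _bn_owners(self):
        out = []
        for layer in self.layers():
            if isinstance(layer, nn.ResBlock):
                out.extend([layer.u1, layer.u2])
            elif isinstance(layer, nn.ConvBNAct):
                out.append(layer)
        return out

    def _all_bn(self):
        bns = [l for l in self.layers() if isinstance(l, nn.BatchNorm2d)]
        bns += [o.bn for o in self._bn_owners()]
        return bns

    @classmethod
    def load(cls, path) -> "XNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["config"])
        for p, d in zip(model.parameters(), state["params"]):
            p.data = np.asarray(d, np.float32)
        for bn, run in zip(model._all_bn(), state["running"]):
            bn.running = {k: np.asarray(v, np.float32) for k, v in run.items()}
        return model


def build_xnet(config: XNetConfig) -> XNet:
    """Construct a seeded network from its configuration."""
    return XNet(config)


def combined_loss(pred_s, pred_c, label_s, label_c) -> nn.Tensor:
    """Total loss = [(1 - Dice) + CE] over the sagittal arm + the same over
    the coronal arm.  Accepts Tensors (graph mode) or arrays."""
    ls = nn.soft_dice_bce(nn.as_tensor(pred_s), label_s)
    lc = nn.soft_dice_bce(nn.as_tensor(pred_c), label_c)
    return nn.add(ls, lc)


def _label_nchw(stack) -> np.ndarray:
    arr = np.asarray(stack, np.float32)
    if arr.ndim == 3:  # (H, W, C) -> (C, H, W)
        arr = arr.transpose(2, 0, 1)
    return arr


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.epoch_loss) + 1),
             "loss": self.epoch_loss}
        )


def train_model(model: XNet, dataset, epochs: int = 10,
                batch_size: int | None = None, learning_rate: float | None = None,
                seed: int | None = None, optimizer: nn.Adam | None = None):
    """Train on a dataset of ((sag, cor), (label_sag, label_cor)) samples.

    Images are (H, W) arrays in [0, 1]; labels are (H, W, 27) or (27, H, W)
    Boolean stacks.  All intensity-projection variants of one scan enter as
    separate samples.  Returns ``(model, TrainHistory)``; training is
    deterministic for fixed seed/data/config.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    cfg = model.config
    bs = batch_size or cfg.batch_size
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = optimizer or nn.Adam(model.parameters(), lr=lr)
    opt.lr = lr
    history = TrainHistory()

    sag = np.stack([np.asarray(s[0][0], np.float32) for s in dataset])
    cor = np.stack([np.asarray(s[0][1], np.float32) for s in dataset])
    lab_s = np.stack([_label_nchw(s[1][0]) for s in dataset])
    lab_c = np.stack([_label_nchw(s[1][1]) for s in dataset])

    n = len(dataset)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            ys, yc = model.forward(sag[idx], cor[idx], train=True)
            loss = combined_loss(ys, yc, lab_s[idx], lab_c[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at step {opt.t + 1} "
                    f"(batch indices {idx.tolist()})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epoch_loss.append(float(np.mean(losses)))
    return model, history


def fine_tune(models: list[XNet], dataset, lr_divisor: float = 100.0,
              epochs: int = 2, seed: int | None = None):
    """Transfer-learning recipe: for each pretrained model, cut the learning
    rate by ``lr_divisor`` (2e-4 -> 2e-6 at the default) and train for
    ``epochs`` epochs with no layers frozen.  Returns the model list for
    ensembling."""
    if not models:
        raise ValueError("empty model list")
    out = []
    for i, model in enumerate(models):
        if epochs > 0:
            lr = model.config.learning_rate / lr_divisor
            base_seed = model.config.seed if seed is None else seed
            model, _ = train_model(
                model, dataset, epochs=epochs, learning_rate=lr,
                seed=base_seed + i,
            )
        out.append(model)
    return out
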