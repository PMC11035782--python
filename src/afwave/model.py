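"""Residual convolutional backbone with multi-branching sigmoid outputs.

The backbone is the 18-layer residual network: an initial 7x7/64 stride-2
convolution, a 3x3 stride-2 max pool, four stages of two residual blocks at
channel widths 64/128/256/512 (stages 2-4 downsample by 2 with a 1x1
projection shortcut), and global average pooling.  On top of the pooled
feature sit N_b independent affine heads with sigmoid activation — the
multi-branching outputs.  All branches share the backbone parameters; each
head is trained on its own balanced sub-dataset, and inference averages the
branch probabilities.

A ``n_stages`` knob truncates the backbone (e.g. the first two stages,
widths 64/128) for desk-scale experiments; the full four-stage network is
the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    Param,
    ReLU,
    Sequential,
)

__all__ = [
    "ConvSpec",
    "ResidualBlockSpec",
    "MBNetworkSpec",
    "conv2d",
    "feature_layer",
    "ResidualBlock",
    "residual_block",
    "MBResNet",
]

_STAGE_WIDTHS = (64, 128, 256, 512)


# --------------------------------------------------------------------- specs
@dataclass(frozen=True)
class ConvSpec:
    """2DConv(n_input, n_output, n_fdim1 x n_fdim2) with stride/padding."""

    n_input: int
    n_output: int
    kernel: tuple[int, int]
    stride: int = 1
    padding: int = 0

    def validate(self) -> None:
        if min(self.n_input, self.n_output, self.stride, *self.kernel) < 1:
            raise ConfigError("all ConvSpec dimensions must be positive")


@dataclass(frozen=True)
class ResidualBlockSpec:
    conv1: ConvSpec
    conv2: ConvSpec
    shortcut: str = "identity"  # or "projection"


@dataclass(frozen=True)
class MBNetworkSpec:
    """Structural summary of a multi-branching network (for layout checks
    and YAML round trips)."""

    in_channels: int
    stage_widths: tuple[int, ...]
    blocks: tuple[ResidualBlockSpec, ...]
    stem: ConvSpec
    n_branches: int
    feature_dim: int

    def validate(self) -> None:
        if self.n_branches < 1:
            raise ConfigError("n_branches must be >= 1")


# --------------------------------------------------- functional operations
def conv2d(X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Valid-mode 2-D cross-correlation of a single-channel map with a kernel:
    (X (x) theta)_ij = sum_m sum_n X[i+m, j+n] * theta[m, n]."""
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    s1, s2 = theta.shape
    if s1 > X.shape[0] or s2 > X.shape[1]:
        raise ConfigError("kernel larger than input")
    win = np.lib.stride_tricks.sliding_window_view(X, (s1, s2))
    return np.einsum("ijmn,mn->ij", win, theta)


def feature_layer(
    X_prev: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    activation=None,
) -> np.ndarray:
    """One convolutional feature layer: X_q = sigma(sum_p theta_pq (x) X_p + b_q).

    ``X_prev`` is (C_in, H, W); ``weights`` is (C_out, C_in, s1, s2);
    ``bias`` is (C_out,); ``activation`` defaults to identity.
    """
    X_prev = np.asarray(X_prev, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if X_prev.ndim != 3 or weights.ndim != 4:
        raise ConfigError("X_prev must be (C,H,W) and weights (Cout,Cin,s1,s2)")
    if weights.shape[1] != X_prev.shape[0]:
        raise ConfigError(
            f"channel mismatch: weights expect {weights.shape[1]}, input has {X_prev.shape[0]}"
        )
    out = np.stack(
        [
            sum(conv2d(X_prev[p], weights[q, p]) for p in range(X_prev.shape[0])) + bias[q]
            for q in range(weights.shape[0])
        ]
    )
    return out if activation is None else activation(out)


# ------------------------------------------------------------------ modules
class ResidualBlock(Module):
    """Y = F(X) + shortcut(X), with F = conv-BN-ReLU-conv-BN and a trailing
    ReLU after the addition.  The shortcut is the identity when shapes match,
    or a stride-matched 1x1 projection (with BN) when the block changes
    width or resolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None
        self.spec = ResidualBlockSpec(
            conv1=ConvSpec(in_channels, out_channels, (3, 3), stride, 1),
            conv2=ConvSpec(out_channels, out_channels, (3, 3), 1, 1),
            shortcut="identity" if self.proj is None else "projection",
        )

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f = self.conv1.forward(x, train)
        f = self.bn1.forward(f, train)
        f = self.relu1.forward(f, train)
        f = self.conv2.forward(f, train)
        f = self.bn2.forward(f, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            if f.shape != x.shape:
                raise ConfigError(
                    f"identity shortcut needs matching shapes, got {f.shape} vs {x.shape}"
                )
            sc = x
        return self.relu_out.forward(f + sc, train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad_out)
        gf = self.bn2.backward(g)
        gf = self.conv2.backward(gf)
        gf = self.relu1.backward(gf)
        gf = self.bn1.backward(gf)
        gx = self.conv1.backward(gf)
        if self.proj is not None:
            gx = gx + self.proj.backward(self.proj_bn.backward(g))
        else:
            gx = gx + g
        return gx


def residual_block(X: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Apply one residual block to a (N, C, H, W) batch (inference mode)."""
    return block.forward(np.asarray(X, dtype=np.float32), train=False)


class MBResNet(Module):
    """Residual backbone shared by ``n_branches`` sigmoid output heads.

    ``forward`` returns per-branch AF probabilities of shape
    (batch, n_branches); backprop routes each branch's gradient through its
    head and sums head gradients at the pooled feature, so every update
    touches the shared backbone.
    """

    def __init__(
        self,
        n_branches: int = 1,
        in_channels: int = 1,
        n_stages: int = 4,
        blocks_per_stage: int = 2,
        seed: int = 0,
    ):
        if n_branches < 1:
            raise ConfigError("n_branches must be >= 1")
        if not 1 <= n_stages <= 4:
            raise ConfigError("n_stages must be in 1..4")
        rng = np.random.default_rng(seed)
        widths = _STAGE_WIDTHS[:n_stages]

        layers: list[Module] = [
            Conv2d(in_channels, widths[0], 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(widths[0]),
            ReLU(),
            MaxPool2d(3, stride=2, padding=1),
        ]
        self.blocks: list[ResidualBlock] = []
        prev = widths[0]
        for si, w in enumerate(widths):
            for bi in range(blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                blk = ResidualBlock(prev, w, stride=stride, rng=rng)
                self.blocks.append(blk)
                layers.append(blk)
                prev = w
        layers.append(GlobalAvgPool())
        self.backbone = Sequential(*layers)
        self.heads = [Linear(prev, 1, rng=rng) for _ in range(n_branches)]
        self.n_branches = n_branches
        self.in_channels = in_channels
        self.feature_dim = prev
        self.stage_widths = widths
        self._feat_cache = None

    # ----------------------------------------------------------- structure
    def spec(self) -> MBNetworkSpec:
        stem = ConvSpec(self.in_channels, self.stage_widths[0], (7, 7), 2, 3)
        return MBNetworkSpec(
            in_channels=self.in_channels,
            stage_widths=tuple(self.stage_widths),
            blocks=tuple(b.spec for b in self.blocks),
            stem=stem,
            n_branches=self.n_branches,
            feature_dim=self.feature_dim,
        )

    def describe(self) -> list[str]:
        """Human-readable layer table (2DConv(n_in, n_out, k x k) notation)."""
        rows = [f"2DConv({self.in_channels}, {self.stage_widths[0]}, 7x7) stride 2"]
        rows.append("MaxPool 3x3 stride 2")
        for b in self.blocks:
            c1 = b.spec.conv1
            rows.append(
                f"ResBlock[2DConv({c1.n_input}, {c1.n_output}, 3x3) stride {c1.stride}, "
                f"2DConv({c1.n_output}, {c1.n_output}, 3x3)] shortcut={b.spec.shortcut}"
            )
        rows.append("GlobalAvgPool")
        rows.append(f"{self.n_branches} x [Linear({self.feature_dim}, 1) + sigmoid]")
        return rows

    def params(self) -> list[Param]:
        return self.backbone.params() + [p for h in self.heads for p in h.params()]

    # ------------------------------------------------------------- forward
    def forward_features(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise InputError(f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        if min(x.shape[2], x.shape[3]) < 8:
            raise InputError("input image too small for the stride-2 stem and pool")
        return self.backbone.forward(x, train=train)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        feat = self.forward_features(x, train=train)
        if train:
            self._feat_cache = feat
        logits = np.concatenate(
            [h.forward(feat, train=train) for h in self.heads], axis=1
        )
        return _sigmoid(logits)

    def backward_from_logits(self, grad_logits: np.ndarray) -> None:
        """Backprop from d(loss)/d(logit) per branch, shape (N, n_branches)."""
        gfeat = np.zeros_like(self._feat_cache)
        for i, h in enumerate(self.heads):
            gfeat += h.backward(grad_logits[:, i : i + 1].astype(np.float32))
        self.backbone.backward(gfeat)

    # -------------------------------------------------------- persistence
    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps) :]
        for bn, (m, v) in zip(self._batchnorms(), zip(rest[0::2], rest[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def save(self, path) -> None:
        np.savez(path, *self.state())

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state([z[k] for k in z.files])

    def _batchnorms(self):
        out = []
        for layer in self.backbone.layers:
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, ResidualBlock):
                out += [layer.bn1, layer.bn2]
                if layer.proj_bn is not None:
                    out.append(layer.proj_bn)
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
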