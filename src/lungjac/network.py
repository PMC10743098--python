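"""Multiscale residual regression network for log2-Jacobian maps.

The model maps one or two normalized CT channels to a single-channel map of
``Y = log2 J`` at the same spatial size.  It is an encoder with ``L`` levels
operating at successively halved resolutions: each level applies a residual
identity block (channels and size preserved) at ``C_l = C_0 * 2^l`` channels,
and a residual down block (spatial /2, channels x2) leads to the next level.
Each identity-block output is brought back to full resolution by an
upconvolution with ``C_0`` filters; the ``L`` full-resolution maps are
concatenated into a ``C_0 * L``-channel multiscale representation, and two
integration convolutions (the last one linear) produce the output.  All other
convolutions carry instance normalization and ReLU; in residual blocks the
normalization sits before the residual addition and the activation after it.
Parameters are He-normal initialized.

Inputs must have spatial extents divisible by ``2^(L-1)``; the preprocessing
module pads to this multiple and predictions are un-padded afterwards.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .deformation import JacobianMap
from .preprocess import PreparedCase, unpad
from .volumes import LungMask, Volume3D

__all__ = ["NetworkConfig", "JacRegNet", "build_network", "predict_jacobian",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``levels`` is the number of resolution levels L (the deepest operates at
    1/2^(L-1) of the input); ``base_filters`` is C_0, with level l using
    C_0 * 2^l channels; ``in_channels`` is 1 (single image) or 2 (FRC+TLC
    pair).
    """

    levels: int = 4
    base_filters: int = 8
    in_channels: int = 2
    kernel_size: int = 3
    norm_epsilon: float = 1e-5
    # width of the first integration convolution; defaults to C_0 * L
    integration_channels: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def channels_at(self, level: int) -> int:
        return self.base_filters * 2**level

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class _ConvNormAct:
    """Convolution + instance norm + ReLU."""

    def __init__(self, cin, cout, k, stride, eps, rng, dtype):
        self.conv = nn.Conv3d(cin, cout, k, stride, rng=rng, dtype=dtype)
        self.norm = nn.InstanceNorm3d(cout, eps, dtype=dtype)
        self.act = nn.ReLU()

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, gy):
        return self.conv.backward(self.norm.backward(self.act.backward(gy)))


class _ResidualIdentityBlock:
    """conv-norm-relu-conv-norm, + input, relu; channels and size preserved.

    With all weights zeroed the block reduces to the identity followed by
    ReLU's gradient mask — the residual path is exact.
    """

    def __init__(self, channels, k, eps, rng, dtype):
        self.conv1 = nn.Conv3d(channels, channels, k, rng=rng, dtype=dtype)
        self.norm1 = nn.InstanceNorm3d(channels, eps, dtype=dtype)
        self.act1 = nn.ReLU()
        self.conv2 = nn.Conv3d(channels, channels, k, rng=rng, dtype=dtype)
        self.norm2 = nn.InstanceNorm3d(channels, eps, dtype=dtype)
        self.act_out = nn.ReLU()

    def parameters(self):
        return (self.conv1.parameters() + self.norm1.parameters()
                + self.conv2.parameters() + self.norm2.parameters())

    def forward(self, x):
        z = self.act1.forward(self.norm1.forward(self.conv1.forward(x)))
        z = self.norm2.forward(self.conv2.forward(z))
        return self.act_out.forward(z + x)

    def backward(self, gy):
        g = self.act_out.backward(gy)
        gz = self.conv1.backward(self.norm1.backward(self.act1.backward(
            self.conv2.backward(self.norm2.backward(g)))))
        return gz + g


class _ResidualDownBlock:
    """Stride-2 conv (channels x2) + norm on the main path, stride-2 1x1x1
    projection on the shortcut, addition, then ReLU."""

    def __init__(self, cin, k, eps, rng, dtype):
        cout = cin * 2
        self.conv = nn.Conv3d(cin, cout, k, stride=2, rng=rng, dtype=dtype)
        self.norm = nn.InstanceNorm3d(cout, eps, dtype=dtype)
        self.proj = nn.Conv3d(cin, cout, 1, stride=2, rng=rng, dtype=dtype)
        self.act = nn.ReLU()

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters() + self.proj.parameters()

    def forward(self, x):
        main = self.norm.forward(self.conv.forward(x))
        short = self.proj.forward(x)
        return self.act.forward(main + short)

    def backward(self, gy):
        g = self.act.backward(gy)
        gx = self.conv.backward(self.norm.backward(g))
        gx = gx + self.proj.backward(g)
        return gx


class _UpBranch:
    """Upconvolution of a level's features back to full resolution, C_0 wide."""

    def __init__(self, cin, c0, factor, eps, rng, dtype):
        if factor == 1:
            self.up = nn.Conv3d(cin, c0, 1, rng=rng, dtype=dtype)
        else:
            self.up = nn.ConvTranspose3d(cin, c0, factor, rng=rng, dtype=dtype)
        self.norm = nn.InstanceNorm3d(c0, eps, dtype=dtype)
        self.act = nn.ReLU()

    def parameters(self):
        return self.up.parameters() + self.norm.parameters()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.up.forward(x)))

    def backward(self, gy):
        return self.up.backward(self.norm.backward(self.act.backward(gy)))


class JacRegNet:
    """The trainable volume-to-volume regression model."""

    def __init__(self, cfg: NetworkConfig, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L, c0, k, eps = cfg.levels, cfg.base_filters, cfg.kernel_size, cfg.norm_epsilon
        self.stem = _ConvNormAct(cfg.in_channels, c0, k, 1, eps, rng, dtype)
        self.id_blocks = [
            _ResidualIdentityBlock(cfg.channels_at(l), k, eps, rng, dtype) for l in range(L)
        ]
        self.down_blocks = [
            _ResidualDownBlock(cfg.channels_at(l), k, eps, rng, dtype) for l in range(L - 1)
        ]
        self.branches = [
            _UpBranch(cfg.channels_at(l), c0, 2**l, eps, rng, dtype) for l in range(L)
        ]
        width = cfg.integration_channels or c0 * L
        self.integrate1 = _ConvNormAct(c0 * L, width, k, 1, eps, rng, dtype)
        self.integrate2 = nn.Conv3d(width, 1, 1, rng=rng, dtype=dtype)  # linear output
        self._branch_channels = c0

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        ps = self.stem.parameters()
        for b in self.id_blocks:
            ps += b.parameters()
        for b in self.down_blocks:
            ps += b.parameters()
        for b in self.branches:
            ps += b.parameters()
        ps += self.integrate1.parameters() + self.integrate2.parameters()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- computation -------------------------------------------------------

    def _check_input(self, x: np.ndarray):
        if x.ndim != 4:
            raise ValueError(f"expected (C, nx, ny, nz) input, got shape {x.shape}")
        if x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"arm/input mismatch: model expects {self.cfg.in_channels} channel(s), "
                f"got {x.shape[0]}"
            )
        d = self.cfg.divisor
        if any(s % d for s in x.shape[1:]):
            raise ValueError(f"spatial extents {x.shape[1:]} must be divisible by {d}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map input channels to a single-channel log2-Jacobian estimate."""
        self._check_input(x)
        a = self.stem.forward(np.asarray(x))
        feats = []
        for l in range(self.cfg.levels):
            a = self.id_blocks[l].forward(a)
            feats.append(a)
            if l < self.cfg.levels - 1:
                a = self.down_blocks[l].forward(a)
        ups = [self.branches[l].forward(feats[l]) for l in range(self.cfg.levels)]
        cat = np.concatenate(ups, axis=0)
        z = self.integrate1.forward(cat)
        return self.integrate2.forward(z)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for one sample; returns grad wrt input."""
        g = self.integrate1.backward(self.integrate2.backward(gy))
        c0 = self._branch_channels
        gfeat = [
            self.branches[l].backward(g[l * c0:(l + 1) * c0])
            for l in range(self.cfg.levels)
        ]
        gid = self.id_blocks[-1].backward(gfeat[-1])
        for l in range(self.cfg.levels - 2, -1, -1):
            gd = self.down_blocks[l].backward(gid)
            gid = self.id_blocks[l].backward(gfeat[l] + gd)
        return self.stem.backward(gid)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference; returns the (nx, ny, nz) log2-J estimate."""
        return self.forward(x)[0]

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the model")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w


def build_network(cfg: NetworkConfig, dtype=np.float32) -> JacRegNet:
    """Construct the model with He-normal initialized parameters."""
    return JacRegNet(cfg, dtype=dtype)


def expected_parameter_count(cfg: NetworkConfig) -> int:
    """Closed-form layer-ledger parameter count for a given configuration.

    Independent of the model object; used to pin the construction.
    """
    k3 = cfg.kernel_size**3
    c0, L = cfg.base_filters, cfg.levels

    def conv(cin, cout, k=k3):
        return cin * cout * k + cout

    def norm(c):
        return 2 * c

    total = conv(cfg.in_channels, c0) + norm(c0)                    # stem
    for l in range(L):
        c = cfg.channels_at(l)
        total += 2 * (conv(c, c) + norm(c))                         # identity block
    for l in range(L - 1):
        c = cfg.channels_at(l)
        total += conv(c, 2 * c) + norm(2 * c) + conv(c, 2 * c, 1)   # down block
    for l in range(L):
        c = cfg.channels_at(l)
        kup = (2**l) ** 3 if l > 0 else 1
        total += conv(c, c0, kup) + norm(c0)                        # up branch
    width = cfg.integration_channels or c0 * L
    total += conv(c0 * L, width) + norm(width)                      # integration 1
    total += conv(width, 1, 1)                                      # integration 2 (linear)
    return total


def predict_jacobian(model: JacRegNet, prepared: PreparedCase, arm) -> JacobianMap:
    """Run inference for one case and return the decoded Jacobian map.

    ``arm`` provides ``input_factor`` ('single'/'paired') and ``output_space``
    ('FRC'/'TLC'); channels are selected accordingly and the prediction is
    un-padded back to the cropped grid.  Positivity of J is guaranteed by the
    log2 decoding.
    """
    x = select_channels(prepared.x, arm)
    y = model.predict(x)
    y = unpad(y, prepared.pads)
    mask = unpad(prepared.mask(arm.output_space), prepared.pads)
    y = np.where(mask > 0, y, 0.0)
    Yvol = Volume3D(y.astype(np.float32), prepared.spacing, (0.0, 0.0, 0.0),
                    intensity_kind="log2_jacobian")
    jmap = JacobianMap.from_Y(Yvol, frame=arm.output_space.upper())
    return jmap


def select_channels(x: np.ndarray, arm) -> np.ndarray:
    """Pick the network input channels for a study arm from the (FRC, TLC) stack."""
    factor = arm.input_factor
    space = arm.output_space.upper()
    if factor == "paired":
        return x
    if factor == "single":
        return x[0:1] if space == "FRC" else x[1:2]
    raise ValueError(f"unknown input factor {factor!r}")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: JacRegNet, path, extra: dict | None = None) -> Path:
    """Serialize weights and the embedded NetworkConfig to a single file."""
    path = Path(path)
    if path.suffix != ".npz":  # np.savez appends .npz silently otherwise
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.parameters())}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path) -> tuple[JacRegNet, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = NetworkConfig(**meta["config"])
        model = build_network(cfg)
        n = len(model.parameters())
        weights = [z[f"param_{i:04d}"] for i in range(n)]
    model.set_weights(weights)
    return model, meta["extra"]
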