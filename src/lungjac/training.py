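"""Losses, the optimization loop, and the 2x2 factorial training harness.

The training target is the signed log2-Jacobian ``Y``.  The loss is a convex
combination of a mask-restricted mean absolute error and a mask-restricted
structural-similarity (SSIM) term,

    L_total = alpha * L_MAE + (1 - alpha) * L_SSIM,      alpha = 0.5

with per-voxel SSIM computed from Gaussian-weighted local means, variances
and covariance over 7^3 patches (sigma 1.5), constants C1 = (K1 * Delta)^2,
C2 = (K2 * Delta)^2 with K1 = 0.01, K2 = 0.03 and dynamic range Delta = 5.
SSIM statistics are computed over the full padded volume (patches near the
lung boundary see background values) and then averaged over in-mask voxels.

Optimization uses Adam with the AMSGrad variant at learning rate 1e-4 and
He-normal initialization.  The factorial harness trains the four study arms
{single, paired} x {FRC, TLC} on one shared train/validation/test split;
single-input arms consume only the image matching their output space.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import NetworkConfig, JacRegNet, build_network, select_channels
from .preprocess import PreparedCase, PreprocessConfig, prepare_case

__all__ = [
    "SSIMParams", "LossConfig", "TrainConfig", "StudyArm", "ALL_ARMS",
    "loss_mae", "ssim_map", "loss_ssim", "loss_total", "loss_total_and_grad",
    "train_arm", "run_factorial", "TrainResult", "FactorialResult",
    "TrainingDiverged", "split_cohort",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SSIMParams:
    patch_size: int = 7
    gaussian_sigma: float = 1.5
    dynamic_range: float = 5.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.patch_size % 2 != 1:
            raise ValueError("patch_size must be odd")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("C1 and C2 must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    def kernel1d(self) -> np.ndarray:
        r = (self.patch_size - 1) // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(x**2) / (2.0 * self.gaussian_sigma**2))
        return w / w.sum()


@dataclasses.dataclass
class LossConfig:
    alpha: float = 0.5
    ssim: SSIMParams = dataclasses.field(default_factory=SSIMParams)

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    amsgrad: bool = True
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass(frozen=True)
class StudyArm:
    """One cell of the 2x2 design: input factor x output space.

    Single-input arms consume only the image matching the output space (the
    FRC image for FRC-space prediction, the TLC image for TLC-space).
    """

    input_factor: str  # "single" | "paired"
    output_space: str  # "FRC" | "TLC"

    def __post_init__(self):
        if self.input_factor not in ("single", "paired"):
            raise ValueError(f"unknown input factor {self.input_factor!r}")
        if self.output_space.upper() not in ("FRC", "TLC"):
            raise ValueError(f"unknown output space {self.output_space!r}")
        object.__setattr__(self, "output_space", self.output_space.upper())

    @property
    def in_channels(self) -> int:
        return 2 if self.input_factor == "paired" else 1

    @property
    def name(self) -> str:
        return f"{self.input_factor}_{self.output_space.lower()}"


ALL_ARMS = (
    StudyArm("single", "FRC"),
    StudyArm("paired", "FRC"),
    StudyArm("single", "TLC"),
    StudyArm("paired", "TLC"),
)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _arr(x) -> np.ndarray:
    return np.asarray(getattr(x, "data", x), dtype=np.float64)


def _mask_arr(mask) -> np.ndarray:
    m = np.asarray(getattr(mask, "data", mask))
    m = (m > 0)
    if not np.any(m):
        raise ValueError("empty mask")
    return m


def loss_mae(Y, Y_hat, mask) -> float:
    """Mean absolute error over in-mask voxels."""
    m = _mask_arr(mask)
    return float(np.abs(_arr(Y) - _arr(Y_hat))[m].mean())


def _gfilter(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable Gaussian-weighted patch filter with zero padding.

    Zero padding makes the filter match brute-force patch extraction from a
    zero-padded volume and makes the operator self-adjoint (the kernel is
    symmetric), which the analytic SSIM gradient relies on.
    """
    out = x
    for axis in range(3):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="constant", cval=0.0)
    return out


def _ssim_terms(a: np.ndarray, b: np.ndarray, p: SSIMParams):
    k = p.kernel1d()
    mu_a = _gfilter(a, k)
    mu_b = _gfilter(b, k)
    var_a = _gfilter(a * a, k) - mu_a**2
    var_b = _gfilter(b * b, k) - mu_b**2
    cov = _gfilter(a * b, k) - mu_a * mu_b
    n1 = 2.0 * mu_a * mu_b + p.c1
    d1 = mu_a**2 + mu_b**2 + p.c1
    n2 = 2.0 * cov + p.c2
    d2 = var_a + var_b + p.c2
    return k, mu_a, mu_b, n1, d1, n2, d2


def ssim_map(Y, Y_hat, params: SSIMParams | None = None) -> np.ndarray:
    """Per-voxel SSIM between two volumes (values <= 1)."""
    p = params or SSIMParams()
    a, b = _arr(Y), _arr(Y_hat)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    _, _, _, n1, d1, n2, d2 = _ssim_terms(a, b, p)
    return (n1 * n2) / (d1 * d2)


def loss_ssim(Y, Y_hat, mask, params: SSIMParams | None = None) -> float:
    """Mean over in-mask voxels of (1 - SSIM)."""
    m = _mask_arr(mask)
    s = ssim_map(Y, Y_hat, params)
    return float((1.0 - s)[m].mean())


def loss_total(Y, Y_hat, mask, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    total = 0.0
    if cfg.alpha > 0:
        total += cfg.alpha * loss_mae(Y, Y_hat, mask)
    if cfg.alpha < 1:
        total += (1.0 - cfg.alpha) * loss_ssim(Y, Y_hat, mask, cfg.ssim)
    return float(total)


def loss_total_and_grad(Y, Y_hat, mask, cfg: LossConfig | None = None):
    """Total loss and its analytic gradient with respect to the prediction."""
    cfg = cfg or LossConfig()
    a, b = _arr(Y), _arr(Y_hat)
    m = _mask_arr(mask)
    w = m.astype(np.float64) / m.sum()
    grad = np.zeros_like(b)
    total = 0.0
    if cfg.alpha > 0:
        total += cfg.alpha * float(np.abs(a - b)[m].mean())
        grad += cfg.alpha * np.sign(b - a) * w
    if cfg.alpha < 1:
        p = cfg.ssim
        k, mu_a, mu_b, n1, d1, n2, d2 = _ssim_terms(a, b, p)
        S = (n1 * n2) / (d1 * d2)
        total += (1.0 - cfg.alpha) * float((1.0 - S)[m].mean())
        dLdS = -(1.0 - cfg.alpha) * w
        g_mu = dLdS * (2.0 * mu_a * n2 / (d1 * d2) - 2.0 * mu_b * S / d1)
        g_var = dLdS * (-S / d2)
        g_cov = dLdS * (2.0 * n1 / (d1 * d2))
        grad += (
            _gfilter(g_mu, k)
            + 2.0 * b * _gfilter(g_var, k) - 2.0 * _gfilter(g_var * mu_b, k)
            + a * _gfilter(g_cov, k) - _gfilter(g_cov * mu_a, k)
        )
    return float(total), grad


# ---------------------------------------------------------------------------
# Optimization loop
# ---------------------------------------------------------------------------


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


@dataclasses.dataclass
class TrainResult:
    arm: StudyArm
    model: JacRegNet
    history: pd.DataFrame
    best_epoch: int
    train_ids: list[str]
    val_ids: list[str]


def _sample_loss_and_grad(model, sample: PreparedCase, arm: StudyArm, loss_cfg: LossConfig,
                          scale: float = 1.0, backward: bool = True) -> float:
    x = select_channels(sample.x, arm)
    y_hat = model.forward(x.astype(np.float32))
    y = sample.target(arm.output_space)
    m = sample.mask(arm.output_space)
    loss, grad = loss_total_and_grad(y, y_hat[0], m, loss_cfg)
    if backward:
        model.backward((grad * scale)[None].astype(y_hat.dtype))
    return loss


def _eval_loss(model, samples, arm, loss_cfg) -> float:
    losses = []
    for s in samples:
        x = select_channels(s.x, arm)
        y_hat = model.predict(x.astype(np.float32))
        losses.append(loss_total(s.target(arm.output_space), y_hat,
                                 s.mask(arm.output_space), loss_cfg))
    return float(np.mean(losses))


def train_arm(
    arm: StudyArm,
    dataset: list[PreparedCase],
    net_cfg: NetworkConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> TrainResult:
    """Optimize one study arm; deterministic given the seed.

    A validation subset (``val_fraction`` of the training cases) is held out
    for checkpoint selection; the returned model carries the weights of the
    epoch with the best validation loss (best training loss when the dataset
    is too small for a validation split).
    """
    from . import nn

    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    base = net_cfg or NetworkConfig()
    net_cfg = dataclasses.replace(base, in_channels=arm.in_channels,
                                  seed=base.seed + {"FRC": 0, "TLC": 1}[arm.output_space]
                                  + {"single": 0, "paired": 2}[arm.input_factor])
    model = build_network(net_cfg)

    rng = np.random.default_rng(train_cfg.seed)
    idx = np.arange(len(dataset))
    rng.shuffle(idx)
    n_val = int(round(train_cfg.val_fraction * len(dataset)))
    n_val = min(n_val, len(dataset) - 1)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    train_set = [dataset[i] for i in tr_idx]
    val_set = [dataset[i] for i in val_idx]

    opt = nn.AMSGrad(model.parameters(), lr=train_cfg.learning_rate,
                     amsgrad=train_cfg.amsgrad)
    rows = []
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            for i in batch:
                loss = _sample_loss_and_grad(model, train_set[i], arm, loss_cfg,
                                             scale=1.0 / len(batch))
                epoch_losses.append(loss)
            opt.step()
        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(model, val_set, arm, loss_cfg) if val_set else np.nan
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if not np.isfinite(train_loss):
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch} in arm {arm.name}",
                pd.DataFrame(rows),
            )
        select_loss = val_loss if val_set else train_loss
        if select_loss < best_loss:
            best_loss = select_loss
            best_weights = model.get_weights()
            best_epoch = epoch
    model.set_weights(best_weights)
    return TrainResult(
        arm=arm, model=model, history=pd.DataFrame(rows), best_epoch=best_epoch,
        train_ids=[train_set[i].case_id for i in range(len(train_set))],
        val_ids=[s.case_id for s in val_set],
    )


# ---------------------------------------------------------------------------
# Factorial harness
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FactorialResult:
    results: dict[str, TrainResult]
    train_cases: list[PreparedCase]
    test_cases: list[PreparedCase]
    manifest: dict


def split_cohort(n: int, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared, seeded train/test split (defaults mimic a 90/10 hold-out)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return np.sort(idx[n_test:]), np.sort(idx[:n_test])


def _split_hash(ids: list[str]) -> str:
    return hashlib.sha256("|".join(sorted(ids)).encode()).hexdigest()[:16]


def run_factorial(
    cohort,
    net_cfg: NetworkConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    test_fraction: float = 0.1,
    arms=ALL_ARMS,
) -> FactorialResult:
    """Train all four arms on one shared split with shared seeds.

    ``cohort`` may be a list of phantom cases (preprocessed here) or of
    already-prepared cases.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    if cohort and not isinstance(cohort[0], PreparedCase):
        multiple = net_cfg.divisor
        cohort = [prepare_case(c, preprocess_cfg, multiple=multiple) for c in cohort]
    tr_idx, te_idx = split_cohort(len(cohort), test_fraction, train_cfg.seed)
    train_cases = [cohort[i] for i in tr_idx]
    test_cases = [cohort[i] for i in te_idx]
    results: dict[str, TrainResult] = {}
    for arm in arms:
        results[arm.name] = train_arm(arm, train_cases, net_cfg, loss_cfg, train_cfg)
    manifest = {
        "arms": sorted(results.keys()),
        "n_train": len(train_cases),
        "n_test": len(test_cases),
        "train_split_hash": _split_hash([c.case_id for c in train_cases]),
        "test_split_hash": _split_hash([c.case_id for c in test_cases]),
        "seed": train_cfg.seed,
        "network": net_cfg.to_dict(),
        "learning_rate": train_cfg.learning_rate,
        "epochs": train_cfg.epochs,
    }
    return FactorialResult(results=results, train_cases=train_cases,
                           test_cases=test_cases, manifest=manifest)
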