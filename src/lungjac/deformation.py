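"""Transformations and Jacobian-determinant mathematics.

A deformation ``h`` maps points of the fixed-image frame into the moving-image
frame, ``h(x) = x + u(x)`` for a displacement field ``u`` in mm.  The
determinant of its spatial Jacobian matrix is the voxelwise multiplicative
local volume change: ``J > 1`` expansion, ``J < 1`` contraction.  When the
fixed image is the expiratory (FRC) scan, ``J_FRC`` measures expansion toward
inspiration (TLC); registering the other way round, ``J_TLC`` measures the
reciprocal contraction, and for a consistent pair
``J_FRC(x) * J_TLC(h(x)) = 1``.

Targets are encoded as ``Y = log2(J)`` so reciprocal volume ratios have equal
magnitude and opposite sign.

Three analytic deformation families with closed-form Jacobians (affine,
separable sinusoid, radial bump) and their compositions are provided as exact
ground-truth generators standing in for the output contract of a deformable
image registration algorithm.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import LungMask, Volume3D, _as_triple

__all__ = [
    "DisplacementField",
    "JacobianMap",
    "AnalyticDeformation",
    "Affine",
    "SeparableSinusoid",
    "RadialBump",
    "Compose",
    "jacobian_determinant",
    "log2_encode",
    "log2_decode",
    "evaluate_analytic",
    "invert_analytic",
]

INVERSE_TOL_MM = 1e-3
INVERSE_MAX_ITER = 50


class FoldingWarning(UserWarning):
    """Raised as a warning when a displacement field folds (J <= 0 in-mask)."""


# ---------------------------------------------------------------------------
# Displacement fields and Jacobian maps
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm on a regular grid.

    ``u`` has shape ``(nx, ny, nz, 3)``; ``frame`` names the fixed-image space
    the field lives in (``"FRC"`` or ``"TLC"``).
    """

    u: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "FRC"

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"displacement field must have shape (nx,ny,nz,3), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]


@dataclasses.dataclass
class JacobianMap:
    """Paired linear (J) and log2 (Y) encodings of a volume-change map."""

    J: Volume3D
    Y: Volume3D
    frame: str = "FRC"
    folded: bool = False  # quality flag: J <= 0 occurred in-mask

    @classmethod
    def from_J(cls, J: Volume3D, frame: str = "FRC", mask: LungMask | None = None,
               folded: bool = False) -> "JacobianMap":
        Y = log2_encode(J, mask=mask)
        Jv = J.copy(intensity_kind="jacobian")
        return cls(J=Jv, Y=Y, frame=frame, folded=folded)

    @classmethod
    def from_Y(cls, Y: Volume3D, frame: str = "FRC") -> "JacobianMap":
        J = log2_decode(Y)
        Yv = Y.copy(intensity_kind="log2_jacobian")
        return cls(J=J, Y=Yv, frame=frame, folded=False)


def log2_encode(J: Volume3D, mask: LungMask | None = None) -> Volume3D:
    """``Y = log2 J``; expansion maps to ``Y > 0``, contraction to ``Y < 0``.

    With a mask, positivity is enforced in-mask only and out-of-mask voxels
    with non-positive J are encoded as 0 (no volume change).
    """
    data = np.asarray(J.data, dtype=np.float64)
    if mask is None:
        if np.any(data <= 0):
            raise ValueError("log2_encode requires strictly positive J")
        Y = np.log2(data)
    else:
        inside = mask.as_bool()
        if np.any(data[inside] <= 0):
            raise ValueError("log2_encode: non-positive J inside the lung mask")
        Y = np.where(data > 0, np.log2(np.where(data > 0, data, 1.0)), 0.0)
    return Volume3D(Y.astype(np.float32), J.spacing, J.origin, intensity_kind="log2_jacobian")


def log2_decode(Y: Volume3D) -> Volume3D:
    """``J = 2**Y``, strictly positive by construction."""
    if not np.all(np.isfinite(Y.data)):
        raise ValueError("log2_decode requires finite Y")
    J = np.exp2(np.asarray(Y.data, dtype=np.float64))
    return Volume3D(J.astype(np.float32), Y.spacing, Y.origin, intensity_kind="jacobian")


def jacobian_determinant(field: DisplacementField, mask: LungMask) -> JacobianMap:
    """Numeric ``det(I + du/dx)`` of a displacement field, in physical units.

    Central differences in the interior, first-order one-sided differences on
    the outermost voxel layer.  Central differences make the result exact (to
    floating point) for affine displacements.  Non-positive determinants
    inside the mask set the ``folded`` quality flag and raise a
    ``FoldingWarning`` rather than an error.
    """
    if field.shape != mask.shape:
        raise ValueError(f"field shape {field.shape} != mask shape {mask.shape}")
    u = field.u.astype(np.float64)
    # G[i][j] = d u_i / d x_j, derivatives taken in mm.
    G = np.empty(field.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        grads = np.gradient(u[..., i], *field.spacing, edge_order=1)
        for j in range(3):
            G[..., i, j] = grads[j]
    F = G
    for i in range(3):
        F[..., i, i] += 1.0
    det = (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )
    folded = bool(np.any(det[mask.as_bool()] <= 0))
    if folded:
        warnings.warn(
            "displacement field folds inside the lung mask (J <= 0); "
            "case flagged, values retained",
            FoldingWarning,
        )
    # folded voxels are recorded via the flag; the stored map replaces them
    # with 1 so the log2 encoding stays defined
    Jsafe = det if not folded else np.where(det > 0, det, 1.0)
    Jvol = Volume3D(Jsafe, field.spacing, field.origin, intensity_kind="jacobian")
    return JacobianMap.from_J(Jvol, frame=field.frame, mask=mask, folded=folded)


# ---------------------------------------------------------------------------
# Analytic deformation families
# ---------------------------------------------------------------------------


class AnalyticDeformation:
    """A deformation with closed-form evaluation, Jacobian, and inverse.

    Subclasses operate on arrays of physical points with shape ``(..., 3)``.
    """

    def __call__(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def jacobian(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def inverse(self) -> "AnalyticDeformation":  # pragma: no cover - abstract
        raise NotImplementedError


@dataclasses.dataclass
class Affine(AnalyticDeformation):
    """``h(x) = center + A (x - center) + t`` with constant Jacobian det(A)."""

    A: np.ndarray
    t: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if np.linalg.det(self.A) <= 0:
            raise ValueError("affine deformation must be orientation-preserving (det > 0)")

    @classmethod
    def scaling(cls, scales, center=(0.0, 0.0, 0.0)) -> "Affine":
        s = np.broadcast_to(np.asarray(scales, dtype=float), (3,))
        return cls(A=np.diag(s), center=np.asarray(center, dtype=float))

    def __call__(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        return self.center + (pts - self.center) @ self.A.T + self.t

    def jacobian(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        return np.full(pts.shape[:-1], float(np.linalg.det(self.A)))

    def inverse(self) -> "Affine":
        Ainv = np.linalg.inv(self.A)
        return Affine(A=Ainv, t=-Ainv @ self.t, center=self.center)


@dataclasses.dataclass
class SeparableSinusoid(AnalyticDeformation):
    """Per-axis ``h_i(x) = x_i + amp_i * sin(freq_i (x_i - center_i) + phase_i)``.

    Separability makes the Jacobian an exact product of per-axis factors
    ``1 + amp_i freq_i cos(...)``; positivity requires ``|amp_i freq_i| < 1``.
    """

    amp: np.ndarray
    freq: np.ndarray
    phase: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.amp = np.broadcast_to(np.asarray(self.amp, dtype=float), (3,)).copy()
        self.freq = np.broadcast_to(np.asarray(self.freq, dtype=float), (3,)).copy()
        self.phase = np.broadcast_to(np.asarray(self.phase, dtype=float), (3,)).copy()
        self.center = np.broadcast_to(np.asarray(self.center, dtype=float), (3,)).copy()
        prod = np.abs(self.amp * self.freq)
        if np.any(prod >= 1.0):
            raise ValueError(
                f"|amp*freq| must be < 1 for an orientation-preserving map, got {prod}"
            )

    def _arg(self, pts):
        return self.freq * (np.asarray(pts, dtype=np.float64) - self.center) + self.phase

    def __call__(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        return pts + self.amp * np.sin(self._arg(pts))

    def jacobian(self, pts):
        factors = 1.0 + self.amp * self.freq * np.cos(self._arg(pts))
        return np.prod(factors, axis=-1)

    def inverse(self) -> "_SinusoidInverse":
        return _SinusoidInverse(self)


@dataclasses.dataclass
class _SinusoidInverse(AnalyticDeformation):
    """Fixed-point inverse of a separable sinusoid (per-axis contraction map)."""

    fwd: SeparableSinusoid

    def __call__(self, pts):
        y = np.asarray(pts, dtype=np.float64)
        x = y.copy()
        for _ in range(INVERSE_MAX_ITER):
            x_new = y - self.fwd.amp * np.sin(self.fwd._arg(x))
            delta = np.abs(x_new - x).max() if x.size else 0.0
            x = x_new
            if delta < INVERSE_TOL_MM * 0.1:
                break
        else:
            raise RuntimeError("sinusoid inverse fixed-point iteration did not converge")
        return x

    def jacobian(self, pts):
        x = self(pts)
        return 1.0 / self.fwd.jacobian(x)

    def inverse(self) -> SeparableSinusoid:
        return self.fwd


@dataclasses.dataclass
class RadialBump(AnalyticDeformation):
    """Radial compression/expansion pocket around ``center``.

    ``h(x) = center + (1 - a * exp(-r^2 / (2 sigma^2))) * (x - center)`` with
    ``r = |x - center|``.  For ``a > 0`` the neighborhood of ``center`` is
    compressed (local J < 1), emulating a low-distensibility gas-trapping
    pocket.  Positivity holds for ``|a| < 1``.
    Closed-form Jacobian: ``J = g'(r) * (g(r)/r)^2`` with ``g(r) = r (1 - a E)``,
    ``E = exp(-r^2/(2 sigma^2))``, ``g'(r) = 1 - a E (1 - r^2/sigma^2)``.
    """

    a: float
    sigma: float
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if not (abs(self.a) < 1.0):
            raise ValueError("|a| must be < 1 for an orientation-preserving radial bump")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def _E(self, r2):
        return np.exp(-r2 / (2.0 * self.sigma**2))

    def __call__(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        d = pts - self.center
        r2 = np.sum(d * d, axis=-1, keepdims=True)
        return self.center + d * (1.0 - self.a * self._E(r2))

    def jacobian(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        d = pts - self.center
        r2 = np.sum(d * d, axis=-1)
        E = self._E(r2)
        radial = 1.0 - self.a * E * (1.0 - r2 / self.sigma**2)   # g'(r)
        tangential = 1.0 - self.a * E                            # g(r)/r
        return radial * tangential**2

    def inverse(self) -> "_RadialInverse":
        return _RadialInverse(self)


@dataclasses.dataclass
class _RadialInverse(AnalyticDeformation):
    """Fixed-point inverse of a radial bump (solves g(r) = r_y per point)."""

    fwd: RadialBump

    def __call__(self, pts):
        y = np.asarray(pts, dtype=np.float64)
        d = y - self.fwd.center
        ry = np.sqrt(np.sum(d * d, axis=-1))
        r = ry.copy()
        for _ in range(INVERSE_MAX_ITER):
            r_new = ry + self.fwd.a * r * self.fwd._E(r * r)
            delta = np.abs(r_new - r).max() if r.size else 0.0
            r = np.maximum(r_new, 0.0)
            if delta < INVERSE_TOL_MM * 0.1:
                break
        else:
            raise RuntimeError("radial inverse fixed-point iteration did not converge")
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(ry > 0, r / np.where(ry > 0, ry, 1.0), 1.0)
        return self.fwd.center + d * scale[..., None]

    def jacobian(self, pts):
        x = self(pts)
        return 1.0 / self.fwd.jacobian(x)

    def inverse(self) -> RadialBump:
        return self.fwd


@dataclasses.dataclass
class Compose(AnalyticDeformation):
    """``h = outer ∘ inner``; Jacobian by the chain rule, exact."""

    outer: AnalyticDeformation
    inner: AnalyticDeformation

    def __call__(self, pts):
        return self.outer(self.inner(pts))

    def jacobian(self, pts):
        xin = self.inner(pts)
        return self.outer.jacobian(xin) * self.inner.jacobian(pts)

    def inverse(self) -> "Compose":
        return Compose(outer=self.inner.inverse(), inner=self.outer.inverse())


def compose_all(*defs: AnalyticDeformation) -> AnalyticDeformation:
    """Compose left-to-right as outermost-to-innermost: h = d0 ∘ d1 ∘ ... ∘ dn."""
    if not defs:
        raise ValueError("need at least one deformation")
    out = defs[0]
    for d in defs[1:]:
        out = Compose(outer=out, inner=d)
    return out


# ---------------------------------------------------------------------------
# Sampling analytic deformations on grids
# ---------------------------------------------------------------------------


def evaluate_analytic(
    deformation: AnalyticDeformation,
    template: Volume3D | LungMask,
    frame: str = "FRC",
    mask: LungMask | None = None,
) -> tuple[DisplacementField, JacobianMap]:
    """Sample a deformation and its exact Jacobian on a volume's grid."""
    shape = template.shape
    axes = [template.origin[a] + template.spacing[a] * np.arange(shape[a]) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    mapped = deformation(pts)
    u = mapped - pts
    J = deformation.jacobian(pts)
    if np.any(J <= 0):
        raise ValueError("analytic deformation parameters produce non-positive Jacobian")
    field = DisplacementField(u=u, spacing=template.spacing, origin=template.origin, frame=frame)
    Jvol = Volume3D(J.astype(np.float32), template.spacing, template.origin,
                    intensity_kind="jacobian")
    jmap = JacobianMap.from_J(Jvol, frame=frame, mask=mask)
    return field, jmap


def invert_analytic(deformation: AnalyticDeformation) -> AnalyticDeformation:
    """Inverse transformation ``g`` with ``h(g(x)) = x`` to ~1e-3 mm.

    Closed form for affine; per-point fixed-point iteration for the sinusoid
    and radial families (and compositions thereof).
    """
    return deformation.inverse()


# ---------------------------------------------------------------------------
# 4D NIfTI I/O for displacement fields
# ---------------------------------------------------------------------------


def write_displacement_field(field: DisplacementField, path) -> Path:
    """Write as 4D NIfTI with the vector component along the fourth axis (mm)."""
    path = Path(path)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(field.spacing)
    aff[:3, 3] = field.origin
    img = nib.Nifti1Image(field.u.astype(np.float32), aff)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_displacement_field(path, frame: str = "FRC") -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"expected 4D displacement field with 3 components, got {data.shape}")
    aff = img.affine
    return DisplacementField(
        u=data.astype(np.float64),
        spacing=tuple(np.diag(aff[:3, :3])),
        origin=tuple(aff[:3, 3]),
        frame=frame,
    )
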