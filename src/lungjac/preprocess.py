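"""Preprocessing chain for paired inflation CT.

Order of operations, applied identically to every case:

1. anti-alias Gaussian smoothing (intensity volumes only) and resampling to
   isotropic target spacing (default 3 mm); masks and label maps are
   nearest-neighbor resampled without smoothing;
2. cropping to the union bounding box of the two lung masks;
3. masking (out-of-lung voxels set to the background HU, default -1024);
4. clamping to [-1024, 200] HU and linear rescaling to [-1, 1];
5. symmetric padding so each extent is divisible by the network's
   downsampling factor (fill = -1, the normalized background).

Ground-truth log2-Jacobian maps follow the same resample/crop/pad path with
linear interpolation and are set to 0 outside the lung.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .volumes import LungMask, ROILabelMap, Volume3D, bounding_box_union, crop_to_box

__all__ = [
    "PreprocessConfig",
    "resample_isotropic",
    "crop_mask_normalize",
    "pad_to_multiple",
    "unpad",
    "PreparedCase",
    "prepare_case",
]


@dataclasses.dataclass
class PreprocessConfig:
    target_spacing: float = 3.0
    clamp_lo: float = -1024.0
    clamp_hi: float = 200.0
    rescale_lo: float = -1.0
    rescale_hi: float = 1.0
    background_hu: float = -1024.0
    # anti-alias sigma in input voxels per axis = sigma_per_ratio * downsample ratio,
    # skipped when the ratio is <= 1 (upsampling)
    sigma_per_ratio: float = 0.5
    smoothing: bool = True

    def __post_init__(self):
        if self.clamp_lo >= self.clamp_hi:
            raise ValueError("clamp_lo must be < clamp_hi")
        if self.rescale_lo >= self.rescale_hi:
            raise ValueError("rescale_lo must be < rescale_hi")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")

    def normalize(self, hu: np.ndarray) -> np.ndarray:
        """Clamp to [clamp_lo, clamp_hi] and map affinely to [rescale_lo, rescale_hi]."""
        c = np.clip(hu, self.clamp_lo, self.clamp_hi)
        frac = (c - self.clamp_lo) / (self.clamp_hi - self.clamp_lo)
        return self.rescale_lo + frac * (self.rescale_hi - self.rescale_lo)


def resample_isotropic(v, cfg: PreprocessConfig, interpolation: str = "linear"):
    """Resample a volume/mask/label map to isotropic ``cfg.target_spacing``.

    Intensity volumes are Gaussian pre-smoothed when downsampling and linearly
    interpolated; masks/label maps use nearest-neighbor with no smoothing.
    Output shape is ``ceil(input_extent / target_spacing)`` per axis.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    spacing_in = np.asarray(v.spacing, dtype=float)
    t = cfg.target_spacing
    ratios = t / spacing_in
    out_shape = tuple(int(math.ceil(s * sp / t)) for s, sp in zip(v.shape, spacing_in))
    data = np.asarray(v.data, dtype=np.float64)
    if interpolation == "linear" and cfg.smoothing:
        sigmas = np.where(ratios > 1.0, cfg.sigma_per_ratio * ratios, 0.0)
        if np.any(sigmas > 0):
            data = ndimage.gaussian_filter(data, sigma=sigmas, mode="nearest")
    coords = np.meshgrid(
        *[np.arange(n) * r for n, r in zip(out_shape, ratios)], indexing="ij"
    )
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(data, np.stack(coords), order=order, mode="nearest")
    spacing_out = (t, t, t)
    if isinstance(v, LungMask):
        return LungMask(out.astype(np.uint8), spacing_out, v.origin)
    if isinstance(v, ROILabelMap):
        return ROILabelMap(np.rint(out).astype(np.uint16), dict(v.label_table),
                           spacing_out, v.origin)
    return Volume3D(out.astype(np.float32), spacing_out, v.origin, v.intensity_kind)


def crop_mask_normalize(
    i_frc: Volume3D,
    i_tlc: Volume3D,
    m_frc: LungMask,
    m_tlc: LungMask,
    cfg: PreprocessConfig,
):
    """Crop to the union mask bounding box, mask, clamp, and rescale to [-1, 1].

    Returns the two normalized images, the two cropped masks, and the crop box
    (half-open index intervals) for provenance.
    """
    for other in (i_tlc, m_frc, m_tlc):
        if not i_frc.same_grid(other):
            raise ValueError("all four inputs must share one grid")
    box = bounding_box_union(m_frc, m_tlc)
    out_images = []
    for img, mask in ((i_frc, m_frc), (i_tlc, m_tlc)):
        hu = crop_to_box(np.asarray(img.data, dtype=np.float64), box)
        m = crop_to_box(mask.data, box)
        hu = np.where(m > 0, hu, cfg.background_hu)
        norm = cfg.normalize(hu)
        origin = tuple(img.origin[a] + box[a, 0] * img.spacing[a] for a in range(3))
        out_images.append(
            Volume3D(norm.astype(np.float32), img.spacing, origin, intensity_kind="normalized")
        )
    out_masks = []
    for mask in (m_frc, m_tlc):
        origin = tuple(mask.origin[a] + box[a, 0] * mask.spacing[a] for a in range(3))
        out_masks.append(LungMask(crop_to_box(mask.data, box), mask.spacing, origin))
    return out_images[0], out_images[1], out_masks[0], out_masks[1], box


def pad_to_multiple(data: np.ndarray, multiple: int, fill: float = -1.0):
    """Symmetrically pad a 3D array so each extent divides ``multiple``.

    Returns ``(padded, pads)`` with ``pads`` a list of (before, after) per
    axis, for inverse cropping of predictions.
    """
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    pads = []
    for n in data.shape[:3]:
        target = int(math.ceil(n / multiple)) * multiple
        extra = target - n
        pads.append((extra // 2, extra - extra // 2))
    padded = np.pad(data, pads, mode="constant", constant_values=fill)
    return padded, pads


def unpad(data: np.ndarray, pads) -> np.ndarray:
    """Inverse of :func:`pad_to_multiple` (bit-exact round trip)."""
    sl = tuple(slice(lo, data.shape[a] - hi) for a, (lo, hi) in enumerate(pads))
    return data[sl]


def random_placement_pads(shape, multiple: int, rng: np.random.Generator) -> list:
    """Random canvas growth and placement for a cropped volume.

    The canvas per axis is the next multiple of ``multiple`` at or above the
    extent plus a random 0..multiple-1 growth, and the content sits at a
    random offset inside it.  This decouples the array bounds from the crop
    box: with tight symmetric padding the distance from the lung edge to the
    array edge would directly encode the expiratory-to-inspiratory size
    ratio, handing single-input models the inflation magnitude through pure
    geometry.  It doubles as translation augmentation.  Deterministic given
    the generator.
    """
    pads = []
    for n in shape[:3]:
        grown = n + int(rng.integers(0, multiple))
        target = int(math.ceil(grown / multiple)) * multiple
        lo = int(rng.integers(0, target - n + 1))
        pads.append((lo, target - n - lo))
    return pads


def _apply_pads(data: np.ndarray, pads, fill: float) -> np.ndarray:
    return np.pad(data, pads, mode="constant", constant_values=fill)


@dataclasses.dataclass
class PreparedCase:
    """A case after the full preprocessing chain, ready for the network.

    ``x_frc``/``x_tlc`` hold the normalized image channels stacked as
    ``(C, nx, ny, nz)`` with channel order (FRC, TLC); ``y_*`` the padded
    log2-Jacobian targets in each output space; ``mask_*`` the padded lung
    masks.  ``pads`` and ``box`` record the padding and crop for provenance
    and for mapping predictions back onto the cropped grid.
    """

    case_id: str
    x: np.ndarray                 # (2, ...) normalized channels, order (FRC, TLC)
    y_frc: np.ndarray             # padded log2-J target, FRC frame
    y_tlc: np.ndarray
    mask_frc: np.ndarray          # padded {0,1} masks
    mask_tlc: np.ndarray
    pads: list
    box: np.ndarray
    spacing: tuple[float, float, float]
    effort_true: float
    meta: dict

    def target(self, output_space: str) -> np.ndarray:
        return self.y_frc if output_space.upper() == "FRC" else self.y_tlc

    def mask(self, output_space: str) -> np.ndarray:
        return self.mask_frc if output_space.upper() == "FRC" else self.mask_tlc


def prepare_case(case, cfg: PreprocessConfig | None = None, multiple: int = 8,
                 placement: str = "random") -> PreparedCase:
    """Run the full chain on a phantom case (or any case with its fields).

    ``placement='random'`` (default) pads onto a randomly grown canvas with
    a random, case-seeded offset (see :func:`random_placement_pads`);
    ``'symmetric'`` uses the minimal symmetric padding.
    """
    cfg = cfg or PreprocessConfig()
    i_frc = resample_isotropic(case.I_FRC, cfg, "linear")
    i_tlc = resample_isotropic(case.I_TLC, cfg, "linear")
    m_frc = resample_isotropic(case.M_FRC, cfg, "nearest")
    m_tlc = resample_isotropic(case.M_TLC, cfg, "nearest")
    y_frc_v = resample_isotropic(case.J_FRC.Y, cfg, "linear")
    y_tlc_v = resample_isotropic(case.J_TLC.Y, cfg, "linear")

    nf, nt, mf, mt, box = crop_mask_normalize(i_frc, i_tlc, m_frc, m_tlc, cfg)
    y_frc = crop_to_box(np.asarray(y_frc_v.data, dtype=np.float64), box)
    y_tlc = crop_to_box(np.asarray(y_tlc_v.data, dtype=np.float64), box)
    y_frc = np.where(mf.data > 0, y_frc, 0.0)
    y_tlc = np.where(mt.data > 0, y_tlc, 0.0)

    fill = cfg.rescale_lo
    if placement == "random":
        seed = getattr(getattr(case, "params", None), "seed", 0)
        rng = np.random.default_rng((int(seed) * 2654435761 + 97) % 2**31)
        pads = random_placement_pads(nf.data.shape, multiple, rng)
    elif placement == "symmetric":
        _, pads = pad_to_multiple(np.asarray(nf.data), multiple, fill)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    xf = _apply_pads(np.asarray(nf.data, dtype=np.float64), pads, fill)
    xt = _apply_pads(np.asarray(nt.data, dtype=np.float64), pads, fill)
    yf = _apply_pads(y_frc, pads, 0.0)
    yt = _apply_pads(y_tlc, pads, 0.0)
    mfp = _apply_pads(mf.data.astype(np.float64), pads, 0.0)
    mtp = _apply_pads(mt.data.astype(np.float64), pads, 0.0)

    return PreparedCase(
        case_id=case.case_id,
        x=np.stack([xf, xt]).astype(np.float32),
        y_frc=yf.astype(np.float32),
        y_tlc=yt.astype(np.float32),
        mask_frc=(mfp > 0.5).astype(np.float32),
        mask_tlc=(mtp > 0.5).astype(np.float32),
        pads=pads,
        box=box,
        spacing=(cfg.target_spacing,) * 3,
        effort_true=getattr(case, "effort_true", float("nan")),
        meta={"case_id": case.case_id},
    )
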