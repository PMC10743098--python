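"""Synthetic paired-inflation CT phantom with exact ground-truth Jacobians.

Each case emulates an expiration/inspiration (FRC/TLC) chest-CT pair:

* a two-lung ellipsoidal support with >= 2 lobe compartments and per-case
  anatomical size jitter;
* a ground-truth deformation ``h`` composed of (outer to inner) an
  anisotropic affine "effort" inflation about the thorax center (the
  craniocaudal axis takes a random share of the volume change, emulating
  diaphragm-dominated breathing), a smooth separable-sinusoid heterogeneity,
  and radial low-distensibility pockets emulating gas trapping — all with
  closed-form Jacobians, so ``J`` is exact in both frames;
* FRC intensities from a tissue-fraction model,
  ``HU = -1000 * airfrac + tissue_hu * (1 - airfrac)``, where the local air
  fraction is coupled to the *heterogeneous* part of the Jacobian (poorly
  expanding regions trap gas and appear darker at FRC) plus a smooth random
  texture.  Because the coupling deliberately excludes the global effort
  scale, two cases can share an identical FRC image yet differ in effort:
  effort is identifiable from the image pair but not from a single image;
* TLC intensities by tissue-mass conservation (the sponge model),
  ``I_TLC(h(x)) + 1000 = (I_FRC(x) + 1000) / J_FRC(x)``, sampled exactly on
  the TLC grid through the analytic inverse;
* independent additive Gaussian HU noise per frame, noisier at FRC
  (emulating 50 mAs expiration vs. 200 mAs inspiration scans).

``PhantomParams.effort`` is the commanded affine inflation (target whole-lung
volume ratio); the achieved ratio ``PhantomCase.effort_true`` is measured
from the generated masks and is slightly lower when trapping pockets are
present, mirroring reduced inflation in diseased lungs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .deformation import (
    Affine,
    AnalyticDeformation,
    Compose,
    JacobianMap,
    RadialBump,
    SeparableSinusoid,
    compose_all,
)
from .volumes import LungMask, ROILabelMap, Volume3D, write_volume

__all__ = ["PhantomParams", "PhantomCase", "simulate_phantom", "simulate_cohort"]

AIR_HU = -1000.0
LOBE_NAMES = {1: "left_lower", 2: "left_upper", 3: "right_lower", 4: "right_upper"}


@dataclasses.dataclass
class PhantomParams:
    """Knobs of the paired-inflation phantom.

    effort:
        Commanded whole-lung TLC/FRC volume ratio (>= 1).
    heterogeneity:
        Per-axis amplitude budget ``|amp * freq|`` of the sinusoidal component
        of the deformation (0 disables it; must stay < 1 for positivity).
    disease_fraction:
        Approximate fraction of lung volume covered by low-distensibility
        trapped pockets (controls the number of radial pockets).
    air_fraction_base / air_fraction_couple / air_fraction_range:
        Baseline FRC air fraction, its coupling to local (effort-free)
        expansion, and the clipping range.
    noise_sd_frc / noise_sd_tlc:
        Additive Gaussian HU noise; the FRC (low-dose) frame is noisier.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: float = 3.0
    effort: float = 1.7
    heterogeneity: float = 0.15
    disease_fraction: float = 0.15
    air_fraction_base: float = 0.75
    air_fraction_couple: float = 0.5
    air_fraction_range: tuple[float, float] = (0.5, 0.93)
    texture_amp: float = 0.02
    tissue_hu: float = 40.0
    pocket_strength: float = 0.15
    pocket_sigma_mm: float = 7.0
    # fraction of the volume change taken by the craniocaudal axis
    z_effort_fraction_range: tuple[float, float] = (0.4, 0.6)
    anatomy_jitter: float = 0.12
    noise_sd_frc: float = 30.0
    noise_sd_tlc: float = 15.0
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self):
        if self.effort < 1.0:
            raise ValueError("effort must be >= 1 (TLC is the larger volume)")
        if not (0.0 <= self.heterogeneity < 1.0):
            raise ValueError("heterogeneity must lie in [0, 1)")
        if not (0.0 <= self.disease_fraction < 1.0):
            raise ValueError("disease_fraction must lie in [0, 1)")
        if self.noise_sd_frc < 0 or self.noise_sd_tlc < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.air_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("air_fraction_range must satisfy 0 < lo < hi < 1")


@dataclasses.dataclass
class PhantomCase:
    """One generated FRC/TLC pair with exact ground truth in both frames."""

    case_id: str
    I_FRC: Volume3D
    I_TLC: Volume3D
    M_FRC: LungMask
    M_TLC: LungMask
    lobes_frc: ROILabelMap
    lobes_tlc: ROILabelMap
    J_FRC: JacobianMap
    J_TLC: JacobianMap
    h: AnalyticDeformation
    effort_true: float
    params: PhantomParams

    @property
    def lobes(self) -> ROILabelMap:
        """FRC-frame lobe partition (the default evaluation frame)."""
        return self.lobes_frc


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


class _Anatomy:
    """Static FRC-frame anatomy: two ellipsoidal lungs inside a soft-tissue body.

    Sizes are fractions of the grid half-extent so phantoms fit any grid, and
    are jittered per case (overall and per-axis scale, craniocaudal shift) to
    emulate subject-to-subject anatomical variability.
    """

    def __init__(self, center: np.ndarray, half_extent: float,
                 rng: np.random.Generator | None = None, size_jitter: float = 0.12):
        self.center = center
        h = half_extent
        if rng is None:
            scale = np.ones(3)
            z_shift = 0.0
        else:
            scale = rng.uniform(1.0 - size_jitter, 1.0 + size_jitter) \
                * rng.uniform(0.95, 1.05, size=3)
            z_shift = rng.uniform(-0.03, 0.03) * h
        offset = 0.35 * h * scale[0]
        lung_c = center + np.array([0.0, 0.0, z_shift])
        self.lung_centers = np.array([lung_c + (-offset, 0.0, 0.0),
                                      lung_c + (offset, 0.0, 0.0)])
        self.lung_axes = np.array([0.24, 0.36, 0.50]) * h * scale
        self.body_axes = np.array([0.88, 0.65, 0.85]) * h

    def lung_value(self, pts: np.ndarray) -> np.ndarray:
        """min over lungs of the ellipsoid implicit value; < 0 means inside."""
        vals = []
        for c in self.lung_centers:
            d = (pts - c) / self.lung_axes
            vals.append(np.sum(d * d, axis=-1) - 1.0)
        return np.minimum(vals[0], vals[1])

    def in_lung(self, pts: np.ndarray) -> np.ndarray:
        return self.lung_value(pts) < 0.0

    def in_body(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - self.center) / self.body_axes
        return np.sum(d * d, axis=-1) < 1.0

    def lobe_label(self, pts: np.ndarray) -> np.ndarray:
        """1..4: {left, right} x {lower, upper}; 0 outside the lungs."""
        pts = np.asarray(pts)
        inside = self.in_lung(pts)
        right = pts[..., 0] >= self.center[0]
        upper = pts[..., 2] >= self.center[2]
        lab = 1 + 2 * right.astype(np.uint16) + upper.astype(np.uint16)
        return np.where(inside, lab, 0).astype(np.uint16)

    def sample_in_lung(self, rng: np.random.Generator, shrink: float = 0.7) -> np.ndarray:
        """A random point well inside one of the two lungs."""
        c = self.lung_centers[int(rng.integers(2))]
        while True:
            p = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(p * p) < 1.0:
                return c + p * self.lung_axes * shrink


def _build_deformation(p: PhantomParams, anatomy: _Anatomy,
                       rng: np.random.Generator
                       ) -> tuple[AnalyticDeformation, AnalyticDeformation | None]:
    """Affine effort ∘ sinusoid heterogeneity ∘ radial trapping pockets.

    The effort inflation is anisotropic: the craniocaudal axis takes a random
    fraction of the volume change (diaphragm-dominated breathing) and the
    remainder splits randomly between the transverse axes, with the per-axis
    scales multiplying exactly to the commanded volume ratio.  Returns the
    full deformation and its heterogeneous (effort-free) part.
    """
    parts: list[AnalyticDeformation] = []
    v_z = rng.uniform(*p.z_effort_fraction_range)
    u = rng.uniform(0.3, 0.7)
    v = np.array([(1.0 - v_z) * u, (1.0 - v_z) * (1.0 - u), v_z])
    scale = p.effort ** v
    affine = Affine.scaling(scale, center=anatomy.center)
    if p.heterogeneity > 0:
        wavelength = rng.uniform(40.0, 80.0, size=3)           # mm
        freq = 2.0 * np.pi / wavelength                        # rad/mm
        budget = p.heterogeneity * rng.uniform(0.6, 1.0, size=3)
        amp = budget / freq
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        parts.append(SeparableSinusoid(amp=amp, freq=freq, phase=phase, center=anatomy.center))
    if p.disease_fraction > 0 and p.pocket_strength > 0:
        lung_vol = 2.0 * (4.0 / 3.0) * np.pi * np.prod(anatomy.lung_axes)
        pocket_vol = (4.0 / 3.0) * np.pi * (1.2 * p.pocket_sigma_mm) ** 3
        n_pockets = max(1, int(round(p.disease_fraction * lung_vol / pocket_vol)))
        for _ in range(n_pockets):
            parts.append(RadialBump(a=p.pocket_strength, sigma=p.pocket_sigma_mm,
                                    center=anatomy.sample_in_lung(rng)))
    hetero = compose_all(*parts) if parts else None
    h = Compose(outer=affine, inner=hetero) if hetero is not None else affine
    return h, hetero


# ---------------------------------------------------------------------------
# Intensity model
# ---------------------------------------------------------------------------


class _IntensityModel:
    """Analytic FRC HU field from the tissue-fraction (sponge) model."""

    def __init__(self, p: PhantomParams, anatomy: _Anatomy,
                 hetero: AnalyticDeformation | None, rng: np.random.Generator):
        self.p = p
        self.anatomy = anatomy
        # heterogeneous (effort-free) part of the ground-truth deformation
        self.hetero = hetero
        # smooth band-limited random texture: a few random 3D cosines
        n_waves = 8
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelengths = rng.uniform(25.0, 60.0, size=n_waves)
        self.kvecs = dirs * (2.0 * np.pi / wavelengths)[:, None]
        self.psis = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
        self.eps = p.texture_amp / np.sqrt(n_waves / 2.0)

    def texture(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[:-1])
        for k, psi in zip(self.kvecs, self.psis):
            out += self.eps * np.cos(pts @ k + psi)
        return out

    def air_fraction(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        j_local = self.hetero.jacobian(pts) if self.hetero is not None else np.ones(pts.shape[:-1])
        af = p.air_fraction_base - p.air_fraction_couple * (j_local - 1.0) + self.texture(pts)
        return np.clip(af, *p.air_fraction_range)

    def hu_frc(self, pts: np.ndarray) -> np.ndarray:
        """Noiseless FRC HU at arbitrary physical points."""
        af = self.air_fraction(pts)
        lung_hu = AIR_HU * af + self.p.tissue_hu * (1.0 - af)
        body_hu = np.where(self.anatomy.in_body(pts), self.p.tissue_hu, AIR_HU)
        return np.where(self.anatomy.in_lung(pts), lung_hu, body_hu)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_phantom(p: PhantomParams) -> PhantomCase:
    """Generate one paired-inflation case with exact analytic ground truth."""
    rng = np.random.default_rng(p.seed)
    shape = tuple(int(s) for s in p.grid_shape)
    spacing = (p.spacing,) * 3
    origin = (0.0, 0.0, 0.0)
    center = np.array([(s - 1) * p.spacing / 2.0 for s in shape])
    half_extent = min((s - 1) * sp for s, sp in zip(shape, spacing)) / 2.0
    anatomy = _Anatomy(center, half_extent, rng, size_jitter=p.anatomy_jitter)

    h, hetero = _build_deformation(p, anatomy, rng)

    axes = [origin[a] + p.spacing * np.arange(shape[a]) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    # --- ground truth Jacobian in the FRC frame
    J_frc_grid = h.jacobian(pts)
    if np.any(J_frc_grid <= 0):
        raise ValueError("phantom parameters produce non-positive ground-truth Jacobian")

    # --- FRC frame
    in_lung_frc = anatomy.in_lung(pts)
    if not np.any(in_lung_frc):
        raise ValueError("empty lung support; enlarge the grid")
    M_FRC = LungMask(in_lung_frc.astype(np.uint8), spacing, origin)
    model = _IntensityModel(p, anatomy, hetero, rng)
    hu_frc = model.hu_frc(pts)

    # --- TLC frame via the analytic inverse + mass conservation
    h_inv = h.inverse()
    back = h_inv(pts)                       # FRC-frame location of each TLC voxel
    in_lung_tlc = anatomy.in_lung(back)
    if not np.any(in_lung_tlc):
        raise ValueError("empty TLC lung support")
    M_TLC = LungMask(in_lung_tlc.astype(np.uint8), spacing, origin)
    J_at_back = h.jacobian(back)
    hu_frc_at_back = model.hu_frc(back)
    hu_tlc_lung = AIR_HU + (hu_frc_at_back - AIR_HU) / J_at_back
    body_hu = np.where(anatomy.in_body(pts), p.tissue_hu, AIR_HU)
    hu_tlc = np.where(in_lung_tlc, hu_tlc_lung, body_hu)

    # --- additive dose-dependent noise (after the conservation coupling)
    if p.noise_sd_frc > 0:
        hu_frc = hu_frc + rng.normal(0.0, p.noise_sd_frc, size=shape)
    if p.noise_sd_tlc > 0:
        hu_tlc = hu_tlc + rng.normal(0.0, p.noise_sd_tlc, size=shape)

    I_FRC = Volume3D(hu_frc.astype(np.float32), spacing, origin, intensity_kind="HU")
    I_TLC = Volume3D(hu_tlc.astype(np.float32), spacing, origin, intensity_kind="HU")

    lobes_frc = ROILabelMap(anatomy.lobe_label(pts), dict(LOBE_NAMES), spacing, origin)
    lobes_tlc = ROILabelMap(
        np.where(in_lung_tlc, anatomy.lobe_label(back), 0).astype(np.uint16),
        dict(LOBE_NAMES), spacing, origin,
    )

    Jf = Volume3D(J_frc_grid.astype(np.float32), spacing, origin, intensity_kind="jacobian")
    J_FRC = JacobianMap.from_J(Jf, frame="FRC", mask=M_FRC)
    Jt = Volume3D((1.0 / J_at_back).astype(np.float32), spacing, origin, intensity_kind="jacobian")
    J_TLC = JacobianMap.from_J(Jt, frame="TLC", mask=M_TLC)

    effort_true = M_TLC.volume_mm3 / M_FRC.volume_mm3
    return PhantomCase(
        case_id=p.case_id,
        I_FRC=I_FRC, I_TLC=I_TLC, M_FRC=M_FRC, M_TLC=M_TLC,
        lobes_frc=lobes_frc, lobes_tlc=lobes_tlc,
        J_FRC=J_FRC, J_TLC=J_TLC,
        h=h, effort_true=float(effort_true), params=p,
    )


def simulate_cohort(
    n: int,
    severity_spread: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    effort_range: tuple[float, float] = (1.2, 2.2),
    disease_fraction_max: float = 0.3,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    spacing: float = 3.0,
    noise_sd_frc: float = 30.0,
    noise_sd_tlc: float = 15.0,
    heterogeneity: float = 0.15,
) -> list[PhantomCase]:
    """Simulate ``n`` cases stratified over a severity range.

    Disease severity (the trapped-pocket fraction) is stratified over equal
    bins of ``severity_spread`` — emulating a cohort uniformly distributed
    over disease-severity groups.  Inspiration effort is stratified over
    ``effort_range`` *independently* of severity (bin assignment shuffled):
    effort is a subject-dependent breath-hold depth, not a disease property,
    which is exactly what makes it unidentifiable from a single image.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = severity_spread
    rng = np.random.default_rng(seed)
    child_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
    effort_bins = rng.permutation(n)
    cases = []
    for i in range(n):
        sev = lo + (hi - lo) * (i + rng.uniform(0.0, 1.0)) / n
        e_frac = (effort_bins[i] + rng.uniform(0.0, 1.0)) / n
        effort = effort_range[0] + e_frac * (effort_range[1] - effort_range[0])
        params = PhantomParams(
            grid_shape=grid_shape,
            spacing=spacing,
            effort=float(effort),
            heterogeneity=heterogeneity,
            disease_fraction=float(sev * disease_fraction_max),
            noise_sd_frc=noise_sd_frc,
            noise_sd_tlc=noise_sd_tlc,
            seed=child_seeds[i],
            case_id=f"case_{i:04d}",
        )
        cases.append(simulate_phantom(params))
    return cases


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------


def write_case(case: PhantomCase, out_dir) -> Path:
    """Write one case as NIfTI files plus a JSON manifest entry."""
    out_dir = Path(out_dir) / case.case_id
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(case.I_FRC, out_dir / "I_FRC.nii.gz")
    write_volume(case.I_TLC, out_dir / "I_TLC.nii.gz")
    write_volume(case.M_FRC, out_dir / "M_FRC.nii.gz")
    write_volume(case.M_TLC, out_dir / "M_TLC.nii.gz")
    write_volume(case.lobes_frc, out_dir / "lobes_FRC.nii.gz")
    write_volume(case.lobes_tlc, out_dir / "lobes_TLC.nii.gz")
    write_volume(case.J_FRC.J, out_dir / "J_FRC.nii.gz")
    write_volume(case.J_TLC.J, out_dir / "J_TLC.nii.gz")
    meta = {
        "case_id": case.case_id,
        "effort_commanded": case.params.effort,
        "effort_true": case.effort_true,
        "disease_fraction": case.params.disease_fraction,
        "heterogeneity": case.params.heterogeneity,
        "noise_sd_frc": case.params.noise_sd_frc,
        "noise_sd_tlc": case.params.noise_sd_tlc,
        "seed": case.params.seed,
        "spacing_mm": case.params.spacing,
        "grid_shape": list(case.params.grid_shape),
    }
    (out_dir / "case.json").write_text(json.dumps(meta, indent=2))
    return out_dir
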