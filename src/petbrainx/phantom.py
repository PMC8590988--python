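"""Seeded synthetic whole-body FDG-PET phantoms with ground truth.

The generator emulates the gross SUV topography of clinical whole-body
FDG-PET: soft tissue around SUV 1-2.5, a metabolically bright brain
(SUV 6-8) at the superior end, a very hot urinary bladder (up to SUV
~30), an optional injection-site hot streak along one arm, optional
superior truncation of the field of view (the "not containing entire
brain" class of torso protocols) and optional hypometabolic brain
lesions mimicking peri-metastatic edema.  Reconstruction is emulated by
an isotropic Gaussian point-spread blur (default 5 mm FWHM) followed by
additive Gaussian noise.

Anatomy is stacked ellipsoids, deliberately simple: no attenuation,
scatter or sinogram physics (see docs/methods.md for what this does and
does not exercise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import boxes
from .volume import Volume

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

TORSO = "torso"
TOTAL_BODY = "total_body"


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hypometabolic brain lesion.

    ``center_voxel`` is in grid voxel indices; ``radius_mm`` in mm;
    ``multiplier`` scales the brain SUV inside the sphere and must be
    < 1 (edematous tissue is hypometabolic).
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float = 12.0
    multiplier: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.multiplier < 1.0):
            raise ValueError(f"lesion multiplier must be in [0, 1), got {self.multiplier}")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 64, 192)
    voxel_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    coverage: str = TOTAL_BODY
    brain_truncation_fraction: float = 0.0
    lesion: LesionSpec | None = None
    artifact: bool = False
    noise_sd: float = 0.15
    psf_fwhm_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if any(g < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 16, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if not (0.0 <= self.brain_truncation_fraction <= 1.0):
            raise ValueError("brain_truncation_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coverage not in (TORSO, TOTAL_BODY):
            raise ValueError(f"unknown coverage {self.coverage!r}")


@dataclass
class GroundTruth:
    whole_brain_present: bool
    brain_box: boxes.Box3D | None = None
    lesion_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None  # unblurred brain label, for validation

    def __post_init__(self):
        if not self.whole_brain_present:
            self.brain_box = None


# SUV palette; values are config-level constants chosen so that all
# tissues except urine stay below SUV 30.
BRAIN_SUV = (6.0, 8.0)
BODY_SUV = (1.0, 2.2)
HEAD_SUV = (1.2, 1.8)
BLADDER_SUV = (15.0, 30.0)
ARTIFACT_SUV = (10.0, 25.0)


def _ellipsoid_mask(shape, center_vox, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center_vox, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Generate one phantom volume plus its ground truth.

    Deterministic for a fixed ``spec.seed``: anatomy (brain/body size
    and position, tissue SUV levels, bladder intensity) is drawn from a
    generator seeded with it.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_mm

    # -- sample anatomy (mm where physical, voxels where positional) --
    brain_r_mm = np.array(
        [rng.uniform(52, 62), rng.uniform(62, 75), rng.uniform(46, 58)]
    )
    brain_suv = rng.uniform(*BRAIN_SUV)
    head_suv = rng.uniform(*HEAD_SUV)
    body_suv = rng.uniform(*BODY_SUV)
    bladder_suv = rng.uniform(*BLADDER_SUV)
    margin_mm = rng.uniform(6.0, 20.0)
    cx = nx / 2.0 + rng.uniform(-3, 3)
    cy = ny / 2.0 + rng.uniform(-3, 3)

    brain_r_vox = brain_r_mm / np.array([vx, vy, vz])
    # superior truncation: push the brain up so the stated fraction of
    # its height lies beyond the top grid face
    brain_height_vox = 2.0 * brain_r_vox[2]
    cz = (nz - 1) - margin_mm / vz - brain_r_vox[2] \
        + spec.brain_truncation_fraction * brain_height_vox \
        + (spec.brain_truncation_fraction > 0) * (margin_mm / vz)
    brain_center = np.array([cx, cy, cz])

    shape = (nx, ny, nz)
    brain_mask = _ellipsoid_mask(shape, brain_center, brain_r_vox)
    head_mask = _ellipsoid_mask(shape, brain_center, (brain_r_mm + 10.0) / np.array([vx, vy, vz]))

    # torso below the head, elongated in z
    torso_r_mm = np.array(
        [rng.uniform(140, 170), rng.uniform(80, 110), rng.uniform(220, 280)]
    )
    torso_top_z = cz - brain_r_vox[2] - rng.uniform(20, 40) / vz
    torso_center = np.array([nx / 2.0, ny / 2.0, torso_top_z - torso_r_mm[2] / vz])
    torso_r_vox = torso_r_mm / np.array([vx, vy, vz])
    torso_mask = _ellipsoid_mask(shape, torso_center, torso_r_vox)

    leg_masks = np.zeros(shape, dtype=bool)
    if spec.coverage == TOTAL_BODY:
        leg_top = torso_center[2]
        for side in (-1.0, 1.0):
            leg_center = np.array([nx / 2.0 + side * 60.0 / vx, ny / 2.0, leg_top / 2.0])
            leg_r = np.array([55.0 / vx, 55.0 / vy, max(leg_top / 2.0 + 2.0, 4.0)])
            leg_masks |= _ellipsoid_mask(shape, leg_center, leg_r)

    bladder_center = np.array(
        [nx / 2.0 + rng.uniform(-1, 1), ny / 2.0 + rng.uniform(-1, 1),
         torso_center[2] - torso_r_vox[2] * 0.75]
    )
    bladder_mask = _ellipsoid_mask(shape, bladder_center, 12.0 / np.array([vx, vy, vz]))

    suv = np.zeros(shape, dtype=np.float32)
    suv[leg_masks] = body_suv * 0.8
    suv[torso_mask] = body_suv
    suv[head_mask] = head_suv
    suv[brain_mask] = brain_suv
    suv[bladder_mask & torso_mask] = bladder_suv

    if spec.artifact:
        # hot venous streak along one arm, lateral to the torso
        side = rng.choice([-1.0, 1.0])
        arm_x = int(round(nx / 2.0 + side * (torso_r_vox[0] * 0.9)))
        arm_x = int(np.clip(arm_x, 0, nx - 1))
        z_hi = int(np.clip(round(torso_top_z), 1, nz - 1))
        z_lo = int(np.clip(z_hi - round(rng.uniform(100, 200) / vz), 0, z_hi - 1))
        suv[arm_x, int(ny / 2), z_lo:z_hi] = rng.uniform(*ARTIFACT_SUV)

    lesion_mask = None
    if spec.lesion is not None:
        c = tuple(int(v) for v in spec.lesion.center_voxel)
        if not (all(0 <= ci < si for ci, si in zip(c, shape)) and brain_mask[c]):
            raise ValueError(f"lesion center {c} lies outside the brain")
        lesion_mask = _ellipsoid_mask(
            shape, np.array(c, dtype=float), spec.lesion.radius_mm / np.array([vx, vy, vz])
        ) & brain_mask
        suv[lesion_mask] *= spec.lesion.multiplier

    whole = spec.brain_truncation_fraction == 0.0
    truth = GroundTruth(
        whole_brain_present=whole,
        brain_box=boxes.from_mask(brain_mask) if whole else None,
        lesion_mask=lesion_mask,
        brain_mask=brain_mask,
    )

    sigma_vox = (spec.psf_fwhm_mm / FWHM_TO_SIGMA) / np.array([vx, vy, vz])
    blurred = ndimage.gaussian_filter(suv, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    np.clip(blurred, 0.0, None, out=blurred)

    return Volume(blurred.astype(np.float32), spec.voxel_mm), truth


@dataclass(frozen=True)
class CohortSpec:
    """Distribution over phantom specs for a simulated cohort.

    ``truncated_fraction`` of phantoms (exact count, rounded) get a
    superior truncation drawn from ``truncation_range`` and therefore a
    false whole-brain label; the rest contain the full brain.
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    truncated_fraction: float = 0.3
    truncation_range: tuple[float, float] = (0.25, 0.8)
    torso_probability: float = 0.5
    artifact_probability: float = 0.2
    lesion: LesionSpec | None = None

    def __post_init__(self):
        if not (0.0 <= self.truncated_fraction <= 1.0):
            raise ValueError("truncated_fraction must be in [0, 1]")


def generate_cohort(
    n: int, spec_distribution: CohortSpec | None = None, seed: int = 0
) -> list[tuple[Volume, GroundTruth]]:
    """Generate ``n`` randomized phantoms.

    Exactly ``round(n * truncated_fraction)`` phantoms are truncated
    (brain absent); their positions in the returned list are a seeded
    permutation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = spec_distribution or CohortSpec()
    rng = np.random.default_rng(seed)
    n_trunc = int(round(n * dist.truncated_fraction))
    truncated = np.zeros(n, dtype=bool)
    truncated[:n_trunc] = True
    rng.shuffle(truncated)

    out = []
    for i in range(n):
        frac = rng.uniform(*dist.truncation_range) if truncated[i] else 0.0
        coverage = TORSO if rng.random() < dist.torso_probability else TOTAL_BODY
        artifact = bool(rng.random() < dist.artifact_probability)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            dist.base,
            brain_truncation_fraction=float(frac),
            coverage=coverage,
            artifact=artifact,
            seed=sub_seed,
        )
        if dist.lesion is not None:
            # place the lesion relative to the realized brain: generate
            # once without lesion to locate the brain, then re-generate
            probe_vol, probe_truth = generate_phantom(spec)
            if probe_truth.brain_box is None:
                raise ValueError("cannot place a lesion in a truncated phantom")
            bb = probe_truth.brain_box
            center = tuple(
                int(m + 0.5 * s + d)
                for m, s, d in zip(
                    bb.min_corner, bb.size, (rng.integers(-3, 4), rng.integers(-3, 4), 0)
                )
            )
            spec = replace(spec, lesion=replace(dist.lesion, center_voxel=center))
        out.append(generate_phantom(spec))
    return out


TEMPLATE_SHAPE = (80, 88, 72)
TEMPLATE_VOXEL_MM = (2.0, 2.0, 2.0)


def canonical_brain(seed: int, jitter: bool = True) -> Volume:
    """One brain-only crop on the fixed canonical template grid (2 mm)."""
    rng = np.random.default_rng(seed)
    shape = TEMPLATE_SHAPE
    v = np.array(TEMPLATE_VOXEL_MM)
    if jitter:
        radii_mm = np.array(
            [rng.uniform(52, 62), rng.uniform(62, 75), rng.uniform(46, 58)]
        )
        suv = rng.uniform(*BRAIN_SUV)
    else:
        radii_mm = np.array([57.0, 68.5, 52.0])
        suv = float(np.mean(BRAIN_SUV))
    center = (np.array(shape) - 1) / 2.0
    data = np.where(
        _ellipsoid_mask(shape, center, radii_mm / v), np.float32(suv), np.float32(0.0)
    )
    sigma = (5.0 / FWHM_TO_SIGMA) / v
    data = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
    return Volume(data, TEMPLATE_VOXEL_MM)


def make_template(n: int, seed: int = 0) -> Volume:
    """Voxelwise mean of ``n`` canonical brains: the registration target."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    acc = None
    for child in ss.spawn(n):
        vol = canonical_brain(int(child.generate_state(1)[0] % (2**31 - 1)))
        acc = vol.data if acc is None else acc + vol.data
    return Volume(acc / n, TEMPLATE_VOXEL_MM)
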