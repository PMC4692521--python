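"""Deterministic synthetic phantoms for every stage of the pipeline.

Each generator returns a :class:`PhantomTruth` bundling the generated
volumes with the analytic ground truth needed to score the methods
(true thickness, true volumes, analytic surface area, the buried-sulcus
mask, ...).  Regeneration with the same parameters and seed is
bit-identical.

Default T2-like contrast (arbitrary units, WM brighter than CGM as in the
neonatal brain): CSF 200, WM 140, deep GM 110, CGM 90, background 20,
Gaussian noise sd 8.  The folded-ribbon phantom reproduces the two
pathologies the delineation method targets: partial-volume (PV) voxels of
intermediate intensity along the CGM-WM interface, and buried sulci whose
CSF is thinner than the PV width and therefore indistinguishable from
cortex in intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .growth_models import gompertz_eval
from .atlas4d import SubjectRecord
from .io_core import (
    IntensityVolume,
    LabelLUT,
    LabelVolume,
    ProbabilityMaps,
    affine_from_spacing,
    phantom_lut,
    PHANTOM_BG_EXTRA,
    PHANTOM_BG_INTRA,
    PHANTOM_CGM_LEFT,
    PHANTOM_CGM_RIGHT,
    PHANTOM_CSF,
    PHANTOM_DEEPGM,
    PHANTOM_WM,
)

DEFAULT_INTENSITIES = {
    PHANTOM_BG_EXTRA: 20.0,
    PHANTOM_WM: 140.0,
    PHANTOM_CGM_LEFT: 90.0,
    PHANTOM_CGM_RIGHT: 90.0,
    PHANTOM_DEEPGM: 110.0,
    PHANTOM_CSF: 200.0,
    PHANTOM_BG_INTRA: 180.0,
}
DEFAULT_NOISE_SD = 8.0


@dataclass
class PhantomTruth:
    """A generated phantom plus everything needed to score methods on it."""

    labels: LabelVolume  # apparent labels (buried sulci filled with CGM)
    intensity: IntensityVolume
    lut: LabelLUT
    seed: int | None = None
    true_labels: LabelVolume | None = None  # None when identical to `labels`
    true_thickness_mm: float | None = None
    true_volumes_mm3: dict[int, float] = field(default_factory=dict)
    analytic_area_mm2: float | None = None
    analytic_volume_mm3: float | None = None
    buried_sulcus_mask: np.ndarray | None = None
    pv_mask: np.ndarray | None = None
    contact_plane: np.ndarray | None = None

    @property
    def truth_labels(self) -> LabelVolume:
        return self.true_labels if self.true_labels is not None else self.labels

    def tissue_priors(self, sigma_mm: float = 2.0) -> ProbabilityMaps:
        """Blurred one-hot priors from the true labels, renormalized.

        Emulates atlas-propagated spatial priors: sharp at a distance from
        boundaries, ambiguous near them.
        """
        lab = self.truth_labels
        onehot = ProbabilityMaps.from_labels(lab)
        data = onehot.data.copy()
        if sigma_mm > 0:
            for k in range(data.shape[0]):
                data[k] = ndimage.gaussian_filter(data[k], sigma=sigma_mm / lab.spacing)
        pm = ProbabilityMaps(list(onehot.class_ids), np.clip(data, 0, 1))
        return pm.normalize()


def _as_spacing(spacing) -> np.ndarray:
    spacing = np.asarray(spacing, float)
    if spacing.ndim == 0:
        spacing = np.repeat(spacing, 3)
    return spacing


def _intensity_from_labels(
    labels: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    img = np.zeros(labels.shape, float)
    for lid, val in DEFAULT_INTENSITIES.items():
        img[labels == lid] = val
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, labels.shape)
    return img


# ---------------------------------------------------------------------------
# simple geometric phantoms
# ---------------------------------------------------------------------------


def _radial_grid(shape, spacing, center=None):
    spacing = _as_spacing(spacing)
    idx = np.indices(shape).astype(float)
    if center is None:
        center = (np.asarray(shape) - 1) / 2.0
    r = np.sqrt(sum(((idx[a] - center[a]) * spacing[a]) ** 2 for a in range(3)))
    return r


def make_sphere_phantom(
    radius: float,
    spacing=1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    margin_mm: float = 4.0,
) -> PhantomTruth:
    """A WM-filled sphere in background, with its analytic area and volume."""
    spacing = _as_spacing(spacing)
    if radius < 5 * float(spacing.min()):
        raise ValueError("radius too small for the grid spacing")
    shape = tuple(int(np.ceil(2 * (radius + margin_mm) / spacing[a])) | 1 for a in range(3))
    r = _radial_grid(shape, spacing)
    labels = np.where(r <= radius, PHANTOM_WM, PHANTOM_BG_EXTRA).astype(np.int32)
    rng = np.random.default_rng(seed)
    img = _intensity_from_labels(labels, noise_sd, rng)
    lut = phantom_lut()
    aff = affine_from_spacing(spacing)
    voxel = float(np.prod(spacing))
    return PhantomTruth(
        labels=LabelVolume(labels, aff, lut),
        intensity=IntensityVolume(img, aff),
        lut=lut,
        seed=seed,
        analytic_area_mm2=4 * np.pi * radius**2,
        analytic_volume_mm3=4 / 3 * np.pi * radius**3,
        true_volumes_mm3={PHANTOM_WM: float((labels == PHANTOM_WM).sum()) * voxel},
    )


def make_shell_phantom(
    r1: float,
    r2: float,
    spacing=1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_mm: float = 4.0,
) -> PhantomTruth:
    """CGM shell (r1 < r <= r2) between a WM core and a CSF exterior."""
    if r2 <= r1:
        raise ValueError("r2 must exceed r1")
    spacing = _as_spacing(spacing)
    shape = tuple(int(np.ceil(2 * (r2 + margin_mm) / spacing[a])) | 1 for a in range(3))
    r = _radial_grid(shape, spacing)
    labels = np.full(shape, PHANTOM_CSF, np.int32)
    labels[r <= r2] = PHANTOM_CGM_LEFT
    labels[r <= r1] = PHANTOM_WM
    rng = np.random.default_rng(seed)
    img = _intensity_from_labels(labels, noise_sd, rng)
    lut = phantom_lut()
    aff = affine_from_spacing(spacing)
    voxel = float(np.prod(spacing))
    counts = dict(zip(*np.unique(labels, return_counts=True)))
    return PhantomTruth(
        labels=LabelVolume(labels, aff, lut),
        intensity=IntensityVolume(img, aff),
        lut=lut,
        seed=seed,
        true_thickness_mm=r2 - r1,
        true_volumes_mm3={int(k): float(v) * voxel for k, v in counts.items()},
    )


def make_slab_phantom(
    thickness: float = 4.0,
    spacing=1.0,
    extent_mm: float = 24.0,
) -> PhantomTruth:
    """A flat CGM slab between a WM half-space below and CSF above."""
    spacing = _as_spacing(spacing)
    shape = tuple(
        int(np.ceil(extent_mm / spacing[a])) | 1 for a in range(2)
    ) + (int(np.ceil((thickness + 2 * 6.0) / spacing[2])) | 1,)
    z = np.indices(shape)[2] * spacing[2]
    z_wm_top = 6.0
    labels = np.full(shape, PHANTOM_CSF, np.int32)
    labels[z <= z_wm_top] = PHANTOM_WM
    labels[(z > z_wm_top) & (z <= z_wm_top + thickness)] = PHANTOM_CGM_LEFT
    lut = phantom_lut()
    aff = affine_from_spacing(spacing)
    img = _intensity_from_labels(labels, 0.0, np.random.default_rng(0))
    return PhantomTruth(
        labels=LabelVolume(labels, aff, lut),
        intensity=IntensityVolume(img, aff),
        lut=lut,
        true_thickness_mm=thickness,
    )


# ---------------------------------------------------------------------------
# folded cortical ribbon
# ---------------------------------------------------------------------------


def make_folded_ribbon_phantom(
    t0: float = 2.0,
    wavelength: float = 10.0,
    amplitude: float = 10.0,
    buried: bool = False,
    pv_width: float = 5.0,
    spacing=1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    shape=(64, 32, 64),
    pv_boundary: bool = False,
) -> PhantomTruth:
    """Sinusoidally folded constant-thickness cortical ribbon.

    The WM surface is z = z_mid + amplitude*cos(2*pi*x/wavelength); the
    CGM ribbon is the set of voxels within Euclidean distance ``t0`` (mm)
    of the WM, so its thickness is ``t0`` normal to the interface
    everywhere the folds leave room.  The remainder above is CSF.

    With ``buried=True``, sulcal CSF locally thinner than ``pv_width``
    voxels (found by morphological opening with a ball of that diameter)
    is recorded in ``buried_sulcus_mask``, relabelled CGM in the apparent
    labels and given CGM-distributed intensity - emulating sulci fused by
    partial volume.  With ``pv_boundary=True`` the WM-side interface layer
    additionally receives intermediate WM/CGM mixture intensities
    (recorded in ``pv_mask``) to exercise the EM PV class.
    """
    spacing = _as_spacing(spacing)
    if t0 < 2 * float(spacing.min()):
        raise ValueError("t0 must be at least two voxels")
    if 2 * amplitude + t0 + 6 > shape[2] * spacing[2]:
        raise ValueError("amplitude too large for the grid")
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None] * spacing[0]
    z = np.arange(nz)[None, None, :] * spacing[2]
    z_mid = 0.45 * nz * spacing[2]
    surface = z_mid + amplitude * np.cos(2 * np.pi * x / wavelength)
    wm = np.broadcast_to(z <= surface, shape).copy()

    dist = ndimage.distance_transform_edt(~wm, sampling=spacing)
    cgm = (dist > 0) & (dist <= t0)
    labels = np.full(shape, PHANTOM_CSF, np.int32)
    labels[wm] = PHANTOM_WM
    labels[cgm] = PHANTOM_CGM_LEFT

    true_labels = labels.copy()
    rng = np.random.default_rng(seed)
    img = _intensity_from_labels(labels, 0.0, rng)

    buried_mask = np.zeros(shape, bool)
    if buried:
        csf = labels == PHANTOM_CSF
        rad_vox = max(1, int(round(pv_width / 2)))
        ball = _ball_structure(rad_vox, spacing)
        # erosion with border_value=1 so grid edges do not count as thin
        opened = ndimage.binary_dilation(
            ndimage.binary_erosion(csf, structure=ball, border_value=1), structure=ball
        )
        buried_mask = csf & ~opened
        labels[buried_mask] = PHANTOM_CGM_LEFT
        img[buried_mask] = DEFAULT_INTENSITIES[PHANTOM_CGM_LEFT]

    pv_mask = np.zeros(shape, bool)
    if pv_boundary:
        struct = ndimage.generate_binary_structure(3, 1)
        pv_mask = wm & ndimage.binary_dilation(labels == PHANTOM_CGM_LEFT, structure=struct)
        alpha = rng.uniform(0.25, 0.75, int(pv_mask.sum()))
        img[pv_mask] = (
            alpha * DEFAULT_INTENSITIES[PHANTOM_WM]
            + (1 - alpha) * DEFAULT_INTENSITIES[PHANTOM_CGM_LEFT]
        )

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)

    lut = phantom_lut()
    aff = affine_from_spacing(spacing)
    voxel = float(np.prod(spacing))
    counts = dict(zip(*np.unique(true_labels, return_counts=True)))
    return PhantomTruth(
        labels=LabelVolume(labels, aff, lut),
        intensity=IntensityVolume(img, aff),
        lut=lut,
        seed=seed,
        true_labels=LabelVolume(true_labels, aff, lut),
        true_thickness_mm=t0,
        true_volumes_mm3={int(k): float(v) * voxel for k, v in counts.items()},
        buried_sulcus_mask=buried_mask,
        pv_mask=pv_mask,
    )


def _ball_structure(radius_vox: int, spacing) -> np.ndarray:
    spacing = _as_spacing(spacing)
    r_mm = radius_vox * float(spacing.min())
    half = [int(np.ceil(r_mm / spacing[a])) for a in range(3)]
    grids = np.indices([2 * h + 1 for h in half]).astype(float)
    d = np.sqrt(sum(((grids[a] - half[a]) * spacing[a]) ** 2 for a in range(3)))
    return d <= r_mm + 1e-9


# ---------------------------------------------------------------------------
# hemisphere contact
# ---------------------------------------------------------------------------


def make_hemisphere_contact_phantom(spacing=1.0, shape=(48, 24, 24)) -> PhantomTruth:
    """Left and right CGM blocks in face contact over a known plane."""
    spacing = _as_spacing(spacing)
    nx, ny, nz = shape
    labels = np.zeros(shape, np.int32)
    mid = nx // 2
    zlo, zhi = nz // 4, 3 * nz // 4
    labels[:, :, :zlo] = PHANTOM_WM
    labels[nx // 8 : mid, :, zlo:zhi] = PHANTOM_CGM_LEFT
    labels[mid : nx - nx // 8, :, zlo:zhi] = PHANTOM_CGM_RIGHT
    contact = np.zeros(shape, bool)
    contact[mid - 1 : mid + 1, :, zlo:zhi] = True
    lut = phantom_lut()
    aff = affine_from_spacing(spacing)
    img = _intensity_from_labels(labels, 0.0, np.random.default_rng(0))
    return PhantomTruth(
        labels=LabelVolume(labels, aff, lut),
        intensity=IntensityVolume(img, aff),
        lut=lut,
        contact_plane=contact,
    )


# ---------------------------------------------------------------------------
# atlas cohort and growth curves
# ---------------------------------------------------------------------------

ATLAS_CORE_ID = 1
ATLAS_SHELL_ID = 2
ATLAS_CSF_ID = 3
ATLAS_BG_ID = 0


def make_atlas_cohort(
    n: int = 50,
    age_range: tuple[float, float] = (27.0, 45.0),
    radius_law: tuple[float, float] = (2.0, 0.45),
    spacing=1.0,
    seed: int = 0,
    shape=(48, 48, 48),
) -> list[SubjectRecord]:
    """Cohort of concentric-structure label maps with age-dependent size.

    Ages are uniform over ``age_range`` (the cohort's scan-age span);
    the outer shell radius grows linearly with age,
    r(age) = radius_law[0] + radius_law[1] * age, the core is half of it
    and a 2-voxel CSF rind surrounds the shell.  Masks for the four
    classes partition the grid and share one grid (identity warp).
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    spacing = _as_spacing(spacing)
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(age_range[0], age_range[1], n))
    r_grid = _radial_grid(shape, spacing)
    aff = affine_from_spacing(spacing)
    subjects = []
    for i, age in enumerate(ages):
        r_out = radius_law[0] + radius_law[1] * float(age)
        r_core = 0.5 * r_out
        r_csf = r_out + 2 * float(spacing.min())
        core = r_grid <= r_core
        shell = (r_grid > r_core) & (r_grid <= r_out)
        csf = (r_grid > r_out) & (r_grid <= r_csf)
        bg = ~(core | shell | csf)
        subjects.append(
            SubjectRecord(
                subject=f"sub-{i:03d}",
                age_weeks=float(age),
                masks={
                    ATLAS_CORE_ID: core.astype(float),
                    ATLAS_SHELL_ID: shell.astype(float),
                    ATLAS_CSF_ID: csf.astype(float),
                    ATLAS_BG_ID: bg.astype(float),
                },
                affine=aff,
            )
        )
    return subjects


def write_phantom_inputs(truth: PhantomTruth, out_dir, prior_sigma_mm: float = 2.0) -> dict:
    """Write a phantom as pipeline inputs: intensity, per-class priors, LUT.

    Returns the paths dict expected by :class:`neoribbon.pipeline.RunConfig`.
    """
    from pathlib import Path

    from .io_core import write_volume, IntensityVolume

    out = Path(out_dir)
    (out / "priors").mkdir(parents=True, exist_ok=True)
    write_volume(truth.intensity, out / "intensity.nii.gz")
    write_volume(truth.labels, out / "labels.nii.gz")
    truth.lut.to_tsv(out / "lut.tsv")
    priors = truth.tissue_priors(prior_sigma_mm)
    for k in priors.class_ids:
        write_volume(
            IntensityVolume(priors[k], truth.labels.affine),
            out / "priors" / f"prior_{k:03d}.nii.gz",
        )
    return {
        "image": str(out / "intensity.nii.gz"),
        "priors_dir": str(out / "priors"),
        "lut": str(out / "lut.tsv"),
    }


def make_growth_cohort(
    n: int = 200,
    t_range: tuple[float, float] = (28.0, 44.0),
    beta=(100.0, 50.0, 0.4, 35.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy samples from a known Gompertz curve over an age range."""
    if n < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(t_range[0], t_range[1], n))
    y = gompertz_eval(beta, t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return t, y
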