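"""EM tissue segmentation with a CGM-WM partial-volume class.

Intensities inside the brain mask are modelled as a Gaussian mixture with
per-voxel spatial priors: the E-step responsibility of class k at voxel v
is proportional to prior_k(v) * N(x_v; mu_k, sigma_k^2), and the M-step
re-estimates the Gaussian parameters from the responsibilities.  Class
identity therefore comes from the priors, not from intensity order, so the
same code serves neonatal T2 (WM brighter than CGM) and any other contrast.

The boundary between cortical grey matter (CGM) and white matter (WM) is
dominated by partial-volume (PV) voxels of intermediate intensity which a
plain mixture tends to assign to CGM, inflating the cortical ribbon.  The
remedy implemented here adds an explicit PV class whose spatial prior is
confined to the CGM/WM interface; after convergence the PV responsibility
is merged into WM before taking hard labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import LabelLUT, LabelVolume, IntensityVolume, ProbabilityMaps

log = logging.getLogger(__name__)

# Relative floor applied to class variances (fraction of the global
# intensity variance inside the mask); prevents degenerate Gaussians
# collapsing onto single voxels.
VARIANCE_FLOOR_FRACTION = 1e-3
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-5


@dataclass
class GaussianClass:
    id: int
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass
class EMResult:
    posteriors: ProbabilityMaps
    classes: list[GaussianClass]
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    mask: np.ndarray | None = None

    def gaussian(self, class_id: int) -> GaussianClass:
        for c in self.classes:
            if c.id == class_id:
                return c
        raise KeyError(class_id)


def _gauss_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def fit_em_gmm(
    image: IntensityVolume,
    priors: ProbabilityMaps,
    mask: np.ndarray | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    init: dict[int, tuple[float, float]] | None = None,
) -> EMResult:
    """Fit the spatially-weighted Gaussian mixture by EM.

    Parameters
    ----------
    image:
        The intensity volume.
    priors:
        Per-class spatial priors, normalized per voxel over the mask.
    mask:
        Boolean region to segment; defaults to voxels with positive prior mass.
    max_iter, tol:
        Stop when the relative log-likelihood change drops below ``tol``
        or after ``max_iter`` iterations.
    init:
        Optional ``{class_id: (mean, variance)}`` overriding the
        prior-weighted moment initialization (used to seed the PV class).
    """
    if len(priors.class_ids) < 2:
        raise ValueError("need at least 2 classes")
    x_full = image.data.astype(float)
    if mask is None:
        mask = priors.data.sum(axis=0) > 0.5
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x_full.shape:
        raise ValueError("mask shape mismatch")
    pri = priors.data[:, mask]  # (K, N)
    psum = pri.sum(axis=0)
    if np.any(psum <= 0):
        raise ValueError("all-zero prior at voxels inside the mask")
    pri = pri / psum
    x = x_full[mask]
    n_classes = len(priors.class_ids)

    var_floor = VARIANCE_FLOOR_FRACTION * max(float(np.var(x)), 1e-12)

    # initialize from prior-weighted moments
    means = np.empty(n_classes)
    variances = np.empty(n_classes)
    for k in range(n_classes):
        w = pri[k]
        wsum = w.sum()
        if wsum <= 0:
            means[k] = float(x.mean())
            variances[k] = float(np.var(x))
        else:
            means[k] = float((w * x).sum() / wsum)
            variances[k] = float((w * (x - means[k]) ** 2).sum() / wsum)
        variances[k] = max(variances[k], var_floor)
    # uninformative (e.g. uniform) priors give identical moment inits for
    # several classes, a symmetric EM fixed point; spread any such group
    # over intensity quantiles so the classes can separate
    scale = max(float(np.ptp(x)), 1e-12)
    groups: dict[int, list[int]] = {}
    for k in range(n_classes):
        key = int(round(means[k] / scale * 1e6))
        groups.setdefault(key, []).append(k)
    for members in groups.values():
        if len(members) > 1:
            qs = (np.arange(len(members)) + 1.0) / (len(members) + 1.0)
            for m_idx, q in zip(members, qs):
                means[m_idx] = float(np.quantile(x, q))
    if init:
        for cid, (m, v) in init.items():
            k = priors.index(cid)
            means[k], variances[k] = float(m), max(float(v), var_floor)

    trace: list[float] = []
    converged = False
    resp = np.empty_like(pri)
    for _ in range(max_iter):
        # E-step
        for k in range(n_classes):
            resp[k] = pri[k] * _gauss_pdf(x, means[k], variances[k])
        total = resp.sum(axis=0)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        resp /= total
        trace.append(ll)
        # M-step
        for k in range(n_classes):
            rk = resp[k]
            rsum = rk.sum()
            if rsum <= 1e-12:
                continue  # empty class: keep previous parameters
            means[k] = float((rk * x).sum() / rsum)
            variances[k] = max(float((rk * (x - means[k]) ** 2).sum() / rsum), var_floor)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) <= tol * abs(prev):
                converged = True
                break

    # final E-step with the converged parameters
    for k in range(n_classes):
        resp[k] = pri[k] * _gauss_pdf(x, means[k], variances[k])
    total = np.maximum(resp.sum(axis=0), 1e-300)
    resp /= total

    post = np.zeros_like(priors.data)
    post[:, mask] = resp
    classes = [
        GaussianClass(cid, float(means[k]), float(variances[k]))
        for k, cid in enumerate(priors.class_ids)
    ]
    posteriors = ProbabilityMaps(list(priors.class_ids), post)
    return EMResult(posteriors, classes, trace, converged, mask)


def add_pv_class(
    priors: ProbabilityMaps,
    cgm_id: int,
    wm_id: int,
    pv_id: int | None = None,
    kappa: float = 0.5,
) -> tuple[ProbabilityMaps, int]:
    """Append a CGM-WM partial-volume class to the prior maps.

    The PV prior lives only where (1-voxel-dilated) CGM and WM priors
    overlap: pv = kappa * min(dilate(p_cgm), dilate(p_wm)); all priors are
    then renormalized per voxel.  Returns the extended maps and the id
    assigned to the PV class.
    """
    if not (0 < kappa <= 1):
        raise ValueError("kappa must lie in (0, 1]")
    p_cgm = priors[cgm_id]
    p_wm = priors[wm_id]
    if pv_id is None:
        pv_id = max(priors.class_ids) + 1
    if pv_id in priors.class_ids:
        raise ValueError(f"pv id {pv_id} already taken")
    size = (3, 3, 3)
    d_cgm = ndimage.grey_dilation(p_cgm, size=size)
    d_wm = ndimage.grey_dilation(p_wm, size=size)
    pv = kappa * np.minimum(d_cgm, d_wm)
    data = np.concatenate([priors.data, pv[None]], axis=0)
    out = ProbabilityMaps(list(priors.class_ids) + [int(pv_id)], data)
    mask = data.sum(axis=0) > 0
    return out.normalize(mask), int(pv_id)


def init_pv_params(cgm: GaussianClass, wm: GaussianClass, pv_id: int = -1) -> GaussianClass:
    """Seed the PV Gaussian between its parents: mean midway, the larger variance."""
    return GaussianClass(
        id=pv_id,
        mean=0.5 * (cgm.mean + wm.mean),
        variance=max(cgm.variance, wm.variance),
    )


def merge_pv_into_wm(
    result: EMResult,
    pv_id: int,
    wm_id: int,
    lut: LabelLUT,
    affine: np.ndarray | None = None,
) -> tuple[ProbabilityMaps, LabelVolume]:
    """Fold the PV responsibility into WM and take hard labels.

    WM posterior += PV posterior, the PV class is dropped, and the hard
    segmentation is the per-voxel argmax of the merged posteriors (ties to
    the lowest class id).  Voxels outside the EM mask get label 0.
    """
    post = result.posteriors
    k_pv = post.index(pv_id)
    k_wm = post.index(wm_id)
    data = post.data.copy()
    data[k_wm] += data[k_pv]
    data = np.delete(data, k_pv, axis=0)
    ids = [i for i in post.class_ids if i != pv_id]
    merged = ProbabilityMaps(ids, data)
    labels = hard_labels(merged, lut, mask=result.mask, affine=affine)
    return merged, labels


def hard_labels(
    posteriors: ProbabilityMaps,
    lut: LabelLUT,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> LabelVolume:
    """Per-voxel argmax labels; ties broken toward the lowest class id."""
    order = np.argsort(posteriors.class_ids, kind="stable")
    ids_sorted = np.asarray(posteriors.class_ids)[order]
    stack = posteriors.data[order]
    # argmax returns the first maximum, which after sorting is the lowest id
    best = np.argmax(stack, axis=0)
    lab = ids_sorted[best].astype(np.int32)
    if mask is not None:
        lab[~np.asarray(mask, bool)] = 0
    if affine is None:
        affine = np.eye(4)
    return LabelVolume(lab, affine, lut)
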