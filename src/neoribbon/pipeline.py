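"""End-to-end orchestration of the ribbon delineation pipeline.

Stage order follows the method: EM segmentation with the PV class ->
PV merge -> sulci detection and enhancement -> thickness -> surface
reconstruction and labelling -> measurement tables.  Every stage persists
its intermediate artifact (NIfTI with a stage suffix) so any stage can be
re-run from the previous one, and the whole run is deterministic for a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import atlas4d, cortex_geometry, em_pv, surface_metrics
from .io_core import (
    LabelVolume,
    ProbabilityMaps,
    read_label_lut,
    read_volume,
    write_mesh,
    write_volume,
    TISSUE_CGM,
    TISSUE_CSF,
    TISSUE_WM,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    image: str
    priors_dir: str
    lut: str
    out_dir: str
    pv_kappa: float = 0.5
    d_min: float = cortex_geometry.DEFAULT_D_MIN_MM
    r_nbhd: float = cortex_geometry.DEFAULT_NEIGHBOURHOOD_MM
    tau: float | None = None
    blur_sigma: float = surface_metrics.DEFAULT_BLUR_SIGMA_MM
    smooth_iters: int = surface_metrics.DEFAULT_SMOOTH_ITERS
    sigma_w: float = atlas4d.DEFAULT_SIGMA_W
    window: float = atlas4d.DEFAULT_WINDOW
    seed: int = 0
    subject: str = "subject"

    def __post_init__(self) -> None:
        if not (0 < self.pv_kappa <= 1):
            raise ValueError("pv_kappa must lie in (0, 1]")
        if self.d_min <= 0 or self.r_nbhd <= 0:
            raise ValueError("d_min and r_nbhd must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_priors(priors_dir: Path) -> ProbabilityMaps:
    files = sorted(priors_dir.glob("prior_*.nii*"))
    if not files:
        raise FileNotFoundError(f"no prior_<id>.nii[.gz] files in {priors_dir}")
    ids, fields = [], []
    for f in files:
        stem = f.name.split(".")[0]
        ids.append(int(stem.split("_")[1]))
        fields.append(read_volume(f, kind="intensity").data)
    pm = ProbabilityMaps(ids, np.stack(fields))
    return pm.normalize()


def run_ribbon_pipeline(config: RunConfig):
    """Execute segmentation -> PV merge -> sulci -> thickness -> surface ->
    measurements, persisting each stage's artifact under ``out_dir``.

    Returns the measurement DataFrame.  A stage failure raises
    :class:`StageError` naming the stage; earlier outputs stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "segmentation"
    try:
        lut = read_label_lut(config.lut)
        image = read_volume(config.image, kind="intensity")
        priors = _read_priors(Path(config.priors_dir))
        cgm_ids = [i for i in priors.class_ids if i in lut.entries and lut.tissue(i) == TISSUE_CGM]
        wm_ids = [i for i in priors.class_ids if i in lut.entries and lut.tissue(i) == TISSUE_WM]
        csf_ids = [i for i in priors.class_ids if i in lut.entries and lut.tissue(i) == TISSUE_CSF]
        if not cgm_ids or not wm_ids or not csf_ids:
            raise ValueError("priors must include CGM, WM and CSF classes")
        cgm_id, wm_id, csf_id = cgm_ids[0], wm_ids[0], csf_ids[0]
        log.info("[%s] EM with PV class (kappa=%.2f)", stage, config.pv_kappa)
        pv_priors, pv_id = em_pv.add_pv_class(priors, cgm_id, wm_id, kappa=config.pv_kappa)
        pre = em_pv.fit_em_gmm(image, priors)
        pv_init = em_pv.init_pv_params(pre.gaussian(cgm_id), pre.gaussian(wm_id), pv_id)
        result = em_pv.fit_em_gmm(
            image, pv_priors, init={pv_id: (pv_init.mean, pv_init.variance)}
        )
        posteriors, labels = em_pv.merge_pv_into_wm(result, pv_id, wm_id, lut, image.affine)
        write_volume(labels, out / "seg_em.nii.gz")
        post_dir = out / "posteriors"
        post_dir.mkdir(exist_ok=True)
        for k in posteriors.class_ids:
            write_volume(_float_volume(posteriors[k], image.affine), post_dir / f"post_{k:03d}.nii.gz")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "sulci-enhancement"
    try:
        csf_post = posteriors[csf_id]
        labels2, shocks = cortex_geometry.detect_and_enhance(
            labels, csf_post, d_min=config.d_min, r_nbhd=config.r_nbhd, tau=config.tau
        )
        write_volume(labels2, out / "seg_sulci.nii.gz")
        shocks.to_dataframe().to_csv(out / "shocks.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "thickness"
    try:
        tmap = cortex_geometry.cortical_thickness(labels2)
        write_volume(_float_volume(tmap.thickness, image.affine), out / "thickness.nii.gz")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "surface"
    try:
        mesh = surface_metrics.reconstruct_surface(
            labels2, blur_sigma=config.blur_sigma, smooth_iters=config.smooth_iters
        )
        mesh = surface_metrics.exclude_deep_boundary(mesh, labels2)
        mesh = surface_metrics.label_vertices(mesh, labels2)
        curv = surface_metrics.vertex_curvatures(mesh)
        write_mesh(mesh, out / "inner_surface.ply")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "measurements"
    try:
        table = surface_metrics.compute_measurements(
            labels2, lut, mesh, tmap, curv, subject=config.subject
        )
        table.to_csv(out / "measurements.csv", index=False, float_format="%.6g")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return table


def _float_volume(data: np.ndarray, affine: np.ndarray):
    from .io_core import IntensityVolume

    return IntensityVolume(np.nan_to_num(np.asarray(data, float)), affine)


def run_atlas_pipeline(
    manifest: str | Path,
    out_dir: str | Path,
    ages: list[int] | None = None,
    sigma_w: float = atlas4d.DEFAULT_SIGMA_W,
    window: float = atlas4d.DEFAULT_WINDOW,
    lut=None,
):
    """Build and save the 4D atlas from a manifest of pre-warped masks."""
    from .io_core import LabelLUT, LUTEntry, TISSUE_DEEPGM, TISSUE_WM, TISSUE_CSF, TISSUE_BG_EXTRA

    subjects = atlas4d.read_manifest(manifest)
    spec = atlas4d.KernelSpec(sigma_w=sigma_w, window=window)
    timepoints, weights = atlas4d.build_full_atlas(subjects, ages, spec)
    if lut is None:
        ids = sorted({k for s in subjects for k in s.masks})
        lut = LabelLUT(
            {
                i: LUTEntry(f"structure-{i}", TISSUE_DEEPGM if i else TISSUE_BG_EXTRA, "none")
                for i in ids
            }
        )
    atlas4d.save_atlas(timepoints, weights, lut, out_dir, spec)
    return timepoints
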