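"""Spatio-temporal structural atlas by age-weighted kernel regression.

Per-structure probability maps at each template age t are weighted
averages of the subjects' warped label masks,

    P_{k,t} = sum_s w(t_s, t) M_{s,k} / sum_s w(t_s, t),

with a Gaussian kernel over post-menstrual age at scan (sigma_w = 1 week
by default).  Matching the warping protocol, a subject contributes only
to template ages within [a-3, a+3] where a is its rounded age; the
maximum-probability atlas assigns each voxel the structure of highest
probability.  The default weekly grid spans 28-44 weeks (17 timepoints).

Registration to the template space is out of scope: the builder consumes
masks that are already on a common grid, listed in a manifest.  Warped
masks may be fuzzy (interpolation weights in [0, 1]); the regression
formula applies unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import LabelLUT, LabelVolume

log = logging.getLogger(__name__)

DEFAULT_SIGMA_W = 1.0  # weeks
DEFAULT_WINDOW = 3  # weeks, the [a-3, a+3] warping range
DEFAULT_AGES = list(range(28, 45))  # 17 weekly timepoints


@dataclass
class KernelSpec:
    sigma_w: float = DEFAULT_SIGMA_W
    window: float = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be > 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass
class SubjectRecord:
    """A subject's warped per-structure masks on the template grid."""

    subject: str
    age_weeks: float
    masks: dict[int, np.ndarray]  # structure id -> mask in [0, 1]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def rounded_age(self) -> int:
        return int(round(self.age_weeks))


@dataclass
class AtlasTimepoint:
    t: float
    class_ids: list[int]
    P: np.ndarray  # (n_classes, nx, ny, nz)
    affine: np.ndarray
    n_contributors: int
    total_weight: float

    def prob(self, structure_id: int) -> np.ndarray:
        return self.P[self.class_ids.index(int(structure_id))]


def kernel_weight(t_s: float, t: float, spec: KernelSpec | None = None) -> float:
    """Gaussian age kernel, zeroed outside the [a-3, a+3] warping window.

    ``a`` is the subject's age rounded to the nearest week; the window
    mirrors the range of template ages each segmentation is warped to.
    """
    spec = spec or KernelSpec()
    a = round(t_s)
    if np.isfinite(spec.window) and abs(a - t) > spec.window:
        return 0.0
    z = (t_s - t) / spec.sigma_w
    return float(np.exp(-0.5 * z * z) / (spec.sigma_w * np.sqrt(2.0 * np.pi)))


def build_atlas_timepoint(
    subjects: list[SubjectRecord],
    t: float,
    spec: KernelSpec | None = None,
) -> AtlasTimepoint:
    """Kernel-regression probability maps for one template age."""
    spec = spec or KernelSpec()
    if not subjects:
        raise ValueError("empty subject list")
    weights = np.array([kernel_weight(s.age_weeks, t, spec) for s in subjects])
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"zero total kernel weight at t={t}")
    class_ids = sorted({k for s in subjects for k in s.masks})
    shape = next(iter(subjects[0].masks.values())).shape
    P = np.zeros((len(class_ids),) + shape)
    for s, w in zip(subjects, weights):
        if w == 0:
            continue
        for k, m in s.masks.items():
            if m.shape != shape:
                raise ValueError(f"subject {s.subject}: mask grid mismatch")
            P[class_ids.index(k)] += w * np.asarray(m, float)
    P /= total
    return AtlasTimepoint(
        t=t,
        class_ids=class_ids,
        P=P,
        affine=subjects[0].affine,
        n_contributors=int((weights > 0).sum()),
        total_weight=float(total),
    )


def max_probability(tp: AtlasTimepoint, lut: LabelLUT) -> LabelVolume:
    """Eq.-style maximum-probability labels; ties broken to the lowest id."""
    order = np.argsort(tp.class_ids, kind="stable")
    ids_sorted = np.asarray(tp.class_ids)[order]
    best = np.argmax(tp.P[order], axis=0)
    return LabelVolume(ids_sorted[best].astype(np.int32), tp.affine, lut)


def build_full_atlas(
    subjects: list[SubjectRecord],
    ages: list[int] | None = None,
    spec: KernelSpec | None = None,
) -> tuple[list[AtlasTimepoint], pd.DataFrame]:
    """One timepoint per requested age plus a (subject, age) weight manifest.

    Ages with zero contributing weight are omitted with a warning.
    """
    spec = spec or KernelSpec()
    if not subjects:
        raise ValueError("empty subject list")
    ages = DEFAULT_AGES if ages is None else list(ages)
    if sorted(set(ages)) != ages:
        raise ValueError("ages must be sorted and unique")
    timepoints = []
    manifest_rows = []
    for t in ages:
        weights = [kernel_weight(s.age_weeks, t, spec) for s in subjects]
        for s, w in zip(subjects, weights):
            manifest_rows.append({"subject": s.subject, "atlas_age": t, "weight": w})
        if sum(weights) <= 0:
            log.warning("atlas age %s has no contributing subjects; omitted", t)
            continue
        timepoints.append(build_atlas_timepoint(subjects, t, spec))
    return timepoints, pd.DataFrame(manifest_rows)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject", "age_weeks", "structure_id", "mask_path"]


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Load subjects from a CSV manifest (columns: subject, age_weeks,
    structure_id, mask_path).  All masks must share one grid."""
    from .io_core import read_volume

    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    records: dict[str, SubjectRecord] = {}
    base = Path(path).parent
    for row_no, row in df.iterrows():
        try:
            sid = str(row["subject"])
            age = float(row["age_weeks"])
            k = int(row["structure_id"])
            p = Path(row["mask_path"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed manifest row {row_no + 2}: {exc}") from exc
        if not p.is_absolute():
            p = base / p
        vol = read_volume(p, kind="intensity")
        if sid not in records:
            records[sid] = SubjectRecord(sid, age, {}, vol.affine)
        records[sid].masks[k] = vol.data
    return list(records.values())


def save_atlas(
    timepoints: list[AtlasTimepoint],
    manifest: pd.DataFrame,
    lut: LabelLUT,
    out_dir: str | Path,
    spec: KernelSpec | None = None,
) -> None:
    """Write per-structure 4D probability NIfTIs, per-age max-probability
    labels and a JSON sidecar."""
    import nibabel as nib

    from .io_core import write_volume

    spec = spec or KernelSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not timepoints:
        raise ValueError("no atlas timepoints to save")
    class_ids = timepoints[0].class_ids
    affine = timepoints[0].affine
    for ci, k in enumerate(class_ids):
        vol4d = np.stack([tp.P[ci] for tp in timepoints], axis=-1)
        nib.save(nib.Nifti1Image(vol4d.astype(np.float32), affine), str(out / f"prob_structure_{k:03d}.nii.gz"))
    for tp in timepoints:
        write_volume(max_probability(tp, lut), out / f"max_prob_age_{int(tp.t):02d}.nii.gz")
    manifest.to_csv(out / "contributions.csv", index=False)
    sidecar = {
        "ages": [tp.t for tp in timepoints],
        "sigma_w": spec.sigma_w,
        "window": spec.window,
        "structures": class_ids,
        "contributors": {str(tp.t): tp.n_contributors for tp in timepoints},
    }
    (out / "atlas.json").write_text(json.dumps(sidecar, indent=2))
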