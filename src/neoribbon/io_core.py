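"""Core data types and file I/O.

Volumes are held as numpy arrays with a NIfTI-style 4x4 affine mapping
0-based voxel indices to world coordinates in mm.  All distances and
thicknesses downstream are computed in world mm, never in voxel counts,
because neonatal acquisitions are anisotropic (e.g. 0.86 x 0.86 x 1 mm).

Label volumes carry a lookup table (LUT) assigning each integer id a
structure name, a tissue class and a hemisphere.  The packaged full LUT
enumerates the 82 segmented structures (16 lobe-level cortical regions,
bilateral, each as a WM and a CGM structure; plus the subcortical set)
with 83 = CSF, 84 = intra-cranial background and 0 reserved for the
extra-cranial background.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

# ---------------------------------------------------------------------------
# tissue / hemisphere vocabulary
# ---------------------------------------------------------------------------

TISSUE_CGM = "CGM"
TISSUE_WM = "WM"
TISSUE_DEEPGM = "deepGM"
TISSUE_CSF = "CSF"
TISSUE_VENTRICLE = "ventricle"
TISSUE_BG_INTRA = "background-intracranial"
TISSUE_BG_EXTRA = "background-extracranial"

VALID_TISSUES = frozenset(
    {
        TISSUE_CGM,
        TISSUE_WM,
        TISSUE_DEEPGM,
        TISSUE_CSF,
        TISSUE_VENTRICLE,
        TISSUE_BG_INTRA,
        TISSUE_BG_EXTRA,
    }
)

VALID_HEMISPHERES = frozenset({"left", "right", "midline", "none"})

# Label ids used by the phantom generators (a minimal tissue-level LUT).
PHANTOM_BG_EXTRA = 0
PHANTOM_WM = 1
PHANTOM_CGM_LEFT = 2
PHANTOM_CGM_RIGHT = 3
PHANTOM_DEEPGM = 4
PHANTOM_CSF = 5
PHANTOM_BG_INTRA = 6


# ---------------------------------------------------------------------------
# label lookup table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LUTEntry:
    name: str
    tissue: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValueError(f"unknown tissue token {self.tissue!r}")
        if self.hemisphere not in VALID_HEMISPHERES:
            raise ValueError(f"unknown hemisphere token {self.hemisphere!r}")


@dataclass
class LabelLUT:
    """Mapping of integer label id -> (name, tissue, hemisphere)."""

    entries: dict[int, LUTEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries.values()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate structure names in LUT")

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def name(self, label_id: int) -> str:
        return self.entries[int(label_id)].name

    def tissue(self, label_id: int) -> str:
        return self.entries[int(label_id)].tissue

    def hemisphere(self, label_id: int) -> str:
        return self.entries[int(label_id)].hemisphere

    def ids_for_tissue(self, tissues: str | Iterable[str]) -> list[int]:
        if isinstance(tissues, str):
            tissues = {tissues}
        else:
            tissues = set(tissues)
        return sorted(i for i, e in self.entries.items() if e.tissue in tissues)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelLUT":
        return read_label_lut(path)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tname\ttissue\themisphere\n")
            for i in sorted(self.entries):
                e = self.entries[i]
                fh.write(f"{i}\t{e.name}\t{e.tissue}\t{e.hemisphere}\n")


def read_label_lut(path: str | Path) -> LabelLUT:
    """Read a tab-delimited LUT with columns id, name, tissue, hemisphere."""
    path = Path(path)
    entries: dict[int, LUTEntry] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["id", "name", "tissue", "hemisphere"]
        if [c.strip() for c in header[:4]] != required:
            raise ValueError(f"LUT must have columns {required}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            label_id = int(parts[0])
            if label_id in entries:
                raise ValueError(f"{path}:{lineno}: duplicate label id {label_id}")
            entries[label_id] = LUTEntry(parts[1], parts[2], parts[3])
    return LabelLUT(entries)


def default_lut() -> LabelLUT:
    """The packaged 85-entry LUT (82 structures + CSF + two backgrounds)."""
    ref = importlib.resources.files("neoribbon.data") / "structures_lut.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_label_lut(p)


def phantom_lut() -> LabelLUT:
    """Minimal tissue-level LUT used by the synthetic phantoms."""
    return LabelLUT(
        {
            PHANTOM_BG_EXTRA: LUTEntry("background", TISSUE_BG_EXTRA, "none"),
            PHANTOM_WM: LUTEntry("white-matter", TISSUE_WM, "none"),
            PHANTOM_CGM_LEFT: LUTEntry("cortex-left", TISSUE_CGM, "left"),
            PHANTOM_CGM_RIGHT: LUTEntry("cortex-right", TISSUE_CGM, "right"),
            PHANTOM_DEEPGM: LUTEntry("deep-grey", TISSUE_DEEPGM, "none"),
            PHANTOM_CSF: LUTEntry("csf", TISSUE_CSF, "none"),
            PHANTOM_BG_INTRA: LUTEntry("background-in", TISSUE_BG_INTRA, "none"),
        }
    )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def _check_grid(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D")
    if min(data.shape) < 1:
        raise ValueError("every volume extent must be >= 1")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    sp = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(sp <= 0) or not np.all(np.isfinite(sp)):
        raise ValueError("voxel spacing must be strictly positive and finite")


def affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class IntensityVolume:
    """A 3D scalar image on a regular grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid(self.data, self.affine)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]


@dataclass
class LabelVolume:
    """A 3D integer label image plus its lookup table."""

    data: np.ndarray
    affine: np.ndarray
    lut: LabelLUT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid(self.data, self.affine)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int32)
            if not np.array_equal(as_int, self.data):
                raise ValueError("label data must be integral")
            self.data = as_int
        present = np.unique(self.data)
        missing = [int(i) for i in present if i != 0 and int(i) not in self.lut]
        if missing:
            raise ValueError(f"label ids {missing} absent from LUT")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def tissue_mask(self, tissues: str | Iterable[str]) -> np.ndarray:
        """Boolean mask of voxels whose label belongs to the given tissue(s)."""
        ids = self.lut.ids_for_tissue(tissues)
        # id 0 (extra-cranial background) may legitimately be absent from
        # a subset LUT; treat it as background-extracranial by convention.
        mask = np.isin(self.data, ids)
        if TISSUE_BG_EXTRA in (tissues if not isinstance(tissues, str) else {tissues}):
            if 0 not in self.lut:
                mask |= self.data == 0
        return mask


# ---------------------------------------------------------------------------
# probability maps
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityMaps:
    """Per-class 3D probability fields stacked as (n_classes, nx, ny, nz)."""

    class_ids: list[int]
    data: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.class_ids = [int(i) for i in self.class_ids]
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ValueError("duplicate class ids")
        if self.data.ndim != 4 or self.data.shape[0] != len(self.class_ids):
            raise ValueError("data must be (n_classes, nx, ny, nz)")
        if np.any(self.data < -1e-12) or np.any(self.data > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)
        if self.normalized:
            s = self.data.sum(axis=0)
            if np.any(np.abs(s - 1.0) > 1e-6):
                raise ValueError("declared normalized but per-voxel sums != 1")

    def __getitem__(self, class_id: int) -> np.ndarray:
        return self.data[self.index(class_id)]

    def index(self, class_id: int) -> int:
        try:
            return self.class_ids.index(int(class_id))
        except ValueError:
            raise KeyError(f"class id {class_id} not present") from None

    def normalize(self, mask: np.ndarray | None = None) -> "ProbabilityMaps":
        """Divide by the per-voxel sum (inside `mask`, if given)."""
        out = self.data.copy()
        s = out.sum(axis=0)
        where = s > 0 if mask is None else (np.asarray(mask, bool) & (s > 0))
        out[:, where] /= s[where]
        return ProbabilityMaps(list(self.class_ids), out, normalized=mask is None)

    @classmethod
    def from_labels(cls, labels: LabelVolume, class_ids: Iterable[int] | None = None) -> "ProbabilityMaps":
        """One-hot expansion of a label volume; sums to exactly 1 per voxel."""
        ids = sorted(np.unique(labels.data).tolist()) if class_ids is None else [int(i) for i in class_ids]
        data = np.zeros((len(ids),) + labels.data.shape)
        for k, i in enumerate(ids):
            data[k] = labels.data == i
        return cls(ids, data, normalized=class_ids is None)


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm with per-vertex annotations.

    `vertex_excluded` marks vertices dropped from area/curvature summaries
    (the WM-deep GM boundary); `vertex_region` optionally carries the id of
    the nearest cortical structure.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_excluded: np.ndarray | None = None
    vertex_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if len(self.vertices) == 0 or len(self.triangles) == 0:
            raise ValueError("empty mesh")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")
        if self.vertex_excluded is None:
            self.vertex_excluded = np.zeros(len(self.vertices), dtype=bool)
        else:
            self.vertex_excluded = np.asarray(self.vertex_excluded, dtype=bool)
            if self.vertex_excluded.shape != (len(self.vertices),):
                raise ValueError("vertex_excluded length must equal vertex count")
        if self.vertex_region is not None:
            self.vertex_region = np.asarray(self.vertex_region, dtype=np.int64)
            if self.vertex_region.shape != (len(self.vertices),):
                raise ValueError("vertex_region length must equal vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return self.n_vertices - len(edges) + len(self.triangles)

    def is_closed(self) -> bool:
        """Every edge shared by exactly two triangles."""
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem (positive if outward-wound)."""
        v = self.vertices
        t = self.triangles
        return float(
            abs(np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum()) / 6.0
        )


# ---------------------------------------------------------------------------
# volume file I/O (NIfTI-1)
# ---------------------------------------------------------------------------


def read_volume(
    path: str | Path,
    kind: str = "intensity",
    lut: LabelLUT | None = None,
):
    """Read a 3D NIfTI volume as an IntensityVolume or LabelVolume.

    Spacing and affine are taken from the NIfTI header unchanged.  For
    ``kind='label'`` the data must be integral and a LUT must be supplied
    (or every nonzero id present must appear in the packaged full LUT).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if kind == "intensity":
        return IntensityVolume(data.astype(float), affine)
    if kind == "label":
        as_int = np.rint(data).astype(np.int32)
        if not np.allclose(data, as_int, atol=1e-6):
            raise ValueError("non-integral data for kind='label'")
        if lut is None:
            lut = default_lut()
        return LabelVolume(as_int, affine, lut)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: IntensityVolume | LabelVolume, path: str | Path) -> None:
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16 if data.max(initial=0) < 2**15 else np.int32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# mesh file I/O (PLY, GIFTI)
# ---------------------------------------------------------------------------


def write_mesh(mesh: SurfaceMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh with its per-vertex attributes.

    PLY stores `excluded` and `region` as extra vertex properties; GIFTI
    stores them as additional data arrays (shape/label intents).
    """
    path = Path(path)
    if format is None:
        suffix = path.name.lower()
        format = "GIFTI" if suffix.endswith((".gii", ".surf.gii")) else (
            "PLY" if suffix.endswith(".ply") else None
        )
        if format is None:
            raise ValueError(f"cannot infer mesh format from {path.name!r}")
    format = format.upper()
    if format == "PLY":
        _write_ply(mesh, path)
    elif format == "GIFTI":
        _write_gifti(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {format!r}")


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    n = mesh.n_vertices
    region = mesh.vertex_region if mesh.vertex_region is not None else np.full(n, -1, np.int64)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar excluded\nproperty int region\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), ex, rg in zip(mesh.vertices, mesh.vertex_excluded, region):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {int(ex)} {int(rg)}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


def _write_gifti(mesh: SurfaceMesh, path: Path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET")
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(mesh.vertex_excluded.astype(np.int32), intent="NIFTI_INTENT_LABEL")
    )
    if mesh.vertex_region is not None:
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(mesh.vertex_region.astype(np.int32), intent="NIFTI_INTENT_LABEL")
        )
    nib.save(img, str(path))


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if path.name.lower().endswith(".gii"):
        img = nib.load(str(path))
        arrays = img.darrays
        vertices = arrays[0].data.astype(float)
        triangles = arrays[1].data.astype(np.int64)
        excluded = arrays[2].data.astype(bool) if len(arrays) > 2 else None
        region = arrays[3].data.astype(np.int64) if len(arrays) > 3 else None
        return SurfaceMesh(vertices, triangles, excluded, region)
    if path.name.lower().endswith(".ply"):
        return _read_ply(path)
    raise ValueError(f"unsupported mesh file {path.name!r}")


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("truncated PLY header")
            line = line.strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 3))
        excluded = np.zeros(n_vert, dtype=bool)
        region = np.full(n_vert, -1, dtype=np.int64)
        for i in range(n_vert):
            parts = fh.readline().split()
            verts[i] = [float(p) for p in parts[:3]]
            if len(parts) >= 5:
                excluded[i] = bool(int(parts[3]))
                region[i] = int(parts[4])
        tris = np.empty((n_face, 3), dtype=np.int64)
        for i in range(n_face):
            parts = fh.readline().split()
            tris[i] = [int(p) for p in parts[1:4]]
    reg = None if np.all(region == -1) else region
    return SurfaceMesh(verts, tris, excluded, reg)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "subject",
    "structure_id",
    "structure_name",
    "absolute_volume_ml",
    "relative_volume_pct",
    "surface_area_cm2",
    "relative_surface_area_pct",
    "GC_T",
    "MLN_T",
    "GLN_T",
    "median_thickness_mm",
]
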