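"""Surface reconstruction, curvature norms, labelling and measurements."""

import numpy as np
import pytest

from neoribbon import phantoms, surface_metrics as sm
from neoribbon.io_core import (
    LabelVolume,
    PHANTOM_CGM_LEFT,
    PHANTOM_CGM_RIGHT,
    PHANTOM_CSF,
    PHANTOM_DEEPGM,
    PHANTOM_WM,
    SurfaceMesh,
    phantom_lut,
)


class TestReconstruction:
    def test_sphere_mesh_closed_genus_zero(self, sphere30):
        _, mesh, _, _ = sphere30
        assert mesh.is_closed()
        assert mesh.euler_characteristic() == 2

    def test_sphere_area_and_volume_analytic(self, sphere30):
        truth, mesh, _, _ = sphere30
        assert mesh.triangle_areas().sum() == pytest.approx(truth.analytic_area_mm2, rel=0.02)
        assert mesh.enclosed_volume() == pytest.approx(truth.analytic_volume_mm3, rel=0.02)

    def test_default_blur_sigma_is_one_mm(self):
        import inspect

        sig = inspect.signature(sm.reconstruct_surface)
        assert sig.parameters["blur_sigma"].default == 1.0

    def test_empty_interior_rejected(self):
        lut = phantom_lut()
        labels = LabelVolume(np.full((6, 6, 6), PHANTOM_CSF, np.int32), np.eye(4), lut)
        with pytest.raises(ValueError, match="interior"):
            sm.reconstruct_surface(labels)

    def test_smoothing_changes_curvature_norms_but_not_area(self, sphere30):
        """Laplacian smoothing shifts MLN/GC appreciably while the area is stable."""
        truth, smooth, _, _ = sphere30
        rough = sm.reconstruct_surface(truth.labels, smooth_iters=0)
        a_rough = rough.triangle_areas().sum()
        a_smooth = smooth.triangle_areas().sum()
        assert abs(a_smooth - a_rough) / a_rough < 0.02
        c_rough = sm.summarize_curvature(rough, sm.vertex_curvatures(rough, rings=2.5))
        c_smooth = sm.summarize_curvature(smooth, sm.vertex_curvatures(smooth, rings=2.5))
        assert abs(c_rough.MLN_T - c_smooth.MLN_T) / c_smooth.MLN_T > 0.05
        assert abs(c_rough.GC_T - c_smooth.GC_T) / c_smooth.GC_T > 0.02


class TestDeepExclusion:
    @pytest.fixture()
    def block_with_deep_face(self):
        shape = (24, 24, 24)
        lab = np.full(shape, PHANTOM_CSF, np.int32)
        lab[6:18, 6:18, 6:18] = PHANTOM_WM
        lab[6:18, 6:18, 4:6] = PHANTOM_DEEPGM  # slab on the low-z face
        lab[6:18, 6:18, 18:20] = PHANTOM_CGM_LEFT  # cortex on the high-z face
        return LabelVolume(lab, np.eye(4), phantom_lut())

    def test_deep_face_vertices_flagged(self, block_with_deep_face):
        mesh = sm.reconstruct_surface(block_with_deep_face, smooth_iters=5)
        mesh = sm.exclude_deep_boundary(mesh, block_with_deep_face)
        v = mesh.vertices
        footprint = (v[:, 0] > 8) & (v[:, 0] < 16) & (v[:, 1] > 8) & (v[:, 1] < 16)
        bottom = footprint & (v[:, 2] < 4.2)  # underside of the deep GM slab
        top = footprint & (v[:, 2] > 16.5)  # face capped by cortex
        assert bottom.sum() > 0 and top.sum() > 0
        assert mesh.vertex_excluded[bottom].mean() > 0.9
        assert mesh.vertex_excluded[top].mean() < 0.1

    def test_no_deep_gm_means_no_exclusion(self, sphere30):
        truth, mesh, _, _ = sphere30
        out = sm.exclude_deep_boundary(mesh, truth.labels)
        assert out.vertex_excluded.sum() == 0

    def test_area_conservation_under_exclusion(self, block_with_deep_face):
        mesh = sm.reconstruct_surface(block_with_deep_face, smooth_iters=5)
        mesh = sm.exclude_deep_boundary(mesh, block_with_deep_face)
        areas = mesh.triangle_areas()
        keep = sm._triangle_keep(mesh)
        total = areas.sum()
        assert areas[keep].sum() + areas[~keep].sum() == pytest.approx(total, rel=1e-6)


class TestCurvature:
    def test_sphere_pointwise_curvatures(self, sphere30):
        _, mesh, curv, _ = sphere30
        w = sm.vertex_area_weights(mesh)
        R = 30.0
        assert np.average(curv.H, weights=w) == pytest.approx(1 / R, rel=0.05)
        assert np.average(curv.G, weights=w) == pytest.approx(1 / R**2, rel=0.05)
        assert np.average(curv.c, weights=w) == pytest.approx(1 / R, rel=0.05)

    def test_curvedness_bounds_invariants(self, sphere30):
        _, _, curv, _ = sphere30
        assert np.all(curv.c >= np.abs(curv.H) - 1e-12)
        assert np.all(curv.G <= curv.c**2 + 1e-12)
        assert np.all(np.isfinite(curv.k1)) and np.all(np.isfinite(curv.k2))

    def test_flat_plate_interior_is_flat(self):
        shape = (64, 64, 12)
        lab = np.full(shape, PHANTOM_CSF, np.int32)
        lab[:, :, :6] = PHANTOM_WM
        labels = LabelVolume(lab, np.eye(4), phantom_lut())
        mesh = sm.reconstruct_surface(labels)
        curv = sm.vertex_curvatures(mesh)
        interior = (
            (mesh.vertices[:, 0] > 20) & (mesh.vertices[:, 0] < 44)
            & (mesh.vertices[:, 1] > 20) & (mesh.vertices[:, 1] < 44)
            & (mesh.vertices[:, 2] > 4)
        )
        assert interior.sum() > 100
        assert np.abs(curv.H[interior]).max() < 1e-3
        assert np.abs(curv.c[interior]).max() < 1e-3
        assert np.abs(curv.G[interior]).max() < 1e-3

    def test_gauss_bonnet(self, sphere30):
        _, mesh, curv, _ = sphere30
        w = sm.vertex_area_weights(mesh)
        assert float((curv.G * w).sum()) == pytest.approx(4 * np.pi, rel=0.02)


class TestSummaries:
    def test_sphere_norms_equal_one(self, sphere30):
        _, _, _, summary = sphere30
        assert summary.GC_T == pytest.approx(1.0, abs=0.05)
        assert summary.MLN_T == pytest.approx(1.0, abs=0.05)
        assert summary.GLN_T == pytest.approx(1.0, abs=0.05)

    def test_T_equals_radius(self, sphere30):
        _, _, _, summary = sphere30
        assert summary.T == pytest.approx(30.0, rel=0.02)

    def test_scale_invariance(self, sphere30):
        _, mesh, curv, summary = sphere30
        scaled = SurfaceMesh(mesh.vertices * 2.0, mesh.triangles)
        c2 = sm.vertex_curvatures(scaled)
        s2 = sm.summarize_curvature(scaled, c2)
        assert abs(s2.GC_T / summary.GC_T - 1) < 0.01
        assert abs(s2.MLN_T / summary.MLN_T - 1) < 0.01
        assert abs(s2.GLN_T / summary.GLN_T - 1) < 0.01

    def test_zero_retained_area_rejected(self, sphere30):
        _, mesh, curv, _ = sphere30
        excluded = SurfaceMesh(
            mesh.vertices, mesh.triangles, np.ones(mesh.n_vertices, bool)
        )
        with pytest.raises(ValueError, match="area"):
            sm.summarize_curvature(excluded, curv)


class TestVertexLabelling:
    def test_nearest_and_tie_break(self):
        shape = (12, 6, 6)
        lab = np.full(shape, PHANTOM_WM, np.int32)
        lab[2, 3, 3] = PHANTOM_CGM_LEFT  # id 2
        lab[8, 3, 3] = PHANTOM_CGM_RIGHT  # id 3
        labels = LabelVolume(lab, np.eye(4), phantom_lut())
        mesh = SurfaceMesh(
            np.array([[2.1, 3.0, 3.0], [7.0, 3.0, 3.0], [5.0, 3.0, 3.0]]),
            np.array([[0, 1, 2]]),
        )
        out = sm.label_vertices(mesh, labels)
        assert out.vertex_region[0] == PHANTOM_CGM_LEFT  # 0.1 mm vs 5.9 mm
        assert out.vertex_region[1] == PHANTOM_CGM_RIGHT
        assert out.vertex_region[2] == PHANTOM_CGM_LEFT  # exact tie -> lowest id

    def test_every_vertex_labelled(self, sphere30):
        truth, mesh, _, _ = sphere30
        lab = truth.labels.data.copy()
        wm = lab == PHANTOM_WM
        import scipy.ndimage as ndi

        shell = ndi.binary_dilation(wm) & ~wm
        half = np.indices(lab.shape)[0] < lab.shape[0] // 2
        lab[shell & half] = PHANTOM_CGM_LEFT
        lab[shell & ~half] = PHANTOM_CGM_RIGHT
        labels = LabelVolume(lab, truth.labels.affine, truth.lut)
        out = sm.label_vertices(mesh, labels)
        assert set(np.unique(out.vertex_region)) == {PHANTOM_CGM_LEFT, PHANTOM_CGM_RIGHT}

    def test_no_cgm_rejected(self, sphere30):
        truth, mesh, _, _ = sphere30
        with pytest.raises(ValueError, match="CGM"):
            sm.label_vertices(mesh, truth.labels)


class TestMeasurements:
    def test_relative_volume_arithmetic(self):
        shape = (10, 10, 10)
        lab = np.zeros(shape, np.int32)
        lab[:2] = PHANTOM_CGM_LEFT  # 200 voxels
        lab[2:8] = PHANTOM_WM  # 600 voxels
        labels = LabelVolume(lab, np.eye(4), phantom_lut())
        vols = sm.compute_volumes(labels).set_index("structure_id")
        assert vols.loc[PHANTOM_CGM_LEFT, "relative_volume_pct"] == pytest.approx(25.0)
        included = vols["relative_volume_pct"].dropna()
        assert included.sum() == pytest.approx(100.0, abs=0.01)

    def test_csf_does_not_change_relative_volumes(self):
        shape = (10, 10, 10)
        lab = np.zeros(shape, np.int32)
        lab[:2] = PHANTOM_CGM_LEFT
        lab[2:8] = PHANTOM_WM
        labels = LabelVolume(lab, np.eye(4), phantom_lut())
        before = sm.compute_volumes(labels).set_index("structure_id")["relative_volume_pct"]
        lab2 = lab.copy()
        lab2[8:] = PHANTOM_CSF  # 200 extra CSF voxels
        after = sm.compute_volumes(LabelVolume(lab2, np.eye(4), phantom_lut())).set_index(
            "structure_id"
        )["relative_volume_pct"]
        assert after[PHANTOM_CGM_LEFT] == pytest.approx(before[PHANTOM_CGM_LEFT])
        assert after[PHANTOM_WM] == pytest.approx(before[PHANTOM_WM])

    def test_hemispheric_split_surface_areas(self, sphere30):
        truth, mesh, curv, _ = sphere30
        lab = truth.labels.data.copy()
        wm = lab == PHANTOM_WM
        import scipy.ndimage as ndi

        shell = ndi.binary_dilation(wm) & ~wm
        half = np.indices(lab.shape)[0] < lab.shape[0] // 2
        lab[shell & half] = PHANTOM_CGM_LEFT
        lab[shell & ~half] = PHANTOM_CGM_RIGHT
        labels = LabelVolume(lab, truth.labels.affine, truth.lut)
        labelled = sm.label_vertices(mesh, labels)
        table = sm.compute_measurements(labels, truth.lut, labelled, None, curv).set_index(
            "structure_id"
        )
        assert table.loc[PHANTOM_CGM_LEFT, "relative_surface_area_pct"] == pytest.approx(50.0, abs=2.0)
        assert table.loc[PHANTOM_CGM_RIGHT, "relative_surface_area_pct"] == pytest.approx(50.0, abs=2.0)
        total = (
            table.loc[PHANTOM_CGM_LEFT, "surface_area_cm2"]
            + table.loc[PHANTOM_CGM_RIGHT, "surface_area_cm2"]
        )
        assert total * 100 == pytest.approx(mesh.triangle_areas().sum(), rel=1e-6)
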