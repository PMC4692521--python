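"""Voxelwise cortical thickness and sulci detection/enhancement.

Thickness follows the Laplace-equation approach: the electrostatic
potential is solved over the cortical grey matter (CGM) ribbon with
Dirichlet conditions 0 on the CGM-WM interface and 1 on the CGM-CSF
interface, and per-voxel thickness is the arc length of the streamline
through the normalized potential gradient, integrated to both interfaces.
All geometry is computed in world mm so anisotropic grids are handled
correctly.

Buried sulci - opposing sulcal banks fused by partial-volume effects, with
no CSF evidence between them - are found by propagating a front from the
inner cortical surface (fast marching with a speed derived from the CSF
posterior) and detecting shock points where fronts seeded from distant
parts of the interface collide.  Neighbouring CGM voxels from the two
hemispheres are a second shock type.  A shock voxel is relabelled to CSF
only when its streamline distance to the WM (its would-be thickness,
D_WM) exceeds D_allowed, the typical thickness of the neighbouring cortex
plus a tolerance; this keeps genuine thick cortex intact while re-opening
sulci whose apparent thickness is anatomically implausible.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve, cg
from scipy.spatial import cKDTree

from .io_core import (
    LabelVolume,
    TISSUE_BG_EXTRA,
    TISSUE_BG_INTRA,
    TISSUE_CGM,
    TISSUE_CSF,
    TISSUE_DEEPGM,
    TISSUE_VENTRICLE,
    TISSUE_WM,
)

log = logging.getLogger(__name__)

DEFAULT_LAPLACE_TOL = 1e-6
DEFAULT_D_MIN_MM = 3.0
DEFAULT_NEIGHBOURHOOD_MM = 5.0
SPEED_FLOOR = 0.05

SHOCK_BANK = "bank-collision"
SHOCK_HEMI = "inter-hemispheric"


# ---------------------------------------------------------------------------
# Laplace potential over the ribbon
# ---------------------------------------------------------------------------


@dataclass
class LaplaceField:
    """Solved potential: 0 in the inner (WM-side) region, 1 in the outer."""

    potential: np.ndarray  # full-grid float; boundary regions filled 0 / 1
    cgm_mask: np.ndarray
    inner_mask: np.ndarray
    outer_mask: np.ndarray
    valid: np.ndarray  # CGM voxels connected to the boundaries
    spacing: np.ndarray
    residual: float


def ribbon_masks(labels: LabelVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CGM / inner (WM + deep GM + ventricles) / outer (CSF + background) masks."""
    cgm = labels.tissue_mask(TISSUE_CGM)
    inner = labels.tissue_mask([TISSUE_WM, TISSUE_DEEPGM, TISSUE_VENTRICLE])
    outer = labels.tissue_mask([TISSUE_CSF, TISSUE_BG_INTRA, TISSUE_BG_EXTRA])
    return cgm, inner, outer


def solve_laplace(
    cgm_mask: np.ndarray,
    inner_boundary: np.ndarray,
    outer_boundary: np.ndarray,
    spacing,
    tol: float = DEFAULT_LAPLACE_TOL,
) -> LaplaceField:
    """Solve the discrete Laplace equation over the CGM mask.

    Dirichlet values 0 / 1 are imposed on the inner / outer boundary
    regions (which may be whole tissue masks); faces of CGM voxels that
    touch neither CGM nor a boundary get reflecting (Neumann) conditions.
    CGM components with no boundary contact are reported and marked
    invalid (potential fixed at 0.5).
    """
    cgm = np.asarray(cgm_mask, bool)
    inner = np.asarray(inner_boundary, bool) & ~cgm
    outer = np.asarray(outer_boundary, bool) & ~cgm & ~inner
    if not inner.any() or not outer.any():
        raise ValueError("inner and outer boundaries must be non-empty and disjoint")
    spacing = np.asarray(spacing, float)

    # flag CGM components with no Dirichlet contact
    struct = ndimage.generate_binary_structure(3, 1)
    comp, n_comp = ndimage.label(cgm, structure=struct)
    touching = ndimage.binary_dilation(inner | outer, structure=struct)
    valid = np.ones_like(cgm)
    for c in range(1, n_comp + 1):
        sel = comp == c
        if not (sel & touching).any():
            valid[sel] = False
            log.warning("Laplace: CGM component of %d voxels touches no boundary", sel.sum())
    solve_mask = cgm & valid

    idx = -np.ones(cgm.shape, dtype=np.int64)
    coords = np.argwhere(solve_mask)
    n = len(coords)
    idx[tuple(coords.T)] = np.arange(n)

    potential = np.zeros(cgm.shape, dtype=float)
    potential[outer] = 1.0
    potential[cgm] = 0.5

    if n:
        rows, cols, vals = [], [], []
        b = np.zeros(n)
        diag = np.zeros(n)
        shape = cgm.shape
        for axis in range(3):
            w = 1.0 / spacing[axis] ** 2
            for sign in (-1, 1):
                nb = coords.copy()
                nb[:, axis] += sign
                inside = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
                nb_in = nb[inside]
                flat = tuple(nb_in.T)
                here = np.arange(n)[inside]
                nb_idx = idx[flat]
                is_unknown = nb_idx >= 0
                is_inner = inner[flat]
                is_outer = outer[flat]
                diag[here[is_unknown]] += w
                rows.extend(here[is_unknown])
                cols.extend(nb_idx[is_unknown])
                vals.extend([-w] * int(is_unknown.sum()))
                # Dirichlet values live on the tissue interface, i.e. at
                # half-spacing from the voxel centre: ghost-node weight 2w
                diag[here[is_inner | is_outer]] += 2 * w
                b[here[is_outer]] += 2 * w  # interface value 1; inner adds 0
        rows.extend(range(n))
        cols.extend(range(n))
        vals.extend(diag)
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        if n <= 40000:
            u = spsolve(A.tocsc(), b)
        else:
            u, info = cg(A, b, rtol=tol * 1e-2, maxiter=10000, x0=np.full(n, 0.5))
            if info != 0:
                log.warning("Laplace CG did not fully converge (info=%s)", info)
        resid = float(np.max(np.abs(A @ u - b))) if n else 0.0
        # clamp solver round-off; the discrete maximum principle bounds u in (0,1)
        u = np.clip(u, 0.0, 1.0)
        potential[tuple(coords.T)] = u
    else:
        resid = 0.0

    potential[cgm & ~valid] = 0.5
    return LaplaceField(potential, cgm, inner, outer, valid & cgm, spacing, resid)


# ---------------------------------------------------------------------------
# streamline thickness
# ---------------------------------------------------------------------------


@dataclass
class ThicknessMap:
    """Per-CGM-voxel thickness in mm with validity flags.

    ``down_mm`` / ``up_mm`` are the streamline lengths to the inner
    (CGM-WM) and outer (CGM-CSF) interfaces; thickness is their sum.
    """

    thickness: np.ndarray
    valid: np.ndarray
    down_mm: np.ndarray
    up_mm: np.ndarray

    def median(self) -> float:
        vals = self.thickness[self.valid]
        return float(np.median(vals)) if vals.size else float("nan")


def _trilinear(vol: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at continuous voxel coordinates (N, 3)."""
    shape = vol.shape
    p = np.clip(pts, 0, np.asarray(shape) - 1.000001)
    i0 = np.floor(p).astype(np.int64)
    f = p - i0
    out = np.zeros(len(p))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * vol[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def _march(
    start_pts: np.ndarray,
    grad: list[np.ndarray],
    target_ind: np.ndarray,
    spacing: np.ndarray,
    step_mm: float,
    direction: float,
    max_len_mm: float,
    avoid: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """March streamlines along +/- the normalized potential gradient.

    Terminates each line where the trilinearly interpolated indicator of
    the target region crosses 0.5 (the tissue interface), with a
    fractional last step.  Returns (length_mm, ok).
    """
    n = len(start_pts)
    pos = start_pts.astype(float).copy()
    length = np.zeros(n)
    active = np.ones(n, bool)
    ok = np.zeros(n, bool)
    prev_ind = _trilinear(target_ind, pos)
    max_steps = int(max_len_mm / step_mm) + 2

    def grad_at(p):
        g = np.stack([_trilinear(grad[a], p) for a in range(3)], axis=1)
        norm = np.linalg.norm(g, axis=1)
        return g, norm

    for _ in range(max_steps):
        act = np.where(active)[0]
        if act.size == 0:
            break
        p = pos[act]
        g, norm = grad_at(p)
        dead = norm < 1e-12
        norm[dead] = 1.0
        d = direction * g / norm[:, None]
        # RK2 midpoint, stepping in world mm (converted to index units)
        mid = p + 0.5 * step_mm * d / spacing
        g2, norm2 = grad_at(mid)
        dead2 = norm2 < 1e-12
        g2[dead2] = g[dead2]
        norm2[dead2] = norm[dead2]
        d2 = direction * g2 / norm2[:, None]
        newp = p + step_mm * d2 / spacing

        stuck = dead & dead2  # zero gradient: line cannot progress, invalid
        newind = _trilinear(target_ind, newp)
        pos[act] = newp
        in_avoid = np.zeros(len(act), bool)
        if avoid is not None:
            nearest = np.clip(
                np.rint(newp).astype(np.int64), 0, np.asarray(avoid.shape) - 1
            )
            in_avoid = avoid[tuple(nearest.T)]
        crossed = newind >= 0.5
        prev = prev_ind[act]
        with np.errstate(divide="ignore", invalid="ignore"):
            df = newind - prev
            frac = np.where(np.abs(df) > 1e-12, (0.5 - prev) / df, 1.0)
        frac = np.clip(frac, 0.0, 1.0)

        fail = stuck | in_avoid
        finish = crossed & ~fail
        keep = ~fail & ~finish
        length[act[keep]] += step_mm
        length[act[finish]] += step_mm * frac[finish]
        ok[act[finish]] = True
        active[act[fail | finish]] = False
        prev_ind[act] = newind
    return length, ok


def compute_thickness(
    field: LaplaceField,
    spacing=None,
    avoid: np.ndarray | None = None,
    step_mm: float | None = None,
) -> ThicknessMap:
    """Streamline thickness for every valid CGM voxel of a solved field.

    ``avoid`` marks voxels streamlines must not traverse (shock points);
    lines that enter it are flagged invalid but their voxel's neighbours
    are unaffected.
    """
    spacing = field.spacing if spacing is None else np.asarray(spacing, float)
    if step_mm is None:
        step_mm = 0.5 * float(spacing.min())
    phi = field.potential
    grad = list(np.gradient(phi, *spacing))
    coords = np.argwhere(field.cgm_mask & field.valid)
    shape = np.asarray(phi.shape)
    max_len = float((shape * spacing).sum())

    inner_ind = field.inner_mask.astype(float)
    outer_ind = field.outer_mask.astype(float)
    down, ok_down = _march(coords, grad, inner_ind, spacing, step_mm, -1.0, max_len, avoid)
    up, ok_up = _march(coords, grad, outer_ind, spacing, step_mm, +1.0, max_len, avoid)

    thick = np.zeros(phi.shape)
    valid = np.zeros(phi.shape, bool)
    down_map = np.full(phi.shape, np.nan)
    up_map = np.full(phi.shape, np.nan)
    sel = tuple(coords.T)
    total = down + up
    okay = ok_down & ok_up & (total > 0)
    thick[sel] = np.where(okay, total, 0.0)
    valid[sel] = okay
    down_map[sel] = np.where(ok_down, down, np.nan)
    up_map[sel] = np.where(ok_up, up, np.nan)
    return ThicknessMap(thick, valid, down_map, up_map)


def cortical_thickness(
    labels: LabelVolume,
    avoid: np.ndarray | None = None,
    tol: float = DEFAULT_LAPLACE_TOL,
) -> ThicknessMap:
    """Convenience wrapper: ribbon masks -> Laplace solve -> streamlines."""
    cgm, inner, outer = ribbon_masks(labels)
    fieldv = solve_laplace(cgm, inner, outer, labels.spacing, tol)
    return compute_thickness(fieldv, avoid=avoid)


# ---------------------------------------------------------------------------
# fast marching from the inner cortical surface
# ---------------------------------------------------------------------------


@dataclass
class FrontPropagation:
    arrival_time: np.ndarray  # +inf outside the reached domain
    origin_map: np.ndarray  # seed id whose front arrived first; -1 unreached
    seed_coords: np.ndarray  # (n_seeds, 3) voxel indices


def interface_seeds(cgm_mask: np.ndarray, inner_mask: np.ndarray) -> np.ndarray:
    """CGM voxels 6-adjacent to the inner (WM-side) region, one seed each."""
    struct = ndimage.generate_binary_structure(3, 1)
    touching = ndimage.binary_dilation(np.asarray(inner_mask, bool), structure=struct)
    return np.argwhere(np.asarray(cgm_mask, bool) & touching)


def propagate_interface(
    seeds: np.ndarray,
    speed: np.ndarray,
    domain: np.ndarray,
    spacing,
) -> FrontPropagation:
    """Fast-marching solution of |grad T| * F = 1 from per-voxel seeds.

    6-connected upwind scheme on an anisotropic grid.  Each seed voxel is
    its own front (arrival 0); the origin map records, per accepted voxel,
    the seed of the upwind neighbour that determined its arrival time.
    Voxels with zero speed are never reached (arrival +inf).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.int64))
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    domain = np.asarray(domain, bool)
    speed = np.asarray(speed, float)
    if np.any(~np.isfinite(speed)) or np.any(speed < 0):
        raise ValueError("speed must be finite and non-negative")
    if not domain[tuple(seeds.T)].all():
        raise ValueError("seeds must lie inside the domain")
    spacing = np.asarray(spacing, float)
    shape = domain.shape

    T = np.full(shape, np.inf)
    origin = np.full(shape, -1, dtype=np.int64)
    state = np.zeros(shape, dtype=np.int8)  # 0 far, 1 trial, 2 accepted

    inv_h2 = 1.0 / spacing**2
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]

    heap: list[tuple[float, int, int, int]] = []
    for sid, (i, j, k) in enumerate(seeds):
        T[i, j, k] = 0.0
        origin[i, j, k] = sid
        heapq.heappush(heap, (0.0, i, j, k))
        state[i, j, k] = 1

    def update(i: int, j: int, k: int) -> None:
        f = speed[i, j, k]
        if f <= 0:
            return
        # per-axis upwind values; second-order one-sided stencil where two
        # accepted neighbours are available in the upwind direction
        a_vals = []
        here = (i, j, k)
        for axis in range(3):
            best = np.inf
            best_org = -1
            best_sign = 0
            for sign in (-1, 1):
                nn = here[axis] + sign
                if 0 <= nn < shape[axis]:
                    idx = list(here)
                    idx[axis] = nn
                    if state[idx[0], idx[1], idx[2]] == 2:
                        tv = T[idx[0], idx[1], idx[2]]
                        if tv < best:
                            best = tv
                            best_org = origin[idx[0], idx[1], idx[2]]
                            best_sign = sign
            if not np.isfinite(best):
                continue
            a = best
            w = inv_h2[axis]
            nn2 = here[axis] + 2 * best_sign
            if 0 <= nn2 < shape[axis]:
                idx2 = list(here)
                idx2[axis] = nn2
                if state[idx2[0], idx2[1], idx2[2]] == 2:
                    t2 = T[idx2[0], idx2[1], idx2[2]]
                    if t2 <= best:
                        a = (4.0 * best - t2) / 3.0
                        w = 2.25 * inv_h2[axis]
            a_vals.append((a, w, best_org))
        if not a_vals:
            return
        a_vals.sort(key=lambda t: t[0])
        rhs = 1.0 / (f * f)
        # solve sum_i w_i (t - a_i)^2 = rhs over the usable subset
        t_new = np.inf
        for m in range(len(a_vals), 0, -1):
            sub = a_vals[:m]
            sw = sum(w for _, w, _ in sub)
            swa = sum(w * a for a, w, _ in sub)
            swa2 = sum(w * a * a for a, w, _ in sub)
            disc = swa * swa - sw * (swa2 - rhs)
            if disc < 0:
                continue
            t_cand = (swa + np.sqrt(disc)) / sw
            if t_cand >= sub[-1][0] - 1e-12:
                t_new = t_cand
                break
        if t_new < T[i, j, k]:
            T[i, j, k] = t_new
            origin[i, j, k] = a_vals[0][2]
            heapq.heappush(heap, (t_new, i, j, k))
            state[i, j, k] = max(state[i, j, k], 1)

    while heap:
        t, i, j, k = heapq.heappop(heap)
        if state[i, j, k] == 2 or t > T[i, j, k]:
            continue
        state[i, j, k] = 2
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if (
                0 <= ni < shape[0]
                and 0 <= nj < shape[1]
                and 0 <= nk < shape[2]
                and domain[ni, nj, nk]
                and state[ni, nj, nk] != 2
            ):
                update(ni, nj, nk)

    T[~domain] = np.inf
    origin[~domain] = -1
    return FrontPropagation(T, origin, seeds)


def csf_speed(csf_posterior: np.ndarray, domain: np.ndarray, floor: float = SPEED_FLOOR) -> np.ndarray:
    """Front speed from the CSF posterior, floored so PV-obscured sulci stay passable."""
    speed = np.maximum(np.asarray(csf_posterior, float), floor)
    speed[~np.asarray(domain, bool)] = 0.0
    return speed


# ---------------------------------------------------------------------------
# shock points
# ---------------------------------------------------------------------------


@dataclass
class ShockPointSet:
    """Detected front-collision / inter-hemispheric voxels with the relabel rule state."""

    coords: np.ndarray  # (n, 3) voxel indices
    types: np.ndarray  # str per record
    d_wm: np.ndarray  # streamline distance to the CGM-WM interface (mm)
    d_allowed: np.ndarray  # locally permitted thickness (mm)
    relabelled: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def empty(cls) -> "ShockPointSet":
        return cls(
            np.empty((0, 3), np.int64),
            np.empty(0, object),
            np.empty(0),
            np.empty(0),
            np.empty(0, bool),
        )

    def mask(self, shape, include_relabelled: bool = True) -> np.ndarray:
        m = np.zeros(shape, bool)
        if len(self):
            sel = np.ones(len(self), bool) if include_relabelled else ~self.relabelled
            m[tuple(self.coords[sel].T)] = True
        return m

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "i": self.coords[:, 0],
                "j": self.coords[:, 1],
                "k": self.coords[:, 2],
                "type": self.types,
                "D_WM_mm": self.d_wm,
                "D_allowed_mm": self.d_allowed,
                "relabelled": self.relabelled,
            }
        )


def detect_shock_points(
    prop: FrontPropagation,
    labels: LabelVolume,
    seed_coords: np.ndarray | None = None,
    d_min: float = DEFAULT_D_MIN_MM,
) -> ShockPointSet:
    """Bank-collision and inter-hemispheric shock voxels.

    A voxel is a bank collision when a 6-neighbour's front originated from
    a seed at least ``d_min`` mm (world distance) from this voxel's own
    seed AND the two fronts arrive from opposing directions (negative dot
    product of the voxel-to-origin directions) - the direction test
    rejects the benign origin discontinuities ("sutures") that discrete
    front propagation produces even on a convex surface.
    Inter-hemispheric shocks are CGM voxels 26-adjacent to CGM of the
    opposite hemisphere.
    """
    seed_coords = prop.seed_coords if seed_coords is None else np.asarray(seed_coords)
    seed_world = labels.voxel_to_world(seed_coords)
    origin = prop.origin_map
    shape = origin.shape
    reached = origin >= 0

    # unit flow direction: from each voxel's origin seed toward the voxel
    all_idx = np.argwhere(reached)
    all_world = labels.voxel_to_world(all_idx)
    flow = np.zeros(shape + (3,))
    vec = all_world - seed_world[origin[tuple(all_idx.T)]]
    norm = np.linalg.norm(vec, axis=1)
    norm[norm == 0] = 1.0
    flow[tuple(all_idx.T)] = vec / norm[:, None]

    shock = np.zeros(shape, bool)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, shape[axis] - 1)
        sl_b[axis] = slice(1, shape[axis])
        a = origin[tuple(sl_a)]
        b = origin[tuple(sl_b)]
        both = (a >= 0) & (b >= 0) & (a != b)
        if not both.any():
            continue
        d = np.zeros(a.shape)
        d[both] = np.linalg.norm(seed_world[a[both]] - seed_world[b[both]], axis=1)
        dots = np.einsum("...k,...k->...", flow[tuple(sl_a)], flow[tuple(sl_b)])
        far = both & (d >= d_min) & (dots < 0.0)
        pa = np.zeros(shape, bool)
        pb = np.zeros(shape, bool)
        pa[tuple(sl_a)] = far
        pb[tuple(sl_b)] = far
        shock |= pa | pb
    shock &= reached
    bank_coords = np.argwhere(shock)

    # inter-hemispheric: CGM touching CGM of the other hemisphere (26-adjacency)
    left_ids = [
        i
        for i in labels.lut.ids_for_tissue(TISSUE_CGM)
        if labels.lut.hemisphere(i) == "left"
    ]
    right_ids = [
        i
        for i in labels.lut.ids_for_tissue(TISSUE_CGM)
        if labels.lut.hemisphere(i) == "right"
    ]
    hemi_mask = np.zeros(shape, bool)
    if left_ids and right_ids:
        left = np.isin(labels.data, left_ids)
        right = np.isin(labels.data, right_ids)
        struct = np.ones((3, 3, 3), bool)
        hemi_mask = (left & ndimage.binary_dilation(right, structure=struct)) | (
            right & ndimage.binary_dilation(left, structure=struct)
        )
    hemi_mask &= ~shock
    hemi_coords = np.argwhere(hemi_mask)

    coords = np.vstack([bank_coords, hemi_coords]) if len(hemi_coords) else bank_coords
    types = np.array(
        [SHOCK_BANK] * len(bank_coords) + [SHOCK_HEMI] * len(hemi_coords), dtype=object
    )
    n = len(coords)
    return ShockPointSet(
        coords.astype(np.int64),
        types,
        np.zeros(n),
        np.full(n, np.nan),
        np.zeros(n, bool),
    )


# ---------------------------------------------------------------------------
# sulcal enhancement
# ---------------------------------------------------------------------------


def enhance_sulci(
    labels: LabelVolume,
    shocks: ShockPointSet,
    field: LaplaceField | None = None,
    r_nbhd: float = DEFAULT_NEIGHBOURHOOD_MM,
    tau: float | None = None,
    csf_id: int | None = None,
    n_passes: int = 2,
) -> tuple[LabelVolume, ShockPointSet]:
    """Thickness-constrained relabelling of shock voxels to CSF.

    For each shock voxel i still labelled CGM, D_WM,i is the streamline
    length from i down the potential gradient to the CGM-WM interface (the
    thickness it would contribute if kept).  D_allowed is the median
    thickness of valid neighbouring cortex - voxels within ``r_nbhd`` mm
    whose own streamlines avoid shock points - plus ``tau`` (default half
    the minimum voxel spacing).  The voxel becomes CSF iff
    D_WM,i > D_allowed.  The relabel -> re-solve -> re-measure cycle runs
    ``n_passes`` times (default two: one correcting pass, one verifying
    pass); non-shock voxels are never touched.
    """
    spacing = labels.spacing
    if tau is None:
        tau = 0.5 * float(spacing.min())
    if csf_id is None:
        ids = labels.lut.ids_for_tissue(TISSUE_CSF)
        if not ids:
            raise ValueError("LUT has no CSF label to relabel into")
        csf_id = ids[0]

    out = labels.data.copy()
    n = len(shocks)
    d_wm = shocks.d_wm.copy()
    d_allowed = shocks.d_allowed.copy()
    relabelled = shocks.relabelled.copy()
    if n == 0:
        return labels, shocks

    for pass_no in range(n_passes):
        lab = LabelVolume(out, labels.affine, labels.lut)
        cgm, inner, outer = ribbon_masks(lab)
        fld = field if (field is not None and pass_no == 0) else solve_laplace(
            cgm, inner, outer, spacing
        )
        active = ~relabelled
        active &= cgm[tuple(shocks.coords.T)]
        if not active.any():
            break
        avoid = shocks.mask(out.shape, include_relabelled=False)
        tmap = compute_thickness(fld, avoid=avoid)
        # thickness samples from cortex unaffected by shocks
        sample_mask = tmap.valid & ~avoid
        sample_coords = np.argwhere(sample_mask)
        if len(sample_coords) == 0:
            log.warning("sulci enhancement: no valid neighbourhood thickness anywhere")
            break
        sample_world = lab.voxel_to_world(sample_coords)
        sample_thick = tmap.thickness[tuple(sample_coords.T)]
        tree = cKDTree(sample_world)

        # D_WM for the active shock voxels: plain down-streamline (no avoid)
        tmap_raw = compute_thickness(fld, avoid=None)
        act_idx = np.where(active)[0]
        act_coords = shocks.coords[act_idx]
        dwm_vals = tmap_raw.down_mm[tuple(act_coords.T)]
        shock_world = lab.voxel_to_world(act_coords)
        changed = False
        k_fallback = min(16, len(sample_coords))
        for m, si in enumerate(act_idx):
            dwm = dwm_vals[m]
            if not np.isfinite(dwm):
                continue
            nb = tree.query_ball_point(shock_world[m], r_nbhd)
            if not nb:
                # deeply buried sulcus: no shock-free cortex within r_nbhd;
                # fall back to the nearest valid ribbon samples
                _, nb = tree.query(shock_world[m], k=k_fallback)
                nb = np.atleast_1d(nb)
            allowed = float(np.median(sample_thick[nb])) + tau
            d_wm[si] = float(dwm)
            d_allowed[si] = allowed
            if dwm > allowed:
                relabelled[si] = True
                out[tuple(shocks.coords[si])] = csf_id
                changed = True
        if not changed:
            break

    new_labels = LabelVolume(out, labels.affine, labels.lut)
    new_shocks = ShockPointSet(shocks.coords, shocks.types, d_wm, d_allowed, relabelled)
    return new_labels, new_shocks


def detect_and_enhance(
    labels: LabelVolume,
    csf_posterior: np.ndarray,
    d_min: float = DEFAULT_D_MIN_MM,
    r_nbhd: float = DEFAULT_NEIGHBOURHOOD_MM,
    tau: float | None = None,
) -> tuple[LabelVolume, ShockPointSet]:
    """Full sulci pipeline: front propagation, shock detection, enhancement."""
    cgm, inner, outer = ribbon_masks(labels)
    domain = cgm | labels.tissue_mask([TISSUE_CSF, TISSUE_BG_INTRA])
    seeds = interface_seeds(cgm, inner)
    if len(seeds) == 0:
        raise ValueError("no CGM-WM interface voxels found")
    speed = csf_speed(csf_posterior, domain)
    prop = propagate_interface(seeds, speed, domain, labels.spacing)
    shocks = detect_shock_points(prop, labels, seeds, d_min=d_min)
    return enhance_sulci(labels, shocks, r_nbhd=r_nbhd, tau=tau)
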