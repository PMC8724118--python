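"""Morphometric indices of a binary trabecular volume.

Implements the standard histomorphometric set for cubic VOIs: bone volume
fraction (BV/TV), bone surface density (BS/TV, marching-cubes triangulation),
local trabecular thickness and marrow spacing (Tb.Th., Tb.Sp.; maximal
inscribed spheres), connectivity density (Conn.D., via the Euler
characteristic) and the ellipsoid factor (EF) quantifying rod- versus
plate-likeness.  Lengths are reported in micrometres, BS/TV in 1/mm and
Conn.D. in 1/mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .stats import DescriptiveStats, describe
from .volume import BinaryVolume


# ---------------------------------------------------------------------------
# volume and surface fractions


def bone_volume_fraction(vol: BinaryVolume) -> float:
    """BV/TV: foreground voxel count over total voxel count."""
    return vol.bone_voxels / vol.grid.size


def bone_surface_mesh(vol: BinaryVolume, smoothing_sigma: float = 1.0):
    """Marching-cubes triangulation of the bone/marrow interface (voxel units).

    The binary occupancy is meshed at iso-level 0.5 after a light Gaussian
    anti-aliasing (default sigma of one voxel); the smoothing suppresses the
    staircase artifact that otherwise inflates triangulated areas of oblique
    and curved interfaces by up to ~10 %, while leaving axis-aligned planes
    untouched.  Pass ``smoothing_sigma=0`` for the raw binary mesh.  Faces
    where the structure is clipped by the VOI boundary are not generated
    (open boundary: the cubes are interior VOIs, so cut faces are not bone
    surface).  Returns ``(verts, faces)``.
    """
    if vol.bone_voxels == 0:
        raise ValueError("cannot mesh an empty foreground")
    grid = vol.grid.astype(np.float32)
    if smoothing_sigma > 0:
        grid = ndimage.gaussian_filter(grid, smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.5)
    return verts, faces


def bone_surface_density(
    vol: BinaryVolume, closed_boundary: bool = False, smoothing_sigma: float = 1.0
) -> float:
    """BS/TV in 1/mm: triangulated bone surface area over total volume.

    With ``closed_boundary=True`` the volume is zero-padded first so that
    structures cut by the VOI boundary are capped and contribute their cut
    faces to the area (the default excludes them).
    """
    if vol.bone_voxels == 0:
        warnings.warn("empty foreground: BS/TV = 0", stacklevel=2)
        return 0.0
    grid = vol.grid.astype(np.float32)
    if smoothing_sigma > 0:
        grid = ndimage.gaussian_filter(grid, smoothing_sigma)
    if closed_boundary:
        grid = np.pad(grid, 1, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.5)
    area_vox2 = measure.mesh_surface_area(verts, faces)
    area_mm2 = area_vox2 * vol.voxel_size_mm**2
    return area_mm2 / vol.total_volume_mm3


def surface_model_predict(bv_tv: float, k: float) -> float:
    """One-parameter surface-fraction model ``BS/TV = K * x * (1 - x)``.

    The form is the simplest satisfying the physical constraint that both an
    empty volume (x = 0) and a fully solid one (x = 1) expose no bone surface.
    """
    if not 0.0 <= bv_tv <= 1.0:
        raise ValueError(f"BV/TV must lie in [0, 1], got {bv_tv}")
    return k * bv_tv * (1.0 - bv_tv)


# ---------------------------------------------------------------------------
# local thickness (maximal inscribed spheres)


def local_thickness_map(vol: BinaryVolume, phase: str = "foreground") -> np.ndarray:
    """Local thickness in voxels at every voxel of the selected phase.

    Thickness at v is the diameter of the largest sphere that contains v and
    fits entirely inside the phase (sphere painting over the Euclidean
    distance transform, Hildebrand-Ruegsegger definition).  Sphere radii are
    the center-to-nearest-complement-center distances; radii are processed in
    descending 0.5-voxel bins.
    """
    if phase not in ("foreground", "background"):
        raise ValueError("phase must be 'foreground' or 'background'")
    mask = vol.grid if phase == "foreground" else ~vol.grid
    if not mask.any():
        raise ValueError(f"{phase} phase is empty")
    dt = ndimage.distance_transform_edt(mask)
    th = np.zeros(mask.shape, dtype=np.float64)
    rmax = float(dt.max())
    # descending radius bins; painting larger spheres first lets later bins
    # fill only still-unpainted voxels.  Each bin is painted by thresholding
    # the distance transform to the bin's sphere centers at the bin radius.
    edges = np.arange(0.0, rmax + 0.5, 0.5)[::-1]
    for lo in edges:
        sel = (dt > lo) & (dt <= lo + 0.5)
        if not sel.any():
            continue
        r = float(dt[sel].max())
        dist_to_centers = ndimage.distance_transform_edt(~sel)
        target = (dist_to_centers <= r) & mask & (th == 0)
        th[target] = 2.0 * r
    # voxels never covered (cannot happen: each voxel covers itself)
    th[mask & (th == 0)] = 2.0 * dt[mask & (th == 0)]
    return th


def local_thickness(
    vol: BinaryVolume, phase: str = "foreground"
) -> tuple[np.ndarray, DescriptiveStats]:
    """Thickness map (micrometres) and descriptive statistics over the phase.

    ``phase='foreground'`` yields Tb.Th., ``phase='background'`` Tb.Sp.
    """
    th_vox = local_thickness_map(vol, phase=phase)
    mask = vol.grid if phase == "foreground" else ~vol.grid
    th_um = th_vox * vol.voxel_size_um
    return th_um, describe(th_um[mask])


# ---------------------------------------------------------------------------
# connectivity


def euler_characteristic(grid: np.ndarray, connectivity: int = 26) -> int:
    """3-D Euler characteristic of the foreground voxel complex.

    ``connectivity=26`` (default) treats diagonally touching bone voxels as
    connected, the convention of trabecular analysis software; it equals the
    alternating cell count vertices - edges + faces - cubes of the closed
    union-of-cubes complex, where corner-touching cubes share a vertex.
    ``connectivity=6`` is the face-adjacency alternative.
    """
    conn = {6: 1, 26: 3}.get(connectivity)
    if conn is None:
        raise ValueError("connectivity must be 6 or 26")
    return int(measure.euler_number(grid, connectivity=conn))


def connectivity_density(vol: BinaryVolume, connectivity: int = 26) -> tuple[float, dict]:
    """Conn.D. in 1/mm^3 with a diagnostic on the one-component assumption.

    Conn.D. = (1 - chi) / TV estimates the number of independent trabecular
    connections (first Betti number) per unit volume, assuming a single
    connected component without enclosed marrow cavities.  Multi-component
    volumes can yield negative values; these are reported as computed, with
    the component count attached for auditing.
    """
    if vol.bone_voxels == 0:
        raise ValueError("connectivity density requires a nonempty foreground")
    chi = euler_characteristic(vol.grid, connectivity=connectivity)
    structure = np.ones((3, 3, 3)) if connectivity == 26 else None
    _, n_components = ndimage.label(vol.grid, structure=structure)
    conn_d = (1.0 - chi) / vol.total_volume_mm3
    return conn_d, {"euler": chi, "n_components": int(n_components)}


# ---------------------------------------------------------------------------
# ellipsoid factor


def ef_from_semiaxes(a: float, b: float, c: float) -> float:
    """EF = a/b - b/c for semi-axes sorted a <= b <= c.

    -1 is the oblate (plate) limit, +1 the prolate (rod) limit; a sphere
    (a = b = c) scores exactly 0.
    """
    a, b, c = sorted((float(a), float(b), float(c)))
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    return a / b - b / c


_SPHERE_DIRS: Optional[np.ndarray] = None


def _sphere_dirs(n: int = 146) -> np.ndarray:
    global _SPHERE_DIRS
    if _SPHERE_DIRS is None or len(_SPHERE_DIRS) != n:
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        _SPHERE_DIRS = np.stack(
            [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
        )
    return _SPHERE_DIRS


def _ellipsoid_inside(center, axes_mat, semi, mask, free_boundary=False) -> bool:
    """Check that the ellipsoid surface samples all fall on foreground voxels.

    A half-voxel margin is subtracted from the semi-axes before sampling to
    compensate the nearest-voxel rounding of the lookup, which would
    otherwise reject surface points lying inside the phase but within half a
    voxel of its boundary.  With ``free_boundary`` samples outside the volume
    are treated as bone (the structure is assumed to continue past the VOI);
    by default they count as marrow.
    """
    semi = np.maximum(semi - 0.5, 0.3)
    shape = np.asarray(mask.shape)
    for dirs in _dir_sets():
        pts = center[None, :] + (dirs * semi[None, :]) @ axes_mat.T
        idx = np.rint(pts).astype(int)
        inb = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
        if not inb.all():
            if not free_boundary:
                continue
            idx = idx[inb]
            if len(idx) == 0:
                return True
        if mask[idx[:, 0], idx[:, 1], idx[:, 2]].all():
            return True
    return False


_DIR_SETS: Optional[list] = None


def _dir_sets() -> list:
    """Three fixed rotations of the surface sample set.

    A trial passes if any rotated sample set lies fully inside: this keeps
    marginal (boundary-grazing) growth steps from stalling one axis on a
    single unlucky rounding while the symmetric partner axis continues.
    """
    global _DIR_SETS
    if _DIR_SETS is None:
        base = _sphere_dirs()
        rng = np.random.default_rng(1234)
        sets = [base]
        for _ in range(2):
            q, _r = np.linalg.qr(rng.standard_normal((3, 3)))
            sets.append(base @ q.T)
        _DIR_SETS = sets
    return _DIR_SETS


def _moment_triad(mask: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Orthonormal triad from the local second moment of the bone phase.

    Aligns ellipsoid axes with the local structure (rod axis, plate plane)
    so greedy axis growth is not handicapped by an oblique start.
    """
    r = int(np.clip(np.ceil(4 * radius), 3, 12))
    lo = np.maximum(np.rint(center).astype(int) - r, 0)
    hi = np.minimum(np.rint(center).astype(int) + r + 1, mask.shape)
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.argwhere(sub) + lo - center
    if len(pts) < 4:
        return np.eye(3)
    cov = pts.T @ pts / len(pts)
    _, vecs = np.linalg.eigh(cov)
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def _hillclimb_to_ridge(dt: np.ndarray, p: np.ndarray, max_steps: int = 200) -> np.ndarray:
    """Greedy 26-neighborhood ascent of the distance transform.

    Moves a seed onto the medial ridge so the initial inscribed sphere is
    locally maximal (seeds drawn from thin or boundary-clipped skeletons can
    otherwise start far off-axis).
    """
    p = p.copy()
    shape = dt.shape
    for _ in range(max_steps):
        z, y, x = p
        sl = dt[
            max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2
        ]
        off = np.unravel_index(np.argmax(sl), sl.shape)
        cand = np.array([max(z - 1, 0) + off[0], max(y - 1, 0) + off[1], max(x - 1, 0) + off[2]])
        if dt[tuple(cand)] <= dt[tuple(p)]:
            return p
        p = cand
    return p


@dataclass
class EllipsoidFactorResult:
    values: np.ndarray  # EF per evaluation point
    points: np.ndarray  # (n, 3) seed voxel coordinates (z, y, x)
    stats: DescriptiveStats


def ellipsoid_factor(
    vol: BinaryVolume,
    n_seeds: int = 64,
    seed: int = 0,
    n_triads: int = 4,
    n_iterations: int = 100,
    step: float = 0.5,
    boundary: str = "background",
) -> EllipsoidFactorResult:
    """Ellipsoid factor at sampled medial-skeleton points.

    At each seed point the maximal inscribed sphere (radius from the distance
    transform) is grown into an ellipsoid: semi-axes along an orthonormal
    triad are dilated greedily, keeping growth steps whose surface stays
    inside the bone phase; the largest-volume ellipsoid over the attempted
    triads (the axis-aligned triad plus ``n_triads - 1`` random ones) wins.
    EF = a/b - b/c of its sorted semi-axes, in [-1, 1].

    ``boundary`` controls how growth interacts with the VOI faces:
    ``"background"`` (default) stops ellipsoids at the volume boundary,
    ``"foreground"`` lets them continue as if the structure extended past it
    (appropriate for phantoms of notionally unbounded rods and plates).
    """
    if boundary not in ("background", "foreground"):
        raise ValueError("boundary must be 'background' or 'foreground'")
    free = boundary == "foreground"
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    mask = vol.grid
    if not mask.any():
        raise ValueError("ellipsoid factor requires a nonempty foreground")
    rng = np.random.default_rng(seed)
    dt = ndimage.distance_transform_edt(mask)
    if dt.max() <= 1.0:
        warnings.warn(
            "structure thinner than one voxel everywhere: EF evaluated on unit spheres",
            stacklevel=2,
        )
    skel = morphology.skeletonize(mask)
    pts = np.argwhere(skel if skel.any() else mask)
    take = rng.choice(len(pts), size=min(n_seeds, len(pts)), replace=False)
    pts = np.array([_hillclimb_to_ridge(dt, p) for p in pts[take]])

    values = np.empty(len(pts))
    for i, p in enumerate(pts):
        center = p.astype(float)
        r0 = max(float(dt[tuple(p)]) - 0.5, 0.5)
        best_semi = np.array([r0, r0, r0])
        best_volume = r0**3
        triads = [np.eye(3), _moment_triad(mask, center, r0)]
        for _ in range(max(n_triads - 2, 0)):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            triads.append(q)
        for axes_mat in triads:
            semi = np.array([r0, r0, r0])
            for _ in range(n_iterations):
                grew = False
                for ax in rng.permutation(3):
                    trial = semi.copy()
                    trial[ax] += step
                    if _ellipsoid_inside(center, axes_mat, trial, mask, free):
                        semi = trial
                        grew = True
                if not grew:
                    break
            v = float(np.prod(semi))
            if v > best_volume:
                best_volume, best_semi = v, semi
        values[i] = ef_from_semiaxes(*np.sort(best_semi))
    return EllipsoidFactorResult(values=values, points=pts, stats=describe(values))


# ---------------------------------------------------------------------------
# bundled result


@dataclass
class MorphometryResult:
    """Per-sample morphometric indices (Table-style units)."""

    bv_tv: float
    bs_tv: float  # 1/mm
    tb_th_um: DescriptiveStats
    tb_sp_um: DescriptiveStats
    conn_d: float  # 1/mm^3
    conn_diag: dict
    ef: Optional[DescriptiveStats] = None

    def as_record(self) -> dict:
        rec = {
            "bv_tv": self.bv_tv,
            "bs_tv": self.bs_tv,
            "tb_th_um": self.tb_th_um.mean,
            "tb_th_sd_um": self.tb_th_um.sd,
            "tb_sp_um": self.tb_sp_um.mean,
            "tb_sp_sd_um": self.tb_sp_um.sd,
            "conn_d": self.conn_d,
            "euler": self.conn_diag["euler"],
            "n_components": self.conn_diag["n_components"],
        }
        if self.ef is not None:
            rec["ef"] = self.ef.mean
            rec["ef_sd"] = self.ef.sd
        return rec


def analyze_morphometry(
    vol: BinaryVolume,
    with_ef: bool = True,
    n_ef_seeds: int = 64,
    seed: int = 0,
) -> MorphometryResult:
    """Compute the full morphometric index set for one volume."""
    vol.require_both_phases("morphometry")
    _, tb_th = local_thickness(vol, "foreground")
    _, tb_sp = local_thickness(vol, "background")
    conn_d, diag = connectivity_density(vol)
    ef = ellipsoid_factor(vol, n_seeds=n_ef_seeds, seed=seed).stats if with_ef else None
    return MorphometryResult(
        bv_tv=bone_volume_fraction(vol),
        bs_tv=bone_surface_density(vol),
        tb_th_um=tb_th,
        tb_sp_um=tb_sp,
        conn_d=conn_d,
        conn_diag=diag,
        ef=ef,
    )
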