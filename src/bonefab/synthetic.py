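"""Seeded synthetic binary volumes with known ground truth.

Two families are provided:

* analytic phantoms (``sphere``, ``slab``, ``rod_lattice``, ``parallel_plates``)
  whose morphometric and topological properties are known in closed form, and
* ``grf_trabecular``: a thresholded, anisotropically smoothed Gaussian random
  field emulating the oriented two-phase architecture of cancellous bone, with
  controllable volume fraction, principal orientation and anisotropy stretch.

All randomness flows from one explicit integer seed; there is no global
random state, and regeneration with an identical spec is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume

KINDS = ("sphere", "slab", "rod_lattice", "parallel_plates", "grf_trabecular")

_AXES = {"z": 0, "y": 1, "x": 2}


def _as_shape(shape) -> tuple[int, int, int]:
    if np.isscalar(shape):
        shape = (int(shape),) * 3
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 2:
        raise ValueError(f"shape must be 3 axes of >= 2 voxels, got {shape}")
    return shape


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction must be a nonzero vector")
    return v / n


@dataclass
class PhantomSpec:
    """Specification of one synthetic volume.

    ``params`` is kind-specific: ``radius`` (sphere); ``thickness``, ``axis``
    (slab); ``n_nodes``, ``spacing``, ``rod_radius`` (rod_lattice);
    ``thickness``, ``period``, ``axis`` (parallel_plates); ``bv_tv``,
    ``direction`` (z, y, x), ``stretch`` (three ratios >= 1, first along
    ``direction``) and ``sigma_voxels`` (grf_trabecular).
    """

    kind: str
    shape: tuple[int, int, int] | int
    voxel_size_um: float = 80.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")
        self.shape = _as_shape(self.shape)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.kind == "grf_trabecular":
            bv_tv = self.params.get("bv_tv", 0.133)
            if not 0.0 < bv_tv < 1.0:
                raise ValueError(f"target BV/TV must lie strictly in (0, 1), got {bv_tv}")
            if min(self.shape) < 16:
                raise ValueError("grf_trabecular needs >= 16 voxels per axis")
            if "direction" in self.params:
                self.params["direction"] = _unit(self.params["direction"])
            stretch = np.asarray(self.params.get("stretch", (1.0, 1.0, 1.0)), dtype=float)
            if stretch.shape != (3,) or np.any(stretch < 1.0):
                raise ValueError("stretch must be three ratios >= 1")
            self.params["stretch"] = stretch


# ---------------------------------------------------------------------------
# analytic phantoms


def _sphere(shape, params) -> np.ndarray:
    r = float(params["radius"])
    if r <= 0 or 2 * r > min(shape) - 2:
        raise ValueError(f"sphere of radius {r} does not fit inside {shape}")
    c = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    return d2 <= r * r


def _slab(shape, params) -> np.ndarray:
    t = int(params["thickness"])
    ax = _AXES[params.get("axis", "z")]
    if not 0 < t <= shape[ax]:
        raise ValueError(f"slab thickness {t} infeasible on axis of length {shape[ax]}")
    grid = np.zeros(shape, dtype=bool)
    lo = (shape[ax] - t) // 2
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, lo + t)
    grid[tuple(sl)] = True
    return grid


def _parallel_plates(shape, params) -> np.ndarray:
    t = int(params["thickness"])
    period = int(params["period"])
    ax = _AXES[params.get("axis", "z")]
    if not 0 < t < period:
        raise ValueError(f"need 0 < thickness ({t}) < period ({period})")
    coord = np.arange(shape[ax])
    mask1d = (coord % period) < t
    sl = [np.newaxis] * 3
    sl[ax] = slice(None)
    return np.broadcast_to(mask1d[tuple(sl)], shape).copy()


def _rod_lattice(shape, params) -> np.ndarray:
    n = int(params.get("n_nodes", 3))
    spacing = int(params.get("spacing", 8))
    r = float(params.get("rod_radius", 1.5))
    if n < 2:
        raise ValueError("rod_lattice needs n_nodes >= 2")
    extent = (n - 1) * spacing
    if 2 * r >= spacing:
        raise ValueError("rods merge: need rod_radius < spacing / 2")
    for ax in range(3):
        if extent + 2 * np.ceil(r) + 2 > shape[ax]:
            raise ValueError(f"lattice extent {extent} does not fit axis {ax} of {shape[ax]}")
    start = [(shape[ax] - extent) // 2 for ax in range(3)]
    nodes = [start[ax] + spacing * np.arange(n) for ax in range(3)]
    grid = np.zeros(shape, dtype=bool)
    coords = [np.arange(s, dtype=float) for s in shape]
    # rods along each axis: full lines through every perpendicular node pair
    for ax in range(3):
        p, q = [a for a in range(3) if a != ax]
        dp = coords[p][:, None] - nodes[p][None, :]
        dq = coords[q][:, None] - nodes[q][None, :]
        # in-plane mask: within radius of any node line
        plane = (
            (dp[:, None, :, None] ** 2 + dq[None, :, None, :] ** 2) <= r * r
        ).any(axis=(2, 3))
        along = (coords[ax] >= nodes[ax][0]) & (coords[ax] <= nodes[ax][-1])
        idx = [None, None, None]
        idx[ax] = slice(None)
        idx[p], idx[q] = slice(None), slice(None)
        mask = np.zeros(shape, dtype=bool)
        shp = [1, 1, 1]
        shp[ax] = shape[ax]
        along_b = along.reshape(shp)
        shp = [1, 1, 1]
        shp[p], shp[q] = shape[p], shape[q]
        plane_b = plane.reshape(shp)
        mask = along_b & plane_b
        grid |= mask
    return grid


# ---------------------------------------------------------------------------
# Gaussian-random-field trabecular emulator


def _rotation_from_z(d: np.ndarray) -> np.ndarray:
    """Proper rotation (in (z, y, x) coordinates) taking the z-axis to ``d``."""
    z = np.array([1.0, 0.0, 0.0])  # (z, y, x) ordering: first component is z
    d = _unit(d)
    c = float(np.dot(z, d))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([-1.0, 1.0, -1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _grf_trabecular(shape, voxel_size_um, seed, params) -> tuple[np.ndarray, dict]:
    bv_tv = float(params.get("bv_tv", 0.133))
    stretch = np.asarray(params.get("stretch", (1.0, 1.0, 1.0)), dtype=float)
    sigma = float(params.get("sigma_voxels", 2.0))
    direction = params.get("direction")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    # anisotropic correlation: per-axis sigma = base * stretch, principal
    # stretch along the local z-axis; periodic smoothing keeps the field
    # statistically homogeneous under the later rotation resampling
    sigmas = sigma * stretch
    fld = ndimage.gaussian_filter(noise, sigma=sigmas, mode="wrap")
    if direction is not None:
        d = _unit(direction)
        if abs(d[0]) < 1 - 1e-12:  # skip identity rotation (d == z-axis)
            rot = _rotation_from_z(d)
            center = (np.asarray(shape) - 1) / 2.0
            offset = center - rot.T @ center
            fld = ndimage.affine_transform(
                fld, rot.T, offset=offset, order=1, mode="grid-wrap"
            )
    thr = np.quantile(fld, 1.0 - bv_tv)
    grid = fld > thr
    truth = {
        "bv_tv": bv_tv,
        "direction": None if direction is None else list(map(float, _unit(direction))),
        "stretch": list(map(float, stretch)),
        "sigma_voxels": sigma,
        "seed": int(seed),
    }
    return grid, truth


# ---------------------------------------------------------------------------
# public API


def make_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Voxelize a phantom; deterministic given ``spec`` (including its seed)."""
    shape = _as_shape(spec.shape)
    meta: dict = {"phantom": spec.kind}
    if spec.kind == "sphere":
        grid = _sphere(shape, spec.params)
    elif spec.kind == "slab":
        grid = _slab(shape, spec.params)
    elif spec.kind == "parallel_plates":
        grid = _parallel_plates(shape, spec.params)
    elif spec.kind == "rod_lattice":
        grid = _rod_lattice(shape, spec.params)
    elif spec.kind == "grf_trabecular":
        grid, truth = _grf_trabecular(shape, spec.voxel_size_um, spec.seed, spec.params)
        meta["ground_truth"] = truth
    else:  # pragma: no cover - guarded in PhantomSpec
        raise ValueError(spec.kind)
    return BinaryVolume(grid=grid, voxel_size_um=spec.voxel_size_um, meta=meta)


def make_cohort(
    n: int,
    bvtv_range: tuple[float, float] = (0.082, 0.194),
    orientation_jitter_deg: float = 6.0,
    seed: int = 0,
    shape: int | tuple[int, int, int] = 64,
    voxel_size_um: float = 80.0,
    stretch_primary: tuple[float, float] = (1.8, 2.2),
    plate_fraction: float = 0.5,
) -> list[tuple[BinaryVolume, dict]]:
    """Generate a cohort of trabecular phantoms emulating a vertebral study.

    Target BV/TV values span ``bvtv_range`` (endpoints included); the
    principal trabecular direction is the z-axis tilted by a folded-normal
    angle of scale ``orientation_jitter_deg`` at uniform azimuth.  A fraction
    of samples is plate-like (two stretched axes), the rest rod-like (one).
    Returns ``(volume, ground_truth)`` pairs; reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = bvtv_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"bvtv_range must satisfy 0 < lo <= hi < 1, got {bvtv_range}")
    rng = np.random.default_rng(seed)
    targets = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    order = rng.permutation(n)
    out = []
    levels = ("L1", "L2", "L3", "L4", "L5")
    regions = ("ac", "pc", "pl", "pr")
    for i in range(n):
        bv_tv = float(targets[order[i]])
        tilt = np.deg2rad(abs(rng.normal(0.0, orientation_jitter_deg)))
        azim = rng.uniform(0, 2 * np.pi)
        # (z, y, x) components of the tilted principal direction
        d = np.array([np.cos(tilt), np.sin(tilt) * np.sin(azim), np.sin(tilt) * np.cos(azim)])
        s1 = rng.uniform(*stretch_primary)
        if rng.uniform() < plate_fraction:
            stretch = (s1, rng.uniform(0.6, 0.9) * s1, 1.0)  # plate-like: two long axes
        else:
            stretch = (s1, 1.0, 1.0)  # rod-like: one long axis
        sample_seed = int(rng.integers(0, 2**31 - 1))
        label = f"S{i:03d}"
        level = levels[(i // len(regions)) % len(levels)]
        region = regions[i % len(regions)]
        spec = PhantomSpec(
            kind="grf_trabecular",
            shape=shape,
            voxel_size_um=voxel_size_um,
            seed=sample_seed,
            params={"bv_tv": bv_tv, "direction": d, "stretch": stretch},
        )
        vol = make_phantom(spec)
        vol.label, vol.level, vol.region = label, level, region
        truth = dict(vol.meta["ground_truth"])
        truth.update(label=label, level=level, region=region, tilt_deg=float(np.rad2deg(tilt)))
        out.append((vol, truth))
    return out
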