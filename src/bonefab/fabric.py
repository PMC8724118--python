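"""Structural anisotropy by the mean-intercept-length (MIL) method.

A parallel grid of test lines is cast through the binary volume for each of
``n_directions`` directions on the unit hemisphere.  Along each line the
bone/marrow phase crossings are counted; MIL(w) = total test-line length
inside the VOI divided by the number of crossings.  Plotted as a radius, the
directional MIL traces an ellipsoid, so the values are least-squares fitted
to a positive-definite second-rank tensor M via  w' M w = 1 / MIL(w)^2.
The fabric tensor is A = M^(-1/2); its normalized eigenvalues weight the
fabric-elasticity relations and its eigenvectors give the principal
trabecular directions.  The degree of anisotropy is DA = 1 - D1/D3 with
D1 <= D2 <= D3 the eigenvalues of M.

Vectors and tensors use the array axis order (z, y, x); the z unit vector is
the slice axis (superior-inferior after endplate alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryVolume

try:  # optional JIT acceleration; the numpy path is semantically identical
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_Z = np.array([1.0, 0.0, 0.0])  # axis-0 (slice) unit vector in (z, y, x)
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# direction sets


def direction_set(n: int, seed: int = 0, method: str = "fibonacci") -> np.ndarray:
    """``n`` unit directions covering the hemisphere (MIL is antipodally even).

    ``fibonacci`` (default) is a seeded-rotation low-discrepancy lattice;
    ``random`` draws i.i.d. uniform directions.
    """
    if n < 1:
        raise ValueError("need n >= 1 directions")
    rng = np.random.default_rng(seed)
    if method == "random":
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v
    if method != "fibonacci":
        raise ValueError("method must be 'fibonacci' or 'random'")
    i = np.arange(n) + 0.5
    z = i / n  # hemisphere: cos(polar) in (0, 1)
    theta = np.pi * (1 + 5**0.5) * i
    s = np.sqrt(1 - z * z)
    dirs = np.stack([z, s * np.sin(theta), s * np.cos(theta)], axis=1)
    # seeded random rotation so different seeds sample different lattices
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return dirs @ q.T


# ---------------------------------------------------------------------------
# line casting


def _orthobasis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = direction / np.linalg.norm(direction)
    a = _Y if abs(w[0]) > 0.9 else _Z
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def count_crossings(
    grid: np.ndarray,
    origins: np.ndarray,
    direction: np.ndarray,
    t_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Crossings and in-volume sample counts for an explicit set of lines.

    Points ``p = origin + t * direction`` are sampled at the given ``t``
    values; the bone occupancy is *trilinearly interpolated* at each point
    and a crossing is a change of the thresholded phase (occupancy >= 0.5)
    between consecutive retained samples.  Interpolation matters: thresholded
    nearest-voxel lookups cross the jagged voxel boundary several times when
    a ray runs obliquely past a flat interface, which inflates crossing
    counts off the lattice axes and biases the fitted fabric toward them;
    the interpolated occupancy crosses its 0.5 level once, like the marching
    cubes iso-surface.  Samples whose interpolation support leaves the grid
    are discarded.  Returns ``(crossings_per_line, n_valid_per_line)``.
    """
    direction = np.asarray(direction, dtype=float)
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    pts = origins[:, None, :] + t_values[None, :, None] * direction[None, None, :]
    shape = np.asarray(grid.shape)
    valid = np.all((pts >= 0.0) & (pts <= (shape - 1)[None, None, :]), axis=2)
    p = np.where(valid[..., None], pts, 0.0)
    i0 = np.minimum(p.astype(np.int64), shape[None, None, :] - 2)
    f = p - i0
    g = grid.astype(np.float64)
    z0, y0, x0 = i0[..., 0], i0[..., 1], i0[..., 2]
    fz, fy, fx = f[..., 0], f[..., 1], f[..., 2]
    # nested lerp: x, then y, then z (mirrors the JIT kernel exactly)
    c00 = g[z0, y0, x0] * (1 - fx) + g[z0, y0, x0 + 1] * fx
    c01 = g[z0, y0 + 1, x0] * (1 - fx) + g[z0, y0 + 1, x0 + 1] * fx
    c10 = g[z0 + 1, y0, x0] * (1 - fx) + g[z0 + 1, y0, x0 + 1] * fx
    c11 = g[z0 + 1, y0 + 1, x0] * (1 - fx) + g[z0 + 1, y0 + 1, x0 + 1] * fx
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    vals = (c0 * (1 - fz) + c1 * fz) >= 0.5
    both = valid[:, 1:] & valid[:, :-1]
    crossings = ((vals[:, 1:] != vals[:, :-1]) & both).sum(axis=1)
    return crossings, valid.sum(axis=1)


if _numba is not None:

    @_numba.njit(cache=False, fastmath=False)
    def _crossings_kernel(grid, origins, direction, t0, dt, nt):  # pragma: no cover
        nz, ny, nx = grid.shape
        total_cross = 0
        total_valid = 0
        for li in range(origins.shape[0]):
            oz, oy, ox = origins[li, 0], origins[li, 1], origins[li, 2]
            prev = -1
            for k in range(nt):
                t = t0 + k * dt
                pz = oz + t * direction[0]
                py = oy + t * direction[1]
                px = ox + t * direction[2]
                if 0.0 <= pz <= nz - 1 and 0.0 <= py <= ny - 1 and 0.0 <= px <= nx - 1:
                    z0 = min(int(pz), nz - 2)
                    y0 = min(int(py), ny - 2)
                    x0 = min(int(px), nx - 2)
                    fz = pz - z0
                    fy = py - y0
                    fx = px - x0
                    c00 = grid[z0, y0, x0] * (1 - fx) + grid[z0, y0, x0 + 1] * fx
                    c01 = grid[z0, y0 + 1, x0] * (1 - fx) + grid[z0, y0 + 1, x0 + 1] * fx
                    c10 = grid[z0 + 1, y0, x0] * (1 - fx) + grid[z0 + 1, y0, x0 + 1] * fx
                    c11 = grid[z0 + 1, y0 + 1, x0] * (1 - fx) + grid[z0 + 1, y0 + 1, x0 + 1] * fx
                    c0 = c00 * (1 - fy) + c01 * fy
                    c1 = c10 * (1 - fy) + c11 * fy
                    val = 1 if c0 * (1 - fz) + c1 * fz >= 0.5 else 0
                    total_valid += 1
                    if prev >= 0 and val != prev:
                        total_cross += 1
                    prev = val
                else:
                    prev = -1  # leaving the box breaks the sample run
        return total_cross, total_valid


def _direction_totals(grid_u8, origins, direction, t_values) -> tuple[int, int]:
    """Total crossings and in-volume samples over a line bundle (fast path)."""
    if _numba is not None and len(t_values) > 1:
        return _crossings_kernel(
            grid_u8,
            np.ascontiguousarray(origins),
            np.ascontiguousarray(direction),
            float(t_values[0]),
            float(t_values[1] - t_values[0]),
            len(t_values),
        )
    cr, nv = count_crossings(grid_u8.astype(bool), origins, direction, t_values)
    return int(cr.sum()), int(nv.sum())


@dataclass
class MILSet:
    """Directional mean intercept lengths retained for the tensor fit."""

    directions: np.ndarray  # (n, 3) unit vectors, (z, y, x) components
    mil_mm: np.ndarray  # (n,)
    total_intercepts: np.ndarray  # crossings per direction
    total_length_mm: np.ndarray  # in-volume test line length per direction
    line_spacing_voxels: float
    step_voxels: float
    n_dropped: int = 0  # directions discarded for zero crossings

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("MIL directions must be unit vectors")
        if np.any(self.mil_mm <= 0):
            raise ValueError("retained MIL values must be positive")

    def __len__(self) -> int:
        return len(self.directions)


def sample_mil(
    vol: BinaryVolume,
    n_directions: int = 5000,
    line_spacing: float = 1.0,
    seed: int = 0,
    step: float = 0.5,
    method: str = "fibonacci",
) -> MILSet:
    """Measure MIL in ``n_directions`` directions over the hemisphere.

    For every direction a parallel grid of lines with in-plane spacing
    ``line_spacing`` voxels (origin dithered from the seed) is clipped to the
    volume and sampled at ``step``-voxel increments; MIL is the crossings
    normalization total-length / phase-crossings, converted to millimetres.
    Directions whose lines record no crossing are dropped and counted.
    """
    vol.require_both_phases("MIL sampling")
    if n_directions < 9:
        raise ValueError("need at least 9 directions to constrain a symmetric tensor")
    if line_spacing <= 0 or step <= 0:
        raise ValueError("line_spacing and step must be positive")
    grid = vol.grid
    shape = np.asarray(grid.shape, dtype=float)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape) / 2.0)
    dirs = direction_set(n_directions, seed=seed, method=method)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    t_values = np.arange(-radius, radius + step, step)
    n_off = int(np.floor(radius / line_spacing))
    base_offsets = np.arange(-n_off, n_off + 1, dtype=float)

    kept_dirs, mils, crossings_out, lengths = [], [], [], []
    n_dropped = 0
    vox_mm = vol.voxel_size_mm
    grid_u8 = np.ascontiguousarray(grid.astype(np.uint8))
    for w in dirs:
        u, v = _orthobasis(w)
        da, db = rng.uniform(-0.5, 0.5, size=2)
        a = (base_offsets + da) * line_spacing
        b = (base_offsets + db) * line_spacing
        aa, bb = np.meshgrid(a, b, indexing="ij")
        origins = center[None, :] + aa.reshape(-1, 1) * u + bb.reshape(-1, 1) * v
        # keep only lines whose closest approach can hit the bounding sphere
        r2 = aa.reshape(-1) ** 2 + bb.reshape(-1) ** 2
        origins = origins[r2 <= radius * radius]
        c_tot, n_valid = _direction_totals(grid_u8, origins, w, t_values)
        l_tot = float(n_valid) * step
        if c_tot == 0:
            n_dropped += 1
            continue
        kept_dirs.append(w)
        crossings_out.append(c_tot)
        lengths.append(l_tot * vox_mm)
        mils.append(l_tot * vox_mm / c_tot)
    if len(kept_dirs) < 9:
        raise ValueError(
            f"only {len(kept_dirs)} usable directions after dropping zero-crossing ones; "
            "volume may be (nearly) single-phase"
        )
    return MILSet(
        directions=np.asarray(kept_dirs),
        mil_mm=np.asarray(mils),
        total_intercepts=np.asarray(crossings_out),
        total_length_mm=np.asarray(lengths),
        line_spacing_voxels=line_spacing,
        step_voxels=step,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# tensor fit and eigen-analysis


@dataclass
class MaterialAnisotropyTensor:
    """Symmetric positive-definite MIL ellipsoid tensor M with eigen-system."""

    m: np.ndarray  # (3, 3), symmetric
    eigenvalues: np.ndarray  # ascending D1 <= D2 <= D3
    eigenvectors: np.ndarray  # columns matching eigenvalues

    def __post_init__(self) -> None:
        if not np.allclose(self.m, self.m.T):
            raise ValueError("M must be symmetric")
        if np.any(self.eigenvalues <= 0):
            raise ValueError(
                "MIL tensor is not positive definite; use more directions or a larger volume"
            )


def fit_anisotropy_tensor(mil: MILSet) -> MaterialAnisotropyTensor:
    """Least-squares fit of ``w' M w = 1 / MIL(w)^2`` over all directions."""
    w = mil.directions
    if len(w) < 9:
        raise ValueError("need at least 9 usable directions")
    y = 1.0 / mil.mil_mm**2
    design = np.column_stack(
        [
            w[:, 0] ** 2,
            w[:, 1] ** 2,
            w[:, 2] ** 2,
            2 * w[:, 0] * w[:, 1],
            2 * w[:, 0] * w[:, 2],
            2 * w[:, 1] * w[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    m = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    evals, evecs = np.linalg.eigh(m)
    return MaterialAnisotropyTensor(m=m, eigenvalues=evals, eigenvectors=evecs)


def degree_of_anisotropy(t: MaterialAnisotropyTensor) -> float:
    """DA = 1 - D1/D3 in [0, 1): 0 isotropic, -> 1 fully oriented."""
    d1, d3 = float(t.eigenvalues[0]), float(t.eigenvalues[-1])
    return 1.0 - d1 / d3


@dataclass
class FabricResult:
    """Fabric tensor A = M^(-1/2) with eigen-system, DA and orientation angles."""

    a: np.ndarray  # (3, 3) fabric tensor
    a_eigenvalues: np.ndarray  # descending A11 > A22 > A33
    eigenvectors: np.ndarray  # columns e1, e2, e3 matching a_eigenvalues
    lam: np.ndarray  # normalized eigenvalues, sum exactly 1
    da: float
    m_eigenvalues: np.ndarray  # ascending D1 <= D2 <= D3 of M
    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (alpha, beta, gamma)
    degenerate: bool = False
    n_directions_used: int = 0
    n_dropped: int = 0
    extras: dict = field(default_factory=dict)

    def as_record(self) -> dict:
        return {
            "da": self.da,
            "d1": float(self.m_eigenvalues[0]),
            "d2": float(self.m_eigenvalues[1]),
            "d3": float(self.m_eigenvalues[2]),
            "lambda1": float(self.lam[0]),
            "lambda2": float(self.lam[1]),
            "lambda3": float(self.lam[2]),
            "alpha_deg": self.angles_deg[0],
            "beta_deg": self.angles_deg[1],
            "gamma_deg": self.angles_deg[2],
            "n_mil_directions": self.n_directions_used,
            "n_mil_dropped": self.n_dropped,
        }


def fabric_from_anisotropy(t: MaterialAnisotropyTensor) -> FabricResult:
    """Fabric tensor A = M^(-1/2), normalized eigenvalues and DA.

    A shares eigenvectors with M; its eigenvalues are D_i^(-1/2), sorted
    descending (the ellipsoid radii: the largest fabric eigenvalue marks the
    principal trabecular direction).  lambda_i = A_ii / (A11 + A22 + A33)
    sums to one by construction.  On near-degenerate eigenvalues (relative
    gap < 1e-6) eigenvectors are ordered to maximize |e . z| then |e . y|,
    and the result is flagged.
    """
    d = t.eigenvalues
    a_vals = d**-0.5  # ascending d -> descending A
    vecs = t.eigenvectors.copy()
    degenerate = False
    span = float(a_vals.max())
    i = 0
    order = np.arange(3)
    while i < 2:
        j = i
        while j < 2 and abs(a_vals[order[j]] - a_vals[order[j + 1]]) < 1e-6 * span:
            j += 1
        if j > i:
            degenerate = True
            block = order[i : j + 1]
            key = sorted(
                block,
                key=lambda k: (abs(vecs[0, k]), abs(vecs[1, k])),
                reverse=True,
            )
            order[i : j + 1] = key
        i = j + 1
    a_vals = a_vals[order]
    vecs = vecs[:, order]
    # canonical sign: principal component of each eigenvector positive
    for k in range(3):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    a = (vecs * a_vals[None, :]) @ vecs.T
    lam = a_vals / a_vals.sum()
    fr = FabricResult(
        a=a,
        a_eigenvalues=a_vals,
        eigenvectors=vecs,
        lam=lam,
        da=degree_of_anisotropy(t),
        m_eigenvalues=d.copy(),
        degenerate=degenerate,
    )
    fr.angles_deg = orientation_angles(fr)
    return fr


def orientation_angles(f: FabricResult) -> tuple[float, float, float]:
    """Direction-cosine angles (alpha, beta, gamma) of the principal axis.

    gamma is the angle between e1 (eigenvector of the largest fabric
    eigenvalue, i.e. the principal trabecular direction) and the z axis,
    folded into [0, 90] degrees; alpha and beta are measured against x and y.
    """
    e1 = f.eigenvectors[:, 0]
    def ang(axis):
        return float(np.degrees(np.arccos(np.clip(abs(np.dot(e1, axis)), 0.0, 1.0))))
    return (ang(_X), ang(_Y), ang(_Z))


def measure_fabric(
    vol: BinaryVolume,
    n_directions: int = 5000,
    line_spacing: float = 1.0,
    seed: int = 0,
    step: float = 0.5,
    method: str = "fibonacci",
) -> FabricResult:
    """MIL sampling, tensor fit and fabric eigen-analysis in one call."""
    mil = sample_mil(
        vol,
        n_directions=n_directions,
        line_spacing=line_spacing,
        seed=seed,
        step=step,
        method=method,
    )
    t = fit_anisotropy_tensor(mil)
    fr = fabric_from_anisotropy(t)
    fr.n_directions_used = len(mil)
    fr.n_dropped = mil.n_dropped
    return fr
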