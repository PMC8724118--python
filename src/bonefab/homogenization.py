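"""Fabric-elasticity homogenization: (normalized fabric eigenvalues, BV/TV)
to an orthotropic stiffness tensor, plus the engineering-constant extraction.

The orthotropic elastic constants in the fabric eigenbasis are

    c_iiii = Et [k1 + 2 k6 + (k2 + 2 k7) II + 2 (k3 + 2 k8) li
             + (2 k4 + k5 + 4 k9) li^2]
    c_iijj = Et [k1 + k2 II + k3 (li + lj) + k4 (li^2 + lj^2) + k5 li lj]
    c_ijij = Et [k6 + k7 II + k8 (li + lj) + k9 (li^2 + lj^2)]

with ``II = l1 l2 + l1 l3 + l2 l3`` over the normalized fabric eigenvalues
``l`` (sum 1) and nine scalar functions of volume fraction

    k_i = k_ia + k_ib (BV/TV)^p .

Two constants profiles ship as JSON configuration (never hard-coded):

* ``"printed"`` -- the literature table as printed.  Note: an independent
  evaluation shows this set yields a non-positive-definite stiffness across
  the whole physiological (BV/TV, l) domain; use
  :func:`audit_positive_definiteness` to reproduce that finding.
* ``"calibrated"`` -- same k_a column and exponent, with the k_b column
  recalibrated so the model reproduces the reported cohort-mean orthotropic
  constants at the cohort-mean volume fraction and fabric (see
  :func:`calibrate_kb_from_mean_constants` and docs/methods.md).  This is the
  profile that yields physically valid stiffness over the observed domain.

Voigt order is (11, 22, 33, 23, 13, 12) with the engineering shear
convention in the compliance, so G_i = 1/S_ii holds literally; tensor shear
convention is used internally for rotations and the directional modulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

_VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))


# ---------------------------------------------------------------------------
# constants profiles


@dataclass
class KabelConstants:
    """The 18 fit constants, exponent p and tissue modulus Et (GPa)."""

    k_a: np.ndarray  # (9,)
    k_b: np.ndarray  # (9,)
    p: float = 1.6
    tissue_modulus_gpa: float = 15.0
    name: str = "custom"

    def __post_init__(self) -> None:
        self.k_a = np.asarray(self.k_a, dtype=float)
        self.k_b = np.asarray(self.k_b, dtype=float)
        if self.k_a.shape != (9,) or self.k_b.shape != (9,):
            raise ValueError("k_a and k_b must each hold nine constants")
        if not self.p > 0:
            raise ValueError("exponent p must be > 0")
        if not self.tissue_modulus_gpa > 0:
            raise ValueError("tissue modulus must be > 0")

    @classmethod
    def from_json(cls, path) -> "KabelConstants":
        d = json.loads(Path(path).read_text())
        return cls(
            k_a=d["k_a"],
            k_b=d["k_b"],
            p=d.get("p", 1.6),
            tissue_modulus_gpa=d.get("Et_GPa", 15.0),
            name=d.get("name", Path(path).stem),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "k_a": self.k_a.tolist(),
                    "k_b": self.k_b.tolist(),
                    "p": self.p,
                    "Et_GPa": self.tissue_modulus_gpa,
                },
                indent=2,
            )
        )

    @classmethod
    def profile(cls, name: str = "printed") -> "KabelConstants":
        """Load a shipped constants profile (``printed`` or ``calibrated``)."""
        ref = resources.files("bonefab.data").joinpath(f"kabel_{name}.json")
        with resources.as_file(ref) as path:
            return cls.from_json(path)


def k_functions(bv_tv: float, constants: KabelConstants) -> np.ndarray:
    """The nine volume-fraction functions ``k_i = k_ia + k_ib (BV/TV)^p``."""
    if not 0.0 <= bv_tv <= 1.0:
        raise ValueError(f"BV/TV must lie in [0, 1], got {bv_tv}")
    return constants.k_a + constants.k_b * bv_tv**constants.p


# ---------------------------------------------------------------------------
# stiffness assembly


@dataclass
class OrthotropicElasticity:
    """6x6 orthotropic stiffness in the fabric eigenbasis, with derived
    compliance and engineering constants once :func:`engineering_constants`
    has completed it.  Axis order is (x', y', z') = Voigt indices (1, 2, 3).
    """

    c_voigt: np.ndarray  # (6, 6) stiffness, GPa
    tissue_modulus_gpa: float
    lam: np.ndarray  # normalized fabric eigenvalues per axis (x', y', z')
    bv_tv: float
    valid: bool  # positive definiteness of the stiffness
    eigen_spectrum: np.ndarray  # eigenvalues of c_voigt (diagnostic)
    s_voigt: Optional[np.ndarray] = None  # (6, 6) compliance, 1/GPa
    E: Optional[np.ndarray] = None  # (E_x', E_y', E_z'), GPa
    G: Optional[np.ndarray] = None  # (G_y'z', G_x'z', G_x'y'), GPa
    nu: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def c_normalized(self) -> np.ndarray:
        """Stiffness in units of the tissue modulus Et."""
        return self.c_voigt / self.tissue_modulus_gpa

    def as_record(self) -> dict:
        et = self.tissue_modulus_gpa
        rec = {"stiffness_valid": self.valid, "bv_tv_used": self.bv_tv}
        if self.E is not None:
            for name, val in zip(("E_x", "E_y", "E_z"), self.E):
                rec[f"{name}_gpa"] = float(val)
                rec[f"{name}_over_Et"] = float(val / et)
            for name, val in zip(("G_yz", "G_xz", "G_xy"), self.G):
                rec[f"{name}_gpa"] = float(val)
                rec[f"{name}_over_Et"] = float(val / et)
            rec.update({f"nu_{k}": float(v) for k, v in self.nu.items()})
        return rec


def assemble_stiffness(
    lam: Sequence[float],
    bv_tv: float,
    constants: Optional[KabelConstants] = None,
    order_by_stiffness: bool = True,
) -> OrthotropicElasticity:
    """Assemble the orthotropic stiffness from fabric eigenvalues and BV/TV.

    ``lam`` are the three normalized fabric eigenvalues (sum 1, each > 0).
    With ``order_by_stiffness`` (default) the axes are permuted so that the
    axial Young's moduli satisfy E_x' <= E_y' <= E_z', i.e. z' is the stiff
    principal trabecular axis as conventionally reported; the returned
    ``lam`` field records the permuted assignment.  A non-positive-definite
    result is returned with ``valid=False`` and a structured warning -- never
    silently clipped -- so cohort runs can complete and report offenders.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (3,):
        raise ValueError("lam must hold three eigenvalues")
    if abs(lam.sum() - 1.0) > 1e-9:
        raise ValueError(f"normalized eigenvalues must sum to 1, got {lam.sum()!r}")
    if np.any(lam <= 0):
        raise ValueError("each normalized eigenvalue must be > 0")
    if constants is None:
        constants = KabelConstants.profile("printed")
    k = k_functions(bv_tv, constants)
    et = constants.tissue_modulus_gpa

    def build(lmb: np.ndarray) -> np.ndarray:
        ii = lmb[0] * lmb[1] + lmb[0] * lmb[2] + lmb[1] * lmb[2]
        c = np.zeros((6, 6))
        for i in range(3):
            li = lmb[i]
            c[i, i] = et * (
                k[0]
                + 2 * k[5]
                + (k[1] + 2 * k[6]) * ii
                + 2 * (k[2] + 2 * k[7]) * li
                + (2 * k[3] + k[4] + 4 * k[8]) * li**2
            )
        for i, j in ((0, 1), (0, 2), (1, 2)):
            li, lj = lmb[i], lmb[j]
            c[i, j] = c[j, i] = et * (
                k[0] + k[1] * ii + k[2] * (li + lj) + k[3] * (li**2 + lj**2) + k[4] * li * lj
            )
        for v, (i, j) in zip((3, 4, 5), ((1, 2), (0, 2), (0, 1))):
            li, lj = lmb[i], lmb[j]
            c[v, v] = et * (k[5] + k[6] * ii + k[7] * (li + lj) + k[8] * (li**2 + lj**2))
        return c

    order = np.arange(3)
    c = build(lam)
    if order_by_stiffness:
        # rank axes by compliance-derived axial moduli where possible,
        # falling back to the diagonal stiffness for invalid tensors
        try:
            s = np.linalg.inv(c)
            e_axial = 1.0 / np.diag(s)[:3]
        except np.linalg.LinAlgError:
            e_axial = np.diag(c)[:3]
        order = np.argsort(e_axial)
        lam = lam[order]
        c = build(lam)

    spectrum = np.linalg.eigvalsh(c)
    valid = bool(spectrum[0] > 1e-9 * max(abs(spectrum[-1]), 1.0))
    result = OrthotropicElasticity(
        c_voigt=c,
        tissue_modulus_gpa=et,
        lam=lam,
        bv_tv=float(bv_tv),
        valid=valid,
        eigen_spectrum=spectrum,
    )
    if not valid:
        result.warnings.append(
            {
                "kind": "non_positive_definite_stiffness",
                "constants_profile": constants.name,
                "bv_tv": float(bv_tv),
                "lam": lam.tolist(),
                "spectrum": spectrum.tolist(),
            }
        )
    return result


_NU_KEYS = ("yz", "xz", "xy", "zy", "zx", "yx")
_NU_INDEX = {"yz": (1, 2), "xz": (0, 2), "xy": (0, 1), "zy": (2, 1), "zx": (2, 0), "yx": (1, 0)}


def engineering_constants(e: OrthotropicElasticity) -> OrthotropicElasticity:
    """Complete an elasticity with S = C^-1 and the nine engineering constants.

    Uses the engineering shear convention so E_i = 1/S_ii (i = 1..3) and
    G_i = 1/S_ii (i = 4..6) hold literally; nu_ij = -S_ij / S_ii.  The three
    dependent Poisson ratios satisfy the compliance-symmetry reciprocity
    nu_ij / E_i = nu_ji / E_j.
    """
    if not e.valid:
        raise ValueError(
            "stiffness is not positive definite; eigenvalue spectrum: "
            f"{e.eigen_spectrum.tolist()}"
        )
    s = np.linalg.inv(e.c_voigt)
    e.s_voigt = s
    e.E = 1.0 / np.diag(s)[:3]
    e.G = 1.0 / np.diag(s)[3:]
    e.nu = {key: float(-s[i, j] / s[i, i]) for key, (i, j) in _NU_INDEX.items()}
    return e


# ---------------------------------------------------------------------------
# fourth-rank conversions, rotation, directional modulus


def stiffness_voigt_to_tensor(c_voigt: np.ndarray) -> np.ndarray:
    """Expand a 6x6 Voigt stiffness to the full (3,3,3,3) tensor."""
    c = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            v = c_voigt[a, b]
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    c[ii, jj, kk, ll] = v
    return c


def stiffness_tensor_to_voigt(c: np.ndarray) -> np.ndarray:
    out = np.zeros((6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            out[a, b] = c[i, j, k, l]
    return out


def compliance_voigt_to_tensor(s_voigt: np.ndarray) -> np.ndarray:
    """Expand an engineering-convention 6x6 compliance to the full tensor.

    Tensor components carry factors 1, 1/2, 1/4 for zero, one and two shear
    Voigt indices respectively.
    """
    s = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        fa = 1.0 if a < 3 else 0.5
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            fb = 1.0 if b < 3 else 0.5
            v = s_voigt[a, b] * fa * fb
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    s[ii, jj, kk, ll] = v
    return s


def rotate_stiffness(c_voigt: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness by a proper rotation matrix (fourth-rank rule)."""
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    if np.linalg.det(r) < 0:
        r = r.copy()
        r[:, 2] = -r[:, 2]  # sign-fix an improper eigenvector set
    c = stiffness_voigt_to_tensor(c_voigt)
    c_rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", r, r, r, r, c, optimize=True)
    return stiffness_tensor_to_voigt(c_rot)


def rotate_to_global(e: OrthotropicElasticity, eigvecs: np.ndarray) -> np.ndarray:
    """Stiffness in the volume axes, given the fabric eigenvector columns."""
    return rotate_stiffness(e.c_voigt, eigvecs)


def directional_modulus(e: OrthotropicElasticity, n: Sequence[float]) -> float:
    """Young's modulus for a uniaxial test along unit direction ``n``.

    ``E(n) = 1 / (n_i n_j n_k n_l S_ijkl)`` with the full fourth-rank
    compliance (tensor shear convention); at a principal axis this reduces
    exactly to the axial engineering modulus.  ``n`` is given in the frame
    the elasticity lives in -- components (x', y', z') for a tensor in the
    fabric eigenbasis.
    """
    if e.s_voigt is None:
        engineering_constants(e)
    n = np.asarray(n, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    n = n / norm
    s = compliance_voigt_to_tensor(e.s_voigt)
    denom = float(np.einsum("i,j,k,l,ijkl->", n, n, n, n, s))
    return 1.0 / denom


def modulus_surface(e: OrthotropicElasticity, n_points: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Sample the directional Young's modulus over a spherical point set.

    Returns ``(directions, E_values)`` -- the raw data of the familiar
    three-lobed stiffness surface rendering.
    """
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * i / n_points)
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )
    if e.s_voigt is None:
        engineering_constants(e)
    s = compliance_voigt_to_tensor(e.s_voigt)
    denom = np.einsum("pi,pj,pk,pl,ijkl->p", dirs, dirs, dirs, dirs, s, optimize=True)
    return dirs, 1.0 / denom


# ---------------------------------------------------------------------------
# audit and calibration


def audit_positive_definiteness(
    constants: KabelConstants,
    bv_tv_values: Sequence[float] = tuple(np.linspace(0.082, 0.194, 15)),
    lam_sets: Optional[Sequence[Sequence[float]]] = None,
) -> dict:
    """Survey stiffness positive definiteness over a (BV/TV, lambda) domain.

    The default domain is the observed cohort range of volume fractions
    crossed with fabric eigenvalue triples from near-isotropy to strong
    anisotropy.  Returns counts, the valid fraction and example offenders.
    This is a report, not a gate: some printed constants tables fail it
    everywhere (see module docstring).
    """
    if lam_sets is None:
        lam_sets = []
        for l1 in np.linspace(0.34, 0.46, 7):
            for l2 in np.linspace(0.27, min(0.40, l1), 5):
                l3 = 1.0 - l1 - l2
                if 0.15 < l3 <= l2 <= l1:
                    lam_sets.append((l1, l2, l3))
    n_total = n_valid = 0
    offenders = []
    records = []
    for bv in bv_tv_values:
        for lam in lam_sets:
            e = assemble_stiffness(lam, bv, constants, order_by_stiffness=False)
            n_total += 1
            if e.valid:
                n_valid += 1
            elif len(offenders) < 5:
                offenders.append({"bv_tv": float(bv), "lam": list(map(float, lam))})
            records.append((float(bv), tuple(map(float, lam)), e.valid))
    return {
        "constants_profile": constants.name,
        "n_total": n_total,
        "n_valid": n_valid,
        "valid_fraction": n_valid / n_total if n_total else float("nan"),
        "example_offenders": offenders,
    }


def calibrate_kb_from_mean_constants(
    e_over_et: Sequence[float],
    g_over_et: Sequence[float],
    nu: Sequence[float],
    lam: Sequence[float],
    bv_tv: float,
    base: Optional[KabelConstants] = None,
    name: str = "calibrated",
) -> KabelConstants:
    """Re-derive the k_b column from nine target mean engineering constants.

    Builds the orthotropic compliance from ``(E_x, E_y, E_z)/Et``,
    ``(G_yz, G_xz, G_xy)/Et`` and ``(nu_yz, nu_xz, nu_xy)``, inverts it to a
    target stiffness, and solves the (linear) nine-equation system for the
    nine ``k_i`` at the given mean fabric ``lam`` and mean ``bv_tv``; the
    ``k_a`` column and exponent of ``base`` are retained and
    ``k_b = (k - k_a) / (BV/TV)^p``.  ``lam`` is given in axis order
    (x', y', z').
    """
    if base is None:
        base = KabelConstants.profile("printed")
    lam = np.asarray(lam, dtype=float)
    ex, ey, ez = e_over_et
    gyz, gxz, gxy = g_over_et
    nyz, nxz, nxy = nu
    s = np.zeros((6, 6))
    s[0, 0], s[1, 1], s[2, 2] = 1 / ex, 1 / ey, 1 / ez
    s[0, 1] = s[1, 0] = -nxy / ex
    s[0, 2] = s[2, 0] = -nxz / ex
    s[1, 2] = s[2, 1] = -nyz / ey
    s[3, 3], s[4, 4], s[5, 5] = 1 / gyz, 1 / gxz, 1 / gxy
    c_target = np.linalg.inv(s)  # in units of Et

    ii = lam[0] * lam[1] + lam[0] * lam[2] + lam[1] * lam[2]
    rows, rhs = [], []
    for i in range(3):  # c_iiii
        li = lam[i]
        rows.append([1, ii, 2 * li, 2 * li**2, li**2, 2, 2 * ii, 4 * li, 4 * li**2])
        rhs.append(c_target[i, i])
    for i, j in ((0, 1), (0, 2), (1, 2)):  # c_iijj
        li, lj = lam[i], lam[j]
        rows.append([1, ii, li + lj, li**2 + lj**2, li * lj, 0, 0, 0, 0])
        rhs.append(c_target[i, j])
    for v, (i, j) in zip((3, 4, 5), ((1, 2), (0, 2), (0, 1))):  # c_ijij
        li, lj = lam[i], lam[j]
        rows.append([0, 0, 0, 0, 0, 1, ii, li + lj, li**2 + lj**2])
        rhs.append(c_target[v, v])
    # with only three distinct eigenvalues the system has a one-dimensional
    # null space; the minimum-norm solution reproduces the targets exactly
    k, *_ = np.linalg.lstsq(np.asarray(rows, dtype=float), np.asarray(rhs, dtype=float), rcond=None)
    f = bv_tv**base.p
    k_b = (k - base.k_a) / f
    return KabelConstants(
        k_a=base.k_a.copy(),
        k_b=k_b,
        p=base.p,
        tissue_modulus_gpa=base.tissue_modulus_gpa,
        name=name,
    )
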