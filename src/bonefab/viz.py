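"""Optional figures and mesh exports (matplotlib is imported lazily)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .homogenization import OrthotropicElasticity, modulus_surface
from .pipeline import MODULUS_COLUMNS, CohortResult


def plot_surface_model_fit(result: CohortResult, path) -> Path:
    """BS/TV against BV/TV with the fitted one-parameter model curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["bv_tv"], table["bs_tv"], s=18, color="k")
    if result.surface_model:
        k = result.surface_model["K"]
        x = np.linspace(0, table["bv_tv"].max() * 1.15, 200)
        ax.plot(x, k * x * (1 - x), "--", color="tab:blue",
                label=f"K x(1-x), K = {k:.2f}, R$^2$ = {result.surface_model['r_squared']:.3f}")
        ax.legend(frameon=False)
    ax.set_xlabel("BV/TV (-)")
    ax.set_ylabel("BS/TV (1/mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_modulus_power_laws(result: CohortResult, path) -> Path:
    """Young's and shear moduli against BV/TV with fitted power laws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = np.linspace(table["bv_tv"].min() * 0.9, table["bv_tv"].max() * 1.05, 200)
    for col in MODULUS_COLUMNS:
        if col not in table.columns:
            continue
        label = col.replace("_gpa", "").replace("_", " ")
        pts = ax.scatter(table["bv_tv"], table[col], s=12, label=label)
        fit = result.power_law_fits.get(col)
        if fit:
            ax.plot(x, fit["a"] * x ** fit["b"], "--", lw=1, color=pts.get_facecolor()[0])
    ax.set_xlabel("BV/TV (-)")
    ax.set_ylabel("modulus (GPa)")
    ax.legend(frameon=False, fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def export_modulus_surface_obj(e: OrthotropicElasticity, path, n_points: int = 2000) -> Path:
    """Directional Young's modulus surface as a Wavefront OBJ point/face set.

    The radius in each direction equals E(n); a convex-hull triangulation
    gives the familiar stiffness-surface rendering.
    """
    from scipy.spatial import ConvexHull

    dirs, vals = modulus_surface(e, n_points=n_points)
    pts = dirs * vals[:, None]
    hull = ConvexHull(dirs)  # triangulate on the unit sphere topology
    lines = [f"v {p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in pts]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in hull.simplices]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def export_fabric_ellipsoid_obj(fabric, path, n_points: int = 1000) -> Path:
    """MIL ellipsoid of a fabric result as a Wavefront OBJ mesh.

    Radii are the fabric eigenvalues (the MIL extremes) along the fabric
    eigenvectors -- the graphical-abstract-style anisotropy glyph.
    """
    from scipy.spatial import ConvexHull

    i = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * i / n_points)
    theta = np.pi * (1 + 5**0.5) * i
    sphere = np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )
    pts = (sphere * fabric.a_eigenvalues[None, :]) @ fabric.eigenvectors.T
    hull = ConvexHull(sphere)
    lines = [f"v {p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in pts]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in hull.simplices]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
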