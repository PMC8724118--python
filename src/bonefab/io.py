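"""Volume I/O, isodata binarization, cubic VOI cropping and voxel-size degradation.

TIFF is the native interchange format: either a directory of equally sized 2-D
slices (ordered by natural filename sort) or a single multi-page TIFF.  Binary
volumes are written as 8-bit pages (0 = marrow, 255 = bone) with a JSON
sidecar recording the voxel size and sample tags.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from skimage.filters import threshold_isodata

from .volume import BinaryVolume, GrayVolume

PathLike = Union[str, Path]


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def read_stack(path: PathLike, voxel_size_um: float, label: str | None = None) -> GrayVolume:
    """Read a slice directory or a multi-page TIFF into a grayscale volume.

    Slices in a directory are stacked in natural sort order of their file
    names; integer intensities are preserved.  All slices must share one shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise IOError(f"no TIFF slices found in directory {path}")
        slices = []
        shape0 = None
        for f in files:
            img = tifffile.imread(f)
            if img.ndim != 2:
                raise IOError(f"slice {f.name} is not a 2-D image (shape {img.shape})")
            if shape0 is None:
                shape0 = img.shape
            elif img.shape != shape0:
                raise IOError(
                    f"slice {f.name} has shape {img.shape}, expected {shape0} "
                    f"(all slices in a stack must match)"
                )
            slices.append(img)
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            raise IOError(f"{path} holds a single 2-D page; a volume needs >= 2 slices")
        if data.ndim != 3:
            raise IOError(f"{path} is not a 3-D stack (shape {data.shape})")
    return GrayVolume(data=data, voxel_size_um=voxel_size_um, label=label)


def write_volume(vol: BinaryVolume, path: PathLike, ground_truth: dict | None = None) -> Path:
    """Write a binary volume as multi-page 8-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (vol.grid.astype(np.uint8) * 255))
    sidecar = {
        "voxel_size_um": vol.voxel_size_um,
        "label": vol.label,
        "region": vol.region,
        "level": vol.level,
    }
    if ground_truth:
        sidecar["ground_truth"] = ground_truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_binary_volume(path: PathLike, voxel_size_um: float | None = None) -> BinaryVolume:
    """Read a binary volume written by :func:`write_volume` (sidecar optional)."""
    path = Path(path)
    data = tifffile.imread(path)
    label = region = level = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size_um = voxel_size_um or meta.get("voxel_size_um")
        label, region, level = meta.get("label"), meta.get("region"), meta.get("level")
    if voxel_size_um is None:
        raise IOError(f"no voxel size given and no sidecar found for {path}")
    return BinaryVolume(
        grid=data > 0, voxel_size_um=voxel_size_um, label=label, region=region, level=level
    )


def isodata_threshold(gray: GrayVolume) -> float:
    """Isodata threshold of the full integer histogram.

    The returned level T satisfies the isodata fixed point
    ``T = (mean(values <= T) + mean(values > T)) / 2`` to within one gray
    level; foreground is defined as values strictly above T.
    """
    data = np.asarray(gray.data)
    if data.min() == data.max():
        raise ValueError("constant image: isodata threshold is undefined")
    return float(threshold_isodata(data))


def isodata_binarize(gray: GrayVolume) -> BinaryVolume:
    """Binarize a grayscale stack with the isodata algorithm (bone = above T)."""
    t = isodata_threshold(gray)
    return BinaryVolume(
        grid=np.asarray(gray.data) > t,
        voxel_size_um=gray.voxel_size_um,
        label=gray.label,
        meta={"isodata_threshold": t},
    )


def crop_cube(vol: BinaryVolume, origin: tuple[int, int, int], side_voxels: int) -> BinaryVolume:
    """Cut an axis-aligned cubic VOI of ``side_voxels`` per edge at ``origin`` (z, y, x)."""
    if side_voxels < 2:
        raise ValueError(f"side_voxels must be >= 2, got {side_voxels}")
    origin = tuple(int(o) for o in origin)
    for ax, (o, n) in enumerate(zip(origin, vol.shape)):
        if o < 0 or o + side_voxels > n:
            raise ValueError(
                f"cube [{o}, {o + side_voxels}) exceeds axis {ax} extent [0, {n})"
            )
    z, y, x = origin
    s = side_voxels
    return vol.with_grid(vol.grid[z : z + s, y : y + s, x : x + s].copy())


def degrade_voxel_size(vol: BinaryVolume, factor: int) -> BinaryVolume:
    """Coarsen the voxel grid by an integer factor (voxel-size sensitivity study).

    Each output voxel aggregates a ``factor^3`` block by its mean occupancy;
    blocks with mean >= 0.5 become bone (majority rule, ties to bone), which
    preserves BV/TV in expectation.  Axes not divisible by ``factor`` are
    trimmed at the trailing end, never padded.  ``factor = 1`` is the identity.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return vol.with_grid(vol.grid.copy())
    nz, ny, nx = (n - n % factor for n in vol.shape)
    if min(nz, ny, nx) < 2 * factor:
        raise ValueError(f"volume {vol.shape} too small to degrade by factor {factor}")
    g = vol.grid[:nz, :ny, :nx].astype(np.float64)
    g = g.reshape(nz // factor, factor, ny // factor, factor, nx // factor, factor)
    mean = g.mean(axis=(1, 3, 5))
    return vol.with_grid(mean >= 0.5, voxel_size_um=vol.voxel_size_um * factor)
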