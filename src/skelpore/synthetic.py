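"""Seeded generators of 3D fixtures with known topology and geometry.

These stand in for micro-CT pore-space images: simple shapes whose Euler
characteristic, component count and skeleton structure are known a priori
(tube chi=1, torus chi=0, Y-junction chi=1, hollow cube chi=2), plus a
correlated random porous medium emulating realistic pore-space fractions.
Every generator is deterministic given its arguments.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from skelpore.volumes import VoxelVolume

__all__ = [
    "make_tube",
    "make_torus",
    "make_y_junction",
    "make_cavity_cube",
    "make_random_porous",
]


def make_tube(
    radius: int,
    length: int,
    axis: int = 2,
    pad: int = 2,
    cap: int | None = None,
    resolution: float = 1.0,
) -> VoxelVolume:
    """Solid circular cylinder along ``axis`` (chi = 1, one component).

    The cross-section is the lattice disk of squared radius strictly below
    ``radius**2``, so ``radius=1`` degenerates to a one-voxel-wide line.
    ``pad`` is the transverse background margin; ``cap`` (default ``pad``)
    the axial one — ``cap=0`` leaves the tube flush with the volume ends,
    which the plane-injection benchmark wants.
    """
    if radius < 1 or length < 3:
        raise ValueError("need radius >= 1 and length >= 3")
    if cap is None:
        cap = pad
    side = 2 * radius - 1 + 2 * pad
    cx = side // 2
    u = np.arange(side) - cx
    disk = (u[:, None] ** 2 + u[None, :] ** 2) < radius**2
    grid = np.zeros((side, side, length + 2 * cap), dtype=bool)
    grid[:, :, cap : cap + length] = disk[:, :, None]
    grid = np.moveaxis(grid, 2, axis)
    return VoxelVolume(grid, resolution=resolution)


def make_torus(major_r: int, minor_r: int, pad: int = 2, resolution: float = 1.0) -> VoxelVolume:
    """Solid torus around the z-axis (chi = 0, one component, one tunnel)."""
    if not major_r > minor_r >= 1:
        raise ValueError("need major_r > minor_r >= 1")
    side = 2 * (major_r + minor_r) + 1 + 2 * pad
    depth = 2 * minor_r + 1 + 2 * pad
    cx, cz = side // 2, depth // 2
    x = np.arange(side) - cx
    z = np.arange(depth) - cz
    rho = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
    d2 = (rho[:, :, None] - major_r) ** 2 + z[None, None, :] ** 2
    grid = d2 < minor_r**2
    return VoxelVolume(grid, resolution=resolution)


def make_y_junction(
    arm_radius: int, arm_length: int, pad: int = 2, resolution: float = 1.0
) -> VoxelVolume:
    """Three tubes meeting at a center, 120 degrees apart in the xy-plane
    (chi = 1, one component, three skeleton endings)."""
    if arm_radius < 1 or arm_length < 3:
        raise ValueError("need arm_radius >= 1 and arm_length >= 3")
    reach = arm_length + arm_radius + pad
    side = 2 * reach + 1
    depth = 2 * arm_radius + 1 + 2 * pad
    cx, cz = reach, depth // 2
    ii, jj, kk = np.meshgrid(
        np.arange(side) - cx, np.arange(side) - cx, np.arange(depth) - cz, indexing="ij"
    )
    grid = np.zeros((side, side, depth), dtype=bool)
    for angle in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
        ux, uy = np.cos(angle), np.sin(angle)
        t = np.clip(ii * ux + jj * uy, 0.0, float(arm_length))
        d2 = (ii - t * ux) ** 2 + (jj - t * uy) ** 2 + kk**2
        grid |= d2 < arm_radius**2
    return VoxelVolume(grid, resolution=resolution)


def make_cavity_cube(
    outer: int = 10, inner: tuple[int, int] = (3, 6), pad: int = 1, resolution: float = 1.0
) -> VoxelVolume:
    """Solid cube with a concentric cubic cavity (chi = 2 by default:
    one component plus one cavity).  ``inner`` gives the inclusive voxel
    index range of the cavity within the outer cube."""
    lo, hi = inner
    if not 0 < lo <= hi < outer - 1:
        raise ValueError("cavity must be strictly inside the cube")
    side = outer + 2 * pad
    grid = np.zeros((side, side, side), dtype=bool)
    grid[pad : pad + outer, pad : pad + outer, pad : pad + outer] = True
    grid[pad + lo : pad + hi + 1, pad + lo : pad + hi + 1, pad + lo : pad + hi + 1] = False
    return VoxelVolume(grid, resolution=resolution)


def make_random_porous(
    dims: tuple[int, int, int],
    target_porosity: float,
    correlation_length: float = 2.0,
    seed: int = 0,
    resolution: float = 1.0,
) -> VoxelVolume:
    """Correlated random porous medium at a prescribed pore fraction.

    Seeded white noise is smoothed with a Gaussian kernel of standard
    deviation ``correlation_length`` and thresholded at the empirical
    quantile matching ``target_porosity``; the achieved porosity is within
    one voxel of the target count.
    """
    if not 0.0 < target_porosity < 1.0:
        raise ValueError("target_porosity must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(dims)
    field = ndimage.gaussian_filter(field, sigma=correlation_length)
    n = field.size
    k = int(round((1.0 - target_porosity) * n))
    k = min(max(k, 0), n - 1)
    thresh = np.partition(field.ravel(), k)[k]
    grid = field >= thresh
    return VoxelVolume(grid, resolution=resolution)
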