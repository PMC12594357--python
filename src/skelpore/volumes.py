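"""Binary 3D volumes: the coordinate conventions, I/O and binarization.

Conventions used throughout the package:

* voxels are indexed ``(i, j, k)``, 0-based; ``k`` is the depth axis and
  "planes" (e.g. in the diffusion calibration benchmark) are constant-``k``
  slices;
* the pore phase (the object) is 26-connected, the background 6-connected;
* the array border counts as background;
* all geometry is computed in voxel units; the physical ``resolution``
  (voxel edge length, micrometres) is applied only when exporting physical
  volumes/areas/distances and when converting diffusion coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "load_volume",
    "save_volume",
    "binarize",
    "boundary",
    "porosity",
    "CONN26",
]

#: 3x3x3 structuring element giving 26-connectivity for the pore phase.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelVolume:
    """A binary 3D image of pore space.

    Parameters
    ----------
    grid
        Boolean array of shape ``(nx, ny, nz)``; ``True`` marks pore voxels
        (the set S).
    resolution
        Voxel edge length in micrometres. Purely a reporting scale; all
        internal geometry is in voxel units.
    """

    grid: np.ndarray
    resolution: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {g.shape}")
        if g.dtype != bool:
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)
        if not (self.resolution > 0):
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)

    @property
    def n_pore(self) -> int:
        """Number of pore voxels |S|."""
        return int(self.grid.sum())

    def components(self) -> int:
        """Number of 26-connected components of the pore set."""
        _, n = ndimage.label(self.grid, structure=CONN26)
        return int(n)


def porosity(volume: VoxelVolume) -> float:
    """Pore-voxel fraction of the whole image (0..1)."""
    return volume.n_pore / volume.grid.size


def _tiff_pages(grid: np.ndarray) -> np.ndarray:
    # one page per k-plane: page k holds grid[:, :, k]
    return np.moveaxis(grid, 2, 0)


def save_volume(volume: VoxelVolume, path: str | Path, format: str = "tiff-stack") -> None:
    """Write a volume to disk.

    ``tiff-stack`` writes a multi-page TIFF (one page per k-plane, uint8
    0/255).  ``raw`` writes an uint8 stream with ``i`` the fastest axis and
    a JSON sidecar ``<path>.json`` recording dims and resolution.
    """
    path = Path(path)
    if format == "tiff-stack":
        import tifffile

        tifffile.imwrite(path, _tiff_pages(volume.grid.astype(np.uint8) * 255))
    elif format == "raw":
        volume.grid.astype(np.uint8).flatten(order="F").tofile(path)
        sidecar = {"dims": list(volume.dims), "resolution": volume.resolution, "dtype": "uint8"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown format {format!r}")


def save_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a 3D label image as a 32-bit unsigned multi-page TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), _tiff_pages(np.asarray(labels).astype(np.uint32)))


def load_volume(
    path: str | Path,
    format: str = "tiff-stack",
    dims: tuple[int, int, int] | None = None,
    resolution: float | None = None,
) -> VoxelVolume:
    """Read a volume from disk; any nonzero voxel becomes pore.

    For ``raw``, dims are taken from the JSON sidecar unless given
    explicitly; a file whose byte length does not match the dims is
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tiff-stack":
        import tifffile

        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        grid = np.moveaxis(pages, 0, 2) != 0
        return VoxelVolume(grid, resolution=resolution if resolution is not None else 1.0)
    if format == "raw":
        sidecar_path = Path(str(path) + ".json")
        if dims is None or resolution is None:
            if not sidecar_path.exists():
                raise ValueError(f"raw volume {path} needs dims/resolution or sidecar {sidecar_path}")
            sidecar = json.loads(sidecar_path.read_text())
            dims = dims or tuple(sidecar["dims"])
            resolution = resolution if resolution is not None else float(sidecar["resolution"])
        data = np.fromfile(path, dtype=np.uint8)
        expected = int(np.prod(dims))
        if data.size != expected:
            raise ValueError(
                f"raw file {path} holds {data.size} voxels but dims {dims} require {expected}"
            )
        grid = data.reshape(dims, order="F") != 0
        return VoxelVolume(grid, resolution=resolution)
    raise ValueError(f"unknown format {format!r}")


def binarize(
    gray: np.ndarray,
    median_radius: int = 1,
    resolution: float = 1.0,
    invert: bool = False,
) -> VoxelVolume:
    """Median-filter then Otsu-threshold a gray-level volume.

    Dark voxels become pore, matching CT images in which pore space is
    imaged dark; ``invert=True`` flips that choice.  The threshold value
    itself belongs to the dark class (the skimage convention), so an
    already-binary image keeps its zero phase as pore.  A constant image
    admits no threshold and is rejected.
    """
    from skimage.filters import threshold_otsu

    gray = np.asarray(gray)
    if gray.ndim != 3:
        raise ValueError(f"gray must be 3D, got shape {gray.shape}")
    if median_radius > 0:
        gray = ndimage.median_filter(gray, size=2 * median_radius + 1)
    if np.unique(gray).size < 2:
        raise ValueError("image is constant after median filtering; no Otsu threshold exists")
    thresh = threshold_otsu(gray)
    pore = gray > thresh if invert else gray <= thresh
    return VoxelVolume(pore, resolution=resolution)


def boundary(volume: VoxelVolume) -> np.ndarray:
    """Boolean mask of the pore voxels on the boundary B of S.

    A pore voxel is on B when at least one of its 26 neighbors lies outside
    S; voxels on the array border always qualify (border = background).
    """
    interior = ndimage.binary_erosion(volume.grid, structure=CONN26, border_value=0)
    return volume.grid & ~interior
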