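"""Reading, writing and normalization of binary vasculature volumes.

All volumes are held as contiguous 3D ``uint8`` arrays of {0, 1} indexed
``(z, y, x)``, with the per-axis physical resolution stored in the same
axis order.  2D images are padded to a single-slice 3D array so the rest
of the pipeline only ever sees three axes; the padded z axis is assigned
a unit resolution.

Any nonzero source value is treated as foreground: the pipeline only
accepts pre-segmented data, so no thresholding parameter is exposed.
NIfTI affine/orientation metadata is ignored — the caller-supplied
resolution is authoritative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BinaryVolume",
    "EmptyVolumeWarning",
    "VolumeFormatError",
    "load_volume",
    "save_volume",
    "binarize",
    "foreground_fraction",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp")


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be read or has an unsupported format."""


class EmptyVolumeWarning(UserWarning):
    """Emitted when a loaded volume contains no foreground voxels."""


@dataclass
class BinaryVolume:
    """A pre-segmented vasculature volume.

    Attributes
    ----------
    data :
        Contiguous 3D ``uint8`` array of {0, 1}; background is 0,
        vessel foreground is 1.  Axis order is ``(z, y, x)``.
    resolution :
        Physical units per voxel along ``(z, y, x)`` (e.g. μm, or px
        for 2D images).  All components are strictly positive.
    ndim_original :
        2 for images that were padded to a single slice, otherwise 3.
    """

    data: np.ndarray
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ndim_original: int = 3

    def __post_init__(self) -> None:
        data = np.ascontiguousarray(self.data)
        if data.ndim == 2:
            data = data[np.newaxis, ...]
            self.ndim_original = 2
        if data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 2D or 3D array, got {data.ndim} dimensions"
            )
        self.data = binarize(data)
        res = tuple(float(r) for r in self.resolution)
        if len(res) == 2:
            res = (1.0, *res)
        if len(res) != 3:
            raise ValueError("resolution must have 2 or 3 components")
        if not all(np.isfinite(r) and r > 0 for r in res):
            raise ValueError(f"resolution components must be positive and finite, got {res}")
        self.resolution = res

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel (product of the resolutions)."""
        return float(np.prod(self.resolution))

    def foreground_count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(
            self.data.copy(), self.resolution, ndim_original=self.ndim_original
        )


def binarize(data: np.ndarray) -> np.ndarray:
    """Map any nonzero value to 1, preserving shape; returns contiguous uint8."""
    return np.ascontiguousarray(data != 0, dtype=np.uint8)


def load_volume(path: str | Path, resolution=(1.0, 1.0, 1.0)) -> BinaryVolume:
    """Load a pre-segmented volume or 2D image as a :class:`BinaryVolume`.

    Parameters
    ----------
    path :
        A NIfTI file (``.nii``/``.nii.gz``), a (multi-page) TIFF stack,
        or a single 2D PNG/JPEG/BMP image.
    resolution :
        Physical units per voxel in ``(z, y, x)`` axis order; a 2-tuple
        ``(y, x)`` is accepted for 2D images (z defaults to 1).

    Notes
    -----
    Any nonzero value in the source is foreground.  2D images become
    shape ``(1, H, W)`` with ``ndim_original=2``.  An all-zero volume
    raises :class:`EmptyVolumeWarning` (a warning, not an error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    name = path.name.lower()
    try:
        if name.endswith(_NIFTI_SUFFIXES):
            arr = np.asanyarray(nib.load(path).dataobj)
        elif name.endswith(_TIFF_SUFFIXES):
            import tifffile

            arr = tifffile.imread(path)
        elif name.endswith(_IMAGE_SUFFIXES):
            import imageio.v3 as iio

            arr = iio.imread(path)
            if arr.ndim == 3:  # RGB(A) image: any nonzero channel is foreground
                arr = arr.any(axis=-1)
        else:
            raise VolumeFormatError(f"unsupported volume format: {path.name}")
    except VolumeFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc

    arr = np.squeeze(arr)
    if arr.ndim not in (2, 3):
        raise VolumeFormatError(
            f"{path.name}: expected a 2D or 3D dataset, got shape {arr.shape}"
        )
    volume = BinaryVolume(arr, resolution)
    if volume.foreground_count() == 0:
        warnings.warn(
            f"{path.name} contains no foreground voxels", EmptyVolumeWarning,
            stacklevel=2,
        )
    return volume


def save_volume(volume: BinaryVolume, path: str | Path) -> Path:
    """Write the 0/1 array as NIfTI with the resolution in the header zooms.

    The affine is a plain scaling matrix; orientation metadata is not
    round-tripped (see module notes).
    """
    path = Path(path)
    affine = np.diag([*volume.resolution[::-1], 1.0])
    img = nib.Nifti1Image(volume.data.astype(np.uint8), affine)
    img.header.set_zooms(volume.resolution[::-1])
    nib.save(img, path)
    return path


def foreground_fraction(volume: BinaryVolume) -> float:
    """Fraction of voxels that are vessel foreground (percent-area/volume basis)."""
    return volume.foreground_count() / volume.data.size
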