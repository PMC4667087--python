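"""NIfTI input/output and the geometry contract shared by all pipeline stages.

Every downstream computation assumes the channels of one subject/visit are
already co-registered: identical grid shape, voxel size and affine.  This
module enforces that contract at assembly time and refuses mismatched grids
rather than silently resampling.  Volume arithmetic everywhere is voxel count
times voxel volume (mm^3), reported in cm^3; an interslice gap, when present
in the acquisition, is carried as metadata only and never added to the voxel
volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Channel names recognised by the pipeline, in canonical feature order.
CHANNEL_NAMES = ("FLAIR", "T2", "MT")

#: Tolerance (mm) for geometry equality between channels.
GEOMETRY_TOL_MM = 1e-4


@dataclass
class ChannelImage:
    """A single co-registered scalar MRI volume (one pulse sequence).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities.  NaN outside the brain mask is permitted.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in mm (positive).
    affine : ndarray, shape (4, 4)
        Grid-to-world transform.
    channel_name : str
        One of :data:`CHANNEL_NAMES`.
    interslice_gap_mm : float
        Acquisition gap between slices; recorded only.
    """

    data: np.ndarray
    voxel_size_mm: tuple
    affine: np.ndarray
    channel_name: str
    interslice_gap_mm: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"channel {self.channel_name!r}: expected a 3-D volume, "
                f"got {self.data.ndim}-D"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(
                f"channel {self.channel_name!r}: voxel sizes must be 3 positive "
                f"reals, got {self.voxel_size_mm}"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def default_affine(voxel_size_mm) -> np.ndarray:
    """Diagonal affine placing voxel (0,0,0) at the world origin."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def read_channel(path, channel_name: str) -> ChannelImage:
    """Load one NIfTI channel volume.

    Raises
    ------
    ValueError
        If the file cannot be read or is not a 3-D image.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.info("%s: %d NaN voxels (outside-mask values permitted)", path, n_nan)
    return ChannelImage(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=np.float64),
        channel_name=channel_name,
    )


def write_channel(image: ChannelImage, path) -> Path:
    """Write a channel volume as NIfTI-1 (float32 data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(image.data.astype(np.float32), image.affine)
    nii.header.set_zooms(image.voxel_size_mm)
    nib.save(nii, str(path))
    return path


def write_mask(mask: np.ndarray, voxel_size_mm, affine, path) -> Path:
    """Write a boolean mask as a uint8 NIfTI volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nii.header.set_zooms(tuple(voxel_size_mm))
    nib.save(nii, str(path))
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return data > 0


@dataclass
class MultispectralVolume:
    """Co-registered multi-channel volume plus brain mask.

    Channel order is preserved and defines the downstream feature order.
    """

    channels: list
    brain_mask: np.ndarray

    def __post_init__(self):
        if len(self.channels) < 2:
            raise ValueError("need at least 2 channels for multispectral analysis")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if ch.shape != ref.shape:
                raise ValueError(
                    f"channel {ch.channel_name!r} shape {ch.shape} does not match "
                    f"{ref.channel_name!r} shape {ref.shape}; inputs must be "
                    "co-registered on one grid"
                )
            if np.max(np.abs(np.asarray(ch.voxel_size_mm) - ref.voxel_size_mm)) > GEOMETRY_TOL_MM:
                raise ValueError(
                    f"channel {ch.channel_name!r} voxel size differs from "
                    f"{ref.channel_name!r} beyond {GEOMETRY_TOL_MM} mm"
                )
            if np.max(np.abs(ch.affine - ref.affine)) > GEOMETRY_TOL_MM:
                raise ValueError(
                    f"channel {ch.channel_name!r} affine differs from "
                    f"{ref.channel_name!r}; missing registration?"
                )
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != ref.shape:
            raise ValueError("brain mask shape does not match channel grid")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> tuple:
        return tuple(ch.channel_name for ch in self.channels)

    @property
    def shape(self) -> tuple:
        return self.channels[0].shape

    @property
    def voxel_size_mm(self) -> tuple:
        return self.channels[0].voxel_size_mm

    @property
    def affine(self) -> np.ndarray:
        return self.channels[0].affine

    @property
    def voxel_volume_mm3(self) -> float:
        return self.channels[0].voxel_volume_mm3

    def data_stack(self) -> np.ndarray:
        """Stack channels along a trailing axis: shape (nx, ny, nz, n_channels)."""
        return np.stack([ch.data for ch in self.channels], axis=-1)

    def get_channel(self, name: str) -> ChannelImage:
        for ch in self.channels:
            if ch.channel_name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")


def assemble_multispectral(channels: Sequence[ChannelImage], brain_mask: np.ndarray) -> MultispectralVolume:
    """Bundle channels sharing one grid into a :class:`MultispectralVolume`.

    The geometry contract (shape, voxel size, affine within
    :data:`GEOMETRY_TOL_MM`) is verified; violations raise naming the
    offending channel, which usually signals missing registration.
    """
    msv = MultispectralVolume(channels=list(channels), brain_mask=brain_mask)
    logger.info(
        "assembled %d channels, %d in-mask voxels",
        msv.n_channels,
        int(msv.brain_mask.sum()),
    )
    return msv


def compute_brain_mask(image: ChannelImage, quantile: float = 0.5) -> np.ndarray:
    """Phantom-world brain extraction by intensity thresholding.

    The mask is the largest connected component of voxels brighter than the
    given quantile of the nonzero intensities, with holes filled slice-wise
    (interior tissue darker than the threshold is recovered by the fill).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly between 0 and 1")
    data = np.nan_to_num(image.data, nan=0.0)
    nonzero = data[data > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero image: cannot compute a brain mask")
    thr = float(np.quantile(nonzero, quantile))
    fg = data > thr
    if not fg.any():
        # uniform positive image: quantile equals every value, nothing above it
        fg = data > 0
    # close small noise gaps in-plane so the hole fill sees an unbroken rim
    # (padded so the closing cannot erode the array border)
    struct = np.ones((3, 3, 1), dtype=bool)
    padded = np.pad(fg, 1)
    fg = ndimage.binary_closing(padded, structure=struct, iterations=1)[1:-1, 1:-1, 1:-1]
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no foreground voxels above threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    filled = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return filled
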