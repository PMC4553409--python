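"""In-memory containers for 4D BOLD runs and integer-labelled parcellations.

Volumes are plain numpy arrays in a common voxel grid; NIfTI I/O goes through
nibabel. No spatial preprocessing (realignment, normalisation) happens here —
inputs are assumed to already share a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["BoldImage", "Parcellation"]


@dataclass
class BoldImage:
    """A preprocessed 4D BOLD run.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal, arbitrary units.
    tr : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (x, y, z), optional
        Brain mask; defaults to all voxels.
    voxel_size_mm : tuple of float
        Voxel edge lengths in millimetres, used to convert smoothing FWHM
        from mm to voxels.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial grid of data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(tuple(self.voxel_size_mm) + (self.tr,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask: np.ndarray | None = None, tr: float | None = None) -> "BoldImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=float),
            tr=tr,
            mask=mask,
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        )


@dataclass
class Parcellation:
    """Integer ROI label volume (0 = background) with optional nuisance masks.

    ``labels`` maps each voxel to an ROI id in 1..R (AAL-style). ``names``
    maps ids to human-readable region names; synthetic atlases use ``R{id}``.
    White-matter and CSF masks, when present, are disjoint from the ROIs and
    provide the nuisance-signal compartments.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    wm_mask: np.ndarray | None = None
    csf_mask: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(int)
        if not self.names:
            self.names = {int(r): f"R{int(r)}" for r in self.region_ids}

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def save(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))

    @classmethod
    def load(cls, path, names: dict[int, str] | None = None) -> "Parcellation":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        return cls(
            labels=np.asanyarray(img.dataobj).astype(int),
            names=names or {},
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        )
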