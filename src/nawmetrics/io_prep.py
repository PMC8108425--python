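"""Volume I/O and paired-intensity extraction.

Inputs are pairs of co-registered, brain-extracted, bias-field-corrected
3D T1w and FLAIR volumes plus a binary brain mask, all in NIfTI-1.  The
tool validates the co-registration contract (identical array shapes) but
never resamples: spatial preprocessing happens upstream.

Mask linearization is row-major (C order) over the 3D array and is the
fixed voxel order used everywhere labels are mapped back to space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumePair",
    "PairedIntensities",
    "ShapeMismatchError",
    "EmptyMaskError",
    "load_volume_pair",
    "save_volume_pair",
    "extract_paired_intensities",
]

#: minimum in-mask voxels for a pair to be usable at all
MIN_MASK_VOXELS = 1000


class ShapeMismatchError(ValueError):
    """Volumes of one subject do not share a grid (not co-registered/resampled)."""


class EmptyMaskError(ValueError):
    """Brain mask has too few voxels to support histogram analysis."""


@dataclass
class VolumePair:
    """Co-registered T1w + FLAIR volumes with a brain mask.

    Intensities are in arbitrary scanner units.  Negative in-mask values
    (possible after bias-field correction) are permitted and only flagged;
    they are clipped later, at the histogram stage.
    """

    t1w: np.ndarray
    flair: np.ndarray
    brain_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.t1w = np.asarray(self.t1w, dtype=np.float64)
        self.flair = np.asarray(self.flair, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask) != 0
        if not (self.t1w.ndim == self.flair.ndim == self.brain_mask.ndim == 3):
            raise ShapeMismatchError("all volumes must be 3D")
        if not (self.t1w.shape == self.flair.shape == self.brain_mask.shape):
            raise ShapeMismatchError(
                f"volume shapes differ: t1w {self.t1w.shape}, "
                f"flair {self.flair.shape}, mask {self.brain_mask.shape}"
            )
        n = int(self.brain_mask.sum())
        if n < MIN_MASK_VOXELS:
            raise EmptyMaskError(
                f"brain mask has {n} voxels (< {MIN_MASK_VOXELS})"
            )
        finite = np.isfinite(self.t1w[self.brain_mask]) & np.isfinite(
            self.flair[self.brain_mask]
        )
        if finite.any():
            t1_in = self.t1w[self.brain_mask][finite]
            fl_in = self.flair[self.brain_mask][finite]
            self.has_negative_intensities = bool(
                (t1_in < 0).any() or (fl_in < 0).any()
            )
        else:
            self.has_negative_intensities = False

    @property
    def n_mask_voxels(self) -> int:
        return int(self.brain_mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class PairedIntensities:
    """In-mask (T1w, FLAIR) intensities in row-major mask order."""

    t1_values: np.ndarray
    flair_values: np.ndarray
    n_voxels: int
    n_nonfinite_excluded: int = 0

    def __post_init__(self) -> None:
        self.t1_values = np.asarray(self.t1_values, dtype=np.float64)
        self.flair_values = np.asarray(self.flair_values, dtype=np.float64)
        if not (len(self.t1_values) == len(self.flair_values) == self.n_voxels):
            raise ValueError("t1/flair value lengths must equal n_voxels")

    def as_array(self) -> np.ndarray:
        """(n_voxels, 2) array with columns (t1, flair)."""
        return np.column_stack([self.t1_values, self.flair_values])


def _load_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ShapeMismatchError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), zooms


def load_volume_pair(
    t1_path: str | Path,
    flair_path: str | Path,
    mask_path: str | Path,
    subject_id: str | None = None,
) -> VolumePair:
    """Read a T1w/FLAIR/mask triplet and validate the co-registration contract.

    Raises :class:`ShapeMismatchError` when the three grids differ (the
    inputs were not co-registered and resampled upstream) and
    :class:`EmptyMaskError` when the mask is degenerate.  Voxel size is
    taken from the T1w header.
    """
    t1w, affine, zooms = _load_3d(t1_path)
    flair, _, _ = _load_3d(flair_path)
    mask, _, _ = _load_3d(mask_path)
    if subject_id is None:
        subject_id = Path(t1_path).name.split(".")[0]
    return VolumePair(
        t1w=t1w,
        flair=flair,
        brain_mask=mask,
        voxel_size=zooms,
        subject_id=subject_id,
        affine=affine,
    )


def save_volume_pair(
    pair: VolumePair,
    t1_path: str | Path,
    flair_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write a VolumePair back to three NIfTI files (lossless float64)."""
    for data, path in (
        (pair.t1w, t1_path),
        (pair.flair, flair_path),
        (pair.brain_mask.astype(np.uint8), mask_path),
    ):
        img = nib.Nifti1Image(np.asarray(data), pair.affine)
        img.header.set_zooms(pair.voxel_size)
        nib.save(img, str(path))


def extract_paired_intensities(pair: VolumePair) -> PairedIntensities:
    """Pull the in-mask (t1, flair) pairs in row-major mask order.

    Non-finite voxels (in either contrast) are dropped and counted in
    ``n_nonfinite_excluded``.  Raises ``ValueError`` when no finite voxel
    remains.
    """
    mask = pair.brain_mask
    t1 = pair.t1w[mask]  # row-major (C-order) linearization of the mask
    fl = pair.flair[mask]
    finite = np.isfinite(t1) & np.isfinite(fl)
    n_excluded = int((~finite).sum())
    if n_excluded == finite.size:
        raise ValueError("all in-mask voxels are non-finite")
    if n_excluded:
        warnings.warn(
            f"{pair.subject_id or 'subject'}: excluded {n_excluded} "
            "non-finite in-mask voxels",
            stacklevel=2,
        )
    return PairedIntensities(
        t1_values=t1[finite],
        flair_values=fl[finite],
        n_voxels=int(finite.sum()),
        n_nonfinite_excluded=n_excluded,
    )
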