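"""Reading, normalizing, and slicing 3D brain volumes.

Volumes are held in a fixed anatomical convention (closest-to-RAS axis
order), so that the three slicing orientations map to fixed array axes:

* sagittal — axis 0 (left–right),
* coronal  — axis 1 (posterior–anterior),
* axial    — axis 2 (inferior–superior).

All indexing is 0-based with half-open ``[start, end)`` ranges.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Orientation",
    "Volume3D",
    "Slice2D",
    "read_volume",
    "write_volume",
    "normalize_intensities",
    "crop_background",
    "extract_slice",
]


class Orientation(enum.Enum):
    """A slicing plane and the volume axis it iterates over."""

    SAGITTAL = ("sagittal", 0)
    CORONAL = ("coronal", 1)
    AXIAL = ("axial", 2)

    def __init__(self, label: str, axis_index: int) -> None:
        self.label = label
        self.axis_index = axis_index

    @classmethod
    def from_name(cls, name: str) -> "Orientation":
        for o in cls:
            if o.label == name.lower():
                return o
        raise ValueError(f"unknown orientation {name!r}; expected one of "
                         f"{[o.label for o in cls]}")


@dataclass
class Volume3D:
    """A single-subject 3D image ``I`` with shape ``(X, Y, Z)``.

    ``voxels`` is a float array; ``class_label`` is free-form (e.g.
    ``"positive"``/``"negative"``) and optional.
    """

    voxels: np.ndarray
    subject_id: str = "unknown"
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"Volume3D requires a 3D array, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume3D voxels must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class Slice2D:
    """A normalized 2D slice ``V`` with channel-replicated pixels.

    ``pixels`` is the single-channel ``H×W`` plane in ``[0, 1]``;
    ``channels()`` replicates it to ``H×W×3`` for feature extractors and
    the classifier, which expect three input channels.
    """

    pixels: np.ndarray
    subject_id: str = "unknown"
    orientation: Orientation | None = None
    segment_index: int | None = None
    slice_index: int | None = None

    def channels(self, n: int = 3) -> np.ndarray:
        return np.repeat(self.pixels[:, :, None], n, axis=2)


def read_volume(path: str | Path, subject_id: str | None = None,
                class_label: str | None = None) -> Volume3D:
    """Load a NIfTI-1/-2 file (optionally gzipped) as a :class:`Volume3D`.

    The image is reoriented to the closest canonical (RAS) axis order so
    orientation names map to fixed axes. NaN voxels are replaced by 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D image, got shape {tuple(data.shape)} from {path}")
    data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    return Volume3D(voxels=data, subject_id=subject_id or path.stem.split(".")[0],
                    class_label=class_label)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI with an identity (RAS) affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def normalize_intensities(vol: Volume3D) -> Volume3D:
    """Min–max rescale voxel intensities to span exactly ``[0, 1]``.

    The map is monotone, so voxel ordering is preserved. A constant
    volume cannot be rescaled and raises ``ValueError``.
    """
    lo = float(vol.voxels.min())
    hi = float(vol.voxels.max())
    if hi == lo:
        raise ValueError(
            f"cannot normalize a constant volume (all voxels == {lo})")
    scaled = (vol.voxels - lo) / (hi - lo)
    return Volume3D(scaled, subject_id=vol.subject_id,
                    class_label=vol.class_label)


def crop_background(vol: Volume3D, threshold_fraction: float = 0.05) -> Volume3D:
    """Crop to the tightest bounding box of voxels above ``threshold_fraction``.

    Expects a ``[0, 1]``-normalized volume. If no voxel exceeds the
    threshold the input is returned unchanged (never an empty volume).
    """
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1)")
    mask = vol.voxels > threshold_fraction
    if not mask.any():
        return vol
    slices = []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return Volume3D(vol.voxels[tuple(slices)], subject_id=vol.subject_id,
                    class_label=vol.class_label)


def _normalize_plane(plane: np.ndarray) -> np.ndarray:
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        # constant slices (edge of brain) degrade to all-zeros rather
        # than aborting a pipeline run
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def extract_slice(vol: Volume3D, orientation: Orientation, index: int,
                  *, normalize: bool = True,
                  segment_index: int | None = None) -> Slice2D:
    """Extract the 2D plane at ``index`` along ``orientation``'s axis.

    The plane is min–max normalized to ``[0, 1]`` per slice (the entropy
    histograms downstream are per-slice quantities); pass
    ``normalize=False`` for raw intensities.
    """
    dim = vol.dims[orientation.axis_index]
    if not 0 <= index < dim:
        raise IndexError(
            f"slice index {index} out of range [0, {dim}) along "
            f"{orientation.label}")
    plane = np.take(vol.voxels, index, axis=orientation.axis_index)
    if normalize:
        plane = _normalize_plane(plane)
    return Slice2D(pixels=plane, subject_id=vol.subject_id,
                   orientation=orientation, segment_index=segment_index,
                   slice_index=index)
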