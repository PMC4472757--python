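"""Volume I/O, intensity calibration and lumen segmentation.

The segmentation rule is deliberately simple and fully reproducible: the
lumen/soft-tissue threshold is the midpoint of the mean blood and mean muscle
intensity, measured in two user-supplied regions of interest, and the binary
mask is the 26-connected component of the thresholded volume that contains a
seed point.  For contrast-enhanced micro-CT angiography this midpoint rule
places the boundary close to the half-occupancy isosurface of the vessel wall
whenever the muscle ROI is representative of the perivascular background.

Coordinate convention: voxel indices are 0-based along array axes (x, y, z);
world coordinates are millimetres at voxel centres,
``world = origin + index * spacing``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Volume3D",
    "IntensityCalibration",
    "SegmentationMask",
    "DegenerateContrastWarning",
    "read_volume",
    "write_volume",
    "calibrate",
    "segment",
]


class DegenerateContrastWarning(UserWarning):
    """Blood and muscle ROI means coincide; the threshold carries no contrast."""


@dataclass
class Volume3D:
    """A 3-D scalar grid with physical spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary (scanner-calibrated) units.
    spacing : tuple of float
        Voxel edge length in mm per axis; strictly positive.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_to_index(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index for a world point (mm); may lie outside bounds."""
        p = np.asarray(point_mm, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)
        return tuple(int(i) for i in idx)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def roi_slices(self, box_mm) -> tuple[slice, slice, slice]:
        """Slices selecting voxels whose centres fall inside a world-space box.

        ``box_mm`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` in mm,
        inclusive on both ends.
        """
        lo_mm, hi_mm = (np.asarray(b, dtype=float) for b in box_mm)
        if np.any(hi_mm < lo_mm):
            raise ValueError("ROI box has max < min")
        spacing = np.asarray(self.spacing)
        origin = np.asarray(self.origin)
        lo = np.ceil((lo_mm - origin) / spacing - 1e-9).astype(int)
        hi = np.floor((hi_mm - origin) / spacing + 1e-9).astype(int)
        lo = np.clip(lo, 0, np.asarray(self.shape))
        hi = np.clip(hi, -1, np.asarray(self.shape) - 1)
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))


@dataclass(frozen=True)
class IntensityCalibration:
    """Blood/muscle ROI means and the derived midpoint threshold."""

    mean_blood: float
    mean_muscle: float

    def __post_init__(self) -> None:
        if self.mean_blood < self.mean_muscle:
            raise ValueError(
                f"mean blood intensity ({self.mean_blood}) below mean muscle "
                f"intensity ({self.mean_muscle}); check the ROIs"
            )

    @property
    def threshold(self) -> float:
        """Midpoint of the blood and muscle means (exact)."""
        return (self.mean_blood + self.mean_muscle) / 2.0


@dataclass
class SegmentationMask:
    """Binary lumen mask aligned to its source volume, with provenance."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing))


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: Volume3D, path, format: str | None = None) -> Path:
    """Write a volume as NIfTI (``.nii``), TIFF stack or raw, spacing included.

    TIFF and raw files carry a JSON sidecar (``<name>.json``) holding spacing,
    origin, dtype and shape, because those containers have no authoritative
    physical-spacing field.  NIfTI uses the NIfTI-2 header, whose float64
    fields preserve spacing exactly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti2Image(volume.intensities, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    elif fmt in ("tiff", "raw"):
        if fmt == "tiff":
            # axis 2 (z) becomes the page axis
            tifffile.imwrite(str(path), np.ascontiguousarray(np.moveaxis(volume.intensities, 2, 0)))
        else:
            volume.intensities.astype(volume.intensities.dtype).tofile(str(path))
        meta = {
            "spacing_mm": list(volume.spacing),
            "origin_mm": list(volume.origin),
            "dtype": str(volume.intensities.dtype),
            "shape": list(volume.shape),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def read_volume(path, format: str | None = None) -> Volume3D:
    """Read a volume written by :func:`write_volume`.

    Raises
    ------
    FileNotFoundError
        If the file, or the JSON spacing sidecar of a TIFF/raw volume, is
        missing.  Spacing is load-bearing (all diameters are in mm), so a
        volume without spacing metadata is rejected rather than defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume3D(data, tuple(float(z) for z in zooms), origin)
    if fmt in ("tiff", "raw"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing spacing sidecar {sidecar.name!r} for {path.name!r}: "
                "voxel spacing in mm is required"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing_mm" not in meta:
            raise ValueError(f"sidecar {sidecar} lacks 'spacing_mm'")
        if fmt == "tiff":
            data = np.moveaxis(tifffile.imread(str(path)), 0, 2)
        else:
            data = np.fromfile(str(path), dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
        return Volume3D(
            np.ascontiguousarray(data),
            tuple(meta["spacing_mm"]),
            tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        )
    raise ValueError(f"unknown volume format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith(".raw"):
        return "raw"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


# ---------------------------------------------------------------------------
# Calibration and segmentation


def calibrate(volume: Volume3D, blood_roi, muscle_roi) -> IntensityCalibration:
    """Measure blood/muscle means in two world-space box ROIs.

    The threshold is their midpoint — the discrimination rule for
    contrast-enhanced blood against soft tissue.  Overlapping ROIs warn;
    an ROI that selects no voxel is an error; equal means yield a valid but
    contrast-free calibration and a :class:`DegenerateContrastWarning`.
    """
    sl_blood = volume.roi_slices(blood_roi)
    sl_muscle = volume.roi_slices(muscle_roi)
    blood_vox = volume.intensities[sl_blood]
    muscle_vox = volume.intensities[sl_muscle]
    if blood_vox.size == 0:
        raise ValueError("blood ROI selects no voxels")
    if muscle_vox.size == 0:
        raise ValueError("muscle ROI selects no voxels")
    if _slices_overlap(sl_blood, sl_muscle):
        warnings.warn("blood and muscle ROIs overlap", UserWarning, stacklevel=2)
    mean_blood = float(blood_vox.mean())
    mean_muscle = float(muscle_vox.mean())
    if mean_blood == mean_muscle:
        warnings.warn(
            "blood and muscle ROI means are equal; threshold has no contrast",
            DegenerateContrastWarning,
            stacklevel=2,
        )
    return IntensityCalibration(mean_blood=mean_blood, mean_muscle=mean_muscle)


def _slices_overlap(a, b) -> bool:
    return all(s1.start < s2.stop and s2.start < s1.stop for s1, s2 in zip(a, b))


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment(
    volume: Volume3D,
    calibration: IntensityCalibration | float,
    seed_point,
    closing_radius_vox: int = 0,
) -> SegmentationMask:
    """Threshold at the calibration midpoint and keep the seed's component.

    Parameters
    ----------
    calibration : IntensityCalibration or float
        Calibration object, or a raw threshold in intensity units.
    seed_point : 3-tuple of float
        World coordinates (mm) of a point inside the vessel; its voxel must be
        at or above the threshold.
    closing_radius_vox : int
        Optional morphological closing radius (voxels) applied to the
        thresholded volume before component extraction; default off.
    """
    threshold = calibration if isinstance(calibration, (int, float)) else calibration.threshold
    idx = volume.world_to_index(seed_point)
    if any(i < 0 or i >= n for i, n in zip(idx, volume.shape)):
        raise ValueError(f"seed point {seed_point} maps outside the volume at index {idx}")
    if volume.intensities[idx] < threshold:
        raise ValueError(
            f"seed voxel intensity {volume.intensities[idx]:.3f} is below the "
            f"threshold {threshold:.3f}; place the seed inside the lumen"
        )
    above = volume.intensities >= threshold
    if closing_radius_vox > 0:
        r = int(closing_radius_vox)
        ball = _ball_structure(r)
        above = ndimage.binary_closing(above, structure=ball)
        # closing must not delete the seed
        above[idx] = True
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    component = labels == labels[idx]
    return SegmentationMask(
        component,
        volume.spacing,
        volume.origin,
        provenance={
            "threshold": float(threshold),
            "seed_point_mm": [float(v) for v in np.asarray(seed_point, dtype=float)],
            "seed_index": list(idx),
            "closing_radius_vox": int(closing_radius_vox),
        },
    )


def _ball_structure(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius
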