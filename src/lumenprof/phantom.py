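"""Synthetic micro-CT phantoms of curved, stenosed vessels with known truth.

The generator emulates contrast-enhanced neck CT of the murine common carotid
arteries: a tube of varying diameter follows a Catmull-Rom centerline, voxel
intensities encode partial-volume occupancy between a soft-tissue background
and the contrast-filled lumen, a muscle block sits beside the vessel to host
the calibration ROI, and Gaussian blur plus Gaussian noise stand in for the
scanner's point-spread function and detector noise.  A companion virtual
sectioner produces histology-like cross-sections with controllable shrinkage
and embedding-compression artefacts.

Defaults follow the imaging conditions of the study this package models:
18 um isotropic voxels and blood at 148.3 intensity units in vivo, 9 um and
155.8 units ex vivo, vessel diameters around 0.328 mm (ligated LCCA) and
0.454 mm (control RCCA), and a 4.2 mm arch-to-bifurcation span that yields
nine histology sections at 500 um spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import ellipe

from .volume import Volume3D

__all__ = [
    "VesselSpec",
    "SceneSpec",
    "PhantomTruth",
    "Phantom",
    "HistologyArtefactSpec",
    "HistologySection",
    "build_phantom",
    "virtual_histology",
    "ellipse_semi_axes",
]

#: default common-carotid arc length (mm); nine 0.5 mm sections span it
DEFAULT_VESSEL_LENGTH_MM = 4.2
#: ligated-side / control-side mean diameters (mm)
LCCA_DIAMETER_MM = 0.328
RCCA_DIAMETER_MM = 0.454

_MUSCLE_GAP_VOX = 10       # gap between vessel bounding box and muscle block
_MUSCLE_SIZE_VOX = (12, 16, 16)
_MARGIN_VOX = 4            # auto-sizing margin around the vessel surface


@dataclass
class VesselSpec:
    """Geometry of one tubular vessel.

    The centerline is a uniform Catmull-Rom spline through
    ``centerline_control_points``; if ``length`` is given, the curve is scaled
    uniformly about its first point to that arc length.  Stenoses are smooth
    cosine-squared constrictions: ``(position_fraction, severity, extent)``
    narrows the diameter to ``base_diameter * (1 - severity)`` at the centre
    of a window of ``extent`` (fraction of total length).  ``severity < 1``:
    the lumen never fully occludes, mirroring a partial ligation.
    """

    centerline_control_points: list
    base_diameter: float
    stenoses: list = field(default_factory=list)
    length: float | None = None
    vessel_id: str = "v0"

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline_control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("need >= 2 three-dimensional control points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError(
                "consecutive duplicate control points: non-increasing "
                "centerline parameterization is rejected"
            )
        self.centerline_control_points = pts
        if self.base_diameter <= 0:
            raise ValueError("base_diameter must be positive")
        for pos, sev, ext in self.stenoses:
            if not (0.0 < pos < 1.0):
                raise ValueError(f"stenosis position_fraction {pos} not strictly inside (0,1)")
            if not (0.0 <= sev < 1.0):
                raise ValueError(f"stenosis severity {sev} must lie in [0,1)")
            if not (0.0 < ext <= 1.0):
                raise ValueError(f"stenosis extent_fraction {ext} must lie in (0,1]")
        if self.length is not None and self.length <= 0:
            raise ValueError("length must be positive")

    # -- geometry ----------------------------------------------------------

    def sample_centerline(self, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length-resampled centerline.

        Returns ``(points, arc)``: points (n, 3) in mm at arc-length steps of
        at most ``step_mm``, and the cumulative arc length (n,), starting at 0
        and ending at the total length.
        """
        dense = _catmull_rom(self.centerline_control_points, samples_per_segment=256)
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if self.length is not None:
            scale = self.length / total
            dense = dense[0] + (dense - dense[0]) * scale
            arc = arc * scale
            total = self.length
        n = max(int(np.ceil(total / step_mm)) + 1, 2)
        target = np.linspace(0.0, total, n)
        pts = np.column_stack([np.interp(target, arc, dense[:, k]) for k in range(3)])
        return pts, target

    def total_length(self) -> float:
        if self.length is not None:
            return float(self.length)
        dense = _catmull_rom(self.centerline_control_points, samples_per_segment=256)
        return float(np.linalg.norm(np.diff(dense, axis=0), axis=1).sum())

    def diameter_at(self, t) -> np.ndarray:
        """Local diameter (mm) at normalized position(s) ``t`` in [0, 1]."""
        t = np.asarray(t, dtype=float)
        d = np.full(t.shape, self.base_diameter)
        for pos, sev, ext in self.stenoses:
            u = (t - pos) / ext  # window [-1/2, 1/2]
            w = np.where(np.abs(u) <= 0.5, np.cos(np.pi * u) ** 2, 0.0)
            d = d * (1.0 - sev * w)
        return d


def _catmull_rom(control: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Uniform Catmull-Rom spline through all control points."""
    p = np.asarray(control, dtype=float)
    if len(p) == 2:
        u = np.linspace(0.0, 1.0, samples_per_segment + 1)[:, None]
        return p[0] * (1 - u) + p[1] * u
    # phantom endpoints by reflection so the curve passes through p[0], p[-1]
    ext = np.vstack([2 * p[0] - p[1], p, 2 * p[-1] - p[-2]])
    u = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
    out = []
    for i in range(1, len(ext) - 2):
        p0, p1, p2, p3 = ext[i - 1], ext[i], ext[i + 1], ext[i + 2]
        uu = u[:, None]
        out.append(
            0.5
            * (
                2 * p1
                + (-p0 + p2) * uu
                + (2 * p0 - 5 * p1 + 4 * p2 - p3) * uu**2
                + (-p0 + 3 * p1 - 3 * p2 + p3) * uu**3
            )
        )
    out.append(p[-1][None, :])
    return np.vstack(out)


@dataclass
class SceneSpec:
    """One imaging scene: vessels plus intensity/resolution/noise settings.

    Intensities are in the scanner's arbitrary units.  Defaults are the
    in vivo conditions (blood-pool nanoparticle contrast at 18 um voxels);
    :meth:`ex_vivo` gives the post-mortem casting-agent conditions (9 um).
    Only the blood mean and SD are calibrated quantities; muscle and
    background are free parameters.  The default background (90) sits just
    below muscle (100) because the lumen borders perivascular soft tissue of
    near-muscle intensity — the anatomy that makes the blood/muscle midpoint
    threshold cut close to the half-occupancy isosurface of the wall.
    """

    vessels: list
    intensity_blood: float = 148.3
    intensity_muscle: float = 100.0
    intensity_background: float = 90.0
    voxel_size: float | tuple = 0.018
    psf_sigma: float = 0.009
    noise_sd: float = 2.0
    rng_seed: int = 0
    shape: tuple | None = None      # voxels; None = auto-fit around vessels
    origin: tuple | None = None     # mm; None = auto

    def __post_init__(self) -> None:
        if not self.vessels:
            raise ValueError("scene needs at least one vessel")
        self.vessels = list(self.vessels)
        if not (self.intensity_blood > self.intensity_muscle > self.intensity_background):
            raise ValueError(
                "intensity ordering must be blood > muscle > background, got "
                f"{self.intensity_blood} / {self.intensity_muscle} / {self.intensity_background}"
            )
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")

    @classmethod
    def in_vivo(cls, vessels, **kw) -> "SceneSpec":
        """Blood-pool contrast conditions: 18 um voxels, blood 148.3 +/- 2.0."""
        kw.setdefault("voxel_size", 0.018)
        kw.setdefault("intensity_blood", 148.3)
        kw.setdefault("noise_sd", 2.0)
        kw.setdefault("psf_sigma", 0.009)
        return cls(vessels=vessels, **kw)

    @classmethod
    def ex_vivo(cls, vessels, **kw) -> "SceneSpec":
        """Vascular-cast conditions: 9 um voxels, blood 155.8 +/- 1.6."""
        kw.setdefault("voxel_size", 0.009)
        kw.setdefault("intensity_blood", 155.8)
        kw.setdefault("noise_sd", 1.6)
        kw.setdefault("psf_sigma", 0.0045)
        return cls(vessels=vessels, **kw)


@dataclass
class PhantomTruth:
    """Ground truth for one vessel of a built phantom.

    ``true_segment_profile`` holds the nine-segment (diameter, area) pairs
    obtained by binning ``true_diameter`` over normalized arc length exactly
    as the measurement pipeline does, with area = pi d^2 / 4.
    """

    vessel_id: str
    sampled_centerline: np.ndarray   # (n, 3) mm
    arc_length: np.ndarray           # (n,) mm, strictly increasing
    true_diameter: np.ndarray        # (n,) mm
    true_segment_diameter: np.ndarray  # (9,) mm
    true_segment_area: np.ndarray      # (9,) mm^2
    seed_start: np.ndarray           # suggested trace seeds (mm)
    seed_end: np.ndarray

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class Phantom:
    """A built scene: the volume, per-vessel truth, and calibration ROIs."""

    volume: Volume3D
    truths: list
    blood_roi: tuple
    muscle_roi: tuple

    def truth_for(self, vessel_id: str) -> PhantomTruth:
        for t in self.truths:
            if t.vessel_id == vessel_id:
                return t
        raise KeyError(vessel_id)


def _segment_truth(arc: np.ndarray, diam: np.ndarray, n_segments: int = 9):
    """Normalized-arc binning of the true diameters into equidistant segments."""
    t = arc / arc[-1]
    idx = np.minimum((t * n_segments).astype(int), n_segments - 1)
    d = np.array([diam[idx == i].mean() for i in range(n_segments)])
    return d, np.pi * d**2 / 4.0


def build_phantom(scene: SceneSpec) -> Phantom:
    """Rasterize a scene into a noisy, blurred CT volume plus ground truth.

    Voxel intensity is ``background + (blood - background) * occupancy``,
    convolved with a Gaussian PSF and corrupted by seeded Gaussian noise.
    Occupancy at the lumen wall is resolved by supersampling each boundary
    voxel 3x3x3 against the tube's signed distance, so threshold placement
    near the wall behaves like real partial-volume data.  A muscle cuboid is
    placed ``10`` voxels beside the vessel bounding box for the calibration
    ROI.  Truth centerlines are sampled at half-voxel arc steps.
    """
    spacing = np.asarray(scene.voxel_size)
    step = 0.5 * spacing.min()
    sampled = []
    for v in scene.vessels:
        pts, arc = v.sample_centerline(step)
        diam = v.diameter_at(arc / arc[-1])
        sampled.append((v, pts, arc, diam))

    lo = np.min([np.min(p - d[:, None] / 2, axis=0) for _, p, _, d in sampled], axis=0)
    hi = np.max([np.max(p + d[:, None] / 2, axis=0) for _, p, _, d in sampled], axis=0)
    margin = _MARGIN_VOX * spacing
    if scene.origin is None or scene.shape is None:
        # irrational sub-voxel offsets keep synthetic geometry from aligning
        # degenerately with the voxel lattice (axis exactly on voxel centers)
        origin = lo - margin - np.array([np.sqrt(2) - 1, np.sqrt(3) - 1, np.sqrt(5) - 2]) * spacing
        # reserve +x room for the muscle block
        extent = hi + margin - origin
        extent[0] += (_MUSCLE_GAP_VOX + _MUSCLE_SIZE_VOX[0] + _MARGIN_VOX) * spacing[0]
        shape = np.ceil(extent / spacing).astype(int) + 1
    else:
        origin = np.asarray(scene.origin, dtype=float)
        shape = np.asarray(scene.shape, dtype=int)
        if np.any(lo - 2 * spacing < origin) or np.any(hi + 2 * spacing > origin + (shape - 1) * spacing):
            raise ValueError(
                "vessel does not fit inside the requested volume bounds with "
                "a 2-voxel margin; enlarge the volume or shrink the vessel"
            )
    shape = tuple(int(s) for s in shape)

    occupancy = np.zeros(shape, dtype=np.float64)
    for _, pts, arc, diam in sampled:
        _rasterize_tube(occupancy, origin, spacing, pts, diam / 2.0)

    intensity = np.full(shape, scene.intensity_background, dtype=np.float64)
    muscle_slices = _muscle_block_slices(shape, origin, spacing, hi)
    intensity[muscle_slices] = scene.intensity_muscle
    intensity += (scene.intensity_blood - scene.intensity_background) * occupancy

    if scene.psf_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma=scene.psf_sigma / spacing, mode="nearest")
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.rng_seed)
        intensity += rng.normal(0.0, scene.noise_sd, size=shape)

    volume = Volume3D(intensity, tuple(spacing), tuple(origin))

    truths = []
    for v, pts, arc, diam in sampled:
        seg_d, seg_a = _segment_truth(arc, diam)
        clearance = diam.max() / 2.0 + 3.0 * spacing.max()
        if 2 * clearance >= arc[-1]:
            s0, s1 = 0.1 * arc[-1], 0.9 * arc[-1]
        else:
            s0, s1 = clearance, arc[-1] - clearance
        seed_start = np.column_stack([np.interp([s0], arc, pts[:, k]) for k in range(3)])[0]
        seed_end = np.column_stack([np.interp([s1], arc, pts[:, k]) for k in range(3)])[0]
        truths.append(
            PhantomTruth(
                vessel_id=v.vessel_id,
                sampled_centerline=pts,
                arc_length=arc,
                true_diameter=diam,
                true_segment_diameter=seg_d,
                true_segment_area=seg_a,
                seed_start=seed_start,
                seed_end=seed_end,
            )
        )

    blood_roi = _blood_roi(truths[0], spacing)
    muscle_roi = (
        tuple(origin + (np.array([s.start for s in muscle_slices]) + 2) * spacing),
        tuple(origin + (np.array([s.stop for s in muscle_slices]) - 3) * spacing),
    )
    return Phantom(volume=volume, truths=truths, blood_roi=blood_roi, muscle_roi=muscle_roi)


def _blood_roi(truth: PhantomTruth, spacing: np.ndarray) -> tuple:
    """Axis-aligned box well inside the lumen at the vessel midpoint."""
    mid = len(truth.arc_length) // 2
    center = truth.sampled_centerline[mid]
    r = truth.true_diameter[mid] / 2.0
    half = np.maximum(spacing, r / (2.0 * np.sqrt(3.0)))
    return (tuple(center - half), tuple(center + half))


def _muscle_block_slices(shape, origin, spacing, vessel_hi) -> tuple:
    ix0 = int(np.ceil((vessel_hi[0] - origin[0]) / spacing[0])) + _MUSCLE_GAP_VOX
    sx, sy, sz = _MUSCLE_SIZE_VOX
    cy, cz = shape[1] // 2, shape[2] // 2
    return (
        slice(min(ix0, shape[0] - sx - 1), min(ix0 + sx, shape[0] - 1)),
        slice(max(cy - sy // 2, 0), min(cy + sy // 2, shape[1])),
        slice(max(cz - sz // 2, 0), min(cz + sz // 2, shape[2])),
    )


def _rasterize_tube(occupancy, origin, spacing, centerline, radii) -> None:
    """Accumulate tube occupancy (max-combined) on the scene grid.

    Interior voxels (deeper than half the voxel diagonal plus the centerline
    sampling slack) are set to 1, exterior to 0; only the thin boundary shell
    is supersampled 3x3x3.
    """
    lo = np.maximum(np.floor((centerline.min(0) - radii.max() - 2 * spacing - origin) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((centerline.max(0) + radii.max() + 2 * spacing - origin) / spacing),
        np.asarray(occupancy.shape) - 1,
    ).astype(int)
    grids = [np.arange(lo[k], hi[k] + 1) * spacing[k] + origin[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(centerline)
    dist, idx = tree.query(pts, workers=1)
    signed = dist - radii[idx]

    half_diag = 0.5 * float(np.linalg.norm(spacing))
    slack = 0.6 * spacing.min()   # nearest-sample approximation error margin
    occ = np.where(signed <= -(half_diag + slack), 1.0, 0.0)
    shell = np.abs(signed) < half_diag + slack
    if shell.any():
        offs = np.stack(
            np.meshgrid(*[np.array([-1, 0, 1]) / 3.0 * spacing[k] for k in range(3)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        sub = pts[shell][:, None, :] + offs[None, :, :]
        d_sub, i_sub = tree.query(sub.reshape(-1, 3), workers=1)
        inside = (d_sub - radii[i_sub]) < 0.0
        occ[shell] = inside.reshape(-1, offs.shape[0]).mean(axis=1)

    block = occ.reshape(gx.shape)
    view = occupancy[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    np.maximum(view, block, out=view)


# ---------------------------------------------------------------------------
# Virtual histology


@dataclass
class HistologyArtefactSpec:
    """Preparation artefacts applied by the virtual sectioner.

    ``shrink_factor`` is the linear scale left after fixation/embedding
    shrinkage (areas scale by its square).  ``compression_ratio`` maps each
    circular cross-section to an ellipse of the *same perimeter* with the
    given axis ratio, emulating embedding compression that deforms but does
    not destroy the wall.  ``plaque_fraction`` occupies that fraction of the
    shrunken media-circle area with plaque.
    """

    shrink_factor: float = 0.77
    compression_ratio: float = 1.0
    plaque_fraction: float = 0.0
    section_spacing: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrink_factor <= 1.0):
            raise ValueError("shrink_factor must lie in (0, 1]")
        if self.compression_ratio < 1.0:
            raise ValueError("compression_ratio must be >= 1")
        if not (0.0 <= self.plaque_fraction < 1.0):
            raise ValueError("plaque_fraction must lie in [0, 1)")
        if self.section_spacing <= 0:
            raise ValueError("section_spacing must be positive")


@dataclass
class HistologySection:
    """One virtual cross-section: in-plane lumen (or inner-media) contour."""

    vessel_id: str
    position_mm: float
    contour: np.ndarray          # (n, 2) closed polygon vertices, mm
    role: str                    # "lumen" or "inner_media"
    plaque_area_mm2: float = 0.0


def ellipse_semi_axes(perimeter: float, axis_ratio: float) -> tuple[float, float]:
    """Semi-axes (a, b), a = ratio * b, of the ellipse with the given perimeter.

    Uses the complete elliptic integral of the second kind:
    P = 4 a E(1 - b^2/a^2).  Perimeter scales linearly with size, so the
    solution is closed-form given the unit-b perimeter.
    """
    q = float(axis_ratio)
    if q < 1.0:
        raise ValueError("axis_ratio must be >= 1")
    p_unit = 4.0 * q * ellipe(1.0 - 1.0 / q**2)  # perimeter for b = 1
    b = perimeter / p_unit
    return q * b, b


def virtual_histology(scene: SceneSpec, artefacts: HistologyArtefactSpec) -> list:
    """Cut sections perpendicular to each vessel's true centerline.

    Sections are taken at positions 0, spacing, 2*spacing, ... up to the
    vessel length (a 4.2 mm vessel at 0.5 mm spacing yields nine).  Each
    cross-section starts as the true lumen circle, is scaled by the shrink
    factor, and, if requested, deformed to an equal-perimeter ellipse.  With
    a non-zero plaque fraction the contour plays the inner-media role and a
    plaque area (fraction of the shrunken media-circle area) is attached.
    """
    out = []
    rng = np.random.default_rng(artefacts.rng_seed)
    theta = np.linspace(0.0, 2.0 * np.pi, 257)[:-1]
    for vessel in scene.vessels:
        length = vessel.total_length()
        if artefacts.section_spacing > length:
            warnings.warn(
                f"section spacing {artefacts.section_spacing} mm exceeds vessel "
                f"length {length:.3f} mm; taking a single section at position 0",
                UserWarning,
                stacklevel=2,
            )
            positions = np.array([0.0])
        else:
            n = int(np.floor(length / artefacts.section_spacing + 1e-9)) + 1
            positions = np.arange(n) * artefacts.section_spacing
        for pos in positions:
            r_true = float(vessel.diameter_at(pos / length)) / 2.0
            r = artefacts.shrink_factor * r_true
            if artefacts.compression_ratio > 1.0:
                a, b = ellipse_semi_axes(2.0 * np.pi * r, artefacts.compression_ratio)
            else:
                a = b = r
            phi = rng.uniform(0.0, np.pi)
            x, y = a * np.cos(theta), b * np.sin(theta)
            contour = np.column_stack(
                [x * np.cos(phi) - y * np.sin(phi), x * np.sin(phi) + y * np.cos(phi)]
            )
            plaque = artefacts.plaque_fraction * np.pi * r**2
            out.append(
                HistologySection(
                    vessel_id=vessel.vessel_id,
                    position_mm=float(pos),
                    contour=contour,
                    role="inner_media" if artefacts.plaque_fraction > 0 else "lumen",
                    plaque_area_mm2=float(plaque),
                )
            )
    return out
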