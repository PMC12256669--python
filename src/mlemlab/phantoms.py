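"""Digital phantoms for emission-tomography simulation experiments.

This module generates every input used by the simulation laboratory:

* 2-D test patterns — a disk (optionally Gaussian-blurred, to demonstrate
  edge ringing) and a checkerboard with an optional high-contrast "hot spot";
* a simplified 3-D cardiac-torso emission map emulating the geometric and
  intensity features of an NCAT-style myocardial perfusion phantom: a
  truncated half-ellipsoidal left-ventricular (LV) shell with a spherical
  lung lesion adjacent to its lateral wall;
* rigid volume rotation and reorientation of the volume to the cardiac axes.

The cardiac phantom is constructed analytically: each voxel value is
evaluated from the implicit surfaces in the heart's own (un-oriented) frame
after transforming the voxel coordinate by the inverse of the heart
orientation.  Surfaces are antialiased with a linear ramp of about one voxel
to avoid hard aliasing of the binary organ masks.

Coordinate conventions
----------------------
Volumes are indexed ``values[ix, iy, iz]``; ``z`` is the reconstruction axis
(transverse slices are ``values[:, :, iz]``).  Rotations are right-handed
about the named axis; the heart orientation triple ``(ZY, XZ, YX)`` is
applied extrinsically in the listed order as rotations about x, y and z.
In the un-oriented ("cardiac") frame the LV long axis lies along +y with the
apex at +y, and the lateral wall faces +z.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
import yaml

__all__ = [
    "Image2D",
    "Volume3D",
    "SpotSpec",
    "CardiacPhantomSpec",
    "make_disk",
    "make_checkerboard",
    "make_cardiac_phantom",
    "rotate_volume",
    "reorient_to_cardiac_axes",
    "orientation_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Image2D:
    """A nonnegative square pixel grid (a tomographic slice or test pattern)."""

    values: np.ndarray
    pixel_size_mm: float = 2.34

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"Image2D must be square, got shape {self.values.shape}")
        if self.values.shape[0] < 16:
            raise ValueError("Image2D must be at least 16x16")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if np.any(self.values < 0):
            raise ValueError("Image2D values must be nonnegative")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


@dataclass
class Volume3D:
    """A nonnegative voxel grid; z is the reconstruction axis."""

    values: np.ndarray
    voxel_size_mm: float = 2.34
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3-D array")
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("transverse slices (fixed z) must be square")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if np.any(self.values < 0):
            raise ValueError("Volume3D values must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def slice_z(self, iz: int) -> Image2D:
        """Transverse slice at index ``iz`` as an :class:`Image2D`."""
        return Image2D(self.values[:, :, iz].copy(), pixel_size_mm=self.voxel_size_mm)


@dataclass
class SpotSpec:
    """A hot spot: a high-contrast disk (2-D) or sphere (3-D).

    ``intensity_ratio`` is the spot value divided by the reference value;
    the reference is either the pattern's bright background value (for the
    checkerboard) or the myocardium value (for the cardiac phantom).
    """

    shape: str = "sphere"
    intensity_ratio: float = 2.0
    diameter_mm: Optional[float] = None
    diameter_px: Optional[float] = None
    center: Optional[tuple] = None  # grid coordinates; None = module default
    reference: str = "background"

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "sphere"):
            raise ValueError("SpotSpec.shape must be 'disk' or 'sphere'")
        if self.intensity_ratio <= 0:
            raise ValueError("intensity_ratio must be positive")
        if self.reference not in ("background", "myocardium"):
            raise ValueError("reference must be 'background' or 'myocardium'")
        if self.diameter_mm is None and self.diameter_px is None:
            raise ValueError("one of diameter_mm or diameter_px is required")

    def diameter_in_px(self, pixel_size_mm: float) -> float:
        if self.diameter_px is not None:
            return float(self.diameter_px)
        return float(self.diameter_mm) / pixel_size_mm


@dataclass
class CardiacPhantomSpec:
    """Geometry and intensities of the simplified cardiac-torso phantom.

    Defaults follow the study configuration: LV length 94.3 mm, radius
    29.7 mm, myocardium value 75, 2.34 mm isotropic voxels, heart orientation
    (ZY, XZ, YX) = (-90, -20, -50) degrees, and a 30 mm spherical lung lesion
    adjacent to the LV lateral wall.  Wall thickness and the lesion-to-wall
    gap are not fixed by the study and are exposed as parameters.
    """

    lv_length_mm: float = 94.3
    lv_radius_mm: float = 29.7
    wall_thickness_mm: float = 10.0
    myocardium_value: float = 75.0
    background_value: float = 0.5
    orientation_deg: tuple = (-90.0, -20.0, -50.0)
    lesion: Optional[SpotSpec] = None
    matrix: tuple = (256, 256, 256)
    voxel_size_mm: float = 2.34
    lesion_gap_mm: float = 6.0
    # axial position of the lesion along the LV long axis, as a fraction of
    # the LV length from the base (mid-to-basal placement)
    lesion_axial_frac: float = 0.3
    edge_mm: Optional[float] = None  # antialias ramp width; None = 1.5 voxels

    def __post_init__(self) -> None:
        if self.myocardium_value <= self.background_value:
            raise ValueError("myocardium_value must exceed background_value")
        if not (0 < self.wall_thickness_mm < self.lv_radius_mm):
            raise ValueError("wall thickness must be positive and below the LV radius")
        if len(self.matrix) != 3 or self.matrix[0] != self.matrix[1]:
            raise ValueError("matrix must be (N, N, Nz)")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["orientation_deg"] = list(self.orientation_deg)
        d["matrix"] = list(self.matrix)
        if self.lesion is not None and self.lesion.center is not None:
            d["lesion"]["center"] = list(self.lesion.center)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CardiacPhantomSpec":
        d = yaml.safe_load(text)
        if d.get("lesion") is not None:
            les = d["lesion"]
            if les.get("center") is not None:
                les["center"] = tuple(les["center"])
            d["lesion"] = SpotSpec(**les)
        d["orientation_deg"] = tuple(d["orientation_deg"])
        d["matrix"] = tuple(d["matrix"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Rotation helpers
# ---------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def orientation_matrix(orientation_deg: tuple) -> np.ndarray:
    """Rotation matrix for the heart orientation triple (ZY, XZ, YX).

    The three angles are extrinsic rotations about the x, y and z axes,
    composed in the listed order: ``R = Rz(yx) @ Ry(xz) @ Rx(zy)``.
    """
    zy, xz, yx = np.deg2rad(np.asarray(orientation_deg, dtype=float))
    return _rot_z(yx) @ _rot_y(xz) @ _rot_x(zy)


_AXIS_PLANES = {"x": (1, 2), "y": (2, 0), "z": (0, 1)}


def rotate_volume(vol: Volume3D, axis: str, angle_deg: float) -> Volume3D:
    """Rigidly rotate a volume about a grid axis (right-handed), bicubic.

    Interpolation undershoots are clipped to 0; voxels mapped from outside
    the grid are filled with 0.
    """
    if axis not in _AXIS_PLANES:
        raise ValueError(f"invalid axis {axis!r}; expected 'x', 'y' or 'z'")
    axes = _AXIS_PLANES[axis]
    # scipy sorts the axis pair internally; for y the sorted order reverses
    # the plane orientation, so flip the sign to stay right-handed.
    ang = -angle_deg if axis == "y" else angle_deg
    out = ndi.rotate(vol.values, ang, axes=axes, reshape=False, order=3,
                     mode="constant", cval=0.0)
    np.clip(out, 0.0, None, out=out)
    meta = dict(vol.meta)
    R = {"x": _rot_x, "y": _rot_y, "z": _rot_z}[axis](np.deg2rad(angle_deg))
    meta["rotation_applied"] = R @ meta.get("rotation_applied", np.eye(3))
    return Volume3D(out, voxel_size_mm=vol.voxel_size_mm, meta=meta)


def apply_rotation_matrix(vol: Volume3D, R: np.ndarray) -> Volume3D:
    """Resample a volume under an arbitrary rotation matrix (one bicubic pass).

    ``R`` maps input-frame coordinates to output-frame coordinates about the
    grid center; undershoots are clipped to 0 and outside-grid voxels are 0.
    """
    R = np.asarray(R, dtype=float)
    c = (np.asarray(vol.values.shape) - 1) / 2.0
    # affine_transform maps output coords to input coords: p_in = R^T p_out
    out = ndi.affine_transform(vol.values, R.T, offset=c - R.T @ c,
                               order=3, mode="constant", cval=0.0)
    np.clip(out, 0.0, None, out=out)
    meta = dict(vol.meta)
    meta["rotation_applied"] = R @ meta.get("rotation_applied", np.eye(3))
    return Volume3D(out, voxel_size_mm=vol.voxel_size_mm, meta=meta)


def reorient_to_cardiac_axes(vol: Volume3D, orientation_deg: tuple) -> Volume3D:
    """Undo the heart orientation so the LV long axis lies along a grid axis.

    Applies the exact inverse of :func:`orientation_matrix` in a single
    bicubic resampling.  In the reoriented frame the LV long axis is along y
    (fixed-y slices are short-axis planes) and the lateral wall faces +z
    (fixed-x slices are horizontal-long-axis planes).
    """
    zy, xz, yx = orientation_deg
    if zy == xz == yx == 0:
        return Volume3D(vol.values.copy(), vol.voxel_size_mm, dict(vol.meta))
    return apply_rotation_matrix(vol, orientation_matrix(orientation_deg).T)


# ---------------------------------------------------------------------------
# 2-D test patterns
# ---------------------------------------------------------------------------

def make_disk(grid_size: int, diameter_px: float, value: float,
              blur_sigma_px: float = 0.0, pixel_size_mm: float = 2.34) -> Image2D:
    """Centered disk of a given value on a zero background.

    With ``blur_sigma_px > 0`` the disk is Gaussian-smoothed; smoothing
    preserves total intensity up to edge truncation.
    """
    if diameter_px >= grid_size:
        raise ValueError(
            f"disk diameter {diameter_px} px does not fit in a {grid_size} px grid")
    if blur_sigma_px < 0:
        raise ValueError("blur_sigma_px must be nonnegative")
    c = (grid_size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(grid_size), np.arange(grid_size), indexing="ij")
    r = np.hypot(ii - c, jj - c)
    img = np.where(r <= diameter_px / 2.0, float(value), 0.0)
    if blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, blur_sigma_px, mode="constant", cval=0.0)
        np.clip(img, 0.0, None, out=img)
    return Image2D(img, pixel_size_mm=pixel_size_mm)


def make_checkerboard(grid_size: int, square_px: int, low: float, high: float,
                      spot: Optional[SpotSpec] = None,
                      pixel_size_mm: float = 2.34) -> Image2D:
    """Checkerboard of alternating low/high squares, optional hot-spot disk.

    The spot value is ``intensity_ratio`` times the bright-square value and
    overwrites the pattern.  Deterministic; no randomness involved.
    """
    if grid_size % square_px != 0:
        raise ValueError(
            f"grid_size {grid_size} is not divisible by square_px {square_px}")
    if low < 0 or high <= 0:
        raise ValueError("require low >= 0 and high > 0")
    ii, jj = np.meshgrid(np.arange(grid_size), np.arange(grid_size), indexing="ij")
    parity = (ii // square_px + jj // square_px) % 2
    img = np.where(parity == 0, float(high), float(low))
    if spot is not None:
        if spot.shape != "disk":
            raise ValueError("checkerboard spot must be a disk")
        d = spot.diameter_in_px(pixel_size_mm)
        center = spot.center if spot.center is not None else ((grid_size - 1) / 2.0,) * 2
        ci, cj = center
        if (ci - d / 2 < 0 or cj - d / 2 < 0
                or ci + d / 2 > grid_size - 1 or cj + d / 2 > grid_size - 1):
            raise ValueError("spot does not fit fully inside the grid")
        r = np.hypot(ii - ci, jj - cj)
        img = np.where(r <= d / 2.0, spot.intensity_ratio * float(high), img)
    return Image2D(img, pixel_size_mm=pixel_size_mm)


# ---------------------------------------------------------------------------
# Cardiac phantom
# ---------------------------------------------------------------------------

def _smooth_inside(d: np.ndarray, w: float) -> np.ndarray:
    """Linear antialias ramp: 1 well inside (d<0), 0 well outside (d>0)."""
    return np.clip(0.5 - d / w, 0.0, 1.0)


def _ellipsoid_distance(qx, qy, qz, sx, sy, sz):
    """Approximate signed distance to an axis-aligned ellipsoid surface."""
    rho = np.sqrt((qx / sx) ** 2 + (qy / sy) ** 2 + (qz / sz) ** 2)
    grad = np.sqrt((qx / sx**2) ** 2 + (qy / sy**2) ** 2 + (qz / sz**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(grad > 0, rho * (rho - 1.0) / np.maximum(grad, 1e-12),
                     -min(sx, sy, sz))
    return d


def lesion_center_cardiac_frame(spec: CardiacPhantomSpec) -> np.ndarray:
    """Lesion center in the cardiac (un-oriented) frame, mm, relative to the
    LV base center.  The lesion sits on the +z (lateral) side at a fixed
    edge-to-edge gap from the outer wall."""
    if spec.lesion is None:
        raise ValueError("spec has no lesion")
    L, r = spec.lv_length_mm, spec.lv_radius_mm
    y_l = spec.lesion_axial_frac * L
    z_wall = r * np.sqrt(max(0.0, 1.0 - (y_l / L) ** 2))
    rad = (spec.lesion.diameter_mm if spec.lesion.diameter_mm is not None
           else spec.lesion.diameter_px * spec.voxel_size_mm) / 2.0
    return np.array([0.0, y_l, z_wall + spec.lesion_gap_mm + rad])


def make_cardiac_phantom(spec: CardiacPhantomSpec) -> Volume3D:
    """Build the oriented cardiac emission map on the voxel grid.

    The LV is a truncated half-ellipsoidal shell (outer radius
    ``lv_radius_mm``, long-axis length ``lv_length_mm``, open at the base) at
    ``myocardium_value``; blood pool and lung are at ``background_value``
    inside a field-of-view cylinder; the optional lesion is a sphere at
    ``intensity_ratio x myocardium_value``.  Voxel values are evaluated
    analytically in the cardiac frame (no resampling).
    """
    N, _, Nz = spec.matrix
    vs = spec.voxel_size_mm
    w = spec.edge_mm if spec.edge_mm is not None else 1.5 * vs
    L, r, t = spec.lv_length_mm, spec.lv_radius_mm, spec.wall_thickness_mm
    R = orientation_matrix(spec.orientation_deg)

    x = (np.arange(N) - (N - 1) / 2.0) * vs
    z = (np.arange(Nz) - (Nz - 1) / 2.0) * vs
    X, Y, Z = np.meshgrid(x.astype(np.float32), x.astype(np.float32),
                          z.astype(np.float32), indexing="ij")

    # cardiac frame: q = R^T p, with the LV axis midpoint at the volume center
    Rt = R.T.astype(np.float32)
    mid = np.array([0.0, L / 2.0, 0.0], dtype=np.float32)
    qx = Rt[0, 0] * X + Rt[0, 1] * Y + Rt[0, 2] * Z + mid[0]
    qy = Rt[1, 0] * X + Rt[1, 1] * Y + Rt[1, 2] * Z + mid[1]
    qz = Rt[2, 0] * X + Rt[2, 1] * Y + Rt[2, 2] * Z + mid[2]

    f_out = _smooth_inside(_ellipsoid_distance(qx, qy, qz, r, L, r), w)
    f_in = _smooth_inside(_ellipsoid_distance(qx, qy, qz, r - t, L - t, r - t), w)
    f_cut = np.clip(0.5 + qy / w, 0.0, 1.0)  # keep y >= 0 (base plane)
    shell = f_out * (1.0 - f_in) * f_cut
    del f_out, f_in, f_cut

    # Uniform soft-tissue/lung background on a spherical support: a sphere
    # is invariant under any rotation about the center, so volume rotation
    # (the mitigation experiment) conserves total intensity.
    fov_radius = 0.48 * min(N, Nz) * vs
    f_body = _smooth_inside(np.sqrt(X ** 2 + Y ** 2 + Z ** 2) - fov_radius, w)

    vol = spec.background_value * f_body \
        + (spec.myocardium_value - spec.background_value) * shell

    meta = {
        "spec": spec,
        "orientation_matrix": R,
        "long_axis_world": R @ np.array([0.0, 1.0, 0.0]),
        "lateral_direction_world": R @ np.array([0.0, 0.0, 1.0]),
        "lv_center_mm": np.zeros(3),
    }

    if spec.lesion is not None:
        lc = lesion_center_cardiac_frame(spec)
        rad = (spec.lesion.diameter_mm if spec.lesion.diameter_mm is not None
               else spec.lesion.diameter_px * vs) / 2.0
        lc_world = R @ (lc - np.array([0.0, L / 2.0, 0.0]))
        half = np.array([N, N, Nz]) * vs / 2.0
        if np.any(np.abs(lc_world) + rad > half):
            raise ValueError("lesion does not fit fully inside the grid")
        dl = np.sqrt((qx - lc[0]) ** 2 + (qy - lc[1]) ** 2
                     + (qz - lc[2]) ** 2) - np.float32(rad)
        f_les = _smooth_inside(dl, w)
        if np.any(np.minimum(shell, f_les) > 0.05):
            raise ValueError("lesion overlaps the myocardium")
        if spec.lesion.reference != "myocardium":
            raise ValueError("cardiac lesion intensity must reference the myocardium")
        lesion_value = spec.lesion.intensity_ratio * spec.myocardium_value
        vol = vol + (lesion_value - spec.background_value) * f_les
        meta["lesion_center_mm"] = lc_world
        meta["lesion_radius_mm"] = rad
        meta["lesion_value"] = lesion_value

    del qx, qy, qz, shell, f_body
    np.clip(vol, 0.0, None, out=vol)
    return Volume3D(vol.astype(float), voxel_size_mm=vs, meta=meta)
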