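"""Quantification of the hot-spot reconstruction artifact.

The analysis chain mirrors standard myocardial-perfusion processing: the
left ventricle (LV) is segmented on the *control* reconstruction (Otsu
threshold on an upsampled slice, largest connected component), and that one
mask is applied to every hot-spot variant.  Slices are normalized to the
maximum pixel value inside the LV mask, signed error images
(control - index) are formed inside the mask, and wall involvement is
summarized per angular sector (lateral = the sector facing the lesion,
septal = opposite, anterior/inferior in between).  Profile tools
(circumferential and line profiles) and the truncated-Fourier square-wave
overshoot round out the artifact characterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import filters, measure

from .phantoms import Image2D

__all__ = [
    "LVMask",
    "ErrorMap",
    "ProfileCurve",
    "segment_lv",
    "normalize_to_lv",
    "error_image",
    "sector_masks",
    "circumferential_profile",
    "line_profile",
    "wall_error_summary",
    "gibbs_overshoot",
]

SECTORS = ("lateral", "anterior", "septal", "inferior")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class LVMask:
    """LV segmentation derived from the control reconstruction only."""

    mask: np.ndarray                # boolean grid at the working (resized) scale
    resize_scale: int               # upsampling factor relative to the source slice
    threshold: float                # Otsu threshold used
    boundary: list = field(default_factory=list)  # contours (ordered points)
    source_shape: tuple = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def centroid(self) -> np.ndarray:
        """Centroid of the masked wall region (approximates the cavity center)."""
        idx = np.argwhere(self.mask)
        return idx.mean(axis=0)


@dataclass
class ErrorMap:
    """Signed error (control - index after LV normalization), inside the mask."""

    values: np.ndarray
    mask: LVMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("error map and mask shapes differ")

    def masked(self) -> np.ndarray:
        return self.values[self.mask.mask]


@dataclass
class ProfileCurve:
    """Ordered intensity samples along a circumferential or linear path."""

    positions: np.ndarray           # angle (deg) or path length (px)
    values: np.ndarray
    labels: Optional[np.ndarray] = None  # sector label per sample

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("profile positions must be strictly increasing")


# ---------------------------------------------------------------------------
# Segmentation and normalization
# ---------------------------------------------------------------------------

def _resize(values: np.ndarray, scale: int) -> np.ndarray:
    if scale == 1:
        return values.astype(float)
    out = ndi.zoom(values, scale, order=3, mode="nearest")
    np.clip(out, 0.0, None, out=out)
    return out


def segment_lv(control_slice: Image2D, resize_scale: int = 6) -> LVMask:
    """Segment the LV on a control slice: resize, Otsu, largest component.

    The slice is upsampled by ``resize_scale`` (bicubic) to refine the
    boundary, thresholded with Otsu's method, and the largest connected
    component above threshold is kept.
    """
    if resize_scale < 1:
        raise ValueError("resize_scale must be >= 1")
    vals = _resize(control_slice.values, resize_scale)
    thr = float(filters.threshold_otsu(vals))
    fg = vals > thr
    if not np.any(fg):
        raise ValueError("segmentation found no foreground above the Otsu threshold")
    lab, n = ndi.label(fg)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    boundary = measure.find_contours(mask.astype(float), 0.5)
    return LVMask(mask=mask, resize_scale=resize_scale, threshold=thr,
                  boundary=boundary, source_shape=control_slice.values.shape)


def _match_mask_scale(slice_: Image2D, mask: LVMask) -> np.ndarray:
    vals = slice_.values
    if vals.shape == mask.mask.shape:
        return vals.astype(float)
    if vals.shape == mask.source_shape:
        return _resize(vals, mask.resize_scale)
    raise ValueError("slice shape matches neither the mask nor its source")


def normalize_to_lv(slice_: Image2D, mask: LVMask) -> Image2D:
    """Scale a slice by the maximum pixel value inside the LV mask.

    The maximum is mask-restricted, so intense structures outside the LV
    (the hot spot) do not change the normalization.  Returns the slice at
    the mask's working scale.
    """
    if not np.any(mask.mask):
        raise ValueError("mask is empty")
    vals = _match_mask_scale(slice_, mask)
    m = float(vals[mask.mask].max())
    if m <= 0:
        raise ValueError("LV region is identically zero; cannot normalize")
    return Image2D(vals / m,
                   pixel_size_mm=slice_.pixel_size_mm / mask.resize_scale
                   if vals.shape != slice_.values.shape else slice_.pixel_size_mm)


def error_image(control_norm: Image2D, index_norm: Image2D, mask: LVMask) -> ErrorMap:
    """Signed error map control - index, restricted to the LV mask.

    Positive values mean the index image is suppressed relative to the
    control; negative values mean it is artifactually intensified.
    """
    if control_norm.values.shape != mask.mask.shape \
            or index_norm.values.shape != mask.mask.shape:
        raise ValueError("normalized inputs must be at the mask working scale")
    diff = np.where(mask.mask, control_norm.values - index_norm.values, 0.0)
    return ErrorMap(values=diff, mask=mask)


# ---------------------------------------------------------------------------
# Sectors and summaries
# ---------------------------------------------------------------------------

def sector_masks(mask: LVMask, lateral_angle_deg: float,
                 center: Optional[Sequence[float]] = None) -> Dict[str, np.ndarray]:
    """Quadrant sector masks about the LV center.

    ``lateral_angle_deg`` is the in-plane direction (atan2 of axis-1 over
    axis-0 pixel offsets) pointing from the LV center toward the lesion;
    the lateral sector spans +-45 degrees about it, the septal sector is
    opposite, anterior/inferior are the remaining quadrants.
    """
    c = np.asarray(center, dtype=float) if center is not None else mask.centroid
    ii, jj = np.indices(mask.mask.shape)
    ang = np.degrees(np.arctan2(jj - c[1], ii - c[0]))
    rel = (ang - lateral_angle_deg + 180.0) % 360.0 - 180.0
    out = {
        "lateral": (np.abs(rel) <= 45.0),
        "anterior": (rel > 45.0) & (rel <= 135.0),
        "septal": (np.abs(rel) > 135.0),
        "inferior": (rel < -45.0) & (rel >= -135.0),
    }
    return {k: v & mask.mask for k, v in out.items()}


def wall_error_summary(errors: Dict, lateral_angle_deg: float,
                       center: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Per-sector mean and max absolute error for each S/M ratio.

    ``errors`` maps a ratio label to an :class:`ErrorMap` or a list of
    per-slice :class:`ErrorMap` objects (aggregated together).  Returns a
    tidy frame with columns (ratio, sector, mean_abs_error, max_abs_error,
    n_pixels).
    """
    rows = []
    for ratio, maps in errors.items():
        if isinstance(maps, ErrorMap):
            maps = [maps]
        per_sector: Dict[str, list] = {s: [] for s in SECTORS}
        for em in maps:
            sects = sector_masks(em.mask, lateral_angle_deg, center=center)
            for s in SECTORS:
                per_sector[s].append(em.values[sects[s]])
        for s in SECTORS:
            v = np.abs(np.concatenate(per_sector[s])) if per_sector[s] else np.array([])
            rows.append({"ratio": ratio, "sector": s,
                         "mean_abs_error": float(v.mean()) if v.size else 0.0,
                         "max_abs_error": float(v.max()) if v.size else 0.0,
                         "n_pixels": int(v.size)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def circumferential_profile(hla_slice: Image2D, mask: LVMask, n_samples: int = 72,
                            lateral_angle_deg: float = 0.0,
                            center: Optional[Sequence[float]] = None) -> ProfileCurve:
    """Maximum-intensity circumferential profile across the myocardial wall.

    Rays are cast from the LV cavity center at ``n_samples`` equally spaced
    directions; each sample is the maximum intensity along the ray
    restricted to the mask (the wall).  Directions whose ray never meets the
    wall (the open base) yield NaN.  Sample labels follow the quadrant
    sectors relative to ``lateral_angle_deg``.
    """
    if n_samples < 36:
        raise ValueError("n_samples must be at least 36")
    vals = _match_mask_scale(hla_slice, mask)
    c = np.asarray(center, dtype=float) if center is not None else mask.centroid
    ci = int(round(c[0])), int(round(c[1]))
    if mask.mask[ci]:
        raise ValueError("profile center lies on the wall, not in the cavity")
    rmax = float(np.hypot(*mask.mask.shape))
    radii = np.arange(0.0, rmax, 0.5)
    angles = np.linspace(-180.0, 180.0, n_samples, endpoint=False)
    out = np.full(n_samples, np.nan)
    for k, adeg in enumerate(angles):
        a = np.deg2rad(adeg)
        pi = c[0] + radii * np.cos(a)
        pj = c[1] + radii * np.sin(a)
        ok = (pi >= 0) & (pi <= mask.mask.shape[0] - 1) \
            & (pj >= 0) & (pj <= mask.mask.shape[1] - 1)
        if not np.any(ok):
            continue
        coords = np.vstack([pi[ok], pj[ok]])
        inmask = ndi.map_coordinates(mask.mask.astype(float), coords, order=0) > 0.5
        if not np.any(inmask):
            continue
        v = ndi.map_coordinates(vals, coords[:, inmask], order=1)
        out[k] = v.max()
    rel = (angles - lateral_angle_deg + 180.0) % 360.0 - 180.0
    labels = np.where(np.abs(rel) <= 45.0, "lateral",
                      np.where(np.abs(rel) > 135.0, "septal",
                               np.where(rel > 0, "anterior", "inferior")))
    return ProfileCurve(positions=angles, values=out, labels=labels)


def line_profile(slice_: Image2D, line, n_samples: Optional[int] = None) -> ProfileCurve:
    """Intensity profile along a line, sampled at pixel spacing by default.

    ``line`` is either an integer row index or a pair of endpoints
    ``((i0, j0), (i1, j1))`` in pixel coordinates; ``n_samples`` overrides
    the default one-sample-per-pixel spacing.
    """
    vals = slice_.values
    if np.isscalar(line):
        row = int(line)
        if not 0 <= row < vals.shape[0]:
            raise ValueError("row index outside the slice")
        v = vals[row, :].astype(float)
        return ProfileCurve(positions=np.arange(v.size, dtype=float), values=v)
    (i0, j0), (i1, j1) = line
    length = float(np.hypot(i1 - i0, j1 - j0))
    if length == 0:
        raise ValueError("degenerate (zero-length) line")
    n = n_samples if n_samples is not None else int(np.ceil(length)) + 1
    tt = np.linspace(0.0, 1.0, n)
    coords = np.vstack([i0 + tt * (i1 - i0), j0 + tt * (j1 - j0)])
    v = ndi.map_coordinates(vals, coords, order=1)
    return ProfileCurve(positions=tt * length, values=v)


# ---------------------------------------------------------------------------
# Gibbs overshoot
# ---------------------------------------------------------------------------

def gibbs_overshoot(n_terms: int, grid_points: int = 20001) -> float:
    """Peak overshoot of the truncated Fourier series of a unit square wave.

    Builds the ``n_terms``-harmonic partial sum of a 0/1 square wave
    (jump of 1) and returns the maximum overshoot above the upper plateau as
    a percentage of the jump.  The infinite-``n_terms`` limit is the
    Wilbraham-Gibbs constant, about 8.95 %; a single harmonic gives 13.66 %.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    k = 2 * np.arange(1, n_terms + 1) - 1  # odd harmonics

    def partial_sum(x: np.ndarray) -> np.ndarray:
        s = np.zeros_like(x)
        for lo in range(0, k.size, 256):  # chunked to bound memory
            kk = k[lo:lo + 256]
            s += (np.sin(np.outer(x, kk)) / kk).sum(axis=1)
        return 0.5 + (2.0 / np.pi) * s

    # coarse pass on the upper half-plateau near the discontinuity at x = 0
    # (where the first, largest crest lies), then refine around the argmax
    x = np.linspace(0.0, np.pi / 2.0, grid_points)[1:]
    s = partial_sum(x)
    i = int(np.argmax(s))
    dx = x[1] - x[0]
    xf = np.linspace(max(x[i] - 2 * dx, 0.0), x[i] + 2 * dx, 2001)[1:]
    sf = partial_sum(xf)
    return float((max(s.max(), sf.max()) - 1.0) * 100.0)
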