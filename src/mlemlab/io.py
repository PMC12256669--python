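"""Reading and writing images, volumes and figure panels.

Volumes go to multi-page TIFF (pages along z) or NIfTI (.nii / .nii.gz,
with the voxel size in the affine); 2-D images to TIFF or PNG.  Figure
panels use matplotlib with a sequential map for activity images and a
diverging map (zero = mid-gray/black) for signed error images.
"""

from __future__ import annotations

import imageio.v3 as iio
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import tifffile

from .phantoms import Image2D, Volume3D

__all__ = [
    "save_image_tiff", "load_image_tiff", "save_image_png",
    "save_volume_tiff", "load_volume_tiff",
    "save_volume_nifti", "load_volume_nifti",
    "save_error_png", "save_profile_png",
]


def save_image_tiff(path, img: Image2D) -> None:
    tifffile.imwrite(str(path), img.values.astype(np.float32))


def load_image_tiff(path, pixel_size_mm: float = 2.34) -> Image2D:
    return Image2D(tifffile.imread(str(path)).astype(float), pixel_size_mm)


def save_image_png(path, img: Image2D) -> None:
    v = img.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    iio.imwrite(str(path), (255 * scaled).astype(np.uint8))


def save_volume_tiff(path, vol: Volume3D) -> None:
    # pages along z: transpose so page p is the transverse slice z = p
    tifffile.imwrite(str(path), np.moveaxis(vol.values, 2, 0).astype(np.float32))


def load_volume_tiff(path, voxel_size_mm: float = 2.34) -> Volume3D:
    arr = tifffile.imread(str(path)).astype(float)
    return Volume3D(np.moveaxis(arr, 0, 2), voxel_size_mm)


def save_volume_nifti(path, vol: Volume3D) -> None:
    aff = np.diag([vol.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), aff), str(path))


def load_volume_nifti(path) -> Volume3D:
    im = nib.load(str(path))
    vs = float(im.header.get_zooms()[0])
    return Volume3D(np.asarray(im.dataobj, dtype=float), vs)


def save_error_png(path, error: np.ndarray) -> None:
    """Signed error panel on a diverging map, symmetric about zero."""
    lim = float(np.abs(error).max()) or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(error.T, cmap="RdBu_r", vmin=-lim, vmax=lim, origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(str(path), dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_profile_png(path, object_profile, recon_profile) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(object_profile.positions, object_profile.values, "k-", label="object")
    ax.plot(recon_profile.positions, recon_profile.values, "r-", label="reconstruction")
    ax.set_xlabel("position (px)")
    ax.set_ylabel("intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
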