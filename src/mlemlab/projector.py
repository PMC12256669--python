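"""Forward projection (Radon transform), back-projection and Poisson noise.

The forward projector follows the rotate-and-sum construction used
throughout this package: at each acquisition angle the image is rotated with
bicubic interpolation and the pixel values of each column are summed to give
one detector bin.  Rather than physically rotating the image per angle, the
operator is assembled once per geometry as a sparse system matrix whose rows
are exactly the column sums of the bicubic rotation weights (Keys cubic
convolution, a = -1/2 — the classical "bicubic" kernel).  The composition is
mathematically identical to rotate-then-sum, and it makes the back-projector
the exact matrix transpose of the forward projector — a matched adjoint
pair, which is what guarantees the monotone-likelihood property of the EM
iteration built on top of it.

Noise is Poisson: each sinogram bin is an independent count drawn with rate
``count_scale * value``.  Sampling is by inverse CDF on a seeded uniform
field, so paired experiments that differ only in a few source voxels share
their noise (common random numbers) while marginals remain exactly Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .phantoms import Image2D

__all__ = [
    "Sinogram",
    "ProjectionGeometry",
    "forward_project",
    "back_project",
    "add_poisson_noise",
    "forward_project_stack",
    "back_project_stack",
]


@dataclass
class Sinogram:
    """Projection data indexed (detector bin, angle)."""

    values: np.ndarray
    angles_deg: np.ndarray
    bin_size_mm: float = 2.34

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Sinogram values must be 2-D (bins x angles)")
        if self.values.shape[1] != self.angles_deg.size:
            raise ValueError("number of sinogram columns must equal number of angles")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry: square grid, angle set, bins = grid size."""

    grid_size: int
    angles_deg: tuple = tuple(np.arange(0.0, 360.0, 1.0))
    interpolation: str = "bicubic"

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", tuple(ang))
        if ang.size == 0 or np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        if ang[0] < 0 or ang[-1] >= 360.0:
            raise ValueError("angles must lie within [0, 360)")
        if self.interpolation != "bicubic":
            raise ValueError("only bicubic interpolation is supported")

    @property
    def bins(self) -> int:
        return self.grid_size

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @classmethod
    def with_step(cls, grid_size: int, step_deg: float = 1.0) -> "ProjectionGeometry":
        """Full 360-degree arc with the given angular step."""
        return cls(grid_size, tuple(np.arange(0.0, 360.0, step_deg)))


def _keys_kernel(s: np.ndarray) -> np.ndarray:
    """Keys cubic-convolution interpolation kernel with a = -1/2."""
    s = np.abs(s)
    out = np.zeros_like(s)
    m1 = s <= 1.0
    out[m1] = (1.5 * s[m1] - 2.5) * s[m1] ** 2 + 1.0
    m2 = (s > 1.0) & (s < 2.0)
    out[m2] = ((-0.5 * s[m2] + 2.5) * s[m2] - 4.0) * s[m2] + 2.0
    return out


_MATRIX_CACHE: dict = {}


def system_matrix(geom: ProjectionGeometry) -> sparse.csr_matrix:
    """Sparse forward operator of shape (n_angles * bins, grid_size**2).

    Row ``a * bins + j`` holds the weights with which image pixels
    contribute to detector bin ``j`` at angle ``angles_deg[a]``: the column
    sums of the bicubic image-rotation weights at that angle.  Cached per
    geometry.
    """
    key = (geom.grid_size, geom.angles_deg)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    N = geom.grid_size
    c = (N - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    ii = ii.ravel().astype(np.float64)
    jj = jj.ravel().astype(np.float64)
    blocks = []
    for theta in geom.angles_deg:
        a = np.deg2rad(theta)
        cos, sin = np.cos(a), np.sin(a)
        # inverse map: source coordinate sampled for output pixel (i, j)
        si = c + cos * (ii - c) - sin * (jj - c)
        sj = c + sin * (ii - c) + cos * (jj - c)
        fi = np.floor(si).astype(np.int64)
        fj = np.floor(sj).astype(np.int64)
        rows_l, cols_l, data_l = [], [], []
        for di in range(-1, 3):
            wi = _keys_kernel(si - (fi + di))
            gi = fi + di
            for dj in range(-1, 3):
                wj = _keys_kernel(sj - (fj + dj))
                gj = fj + dj
                w = wi * wj
                ok = (gi >= 0) & (gi < N) & (gj >= 0) & (gj < N) & (w != 0.0)
                rows_l.append(jj[ok].astype(np.int64))  # detector bin = column
                cols_l.append(gi[ok] * N + gj[ok])
                data_l.append(w[ok])
        m = sparse.coo_matrix(
            (np.concatenate(data_l),
             (np.concatenate(rows_l), np.concatenate(cols_l))),
            shape=(N, N * N)).tocsr()
        blocks.append(m)
    M = sparse.vstack(blocks, format="csr")
    _MATRIX_CACHE[key] = M
    return M


def _check_image(img: Image2D, geom: ProjectionGeometry) -> None:
    if img.grid_size != geom.grid_size:
        raise ValueError(
            f"image size {img.grid_size} does not match geometry {geom.grid_size}")


def forward_project(img: Image2D, geom: ProjectionGeometry,
                    clip: bool = True) -> Sinogram:
    """Radon transform by rotation + column sums (bicubic interpolation).

    With ``clip=True`` (production default) negative interpolation
    undershoots in the resulting sinogram are clipped to 0; ``clip=False``
    keeps the operator exactly linear (used by adjoint/linearity checks).
    """
    _check_image(img, geom)
    M = system_matrix(geom)
    y = M @ img.values.ravel()
    sino = y.reshape(geom.n_angles, geom.bins).T
    if clip:
        np.clip(sino, 0.0, None, out=sino)
    return Sinogram(sino, np.asarray(geom.angles_deg), bin_size_mm=img.pixel_size_mm)


def back_project(sino: Sinogram, geom: ProjectionGeometry,
                 clip: bool = True) -> Image2D:
    """Unfiltered back-projection: the exact adjoint of :func:`forward_project`."""
    if sino.n_bins != geom.bins or sino.n_angles != geom.n_angles:
        raise ValueError("sinogram shape does not match geometry")
    M = system_matrix(geom)
    x = M.T @ sino.values.T.ravel()
    img = x.reshape(geom.grid_size, geom.grid_size)
    if clip:
        np.clip(img, 0.0, None, out=img)
    return Image2D(img, pixel_size_mm=sino.bin_size_mm)


def forward_project_stack(stack: np.ndarray, geom: ProjectionGeometry,
                          clip: bool = True) -> np.ndarray:
    """Forward-project a stack of slices at once.

    ``stack`` has shape (N, N, S); returns sinograms of shape (bins,
    n_angles, S).  Used by volume reconstruction; identical per-slice to
    :func:`forward_project`.
    """
    N = geom.grid_size
    if stack.shape[0] != N or stack.shape[1] != N:
        raise ValueError("stack does not match geometry grid size")
    S = stack.shape[2]
    M = system_matrix(geom)
    y = M @ stack.reshape(N * N, S, order="C")
    # reshape rows (a * bins + j) -> (angles, bins, S) -> (bins, angles, S)
    sino = y.reshape(geom.n_angles, geom.bins, S).transpose(1, 0, 2)
    if clip:
        np.clip(sino, 0.0, None, out=sino)
    return np.ascontiguousarray(sino)


def back_project_stack(sinos: np.ndarray, geom: ProjectionGeometry,
                       clip: bool = True) -> np.ndarray:
    """Back-project a stack of sinograms (bins, n_angles, S) -> (N, N, S)."""
    if sinos.shape[0] != geom.bins or sinos.shape[1] != geom.n_angles:
        raise ValueError("sinogram stack does not match geometry")
    S = sinos.shape[2]
    M = system_matrix(geom)
    y = sinos.transpose(1, 0, 2).reshape(geom.n_angles * geom.bins, S)
    x = (M.T @ y).reshape(geom.grid_size, geom.grid_size, S)
    if clip:
        np.clip(x, 0.0, None, out=x)
    return np.ascontiguousarray(x)


def add_poisson_noise(sino: Sinogram, seed: int,
                      count_scale: float = 1.0) -> Sinogram:
    """Corrupt a sinogram with Poisson noise.

    Each bin is drawn independently from Poisson(count_scale * value) and
    divided by ``count_scale``; the default scale 1 treats sinogram values as
    expected counts.  Deterministic given ``seed``.
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    if np.any(sino.values < 0):
        raise ValueError("sinogram values must be nonnegative")
    noisy = poisson_sample(sino.values, seed, count_scale)
    return Sinogram(noisy, sino.angles_deg.copy(), bin_size_mm=sino.bin_size_mm)


def poisson_sample(values: np.ndarray, seed: int,
                   count_scale: float = 1.0) -> np.ndarray:
    """Inverse-CDF Poisson sampling of an array of expected values.

    One uniform variate is consumed per element regardless of the rate, so
    two arrays differing in a few elements and sampled with the same seed
    share their noise everywhere else (common random numbers).
    """
    if np.any(np.asarray(values) < 0):
        raise ValueError("expected values must be nonnegative")
    rng = np.random.default_rng(seed)
    u = rng.random(np.shape(values))
    lam = count_scale * np.asarray(values, dtype=float)
    counts = np.where(lam > 0, stats.poisson.ppf(u, np.maximum(lam, 1e-300)), 0.0)
    return counts / count_scale
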