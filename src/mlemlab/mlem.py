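"""Maximum-likelihood expectation-maximization (MLEM) reconstruction.

The estimator maximizes the Poisson likelihood of the measured sinogram S
under the linear emission model lambda = R{X}, using the multiplicative
update

    X^(k+1) = X^k * R^-1{ S / R{X^k} } / R^-1{1},

where R is the forward projector and R^-1 its (unfiltered, adjoint)
back-projection; R^-1{1} is the sensitivity image.  Because the projector
pair in this package is an exact adjoint pair, each update is an exact EM
step and the Poisson log-likelihood is non-decreasing.

The module follows a model/results layout: :class:`MLEM` is constructed
from data (one sinogram or a stack of per-slice sinograms plus the
acquisition geometry) and ``fit()`` returns an :class:`MLEMResults` object
carrying the estimate, iteration snapshots, the log-likelihood trace and a
``summary()`` table.  ``mlem_reconstruct`` and ``reconstruct_volume`` are
thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .phantoms import Image2D, Volume3D
from .projector import (ProjectionGeometry, Sinogram, back_project_stack,
                        forward_project_stack)

__all__ = [
    "MLEM",
    "MLEMResults",
    "mlem_reconstruct",
    "reconstruct_volume",
    "poisson_loglik",
    "sensitivity_image",
    "default_initial",
]

_EPS = 1e-12
DEFAULT_SNAPSHOTS = tuple(range(1, 16, 2))


def sensitivity_image(geom: ProjectionGeometry) -> Image2D:
    """Back-projection of an all-ones sinogram, R^-1{1} (cached per geometry)."""
    ones = np.ones((geom.bins, geom.n_angles, 1))
    sens = back_project_stack(ones, geom, clip=True)[:, :, 0]
    return Image2D(sens)


def default_initial(geom: ProjectionGeometry) -> Image2D:
    """Uniform ones inside the inscribed circle (the field of view), 0 outside."""
    N = geom.grid_size
    c = (N - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    fov = np.hypot(ii - c, jj - c) <= N / 2.0 - 0.5
    return Image2D(fov.astype(float))


def poisson_loglik(sino: Sinogram, estimate_sino: Sinogram) -> float:
    """Poisson log-likelihood sum_b [S_b log(lambda_b) - lambda_b].

    The data-factorial constant is omitted.  Bins with lambda = 0 and S > 0
    contribute -inf; bins with S = 0 contribute -lambda.
    """
    if sino.values.shape != estimate_sino.values.shape:
        raise ValueError("sinogram shapes do not match")
    return float(_loglik_arrays(sino.values, estimate_sino.values))


def _loglik_arrays(S: np.ndarray, lam: np.ndarray) -> float:
    if np.any(lam < 0):
        raise ValueError("estimate sinogram must be nonnegative")
    out = -np.sum(lam)
    pos = S > 0
    if np.any(pos):
        with np.errstate(divide="ignore"):
            logl = np.log(lam[pos])
        out += np.sum(np.where(lam[pos] > 0, S[pos] * logl, -np.inf))
    return float(out)


class MLEM:
    """MLEM model for one sinogram or a stack of per-slice sinograms.

    Parameters
    ----------
    data : Sinogram or ndarray
        The measured projection data.  An ndarray must have shape
        (bins, n_angles) or (bins, n_angles, n_slices).
    geometry : ProjectionGeometry
        Acquisition geometry shared by all slices.
    """

    def __init__(self, data, geometry: ProjectionGeometry):
        if isinstance(data, Sinogram):
            values = data.values[:, :, None]
            self._single = True
        else:
            values = np.asarray(data, dtype=float)
            if values.ndim == 2:
                values = values[:, :, None]
                self._single = True
            elif values.ndim == 3:
                self._single = False
            else:
                raise ValueError("data must be 2-D or 3-D")
        if values.shape[0] != geometry.bins or values.shape[1] != geometry.n_angles:
            raise ValueError("sinogram shape does not match geometry")
        if np.any(values < 0):
            raise ValueError("measured data must be nonnegative")
        self.data = values
        self.geometry = geometry
        self.sensitivity = sensitivity_image(geometry)

    def fit(self, n_iter: int = 15, init: Optional[Image2D] = None,
            snapshot_iters: Sequence[int] = DEFAULT_SNAPSHOTS) -> "MLEMResults":
        """Run ``n_iter`` EM updates and return an :class:`MLEMResults`."""
        if n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        geom = self.geometry
        N = geom.grid_size
        S = self.data
        nslices = S.shape[2]

        sens = self.sensitivity.values
        active = sens > _EPS
        fov = default_initial(geom).values > 0  # inscribed circle

        if init is None:
            x0 = default_initial(geom).values
        else:
            if init.grid_size != N:
                raise ValueError("init size does not match geometry")
            x0 = init.values
            if np.any(x0[fov] <= 0):
                raise ValueError(
                    "initial estimate must be strictly positive inside the FOV")
        X = np.repeat(x0[:, :, None], nslices, axis=2).astype(float)
        X[~active, :] = 0.0

        snapshot_iters = tuple(int(k) for k in snapshot_iters)
        if any(k < 1 or k > n_iter for k in snapshot_iters):
            snapshot_iters = tuple(k for k in snapshot_iters if 1 <= k <= n_iter)
        snapshots: dict = {}
        loglik = np.empty((n_iter, nslices))

        sens_safe = np.where(active, sens, 1.0)[:, :, None]
        for k in range(1, n_iter + 1):
            proj = forward_project_stack(X, geom, clip=True)
            # Per-slice log-likelihood of the current estimate's projection.
            # Projections are clamped at the division guard so bins whose
            # interpolation-spillover counts are tiny cannot send the trace
            # to -inf; the public poisson_loglik keeps the exact convention.
            proj_safe = np.maximum(proj, _EPS)
            for s in range(nslices):
                loglik[k - 1, s] = _loglik_arrays(S[:, :, s], proj_safe[:, :, s])
            # Division guard: no update from bins where both the data and
            # the projected estimate are negligible.  The threshold is
            # relative to the data scale (1e-6 of the peak bin, far below
            # one count) so that interpolation spillover in near-empty bins
            # cannot seed huge ratio spikes once the estimate vanishes there.
            eps_bin = max(_EPS, 1e-6 * float(S.max()))
            ratio = np.where((S < eps_bin) & (proj < eps_bin), 1.0,
                             S / np.maximum(proj, _EPS))
            corr = back_project_stack(ratio, geom, clip=True) / sens_safe
            X = X * corr
            X[~active, :] = 0.0
            if k in snapshot_iters:
                snapshots[k] = X.copy()
        return MLEMResults(model=self, estimate=X, iteration=n_iter,
                           snapshots=snapshots, loglik_trace=loglik)


@dataclass
class MLEMResults:
    """Results of an MLEM fit.

    ``estimate`` holds the final iterate(s) with shape (N, N, n_slices);
    ``loglik_trace[k-1, s]`` is the Poisson log-likelihood of slice ``s``
    evaluated at iterate ``X^(k-1)`` (so the trace is non-decreasing down
    its rows).  Snapshots map iteration number to the full stack at that
    iteration.
    """

    model: MLEM
    estimate: np.ndarray
    iteration: int
    snapshots: dict
    loglik_trace: np.ndarray

    @property
    def final(self) -> Image2D:
        """Final estimate (first slice, for single-sinogram fits)."""
        return Image2D(self.estimate[:, :, 0].copy())

    @property
    def sensitivity(self) -> Image2D:
        return self.model.sensitivity

    def slice_image(self, s: int, iteration: Optional[int] = None) -> Image2D:
        stack = self.estimate if iteration is None else self.snapshots[iteration]
        return Image2D(stack[:, :, s].copy())

    def volume(self, voxel_size_mm: float = 2.34) -> Volume3D:
        return Volume3D(self.estimate.copy(), voxel_size_mm=voxel_size_mm)

    def nrmse(self, truth: Image2D, s: int = 0) -> float:
        """Root-mean-square error normalized by the RMS of the truth."""
        t = truth.values
        d = self.estimate[:, :, s] - t
        return float(np.sqrt(np.mean(d ** 2)) / np.sqrt(np.mean(t ** 2)))

    def summary(self) -> str:
        geom = self.model.geometry
        ll = self.loglik_trace
        lines = [
            "MLEM reconstruction results",
            "===========================",
            f"grid size            : {geom.grid_size} x {geom.grid_size}",
            f"angles               : {geom.n_angles} over 360 deg",
            f"slices               : {self.estimate.shape[2]}",
            f"iterations           : {self.iteration}",
            f"snapshots at         : {sorted(self.snapshots)}",
            f"log-lik (first iter) : {np.sum(ll[0]):.6g}",
            f"log-lik (last iter)  : {np.sum(ll[-1]):.6g}",
            f"monotone trace       : {bool(np.all(np.diff(ll.sum(axis=1)) >= -1e-6 * np.abs(ll.sum(axis=1)[:-1])))}",
            f"min / max estimate   : {self.estimate.min():.6g} / {self.estimate.max():.6g}",
        ]
        return "\n".join(lines)


def mlem_reconstruct(sino: Sinogram, geom: ProjectionGeometry, n_iter: int = 15,
                     init: Optional[Image2D] = None,
                     snapshot_iters: Sequence[int] = DEFAULT_SNAPSHOTS
                     ) -> MLEMResults:
    """Reconstruct a single sinogram (functional wrapper over :class:`MLEM`)."""
    return MLEM(sino, geom).fit(n_iter=n_iter, init=init,
                                snapshot_iters=snapshot_iters)


def reconstruct_volume(slice_sinos: Iterable[Sinogram], geom: ProjectionGeometry,
                       n_iter: int = 15,
                       snapshot_iters: Sequence[int] = DEFAULT_SNAPSHOTS,
                       voxel_size_mm: float = 2.34) -> Volume3D:
    """Reconstruct a volume from one sinogram per transverse slice.

    Each slice is an independent 2-D MLEM reconstruction; the stacked run is
    numerically identical to calling :func:`mlem_reconstruct` per slice.
    """
    sinos = list(slice_sinos)
    if not sinos:
        raise ValueError("no sinograms given")
    for s in sinos:
        if s.n_bins != geom.bins or s.n_angles != geom.n_angles:
            raise ValueError("inconsistent slice geometry")
    stack = np.stack([s.values for s in sinos], axis=2)
    res = MLEM(stack, geom).fit(n_iter=n_iter, snapshot_iters=snapshot_iters)
    return Volume3D(res.estimate, voxel_size_mm=voxel_size_mm,
                    meta={"loglik_trace": res.loglik_trace})
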