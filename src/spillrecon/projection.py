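"""Projection geometry, ray-driven projectors and the Gaussian PSF model.

The projector is a Siddon-style ray tracer: for every sinogram bin a fan of
``rays_per_bin`` parallel sub-rays is traced through the voxel grid and the
exact intersection length with every voxel is accumulated.  The traced
weights are assembled once per (geometry, grid) pair into a sparse matrix
``H``, so ``forward_project`` and ``back_project`` are exact adjoints by
construction.

Resolution modelling is image-space: with a PSF attached the image is
convolved with a separable Gaussian before ray tracing (and after
backprojection for the adjoint), giving the blurred system operator
``H' = H G``.  The same operator serves both the analytical simulation and
the reconstruction.

3D mode (``cylindrical3d``) is a simplified stack of direct planes: each
axial image slice is projected with the shared transverse matrix, and the
axial PSF component couples slices in image space.  Oblique sinogram
bookkeeping (span/ring-difference mixing) is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage, sparse

from .grids import ImageGrid

__all__ = [
    "ProjectionGeometry",
    "PSFModel",
    "SystemModel",
    "forward_project",
    "back_project",
    "attenuation_factors",
    "apply_psf",
    "fwhm_to_sigma",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return float(fwhm) * FWHM_TO_SIGMA


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam sampling: ``n_views`` angles over 180 degrees and
    ``n_tang`` tangential bins of ``bin_size`` mm.  In ``cylindrical3d``
    mode the sinogram carries one direct plane per image slice."""

    n_views: int
    n_tang: int
    bin_size: float
    mode: str = "parallel2d"  # parallel2d | cylindrical3d
    max_ring_difference: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("parallel2d", "cylindrical3d"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.n_views < 1 or self.n_tang < 1:
            raise ValueError("n_views and n_tang must be >= 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.max_ring_difference != 0:
            raise NotImplementedError(
                "only direct planes (max_ring_difference=0) are modelled"
            )

    @property
    def view_angles(self) -> np.ndarray:
        return np.pi * np.arange(self.n_views) / self.n_views

    @property
    def tangential_positions(self) -> np.ndarray:
        return (np.arange(self.n_tang) - (self.n_tang - 1) / 2.0) * self.bin_size


@dataclass(frozen=True)
class PSFModel:
    """Separable Gaussian resolution kernel, FWHM in mm (transverse plane
    and axial direction), truncated at ``kernel_truncation`` sigmas."""

    fwhm_transverse: float
    fwhm_axial: float = 0.0
    kernel_truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_transverse < 0 or self.fwhm_axial < 0:
            raise ValueError("FWHMs must be nonnegative")

    def sigmas_voxels(self, grid: ImageGrid) -> tuple[float, ...]:
        st = fwhm_to_sigma(self.fwhm_transverse)
        sig = [st / grid.voxel_size[0], st / grid.voxel_size[1]]
        if grid.ndim == 3:
            sig.append(fwhm_to_sigma(self.fwhm_axial) / grid.voxel_size[2])
        return tuple(sig)


def apply_psf(image: np.ndarray, psf: PSFModel, grid: ImageGrid) -> np.ndarray:
    """Separable unit-sum Gaussian convolution with reflective boundary."""
    sig = psf.sigmas_voxels(grid)
    if all(s == 0 for s in sig):
        return np.asarray(image, dtype=np.float64).copy()
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64),
        sigma=sig,
        mode="reflect",
        truncate=psf.kernel_truncation,
    )


# ---------------------------------------------------------------------------
# Siddon tracing kernel


@njit(cache=True)
def _trace_rays(angles, svals, rows, weights, nx, ny, dx, dy, xmin, ymin):
    """Exact voxel intersection lengths for a set of 2D parallel rays.

    Each ray i passes through the point ``svals[i] * (cos a, sin a)`` with
    direction ``(-sin a, cos a)``.  Returns COO triplets (bin row, voxel
    column, length * weight); lengths are in mm.
    """
    nray = angles.size
    maxper = nx + ny + 4
    data = np.empty(nray * maxper, np.float64)
    rr = np.empty(nray * maxper, np.int64)
    cc = np.empty(nray * maxper, np.int64)
    tbuf = np.empty(maxper, np.float64)
    k = 0
    xmax = xmin + nx * dx
    ymax = ymin + ny * dy
    for i in range(nray):
        a = angles[i]
        s = svals[i]
        ux = np.cos(a)
        uy = np.sin(a)
        dxr = -uy
        dyr = ux
        px = s * ux
        py = s * uy
        tmin = -1.0e30
        tmax = 1.0e30
        if abs(dxr) > 1.0e-12:
            t1 = (xmin - px) / dxr
            t2 = (xmax - px) / dxr
            lo = min(t1, t2)
            hi = max(t1, t2)
            if lo > tmin:
                tmin = lo
            if hi < tmax:
                tmax = hi
        elif px <= xmin or px >= xmax:
            continue
        if abs(dyr) > 1.0e-12:
            t1 = (ymin - py) / dyr
            t2 = (ymax - py) / dyr
            lo = min(t1, t2)
            hi = max(t1, t2)
            if lo > tmin:
                tmin = lo
            if hi < tmax:
                tmax = hi
        elif py <= ymin or py >= ymax:
            continue
        if tmax <= tmin + 1.0e-12:
            continue
        # collect all grid-plane crossings in (tmin, tmax)
        m = 0
        tbuf[m] = tmin
        m += 1
        if abs(dxr) > 1.0e-12:
            for ip in range(nx + 1):
                t = (xmin + ip * dx - px) / dxr
                if tmin + 1.0e-12 < t < tmax - 1.0e-12:
                    tbuf[m] = t
                    m += 1
        if abs(dyr) > 1.0e-12:
            for ip in range(ny + 1):
                t = (ymin + ip * dy - py) / dyr
                if tmin + 1.0e-12 < t < tmax - 1.0e-12:
                    tbuf[m] = t
                    m += 1
        tbuf[m] = tmax
        m += 1
        ts = np.sort(tbuf[:m])
        for j in range(m - 1):
            ta = ts[j]
            tb = ts[j + 1]
            seg = tb - ta
            if seg <= 1.0e-12:
                continue
            tm = 0.5 * (ta + tb)
            ix = int(np.floor((px + tm * dxr - xmin) / dx))
            iy = int(np.floor((py + tm * dyr - ymin) / dy))
            if 0 <= ix < nx and 0 <= iy < ny:
                data[k] = seg * weights[i]
                rr[k] = rows[i]
                cc[k] = ix * ny + iy
                k += 1
    return data[:k], rr[:k], cc[:k]


def _build_matrix(
    geometry: ProjectionGeometry, grid: ImageGrid, rays_per_bin: int
) -> sparse.csr_matrix:
    """Assemble the transverse system matrix H (bins x voxels), averaging
    ``rays_per_bin`` sub-rays uniformly spread across each tangential bin."""
    nx, ny = grid.shape[0], grid.shape[1]
    dx, dy = grid.voxel_size[0], grid.voxel_size[1]
    xmin = grid.origin[0] - dx / 2.0
    ymin = grid.origin[1] - dy / 2.0
    angs = geometry.view_angles
    svals = geometry.tangential_positions
    R = int(rays_per_bin)
    offsets = ((np.arange(R) + 0.5) / R - 0.5) * geometry.bin_size

    n_rays = geometry.n_views * geometry.n_tang * R
    a = np.empty(n_rays)
    s = np.empty(n_rays)
    rows = np.empty(n_rays, dtype=np.int64)
    w = np.full(n_rays, 1.0 / R)
    idx = 0
    for v in range(geometry.n_views):
        for t in range(geometry.n_tang):
            row = v * geometry.n_tang + t
            for r in range(R):
                a[idx] = angs[v]
                s[idx] = svals[t] + offsets[r]
                rows[idx] = row
                idx += 1
    data, rr, cc = _trace_rays(a, s, rows, w, nx, ny, dx, dy, xmin, ymin)
    H = sparse.coo_matrix(
        (data, (rr, cc)),
        shape=(geometry.n_views * geometry.n_tang, nx * ny),
    ).tocsr()
    H.sum_duplicates()
    return H


class SystemModel:
    """Linear system operators H (project) and H^T (backproject) on one
    (geometry, grid) pair, optionally with an image-space Gaussian PSF."""

    def __init__(
        self,
        geometry: ProjectionGeometry,
        grid: ImageGrid,
        rays_per_bin: int = 10,
        psf: PSFModel | None = None,
    ):
        if rays_per_bin < 1:
            raise ValueError("rays_per_bin must be >= 1")
        if geometry.mode == "parallel2d" and grid.ndim != 2:
            raise ValueError("parallel2d geometry requires a 2D grid")
        if geometry.mode == "cylindrical3d" and grid.ndim != 3:
            raise ValueError("cylindrical3d geometry requires a 3D grid")
        self.geometry = geometry
        self.grid = grid
        self.rays_per_bin = int(rays_per_bin)
        self.psf = psf
        self._matrix: sparse.csr_matrix | None = None

    @property
    def sinogram_shape(self) -> tuple[int, ...]:
        g = self.geometry
        if g.mode == "parallel2d":
            return (g.n_views, g.n_tang)
        return (g.n_views, g.n_tang, self.grid.shape[2])

    @property
    def matrix(self) -> sparse.csr_matrix:
        """The transverse Siddon matrix (built lazily, cached)."""
        if self._matrix is None:
            self._matrix = _build_matrix(self.geometry, self.grid, self.rays_per_bin)
        return self._matrix

    def with_psf(self, psf: PSFModel | None) -> "SystemModel":
        """Same geometry/grid/matrix with a different PSF (matrix shared)."""
        m = SystemModel(self.geometry, self.grid, self.rays_per_bin, psf)
        m._matrix = self.matrix
        return m

    # -- raw (no PSF) linear maps ------------------------------------------

    def _project_raw(self, image: np.ndarray) -> np.ndarray:
        g = self.geometry
        if g.mode == "parallel2d":
            return (self.matrix @ image.ravel()).reshape(g.n_views, g.n_tang)
        nz = self.grid.shape[2]
        flat = image.reshape(-1, nz)  # (nx*ny, nz), C order keeps z last
        sino = self.matrix @ flat
        return sino.reshape(g.n_views, g.n_tang, nz)

    def _backproject_raw(self, sino: np.ndarray) -> np.ndarray:
        g = self.geometry
        if g.mode == "parallel2d":
            return (self.matrix.T @ sino.ravel()).reshape(self.grid.shape)
        nz = self.grid.shape[2]
        flat = sino.reshape(-1, nz)
        img = self.matrix.T @ flat
        return img.reshape(self.grid.shape)

    # -- public operators ---------------------------------------------------

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.shape != tuple(self.grid.shape):
            raise ValueError(
                f"image shape {image.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        if self.psf is not None:
            image = apply_psf(image, self.psf, self.grid)
        return self._project_raw(image)

    def back(self, sino: np.ndarray) -> np.ndarray:
        sino = np.asarray(sino, dtype=np.float64)
        if sino.shape != self.sinogram_shape:
            raise ValueError(
                f"sinogram shape {sino.shape} does not match geometry "
                f"{self.sinogram_shape}"
            )
        img = self._backproject_raw(sino)
        if self.psf is not None:
            img = apply_psf(img, self.psf, self.grid)
        return img


def forward_project(image: np.ndarray, model: SystemModel) -> np.ndarray:
    """Project an image to sinogram space (PSF blur first, if modelled)."""
    return model.forward(image)


def back_project(sino: np.ndarray, model: SystemModel) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`, including the PSF."""
    return model.back(sino)


def attenuation_factors(mu_image: np.ndarray, model: SystemModel) -> np.ndarray:
    """Per-bin survival probabilities exp(-integral mu dl), mu in 1/cm.

    The PSF is never applied to attenuation rays; path lengths traced in mm
    are converted to cm inside the exponent.
    """
    mu_image = np.asarray(mu_image, dtype=np.float64)
    if np.any(mu_image < 0):
        raise ValueError("attenuation coefficients must be nonnegative")
    raw = model.with_psf(None) if model.psf is not None else model
    line_integrals_mm = raw.forward(mu_image)
    return np.exp(-0.1 * line_integrals_mm)
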