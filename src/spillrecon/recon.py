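"""Ordered-subset EM reconstruction with PSF modelling and background
correction (BC) for spill-in from a segmented hot region.

The update, per subset, is the multiplicative EM step

    f_j <- f_j / sum_i H'_ij M_i * sum_i H'_ij [ y_i M_i / (M_i (H'f)_i + A_i + P_i) ]

where ``H'`` is the (optionally PSF-blurred) projector, ``M`` the
multiplicative term, ``A`` the additive (scatter + randoms) term and ``P``
the background term.  ``P`` is built once — segment the hot region, multiply
its mask into an early (default 5-iteration) OSEM+PSF reconstruction,
forward-project with ``H'`` and multiply by ``M`` — and then held fixed for
all BC iterations, so the corrected image excludes the hot region by
construction.

Post-filtering is applied only to the output; it never feeds back into the
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import SinogramSet
from .projection import PSFModel, SystemModel, apply_psf

__all__ = [
    "ReconConfig",
    "BackgroundSpec",
    "ReconResult",
    "osem_reconstruct",
    "make_background_term",
    "post_filter",
    "VARIANTS",
]

VARIANTS = ("OSEM", "OSEM_PSF", "OSEM_PSF_BC")


def _normalise_variant(variant: str) -> str:
    v = variant.strip().upper().replace("+", "_").replace("-", "_")
    if v not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return v


@dataclass
class BackgroundSpec:
    """Inputs for the background term: the hot-region mask S, the number of
    OSEM+PSF iterations N used for the source image f^(N), or a precomputed
    sinogram P."""

    hot_mask: np.ndarray
    source_recon_iterations: int = 5
    precomputed_P: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hot_mask = np.asarray(self.hot_mask).astype(bool)
        if self.source_recon_iterations < 1:
            raise ValueError("source_recon_iterations must be >= 1")


@dataclass
class ReconConfig:
    variant: str = "OSEM"
    n_subsets: int = 28
    n_full_iterations: int = 30
    psf: PSFModel | None = None
    post_filter_fwhm_mm: float | None = None
    bc: BackgroundSpec | None = None
    save_every: int | None = None
    track_loglik: bool = True

    def __post_init__(self) -> None:
        self.variant = _normalise_variant(self.variant)
        if self.n_subsets < 1 or self.n_full_iterations < 1:
            raise ValueError("n_subsets and n_full_iterations must be >= 1")
        if self.variant == "OSEM" and self.psf is not None:
            raise ValueError("plain OSEM models no PSF")
        if self.variant in ("OSEM_PSF", "OSEM_PSF_BC") and self.psf is None:
            raise ValueError(f"{self.variant} requires a PSF model")
        if self.variant == "OSEM_PSF_BC" and self.bc is None:
            raise ValueError("OSEM_PSF_BC requires a BackgroundSpec")


@dataclass
class ReconResult:
    """Image series and bookkeeping from one reconstruction."""

    images: dict[int, np.ndarray]  # unfiltered iterates at saved iterations
    final_unfiltered: np.ndarray
    final: np.ndarray  # post-filtered if a filter was configured
    loglik: list[float]
    config: ReconConfig
    background_term: np.ndarray | None = None

    def image(self, iteration: int | None = None, filtered: bool = False):
        if iteration is None:
            return self.final if filtered else self.final_unfiltered
        img = self.images[iteration]
        fwhm = self.config.post_filter_fwhm_mm
        if filtered and fwhm:
            return _isotropic_filter(img, fwhm, self._grid)
        return img


def _bit_reversed_order(n: int) -> list[int]:
    """Subset processing order: bit-reversed permutation (of the next power
    of two, filtered), spreading angular coverage across sub-iterations."""
    bits = max(1, int(np.ceil(np.log2(max(n, 2)))))
    order = []
    for i in range(1 << bits):
        r = int(bin(i)[2:].zfill(bits)[::-1], 2)
        if r < n:
            order.append(r)
    return order


def _subset_rows(n_views: int, n_tang: int, n_subsets: int) -> list[np.ndarray]:
    """Round-robin view assignment: subset s owns views v with v % S == s."""
    rows = []
    for s in range(n_subsets):
        views = np.arange(s, n_views, n_subsets)
        rows.append(
            (views[:, None] * n_tang + np.arange(n_tang)[None, :]).ravel()
        )
    return rows


class _OsemEngine:
    """Precomputed subset operators for repeated EM updates on one model."""

    def __init__(self, model: SystemModel, psf: PSFModel | None, n_subsets: int):
        g = model.geometry
        if g.n_views % n_subsets != 0:
            raise ValueError(
                f"n_subsets={n_subsets} must divide the view count {g.n_views}"
            )
        self.model = model
        self.grid = model.grid
        self.psf = psf
        self.n_subsets = n_subsets
        self.n_tang = g.n_tang
        self.nz = self.grid.shape[2] if self.grid.ndim == 3 else None
        H = model.matrix
        self._rows = _subset_rows(g.n_views, g.n_tang, n_subsets)
        self._Hs = [H[r] for r in self._rows]
        self._views = [np.arange(s, g.n_views, n_subsets) for s in range(n_subsets)]
        self.order = _bit_reversed_order(n_subsets)

    def _blur(self, img: np.ndarray) -> np.ndarray:
        if self.psf is None:
            return img
        return apply_psf(img, self.psf, self.grid)

    def sub_forward(self, s: int, image: np.ndarray) -> np.ndarray:
        img = self._blur(image)
        if self.nz is None:
            return self._Hs[s] @ img.ravel()
        return self._Hs[s] @ img.reshape(-1, self.nz)

    def sub_back(self, s: int, part: np.ndarray) -> np.ndarray:
        if self.nz is None:
            img = (self._Hs[s].T @ part.ravel()).reshape(self.grid.shape)
        else:
            img = (self._Hs[s].T @ part.reshape(-1, self.nz)).reshape(self.grid.shape)
        return self._blur(img)

    def sub_sino(self, s: int, sino: np.ndarray) -> np.ndarray:
        """Subset view of a full sinogram, flattened over (view, tang)."""
        part = sino[self._views[s]]
        if self.nz is None:
            return part.ravel()
        return part.reshape(-1, self.nz)

    def sensitivities(self, M: np.ndarray) -> list[np.ndarray]:
        return [self.sub_back(s, self.sub_sino(s, M)) for s in range(self.n_subsets)]


def _isotropic_filter(image: np.ndarray, fwhm_mm: float, grid) -> np.ndarray:
    return apply_psf(image, PSFModel(fwhm_mm, fwhm_mm), grid)


def post_filter(image: np.ndarray, fwhm_mm: float, grid) -> np.ndarray:
    """Isotropic Gaussian post-filter (identity for fwhm 0)."""
    if fwhm_mm is None or fwhm_mm == 0:
        return np.asarray(image, dtype=np.float64).copy()
    return _isotropic_filter(image, fwhm_mm, grid)


def make_background_term(
    bc: BackgroundSpec,
    sinos: SinogramSet,
    model: SystemModel,
    config: ReconConfig,
) -> np.ndarray:
    """Background sinogram P = M * H'(S * f^(N)) in prompt (counts) space.

    ``f^(N)`` is an internal OSEM+PSF reconstruction (no BC) of the same
    data at ``bc.source_recon_iterations`` full iterations, unless a
    precomputed P is supplied.
    """
    if bc.precomputed_P is not None:
        return np.asarray(bc.precomputed_P, dtype=np.float64)
    if not bc.hot_mask.any():
        warnings.warn(
            "empty hot mask: background term is zero (degenerates to OSEM+PSF)",
            stacklevel=2,
        )
        return np.zeros_like(sinos.y)
    source_cfg = ReconConfig(
        variant="OSEM_PSF",
        n_subsets=config.n_subsets,
        n_full_iterations=bc.source_recon_iterations,
        psf=config.psf,
        track_loglik=False,
    )
    source = osem_reconstruct(sinos, model, source_cfg)
    hot_image = np.where(bc.hot_mask, source.final_unfiltered, 0.0)
    psf_model = model.with_psf(config.psf)
    return sinos.M * psf_model.forward(hot_image)


def osem_reconstruct(
    sinos: SinogramSet,
    model: SystemModel,
    config: ReconConfig,
    initial: np.ndarray | None = None,
) -> ReconResult:
    """Run OSEM / OSEM+PSF / OSEM+PSF+BC on one noise realisation."""
    if np.any(sinos.A < 0) or np.any(sinos.M <= 0):
        raise ValueError("invalid additive or multiplicative term")
    psf = config.psf
    engine = _OsemEngine(model, psf, config.n_subsets)

    if config.variant == "OSEM_PSF_BC":
        P = make_background_term(config.bc, sinos, model, config)
    else:
        P = np.zeros_like(sinos.y)

    M, A, y = sinos.M, sinos.A, sinos.y
    sens = engine.sensitivities(M)
    total_sens = np.sum(sens, axis=0)
    support = total_sens > 0

    if initial is not None:
        f = np.asarray(initial, dtype=np.float64).copy()
        f[~support] = 0.0
    else:
        f = np.where(support, 1.0, 0.0)

    full_model = model.with_psf(psf)

    def loglik(fcur: np.ndarray) -> float:
        q = M * full_model.forward(fcur) + A + P
        pos = q > 0
        return float(np.sum(y[pos] * np.log(q[pos])) - q.sum())

    images: dict[int, np.ndarray] = {}
    logs: list[float] = []
    for it in range(1, config.n_full_iterations + 1):
        for s in engine.order:
            M_s = engine.sub_sino(s, M)
            proj = engine.sub_forward(s, f)
            q = M_s * proj + engine.sub_sino(s, A) + engine.sub_sino(s, P)
            y_s = engine.sub_sino(s, y)
            ratio = np.zeros_like(q)
            np.divide(y_s * M_s, q, out=ratio, where=q > 0)
            corr = engine.sub_back(s, ratio)
            sen = sens[s]
            f = np.where(sen > 0, f * corr / np.where(sen > 0, sen, 1.0), 0.0)
        if config.track_loglik:
            logs.append(loglik(f))
        if config.save_every and it % config.save_every == 0:
            images[it] = f.copy()
    images.setdefault(config.n_full_iterations, f.copy())

    final = post_filter(f, config.post_filter_fwhm_mm or 0.0, model.grid)
    result = ReconResult(
        images=images,
        final_unfiltered=f,
        final=final,
        loglik=logs,
        config=config,
        background_term=P if config.variant == "OSEM_PSF_BC" else None,
    )
    result._grid = model.grid
    return result
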