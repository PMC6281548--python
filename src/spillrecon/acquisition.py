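"""Analytical simulation of noisy PET acquisitions.

The forward model is ``E[y] = M * H'(x) + A`` with ``M`` the multiplicative
term (attenuation survival x constant normalisation), ``H'`` the PSF-blurred
projector, and ``A`` the additive term (expected scatter + randoms).  Counts
are scaled so that expected trues, scatter and randoms sum exactly to the
requested total, with scatter and randoms at their requested fractions, and
independent Poisson realisations are drawn with per-realisation seeds.

Scatter is a documented surrogate for a physical estimate: the emission is
blurred with a wide (default 40 mm FWHM) Gaussian, forward-projected and
scaled to the target fraction, reproducing scatter's low-frequency character
in projection space.  The reconstruction receives the *expected* additive
term, the idealisation appropriate to a simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .phantoms import EmissionPhantom
from .projection import (
    ProjectionGeometry,
    PSFModel,
    SystemModel,
    apply_psf,
    attenuation_factors,
)

__all__ = [
    "NoiseModel",
    "SinogramSet",
    "simulate_acquisition",
    "normalisation_sinogram",
    "save_sinogram_set",
    "load_sinogram_set",
]

SCATTER_SURROGATE_FWHM_MM = 40.0


@dataclass(frozen=True)
class NoiseModel:
    """Count level and contamination fractions of a simulated acquisition."""

    total_counts: float = 1.0e6
    scatter_fraction: float = 0.35
    randoms_fraction: float = 0.20
    n_realisations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        for f in (self.scatter_fraction, self.randoms_fraction):
            if not 0.0 <= f < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        if self.scatter_fraction + self.randoms_fraction >= 1.0:
            raise ValueError("scatter + randoms fractions must sum to < 1")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")


@dataclass
class SinogramSet:
    """One noise realisation plus the terms the reconstruction needs:
    prompts ``y``, multiplicative ``M``, additive ``A`` (expected
    scatter + randoms), all on one geometry."""

    y: np.ndarray
    M: np.ndarray
    A: np.ndarray
    geometry: ProjectionGeometry
    provenance: dict = field(default_factory=dict)
    expected_trues: np.ndarray | None = None
    expected_scatter: np.ndarray | None = None
    expected_randoms: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.y.shape != self.M.shape or self.y.shape != self.A.shape:
            raise ValueError("y, M and A must share one geometry/shape")
        if np.any(self.M <= 0):
            raise ValueError("multiplicative term must be strictly positive")
        if np.any(self.A < 0) or np.any(self.y < 0):
            raise ValueError("y and A must be nonnegative")


def normalisation_sinogram(
    geometry: ProjectionGeometry,
    model: SystemModel | None = None,
    value: float = 1.0,
) -> np.ndarray:
    """Constant normalisation sinogram (all bins equal ``value``).

    In a simulated acquisition the constant absorbs the global
    counts-per-activity calibration, so that the multiplicative term maps
    SUV-space projections to expected counts and the reconstruction comes
    out directly in SUV units.
    """
    if model is not None:
        return np.full(model.sinogram_shape, float(value))
    return np.full((geometry.n_views, geometry.n_tang), float(value))


def simulate_acquisition(
    phantom: EmissionPhantom,
    model: SystemModel,
    noise: NoiseModel,
    scatter_fwhm_mm: float = SCATTER_SURROGATE_FWHM_MM,
) -> list[SinogramSet]:
    """Simulate ``noise.n_realisations`` Poisson acquisitions of a phantom.

    Expected trues are attenuated PSF-blurred projections of the SUV image;
    scatter and randoms are scaled so that pre-noise expected trues +
    scatter + randoms equal ``total_counts`` exactly at the requested
    fractions.  Realisation ``k`` uses seed ``noise.seed + k``.
    """
    if model.psf is None:
        raise ValueError("simulation requires a PSF on the system model")
    acf = attenuation_factors(phantom.mu_image, model)
    trues = acf * model.forward(phantom.suv_image)
    total_trues = float(trues.sum())
    if total_trues <= 0:
        raise ValueError("phantom projects to zero counts everywhere")

    sf, rf = noise.scatter_fraction, noise.randoms_fraction
    # global counts-per-SUV calibration, absorbed into the constant
    # normalisation so the reconstruction is in SUV units
    count_scale = noise.total_counts * (1.0 - sf - rf) / total_trues
    trues = trues * count_scale

    if sf > 0:
        wide = PSFModel(fwhm_transverse=scatter_fwhm_mm, fwhm_axial=scatter_fwhm_mm)
        scatter_shape = model.with_psf(None).forward(
            apply_psf(phantom.suv_image, wide, model.grid)
        )
        scatter = scatter_shape * (noise.total_counts * sf / scatter_shape.sum())
    else:
        scatter = np.zeros_like(trues)

    randoms = np.full_like(trues, noise.total_counts * rf / trues.size)

    expected = trues + scatter + randoms
    M = acf * normalisation_sinogram(model.geometry, model, value=count_scale)
    A = scatter + randoms

    sets = []
    for k in range(noise.n_realisations):
        seed_k = int(noise.seed) + k
        rng = np.random.default_rng(seed_k)
        y = rng.poisson(expected).astype(np.float64)
        sets.append(
            SinogramSet(
                y=y,
                M=M,
                A=A,
                geometry=model.geometry,
                provenance={
                    "seed": seed_k,
                    "base_seed": int(noise.seed),
                    "realisation": k,
                    "total_counts": float(noise.total_counts),
                    "count_scale": float(count_scale),
                    "scatter_fraction": float(sf),
                    "randoms_fraction": float(rf),
                    "expected_trues_sum": float(trues.sum()),
                    "expected_scatter_sum": float(scatter.sum()),
                    "expected_randoms_sum": float(randoms.sum()),
                },
                expected_trues=trues,
                expected_scatter=scatter,
                expected_randoms=randoms,
            )
        )
    return sets


# ---------------------------------------------------------------------------
# HDF5 serialisation


def save_sinogram_set(sino: SinogramSet, path: str) -> None:
    with h5py.File(path, "w") as fh:
        for name in ("y", "M", "A"):
            fh.create_dataset(name, data=getattr(sino, name))
        g = fh.create_group("geometry")
        g.attrs["mode"] = sino.geometry.mode
        g.attrs["n_views"] = sino.geometry.n_views
        g.attrs["n_tang"] = sino.geometry.n_tang
        g.attrs["bin_size"] = sino.geometry.bin_size
        g.attrs["max_ring_difference"] = sino.geometry.max_ring_difference
        for key, val in sino.provenance.items():
            fh.attrs[key] = val


def load_sinogram_set(path: str) -> SinogramSet:
    with h5py.File(path, "r") as fh:
        g = fh["geometry"]
        geometry = ProjectionGeometry(
            n_views=int(g.attrs["n_views"]),
            n_tang=int(g.attrs["n_tang"]),
            bin_size=float(g.attrs["bin_size"]),
            mode=str(g.attrs["mode"]),
            max_ring_difference=int(g.attrs["max_ring_difference"]),
        )
        return SinogramSet(
            y=fh["y"][()],
            M=fh["M"][()],
            A=fh["A"][()],
            geometry=geometry,
            provenance={k: fh.attrs[k] for k in fh.attrs},
        )
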