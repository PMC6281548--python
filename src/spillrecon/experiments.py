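"""Config-driven experiment runners replicating the simulation studies at
desk scale: the bladder-activity sweep, the lesion-size sweep, the
segmentation-mismatch study and the system-resolution sweep.

Every runner is reproducible from its :class:`ExperimentConfig` plus seed
alone and emits a manifest (config hash, seed, package version) sufficient
for bit-identical re-execution.  Desk-scale defaults — a 2D 128x128 grid at
the scanner's 2.34-mm transverse voxel size, ~1e6 counts and 5 noise
realisations — keep a full study in the minutes range on one CPU; paper-
scale settings remain expressible through the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import metrics
from .acquisition import NoiseModel, simulate_acquisition
from .grids import ImageGrid
from .phantoms import (
    BladderTimeCourse,
    EmissionPhantom,
    grow_bladder,
    make_pelvic_phantom,
    region_mask,
)
from .projection import ProjectionGeometry, PSFModel, SystemModel
from .recon import BackgroundSpec, ReconConfig, osem_reconstruct, post_filter

__all__ = [
    "ExperimentConfig",
    "run_shell_study",
    "run_bladder_sweep",
    "run_lesion_size_sweep",
    "run_segmentation_mismatch",
    "run_resolution_sweep",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a study: phantom, geometry, noise,
    reconstruction settings and metrics requests."""

    # grid / phantom
    grid_shape: tuple[int, ...] = (128, 128)
    voxel_size_mm: tuple[float, ...] = (2.34, 2.34)
    bladder_suvs: tuple[float, ...] = (8.5, 19.3, 33.8, 55.5)
    bladder_volume_ml: float = 500.0
    lesion_diameter_mm: float = 10.0
    lesion_distances_mm: tuple[float, float, float] = (25.0, 35.0, 15.0)
    lesion_suv: float = 8.0
    background_suv: float = 1.0
    background_lesion_distance_mm: float = 70.0
    # geometry / projector
    n_views: int = 168
    n_tang: int = 180
    bin_size_mm: float = 2.0
    rays_per_bin: int = 10
    psf_fwhm_mm: tuple[float, float] = (4.2, 5.7)
    # noise
    total_counts: float = 1.0e6
    scatter_fraction: float = 0.35
    randoms_fraction: float = 0.20
    n_realisations: int = 5
    # reconstruction
    n_subsets: int = 28
    n_iterations: int = 30
    bc_source_iterations: int = 5
    post_filter_fwhm_mm: float = 4.0
    variants: tuple[str, ...] = ("OSEM", "OSEM_PSF", "OSEM_PSF_BC")
    # shells
    shell_n_max: int = 10
    shell_step: int = 2
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: list(v) if isinstance(v, tuple) else v for k, v in d.items()
        }

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def manifest(self) -> dict:
        from . import __version__

        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return {
            "config": self.as_dict(),
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "spillrecon_version": __version__,
        }


def _tiny_preset(**over) -> ExperimentConfig:
    """Small instance for smoke tests; not a study condition."""
    base = dict(
        grid_shape=(48, 48),
        voxel_size_mm=(4.0, 4.0),
        n_views=24,
        n_tang=56,
        bin_size_mm=4.0,
        rays_per_bin=2,
        total_counts=2.0e5,
        n_realisations=2,
        n_subsets=4,
        n_iterations=4,
        bc_source_iterations=2,
        bladder_volume_ml=150.0,
        lesion_distances_mm=(18.0, 26.0, 12.0),
        background_lesion_distance_mm=45.0,
    )
    base.update(over)
    return ExperimentConfig(**base)


# ---------------------------------------------------------------------------
# shared plumbing


def _grid(config: ExperimentConfig) -> ImageGrid:
    return ImageGrid(config.grid_shape, config.voxel_size_mm)


def _geometry(config: ExperimentConfig) -> ProjectionGeometry:
    mode = "parallel2d" if len(config.grid_shape) == 2 else "cylindrical3d"
    return ProjectionGeometry(
        n_views=config.n_views,
        n_tang=config.n_tang,
        bin_size=config.bin_size_mm,
        mode=mode,
    )


def _psf(config: ExperimentConfig) -> PSFModel:
    return PSFModel(*config.psf_fwhm_mm)


def _phantom(config: ExperimentConfig, bladder_suv: float) -> EmissionPhantom:
    return make_pelvic_phantom(
        _grid(config),
        bladder_suv=bladder_suv,
        bladder_volume_ml=config.bladder_volume_ml,
        lesion_diameter_mm=config.lesion_diameter_mm,
        lesion_distances_mm=config.lesion_distances_mm,
        lesion_suv=config.lesion_suv,
        background_suv=config.background_suv,
        background_lesion_distance_mm=config.background_lesion_distance_mm,
    )


def _recon_config(config: ExperimentConfig, variant: str, bladder_mask) -> ReconConfig:
    psf = _psf(config)
    variant = variant.upper().replace("+", "_")
    return ReconConfig(
        variant=variant,
        n_subsets=config.n_subsets,
        n_full_iterations=config.n_iterations,
        psf=None if variant == "OSEM" else psf,
        post_filter_fwhm_mm=config.post_filter_fwhm_mm,
        bc=(
            BackgroundSpec(bladder_mask, config.bc_source_iterations)
            if variant == "OSEM_PSF_BC"
            else None
        ),
        track_loglik=False,
    )


def _simulate(config: ExperimentConfig, phantom: EmissionPhantom, model: SystemModel,
              seed_offset: int = 0):
    noise = NoiseModel(
        total_counts=config.total_counts,
        scatter_fraction=config.scatter_fraction,
        randoms_fraction=config.randoms_fraction,
        n_realisations=config.n_realisations,
        seed=config.seed + seed_offset,
    )
    return simulate_acquisition(phantom, model, noise)


def _reconstruct_mean(config, variant, sinos, model, bladder_mask):
    """Mean unfiltered and mean filtered image over realisations, plus the
    per-realisation filtered images (for SUV statistics)."""
    rc = _recon_config(config, variant, bladder_mask)
    finals_unf, finals_f = [], []
    for ss in sinos:
        res = osem_reconstruct(ss, model, rc)
        finals_unf.append(res.final_unfiltered)
        finals_f.append(res.final)
    mean_unf = np.mean(finals_unf, axis=0)
    mean_f = np.mean(finals_f, axis=0)
    return mean_unf, mean_f, finals_f


def _lesion_stats(config, phantom, images, grid):
    out = {}
    for name in ("L1", "L2", "L3", "B"):
        spec = phantom.region(name)
        roi = metrics.ROISpec(spec.centre, config.lesion_diameter_mm, name)
        out[name] = metrics.suv_stats(images, roi, spec.suv, grid)
    return out


# ---------------------------------------------------------------------------
# studies


def run_shell_study(config: ExperimentConfig, bladder_suv: float | None = None) -> dict:
    """Shell spill-in analysis around the bladder for every variant, on the
    mean image over realisations, with and without the post-filter."""
    suv = bladder_suv if bladder_suv is not None else max(config.bladder_suvs)
    grid = _grid(config)
    phantom = _phantom(config, suv)
    model = SystemModel(_geometry(config), grid, config.rays_per_bin, _psf(config))
    sinos = _simulate(config, phantom, model)
    bladder_mask = region_mask(phantom, "bladder")
    shells = metrics.dilate_shells(bladder_mask, config.shell_n_max, config.shell_step)

    # truth for BC has the hot region removed by construction
    truth = phantom.suv_image
    truth_no_bladder = np.where(bladder_mask, 0.0, truth)
    hot_ref = float(truth[bladder_mask].mean())

    report = {"bladder_suv": suv, "variants": {}, "manifest": config.manifest()}
    for variant in config.variants:
        mean_unf, mean_f, finals_f = _reconstruct_mean(
            config, variant, sinos, model, bladder_mask
        )
        t = truth_no_bladder if variant == "OSEM_PSF_BC" else truth
        sa_unf = metrics.shell_spill_analysis(
            t, mean_unf, bladder_mask, shells, reference_value=hot_ref
        )
        sa_f = metrics.shell_spill_analysis(
            t, mean_f, bladder_mask, shells, reference_value=hot_ref
        )
        stats = _lesion_stats(config, phantom, finals_f, grid)
        report["variants"][variant] = {
            "unfiltered": sa_unf.to_dict(),
            "filtered": sa_f.to_dict(),
            "lesion_stats": {
                k: {
                    "mean_suv_max": v.mean_max,
                    "mean_suv_mean": v.mean_mean,
                    "bias_max_percent": v.bias_max,
                    "bias_mean_percent": v.bias_mean,
                    "sem_max": v.sem_max,
                }
                for k, v in stats.items()
            },
        }
    return report


def run_bladder_sweep(config: ExperimentConfig) -> dict:
    """Per-variant, per-lesion SUV statistics across the bladder-SUV sweep,
    with the percent change between the lowest and highest bladder SUV."""
    if len(config.bladder_suvs) < 2:
        raise ValueError("bladder sweep needs at least two bladder SUVs")
    grid = _grid(config)
    model = SystemModel(_geometry(config), grid, config.rays_per_bin, _psf(config))
    per_suv: dict[float, dict] = {}
    # paired design: the same realisation seeds are reused at every bladder
    # SUV so the percent change is a paired contrast
    for suv in config.bladder_suvs:
        phantom = _phantom(config, suv)
        sinos = _simulate(config, phantom, model)
        bladder_mask = region_mask(phantom, "bladder")
        per_suv[suv] = {}
        for variant in config.variants:
            _, _, finals_f = _reconstruct_mean(
                config, variant, sinos, model, bladder_mask
            )
            per_suv[suv][variant] = _lesion_stats(config, phantom, finals_f, grid)

    lo, hi = min(config.bladder_suvs), max(config.bladder_suvs)
    changes = {}
    for variant in config.variants:
        changes[variant] = {}
        for lesion in ("L1", "L2", "L3", "B"):
            s_lo, s_hi = per_suv[lo][variant][lesion], per_suv[hi][variant][lesion]
            changes[variant][lesion] = {
                "delta_suv_max_percent": metrics.suv_change(
                    s_lo.mean_max, s_hi.mean_max
                ),
                "delta_suv_mean_percent": metrics.suv_change(
                    s_lo.mean_mean, s_hi.mean_mean
                ),
            }
    return {
        "bladder_suvs": list(config.bladder_suvs),
        "suv_stats": {
            suv: {
                var: {
                    les: {
                        "mean_suv_max": st.mean_max,
                        "mean_suv_mean": st.mean_mean,
                        "bias_max_percent": st.bias_max,
                        "bias_mean_percent": st.bias_mean,
                        "sem_max": st.sem_max,
                        "sem_mean": st.sem_mean,
                    }
                    for les, st in d2.items()
                }
                for var, d2 in d1.items()
            }
            for suv, d1 in per_suv.items()
        },
        "percent_change": changes,
        "manifest": config.manifest(),
    }


def run_lesion_size_sweep(
    config: ExperimentConfig,
    diameters_mm: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0),
    bladder_suv: float | None = None,
    variant: str = "OSEM",
) -> dict:
    """Lesion SUV recovery versus lesion diameter (spill-out) at fixed
    bladder activity, including the distant background lesion B."""
    suv = bladder_suv if bladder_suv is not None else max(config.bladder_suvs)
    grid = _grid(config)
    model = SystemModel(_geometry(config), grid, config.rays_per_bin, _psf(config))
    out: dict[float, dict] = {}
    for i, diam in enumerate(diameters_mm):
        cfg = replace(config, lesion_diameter_mm=diam)
        phantom = _phantom(cfg, suv)
        sinos = _simulate(cfg, phantom, model, seed_offset=100 * i)
        bladder_mask = region_mask(phantom, "bladder")
        _, _, finals_f = _reconstruct_mean(cfg, variant, sinos, model, bladder_mask)
        stats = _lesion_stats(cfg, phantom, finals_f, grid)
        out[diam] = {
            les: {"mean_suv_max": st.mean_max, "mean_suv_mean": st.mean_mean}
            for les, st in stats.items()
        }
    return {
        "bladder_suv": suv,
        "variant": variant,
        "diameters_mm": list(diameters_mm),
        "per_diameter": out,
        "manifest": config.manifest(),
    }


def run_segmentation_mismatch(
    config: ExperimentConfig,
    course: BladderTimeCourse | None = None,
    timepoints: tuple[float, ...] | None = None,
) -> dict:
    """Background correction with a stale mask: the bladder grows over the
    scan but the mask segmented at the first timepoint is used throughout.
    Reports the residual activity in the unmasked bladder rim."""
    course = course or BladderTimeCourse.default_90min()
    timepoints = timepoints or course.timepoints
    grid = _grid(config)
    model = SystemModel(_geometry(config), grid, config.rays_per_bin, _psf(config))
    base = make_pelvic_phantom(
        grid,
        bladder_suv=course.suvs[0],
        bladder_volume_ml=course.volumes_ml[0],
        lesion_diameter_mm=config.lesion_diameter_mm,
        lesion_distances_mm=config.lesion_distances_mm,
        lesion_suv=config.lesion_suv,
        background_suv=config.background_suv,
        background_lesion_distance_mm=config.background_lesion_distance_mm,
    )
    stale_mask = region_mask(base, "bladder")
    out = {}
    for i, t in enumerate(timepoints):
        phantom = grow_bladder(base, course, t)
        true_mask = region_mask(phantom, "bladder")
        sinos = _simulate(config, phantom, model, seed_offset=10 * i)
        rc = _recon_config(config, "OSEM_PSF_BC", stale_mask)
        res = osem_reconstruct(sinos[0], model, rc)
        rim = true_mask & ~stale_mask
        rim_mean = float(res.final[rim].mean()) if rim.any() else 0.0
        out[float(t)] = {
            "rim_voxels": int(rim.sum()),
            "rim_mean_activity": rim_mean,
            "bladder_suv": phantom.region("bladder").suv,
        }
    return {"timepoints": [float(t) for t in timepoints], "residual": out,
            "manifest": config.manifest()}


def run_resolution_sweep(
    config: ExperimentConfig,
    fwhms_mm: tuple[float, ...] = (0.0, 2.0, 4.2, 6.0, 8.0),
    bladder_suv: float | None = None,
) -> dict:
    """Shell-1 spill-in (d-bar in the innermost shell) versus the simulated
    system resolution, reconstructed with plain OSEM."""
    suv = bladder_suv if bladder_suv is not None else max(config.bladder_suvs)
    grid = _grid(config)
    geom = _geometry(config)
    out = {}
    for fwhm in fwhms_mm:
        cfg = replace(config, psf_fwhm_mm=(fwhm, fwhm))
        phantom = _phantom(cfg, suv)
        model = SystemModel(geom, grid, cfg.rays_per_bin, PSFModel(fwhm, fwhm))
        sinos = _simulate(cfg, phantom, model)
        bladder_mask = region_mask(phantom, "bladder")
        shells = metrics.dilate_shells(bladder_mask, cfg.shell_n_max, cfg.shell_step)
        rc = ReconConfig(
            variant="OSEM",
            n_subsets=cfg.n_subsets,
            n_full_iterations=cfg.n_iterations,
            post_filter_fwhm_mm=None,
            track_loglik=False,
        )
        mean_img = np.mean(
            [osem_reconstruct(ss, model, rc).final_unfiltered for ss in sinos], axis=0
        )
        sa = metrics.shell_spill_analysis(
            phantom.suv_image, mean_img, bladder_mask, shells
        )
        out[float(fwhm)] = {"shell1_d_bar_percent": sa.d_bar[0]}
    return {"fwhms_mm": [float(f) for f in fwhms_mm], "per_fwhm": out,
            "manifest": config.manifest()}
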