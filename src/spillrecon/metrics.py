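"""Quantitative evaluation: SUV statistics, percent SUV change, morphological
shell spill-in analysis with Bland-Altman limits of agreement, and
contrast-to-noise ratio.

Shell analysis quantifies spill-in from a hot region: the hot mask is
dilated with a Euclidean-ball structuring element (in voxel units), ring
shells between successive dilation radii are extracted, and per-voxel
percent differences between reconstruction and truth are summarised per
shell as mean (d-bar), SD (n-1 denominator) and the 95% limits of agreement
d-bar +/- 1.96 SD.

The percent-difference denominator is not uniquely fixed by convention; the
default normalises by the hot region's true SUV, which keeps shells of true
value ~0 well defined and reads as "spill-in as a percentage of the hot
activity".  Per-voxel normalisation by the local true value is available via
``normalisation='true_voxel'``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

__all__ = [
    "ROISpec",
    "SUVStats",
    "ShellAnalysis",
    "CNRReport",
    "roi_mask",
    "suv_stats",
    "suv_change",
    "dilate_shells",
    "shell_spill_analysis",
    "cnr",
    "normalised_shell_activity",
    "write_suv_csv",
]


@dataclass(frozen=True)
class ROISpec:
    """Spherical ROI, equal in diameter to the lesion it measures."""

    centre: tuple[float, ...]
    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")


def roi_mask(roi: ROISpec, grid: ImageGrid) -> np.ndarray:
    """Voxels whose centres fall inside the ROI sphere (centre-inside rule)."""
    coords = grid.coordinate_images()
    r = roi.diameter / 2.0
    q = sum((c - roi.centre[a]) ** 2 for a, c in enumerate(coords))
    mask = q <= r * r
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} covers no voxel centres")
    return mask


@dataclass
class SUVStats:
    """Per-realisation SUVmax/SUVmean and their summary statistics."""

    suv_max: np.ndarray  # f_i, per realisation
    suv_mean: np.ndarray
    true_suv: float
    n_realisations: int
    mean_max: float = field(init=False)
    mean_mean: float = field(init=False)
    sd_max: float = field(init=False)
    sd_mean: float = field(init=False)
    sem_max: float = field(init=False)
    sem_mean: float = field(init=False)
    bias_max: float = field(init=False)
    bias_mean: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.n_realisations
        if n < 1 or len(self.suv_max) != n or len(self.suv_mean) != n:
            raise ValueError("need one SUV value per realisation")
        self.mean_max = float(np.mean(self.suv_max))
        self.mean_mean = float(np.mean(self.suv_mean))
        ddof = 1 if n > 1 else 0
        self.sd_max = float(np.std(self.suv_max, ddof=ddof))
        self.sd_mean = float(np.std(self.suv_mean, ddof=ddof))
        self.sem_max = self.sd_max / np.sqrt(n)
        self.sem_mean = self.sd_mean / np.sqrt(n)
        self.bias_max = (self.mean_max - self.true_suv) / self.true_suv * 100.0
        self.bias_mean = (self.mean_mean - self.true_suv) / self.true_suv * 100.0


def suv_stats(
    images: list[np.ndarray] | np.ndarray,
    roi: ROISpec,
    true_suv: float,
    grid: ImageGrid,
) -> SUVStats:
    """SUVmax/SUVmean over one ROI across noise realisations, with mean,
    SD (n-1), SEM = SD/sqrt(N) and percent bias (mean - T)/T x 100."""
    mask = roi_mask(roi, grid)
    images = [np.asarray(im) for im in images]
    smax = np.array([float(im[mask].max()) for im in images])
    smean = np.array([float(im[mask].mean()) for im in images])
    return SUVStats(
        suv_max=smax,
        suv_mean=smean,
        true_suv=float(true_suv),
        n_realisations=len(images),
    )


def suv_change(suv_low: float, suv_high: float) -> float:
    """Signed percent change (high - low)/low x 100."""
    if suv_low == 0:
        raise ZeroDivisionError("reference SUV must be nonzero")
    return (suv_high - suv_low) / suv_low * 100.0


# ---------------------------------------------------------------------------
# morphological shells


def dilate_shells(
    mask: np.ndarray, n_max: int = 10, step: int = 2
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Ring shells around a mask from Euclidean-ball dilations in voxel units.

    Returns ``[((lo, hi), shell_mask), ...]`` where shell (lo, hi) holds the
    voxels reached by dilation radius ``hi`` but not ``hi - step`` (e.g.
    shells 1-2, 3-4, ... for step 2).  Shells are pairwise disjoint and
    exclude the original mask.  Voxel anisotropy is ignored, matching a
    "dilate by n voxels" reading.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if step < 1 or n_max < step:
        raise ValueError("need n_max >= step >= 1")
    # distance (in voxel units) from each background voxel to the mask:
    # dilation by a ball of radius n is exactly {distance <= n}
    dist = ndimage.distance_transform_edt(~mask)
    shells = []
    prev = 0
    for hi in range(step, n_max + 1, step):
        shell = (dist > prev) & (dist <= hi) & ~mask
        shells.append(((prev + 1, hi), shell))
        prev = hi
    return shells


@dataclass
class ShellAnalysis:
    """Per-shell spill-in statistics: d-bar, SD over shell voxels, and the
    95% limits of agreement d-bar +/- 1.96 SD."""

    shell_ranges: list[tuple[int, int]]
    d_bar: list[float]
    sd: list[float]
    loa: list[tuple[float, float]]
    d_k: list[np.ndarray]
    normalisation: str

    def to_dict(self) -> dict:
        return {
            "normalisation": self.normalisation,
            "shells": [
                {
                    "range_voxels": list(rng),
                    "d_bar_percent": db,
                    "sd_percent": sd,
                    "loa_percent": list(loa),
                    "n_voxels": int(dk.size),
                }
                for rng, db, sd, loa, dk in zip(
                    self.shell_ranges, self.d_bar, self.sd, self.loa, self.d_k
                )
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def shell_spill_analysis(
    true_image: np.ndarray,
    recon_image: np.ndarray,
    hot_mask: np.ndarray,
    shells: list[tuple[tuple[int, int], np.ndarray]],
    normalisation: str = "hot_suv",
    reference_value: float | None = None,
) -> ShellAnalysis:
    """Per-shell percent activity difference between reconstruction and truth.

    ``normalisation='hot_suv'`` (default): d_k = (recon_k - true_k) / T_hot
    x 100 with T_hot the mean true value inside the hot mask (or
    ``reference_value``).  ``normalisation='true_voxel'``: per-voxel
    denominator true_k.
    """
    true_image = np.asarray(true_image, dtype=np.float64)
    recon_image = np.asarray(recon_image, dtype=np.float64)
    if true_image.shape != recon_image.shape:
        raise ValueError("true and reconstructed images must share one grid")
    hot_mask = np.asarray(hot_mask).astype(bool)

    ranges, dbars, sds, loas, dks = [], [], [], [], []
    for rng, shell in shells:
        if not shell.any():
            raise ValueError(f"shell {rng} is empty")
        diff = recon_image[shell] - true_image[shell]
        if normalisation == "hot_suv":
            ref = (
                float(reference_value)
                if reference_value is not None
                else float(true_image[hot_mask].mean())
            )
            if ref == 0:
                raise ValueError("hot-region reference value is zero")
            d_k = diff / ref * 100.0
        elif normalisation == "true_voxel":
            tv = true_image[shell]
            if np.any(tv == 0):
                raise ValueError(
                    "per-voxel normalisation undefined where true value is zero"
                )
            d_k = diff / tv * 100.0
        else:
            raise ValueError(f"unknown normalisation {normalisation!r}")
        n = d_k.size
        d_bar = float(d_k.mean())
        sd = float(np.sqrt(np.sum((d_k - d_bar) ** 2) / (n - 1))) if n > 1 else 0.0
        ranges.append(rng)
        dbars.append(d_bar)
        sds.append(sd)
        loas.append((d_bar - 1.96 * sd, d_bar + 1.96 * sd))
        dks.append(d_k)
    return ShellAnalysis(
        shell_ranges=ranges,
        d_bar=dbars,
        sd=sds,
        loa=loas,
        d_k=dks,
        normalisation=normalisation,
    )


# ---------------------------------------------------------------------------
# CNR and normalised shell activity


@dataclass
class CNRReport:
    cnr: float
    mean_sphere: float
    mean_background: float
    sd_sphere: float
    sd_background: float


def cnr(
    sphere_mask: np.ndarray, background_mask: np.ndarray, image: np.ndarray
) -> CNRReport:
    """Contrast-to-noise ratio between a sphere and its matched background:
    (mean_s - mean_b) / sqrt(sd_s^2 + sd_b^2)."""
    sphere_mask = np.asarray(sphere_mask).astype(bool)
    background_mask = np.asarray(background_mask).astype(bool)
    if not sphere_mask.any() or not background_mask.any():
        raise ValueError("masks must be nonempty")
    image = np.asarray(image, dtype=np.float64)
    ms, mb = float(image[sphere_mask].mean()), float(image[background_mask].mean())
    ss = float(np.std(image[sphere_mask], ddof=1)) if sphere_mask.sum() > 1 else 0.0
    sb = (
        float(np.std(image[background_mask], ddof=1))
        if background_mask.sum() > 1
        else 0.0
    )
    denom = np.sqrt(ss**2 + sb**2)
    if denom == 0:
        raise ZeroDivisionError("both ROI standard deviations are zero")
    return CNRReport(
        cnr=(ms - mb) / denom,
        mean_sphere=ms,
        mean_background=mb,
        sd_sphere=ss,
        sd_background=sb,
    )


def normalised_shell_activity(
    recon_image: np.ndarray,
    hot_mask: np.ndarray,
    shells: list[tuple[tuple[int, int], np.ndarray]],
    reference_value: float,
) -> list[float]:
    """Mean shell activity divided by a reference activity, per shell."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    recon_image = np.asarray(recon_image, dtype=np.float64)
    return [float(recon_image[shell].mean()) / reference_value for _, shell in shells]


def write_suv_csv(path: str, rows: list[dict]) -> None:
    """Per-lesion report rows (variant, lesion, iteration, SUV stats) as CSV."""
    if not rows:
        raise ValueError("no rows to write")
    keys = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
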