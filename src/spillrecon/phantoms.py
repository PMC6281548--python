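"""Synthetic emission/attenuation phantoms.

Two families are provided, both piecewise-constant in SUV:

* a pelvic-like phantom — a hot spherical bladder inside a soft-tissue body,
  with small satellite lesions at configurable distances from the bladder
  surface and one distant "background" lesion unaffected by spill-in;
* a NEMA-IQ-like phantom — a central hot cylinder ("bottle") surrounded by a
  ring of six fillable spheres of graded diameters, plus six matched cold
  background ROIs used for contrast-to-noise analysis.

A voxel belongs to a region iff its *centre* lies inside the analytic shape;
partial-volume effects are the business of the projector and reconstruction,
not the phantom.  Regions are painted in list order, later regions
overwriting earlier ones, so every voxel with label ``r`` carries exactly
``r.suv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .grids import ImageGrid

__all__ = [
    "RegionSpec",
    "EmissionPhantom",
    "BladderTimeCourse",
    "build_phantom",
    "make_pelvic_phantom",
    "make_nema_phantom",
    "grow_bladder",
    "region_mask",
    "save_phantom",
    "load_phantom",
]

#: linear attenuation coefficient of water at 511 keV, 1/cm
MU_WATER = 0.096


@dataclass(frozen=True)
class RegionSpec:
    """One analytic region: a shape, its SUV and its attenuation.

    ``size`` is the diameter in mm for spheres, ``(diameter, height)`` for
    cylinders (axis along z), and per-axis diameters for ellipsoids.  Kind
    ``background`` paints an ellipsoid-shaped support and is used for the
    soft-tissue body.
    """

    label: str
    kind: str  # sphere | cylinder | ellipsoid | background
    centre: tuple[float, ...]
    size: float | tuple[float, ...]
    suv: float
    mu: float = MU_WATER

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "ellipsoid", "background"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.suv < 0:
            raise ValueError("suv must be nonnegative")
        sizes = np.atleast_1d(np.asarray(self.size, dtype=float))
        if np.any(sizes <= 0):
            raise ValueError("region sizes must be positive")
        object.__setattr__(self, "centre", tuple(float(c) for c in self.centre))

    def radii(self, ndim: int) -> np.ndarray:
        """Per-axis semi-axes in mm."""
        if self.kind == "sphere":
            return np.full(ndim, float(np.atleast_1d(self.size)[0]) / 2.0)
        if self.kind == "cylinder":
            d, h = np.atleast_1d(self.size)[:2] if np.size(self.size) > 1 else (
                float(np.atleast_1d(self.size)[0]),
                np.inf,
            )
            r = np.full(ndim, float(d) / 2.0)
            if ndim == 3:
                r[2] = float(h) / 2.0
            return r
        sizes = np.atleast_1d(np.asarray(self.size, dtype=float)) / 2.0
        if sizes.size == 1:
            return np.full(ndim, sizes[0])
        return sizes[:ndim]


@dataclass
class EmissionPhantom:
    """Voxelised ground truth: SUV image, labels, region specs, attenuation."""

    grid: ImageGrid
    suv_image: np.ndarray
    label_image: np.ndarray
    regions: list[RegionSpec]
    mu_image: np.ndarray
    label_codes: dict[str, int] = field(default_factory=dict)
    rois: list[RegionSpec] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def region(self, label: str) -> RegionSpec:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"no region labelled {label!r}")

    def true_suv(self, label: str) -> float:
        """Ground-truth SUV of a region, from its spec (never re-estimated)."""
        return self.region(label).suv


@dataclass(frozen=True)
class BladderTimeCourse:
    """Bladder filling during a scan: volume and SUV per timepoint (minutes)."""

    timepoints: tuple[float, ...]
    volumes_ml: tuple[float, ...]
    suvs: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("volumes_ml", "suvs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != t.size:
                raise ValueError(f"{name} must match timepoints in length")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")

    def at(self, t: float) -> tuple[float, float]:
        tp = np.asarray(self.timepoints, dtype=float)
        idx = np.flatnonzero(np.isclose(tp, float(t)))
        if idx.size == 0:
            raise ValueError(f"timepoint {t} not in course {self.timepoints}")
        i = int(idx[0])
        return float(self.volumes_ml[i]), float(self.suvs[i])

    @classmethod
    def default_90min(cls) -> "BladderTimeCourse":
        """Filling course over a typical 90-min scan (1/10/30/45/90 min)."""
        return cls(
            timepoints=(1.0, 10.0, 30.0, 45.0, 90.0),
            volumes_ml=(100.0, 150.0, 250.0, 350.0, 500.0),
            suvs=(8.5, 19.3, 33.8, 44.6, 55.5),
        )


# ---------------------------------------------------------------------------
# rasterisation


def _inside(region: RegionSpec, grid: ImageGrid) -> np.ndarray:
    coords = grid.coordinate_images()
    ndim = grid.ndim
    radii = region.radii(ndim)
    rel = [(c - region.centre[a]) for a, c in enumerate(coords)]
    if region.kind == "cylinder" and ndim == 3:
        transverse = (rel[0] / radii[0]) ** 2 + (rel[1] / radii[1]) ** 2 <= 1.0
        axial = np.abs(rel[2]) <= radii[2]
        return transverse & axial
    q = sum((r / rad) ** 2 for r, rad in zip(rel, radii))
    return q <= 1.0


def build_phantom(
    grid: ImageGrid,
    regions: list[RegionSpec],
    rois: list[RegionSpec] | None = None,
    paint_order: list[str] | None = None,
) -> EmissionPhantom:
    """Rasterise regions (later-painted regions overwrite) onto a grid.

    Label codes follow the list order; ``paint_order`` (labels) can override
    the painting sequence, e.g. to let a grown bladder swallow a lesion.
    """
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        raise ValueError("region labels must be unique")
    suv = np.zeros(grid.shape, dtype=np.float64)
    mu = np.zeros(grid.shape, dtype=np.float64)
    lab = np.zeros(grid.shape, dtype=np.int32)
    codes = {r.label: i + 1 for i, r in enumerate(regions)}
    by_label = {r.label: r for r in regions}
    sequence = [by_label[l] for l in paint_order] if paint_order else regions
    if paint_order and set(paint_order) != set(labels):
        raise ValueError("paint_order must cover every region exactly once")
    for r in sequence:
        m = _inside(r, grid)
        suv[m] = r.suv
        mu[m] = r.mu
        lab[m] = codes[r.label]
    return EmissionPhantom(
        grid=grid,
        suv_image=suv,
        label_image=lab,
        regions=list(regions),
        mu_image=mu,
        label_codes=codes,
        rois=list(rois or []),
    )


def region_mask(phantom: EmissionPhantom, label: str | int) -> np.ndarray:
    """Binary mask of one labelled region (exactly ``label_image == code``)."""
    if isinstance(label, str):
        if label not in phantom.label_codes:
            raise KeyError(f"unknown region label {label!r}")
        code = phantom.label_codes[label]
    else:
        code = int(label)
        if code not in phantom.label_codes.values():
            raise KeyError(f"unknown region code {code}")
    return phantom.label_image == code


# ---------------------------------------------------------------------------
# pelvic phantom


def sphere_radius_for_volume(volume_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume (1 ml = 1000 mm^3)."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _check_inside_grid(region: RegionSpec, grid: ImageGrid) -> None:
    radii = region.radii(grid.ndim)
    for a in range(grid.ndim):
        lo = grid.origin[a] - grid.voxel_size[a] / 2.0
        hi = lo + grid.shape[a] * grid.voxel_size[a]
        if region.centre[a] - radii[a] < lo or region.centre[a] + radii[a] > hi:
            raise ValueError(f"region {region.label!r} extends outside the grid")


def make_pelvic_phantom(
    grid: ImageGrid,
    bladder_suv: float = 55.5,
    bladder_volume_ml: float = 500.0,
    lesion_diameter_mm: float = 10.0,
    lesion_distances_mm: tuple[float, float, float] = (25.0, 35.0, 15.0),
    lesion_suv: float = 8.0,
    background_suv: float = 1.0,
    background_lesion_distance_mm: float = 70.0,
    bladder_centre: tuple[float, ...] | None = None,
) -> EmissionPhantom:
    """Pelvic-like phantom: hot bladder, three satellite lesions, one distant
    background lesion B, inside a soft-tissue body.

    ``lesion_distances_mm`` are surface-to-surface distances from the bladder
    for lesions L1..L3 (default: L3 proximal at 15 mm, L1/L2 distant).  On a
    2D grid the bladder is a disc whose radius equals that of the
    equal-volume 3D sphere.
    """
    ndim = grid.ndim
    extent = [grid.shape[a] * grid.voxel_size[a] for a in range(ndim)]
    if bladder_centre is None:
        bladder_centre = tuple([-0.07 * extent[0], -0.05 * extent[1]][:2]) + (
            (0.0,) if ndim == 3 else ()
        )
    r_b = sphere_radius_for_volume(bladder_volume_ml)
    r_l = lesion_diameter_mm / 2.0

    body_size = tuple(0.92 * e for e in extent)
    body = RegionSpec("body", "background", (0.0,) * ndim, body_size, background_suv)
    bladder = RegionSpec("bladder", "sphere", bladder_centre, 2 * r_b, bladder_suv)

    # lesion directions in the transverse plane; B opposite the lesion cluster
    angles = {"L1": 100.0, "L2": 160.0, "L3": -35.0, "B": 10.0}
    distances = {
        "L1": lesion_distances_mm[0],
        "L2": lesion_distances_mm[1],
        "L3": lesion_distances_mm[2],
        "B": background_lesion_distance_mm,
    }
    lesions = []
    for name in ("L1", "L2", "L3", "B"):
        d = distances[name]
        if d <= 0:
            raise ValueError("lesion distances must be positive")
        ang = np.deg2rad(angles[name])
        centre = np.zeros(ndim)
        centre[:2] = np.array(bladder_centre[:2]) + (r_b + d + r_l) * np.array(
            [np.cos(ang), np.sin(ang)]
        )
        lesions.append(
            RegionSpec(name, "sphere", tuple(centre), lesion_diameter_mm, lesion_suv)
        )

    for les in lesions:
        gap = (
            np.linalg.norm(np.array(les.centre) - np.array(bladder_centre))
            - r_b
            - r_l
        )
        if gap <= 0:
            raise ValueError(f"lesion {les.label!r} overlaps the bladder")
        _check_inside_grid(les, grid)
    _check_inside_grid(bladder, grid)

    ph = build_phantom(grid, [body, bladder] + lesions)
    ph.provenance.append(
        f"pelvic phantom: bladder SUV {bladder_suv}, volume {bladder_volume_ml} ml, "
        f"lesions d={lesion_diameter_mm} mm at {lesion_distances_mm} mm"
    )
    return ph


# ---------------------------------------------------------------------------
# NEMA-IQ-like phantom

NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


def make_nema_phantom(
    grid: ImageGrid,
    sphere_activity: float = 1.0,
    bottle_activity: float = 1.38,
    ring_radius_mm: float = 75.0,
    bottle_diameter_mm: float = 70.0,
    bottle_height_mm: float = 130.0,
) -> EmissionPhantom:
    """NEMA-IQ-like phantom: central hot 500-ml bottle, six spheres S1..S6
    (diameters 10/13/17/22/28/37 mm) on a ring, in a cold water body.

    Six same-sized cold background ROIs B1..B6 at the same bottle distance are
    returned as ROI metadata (``phantom.rois``), not painted into the
    emission.  Default activities reflect the bottle:sphere concentration
    ratio of the physical phantom (77.9 MBq / 500 ml vs 5.38 MBq shared
    across the six spheres).
    """
    ndim = grid.ndim
    extent = [grid.shape[a] * grid.voxel_size[a] for a in range(ndim)]
    body_d = 0.92 * min(extent[:2])
    body_size = (body_d, body_d) + ((0.92 * extent[2],) if ndim == 3 else ())
    body = RegionSpec("body", "background", (0.0,) * ndim, body_size, 0.0)
    bottle = RegionSpec(
        "bottle",
        "cylinder" if ndim == 3 else "sphere",
        (0.0,) * ndim,
        (bottle_diameter_mm, bottle_height_mm) if ndim == 3 else bottle_diameter_mm,
        bottle_activity,
    )

    regions = [body, bottle]
    rois = []
    n = len(NEMA_SPHERE_DIAMETERS_MM)
    for i, diam in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        if ring_radius_mm - bottle_diameter_mm / 2.0 - diam / 2.0 <= 0:
            raise ValueError(f"sphere S{i + 1} overlaps the bottle")
        ang = 2.0 * np.pi * i / n
        centre = np.zeros(ndim)
        centre[:2] = ring_radius_mm * np.array([np.cos(ang), np.sin(ang)])
        regions.append(
            RegionSpec(f"S{i + 1}", "sphere", tuple(centre), diam, sphere_activity)
        )
        # matched cold background ROI: same size, interleaved between the hot
        # spheres at (approximately) the same bottle distance.  The offset
        # from the paired sphere is snapped to the voxel lattice so the ROI
        # mask is an exact translate of the sphere mask (identical voxel
        # count by construction).
        bang = ang + np.pi / n
        ideal = np.zeros(ndim)
        ideal[:2] = ring_radius_mm * np.array([np.cos(bang), np.sin(bang)])
        offset = ideal - centre
        vox = np.array(grid.voxel_size)
        bcentre = centre + np.round(offset / vox) * vox
        rois.append(RegionSpec(f"B{i + 1}", "sphere", tuple(bcentre), diam, 0.0))

    # analytic disjointness of every sphere/ROI against the bottle and
    # each other (hard error per contract)
    placed = regions[1:] + rois
    for i, a in enumerate(placed):
        for b in placed[i + 1 :]:
            ra = a.radii(2)[0] if a.kind == "cylinder" else a.radii(ndim)[0]
            rb_ = b.radii(2)[0] if b.kind == "cylinder" else b.radii(ndim)[0]
            gap = (
                np.linalg.norm(np.array(a.centre[:2]) - np.array(b.centre[:2]))
                - ra
                - rb_
            )
            if gap <= 0:
                raise ValueError(f"regions {a.label!r} and {b.label!r} overlap")

    ph = build_phantom(grid, regions, rois=rois)
    ph.provenance.append(
        f"NEMA-IQ phantom: bottle activity {bottle_activity}, "
        f"sphere activity {sphere_activity}"
    )
    return ph


# ---------------------------------------------------------------------------
# bladder growth


def _growth_delta(volume_ratio: float, ndim: int) -> float:
    """Solve for delta such that the anisotropically grown bladder
    (semi-axes r(1+delta) transverse, r(1+2 delta) anterior) has the
    requested volume ratio."""
    if volume_ratio < 1.0:
        raise ValueError("bladder shrinkage is not modelled")
    if ndim == 3:
        # (1+d)^2 (1+2d) = ratio
        coeffs = [2.0, 5.0, 4.0, 1.0 - volume_ratio]
    else:
        # (1+d)(1+2d) = ratio
        coeffs = [2.0, 3.0, 1.0 - volume_ratio]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    real = real[real >= -1e-12]
    if real.size == 0:
        raise RuntimeError("no valid growth solution")
    return float(max(real.min(), 0.0))


def grow_bladder(
    phantom: EmissionPhantom, course: BladderTimeCourse, t: float
) -> EmissionPhantom:
    """Bladder state at scan time ``t``: volume rescaled with a 2:1
    anisotropic bias toward +y (anterior surrogate, posterior surface kept
    fixed) and SUV set from the course.  All other regions are unchanged.

    The input phantom is taken to be the state at the first timepoint.  If
    growth swallows a lesion this is recorded as a provenance warning, not an
    error — it is precisely the stale-segmentation failure mode under study.
    """
    volume, suv = course.at(t)
    v0 = course.volumes_ml[0]
    ratio = volume / v0
    bladder = phantom.region("bladder")
    ndim = phantom.grid.ndim
    r0 = bladder.radii(ndim)[0]
    delta = _growth_delta(ratio, ndim)
    ax = r0 * (1.0 + delta)
    ay = r0 * (1.0 + 2.0 * delta)
    centre = list(bladder.centre)
    centre[1] += ay - r0  # posterior surface fixed; all growth toward +y
    size = (2 * ax, 2 * ay) + ((2 * ax,) if ndim == 3 else ())
    new_bladder = RegionSpec(
        "bladder", "ellipsoid", tuple(centre), size, suv, bladder.mu
    )

    regions = [new_bladder if r.label == "bladder" else r for r in phantom.regions]
    # bladder painted last: an expanding bladder overruns lesion voxels,
    # which is the stale-segmentation failure mode this models
    order = [r.label for r in regions if r.label != "bladder"] + ["bladder"]
    grown = build_phantom(phantom.grid, regions, rois=phantom.rois, paint_order=order)
    grown.provenance = list(phantom.provenance)
    grown.provenance.append(f"bladder grown to t={t} min: {volume} ml, SUV {suv}")

    for r in phantom.regions:
        if r.label in ("bladder", "body"):
            continue
        before = int(np.sum(region_mask(phantom, r.label)))
        after = int(np.sum(region_mask(grown, r.label)))
        if after < before:
            msg = (
                f"bladder growth at t={t} min overlaps lesion {r.label!r} "
                f"({before - after} of {before} voxels lost)"
            )
            warnings.warn(msg, stacklevel=2)
            grown.provenance.append("WARNING: " + msg)
    return grown


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes + YAML region sidecar


def save_phantom(phantom: EmissionPhantom, prefix: str) -> None:
    """Write suv/mu/label volumes as NIfTI and region specs as YAML."""
    import nibabel as nib

    aff = phantom.grid.affine()
    nib.save(nib.Nifti1Image(phantom.suv_image, aff), f"{prefix}_suv.nii.gz")
    nib.save(nib.Nifti1Image(phantom.mu_image, aff), f"{prefix}_mu.nii.gz")
    nib.save(
        nib.Nifti1Image(phantom.label_image.astype(np.int16), aff),
        f"{prefix}_labels.nii.gz",
    )
    side = {
        "voxel_size": list(phantom.grid.voxel_size),
        "shape": list(phantom.grid.shape),
        "origin": list(phantom.grid.origin),
        "label_codes": phantom.label_codes,
        "provenance": phantom.provenance,
        "regions": [_spec_to_dict(r) for r in phantom.regions],
        "rois": [_spec_to_dict(r) for r in phantom.rois],
    }
    with open(f"{prefix}_regions.yaml", "w") as fh:
        yaml.safe_dump(side, fh)


def _spec_to_dict(r: RegionSpec) -> dict:
    return {
        "label": r.label,
        "kind": r.kind,
        "centre": [float(c) for c in r.centre],
        "size": [float(s) for s in np.atleast_1d(r.size)],
        "suv": float(r.suv),
        "mu": float(r.mu),
    }


def _spec_from_dict(d: dict) -> RegionSpec:
    size = d["size"]
    return RegionSpec(
        d["label"],
        d["kind"],
        tuple(d["centre"]),
        size[0] if len(size) == 1 else tuple(size),
        d["suv"],
        d["mu"],
    )


def load_phantom(prefix: str) -> EmissionPhantom:
    import nibabel as nib

    with open(f"{prefix}_regions.yaml") as fh:
        side = yaml.safe_load(fh)
    grid = ImageGrid(
        tuple(side["shape"]), tuple(side["voxel_size"]), tuple(side["origin"])
    )
    suv = np.asarray(nib.load(f"{prefix}_suv.nii.gz").dataobj, dtype=np.float64)
    mu = np.asarray(nib.load(f"{prefix}_mu.nii.gz").dataobj, dtype=np.float64)
    lab = np.asarray(nib.load(f"{prefix}_labels.nii.gz").dataobj, dtype=np.int32)
    return EmissionPhantom(
        grid=grid,
        suv_image=suv,
        label_image=lab,
        regions=[_spec_from_dict(r) for r in side["regions"]],
        mu_image=mu,
        label_codes={k: int(v) for k, v in side["label_codes"].items()},
        rois=[_spec_from_dict(r) for r in side.get("rois", [])],
        provenance=list(side.get("provenance", [])),
    )
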