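"""Seeded synthetic-data generators with exact ground truth.

Every generator is a pure function of ``(spec, seed)``: identical inputs
yield bit-identical arrays.  The generators emulate the four data modalities
of a regional microglia-depletion study:

* two-photon 3D stacks of sparse bright cells (soma + radiating processes)
  over a noisy background, at anisotropic voxel pitch,
* chromogenic (DAB-style) brightfield slides with stained cell bodies on
  counterstained tissue, including deliberately touching cell pairs,
* fluorescent in-situ hybridization slides with punctate dots at a
  programmed percent-of-tissue-area,
* multi-animal dose-group cohorts with programmed per-region depletion
  fractions and lognormal between-animal variability.

None of this is a physics simulation: there is no PSF model and no optical
sectioning; somata are Gaussian-blurred balls and processes thin tapering
cylinders, which is sufficient to exercise detection, splitting and density
arithmetic against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PlacementError",
    "StackSpec",
    "CellTruth",
    "SlideSpec",
    "SlideTruth",
    "FishSpec",
    "GroupSpec",
    "RegionSpec",
    "ExperimentDesign",
    "generate_stack",
    "generate_ihc_slide",
    "generate_fish_slide",
    "generate_cohort",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a placement constraint."""


# ---------------------------------------------------------------------------
# 3D fluorescence stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSpec:
    """Geometry and content of a synthetic two-photon stack.

    Defaults carry the acquisition geometry of the emulated instrument:
    0.592 um/pixel in-plane and a 1.5 um z-step.  ``shape_xyz`` is the voxel
    count per axis in (x, y, z) order; arrays are stored (z, y, x).
    """

    shape_xyz: tuple[int, int, int] = (256, 256, 40)
    voxel_xy: float = 0.592
    voxel_z: float = 1.5
    n_cells: int = 20
    soma_radius_range: tuple[float, float] = (3.5, 5.0)
    n_processes_range: tuple[int, int] = (2, 6)
    process_length_range: tuple[float, float] = (8.0, 15.0)
    min_separation: float = 30.0
    foreground_intensity: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 20.0

    def validate(self) -> None:
        if any(s < 1 for s in self.shape_xyz):
            raise ValueError("all stack dimensions must be >= 1 voxel")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel pitches must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_cells > 1 and self.min_separation <= 2 * self.soma_radius_range[1]:
            raise ValueError(
                "min_separation must exceed twice the largest soma radius"
            )
        for lo, hi in (
            self.soma_radius_range,
            self.n_processes_range,
            self.process_length_range,
        ):
            if lo > hi or lo < 0:
                raise ValueError("ranges must be ordered and non-negative")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical stack extent in um, (x, y, z)."""
        nx, ny, nz = self.shape_xyz
        return (nx * self.voxel_xy, ny * self.voxel_xy, nz * self.voxel_z)

    @property
    def volume_mm3(self) -> float:
        ex, ey, ez = self.extent_um
        return ex * ey * ez * 1e-9


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell.

    ``true_volume`` is the analytic soma+process volume in um^3: a sphere of
    ``soma_radius`` plus one cylinder per process (overlaps ignored).
    """

    cell_id: int
    centroid: tuple[float, float, float]  # (x, y, z) um
    soma_radius: float
    true_volume: float


def _place_points(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_separation: float,
) -> np.ndarray:
    """Rejection-sample ``n`` points in the box [lo, hi] (um, xyz) with a
    pairwise minimum separation.  Raises :class:`PlacementError` when any
    single point exhausts the attempt cap."""
    if np.any(hi <= lo):
        raise PlacementError("placement box is empty; stack too small for margins")
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            p = rng.uniform(lo, hi)
            if not pts:
                pts.append(p)
                break
            d2 = np.sum((np.asarray(pts) - p) ** 2, axis=1)
            if d2.min() >= min_separation**2:
                pts.append(p)
                break
        else:
            raise PlacementError(
                f"could not place point {len(pts) + 1}/{n} at separation "
                f"{min_separation} um after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return np.asarray(pts).reshape(n, 3)


def _stamp_ball(
    img: np.ndarray,
    center_um_xyz: np.ndarray,
    radius_um: float,
    value: float,
    pitches_zyx: tuple[float, float, float],
) -> None:
    """Max-combine a ball of physical radius into ``img`` (z, y, x)."""
    pz, py, px = pitches_zyx
    cx, cy, cz = center_um_xyz
    center_vox = np.array([cz / pz - 0.5, cy / py - 0.5, cx / px - 0.5])
    half = np.array([radius_um / pz, radius_um / py, radius_um / px]) + 1.0
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, img.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) - center_vox[0]) * pz,
        (np.arange(lo[1], hi[1]) - center_vox[1]) * py,
        (np.arange(lo[2], hi[2]) - center_vox[2]) * px,
        indexing="ij",
    )
    mask = zz * zz + yy * yy + xx * xx <= radius_um**2
    sub = img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(sub, np.where(mask, value, 0.0), out=sub)


def generate_stack(
    spec: StackSpec, seed: int
) -> tuple[np.ndarray, list[CellTruth]]:
    """Render a synthetic stack; returns ``(voxels, truth)``.

    ``voxels`` is a float32 array of shape (nz, ny, nx).  Bright objects
    correspond one-to-one with the returned :class:`CellTruth` records and
    all pairwise centroid distances are >= ``spec.min_separation``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape_xyz
    img = np.zeros((nz, ny, nx), dtype=np.float64)
    pitches = (spec.voxel_z, spec.voxel_xy, spec.voxel_xy)
    extent = np.asarray(spec.extent_um)

    r_max = spec.soma_radius_range[1]
    margin = r_max + 1.0
    centers = _place_points(
        rng,
        spec.n_cells,
        lo=np.full(3, margin),
        hi=extent - margin,
        min_separation=spec.min_separation,
    )

    truths: list[CellTruth] = []
    proc_radius = 0.75  # um; thin microglial process calibre
    for i in range(spec.n_cells):
        c = centers[i]
        r = rng.uniform(*spec.soma_radius_range)
        n_proc = int(rng.integers(spec.n_processes_range[0], spec.n_processes_range[1] + 1))
        _stamp_ball(img, c, r, spec.foreground_intensity, pitches)
        total_proc_len = 0.0
        for _ in range(n_proc):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            length = rng.uniform(*spec.process_length_range)
            total_proc_len += length
            # tapering cylinder: intensity falls from 0.8 fg at the soma
            # surface to 0.4 fg at the tip
            n_steps = max(2, int(length / 0.4))
            for s in np.linspace(0.0, 1.0, n_steps):
                p = c + v * (r + s * length)
                if np.any(p < 0) or np.any(p > extent):
                    break
                val = spec.foreground_intensity * (0.8 - 0.4 * s)
                _stamp_ball(img, p, proc_radius, val, pitches)
        vol = 4.0 / 3.0 * math.pi * r**3 + math.pi * proc_radius**2 * total_proc_len
        truths.append(
            CellTruth(cell_id=i + 1, centroid=tuple(c), soma_radius=r, true_volume=vol)
        )

    # slight blur softens the rasterized edges (no PSF model intended)
    sigma_vox = [0.5 / p for p in pitches]
    img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    img += spec.background_level
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return img.astype(np.float32), truths


# ---------------------------------------------------------------------------
# Brightfield IHC slides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideSpec:
    """Synthetic chromogenic slide: stained cell bodies on counterstained
    tissue over a white background."""

    shape_xy: tuple[int, int] = (1024, 1024)
    mpp: float = 0.46
    tissue_fraction: float = 0.7
    n_positive_cells: int = 100
    cell_radius_range: tuple[float, float] = (4.0, 6.0)
    touching_pair_fraction: float = 0.2
    stain_color: tuple[int, int, int] = (140, 95, 45)  # DAB brown
    counterstain_color: tuple[int, int, int] = (190, 175, 215)  # hematoxylin
    noise_sd: float = 3.0

    def validate(self) -> None:
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must be in (0, 1]")
        if not (0.0 <= self.touching_pair_fraction <= 1.0):
            raise ValueError("touching_pair_fraction must be in [0, 1]")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.n_positive_cells < 0:
            raise ValueError("n_positive_cells must be >= 0")


@dataclass(frozen=True)
class SlideTruth:
    """Ground truth for a rendered slide."""

    centers_px: np.ndarray  # (n, 2) float, (row, col)
    tissue_mask: np.ndarray  # bool (h, w)
    stain_mask: np.ndarray  # bool (h, w): pixels rendered with stain
    n_touching_pairs: int


def _tissue_mask(shape_hw: tuple[int, int], fraction: float) -> np.ndarray:
    """Centered ellipse (or rectangle for high fractions) covering
    approximately ``fraction`` of the image."""
    h, w = shape_hw
    if fraction >= 0.75:
        # ellipse cannot exceed pi/4 of the frame; fall back to a rectangle
        s = math.sqrt(fraction)
        mask = np.zeros(shape_hw, dtype=bool)
        rh, rw = int(round(h * s)), int(round(w * s))
        r0, c0 = (h - rh) // 2, (w - rw) // 2
        mask[r0 : r0 + rh, c0 : c0 + rw] = True
        return mask
    a = (h / 2) * math.sqrt(fraction / (math.pi / 4))
    b = (w / 2) * math.sqrt(fraction / (math.pi / 4))
    rr, cc = np.ogrid[:h, :w]
    return ((rr - (h - 1) / 2) / a) ** 2 + ((cc - (w - 1) / 2) / b) ** 2 <= 1.0


def _inside_ellipse_margin(
    p: np.ndarray, shape_hw: tuple[int, int], fraction: float, margin_px: float
) -> bool:
    h, w = shape_hw
    if fraction >= 0.75:
        s = math.sqrt(fraction)
        rh, rw = h * s / 2, w * s / 2
        return (
            abs(p[0] - (h - 1) / 2) <= rh - margin_px
            and abs(p[1] - (w - 1) / 2) <= rw - margin_px
        )
    a = (h / 2) * math.sqrt(fraction / (math.pi / 4)) - margin_px
    b = (w / 2) * math.sqrt(fraction / (math.pi / 4)) - margin_px
    if a <= 0 or b <= 0:
        return False
    return ((p[0] - (h - 1) / 2) / a) ** 2 + ((p[1] - (w - 1) / 2) / b) ** 2 <= 1.0


def generate_ihc_slide(
    spec: SlideSpec, seed: int
) -> tuple[np.ndarray, SlideTruth]:
    """Render a synthetic IHC slide; returns ``(rgb_uint8, truth)``.

    ``touching_pair_fraction`` of the cells are laid out as overlapping
    pairs whose intensity profiles retain two local minima (each member is
    darkest at its own centre), the fixture for minima-controlled watershed
    splitting.  Truth lists every cell centre including both pair members.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    w, h = spec.shape_xy
    shape_hw = (h, w)
    tissue = _tissue_mask(shape_hw, spec.tissue_fraction)

    n = spec.n_positive_cells
    n_pairs = int(round(spec.touching_pair_fraction * n / 2.0))
    n_singles = n - 2 * n_pairs

    r_lo, r_hi = (r / spec.mpp for r in spec.cell_radius_range)  # px
    r_max = r_hi
    # anchor points: one per single cell, one per pair; pairs get a second
    # centre at ~1.5 r so the disks overlap but keep two darkness minima
    anchor_sep = 2 * r_max + 4 + 1.6 * r_max  # keeps distinct objects apart
    anchors: list[np.ndarray] = []
    for k in range(n_singles + n_pairs):
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            p = rng.uniform([0, 0], [h - 1, w - 1])
            if not _inside_ellipse_margin(
                p, shape_hw, spec.tissue_fraction, margin_px=2.6 * r_max + 2
            ):
                continue
            if anchors:
                d2 = np.sum((np.asarray(anchors) - p) ** 2, axis=1)
                if d2.min() < anchor_sep**2:
                    continue
            anchors.append(p)
            break
        else:
            raise PlacementError(
                f"could not place object {k + 1}/{n_singles + n_pairs} "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )

    centers: list[np.ndarray] = []
    radii: list[float] = []
    for k, p in enumerate(anchors):
        r1 = rng.uniform(r_lo, r_hi)
        if k < n_singles:
            centers.append(p)
            radii.append(r1)
        else:
            r2 = rng.uniform(r_lo, r_hi)
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.75 * (r1 + r2)  # overlap: d < r1 + r2
            off = 0.5 * d * np.array([math.sin(theta), math.cos(theta)])
            centers.extend([p - off, p + off])
            radii.extend([r1, r2])

    # shade map: darkest-wins radial profile, darkest at each cell centre
    shade = np.full(shape_hw, np.inf)
    for c, r in zip(centers, radii):
        ir = int(math.ceil(r)) + 1
        r0, c0 = int(round(c[0])), int(round(c[1]))
        rows = slice(max(r0 - ir, 0), min(r0 + ir + 1, h))
        cols = slice(max(c0 - ir, 0), min(c0 + ir + 1, w))
        rr, cc = np.mgrid[rows, cols]
        d = np.hypot(rr - c[0], cc - c[1])
        prof = np.where(d <= r, 0.55 + 0.45 * (d / max(r, 1e-9)), np.inf)
        shade[rows, cols] = np.minimum(shade[rows, cols], prof)
    stain_mask = np.isfinite(shade)

    img = np.full((h, w, 3), 255.0)
    img[tissue] = np.asarray(spec.counterstain_color, dtype=float)
    sc = np.asarray(spec.stain_color, dtype=float)
    img[stain_mask] = shade[stain_mask, None] * sc[None, :]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)

    truth = SlideTruth(
        centers_px=np.asarray(centers).reshape(len(centers), 2),
        tissue_mask=tissue,
        stain_mask=stain_mask,
        n_touching_pairs=n_pairs,
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# FISH slides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FishSpec:
    """Synthetic FISH channel: punctate dots on tissue, built to a target
    percent-of-tissue-area stained."""

    shape_xy: tuple[int, int] = (512, 512)
    mpp: float = 0.325
    target_percent_area: float = 2.08
    dot_radius: float = 1.0  # um
    tissue_mask_fraction: float = 0.7
    background_level: float = 10.0
    dot_intensity: float = 180.0
    noise_sd: float = 3.0

    def validate(self) -> None:
        if not (0.0 <= self.target_percent_area <= 100.0):
            raise ValueError("target_percent_area must be in [0, 100]")
        if self.dot_radius <= 0 or self.mpp <= 0:
            raise ValueError("dot_radius and mpp must be positive")


def _disk_offsets(radius_px: float) -> np.ndarray:
    ir = int(math.ceil(radius_px))
    rr, cc = np.mgrid[-ir : ir + 1, -ir : ir + 1]
    mask = rr * rr + cc * cc <= radius_px * radius_px
    return np.stack([rr[mask], cc[mask]], axis=1)


def generate_fish_slide(
    spec: FishSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render a FISH channel; returns ``(signal, tissue_mask, true_percent)``.

    ``true_percent`` is the exact stained-pixel fraction of the tissue, and
    is guaranteed within 0.5 percentage points of the target (else a
    :class:`ValueError` is raised: the dot granularity cannot reach it).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    w, h = spec.shape_xy
    tissue = _tissue_mask((h, w), spec.tissue_mask_fraction)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")

    signal_mask = np.zeros((h, w), dtype=bool)
    if spec.target_percent_area >= 100.0:
        signal_mask = tissue.copy()
    elif spec.target_percent_area > 0.0:
        offsets = _disk_offsets(max(spec.dot_radius / spec.mpp, 1.0))
        a_dot = len(offsets)
        n_dots = int(round(spec.target_percent_area / 100.0 * n_tissue / a_dot))
        achievable = n_dots * a_dot / n_tissue * 100.0
        if abs(achievable - spec.target_percent_area) > 0.5:
            raise ValueError(
                f"target {spec.target_percent_area}% unreachable with dot "
                f"radius {spec.dot_radius} um (closest {achievable:.3f}%)"
            )
        eroded = ndimage.binary_erosion(
            tissue, iterations=int(math.ceil(spec.dot_radius / spec.mpp)) + 1
        )
        valid = np.argwhere(eroded)
        if len(valid) == 0 and n_dots > 0:
            raise PlacementError("tissue too small for any dot")
        placed = 0
        occupied = np.zeros((h, w), dtype=bool)
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS * max(n_dots, 1)):
            if placed >= n_dots:
                break
            c = valid[rng.integers(len(valid))]
            px = offsets + c
            if occupied[px[:, 0], px[:, 1]].any():
                continue
            signal_mask[px[:, 0], px[:, 1]] = True
            # guard ring keeps dots disjoint so the stained area stays an
            # exact multiple of the single-dot pixel area
            guard = _disk_offsets(max(spec.dot_radius / spec.mpp, 1.0) + 1.5) + c
            guard = guard[
                (guard[:, 0] >= 0)
                & (guard[:, 0] < h)
                & (guard[:, 1] >= 0)
                & (guard[:, 1] < w)
            ]
            occupied[guard[:, 0], guard[:, 1]] = True
            placed += 1
        if placed < n_dots:
            raise PlacementError(
                f"placed only {placed}/{n_dots} dots without overlap"
            )

    true_percent = signal_mask[tissue].sum() / n_tissue * 100.0
    img = np.full((h, w), spec.background_level)
    img[signal_mask] = spec.dot_intensity
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return img.astype(np.float32), tissue, float(true_percent)


# ---------------------------------------------------------------------------
# Multi-animal cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One dose group: per-region depletion fraction relative to control."""

    name: str
    n_animals: int
    depletion: Mapping[str, float] = field(default_factory=dict)

    def is_control(self, regions: Sequence[str]) -> bool:
        return all(self.depletion.get(r, 0.0) == 0.0 for r in regions)


@dataclass(frozen=True)
class RegionSpec:
    """One brain region: baseline density and between-animal variability."""

    name: str
    baseline_density: float  # cells/mm^3
    between_animal_cv: float = 0.10


@dataclass(frozen=True)
class ExperimentDesign:
    """Multi-group, multi-region cohort design.

    Exactly one group must have zero depletion in every region (the
    control); every group needs at least two animals.  Between-animal
    variability is lognormal with the stated CV, mean-preserving.
    """

    groups: tuple[GroupSpec, ...]
    regions: tuple[RegionSpec, ...]
    seed: int = 0
    stack_template: StackSpec = field(default_factory=StackSpec)

    def validate(self) -> None:
        names = [r.name for r in self.regions]
        controls = [g for g in self.groups if g.is_control(names)]
        if len(controls) != 1:
            raise ValueError(
                f"exactly one control group (zero depletion everywhere) "
                f"required, found {len(controls)}"
            )
        for g in self.groups:
            if g.n_animals < 2:
                raise ValueError(f"group {g.name!r} needs >= 2 animals")
            for r, f in g.depletion.items():
                if not (0.0 <= f < 1.0):
                    raise ValueError(f"depletion fraction for {g.name}/{r} not in [0,1)")

    @property
    def control_name(self) -> str:
        names = [r.name for r in self.regions]
        return next(g.name for g in self.groups if g.is_control(names))


def default_design(seed: int = 0) -> ExperimentDesign:
    """A three-region, four-group design emulating an adult ligand-blocking
    study: a white-matter region depleted by anti-CSF1, a gray-matter region
    depleted by anti-IL-34, and a mixed region needing the combination."""
    return ExperimentDesign(
        groups=(
            GroupSpec("control", 6, {}),
            GroupSpec("anti-IL-34", 6, {"fimbria": 0.10, "cortex": 0.43, "dentate_gyrus": 0.30}),
            GroupSpec("anti-CSF1", 6, {"fimbria": 0.65, "cortex": 0.10, "dentate_gyrus": 0.10}),
            GroupSpec("combo", 6, {"fimbria": 0.70, "cortex": 0.50, "dentate_gyrus": 0.60}),
        ),
        regions=(
            RegionSpec("fimbria", 5000.0),
            RegionSpec("cortex", 6500.0),
            RegionSpec("dentate_gyrus", 8000.0),
        ),
        seed=seed,
    )


def generate_cohort(design: ExperimentDesign):
    """Simulate a cohort; returns ``(table, stack_specs)``.

    ``table`` is a :class:`pandas.DataFrame` with one row per animal x
    region: columns ``animal_id, group, sex, region, density,
    expected_count``.  ``density`` (cells/mm^3) is the animal's expected
    density — baseline x (1 - depletion) x a mean-preserving lognormal
    factor with the region's CV.  ``expected_count`` is that density times
    the template stack volume.  ``stack_specs`` maps ``(animal_id, region)``
    to a :class:`StackSpec` whose ``n_cells`` rounds the expected count, so
    image-level stages can be driven from the same truth.
    """
    import pandas as pd

    design.validate()
    rng = np.random.default_rng(design.seed)
    vol = design.stack_template.volume_mm3
    rows = []
    stack_specs: dict[tuple[str, str], StackSpec] = {}
    for g in design.groups:
        for a in range(g.n_animals):
            animal_id = f"{g.name}-{a + 1:02d}"
            sex = "M" if a % 2 == 0 else "F"  # metadata only; no sex effect
            for reg in design.regions:
                frac = g.depletion.get(reg.name, 0.0)
                mean_density = reg.baseline_density * (1.0 - frac)
                cv = reg.between_animal_cv
                if cv > 0:
                    s = math.sqrt(math.log1p(cv * cv))
                    factor = rng.lognormal(mean=-0.5 * s * s, sigma=s)
                else:
                    factor = 1.0
                density = mean_density * factor
                expected = density * vol
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": g.name,
                        "sex": sex,
                        "region": reg.name,
                        "density": density,
                        "expected_count": expected,
                    }
                )
                stack_specs[(animal_id, reg.name)] = replace(
                    design.stack_template, n_cells=int(round(expected))
                )
    return pd.DataFrame(rows), stack_specs
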