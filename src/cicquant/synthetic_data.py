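"""Synthetic co-incubation scenes and tissue cores with planted ground truth.

The generator emulates the two assay geometries:

* **Co-incubation scenes** — three fluorescence channels: green for
  CellTracker-stained viable cells, red for dead (hyperthermia-killed)
  cells, blue for DAPI nuclei.  Free viable cells, free dead cells, and
  cell-in-cell (CIC) pairs are rendered as filled disks.  In a CIC pair a
  circular dead cell sits fully inside a viable host whose nucleus carries
  a semicircular indentation (the crescent imprint) adjacent to the
  engulfed cell.

* **Tissue cores** — a single immunohistochemistry channel showing a 1-mm
  circular core in which cells appear as membrane rings; ring intensity
  increases monotonically with the E-cadherin level (0-3), and CIC figures
  are rendered as a ring inside a ring.

Every generated image comes with a complete truth record (who is viable,
dead, host, engulfed; which pairs exist), so downstream segmentation,
detection, and quantification can be scored against a known answer.
Identical spec + seed always reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from skimage import draw

from .image_io import ImageStack

# Rendering intensities (8-bit scale).  Cells and nuclei are well separated
# from background so that Otsu thresholding is stable under the default noise.
CELL_INTENSITY = 120.0
NUCLEUS_INTENSITY = 180.0

# Tissue rendering: in-core tissue background and per-level membrane means.
TISSUE_BACKGROUND = 20.0
OUTSIDE_CORE = 5.0
#: Mean membrane-ring gray level for E-cadherin score levels 0..3.
ECAD_LEVEL_MEANS = (28.0, 70.0, 130.0, 190.0)

MAX_PLACEMENT_ATTEMPTS = 10_000

#: Minimum rasterized nuclear solidity deficit a planted CIC pair must show.
#: Rasterization of subpixel disk positions can shallow a nominal bite; the
#: generator resamples the pair geometry until the rendered nucleus really
#: carries the crescent it promises in the truth record.
MIN_PLANTED_CRESCENT = 0.12


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object (scene too crowded)."""


@dataclass(frozen=True)
class TruthObject:
    object_id: int
    cls: str  # viable_free | dead_free | cic_host | cic_engulfed
    center: tuple[float, float]  # (row, col)
    radius_px: float


@dataclass
class GroundTruth:
    """Planted truth for one scene: all objects plus host/engulfed pairs."""

    objects: list[TruthObject]
    pairs: list[tuple[int, int]]  # (host_id, engulfed_id)

    def __post_init__(self) -> None:
        ids = [o.object_id for o in self.objects]
        if len(ids) != len(set(ids)):
            raise ValueError("object_ids are not unique")
        engulfed = [o.object_id for o in self.objects if o.cls == "cic_engulfed"]
        paired = [e for _, e in self.pairs]
        if sorted(engulfed) != sorted(paired):
            raise ValueError("every cic_engulfed object must appear in exactly one pair")

    def by_class(self, *classes: str) -> list[TruthObject]:
        return [o for o in self.objects if o.cls in classes]

    @property
    def n_viable(self) -> int:
        return len(self.by_class("viable_free", "cic_host"))

    @property
    def n_dead(self) -> int:
        return len(self.by_class("dead_free", "cic_engulfed"))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic co-incubation scene.

    ``crescent_depth`` is the fraction of the host-nucleus radius indented
    by the engulfed cell.  The default 1.0 carves the bite to the nucleus
    center, producing the half-moon (crescent-shaped) host nucleus typical
    of an engulfment event.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 2.0
    n_viable_free: int = 8
    n_dead_free: int = 5
    n_cic: int = 3
    cell_radius_px: tuple[int, int] = (16, 22)
    nucleus_radius_px: tuple[int, int] = (7, 10)
    engulfed_radius_px: tuple[int, int] = (6, 9)
    crescent_depth: float = 1.0
    background_level: float = 8.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_viable_free, self.n_dead_free, self.n_cic) < 0:
            raise ValueError("object counts must be >= 0")
        if self.engulfed_radius_px[1] >= self.cell_radius_px[0]:
            raise ValueError(
                f"engulfed radius max {self.engulfed_radius_px[1]} must be < "
                f"cell radius min {self.cell_radius_px[0]} (engulfed cell must fit in host)"
            )
        if not 0.0 <= self.crescent_depth <= 1.0:
            raise ValueError(f"crescent_depth must be in [0,1], got {self.crescent_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for lo, hi in (self.cell_radius_px, self.nucleus_radius_px, self.engulfed_radius_px):
            if lo < 1 or hi < lo:
                raise ValueError("radius ranges must satisfy 1 <= min <= max")


def _sample_center(rng: np.random.Generator, spec: SceneSpec, radius: float,
                   placed: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Rejection-sample a center keeping the full disk in frame and clear of others."""
    margin = radius + 2
    if spec.height_px - 2 * margin <= 0 or spec.width_px - 2 * margin <= 0:
        raise PlacementError(
            f"object of radius {radius} px does not fit a "
            f"{spec.height_px}x{spec.width_px} frame"
        )
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        r = rng.uniform(margin, spec.height_px - margin)
        c = rng.uniform(margin, spec.width_px - margin)
        if all(math.hypot(r - pr, c - pc) > radius + prad + 2 for pr, pc, prad in placed):
            return r, c
    raise PlacementError(
        f"could not place object of radius {radius} px after "
        f"{MAX_PLACEMENT_ATTEMPTS} attempts: scene too crowded "
        f"({len(placed)} objects already placed in {spec.height_px}x{spec.width_px})"
    )


def _sample_cic_geometry(rng: np.random.Generator, spec: SceneSpec
                         ) -> tuple[int, int, int, float, float]:
    """Sample (host R, nucleus r_n, engulfed r_e, engulfed offset, nucleus offset).

    Offsets are along one axis from the host center; the nucleus sits on the
    far side of the engulfed cell so that the bite of depth
    ``crescent_depth * r_n`` lands on the nucleus edge facing it.  Radii are
    resampled until both disks fit inside the host with 1-px clearance.
    """
    for _ in range(1000):
        R = int(rng.integers(spec.cell_radius_px[0], spec.cell_radius_px[1] + 1))
        r_n = int(rng.integers(spec.nucleus_radius_px[0], spec.nucleus_radius_px[1] + 1))
        r_e = int(rng.integers(spec.engulfed_radius_px[0], spec.engulfed_radius_px[1] + 1))
        d = spec.crescent_depth * r_n
        off_e = R - r_e - 2  # push engulfed cell toward the host edge
        if off_e < 0:
            continue
        off_n = off_e - (r_n + r_e - d)  # may be negative: other side of center
        if abs(off_n) + r_n <= R - 1:
            return R, r_n, r_e, off_e, off_n
    raise PlacementError(
        "no feasible CIC geometry for the given radius ranges and crescent depth"
    )


def _disk(img: np.ndarray, center: tuple[float, float], radius: float, value: float) -> None:
    rr, cc = draw.disk(center, radius, shape=img.shape)
    img[rr, cc] = value


def _raster_solidity_deficit(mask: np.ndarray) -> float:
    """1 - area / rasterized-convex-hull area of a boolean pixel set.

    Hull over pixel centers; a pixel counts as hull when its center is
    inside or on the polygon (same convention the detector uses).
    """
    from scipy.spatial import ConvexHull

    rows, cols = np.nonzero(mask)
    pts = np.stack([rows, cols], axis=1).astype(float)
    try:
        hull = ConvexHull(pts)
    except Exception:  # degenerate (point/line) pixel sets are convex
        return 0.0
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1),
                         indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = (centers @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9).all(axis=1)
    return 1.0 - len(rows) / int(inside.sum())


def generate_coincubation_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one three-channel scene and its ground truth.

    Object layout: free viable and free dead cells are disjoint disks; each
    CIC pair is a dead disk fully inside a viable host disk, with the host
    nucleus carved by a circular bite adjacent to the engulfed cell.  Free
    viable cells carry an intact (convex) nucleus.  Additive Gaussian noise
    of sd ``noise_sigma`` is applied last and clipped to 8-bit.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    green = np.full(shape, spec.background_level, dtype=np.float64)
    red = np.full(shape, spec.background_level, dtype=np.float64)
    blue = np.full(shape, spec.background_level, dtype=np.float64)

    objects: list[TruthObject] = []
    pairs: list[tuple[int, int]] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, exclusion radius)
    next_id = 1

    # CIC pairs first (largest footprint places easiest in an empty frame).
    for _ in range(spec.n_cic):
        hr = hc = None
        for _attempt in range(200):
            R, r_n, r_e, off_e, off_n = _sample_cic_geometry(rng, spec)
            if hr is None:
                hr, hc = _sample_center(rng, spec, R, placed)
            theta = rng.uniform(0, 2 * math.pi)
            u = (math.cos(theta), math.sin(theta))
            e_center = (hr + off_e * u[0], hc + off_e * u[1])
            n_center = (hr + off_n * u[0], hc + off_n * u[1])

            # rasterize nucleus-with-bite and check the planted crescent
            # survives rasterization before painting anything
            nucleus_px = np.zeros(shape, dtype=bool)
            nr, nc = draw.disk(n_center, r_n, shape=shape)
            nucleus_px[nr, nc] = True
            rr, cc = draw.disk(e_center, r_e, shape=shape)
            bite = np.zeros(shape, dtype=bool)
            bite[rr, cc] = True
            carved = nucleus_px & ~bite
            if spec.crescent_depth == 0.0 or \
                    _raster_solidity_deficit(carved) >= MIN_PLANTED_CRESCENT:
                break
        else:
            raise PlacementError(
                "could not realize a planted crescent at the requested depth")

        _disk(green, (hr, hc), R, CELL_INTENSITY)
        _disk(red, e_center, r_e, CELL_INTENSITY)
        blue[carved] = NUCLEUS_INTENSITY

        host_id, eng_id = next_id, next_id + 1
        next_id += 2
        objects.append(TruthObject(host_id, "cic_host", (hr, hc), R))
        objects.append(TruthObject(eng_id, "cic_engulfed", e_center, r_e))
        pairs.append((host_id, eng_id))
        placed.append((hr, hc, R))

    for _ in range(spec.n_viable_free):
        R = int(rng.integers(spec.cell_radius_px[0], spec.cell_radius_px[1] + 1))
        r_n = int(rng.integers(spec.nucleus_radius_px[0], spec.nucleus_radius_px[1] + 1))
        r_, c_ = _sample_center(rng, spec, R, placed)
        jitter = R - r_n - 2
        dr, dc = rng.uniform(-1, 1, 2) * max(jitter, 0) * 0.3
        _disk(green, (r_, c_), R, CELL_INTENSITY)
        _disk(blue, (r_ + dr, c_ + dc), r_n, NUCLEUS_INTENSITY)
        objects.append(TruthObject(next_id, "viable_free", (r_, c_), R))
        placed.append((r_, c_, R))
        next_id += 1

    for _ in range(spec.n_dead_free):
        r_e = int(rng.integers(spec.engulfed_radius_px[0], spec.engulfed_radius_px[1] + 1))
        r_, c_ = _sample_center(rng, spec, r_e, placed)
        _disk(red, (r_, c_), r_e, CELL_INTENSITY)
        objects.append(TruthObject(next_id, "dead_free", (r_, c_), r_e))
        placed.append((r_, c_, r_e))
        next_id += 1

    channels = {}
    for name, img in (("green", green), ("red", red), ("dapi", blue)):
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, shape)
        channels[name] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = ImageStack(channels=channels, pixel_size_um=spec.pixel_size_um, bit_depth=8)
    return stack, GroundTruth(objects=objects, pairs=pairs)


# ---------------------------------------------------------------------------
# Tissue cores


@dataclass(frozen=True)
class TissueCoreSpec:
    """Parameters of one synthetic 1-mm tissue-microarray core."""

    core_diameter_mm: float = 1.0
    pixel_size_um: float = 2.0
    n_cells: int = 150
    n_cic: int = 0
    ecad_level: int = 1
    t_stage: str = "unknown"
    n_stage: str = "unknown"
    m_stage: str = "unknown"
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cic > self.n_cells:
            raise ValueError(f"n_cic {self.n_cic} exceeds n_cells {self.n_cells}")
        if self.core_diameter_mm <= 0:
            raise ValueError("core_diameter_mm must be > 0")
        if self.ecad_level not in (0, 1, 2, 3):
            raise ValueError(f"ecad_level must be one of 0..3, got {self.ecad_level}")
        if min(self.n_cells, self.n_cic) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def diameter_px(self) -> int:
        return int(round(self.core_diameter_mm * 1000.0 / self.pixel_size_um))

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.core_diameter_mm / 2) ** 2


@dataclass
class TissueCoreTruth:
    """Planted truth for one core; ``membrane_mask`` marks stained membrane pixels."""

    n_cells: int
    n_cic: int
    area_mm2: float
    ecad_level: int
    t_stage: str
    n_stage: str
    m_stage: str
    membrane_mask: np.ndarray | None = None


def _ring(img: np.ndarray, mask: np.ndarray, center: tuple[float, float],
          radius: float, thickness: float, value: float) -> None:
    rr, cc = draw.disk(center, radius, shape=img.shape)
    outer = np.zeros(img.shape, dtype=bool)
    outer[rr, cc] = True
    rr, cc = draw.disk(center, max(radius - thickness, 1), shape=img.shape)
    outer[rr, cc] = False
    img[outer] = value
    mask |= outer


def generate_tissue_core(spec: TissueCoreSpec) -> tuple[ImageStack, TissueCoreTruth]:
    """Render one IHC core image and its truth record.

    Cells are membrane rings at the mean gray level of ``ecad_level`` (plus
    per-cell jitter); CIC figures are a ring inside a ring.  Mean membrane
    intensity increases strictly with the level by construction.
    """
    rng = np.random.default_rng(spec.seed)
    d_px = spec.diameter_px
    pad = 10
    side = d_px + 2 * pad
    center = (side / 2, side / 2)
    img = np.full((side, side), OUTSIDE_CORE, dtype=np.float64)
    rr, cc = draw.disk(center, d_px / 2, shape=img.shape)
    img[rr, cc] = TISSUE_BACKGROUND
    membrane = np.zeros(img.shape, dtype=bool)

    level_mean = ECAD_LEVEL_MEANS[spec.ecad_level]
    core_r = d_px / 2

    def sample_center(radius: float) -> tuple[float, float]:
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            ang = rng.uniform(0, 2 * math.pi)
            rad = core_r * math.sqrt(rng.uniform(0, 1))
            r_ = center[0] + rad * math.sin(ang)
            c_ = center[1] + rad * math.cos(ang)
            if math.hypot(r_ - center[0], c_ - center[1]) + radius < core_r:
                return r_, c_
        raise PlacementError("could not place cell inside core")

    n_plain = spec.n_cells - spec.n_cic
    for _ in range(n_plain):
        radius = rng.uniform(8, 12)
        ctr = sample_center(radius)
        value = max(level_mean + rng.normal(0, 5), TISSUE_BACKGROUND + 2)
        _ring(img, membrane, ctr, radius, 2.0, value)

    for _ in range(spec.n_cic):
        radius = rng.uniform(11, 14)
        ctr = sample_center(radius)
        value = max(level_mean + rng.normal(0, 5), TISSUE_BACKGROUND + 2)
        _ring(img, membrane, ctr, radius, 2.0, value)
        _ring(img, membrane, ctr, radius * 0.5, 2.0, value)  # engulfed ring

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    channel = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = ImageStack(channels={"ihc": channel}, pixel_size_um=spec.pixel_size_um,
                       bit_depth=8)
    truth = TissueCoreTruth(
        n_cells=spec.n_cells,
        n_cic=spec.n_cic,
        area_mm2=spec.area_mm2,
        ecad_level=spec.ecad_level,
        t_stage=spec.t_stage,
        n_stage=spec.n_stage,
        m_stage=spec.m_stage,
        membrane_mask=membrane,
    )
    return stack, truth


def generate_cohort(n_cores: int, density_by_group: Mapping[str, float], seed: int = 0,
                    template: TissueCoreSpec | None = None) -> list[TissueCoreSpec]:
    """Draw a cohort of core specs with group-wise CIC densities.

    Each group receives ``n_cores`` cores; per-core CIC counts are Poisson
    with mean ``density x core area`` (rare spatial events).  The group name
    is recorded in ``n_stage`` so the cohort can be aggregated with the same
    machinery as the N-stage tables.  The E-cadherin level is drawn uniformly
    from 0..3.
    """
    if any(d < 0 for d in density_by_group.values()):
        raise ValueError("densities must be >= 0")
    template = template or TissueCoreSpec()
    rng = np.random.default_rng(seed)
    specs: list[TissueCoreSpec] = []
    for group in sorted(density_by_group):
        density = density_by_group[group]
        lam = density * template.area_mm2
        for _ in range(n_cores):
            n_cic = int(rng.poisson(lam))
            n_cells = max(template.n_cells, n_cic)
            specs.append(replace(
                template,
                n_cells=n_cells,
                n_cic=n_cic,
                ecad_level=int(rng.integers(0, 4)),
                n_stage=group,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return specs
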