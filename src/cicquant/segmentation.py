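"""Threshold-based segmentation of fluorescence channels into labeled cells.

The green channel yields viable cells, the red channel dead cells, and the
DAPI channel nuclei.  Segmentation is deliberately simple — global Otsu (or
a fixed threshold), hole filling, small-object removal, and an optional
distance-transform watershed to split touching blobs — because the synthetic
scenes and the assay's real images both present bright convex cells on a
dark background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation as sk_seg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of :func:`segment_channel`.

    ``min_area_px`` defaults to 30 px (~120 um^2 at 2 um/px), below any
    plausible cell, to suppress noise specks; it is scale-dependent and
    should be adjusted with the pixel size.
    """

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.0
    min_area_px: int = 30
    fill_holes: bool = True
    split_touching: bool = False
    watershed_min_distance_px: int = 7

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass
class CellObject:
    """One segmented region: geometry plus class and optional nucleus link.

    ``coords`` are the (row, col) pixels of the region in frame coordinates;
    ``perimeter_px`` is the 4-direction Crofton estimate, the single
    perimeter estimator used throughout (circularity uses the same one).
    """

    id: int
    cls: str  # "viable" | "dead" | "nucleus"
    pixel_count: int
    centroid: tuple[float, float]
    perimeter_px: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    coords: np.ndarray
    border_touching: bool = False
    nucleus_id: int | None = None
    flags: list[str] | None = None


def segment_channel(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment one 2-D intensity channel into a labeled mask.

    Returns an int mask with background 0 and labels 1..n contiguous.  An
    all-constant channel yields an empty mask rather than an error.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError("segment_channel expects a 2-D array")
    if channel.max() == channel.min():
        return np.zeros(channel.shape, dtype=np.int32)

    if params.threshold_method == "otsu":
        thresh = filters.threshold_otsu(channel)
    else:
        thresh = params.fixed_threshold
    binary = channel > thresh

    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)
    # max_size removes components of <= that many pixels; keep >= min_area_px
    binary = morphology.remove_small_objects(binary, max_size=params.min_area_px - 1,
                                             connectivity=2)
    if not binary.any():
        return np.zeros(channel.shape, dtype=np.int32)

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        peaks = feature.peak_local_max(
            distance, min_distance=params.watershed_min_distance_px, labels=binary,
            exclude_border=False)
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = sk_seg.watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary, structure=np.ones((3, 3), dtype=int))

    # drop fragments under min_area_px (watershed can shave small slivers)
    counts = np.bincount(labels.ravel())
    small = counts < params.min_area_px
    small[0] = False
    labels[small[labels]] = 0
    # relabel 1..n contiguous, preserving scan order
    labels, _, _ = sk_seg.relabel_sequential(labels)
    return labels.astype(np.int32)


def extract_objects(mask: np.ndarray, cls: str) -> list[CellObject]:
    """One :class:`CellObject` per label, ordered by label.

    Area is the raw pixel count; the centroid is the pixel-center mean;
    border-touching regions are flagged (they are retained for counting but
    excluded as CIC hosts downstream).
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    objects: list[CellObject] = []
    for rp in measure.regionprops(mask):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        objects.append(CellObject(
            id=int(rp.label),
            cls=cls,
            pixel_count=int(rp.area),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            perimeter_px=float(rp.perimeter_crofton),
            bbox=(minr, minc, maxr, maxc),
            coords=rp.coords.copy(),
            border_touching=touches,
            flags=["border"] if touches else [],
        ))
    objects.sort(key=lambda o: o.id)
    return objects


def assign_nuclei(viable: list[CellObject], cell_mask: np.ndarray,
                  nucleus_mask: np.ndarray) -> list[CellObject]:
    """Link each viable cell to its nucleus.

    A nucleus belongs to the cell whose mask contains its centroid pixel;
    if a cell collects several nuclei the one with the largest pixel overlap
    wins, ties to the lowest nucleus label.  A nucleus whose centroid falls
    on background is attached to the cell it overlaps most (logged), or left
    unassigned.  Cells without any nucleus get ``nucleus_id=None`` and a
    ``no_nucleus`` flag.  Returns the same objects, updated in place.
    """
    cell_mask = np.asarray(cell_mask)
    by_id = {o.id: o for o in viable}
    # candidate nuclei per cell: (overlap, nucleus_label)
    candidates: dict[int, list[tuple[int, int]]] = {o.id: [] for o in viable}

    for rp in measure.regionprops(np.asarray(nucleus_mask)):
        r, c = (int(round(rp.centroid[0])), int(round(rp.centroid[1])))
        r = min(max(r, 0), cell_mask.shape[0] - 1)
        c = min(max(c, 0), cell_mask.shape[1] - 1)
        owner = int(cell_mask[r, c])
        overlaps = cell_mask[rp.coords[:, 0], rp.coords[:, 1]]
        if owner == 0 or owner not in by_id:
            # centroid on background: fall back to the largest-overlap cell
            labels, counts = np.unique(overlaps[overlaps > 0], return_counts=True)
            labels = [l for l in labels if l in by_id]
            if not labels:
                logger.info("nucleus %d has no containing cell; left unassigned", rp.label)
                continue
            owner = int(max(labels, key=lambda l: counts[list(labels).index(l)]))
            logger.info("nucleus %d centroid on background; assigned to cell %d by overlap",
                        rp.label, owner)
        overlap = int((overlaps == owner).sum())
        candidates[owner].append((overlap, int(rp.label)))

    for cell in viable:
        cands = candidates.get(cell.id, [])
        if not cands:
            cell.nucleus_id = None
            cell.flags = (cell.flags or []) + ["no_nucleus"]
            continue
        # largest overlap, then lowest label
        overlap, label = max(cands, key=lambda t: (t[0], -t[1]))
        if len(cands) > 1:
            logger.info("cell %d claimed by %d nuclei; kept nucleus %d (overlap %d)",
                        cell.id, len(cands), label, overlap)
        cell.nucleus_id = label
    return viable
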