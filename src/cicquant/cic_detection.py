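"""Cell-in-cell event detection.

A dead (red) cell counts as engulfed when three morphological criteria hold
simultaneously:

1. **Containment** — the fraction of the dead cell's pixels lying inside a
   viable (green) cell is at least ``containment_min`` (default 0.90; the
   biology demands complete engulfment, the 10% slack absorbs segmentation
   boundary jitter).
2. **Circularity** — the dead cell is round (4*pi*area/perimeter^2 >=
   ``circularity_min``), since a dead cell cannot adhere and spread inside
   its host.
3. **Crescent imprint** — the host nucleus is indented by the engulfed
   cell, quantified as the nuclear solidity deficit
   (1 - area/convex hull area), at least ``crescent_min``, with the hull
   defect adjacent to the engulfed cell.

Each dead cell is assigned to at most one host (highest containment, ties to
the larger host, then lower label); every scored candidate pair is retained
with ``accepted=False`` for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import morphology

from .segmentation import CellObject


@dataclass(frozen=True)
class CicParams:
    containment_min: float = 0.90
    circularity_min: float = 0.70
    crescent_min: float = 0.10
    require_crescent: bool = True
    exclude_border_hosts: bool = True
    #: hull-defect centroid must lie within this multiple of the engulfed
    #: radius of the engulfed centroid for the crescent to count
    crescent_adjacency_factor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("containment_min", "circularity_min", "crescent_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class CicEvent:
    host_id: int
    engulfed_id: int
    containment_fraction: float
    circularity: float
    crescent_score: float
    accepted: bool
    reject_reason: str = ""


def _linear_indices(obj: CellObject, width: int) -> np.ndarray:
    return obj.coords[:, 0].astype(np.int64) * width + obj.coords[:, 1]


def containment_fraction(dead: CellObject, host: CellObject, frame_width: int = 1 << 20) -> float:
    """|pixels(dead) intersect pixels(host)| / |pixels(dead)|.

    Both objects must come from the same frame; ``frame_width`` only needs
    to exceed the frame's column count (it linearizes coordinates).
    """
    if dead.pixel_count == 0:
        raise ValueError("dead object has no pixels")
    # quick bbox rejection
    if (dead.bbox[2] <= host.bbox[0] or host.bbox[2] <= dead.bbox[0]
            or dead.bbox[3] <= host.bbox[1] or host.bbox[3] <= dead.bbox[1]):
        return 0.0
    a = _linear_indices(dead, frame_width)
    b = _linear_indices(host, frame_width)
    inter = np.intersect1d(a, b, assume_unique=True)
    return float(len(inter) / len(a))


def circularity(obj: CellObject) -> float:
    """4*pi*area / perimeter^2 with the Crofton perimeter, capped at 1.0."""
    if obj.pixel_count == 0:
        raise ValueError("object has no pixels")
    if obj.perimeter_px == 0:
        raise ValueError(f"object {obj.id} has zero perimeter")
    return min(4.0 * math.pi * obj.pixel_count / obj.perimeter_px**2, 1.0)


def _hull_mask(crop: np.ndarray) -> np.ndarray:
    """Rasterized convex hull of a boolean crop.

    The hull polygon is taken over the foreground pixel centers and a pixel
    belongs to the rasterized hull when its center lies inside or on the
    polygon.  With this convention a rasterized disk is exactly digitally
    convex (deficit 0).  Degenerate shapes (a single pixel, a 1-px line)
    are their own hull.
    """
    rows, cols = np.nonzero(crop)
    if len(rows) == 0:
        raise ValueError("nucleus has no pixels")
    pts = np.stack([rows, cols], axis=1).astype(float)
    try:
        hull = ConvexHull(pts)
    except Exception:  # QhullError: < 2-D point set, i.e. already convex
        return crop.copy()
    # points inside satisfy A @ x + b <= 0 for every facet (outward normals)
    normals = hull.equations[:, :2]
    offsets_b = hull.equations[:, 2]
    rr, cc = np.meshgrid(np.arange(crop.shape[0]), np.arange(crop.shape[1]),
                         indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = (centers @ normals.T + offsets_b <= 1e-9).all(axis=1)
    return inside.reshape(crop.shape)


def crescent_score(nucleus: CellObject) -> float:
    """Solidity deficit of the nucleus: 1 - area / convex-hull area.

    Zero for a convex nucleus; grows with the depth of the engulfed cell's
    indentation.
    """
    hull = _hull_mask(_object_crop(nucleus))
    return 1.0 - nucleus.pixel_count / int(hull.sum())


def hull_defect_centroid(nucleus: CellObject) -> tuple[float, float] | None:
    """Centroid (frame coords) of hull-minus-shape pixels; None if convex."""
    crop = _object_crop(nucleus)
    defect = _hull_mask(crop) & ~crop
    if not defect.any():
        return None
    rows, cols = np.nonzero(defect)
    return (float(rows.mean() + nucleus.bbox[0]), float(cols.mean() + nucleus.bbox[1]))


def _object_crop(obj: CellObject) -> np.ndarray:
    minr, minc, maxr, maxc = obj.bbox
    crop = np.zeros((maxr - minr, maxc - minc), dtype=bool)
    crop[obj.coords[:, 0] - minr, obj.coords[:, 1] - minc] = True
    return crop


def _equivalent_radius(obj: CellObject) -> float:
    return math.sqrt(obj.pixel_count / math.pi)


def detect_cic(viable: list[CellObject], dead: list[CellObject],
               nuclei: list[CellObject], params: CicParams = CicParams()) -> list[CicEvent]:
    """Score every overlapping (dead, viable) pair and accept CIC events.

    Returns all candidates ordered by (engulfed label, host label); accepted
    events satisfy every enabled criterion and each dead cell appears in at
    most one accepted event.
    """
    nuclei_by_id = {n.id: n for n in nuclei}
    events: list[CicEvent] = []

    for d in sorted(dead, key=lambda o: o.id):
        candidates: list[tuple[CicEvent, CellObject]] = []
        for v in sorted(viable, key=lambda o: o.id):
            cont = containment_fraction(d, v)
            if cont == 0.0:
                continue
            circ = circularity(d)
            reasons = []
            if cont < params.containment_min:
                reasons.append(f"containment {cont:.3f} < {params.containment_min}")
            if circ < params.circularity_min:
                reasons.append(f"circularity {circ:.3f} < {params.circularity_min}")
            if params.exclude_border_hosts and v.border_touching:
                reasons.append("host touches image border")

            crescent = 0.0
            if v.nucleus_id is not None and v.nucleus_id in nuclei_by_id:
                nucleus = nuclei_by_id[v.nucleus_id]
                crescent = crescent_score(nucleus)
                if params.require_crescent:
                    if crescent < params.crescent_min:
                        reasons.append(
                            f"crescent {crescent:.3f} < {params.crescent_min}")
                    else:
                        defect = hull_defect_centroid(nucleus)
                        limit = params.crescent_adjacency_factor * _equivalent_radius(d)
                        if defect is None or math.hypot(
                                defect[0] - d.centroid[0],
                                defect[1] - d.centroid[1]) > limit:
                            reasons.append("nuclear indentation not adjacent to engulfed cell")
            elif params.require_crescent:
                reasons.append("host has no assigned nucleus")

            candidates.append((CicEvent(
                host_id=v.id, engulfed_id=d.id,
                containment_fraction=cont, circularity=circ,
                crescent_score=crescent,
                accepted=not reasons,
                reject_reason="; ".join(reasons),
            ), v))

        # single assignment: keep the best passing host, demote the rest
        passing = [(ev, v) for ev, v in candidates if ev.accepted]
        if len(passing) > 1:
            best = max(passing, key=lambda t: (
                t[0].containment_fraction, t[1].pixel_count, -t[0].host_id))
            for ev, _ in passing:
                if ev is not best[0]:
                    ev.accepted = False
                    ev.reject_reason = "dead cell assigned to a better host"
        events.extend(ev for ev, _ in candidates)

    events.sort(key=lambda e: (e.engulfed_id, e.host_id))
    return events


def events_frame(events: list[CicEvent]):
    """Events as a pandas DataFrame (one row per candidate, audit-friendly)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "host_id": e.host_id,
            "engulfed_id": e.engulfed_id,
            "containment_fraction": e.containment_fraction,
            "circularity": e.circularity,
            "crescent_score": e.crescent_score,
            "accepted": e.accepted,
            "reject_reason": e.reject_reason,
        }
        for e in events
    ])


def overlay_image(shape: tuple[int, int], viable: list[CellObject],
                  dead: list[CellObject], events: list[CicEvent]) -> np.ndarray:
    """RGB overlay for manual verification: viable green, dead red, accepted
    CIC hosts outlined in white."""
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    for v in viable:
        rgb[v.coords[:, 0], v.coords[:, 1], 1] = 128
    for d in dead:
        rgb[d.coords[:, 0], d.coords[:, 1], 0] = 128
    accepted_hosts = {e.host_id for e in events if e.accepted}
    for v in viable:
        if v.id in accepted_hosts:
            crop = _object_crop(v)
            boundary = crop & ~morphology.binary_erosion(crop)
            rows, cols = np.nonzero(boundary)
            rgb[rows + v.bbox[0], cols + v.bbox[1]] = 255
    return rgb
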