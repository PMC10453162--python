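"""E-cadherin intensity measurement and semiquantitative scoring.

Cell-line (fluorescence) mode reports the raw background-subtracted mean
gray level of the stain mask.  Tissue mode bins that mean into the standard
0-3 membranous score: 0 no staining, 1 low-to-moderate, 2 moderate-to-high,
3 high.  The bin cutpoints are calibration inputs; for real slides they must
be set against reference cores, while the defaults here are the midpoints
between the synthetic generator's level means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic_data import ECAD_LEVEL_MEANS, TISSUE_BACKGROUND

#: Default cutpoints between scores 0|1, 1|2, 2|3, in background-subtracted
#: gray levels: midpoints of the generator's level means.
DEFAULT_BIN_EDGES: tuple[float, float, float] = tuple(
    (ECAD_LEVEL_MEANS[i] + ECAD_LEVEL_MEANS[i + 1]) / 2 - TISSUE_BACKGROUND
    for i in range(3)
)


@dataclass
class EcadMeasurement:
    sample_id: str
    mean_gray: float
    score: int | None = None
    bin_edges: tuple[float, float, float] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if self.mean_gray < 0:
            raise ValueError("mean_gray must be >= 0")
        if self.score is not None and self.score not in (0, 1, 2, 3):
            raise ValueError(f"score must be in 0..3, got {self.score}")
        if not (self.bin_edges[0] < self.bin_edges[1] < self.bin_edges[2]):
            raise ValueError("bin_edges must be strictly increasing")


def mean_intensity(channel: np.ndarray, stain_mask: np.ndarray) -> float:
    """Background-subtracted mean intensity over the stain mask.

    Background is the median intensity outside the mask; the subtracted
    mean is clipped at zero (an intensity cannot be negative).
    """
    channel = np.asarray(channel, dtype=np.float64)
    stain_mask = np.asarray(stain_mask, dtype=bool)
    if channel.shape != stain_mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not stain_mask.any():
        raise ValueError("stain mask is empty")
    background = float(np.median(channel[~stain_mask])) if (~stain_mask).any() else 0.0
    return max(float(channel[stain_mask].mean()) - background, 0.0)


def score_intensity(mean_gray: float,
                    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> int:
    """Bin a mean gray level into the 0-3 score.

    The score is the number of edges strictly below ``mean_gray``; a value
    exactly at an edge falls into the lower bin.
    """
    edges = tuple(bin_edges)
    if len(edges) != 3 or not (edges[0] < edges[1] < edges[2]):
        raise ValueError("bin_edges must be three strictly increasing cutpoints")
    return int(sum(mean_gray > e for e in edges))


def score_core(channel: np.ndarray, stain_mask: np.ndarray, sample_id: str = "core",
               bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> EcadMeasurement:
    """Measure and score one tissue core in a single call."""
    mg = mean_intensity(channel, stain_mask)
    return EcadMeasurement(sample_id=sample_id, mean_gray=mg,
                           score=score_intensity(mg, bin_edges),
                           bin_edges=tuple(bin_edges))


def score_distribution(measurements: Iterable[EcadMeasurement]) -> dict:
    """Counts and percentages of cores per score bin.

    Returns ``{"counts": {0: .., 1: .., 2: .., 3: ..}, "percent": {...}}``;
    percentages sum to 100 up to rounding.
    """
    scores = [m.score for m in measurements]
    if not scores:
        raise ValueError("no measurements given")
    if any(s is None for s in scores):
        raise ValueError("all measurements must carry a score")
    counts = {k: scores.count(k) for k in (0, 1, 2, 3)}
    n = len(scores)
    percent = {k: 100.0 * v / n for k, v in counts.items()}
    return {"counts": counts, "percent": percent}
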