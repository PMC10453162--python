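"""Summary statistics: CIC rate, CIC density, and group aggregation.

The CIC rate of a sample is 100 * n_cic / n_viable (percent of viable cells
that have engulfed a dead cell); in tissue cores the density is
n_cic / core area in events per mm^2.  Group tables report mean and sample
SD of density, the fraction of cores with at least one event, and whether
the group is large enough (n >= 5) to enter significance testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cic_detection import CicEvent
from .segmentation import CellObject
from .synthetic_data import TissueCoreTruth

#: Minimum group size for significance testing.
MIN_GROUP_FOR_SIGNIFICANCE = 5


@dataclass
class SampleSummary:
    sample_id: str
    mode: str  # "coincubation" | "tissue"
    n_viable: int
    n_dead: int
    n_cic: int
    cic_rate_percent: float  # NaN when n_viable == 0
    area_mm2: float | None = None
    cic_per_mm2: float | None = None
    ecad_score: int | None = None
    t_stage: str | None = None
    n_stage: str | None = None
    m_stage: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_viable, self.n_dead, self.n_cic) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_cic > self.n_dead:
            raise ValueError("n_cic cannot exceed n_dead (every CIC engulfs a dead cell)")


@dataclass
class GroupSummary:
    group_key: str
    n_samples: int
    mean_cic_per_mm2: float
    sd_cic_per_mm2: float  # NaN for n_samples < 2
    fraction_with_cic: float
    significance_eligible: bool


def cic_rate(n_cic: int, n_viable: int) -> float:
    """Percent of viable cells containing a dead cell; NaN when no viable cells."""
    if n_cic < 0 or n_viable < 0:
        raise ValueError("counts must be >= 0")
    if n_viable == 0:
        return math.nan
    return 100.0 * n_cic / n_viable


def cic_density(n_cic: int, area_mm2: float) -> float:
    """CIC events per mm^2 of tissue."""
    if n_cic < 0:
        raise ValueError("n_cic must be >= 0")
    if area_mm2 <= 0:
        raise ValueError(f"area_mm2 must be > 0, got {area_mm2}")
    return n_cic / area_mm2


def summarize_sample(events: Sequence[CicEvent], viable: Sequence[CellObject],
                     dead: Sequence[CellObject], sample_id: str = "sample",
                     mode: str = "coincubation",
                     area_mm2: float | None = None) -> SampleSummary:
    """Counts and rate for one analyzed image.

    The viable count includes host cells and the dead count includes
    engulfed cells (the rate's denominator is *all* viable cells).
    """
    n_cic = sum(1 for e in events if e.accepted)
    n_viable = len(viable)
    n_dead = len(dead)
    density = None
    if mode == "tissue":
        if area_mm2 is None:
            raise ValueError("tissue mode requires area_mm2")
        density = cic_density(n_cic, area_mm2)
    return SampleSummary(
        sample_id=sample_id, mode=mode, n_viable=n_viable, n_dead=n_dead,
        n_cic=n_cic, cic_rate_percent=cic_rate(n_cic, n_viable),
        area_mm2=area_mm2, cic_per_mm2=density,
    )


def summarize_core(truth: TissueCoreTruth, sample_id: str = "core") -> SampleSummary:
    """Summary of a tissue core from its truth record (manual-count pathway)."""
    return SampleSummary(
        sample_id=sample_id, mode="tissue",
        n_viable=truth.n_cells, n_dead=truth.n_cic, n_cic=truth.n_cic,
        cic_rate_percent=cic_rate(truth.n_cic, truth.n_cells),
        area_mm2=truth.area_mm2,
        cic_per_mm2=cic_density(truth.n_cic, truth.area_mm2),
        ecad_score=truth.ecad_level,
        t_stage=truth.t_stage, n_stage=truth.n_stage, m_stage=truth.m_stage,
    )


def aggregate_groups(summaries: Iterable[SampleSummary], group_key: str
                     ) -> list[GroupSummary]:
    """Group tissue summaries by a stage label or the E-cadherin score.

    ``group_key`` is one of ``t_stage``, ``n_stage``, ``m_stage``,
    ``ecad_score``.  Unknown-stage samples form their own group.  The SD is
    the sample standard deviation (ddof=1), NaN for singleton groups.
    """
    buckets: dict[str, list[SampleSummary]] = {}
    for s in summaries:
        key = getattr(s, group_key)
        key = "unknown" if key is None else str(key)
        buckets.setdefault(key, []).append(s)

    out = []
    for key in sorted(buckets):
        members = buckets[key]
        densities = np.array([m.cic_per_mm2 for m in members], dtype=float)
        out.append(GroupSummary(
            group_key=key,
            n_samples=len(members),
            mean_cic_per_mm2=float(densities.mean()),
            sd_cic_per_mm2=float(densities.std(ddof=1)) if len(members) > 1 else math.nan,
            fraction_with_cic=float(np.mean([m.n_cic >= 1 for m in members])),
            significance_eligible=len(members) >= MIN_GROUP_FOR_SIGNIFICANCE,
        ))
    return out


@dataclass
class ConditionSummary:
    """Per-condition (adherent or suspension) aggregate across cell lines.

    Two views are reported because they answer different questions and do
    not agree arithmetically: the unweighted mean +/- SD of per-line rates,
    and the pooled rate computed from summed counts.
    """

    condition: str
    n_lines: int
    mean_rate_percent: float
    sd_rate_percent: float  # NaN for a single line
    total_viable: int
    total_dead: int
    total_cic: int
    pooled_rate_percent: float
    mean_viable_per_line: float
    mean_dead_per_line: float
    mean_cic_per_line: float


def aggregate_cell_lines(per_line: Mapping[str, SampleSummary], condition: str
                         ) -> ConditionSummary:
    """Aggregate per-line summaries for one co-incubation condition."""
    if not per_line:
        raise ValueError("no cell lines given")
    rates = np.array([s.cic_rate_percent for s in per_line.values()], dtype=float)
    valid = rates[~np.isnan(rates)]  # lines with zero viable cells have no rate
    tv = sum(s.n_viable for s in per_line.values())
    td = sum(s.n_dead for s in per_line.values())
    tc = sum(s.n_cic for s in per_line.values())
    n = len(per_line)
    return ConditionSummary(
        condition=condition,
        n_lines=n,
        mean_rate_percent=float(valid.mean()) if len(valid) else math.nan,
        sd_rate_percent=float(valid.std(ddof=1)) if len(valid) > 1 else math.nan,
        total_viable=tv,
        total_dead=td,
        total_cic=tc,
        pooled_rate_percent=cic_rate(tc, tv),
        mean_viable_per_line=tv / n,
        mean_dead_per_line=td / n,
        mean_cic_per_line=tc / n,
    )


def summaries_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Sample summaries as a results DataFrame (see image_io.RESULTS_COLUMNS)."""
    return pd.DataFrame([
        {
            "sample_id": s.sample_id,
            "mode": s.mode,
            "n_viable": s.n_viable,
            "n_dead": s.n_dead,
            "n_cic": s.n_cic,
            "cic_rate_percent": s.cic_rate_percent,
            "area_mm2": s.area_mm2,
            "cic_per_mm2": s.cic_per_mm2,
            "ecad_score": s.ecad_score,
            "t_stage": s.t_stage,
            "n_stage": s.n_stage,
            "m_stage": s.m_stage,
        }
        for s in summaries
    ])


def groups_frame(groups: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": g.group_key,
            "n_samples": g.n_samples,
            "mean_cic_per_mm2": g.mean_cic_per_mm2,
            "sd_cic_per_mm2": g.sd_cic_per_mm2,
            "fraction_with_cic": g.fraction_with_cic,
            "significance_eligible": g.significance_eligible,
        }
        for g in groups
    ])
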