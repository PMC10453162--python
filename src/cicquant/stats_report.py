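"""Statistical comparisons and the run report.

Covers three statistical analyses: Pearson correlation of
E-cadherin intensity with CIC rate, a paired comparison of per-line CIC
rates between adherent and suspension co-incubation, and pairwise group
comparisons of tissue densities gated by a minimum group size of five.
No multiple-testing correction is applied (the report states how many
comparisons were made).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import MIN_GROUP_FOR_SIGNIFICANCE

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    note: str = ""


@dataclass
class ComparisonResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p: float
    statistic: float
    test_name: str
    paired: bool
    n: int
    dropped: tuple[str, ...] = ()


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided t-based p-value.

    Constant input makes r undefined; the result then carries NaN and an
    explanatory note instead of propagating a bare NaN silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, p=math.nan, n=len(x),
                                 note="undefined: constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def compare_conditions(adherent: Mapping[str, float], suspension: Mapping[str, float],
                       test: str = "paired_t") -> ComparisonResult:
    """Paired comparison of per-line CIC rates between the two conditions.

    Lines present in only one condition (e.g. a line that cannot be
    adherently cultured) are dropped with a logged note.  ``test`` is
    ``paired_t`` (default) or ``wilcoxon``.
    """
    common = sorted(set(adherent) & set(suspension))
    dropped = tuple(sorted((set(adherent) | set(suspension)) - set(common)))
    if dropped:
        logger.info("dropping lines missing one condition: %s", ", ".join(dropped))
    if len(common) < 2:
        raise ValueError(f"need at least 2 complete pairs, got {len(common)}")
    a = np.array([adherent[k] for k in common], dtype=float)
    b = np.array([suspension[k] for k in common], dtype=float)

    if test == "paired_t":
        if np.ptp(a - b) == 0:
            # zero-variance differences: no detectable effect (or exact shift)
            statistic = 0.0 if np.allclose(a, b) else math.inf
            p = 1.0 if np.allclose(a, b) else 0.0
        else:
            res = stats.ttest_rel(a, b)
            statistic, p = float(res.statistic), float(res.pvalue)
        name = "paired t-test"
    elif test == "wilcoxon":
        if np.all(a == b):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b)
            statistic, p = float(res.statistic), float(res.pvalue)
        name = "Wilcoxon signed-rank"
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        p=p, statistic=statistic, test_name=name, paired=True,
        n=len(common), dropped=dropped,
    )


def gate_significance(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise group comparisons, computed only where both groups have n >= 5.

    Empty groups are excluded entirely; pairs with an under-sized group are
    listed with ``p`` empty and note "not calculated".  Welch's t-test is
    used for the eligible pairs.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()
              if len(v) > 0}
    keys = sorted(groups)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            a, b = groups[ka], groups[kb]
            if len(a) >= MIN_GROUP_FOR_SIGNIFICANCE and len(b) >= MIN_GROUP_FOR_SIGNIFICANCE:
                if np.ptp(a) == 0 and np.ptp(b) == 0:
                    p, note = (1.0, "identical constant groups") if a.mean() == b.mean() \
                        else (0.0, "disjoint constant groups")
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                    note = ""
                rows.append({"group_a": ka, "group_b": kb, "n_a": len(a), "n_b": len(b),
                             "p": p, "note": note})
            else:
                rows.append({"group_a": ka, "group_b": kb, "n_a": len(a), "n_b": len(b),
                             "p": math.nan, "note": "not calculated"})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p", "note"])


def format_p(p: float) -> str:
    """Three decimals, with values below 0.001 printed as 'p < 0.001'."""
    if math.isnan(p):
        return "not calculated"
    if p < 0.001:
        return "p < 0.001"
    return f"p = {p:.3f}"


def build_report(tables: Mapping[str, pd.DataFrame | str]) -> str:
    """Assemble a self-contained markdown report from named tables.

    Sections appear in sorted key order; DataFrames are rendered as CSV
    blocks so the report is diff-able.  Missing sections are simply absent
    (a fluorescence-only run produces a report without tissue tables).
    Identical inputs give identical bytes.
    """
    lines = ["# Cell-in-cell quantification report", ""]
    n_comparisons = 0
    for key in sorted(tables):
        value = tables[key]
        lines.append(f"## {key}")
        lines.append("")
        if isinstance(value, pd.DataFrame):
            lines.append("```")
            lines.append(value.to_csv(index=False, float_format="%.4f",
                                      lineterminator="\n").rstrip("\n"))
            lines.append("```")
            if "p" in value.columns:
                n_comparisons += int(value["p"].notna().sum())
        else:
            lines.append(str(value))
        lines.append("")
    lines.append(f"Comparisons made (no multiplicity correction): {n_comparisons}")
    lines.append("")
    return "\n".join(lines)


def write_report(path, tables: Mapping[str, pd.DataFrame | str]) -> None:
    from pathlib import Path

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.md").write_text(build_report(tables))
    for key, value in tables.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.csv", index=False, float_format="%.4f",
                         lineterminator="\n")
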