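"""Rates, densities, and group aggregation, including the printed worked
examples from pooled co-incubation counts."""

import math

import numpy as np
import pytest

from cicquant.cic_detection import CicEvent
from cicquant.quantify import (SampleSummary, aggregate_cell_lines,
                               aggregate_groups, cic_density, cic_rate,
                               summarize_core, summarize_sample)
from cicquant.synthetic_data import TissueCoreTruth


def _event(host, eng, accepted=True):
    return CicEvent(host_id=host, engulfed_id=eng, containment_fraction=1.0,
                    circularity=1.0, crescent_score=0.2, accepted=accepted)


class TestCicRate:
    def test_zero_events(self):
        assert cic_rate(0, 250) == 0.0

    def test_pooled_adherent_worked_example(self):
        # pooled co-incubation totals: 959 CIC over 18,838 viable cells
        assert cic_rate(959, 18838) == pytest.approx(100 * 959 / 18838)
        assert cic_rate(959, 18838) == pytest.approx(5.0908, abs=1e-4)

    def test_no_viable_cells_is_undefined(self):
        assert math.isnan(cic_rate(10, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cic_rate(-1, 10)


class TestCicDensity:
    def test_examples(self):
        assert cic_density(0, 0.785) == 0.0
        assert cic_density(3, math.pi / 4) == pytest.approx(3.8197, abs=1e-4)
        assert cic_density(5, 2.0) == 2.5

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            cic_density(1, 0.0)


class TestSummarizeSample:
    def test_counts_include_hosts_and_engulfed(self):
        # 5 free viable + 2 hosts, 3 free dead + 2 engulfed, 2 accepted events
        viable = [object()] * 7
        dead = [object()] * 5
        events = [_event(1, 10), _event(2, 11), _event(3, 12, accepted=False)]
        s = summarize_sample(events, viable, dead, sample_id="scene7")
        assert (s.n_viable, s.n_dead, s.n_cic) == (7, 5, 2)
        assert s.cic_rate_percent == pytest.approx(100 * 2 / 7)

    def test_tissue_core_density(self):
        truth = TissueCoreTruth(n_cells=100, n_cic=5, area_mm2=math.pi / 4,
                                ecad_level=1, t_stage="T3", n_stage="N0",
                                m_stage="M0")
        s = summarize_core(truth, "core1")
        assert s.cic_per_mm2 == pytest.approx(5 / (math.pi / 4))
        assert s.cic_per_mm2 == pytest.approx(6.366, abs=1e-3)

    def test_empty_image_rate_undefined(self):
        s = summarize_sample([], [], [], sample_id="empty")
        assert (s.n_viable, s.n_dead, s.n_cic) == (0, 0, 0)
        assert math.isnan(s.cic_rate_percent)

    def test_more_cic_than_dead_rejected(self):
        with pytest.raises(ValueError):
            SampleSummary(sample_id="x", mode="coincubation", n_viable=5,
                          n_dead=1, n_cic=2, cic_rate_percent=40.0)


def _tissue_summary(sid, n_cic, n_stage="N0", area=math.pi / 4, ecad=None):
    return SampleSummary(
        sample_id=sid, mode="tissue", n_viable=100, n_dead=n_cic, n_cic=n_cic,
        cic_rate_percent=cic_rate(n_cic, 100), area_mm2=area,
        cic_per_mm2=cic_density(n_cic, area), n_stage=n_stage, ecad_score=ecad)


class TestAggregateGroups:
    def test_hand_arithmetic(self):
        summaries = [_tissue_summary("a", 0), _tissue_summary("b", 0),
                     _tissue_summary("c", 3)]
        (g,) = aggregate_groups(summaries, "n_stage")
        assert g.mean_cic_per_mm2 == pytest.approx(np.mean([0, 0, 3 / (math.pi / 4)]))
        assert g.mean_cic_per_mm2 == pytest.approx(1.273, abs=1e-3)
        assert g.fraction_with_cic == pytest.approx(1 / 3)

    def test_small_group_not_significance_eligible(self):
        summaries = [_tissue_summary(f"s{i}", 1) for i in range(4)]
        (g,) = aggregate_groups(summaries, "n_stage")
        assert g.n_samples == 4 and not g.significance_eligible
        summaries.append(_tissue_summary("s4", 1))
        (g,) = aggregate_groups(summaries, "n_stage")
        assert g.significance_eligible

    def test_all_zero_group(self):
        summaries = [_tissue_summary(f"s{i}", 0) for i in range(6)]
        (g,) = aggregate_groups(summaries, "n_stage")
        assert g.mean_cic_per_mm2 == 0.0
        assert g.sd_cic_per_mm2 == 0.0
        assert g.fraction_with_cic == 0.0

    def test_unknown_stage_forms_own_group(self):
        summaries = [_tissue_summary("a", 1, n_stage="N0"),
                     _tissue_summary("b", 1, n_stage="unknown")]
        groups = {g.group_key for g in aggregate_groups(summaries, "n_stage")}
        assert groups == {"N0", "unknown"}


def _line_summary(n_cic, n_viable, n_dead=None):
    return SampleSummary(sample_id="line", mode="coincubation", n_viable=n_viable,
                         n_dead=n_dead if n_dead is not None else n_cic,
                         n_cic=n_cic, cic_rate_percent=cic_rate(n_cic, n_viable))


class TestAggregateCellLines:
    def test_mean_and_sd_of_rates(self):
        lines = {"A": _line_summary(10, 100), "B": _line_summary(20, 100),
                 "C": _line_summary(30, 100)}
        s = aggregate_cell_lines(lines, "suspension")
        assert s.mean_rate_percent == pytest.approx(20.0)
        assert s.sd_rate_percent == pytest.approx(10.0)

    def test_pooled_totals_conserved(self):
        lines = {"A": _line_summary(5, 120, 30), "B": _line_summary(7, 80, 10)}
        s = aggregate_cell_lines(lines, "adherent")
        assert s.total_viable == 200
        assert s.total_cic == 12
        assert s.total_dead == 40
        assert s.pooled_rate_percent == pytest.approx(100 * 12 / 200)

    def test_suspension_per_line_worked_example(self):
        # 5,509 viable cells and 716 CIC pooled over 12 suspension lines
        lines = {f"L{i}": _line_summary(0, 0) for i in range(11)}
        lines["L11"] = _line_summary(716, 5509)
        s = aggregate_cell_lines(lines, "suspension")
        assert s.mean_viable_per_line == pytest.approx(5509 / 12)
        assert s.mean_viable_per_line == pytest.approx(459.08, abs=0.01)
        assert s.mean_cic_per_line == pytest.approx(716 / 12)

    def test_single_line_sd_undefined(self):
        s = aggregate_cell_lines({"A": _line_summary(3, 50)}, "adherent")
        assert math.isnan(s.sd_rate_percent)
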