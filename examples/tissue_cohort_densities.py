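"""Group-wise CIC density in a synthetic tissue-microarray cohort.

Draws a cohort of 1-mm cores with nodal-stage-dependent CIC densities,
aggregates events per mm^2 by group, and tests pairwise differences with
the minimum-group-size gate (no p-value for groups under five cores).
"""

from cicquant import aggregate_groups, gate_significance, summarize_core
from cicquant.quantify import groups_frame
from cicquant.synthetic_data import TissueCoreTruth, generate_cohort

densities = {"N0": 1.64, "N1": 0.76, "N2": 0.0}
specs = generate_cohort(60, densities, seed=11)
summaries = [
    summarize_core(TissueCoreTruth(s.n_cells, s.n_cic, s.area_mm2, s.ecad_level,
                                   s.t_stage, s.n_stage, s.m_stage), f"core{i}")
    for i, s in enumerate(specs)
]

groups = aggregate_groups(summaries, "n_stage")
print(groups_frame(groups).to_string(index=False))
# mean_cic_per_mm2 estimates the planted density of each stage group;
# fraction_with_cic is the share of cores with at least one event.

values = {g.group_key: [s.cic_per_mm2 for s in summaries if s.n_stage == g.group_key]
          for g in groups}
print()
print(gate_significance(values).to_string(index=False))
# Pairwise Welch tests; a pair is only tested when both groups have >= 5
# cores, otherwise the p column stays empty ("not calculated").
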