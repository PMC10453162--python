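"""Detect cell-in-cell events in a synthetic co-incubation scene.

Generates a three-channel scene (green viable cells, red dead cells, DAPI
nuclei) with three planted engulfment events, runs segmentation and CIC
detection, and prints the per-event scores next to the planted truth.
"""

from cicquant import SceneSpec, analyze_scene, generate_coincubation_scene

spec = SceneSpec(n_viable_free=6, n_dead_free=4, n_cic=3, seed=42)
stack, truth = generate_coincubation_scene(spec)
analysis = analyze_scene(stack)

print(f"planted: {truth.n_viable} viable, {truth.n_dead} dead, "
      f"{len(truth.pairs)} CIC pairs")
print(f"segmented: {len(analysis.viable)} viable, {len(analysis.dead)} dead, "
      f"{len(analysis.nuclei)} nuclei")
print()
print("accepted events (containment / circularity / crescent):")
for e in analysis.events:
    if e.accepted:
        print(f"  host {e.host_id} <- dead {e.engulfed_id}: "
              f"{e.containment_fraction:.2f} / {e.circularity:.2f} / "
              f"{e.crescent_score:.2f}")

s = analysis.summary
print()
print(f"CIC rate: {s.cic_rate_percent:.1f}% "
      f"({s.n_cic} events over {s.n_viable} viable cells)")
# The rate is the percentage of viable cells that have engulfed a dead
# cell; each accepted event passed full containment, a round engulfed
# cell, and a crescent imprint on the host nucleus.
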