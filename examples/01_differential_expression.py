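"""Differential-expression calling on a simulated shock experiment.

Simulates the nine-state triplicate design (wild-type control, four shock
time points, two tolerant mutants each with/without ethanol), then calls
genes responding to the first shock time point with the conjunctive rule:
replicate-mean |log2 ratio| >= 1.0 (two-fold) AND one-sample |Z| >= 2.0.
"""

from thermoevo import (
    SimulationConfig,
    call_de,
    contrast,
    simulate_expression,
    simulate_temporal_patterns,
    temporal_clusters,
)

eset, truth = simulate_expression(SimulationConfig(n_genes=500, seed=1))
control = eset.states[0]
treatment = eset.states[1]

vectors = contrast(eset, treatment, control)
results = call_de(vectors, ratio_cutoff=1.0, z_cutoff=2.0)
called = {r.gene_id for r in results if r.significant}
planted = truth.de_genes[f"{treatment}|{control}"]

print(f"contrast: {treatment} vs {control}")
print(f"significant genes: {len(called)} of {len(results)} tested")
print(f"planted responders recovered: {len(called & planted)}/{len(planted)}")
print(f"false calls: {len(called - planted)}")
# Every planted 2.0 log2-unit responder clears both cutoffs; at noise SD
# 0.25 with triplicates, unplanted genes essentially never do.

frame, archetype = simulate_temporal_patterns(n_genes=300, seed=1)
tc = temporal_clusters(frame, k=3, seed=0)
print(f"\ntemporal clustering: k={tc.k}, {tc.n_effective} effective clusters")
for c in range(tc.k):
    members = [g for g, m in tc.assignments.items() if m == c]
    print(f"  cluster {c}: {len(members)} genes, "
          f"centroid {[round(float(v), 2) for v in tc.centroids[c]]}")
# The three centroids reproduce the planted early-peak, late-rise and
# monotone-repression time courses.
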