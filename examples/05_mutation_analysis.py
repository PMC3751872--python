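"""Mutation analysis: consensus calls, effects, pooled frequencies, mu_g.

Plants mutations of known effect classes on a toy annotated genome, emits
three per-caller call sets (each with private false positives), intersects
them, annotates coding effects under the bacterial genetic code, scores
pooled allele frequencies at 140x depth, and computes the spontaneous
mutation rate per genome per generation.
"""

from dataclasses import replace

from thermoevo import (
    annotate_effects,
    consensus_calls,
    mutation_profile,
    mutation_rate,
    pooled_frequency,
    simulate_genome,
    simulate_mutations,
    simulate_pool_reads,
)

genome, annotation = simulate_genome(n_genes=20, seed=5)
call_sets, truth = simulate_mutations(genome, annotation, seed=5)

consensus, rejected = consensus_calls(list(call_sets.values()))
print(f"callers: {sorted(call_sets)}")
print(f"consensus mutations: {len(consensus)}; "
      f"caller-private calls set aside: {len(rejected)}")

annotated = annotate_effects(consensus, annotation, genome)
planted = dict(truth.planted_effects)
agree = sum(planted[c.key] == c.effect for c in annotated)
print(f"effect annotation matches planted truth: {agree}/{len(annotated)}")

# pooled community sequencing at the mutated loci: three non-synonymous
# mutations near fixation, the rest at intermediate frequency
non_syn = [c for c in annotated if c.effect in ("missense", "nonsense", "frameshift")]
pool_spec = [(c.pos, 0.95 if c in non_syn[:3] else 0.4) for c in annotated]
loci, _ = simulate_pool_reads(pool_spec, depth=140, seed=5)
freq = {l.pos: pooled_frequency(l) for l in loci}
annotated = [replace(c, pooled_freq=freq[c.pos]) for c in annotated]

summary = mutation_profile(annotated, generations=440)
print(f"\nby effect: {summary.by_effect}")
print(f"non-coding/coding ratio: {summary.noncoding_coding_ratio_percent}%")
print(f"candidate beneficial (non-synonymous, pooled frequency > 80%): "
      f"{[(c.gene, c.effect, round(c.pooled_freq, 2)) for c in summary.beneficial]}")
print(f"mu_g over 440 generations: {summary.mu_g}")
print(f"reference: 20 mutations / 440 generations = {mutation_rate(20, 440)}")
# mu_g divides the fixed consensus mutations by the generations elapsed;
# 20 mutations over 440 generations gives the benchmark 0.045.
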