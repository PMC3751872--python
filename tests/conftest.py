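import numpy as np
import pytest

from thermoevo import (
    PolycistronSpec,
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_mutations,
    simulate_operon_reads,
)


@pytest.fixture(scope="session")
def sim_default():
    """Nine-state triplicate dataset with planted DE and a memory pair."""
    return simulate_expression(SimulationConfig(n_genes=500, seed=11))


@pytest.fixture(scope="session")
def toy_genome():
    genome, annotation = simulate_genome(n_genes=20, seed=7)
    return genome, annotation


@pytest.fixture(scope="session")
def operon_sim(toy_genome):
    _, annotation = toy_genome
    forward = [g for g, _, _, st in annotation if st == "+"][:4]
    spec = [
        PolycistronSpec("pc1", forward, splits={"induced": {1}, "control": set()})
    ]
    tracks, links, truth = simulate_operon_reads(
        annotation, spec, depth=50.0, seed=7, conditions=["induced", "control"]
    )
    return annotation, spec, tracks, links, truth


@pytest.fixture(scope="session")
def mutation_sim(toy_genome):
    genome, annotation = toy_genome
    call_sets, truth = simulate_mutations(genome, annotation, seed=13)
    return genome, annotation, call_sets, truth


def exhaustive_partitions(items):
    """All set partitions of *items* (oracle helper for modularity tests)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in exhaustive_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1 :]
        yield [[first]] + part
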