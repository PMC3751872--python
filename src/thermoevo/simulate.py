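"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the design of an ethanol shock/adaptation
microevolution experiment on a thermophilic anaerobe: nine cellular states
(wild-type without ethanol; wild-type shocked with 0.15% ethanol and sampled
at 0.5/1/2/4 h; a 2%-tolerant mutant with and without 2% ethanol; a
6%-tolerant mutant with and without 6% ethanol), each in biological
triplicate, measured as log2 ratios against a common reference. On top of
Gaussian log2 noise it plants:

* per-state differential-expression signatures (a stated fraction of genes
  shifted by a stated log2 effect),
* co-expression blocks realised through shared latent factors with tunable
  within-block Pearson correlation,
* "memory" pairs — states constrained to share a contrast signature, so that
  their relative states are each other's nearest neighbours (the planted
  convergence pair),
* optional group signatures shared by a set of states (e.g. the mutant
  lineage), giving the two-group structure the bootstrap tree should resolve.

Separate generators emit per-base coverage tracks and bridging read-pair
tables over a toy annotated genome with planted suboperon boundaries, pooled
allele counts at a stated sequencing depth (binomial reads, default 140x),
and per-caller variant call sets planted by effect class. Every generator
returns its ground truth, and a fixed seed reproduces every output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionSet
from .mutations import MutationCall, PooledLocus

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PolycistronSpec",
    "NINE_STATES",
    "simulate_expression",
    "simulate_temporal_patterns",
    "simulate_genome",
    "simulate_operon_reads",
    "simulate_pool_reads",
    "simulate_mutations",
]

#: The nine cellular states of the experimental design (control first).
NINE_STATES = [
    "X-0%",
    "X-0.15%-0.5h",
    "X-0.15%-1h",
    "X-0.15%-2h",
    "X-0.15%-4h",
    "X_I-0%",
    "X_I-2%",
    "X_II-0%",
    "X_II-6%",
]


@dataclass
class PolycistronSpec:
    """A planted multi-gene transcription unit with per-condition boundaries.

    ``splits`` maps a condition label to the set of boundary indices *i*
    meaning "split between genes[i] and genes[i+1]". Adjacent suboperons are
    given depth tiers alternating by ``fold_step`` so every planted boundary
    carries a coverage step of exactly that fold. ``silent`` genes get zero
    depth (unexpressed).
    """

    id: str
    genes: list[str]
    splits: dict = field(default_factory=dict)  # condition -> set[int]
    fold_step: float = 3.0
    silent: dict = field(default_factory=dict)  # condition -> set[gene]


@dataclass
class SimulationConfig:
    n_genes: int = 500
    states: list[str] = field(default_factory=lambda: list(NINE_STATES))
    replicates_per_state: int = 3
    noise_sd: float = 0.25
    de_fraction: float = 0.1
    de_effect: float = 2.0
    module_spec: list[tuple[int, float]] = field(default_factory=list)
    memory_spec: list[tuple[str, str]] = field(
        default_factory=lambda: [("X-0.15%-4h", "X_II-0%")]
    )
    group_spec: list[list[str]] = field(default_factory=list)
    operon_spec: list[PolycistronSpec] = field(default_factory=list)
    pool_spec: list[tuple[int, float]] = field(default_factory=list)
    depth: float = 140.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.n_genes < 1 or self.replicates_per_state < 1:
            raise ValueError("n_genes and replicates_per_state must be positive")
        if self.noise_sd < 0 or self.depth < 0:
            raise ValueError("noise_sd and depth must be non-negative")
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes sum to more than n_genes")
        for size, rho in self.module_spec:
            if size < 2 or not 0 < rho < 1:
                raise ValueError(f"bad module spec entry ({size}, {rho})")
        known = set(self.states)
        for a, b in self.memory_spec:
            if a not in known or b not in known:
                raise ValueError(f"memory pair ({a!r}, {b!r}) not among states")
        for grp in self.group_spec:
            for s in grp:
                if s not in known:
                    raise ValueError(f"group state {s!r} not among states")
        for pos, f in self.pool_spec:
            if not 0 <= f <= 1:
                raise ValueError(f"pool frequency {f} at {pos} outside [0, 1]")


@dataclass
class GroundTruth:
    de_genes: dict = field(default_factory=dict)  # contrast label -> set of genes
    module_membership: dict = field(default_factory=dict)  # gene -> module idx
    split_boundaries: dict = field(default_factory=dict)  # (pid, cond) -> {(gi, gj)}
    true_freqs: dict = field(default_factory=dict)  # pos -> fraction
    planted_nearest_state_pair: tuple | None = None
    planted_effects: list = field(default_factory=list)  # mutation truth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionSet, GroundTruth]:
    """Gene x sample log2-ratio matrix with planted DE, modules and memory.

    The first state is the common control. Each other state receives its own
    random DE gene set (``de_fraction`` of genes, signs random, magnitude
    ``de_effect``); states paired in ``memory_spec`` share one signature.
    Co-expression blocks claim genes from the top of the index and add a
    per-sample latent factor scaled so the within-block Pearson correlation
    equals the requested value in expectation.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    reps = config.replicates_per_state
    samples = [(s, r) for s in config.states for r in range(reps)]
    n_samples = len(samples)

    control = config.states[0]
    n_de = int(round(config.de_fraction * config.n_genes))
    signature: dict[str, np.ndarray] = {}
    shared_with = {b: a for a, b in config.memory_spec}
    truth = GroundTruth()
    for state in config.states[1:]:
        if state in shared_with and shared_with[state] in signature:
            sig = signature[shared_with[state]].copy()
        else:
            sig = np.zeros(config.n_genes)
            idx = rng.choice(config.n_genes, size=n_de, replace=False)
            sig[idx] = rng.choice([-1.0, 1.0], size=n_de) * config.de_effect
        signature[state] = sig
        truth.de_genes[f"{state}|{control}"] = {
            genes[i] for i in np.nonzero(sig)[0]
        }
    if config.memory_spec:
        a, b = config.memory_spec[0]
        truth.planted_nearest_state_pair = (f"{a}|{control}", f"{b}|{control}")

    group_sig: dict[str, np.ndarray] = {}
    for grp in config.group_spec:
        sig = np.zeros(config.n_genes)
        idx = rng.choice(config.n_genes, size=max(n_de, 1), replace=False)
        sig[idx] = rng.choice([-1.0, 1.0], size=idx.size) * config.de_effect
        for s in grp:
            group_sig[s] = group_sig.get(s, 0) + sig
        for s in grp:
            if s != control:
                truth.de_genes.setdefault(f"{s}|{control}", set()).update(
                    genes[i] for i in idx
                )

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    for j, (state, _) in enumerate(samples):
        if state in signature:
            values[:, j] += signature[state]
        if state in group_sig:
            values[:, j] += group_sig[state]

    cursor = 0
    for m, (size, rho) in enumerate(config.module_spec):
        loading = config.noise_sd * np.sqrt(rho / (1.0 - rho))
        factors = rng.normal(0.0, 1.0, size=n_samples)
        block = slice(cursor, cursor + size)
        values[block, :] += loading * factors[np.newaxis, :]
        for g in genes[block]:
            truth.module_membership[g] = m
        cursor += size

    return ExpressionSet(genes, samples, values), truth


def simulate_temporal_patterns(
    n_genes: int = 300,
    archetypes: np.ndarray | None = None,
    effect: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Time-course DE profiles drawn from a few planted temporal archetypes.

    Default archetypes over four time points: early peak (shock genes that
    subside), late rise, and monotone repression. Genes are assigned evenly;
    returns the genes x time-points matrix of mean log2 ratios and the
    planted archetype index per gene.
    """
    if archetypes is None:
        archetypes = np.array(
            [
                [1.0, 0.5, 0.1, 0.0],   # early peak
                [0.0, 0.1, 0.5, 1.0],   # late rise
                [-0.2, -0.5, -0.8, -1.0],  # monotone down
            ]
        )
    rng = _rng(seed, 5)
    k, t = archetypes.shape
    labels = np.arange(n_genes) % k
    profiles = archetypes[labels] * effect + rng.normal(0, noise_sd, size=(n_genes, t))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    frame = pd.DataFrame(profiles, index=genes, columns=[f"t{j}" for j in range(t)])
    return frame, dict(zip(genes, (int(v) for v in labels)))


# ---------------------------------------------------------------------------
# toy genome, coverage tracks and read-pair links


def simulate_genome(
    n_genes: int = 20,
    gene_length: int = 300,
    spacer: int = 60,
    seed: int = 0,
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """A toy genome: equally spaced CDSs with no internal stop codons.

    Returns the sequence and a (gene, start, end, strand) annotation with
    1-based inclusive coordinates; all genes are forward-strand except every
    fifth, exercising strand-aware effect annotation.
    """
    if gene_length % 3:
        raise ValueError("gene_length must be a multiple of 3")
    rng = _rng(seed, 3)
    stops = {"TAA", "TAG", "TGA"}
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stops and a + b + c != "ATG"
    ]
    seq_parts: list[str] = []
    annotation = []
    pos = 1
    from Bio.Seq import Seq

    for i in range(n_genes):
        gap = "".join(rng.choice(list("ACGT"), size=spacer))
        body = "".join(rng.choice(codons, size=gene_length // 3 - 2))
        cds = "ATG" + body + "TAA"
        strand = "-" if (i + 1) % 5 == 0 else "+"
        if strand == "-":
            cds_on_genome = str(Seq(cds).reverse_complement())
        else:
            cds_on_genome = cds
        seq_parts.append(gap)
        pos += spacer
        start = pos
        seq_parts.append(cds_on_genome)
        pos += len(cds)
        annotation.append((f"g{i:03d}", start, pos - 1, strand))
    seq_parts.append("".join(rng.choice(list("ACGT"), size=spacer)))
    return "".join(seq_parts), annotation


def simulate_operon_reads(
    annotation: list[tuple[str, int, int, str]],
    operon_spec: list[PolycistronSpec],
    depth: float = 50.0,
    seed: int = 0,
    replicates: int = 3,
    conditions: list[str] | None = None,
    genome_length: int | None = None,
    pair_rate: float = 0.1,
) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Per-base coverage tracks and bridging-pair tables with planted splits.

    For each condition, genes of a polycistron are assigned depth tiers that
    alternate by ``fold_step`` across every planted boundary; per-base counts
    are Poisson around the tier mean. Bridging read-pair counts are positive
    (1 + Poisson) for every adjacency inside a planted transcription unit and
    zero across planted boundaries. Tracks are keyed ``(condition,
    replicate)``; the link table has columns (gene_i, gene_j, replicate,
    condition, n_pairs).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = _rng(seed, 1)
    coords = {g: (s, e, st) for g, s, e, st in annotation}
    for spec in operon_spec:
        missing = [g for g in spec.genes if g not in coords]
        if missing:
            raise ValueError(f"polycistron {spec.id}: genes not annotated: {missing}")
        strands = {coords[g][2] for g in spec.genes}
        if len(strands) > 1:
            raise ValueError(f"polycistron {spec.id} spans both strands")
    if conditions is None:
        conditions = sorted({c for spec in operon_spec for c in spec.splits}) or ["c0"]
    if genome_length is None:
        genome_length = max(e for _, _, e, _ in annotation) + 100

    truth = GroundTruth()
    tracks: dict[tuple[str, int], np.ndarray] = {}
    link_rows = []
    for cond in conditions:
        gene_mean: dict[str, float] = {}
        unit_of: dict[str, int] = {}
        for spec in operon_spec:
            splits = set(spec.splits.get(cond, set()))
            silent = set(spec.silent.get(cond, set()))
            tier = 0
            for i, g in enumerate(spec.genes):
                if i > 0 and (i - 1) in splits:
                    tier += 1
                unit_of[g] = tier
                mult = 0.0 if g in silent else spec.fold_step ** (tier % 2)
                gene_mean[g] = depth * mult
            truth.split_boundaries[(spec.id, cond)] = {
                (spec.genes[i], spec.genes[i + 1]) for i in splits
            }
        for rep in range(replicates):
            track = np.zeros(genome_length)
            for g, mean in gene_mean.items():
                s, e, _ = coords[g]
                if mean > 0:
                    track[s - 1 : e] = rng.poisson(mean, size=e - s + 1)
            tracks[(cond, rep)] = track
            for spec in operon_spec:
                splits = set(spec.splits.get(cond, set()))
                silent = set(spec.silent.get(cond, set()))
                for i in range(len(spec.genes) - 1):
                    gi, gj = spec.genes[i], spec.genes[i + 1]
                    if i in splits or gi in silent or gj in silent:
                        n = 0
                    else:
                        lam = pair_rate * min(gene_mean[gi], gene_mean[gj])
                        n = 1 + int(rng.poisson(lam))
                    link_rows.append(
                        {"gene_i": gi, "gene_j": gj, "replicate": rep,
                         "condition": cond, "n_pairs": n}
                    )
    links = pd.DataFrame(
        link_rows, columns=["gene_i", "gene_j", "replicate", "condition", "n_pairs"]
    )
    return tracks, links, truth


def simulate_pool_reads(
    pool_spec: list[tuple[int, float]],
    depth: float = 140.0,
    seed: int = 0,
    chrom: str = "chr",
) -> tuple[list[PooledLocus], GroundTruth]:
    """Pooled allele counts: binomial alternate reads at ~``depth`` coverage."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = _rng(seed, 2)
    truth = GroundTruth()
    loci = []
    for pos, freq in pool_spec:
        if not 0 <= freq <= 1:
            raise ValueError(f"frequency {freq} at {pos} outside [0, 1]")
        n = max(1, int(rng.poisson(depth)))
        alt = int(rng.binomial(n, freq))
        loci.append(PooledLocus(chrom, pos, ref_reads=n - alt, alt_reads=alt))
        truth.true_freqs[pos] = freq
    return loci, truth


# ---------------------------------------------------------------------------
# planted mutations and per-caller call sets

_EFFECTS = ("synonymous", "missense", "nonsense", "frameshift", "intergenic")


def _plant_snp_with_effect(
    genome: str, gene: tuple[str, int, int, str], effect: str, rng: np.random.Generator
) -> tuple[int, str, str] | None:
    """Find a (pos, ref, alt) inside *gene* whose codon change has *effect*."""
    from Bio.Data import CodonTable
    from Bio.Seq import Seq

    table = CodonTable.unambiguous_dna_by_id[11]

    def aa(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    _, start, end, strand = gene
    cds = genome[start - 1 : end]
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    n_codons = len(cds) // 3
    for ci in rng.permutation(n_codons):
        codon = cds[ci * 3 : ci * 3 + 3]
        if codon in table.stop_codons:
            continue
        for within in rng.permutation(3):
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1 :]
                got = (
                    "nonsense" if aa(mutated) == "*"
                    else "synonymous" if aa(mutated) == aa(codon)
                    else "missense"
                )
                if got != effect:
                    continue
                offset = ci * 3 + within  # within CDS, coding orientation
                if strand == "+":
                    pos = start + offset
                    ref_g, alt_g = codon[within], alt
                else:
                    pos = end - offset
                    ref_g = str(Seq(codon[within]).complement())
                    alt_g = str(Seq(alt).complement())
                return pos, ref_g, alt_g
    return None


def simulate_mutations(
    genome: str,
    annotation: list[tuple[str, int, int, str]],
    effect_counts: dict[str, int] | None = None,
    callers: tuple[str, ...] = ("maq", "samtools", "gatk"),
    extra_per_caller: int = 2,
    seed: int = 0,
    chrom: str = "chr",
) -> tuple[dict[str, list[MutationCall]], GroundTruth]:
    """Plant mutations of known effect classes and emit per-caller call sets.

    Every caller reports all planted (true) mutations plus a few private
    false positives, so the consensus intersection recovers exactly the
    planted set. Defaults mirror the low-tolerance mutant's spectrum scaled
    to a toy genome: a mix of synonymous/missense/nonsense SNPs, one coding
    frameshift indel and a few intergenic SNPs.
    """
    if effect_counts is None:
        effect_counts = {
            "synonymous": 3, "missense": 5, "nonsense": 3,
            "frameshift": 1, "intergenic": 3,
        }
    unknown = set(effect_counts) - set(_EFFECTS)
    if unknown:
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")
    rng = _rng(seed, 4)
    coding = [
        (s, e) for _, s, e, _ in annotation
    ]
    used: set[int] = set()
    truth = GroundTruth()
    true_calls: list[MutationCall] = []

    def in_gene(pos: int) -> bool:
        return any(s <= pos <= e for s, e in coding)

    for effect, count in effect_counts.items():
        placed = 0
        attempts = 0
        while placed < count and attempts < 2000:
            attempts += 1
            if effect == "intergenic":
                pos = int(rng.integers(1, len(genome) + 1))
                if in_gene(pos) or pos in used:
                    continue
                ref = genome[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                true_calls.append(MutationCall(chrom, pos, ref, str(alt)))
            elif effect == "frameshift":
                gene = annotation[int(rng.integers(len(annotation)))]
                pos = int(rng.integers(gene[1], gene[2] + 1))
                if pos in used:
                    continue
                ref = genome[pos - 1]
                ins = rng.choice(list("ACGT"))
                true_calls.append(MutationCall(chrom, pos, ref, ref + str(ins)))
            else:
                gene = annotation[int(rng.integers(len(annotation)))]
                hit = _plant_snp_with_effect(genome, gene, effect, rng)
                if hit is None or hit[0] in used:
                    continue
                pos, ref, alt = hit
                true_calls.append(MutationCall(chrom, pos, ref, alt))
            used.add(pos)
            truth.planted_effects.append((true_calls[-1].key, effect))
            placed += 1
        if placed < count:
            raise RuntimeError(f"could not place {count} {effect} mutations")

    call_sets: dict[str, list[MutationCall]] = {}
    for caller in callers:
        calls = [
            MutationCall(c.chrom, c.pos, c.ref, c.alt, frozenset([caller]))
            for c in true_calls
        ]
        for _ in range(extra_per_caller):  # caller-private false positives
            while True:
                pos = int(rng.integers(1, len(genome) + 1))
                if pos not in used:
                    break
            used.add(pos)
            ref = genome[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            calls.append(MutationCall(chrom, pos, ref, alt, frozenset([caller])))
        call_sets[caller] = sorted(calls, key=lambda c: c.key)
    return call_sets, truth
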