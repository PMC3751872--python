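"""Consensus mutation calling, effect annotation and mutation-rate analysis.

An experimental-evolution lineage resequenced against its ancestor yields
call sets from several variant callers; only calls shared by every caller are
kept (consensus), then annotated against the genome: coding vs non-coding,
and for coding SNPs the amino-acid consequence under the bacterial genetic
code (translation table 11). Single-base indels inside coding sequence are
frameshifts.

Population-level support comes from pooled sequencing of the evolved
community: the frequency of a mutation is the fraction of reads carrying the
alternate allele at its locus. Non-synonymous mutations fixed at high
frequency (strictly above 80% by default) are flagged as candidate beneficial
mutations. The spontaneous genome mutation rate is
``mu_g = mutations fixed / generations elapsed``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "MutationCall",
    "PooledLocus",
    "MutationSummary",
    "consensus_calls",
    "annotate_effects",
    "pooled_frequency",
    "beneficial_flag",
    "mutation_rate",
    "mutation_profile",
]

NON_SYNONYMOUS = {"missense", "nonsense", "frameshift"}


@dataclass(frozen=True)
class MutationCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller_support: frozenset = frozenset()
    region: str | None = None  # "coding" | "non-coding"
    gene: str | None = None
    effect: str | None = None  # synonymous|missense|nonsense|frameshift|intergenic
    pooled_freq: float | None = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class PooledLocus:
    chrom: str
    pos: int
    ref_reads: int
    alt_reads: int

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class MutationSummary:
    n_total: int
    n_snp: int
    n_indel: int
    by_effect: dict
    n_coding: int
    n_noncoding: int
    noncoding_coding_ratio_percent: float
    beneficial: list = field(default_factory=list)
    mu_g: float | None = None


def consensus_calls(
    call_sets: list[list[MutationCall]],
) -> tuple[list[MutationCall], list[MutationCall]]:
    """Intersection of >=2 caller outputs, keyed on (chrom, pos, ref, alt).

    Returns (consensus calls with merged caller support, non-consensus calls)
    — the latter standing in for the study's manual-examination side channel.
    """
    if not call_sets:
        raise ValueError("no call sets provided")
    keyed = [{c.key: c for c in cs} for cs in call_sets]
    shared = set(keyed[0])
    for d in keyed[1:]:
        shared &= set(d)
    consensus, rest = [], []
    seen: set = set()
    for d in keyed:
        for key, call in d.items():
            support = frozenset().union(*(c[key].caller_support for c in keyed if key in c))
            if key in shared:
                if key not in seen:
                    consensus.append(replace(call, caller_support=support))
                    seen.add(key)
            elif key not in seen:
                rest.append(replace(call, caller_support=support))
                seen.add(key)
    consensus.sort(key=lambda c: c.key)
    rest.sort(key=lambda c: c.key)
    return consensus, rest


def _codon_effect(codon_ref: str, codon_alt: str, table_id: int = 11) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa_ref = "*" if codon_ref in table.stop_codons else table.forward_table[codon_ref]
    aa_alt = "*" if codon_alt in table.stop_codons else table.forward_table[codon_alt]
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def annotate_effects(
    calls: list[MutationCall],
    annotation: list[tuple[str, int, int, str]],
    genome: str | Seq,
) -> list[MutationCall]:
    """Classify each call as coding/non-coding and assign its effect.

    ``annotation`` holds (gene, start, end, strand) with 1-based inclusive
    coordinates; gene lengths must be multiples of 3. For coding SNPs the
    affected codon is rebuilt respecting strand and translated with the
    bacterial code; stop gains are nonsense. Single-base indels in coding
    sequence are frameshifts; anything outside annotated genes is intergenic.
    """
    genome = str(genome).upper()
    out = []
    for call in calls:
        if call.pos < 1 or call.pos > len(genome):
            raise ValueError(f"position {call.pos} outside genome of length {len(genome)}")
        if call.is_snp and genome[call.pos - 1] != call.ref.upper():
            raise ValueError(
                f"ref mismatch at {call.chrom}:{call.pos}: genome has "
                f"{genome[call.pos - 1]}, call says {call.ref}"
            )
        hit = next(
            ((g, s, e, st) for g, s, e, st in annotation if s <= call.pos <= e), None
        )
        if hit is None:
            out.append(replace(call, region="non-coding", effect="intergenic"))
            continue
        gene, start, end, strand = hit
        if not call.is_snp:
            out.append(replace(call, region="coding", gene=gene, effect="frameshift"))
            continue
        offset = call.pos - start  # 0-based within gene, forward orientation
        if strand == "-":
            offset = end - call.pos
        codon_idx = offset // 3
        within = offset % 3
        cds = genome[start - 1 : end]
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        codon_ref = cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt_base = call.alt.upper()
        if strand == "-":
            alt_base = str(Seq(alt_base).complement())
        codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
        out.append(
            replace(
                call,
                region="coding",
                gene=gene,
                effect=_codon_effect(codon_ref, codon_alt),
            )
        )
    return out


def pooled_frequency(locus: PooledLocus) -> float:
    """Fraction of reads carrying the alternate allele at a locus."""
    if locus.depth <= 0:
        raise ValueError(f"{locus.chrom}:{locus.pos}: zero depth, frequency undefined")
    return locus.alt_reads / locus.depth


def beneficial_flag(call: MutationCall, threshold: float = 0.80) -> bool:
    """Candidate beneficial: non-synonymous AND pooled frequency > threshold.

    The threshold is strict — a frequency of exactly 0.80 does not qualify.
    """
    if call.pooled_freq is None:
        return False
    return call.effect in NON_SYNONYMOUS and call.pooled_freq > threshold


def mutation_rate(n_mutations: int, generations: int) -> float:
    """Spontaneous mutation rate per genome per generation (mu_g).

    All fixed consensus mutations (SNPs and single-base indels) count;
    reported to two significant figures.
    """
    if generations <= 0:
        raise ValueError(f"generations must be positive, got {generations}")
    if n_mutations < 0:
        raise ValueError("mutation count cannot be negative")
    mu = n_mutations / generations
    return float(f"{mu:.2g}")


def mutation_profile(
    calls: list[MutationCall],
    generations: int | None = None,
    beneficial_threshold: float = 0.80,
) -> MutationSummary:
    """Tally annotated calls by type/region/effect and derived ratios.

    The non-coding/coding ratio is reported as a percentage rounded to one
    decimal (e.g. 3 non-coding vs 17 coding -> 17.6). When ``generations``
    is given, mu_g is included.
    """
    for c in calls:
        if c.region is None:
            raise ValueError(f"unannotated call at {c.chrom}:{c.pos}")
    n_coding = sum(1 for c in calls if c.region == "coding")
    n_noncoding = sum(1 for c in calls if c.region == "non-coding")
    ratio = round(100.0 * n_noncoding / n_coding, 1) if n_coding else 0.0
    beneficial = [c for c in calls if beneficial_flag(c, beneficial_threshold)]
    return MutationSummary(
        n_total=len(calls),
        n_snp=sum(1 for c in calls if c.is_snp),
        n_indel=sum(1 for c in calls if not c.is_snp),
        by_effect=dict(Counter(c.effect for c in calls)),
        n_coding=n_coding,
        n_noncoding=n_noncoding,
        noncoding_coding_ratio_percent=ratio,
        beneficial=beneficial,
        mu_g=mutation_rate(len(calls), generations) if generations else None,
    )
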