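"""End-to-end pipeline runner.

Executes simulate -> differential expression -> state space -> co-expression
networks -> operon dynamics -> mutation analysis on one configuration,
writing per-stage outputs under the output directory and a combined JSON
report. Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from . import __version__
from .expression import call_de, contrast, de_table
from .mutations import annotate_effects, consensus_calls, mutation_profile, pooled_frequency
from .network import build_network, compare_networks, correlations, detect_modules
from .operons import call_suboperons, compare_operons, summarize_coverage
from .simulate import (
    PolycistronSpec,
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_mutations,
    simulate_operon_reads,
    simulate_pool_reads,
)
from .states import absolute_states, bootstrap_tree, distance_matrix, relative_states

log = logging.getLogger("thermoevo")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "thermoevo_out"
    seed: int = 0
    simulation: dict = field(
        default_factory=lambda: {"module_spec": [(10, 0.95)] * 4}
    )
    de: dict = field(default_factory=lambda: {"ratio_cutoff": 1.0, "z_cutoff": 2.0})
    states: dict = field(default_factory=lambda: {"fold_filter": 2.0, "n_boot": 200})
    network: dict = field(default_factory=lambda: {"threshold": 0.98, "min_module_size": 5})
    operons: dict = field(default_factory=lambda: {"fold": 2.0, "min_depth": 5.0, "min_pairs": 1})
    mutations: dict = field(default_factory=lambda: {"generations": 440, "beneficial_threshold": 0.80})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated dataset; return the combined report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": {
                        "de": config.de, "states": config.states,
                        "network": config.network, "operons": config.operons,
                        "mutations": config.mutations,
                    }}

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        eset, truth = simulate_expression(sim)
        tio.write_expression(eset, out / "expression.tsv", out / "samples.tsv")
        genome, annotation = simulate_genome(seed=config.seed)
        tio.write_genome(genome, out / "genome.fasta")
        tio.write_annotation(annotation, out / "annotation.gff3")
        operon_spec = sim.operon_spec or [
            PolycistronSpec(
                "pc1",
                [g for g, *_ in annotation[:4]],
                splits={"c_ref": set(), "c_alt": {1}},
            )
        ]
        conditions = sorted({c for s in operon_spec for c in s.splits})
        tracks, links, op_truth = simulate_operon_reads(
            annotation, operon_spec, depth=50.0, seed=config.seed,
            conditions=conditions,
        )
        for (cond, rep), track in tracks.items():
            tio.write_bedgraph(track, out / f"coverage.{cond}.r{rep}.bedgraph")
        tio.write_links(links, out / "links.tsv")
        call_sets, mut_truth = simulate_mutations(genome, annotation, seed=config.seed)
        pool_spec = sim.pool_spec
        if not pool_spec:
            # pooled community sequencing at the planted loci: a few
            # non-synonymous mutations near fixation, the rest intermediate
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
            pool_spec = []
            n_high = 0
            for (chrom, pos, ref, alt), effect in mut_truth.planted_effects:
                if effect in ("missense", "nonsense", "frameshift") and n_high < 3:
                    pool_spec.append((pos, float(rng.uniform(0.85, 0.99))))
                    n_high += 1
                else:
                    pool_spec.append((pos, float(rng.uniform(0.1, 0.6))))
        loci, pool_truth = simulate_pool_reads(pool_spec, sim.depth, config.seed)
        tio.write_pool_counts(loci, out / "pool_counts.tsv")
        for caller, calls in call_sets.items():
            tio.write_vcf(calls, out / f"calls.{caller}.vcf")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- differential expression --------------------------------------
    stage = "de"
    try:
        control = eset.states[0]
        n_sig = {}
        for state in eset.states[1:]:
            res = call_de(contrast(eset, state, control), **config.de)
            tab = de_table(res)
            tab.to_csv(out / f"de.{state.replace('%', 'pct')}.tsv", sep="\t")
            n_sig[state] = int(tab["significant"].sum())
        report["de"] = {"control": control, "n_significant": n_sig}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- state space ---------------------------------------------------
    stage = "states"
    try:
        profiles = absolute_states(eset)
        dm_abs = distance_matrix(profiles)
        dm_abs.to_frame().to_csv(out / "distances_absolute.tsv", sep="\t")
        contrasts = [(s, control) for s in eset.states[1:]]
        rels, kept = relative_states(eset, contrasts, config.states["fold_filter"])
        dm_rel = distance_matrix(rels)
        dm_rel.to_frame().to_csv(out / "distances_relative.tsv", sep="\t")
        tree = bootstrap_tree(profiles, n_boot=config.states["n_boot"], seed=config.seed)
        (out / "states_absolute.nwk").write_text(tree.newick + "\n")
        off = dm_rel.matrix[np.triu_indices(len(rels), k=1)]
        report["states"] = {
            "n_relative_states": len(rels),
            "n_pairwise_distances": int(off.size),
            "min_relative_distance": float(off.min()),
            "n_genes_after_fold_filter": len(kept),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- co-expression networks ----------------------------------------
    stage = "network"
    try:
        shock = [s for s in eset.states if "0.15%" in s] or eset.states[1:2]
        rest = [s for s in eset.states if s not in shock]
        # shock-condition network vs its control-side counterpart
        grp_a = shock if sum(len(eset.columns_for(s)) for s in shock) >= 4 else None
        grp_b = rest if grp_a is not None else None
        cm_a = correlations(eset, grp_a)
        cm_b = correlations(eset, grp_b)
        net_a = build_network(cm_a, config.network["threshold"])
        net_b = build_network(cm_b, config.network["threshold"])
        comp = compare_networks(net_a, net_b)
        report["network"] = {
            "threshold": config.network["threshold"],
            "nodes_a": net_a.number_of_nodes(),
            "nodes_b": net_b.number_of_nodes(),
            "shared": len(comp.shared),
            "shrinkage_percent": comp.shrinkage_percent,
        }
        if net_a.number_of_nodes():
            part = detect_modules(net_a, config.network["min_module_size"])
            report["network"]["modularity"] = part.modularity
            report["network"]["n_modules"] = len(part.sizes)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- operons --------------------------------------------------------
    stage = "operons"
    try:
        models = {}
        for cond in conditions:
            cov = []
            for rep in range(3):
                track = tracks[(cond, rep)]
                cov.extend(
                    summarize_coverage(
                        track, [(g, s, e) for g, s, e, _ in annotation],
                        cond, rep, config.operons["min_depth"],
                    )
                )
            models[cond] = [
                call_suboperons(
                    spec.id, spec.genes, cov, links, cond,
                    fold=config.operons["fold"],
                    min_depth=config.operons["min_depth"],
                    min_pairs=config.operons["min_pairs"],
                )
                for spec in operon_spec
            ]
        calls = []
        if len(conditions) == 2:
            calls = compare_operons(models[conditions[0]], models[conditions[1]])
        report["operons"] = {
            "conditions": conditions,
            "n_dynamic_calls": len(calls),
            "suboperons": {
                cond: {m.polycistron: m.suboperons for m in ms}
                for cond, ms in models.items()
            },
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- mutations ------------------------------------------------------
    stage = "mutations"
    try:
        consensus, rejected = consensus_calls(list(call_sets.values()))
        annotated = annotate_effects(consensus, annotation, genome)
        freq_by_pos = {l.pos: pooled_frequency(l) for l in loci}
        from dataclasses import replace as _replace
        annotated = [
            _replace(c, pooled_freq=freq_by_pos.get(c.pos)) for c in annotated
        ]
        summary = mutation_profile(
            annotated,
            generations=config.mutations["generations"],
            beneficial_threshold=config.mutations["beneficial_threshold"],
        )
        tio.write_vcf(annotated, out / "consensus.vcf",
                      beneficial={c.key for c in summary.beneficial})
        tio.write_vcf(rejected, out / "non_consensus.vcf")
        report["mutations"] = {
            "n_consensus": summary.n_total,
            "n_snp": summary.n_snp,
            "n_indel": summary.n_indel,
            "by_effect": summary.by_effect,
            "noncoding_coding_ratio_percent": summary.noncoding_coding_ratio_percent,
            "mu_g": summary.mu_g,
            "n_beneficial": len(summary.beneficial),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    tio.write_json(report, out / "report.json")
    log.info("pipeline complete: %s", out / "report.json")
    return report
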