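"""Coverage summarisation and the two-requirement suboperon split rule."""

import numpy as np
import pandas as pd
import pytest

from thermoevo import (
    GeneCoverage,
    PolycistronSpec,
    call_suboperons,
    compare_operons,
    simulate_genome,
    simulate_operon_reads,
    summarize_coverage,
)


def cov(depths_by_rep, condition="c"):
    """GeneCoverage list from {rep: {gene: depth}}."""
    return [
        GeneCoverage(g, condition, rep, d, d >= 5)
        for rep, per_gene in depths_by_rep.items()
        for g, d in per_gene.items()
    ]


def full_links(genes, condition="c", n=10, reps=3):
    rows = [
        {"gene_i": gi, "gene_j": gj, "replicate": r, "condition": condition,
         "n_pairs": n}
        for gi, gj in zip(genes, genes[1:])
        for r in range(reps)
    ]
    return pd.DataFrame(rows)


class TestSummarizeCoverage:
    def test_uniform_depth(self):
        track = np.full(100, 10.0)
        gc = summarize_coverage(track, [("g", 11, 40)])[0]
        assert gc.depth == pytest.approx(10.0) and gc.expressed

    def test_zero_depth_unexpressed(self):
        gc = summarize_coverage(np.zeros(50), [("g", 1, 30)])[0]
        assert gc.depth == 0.0 and not gc.expressed

    def test_half_covered_gene(self):
        track = np.zeros(40)
        track[:20] = 10.0
        gc = summarize_coverage(track, [("g", 1, 40)])[0]
        assert gc.depth == pytest.approx(5.0)

    def test_gene_outside_track_named(self):
        with pytest.raises(ValueError, match="gX"):
            summarize_coverage(np.zeros(10), [("gX", 5, 20)])


class TestCallSuboperons:
    GENES = ["g1", "g2", "g3"]

    def test_printed_rule_example(self):
        # depths (100, 40, 38): ratio g1/g2 = 2.5 > 2 splits; links within g2,g3
        depths = {r: {"g1": 100, "g2": 40, "g3": 38} for r in range(3)}
        links = pd.DataFrame(
            [{"gene_i": "g2", "gene_j": "g3", "replicate": r, "condition": "c",
              "n_pairs": 5} for r in range(3)]
        )
        model = call_suboperons("p", self.GENES, cov(depths), links, "c")
        assert model.suboperons == [["g1"], ["g2", "g3"]]
        assert model.boundaries == {("g1", "g2")}

    def test_no_ratio_exceeds_fold_single_operon(self):
        depths = {r: {"g1": 50, "g2": 50, "g3": 49} for r in range(3)}
        model = call_suboperons(
            "p", self.GENES, cov(depths), full_links(self.GENES), "c"
        )
        assert model.suboperons == [self.GENES]

    def test_ratio_exactly_two_never_splits(self):
        depths = {r: {"g1": 100, "g2": 50, "g3": 50} for r in range(3)}
        model = call_suboperons(
            "p", self.GENES, cov(depths), full_links(self.GENES), "c"
        )
        assert model.suboperons == [self.GENES]

    def test_split_requires_every_replicate(self):
        depths = {
            0: {"g1": 100, "g2": 40, "g3": 40},
            1: {"g1": 100, "g2": 40, "g3": 40},
            2: {"g1": 100, "g2": 60, "g3": 60},  # ratio 1.67 here blocks the split
        }
        model = call_suboperons(
            "p", self.GENES, cov(depths), full_links(self.GENES), "c"
        )
        assert model.suboperons == [self.GENES]

    def test_missing_pair_support_emits_monocistrons(self):
        depths = {r: {"g1": 50, "g2": 50, "g3": 50} for r in range(3)}
        links = full_links(self.GENES).copy()
        links.loc[links.gene_i == "g1", "n_pairs"] = 0
        model = call_suboperons("p", self.GENES, cov(depths), links, "c")
        assert model.suboperons == [["g1"], ["g2", "g3"]]

    def test_unexpressed_gene_breaks_contiguity(self):
        depths = {r: {"g1": 50, "g2": 0, "g3": 50} for r in range(3)}
        model = call_suboperons(
            "p", self.GENES, cov(depths), full_links(self.GENES), "c"
        )
        assert model.unexpressed == ["g2"]
        assert model.suboperons == [["g1"], ["g3"]]

    def test_uniform_scaling_invariance(self):
        base = {r: {"g1": 90, "g2": 30, "g3": 28} for r in range(3)}
        scaled = {r: {g: 7.5 * d for g, d in per.items()} for r, per in base.items()}
        links = full_links(self.GENES)
        m1 = call_suboperons("p", self.GENES, cov(base), links, "c")
        m2 = call_suboperons("p", self.GENES, cov(scaled), links, "c")
        assert m1.suboperons == m2.suboperons

    def test_replicate_count_enforced(self):
        depths = {r: {"g1": 50, "g2": 50, "g3": 50} for r in range(2)}
        with pytest.raises(ValueError, match="replicates"):
            call_suboperons("p", self.GENES, cov(depths), full_links(self.GENES), "c")

    def test_across_mode_requires_pairs_at_boundary(self):
        # coverage step present but no pairs across it: 'across' mode keeps one unit
        depths = {r: {"g1": 100, "g2": 30, "g3": 30} for r in range(3)}
        links = full_links(self.GENES).copy()
        links.loc[links.gene_i == "g1", "n_pairs"] = 0
        m = call_suboperons("p", self.GENES, cov(depths), links, "c",
                            boundary_mode="across")
        assert m.suboperons == [self.GENES]

    def test_suboperons_partition_expressed_genes(self, operon_sim):
        annotation, spec, tracks, links, _ = operon_sim
        for condition in ("induced", "control"):
            coverage = []
            for rep in range(3):
                coverage += summarize_coverage(
                    tracks[(condition, rep)],
                    [(g, s, e) for g, s, e, _ in annotation],
                    condition, rep,
                )
            model = call_suboperons(
                spec[0].id, spec[0].genes, coverage, links, condition
            )
            flat = [g for sub in model.suboperons for g in sub]
            assert flat == [g for g in spec[0].genes if g not in model.unexpressed]


class TestCompareOperons:
    def make(self, pid, cond, boundaries, genes=("g1", "g2", "g3", "g4")):
        from thermoevo import OperonModel

        genes = list(genes)
        subs = []
        cur = [genes[0]]
        for gi, gj in zip(genes, genes[1:]):
            if (gi, gj) in boundaries:
                subs.append(cur)
                cur = [gj]
            else:
                cur.append(gj)
        subs.append(cur)
        return OperonModel(pid, genes, cond, subs, [], set(boundaries))

    def test_identical_models_no_calls(self):
        a = self.make("p", "x", {("g2", "g3")})
        b = self.make("p", "y", {("g2", "g3")})
        assert compare_operons([a], [b]) == []

    def test_one_vs_three_suboperons(self):
        # pentose-transport pattern: single operon in one strain, three in the other
        a = self.make("p", "x", set())
        b = self.make("p", "y", {("g1", "g2"), ("g3", "g4")})
        calls = compare_operons([a], [b])
        assert len(calls) == 1
        assert calls[0].boundary_differences == {("g1", "g2"), ("g3", "g4")}

    def test_planted_condition_specific_split_called(self, operon_sim):
        annotation, spec, tracks, links, truth = operon_sim
        models = {}
        for condition in ("induced", "control"):
            coverage = []
            for rep in range(3):
                coverage += summarize_coverage(
                    tracks[(condition, rep)],
                    [(g, s, e) for g, s, e, _ in annotation],
                    condition, rep,
                )
            models[condition] = [
                call_suboperons(spec[0].id, spec[0].genes, coverage, links, condition)
            ]
        calls = compare_operons(models["induced"], models["control"])
        assert len(calls) == 1
        assert calls[0].boundary_differences == truth.split_boundaries[
            ("pc1", "induced")
        ]

    def test_mismatched_polycistrons_rejected(self):
        a = self.make("p1", "x", set())
        b = self.make("p2", "y", set())
        with pytest.raises(ValueError):
            compare_operons([a], [b])


def test_boundary_recovery_on_simulated_polycistrons():
    """Planted 3-fold boundaries at depth 50 are recovered without false calls."""
    rng = np.random.default_rng(17)
    genome, ann = simulate_genome(n_genes=8, seed=17)
    forward = [g for g, _, _, st in ann if st == "+"][:5]
    recovered = total = false = 0
    for trial in range(25):
        n_splits = int(rng.integers(0, 3))
        splits = set(rng.choice(4, size=n_splits, replace=False).tolist())
        spec = [PolycistronSpec("p", forward, splits={"c": splits}, fold_step=3.0)]
        tracks, links, truth = simulate_operon_reads(
            ann, spec, depth=50.0, seed=int(rng.integers(2**31)), conditions=["c"]
        )
        coverage = []
        for rep in range(3):
            coverage += summarize_coverage(
                tracks[("c", rep)], [(g, s, e) for g, s, e, _ in ann], "c", rep
            )
        model = call_suboperons("p", forward, coverage, links, "c", fold=2.0)
        planted = truth.split_boundaries[("p", "c")]
        recovered += len(model.boundaries & planted)
        false += len(model.boundaries - planted)
        total += len(planted)
    assert false == 0
    assert total == 0 or recovered / total >= 0.95
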