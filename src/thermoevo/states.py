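"""Transcriptome state-space analysis.

The cellular states of a shock/adaptation experiment are compared in two
coordinate systems: *absolute* states (replicate-averaged log2 profiles of
each sampled condition) and *relative* states (contrast profiles, treatment vs
matched control, restricted to genes changing more than a fold-change filter).
Distances between states are Pearson-correlation distances d = 1 − r; the
structure among them is summarised by average-linkage hierarchical clustering
with gene-bootstrap support values, and by a small panel of microevolution
metrics: distinctness, discreteness, resilience, memory and convergence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .expression import ExpressionSet, contrast

__all__ = [
    "StateProfile",
    "RelativeState",
    "DistanceMatrix",
    "BootstrapDendrogram",
    "MicroevolutionReport",
    "absolute_states",
    "relative_states",
    "distance_matrix",
    "bootstrap_tree",
    "microevolution_metrics",
]


@dataclass
class StateProfile:
    label: str
    values: np.ndarray  # per-gene replicate-mean log2 measurement


@dataclass
class RelativeState:
    label: str  # "treatment|control"
    values: np.ndarray  # per-gene mean log2R over the filtered gene set


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class BootstrapDendrogram:
    labels: list[str]
    linkage: np.ndarray
    newick: str
    supports: dict[frozenset, float]  # internal-node leaf set -> % of resamples


@dataclass
class MicroevolutionReport:
    distinctness: dict
    discreteness: dict
    resilience: dict
    memory: list
    convergence: dict

    def to_dict(self) -> dict:
        return {
            "distinctness": self.distinctness,
            "discreteness": self.discreteness,
            "resilience": self.resilience,
            "memory": self.memory,
            "convergence": self.convergence,
        }


def absolute_states(eset: ExpressionSet) -> list[StateProfile]:
    """Replicate-mean log2 profile per state, gene order shared."""
    profiles = []
    for state in eset.states:
        cols = eset.columns_for(state)
        vals = np.nanmean(eset.values[:, cols], axis=1)
        profiles.append(StateProfile(state, vals))
    return profiles


def relative_states(
    eset: ExpressionSet,
    contrasts: list[tuple[str, str]],
    fold_filter: float = 2.0,
) -> tuple[list[RelativeState], list[str]]:
    """Contrast profiles restricted to genes changing more than ``fold_filter``.

    A gene is retained iff its max |mean log2R| over all contrasts strictly
    exceeds log2(fold_filter) ("more than" two-fold, not "at least").

    Returns the relative-state collection and the retained gene ids.
    """
    if fold_filter <= 1:
        raise ValueError(f"fold_filter must be > 1, got {fold_filter}")
    means = []
    labels = []
    for treat, ctrl in contrasts:
        vecs = contrast(eset, treat, ctrl)
        mean = np.array([vecs[g].mean() if g in vecs else np.nan for g in eset.gene_ids])
        means.append(mean)
        labels.append(f"{treat}|{ctrl}")
    mat = np.vstack(means)  # contrasts x genes
    with np.errstate(invalid="ignore"):
        keep = np.nanmax(np.abs(mat), axis=0) > np.log2(fold_filter)
    keep &= ~np.isnan(mat).any(axis=0)
    if not keep.any():
        raise ValueError(
            f"no gene exceeds the {fold_filter}-fold filter; relax fold_filter"
        )
    genes = [g for g, k in zip(eset.gene_ids, keep) if k]
    rels = [RelativeState(lab, mat[i, keep]) for i, lab in enumerate(labels)]
    return rels, genes


def _pearson_distances(vectors: np.ndarray, labels: list[str]) -> np.ndarray:
    sd = vectors.std(axis=1)
    for lab, s in zip(labels, sd):
        if s == 0:
            raise ValueError(f"profile {lab!r} has zero variance")
    r = np.corrcoef(vectors)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def distance_matrix(
    profiles: list[StateProfile] | list[RelativeState],
) -> DistanceMatrix:
    """Pearson-correlation distance d(a, b) = 1 − r(a, b) between profiles."""
    if len(profiles) < 2:
        raise ValueError("need >=2 profiles")
    labels = [p.label for p in profiles]
    vectors = np.vstack([np.asarray(p.values, dtype=float) for p in profiles])
    return DistanceMatrix(labels, _pearson_distances(vectors, labels))


def _clades(linkage: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Leaf-label sets of every internal node of a linkage tree."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = set()
    for i, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.add(merged)
    return clades


def _newick(linkage: np.ndarray, labels: list[str], supports: dict) -> str:
    tree = to_tree(linkage)

    def fmt(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = fmt(node.get_left()), fmt(node.get_right())
        leaf_ids = node.pre_order(lambda x: x.id)
        clade = frozenset(labels[i] for i in leaf_ids)
        sup = supports.get(clade)
        name = "" if sup is None else f"{sup:.0f}"
        return f"({left},{right}){name}"

    return fmt(tree) + ";"


def bootstrap_tree(
    profiles: list[StateProfile] | list[RelativeState],
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapDendrogram:
    """Average-linkage dendrogram on Pearson distances with bootstrap support.

    Genes (profile coordinates) are resampled with replacement ``n_boot``
    times; the support of each internal node of the full-data tree is the
    percentage of resampled trees containing the same leaf set.
    """
    if len(profiles) < 3:
        raise ValueError("need >=3 profiles for a support tree")
    if n_boot < 1:
        raise ValueError("n_boot must be >=1")
    labels = [p.label for p in profiles]
    vectors = np.vstack([np.asarray(p.values, dtype=float) for p in profiles])
    n_genes = vectors.shape[1]

    ref_link = average(squareform(_pearson_distances(vectors, labels), checks=False))
    ref_clades = _clades(ref_link, labels)
    counts = {c: 0 for c in ref_clades}

    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        sub = vectors[:, idx]
        if (sub.std(axis=1) == 0).any():
            continue  # degenerate resample carries no support information
        link = average(squareform(_pearson_distances(sub, labels), checks=False))
        for c in _clades(link, labels):
            if c in counts:
                counts[c] += 1

    supports = {c: 100.0 * k / n_boot for c, k in counts.items()}
    # the root clade (all leaves) is trivially present in every tree
    supports.pop(frozenset(labels), None)
    newick = _newick(ref_link, labels, supports)
    return BootstrapDendrogram(labels, ref_link, newick, supports)


def _offdiag_min(dm: DistanceMatrix) -> tuple[tuple[str, str], float]:
    best: tuple[str, str] | None = None
    best_d = np.inf
    for a, b in itertools.combinations(sorted(dm.labels), 2):
        d = dm.distance(a, b)
        if d < best_d:  # strict: lexicographic tie-break via sorted iteration
            best_d = d
            best = (a, b)
    assert best is not None
    return best, float(best_d)


def microevolution_metrics(
    dm_abs: DistanceMatrix,
    dm_rel: DistanceMatrix,
    groups: dict[str, list[str]],
    trajectory: list[str],
    discrete_state: str | None = None,
    memory_pairs: list[tuple[str, str]] | None = None,
) -> MicroevolutionReport:
    """Quantify the microevolution signatures of a shock/adaptation course.

    distinctness
        Two stated groups of absolute states (e.g. wild-type vs mutant) are
        "distinct" when the minimum between-group distance exceeds the maximum
        within-group distance.
    discreteness
        Distance from one designated absolute state to its nearest neighbour.
    resilience
        Along a stated trajectory of absolute states, whether the final state
        is closer to the first than every intermediate state is.
    memory
        Stated relative-state pairs ranked by similarity (ascending distance).
    convergence
        The globally closest pair of relative states (ties broken
        lexicographically on the label pair).
    """
    for lab in itertools.chain.from_iterable(groups.values()):
        if lab not in dm_abs.labels:
            raise KeyError(f"unknown absolute-state label: {lab!r}")
    for lab in trajectory:
        if lab not in dm_abs.labels:
            raise KeyError(f"unknown trajectory label: {lab!r}")
    if len(groups) != 2:
        raise ValueError("distinctness needs exactly two groups")

    (ga_name, ga), (gb_name, gb) = groups.items()
    inter = [dm_abs.distance(a, b) for a in ga for b in gb]
    intra = [
        dm_abs.distance(a, b)
        for grp in (ga, gb)
        for a, b in itertools.combinations(grp, 2)
    ]
    min_inter = float(min(inter))
    max_intra = float(max(intra)) if intra else 0.0
    distinctness = {
        "groups": [ga_name, gb_name],
        "min_inter": min_inter,
        "max_intra": max_intra,
        "distinct": min_inter > max_intra,
    }

    if discrete_state is None:
        discrete_state = trajectory[-1]
    if discrete_state not in dm_abs.labels:
        raise KeyError(f"unknown state label: {discrete_state!r}")
    others = [l for l in dm_abs.labels if l != discrete_state]
    nn = min(others, key=lambda l: dm_abs.distance(discrete_state, l))
    discreteness = {
        "state": discrete_state,
        "nearest": nn,
        "distance": dm_abs.distance(discrete_state, nn),
    }

    if len(trajectory) < 3:
        raise ValueError("trajectory needs >=3 states")
    origin, *middle, last = trajectory
    d_last = dm_abs.distance(last, origin)
    d_middle = [dm_abs.distance(m, origin) for m in middle]
    resilience = {
        "trajectory": trajectory,
        "distance_to_origin": [0.0] + d_middle + [d_last],
        "resilient": all(d_last < d for d in d_middle),
    }

    memory = []
    for a, b in memory_pairs or []:
        if a not in dm_rel.labels or b not in dm_rel.labels:
            raise KeyError(f"unknown relative-state label in pair ({a!r}, {b!r})")
        memory.append({"pair": [a, b], "distance": dm_rel.distance(a, b)})
    memory.sort(key=lambda m: m["distance"])

    pair, d = _offdiag_min(dm_rel)
    convergence = {"pair": list(pair), "distance": d}

    return MicroevolutionReport(distinctness, discreteness, resilience, memory, convergence)
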