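"""Differential co-expression network construction and comparison.

Networks are built by hard-thresholding a gene-gene Pearson correlation
matrix: an edge joins two genes when |r| reaches the cutoff (default 0.98),
annotated with the correlation sign. The cutoff can alternatively be derived
from the data by the random-matrix-theory (RMT) criterion: as the threshold
rises, the nearest-neighbour spacing distribution (NNSD) of the unfolded
eigenvalues of the pruned matrix transitions from Wigner-Dyson (GOE,
level-repelling — correlated noise) to Poisson (exponential — uncorrelated
modular signal); the selected threshold is the smallest one whose NNSD is
consistent with the Poisson form by a chi-square goodness-of-fit test.

Modules are communities found by fast-greedy (Clauset-Newman-Moore)
modularity maximisation. Two networks built from matched condition groups
(e.g. ethanol-shock ES+ vs control ES−) are compared by node-set algebra,
shrinkage, hub tables and module rewiring of the shared nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .expression import ExpressionSet

__all__ = [
    "CorrelationMatrix",
    "ModulePartition",
    "NetworkComparison",
    "correlations",
    "rmt_threshold",
    "poisson_spacing_test",
    "build_network",
    "detect_modules",
    "compare_networks",
    "first_neighbors",
]


@dataclass
class CorrelationMatrix:
    genes: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]
    dropped: list[str] = field(default_factory=list)  # zero-variance genes


@dataclass
class ModulePartition:
    assignments: dict[str, int]  # node -> module id (1-based, by size)
    sizes: dict[int, int]
    modularity: float
    small_modules: list[int] = field(default_factory=list)  # ids below min_size


@dataclass
class NetworkComparison:
    shared: set
    a_specific: set
    b_specific: set
    shrinkage_percent: float  # (|B| - |A|) / |B| * 100
    hubs_a: list[tuple[str, int]]
    hubs_b: list[tuple[str, int]]
    module_overlap: pd.DataFrame | None = None


def correlations(
    eset: ExpressionSet, states: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson r over the log-ratio columns of one condition group.

    ``states`` selects the sample group (all samples when None). Genes with
    zero variance across the group are dropped and recorded.
    """
    if states is None:
        cols = list(range(len(eset.samples)))
    else:
        cols = [i for s in states for i in eset.columns_for(s)]
    if len(cols) < 3:
        raise ValueError(f"correlation needs >=3 samples, got {len(cols)}")
    if len(cols) < 4:
        warnings.warn("fewer than 4 samples: correlations will be unstable")
    sub = eset.values[:, cols]
    sd = sub.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(eset.gene_ids, keep) if not k]
    genes = [g for g, k in zip(eset.gene_ids, keep) if k]
    r = np.corrcoef(sub[keep])
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, np.clip(r, -1.0, 1.0), dropped)


# ---------------------------------------------------------------------------
# RMT threshold selection


def _unfold(eigenvalues: np.ndarray, spline_k: int = 3) -> np.ndarray:
    """Unfold a spectrum to unit mean spacing via a smoothed cumulative CDF.

    Near-degenerate eigenvalues are collapsed first (hard thresholding
    produces large degenerate blocks whose zero spacings are artefacts of
    symmetry, not of level statistics). The cumulative spectral function is
    then smoothed with a cubic spline and the eigenvalues mapped through it.
    """
    lam = np.sort(eigenvalues)
    # collapse numerical degeneracies
    keep = np.concatenate([[True], np.diff(lam) > 1e-8])
    lam = lam[keep]
    n = lam.size
    if n < 10:
        raise ValueError(f"spectrum too short to unfold ({n} distinct eigenvalues)")
    cdf = (np.arange(n) + 0.5) / n
    spline = UnivariateSpline(lam, cdf, k=min(spline_k, n - 1), s=n * 1e-4)
    unfolded = n * spline(lam)
    return np.diff(np.sort(unfolded))


def poisson_spacing_test(spacings: np.ndarray, alpha: float = 0.05) -> float:
    """Chi-square goodness of fit of spacings against the Poisson (Exp) form.

    Spacings are normalised to unit mean; ~sqrt(N) equal-probability bins
    under Exp(1) are used, guaranteeing expected counts >= 5 (bins are merged
    from the tail if N is small). Returns the p-value; p > alpha means the
    NNSD is consistent with Poisson statistics.
    """
    s = np.asarray(spacings, dtype=float)
    s = s[s >= 0]
    if s.size < 10:
        raise ValueError(f"need >=10 spacings, got {s.size}")
    m = s.mean()
    if m <= 0:
        raise ValueError("spacings have non-positive mean")
    s = s / m
    n = s.size
    n_bins = max(2, min(int(np.sqrt(n)), n // 5))
    # equal-probability bins under Exp(1): edges at -ln(1 - i/k)
    qs = np.arange(1, n_bins) / n_bins
    edges = np.concatenate([[0.0], -np.log1p(-qs), [np.inf]])
    observed, _ = np.histogram(s, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    # one dof lost to the sample size, one to the estimated mean
    chi2 = ((observed - expected) ** 2 / expected).sum()
    dof = n_bins - 2
    if dof < 1:
        dof = 1
    return float(stats.chi2.sf(chi2, dof))


def _pruned_spacings(matrix: np.ndarray, theta: float) -> np.ndarray | None:
    pruned = np.where(np.abs(matrix) >= theta, matrix, 0.0)
    np.fill_diagonal(pruned, 1.0)
    # genes isolated at this threshold contribute trivial unit eigenvalues
    degree = (pruned != 0).sum(axis=0) - 1
    keep = degree > 0
    if keep.sum() < 10:
        return None
    sub = pruned[np.ix_(keep, keep)]
    lam = np.linalg.eigvalsh(sub)
    try:
        return _unfold(lam)
    except ValueError:
        return None


def rmt_threshold(
    cm: CorrelationMatrix,
    grid: np.ndarray | list[float] | None = None,
    alpha: float = 0.05,
) -> float:
    """Select the correlation cutoff at the GOE-to-Poisson NNSD transition.

    Scans ``grid`` (ascending, default 0.50..0.99 step 0.01); at each
    candidate the matrix is pruned, its spectrum unfolded, and the NNSD tested
    against the Poisson form. Returns the smallest candidate not rejected
    (p > alpha); if none qualifies, returns the grid maximum with a warning.
    """
    if cm.matrix.shape[0] < 10:
        raise ValueError("correlation matrix smaller than 10x10: spectrum too short")
    if grid is None:
        grid = np.arange(0.50, 1.00, 0.01)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or (np.diff(grid) <= 0).any():
        raise ValueError("grid must be ascending and non-empty")
    if grid.min() <= 0 or grid.max() > 1:
        raise ValueError("grid values must lie in (0, 1]")
    for theta in grid:
        spacings = _pruned_spacings(cm.matrix, theta)
        if spacings is None:
            # network (or its spectrum) too small to test at this cutoff;
            # a matrix this sparse is already in the modular regime
            warnings.warn(
                f"spectrum too short at threshold {theta:.2f}; accepting it"
            )
            return float(theta)
        if poisson_spacing_test(spacings, alpha) > alpha:
            return float(theta)
    warnings.warn("no grid threshold reached Poisson NNSD; returning grid maximum")
    return float(grid[-1])


# ---------------------------------------------------------------------------
# network construction and comparison


def build_network(cm: CorrelationMatrix, threshold: float = 0.98) -> nx.Graph:
    """Graph with an edge wherever |r| >= threshold, sign-annotated.

    Genes left without any edge are excluded from the node set.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    g = nx.Graph(threshold=threshold)
    idx_i, idx_j = np.nonzero(np.triu(np.abs(cm.matrix) >= threshold, k=1))
    for i, j in zip(idx_i, idx_j):
        r = float(cm.matrix[i, j])
        g.add_edge(cm.genes[i], cm.genes[j], r=r, sign="+" if r >= 0 else "-")
    return g


def detect_modules(net: nx.Graph, min_size: int = 5) -> ModulePartition:
    """Fast-greedy modularity communities of the unweighted edge set.

    Modules are numbered 1..m in decreasing size. Communities smaller than
    ``min_size`` are kept in the partition but listed in ``small_modules``
    rather than silently dropped.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.greedy_modularity_communities(net)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)))
    q = nx.community.modularity(net, communities)
    assignments = {}
    sizes = {}
    small = []
    for mid, comm in enumerate(communities, start=1):
        sizes[mid] = len(comm)
        if len(comm) < min_size:
            small.append(mid)
        for node in comm:
            assignments[node] = mid
    return ModulePartition(assignments, sizes, float(q), small)


def compare_networks(
    a: nx.Graph,
    b: nx.Graph,
    k: int = 20,
    modules_a: ModulePartition | None = None,
    modules_b: ModulePartition | None = None,
) -> NetworkComparison:
    """Node-set algebra, shrinkage, hubs and module rewiring of two networks.

    Shrinkage is (|B| − |A|) / |B| × 100: how much smaller network A is than
    network B. Hub tables list the top-``k`` nodes by degree in each network.
    When module partitions are supplied, shared nodes are tabulated by their
    (module in A, module in B) pair to expose rewiring.
    """
    na, nb = set(a.nodes), set(b.nodes)
    shared = na & nb
    shrink = 100.0 * (len(nb) - len(na)) / len(nb) if nb else 0.0

    def hubs(g: nx.Graph) -> list[tuple[str, int]]:
        return sorted(g.degree, key=lambda t: (-t[1], t[0]))[:k]

    overlap = None
    if modules_a is not None and modules_b is not None:
        rows = [
            {"node": n, "module_a": modules_a.assignments.get(n),
             "module_b": modules_b.assignments.get(n)}
            for n in sorted(shared)
        ]
        overlap = pd.DataFrame(rows)
    return NetworkComparison(
        shared=shared,
        a_specific=na - shared,
        b_specific=nb - shared,
        shrinkage_percent=shrink,
        hubs_a=hubs(a),
        hubs_b=hubs(b),
        module_overlap=overlap,
    )


def first_neighbors(net: nx.Graph, seeds: list[str]) -> nx.Graph:
    """Induced subgraph on the seed nodes and their direct neighbours."""
    present = [s for s in seeds if s in net]
    missing = [s for s in seeds if s not in net]
    if not present:
        raise ValueError(f"none of the seed nodes are in the network: {missing}")
    if missing:
        warnings.warn(f"seed nodes absent from network: {missing}")
    keep = set(present)
    for s in present:
        keep.update(net.neighbors(s))
    return net.subgraph(keep).copy()
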