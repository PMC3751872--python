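"""Differential-expression calling and temporal pattern clustering.

Works on log2-scale two-channel expression measurements (genes x samples).
Significance is the classic conjunctive microarray rule: a gene responds to a
contrast when the replicate-mean |log2 ratio| reaches ``ratio_cutoff`` (default
1.0, i.e. two-fold) AND the one-sample z statistic of the replicate ratios
reaches ``z_cutoff`` (default 2.0). Temporal patterns over a time course are
summarised by Euclidean K-means on the per-time-point mean log2 ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSet",
    "ContrastResult",
    "TemporalClustering",
    "contrast",
    "call_de",
    "temporal_clusters",
]


@dataclass
class ExpressionSet:
    """Gene x sample matrix of log2 measurements with state/replicate labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    samples
        One ``(state, replicate)`` pair per matrix column. Replicate indices
        pair samples across states for contrast computation.
    values
        2-D float array, ``len(gene_ids) x len(samples)``, log2 scale.
        ``NaN`` marks a missing measurement.
    """

    gene_ids: list[str]
    samples: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )

    @property
    def states(self) -> list[str]:
        """State labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s, _ in self.samples:
            seen.setdefault(s, None)
        return list(seen)

    def columns_for(self, state: str) -> list[int]:
        """Column indices of *state*, ordered by replicate index."""
        cols = [(rep, i) for i, (s, rep) in enumerate(self.samples) if s == state]
        if not cols:
            raise KeyError(f"unknown state label: {state!r}")
        return [i for _, i in sorted(cols)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}.r{r}" for s, r in self.samples]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass
class ContrastResult:
    """Per-gene outcome of a treatment-vs-control contrast."""

    gene_id: str
    replicate_log2r: np.ndarray
    mean_log2r: float
    z_score: float
    significant: bool
    direction: str  # "up" | "down" | "none"


@dataclass
class TemporalClustering:
    """K-means partition of DE genes over a time course."""

    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    n_effective: int = field(default=0)


def contrast(
    eset: ExpressionSet, treatment: str, control: str
) -> dict[str, np.ndarray]:
    """Replicate-paired log2 ratios (treatment − control in log2 space).

    Returns a mapping gene id → vector of per-replicate log2R. Genes with a
    missing value in any replicate of either state are excluded (recorded by
    their absence from the result).

    Raises
    ------
    KeyError
        If either state label is unknown.
    ValueError
        If the two states have mismatched replicate counts.
    """
    t_cols = eset.columns_for(treatment)
    c_cols = eset.columns_for(control)
    if len(t_cols) != len(c_cols):
        raise ValueError(
            f"replicate counts differ: {treatment!r} has {len(t_cols)}, "
            f"{control!r} has {len(c_cols)}"
        )
    if len(t_cols) < 2:
        raise ValueError(f"state {treatment!r} needs >=2 replicates for a contrast")
    diff = eset.values[:, t_cols] - eset.values[:, c_cols]
    out: dict[str, np.ndarray] = {}
    for i, gene in enumerate(eset.gene_ids):
        vec = diff[i]
        if np.isnan(vec).any():
            continue
        out[gene] = vec
    return out


def call_de(
    vectors: dict[str, np.ndarray],
    ratio_cutoff: float = 1.0,
    z_cutoff: float = 2.0,
) -> list[ContrastResult]:
    """Apply the conjunctive |mean log2R| / |Z| significance rule.

    mean_log2R is the arithmetic mean of the replicate log2 ratios and
    ``z = mean / (SD / sqrt(n))`` with the sample (ddof=1) standard deviation.
    Both thresholds are inclusive. A zero-variance replicate vector gets
    ``z = ±inf`` so its significance is decided by the ratio cutoff alone.
    """
    results = []
    for gene, vec in vectors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.size < 2:
            raise ValueError(f"gene {gene}: need >=2 replicates, got {vec.size}")
        mean = float(vec.mean())
        sd = float(vec.std(ddof=1))
        if sd == 0.0:
            z = math.copysign(math.inf, mean) if mean != 0.0 else 0.0
        else:
            z = mean / (sd / math.sqrt(vec.size))
        sig = abs(mean) >= ratio_cutoff and abs(z) >= z_cutoff
        direction = "none"
        if sig:
            direction = "up" if mean > 0 else "down"
        results.append(ContrastResult(gene, vec, mean, z, sig, direction))
    return results


def de_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrast results (gene, mean_log2R, z, significant, direction)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "mean_log2R": [r.mean_log2r for r in results],
            "z": [r.z_score for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("gene")


def temporal_clusters(
    de_matrix: pd.DataFrame, k: int = 10, seed: int = 0, n_init: int = 10
) -> TemporalClustering:
    """Cluster DE genes by their time-course profile with Euclidean K-means.

    ``de_matrix`` is genes x time points of mean log2 ratios, restricted by the
    caller to genes significant in at least one time point. ``k`` defaults to
    10, the number of temporal waves the shock response resolves into. A fixed
    seed makes the partition deterministic.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError(f"k must be >=1, got {k}")
    n = de_matrix.shape[0]
    if n == 0:
        raise ValueError("empty DE matrix: no genes to cluster")
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(de_matrix.to_numpy(dtype=float))
    assignments = dict(zip(de_matrix.index, (int(c) for c in labels)))
    return TemporalClustering(
        k=k,
        assignments=assignments,
        centroids=km.cluster_centers_,
        n_effective=len(set(labels)),
    )
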