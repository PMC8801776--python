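"""Stress-expression analysis: expressed/not-expressed calls and K-means.

A gene counts as expressed when any condition exceeds 0 on the log2-TPM
scale (values < 0 denote no or very low expression).  Clustering is Lloyd's
algorithm on the raw rows, best of several restarts by within-cluster sum
of squares, with per-run seeds derived from one master seed and empty
clusters re-seeded from the point farthest from its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class DataError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class ClusteringConfig:
    """Defaults follow the survey protocol: K = 10, 1,000 iterations, 5 runs."""

    k: int = 10
    iterations: int = 1000
    runs: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError("K must be >= 1")
        if self.runs < 1:
            raise ConfigurationError("runs must be >= 1")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")


@dataclass
class ExpressedReport:
    flags: Dict[str, bool]
    expressed_fraction: float
    min_expressed: Optional[float]
    max_expressed: Optional[float]


def mark_expressed(matrix: pd.DataFrame, threshold: float = 0.0) -> ExpressedReport:
    """Expressed iff the per-gene maximum exceeds the threshold (strict).

    Also reports the observed min/max over the expressed genes' maxima so a
    real-data run can be compared against the printed expressed range.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise DataError("empty expression matrix")
    maxima = matrix.max(axis=1)
    flags = {gene: bool(maxima[gene] > threshold) for gene in matrix.index}
    expressed_max = [float(maxima[g]) for g, f in flags.items() if f]
    n = len(flags)
    return ExpressedReport(
        flags=flags,
        expressed_fraction=sum(flags.values()) / n,
        min_expressed=min(expressed_max) if expressed_max else None,
        max_expressed=max(expressed_max) if expressed_max else None,
    )


@dataclass
class KMeansResult:
    labels: Dict[str, int]
    centroids: np.ndarray
    wcss: float
    wcss_per_run: List[float]
    wcss_trajectory: List[float]  # per-iteration WCSS of the winning run


def _lloyd(
    X: np.ndarray, k: int, iterations: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, float, List[float]]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    trajectory: List[float] = []
    prev = np.inf
    for _ in range(iterations):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        reseeded = False
        for j in range(k):
            mask = labels == j
            if mask.any():
                centroids[j] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster from the globally farthest point
                far = d2.min(axis=1).argmax()
                centroids[j] = X[far]
                labels[far] = j
                reseeded = True
        wcss = float(((X - centroids[labels]) ** 2).sum())
        # Lloyd's monotonicity holds whenever no empty-cluster repair fired
        if not reseeded:
            assert wcss <= prev + 1e-8, "WCSS increased during Lloyd iteration"
        trajectory.append(wcss)
        if prev - wcss < 1e-12:
            break
        prev = wcss
    return labels, centroids, trajectory[-1], trajectory


def kmeans_cluster(matrix: pd.DataFrame, config: ClusteringConfig) -> KMeansResult:
    """Best-of-runs Lloyd K-means on the matrix rows (Euclidean)."""
    config.validate()
    n = matrix.shape[0]
    if n < config.k:
        raise ConfigurationError(f"{n} genes < K={config.k}")
    X = matrix.to_numpy(dtype=float)
    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    best: Optional[Tuple[np.ndarray, np.ndarray, float, List[float]]] = None
    per_run: List[float] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        result = _lloyd(X, config.k, config.iterations, rng)
        per_run.append(result[2])
        if best is None or result[2] < best[2]:
            best = result
    labels, centroids, wcss, trajectory = best
    return KMeansResult(
        labels={gene: int(lab) for gene, lab in zip(matrix.index, labels)},
        centroids=centroids,
        wcss=wcss,
        wcss_per_run=per_run,
        wcss_trajectory=trajectory,
    )


@dataclass
class ExpressionSummary:
    per_subfamily: pd.DataFrame  # expressed / not_expressed counts + clusters
    superclade_nonexpressed_share: Dict[str, float]  # share of all non-expressed
    expressed_fraction: float


def subfamily_expression_summary(
    matrix: pd.DataFrame,
    subfamily_of: Mapping[str, str],
    superclade_of: Mapping[str, str],
    flags: Mapping[str, bool],
    cluster_labels: Optional[Mapping[str, int]] = None,
) -> ExpressionSummary:
    """Per-subfamily expressed/non-expressed counts and cluster composition,
    plus each superclade's share of the non-expressed genes."""
    rows: Dict[str, Dict[str, object]] = {}
    for gene in matrix.index:
        subfam = subfamily_of.get(gene, "unassigned")
        row = rows.setdefault(
            subfam, {"subfamily": subfam, "expressed": 0, "not_expressed": 0,
                     "clusters": set()}
        )
        if flags.get(gene, False):
            row["expressed"] += 1
        else:
            row["not_expressed"] += 1
        if cluster_labels is not None and gene in cluster_labels:
            row["clusters"].add(cluster_labels[gene])
    table = pd.DataFrame(
        [
            {
                "subfamily": r["subfamily"],
                "expressed": r["expressed"],
                "not_expressed": r["not_expressed"],
                "n_clusters": len(r["clusters"]),
                "clusters": ",".join(str(c) for c in sorted(r["clusters"])),
            }
            for r in rows.values()
        ]
    ).sort_values("subfamily").reset_index(drop=True)

    nonexp = [g for g in matrix.index if not flags.get(g, False)]
    share: Dict[str, float] = {}
    if nonexp:
        for clade in sorted(set(superclade_of.values())):
            n = sum(1 for g in nonexp if superclade_of.get(g) == clade)
            share[clade] = 100.0 * n / len(nonexp)
    n_genes = len(matrix.index)
    expressed_fraction = sum(1 for g in matrix.index if flags.get(g, False)) / n_genes
    return ExpressionSummary(
        per_subfamily=table,
        superclade_nonexpressed_share=share,
        expressed_fraction=expressed_fraction,
    )
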