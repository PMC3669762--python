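"""Monte-Carlo consensus k-means binning of composition vectors.

Repeated randomized k-means runs are summarized by a co-clustering
support matrix: the fraction of runs in which two scaffolds landed in
the same cluster, pooled over all (k, trial) runs. Consensus bins are
the connected components of the support graph thresholded at the support
cutoff, subject to a minimum bin size; their properties are summarized
in per-bin reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import kmeans_plusplus

from matbin.composition import gc_content
from matbin.seqio import ScaffoldRecord

__all__ = [
    "ConsensusConfig",
    "ConsensusCluster",
    "CoClusterResult",
    "filter_scaffolds",
    "kmeans_trial",
    "consensus",
    "extract_clusters",
    "summarize_cluster",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Parameters of one consensus-binning run.

    Defaults follow the single-k network recipe (k=8, 100 trials,
    support >= 0.90, bins of >= 10 scaffolds, scaffolds >= 10 kb); pass
    ``k_values=range(4, 13)`` for the pooled k-range mode.
    """

    min_scaffold_length: int = 10_000
    k_values: tuple[int, ...] = (8,)
    trials_per_k: int = 100
    support_threshold: float = 0.90
    min_cluster_size: int = 10
    seed: int = 0
    init: str = "random-partition"
    empty_policy: str = "drop"

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_values", tuple(sorted(set(self.k_values))))
        if not self.k_values or min(self.k_values) < 2:
            raise ValueError("every k must be >= 2")
        if self.trials_per_k < 1:
            raise ValueError("trials_per_k must be >= 1")
        if not 0 < self.support_threshold <= 1:
            raise ValueError("support_threshold must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ConsensusCluster:
    """Table-style summary of one consensus bin."""

    member_ids: list[str]
    n_scaffolds: int
    median_size_kb: float
    mean_gc_pct: float
    sd_gc_pct: float
    total_sequence_mb: float
    mean_coverage: float | None = None
    sd_coverage: float | None = None
    site_composition: dict[str, int] = field(default_factory=dict)
    taxon: str | None = None


@dataclass
class CoClusterResult:
    """Support matrix plus demarcated consensus clusters."""

    scaffold_ids: list[str]
    support: np.ndarray  # symmetric, unit diagonal, in [0, 1]
    clusters: list[list[str]]  # member-id lists, each >= min_cluster_size
    unbinned: list[str]
    runs_executed: int
    config: ConsensusConfig

    def labels(self) -> dict[str, int]:
        """scaffold id -> cluster index; unbinned ids map to -1."""
        out = {sid: -1 for sid in self.scaffold_ids}
        for ci, members in enumerate(self.clusters):
            for sid in members:
                out[sid] = ci
        return out

    def support_edges(self, threshold: float | None = None) -> list[tuple[str, str, float]]:
        """Edges (i, j, support) with support >= threshold, i < j by index."""
        t = self.config.support_threshold if threshold is None else threshold
        ii, jj = np.nonzero(np.triu(self.support >= t, k=1))
        return [
            (self.scaffold_ids[i], self.scaffold_ids[j], float(self.support[i, j]))
            for i, j in zip(ii, jj)
        ]


def filter_scaffolds(
    records: Sequence[ScaffoldRecord], min_scaffold_length: int = 10_000
) -> tuple[list[ScaffoldRecord], int]:
    """Keep records with length >= threshold; returns (kept, n_dropped)."""
    kept = [r for r in records if len(r) >= min_scaffold_length]
    n_dropped = len(records) - len(kept)
    if not kept:
        warnings.warn(
            f"no scaffolds pass the {min_scaffold_length} bp length filter",
            stacklevel=2,
        )
    return kept, n_dropped


def _trial_seed(seed: int, k: int, trial: int) -> int:
    """Deterministic per-run seed; runs are independent of execution order."""
    ss = np.random.SeedSequence([seed, k, trial])
    return int(ss.generate_state(1)[0])


def kmeans_trial(
    feature_matrix,
    k: int,
    trial_seed: int,
    init: str = "random-partition",
    empty_policy: str = "drop",
    max_iter: int = 300,
) -> np.ndarray:
    """One Euclidean k-means (Lloyd) run, deterministic for fixed inputs.

    A single randomized initialization governed solely by ``trial_seed``.
    ``init`` is ``"random-partition"`` (centers start as means of a
    random label assignment, so well-separated populations are not
    force-split by seeding) or ``"k-means++"``. ``empty_policy`` decides
    what happens when a cluster empties during iteration: ``"drop"``
    retires it (the effective cluster count may fall below k) or
    ``"reseed-farthest"`` restarts it at the point farthest from its
    current center. Assignment ties break to the lowest cluster index
    (numpy argmin). Labels are in ``{0..k-1}``.
    """
    X = np.asarray(
        feature_matrix.to_numpy() if isinstance(feature_matrix, pd.DataFrame) else feature_matrix,
        dtype=np.float64,
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    if init not in ("random-partition", "k-means++"):
        raise ValueError(f"unknown init {init!r}")
    if empty_policy not in ("drop", "reseed-farthest"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")
    rng = np.random.default_rng(trial_seed)
    # initialization randomness is applied in a canonical (lexicographic)
    # row order so a row permutation of the input permutes the labels
    canon = np.lexsort(X.T[::-1])
    if init == "random-partition":
        canon_labels = rng.integers(0, k, n)
        canon_labels[rng.permutation(n)[:k]] = np.arange(k)  # all non-empty
        labels = np.empty(n, dtype=np.int64)
        labels[canon] = canon_labels
        C = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    else:
        C, _ = kmeans_plusplus(X[canon], k, random_state=int(trial_seed % (2**32)))
        labels = np.full(n, -1)
    Xsq = np.einsum("ij,ij->i", X, X)
    retired = np.zeros(k, dtype=bool)
    for _ in range(max_iter):
        d = Xsq[:, None] - 2.0 * (X @ C.T) + np.einsum("ij,ij->i", C, C)[None, :]
        d[:, retired] = np.inf
        new = d.argmin(axis=1)
        for j in range(k):
            if retired[j] or (new == j).any():
                continue
            if empty_policy == "reseed-farthest":
                far = int(d[np.arange(n), new].argmax())
                new[far] = j
                d[far, :] = np.inf
            else:
                retired[j] = True
        if (new == labels).all():
            break
        labels = new
        for j in range(k):
            if not retired[j] and (labels == j).any():
                C[j] = X[labels == j].mean(axis=0)
    return labels


def consensus(features, config: ConsensusConfig) -> CoClusterResult:
    """Pool co-clustering support over all (k, trial) runs and demarcate bins.

    ``support[i, j]`` is the fraction of the ``len(k_values) *
    trials_per_k`` runs in which scaffolds i and j shared a k-means
    cluster. Per-run seeds derive deterministically from ``config.seed``.
    """
    if isinstance(features, pd.DataFrame):
        ids = [str(i) for i in features.index]
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        ids = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if n < max(config.k_values):
        raise ValueError(
            f"{n} scaffolds but max k is {max(config.k_values)}; cannot cluster"
        )
    co = np.zeros((n, n), dtype=np.int64)
    runs = 0
    for k in config.k_values:
        for trial in range(config.trials_per_k):
            labels = kmeans_trial(
                X, k, _trial_seed(config.seed, k, trial),
                init=config.init, empty_policy=config.empty_policy,
            )
            same = labels[:, None] == labels[None, :]
            co += same
            runs += 1
    support = co / runs
    np.fill_diagonal(support, 1.0)
    member_sets, unbinned = extract_clusters(
        support, config.support_threshold, config.min_cluster_size
    )
    clusters = [[ids[i] for i in comp] for comp in member_sets]
    return CoClusterResult(
        scaffold_ids=ids,
        support=support,
        clusters=clusters,
        unbinned=[ids[i] for i in unbinned],
        runs_executed=runs,
        config=config,
    )


def extract_clusters(
    support: np.ndarray, threshold: float, min_cluster_size: int
) -> tuple[list[list[int]], list[int]]:
    """Connected components of the support graph thresholded at ``threshold``.

    Components with >= ``min_cluster_size`` nodes are clusters (ordered
    by decreasing size, then smallest member index); the rest are
    returned as unbinned indices.
    """
    support = np.asarray(support)
    adj = csr_matrix(np.triu(support >= threshold, k=1))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    clusters = [m for m in comps.values() if len(m) >= min_cluster_size]
    clusters.sort(key=lambda m: (-len(m), m[0]))
    unbinned = sorted(
        i for m in comps.values() if len(m) < min_cluster_size for i in m
    )
    return clusters, unbinned


def summarize_cluster(members: Sequence[ScaffoldRecord]) -> ConsensusCluster:
    """Per-bin report: median length (kb), G+C %% mean +/- SD (n-1),
    total sequence (Mb), coverage mean +/- SD when all members carry it,
    site composition, and majority taxon of annotated members."""
    if not members:
        raise ValueError("cluster must have at least one member")
    lengths = np.array([len(m) for m in members], dtype=float)
    gc_pct = np.array([gc_content(m.sequence) * 100 for m in members])
    sd = float(np.std(gc_pct, ddof=1)) if len(members) > 1 else 0.0
    covs = [m.coverage for m in members]
    mean_cov = sd_cov = None
    if all(c is not None for c in covs):
        arr = np.array(covs, dtype=float)
        mean_cov = float(arr.mean())
        sd_cov = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    sites: dict[str, int] = {}
    taxa: dict[str, int] = {}
    for m in members:
        if m.site:
            sites[m.site] = sites.get(m.site, 0) + 1
        if m.taxon:
            taxa[m.taxon] = taxa.get(m.taxon, 0) + 1
    taxon = max(taxa, key=lambda t: (taxa[t], t)) if taxa else None
    return ConsensusCluster(
        member_ids=[m.id for m in members],
        n_scaffolds=len(members),
        median_size_kb=float(np.median(lengths)) / 1_000,
        mean_gc_pct=float(gc_pct.mean()),
        sd_gc_pct=sd,
        total_sequence_mb=float(lengths.sum()) / 1_000_000,
        mean_coverage=mean_cov,
        sd_coverage=sd_cov,
        site_composition=sites,
        taxon=taxon,
    )
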