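"""Seeded co-expression network construction and weighted module detection.

Every pathology-correlated transcript seeds a neighborhood of its top 1% of
co-expression partners (signed Pearson ranking); the union of neighborhoods
forms the network. An unsigned weighted adjacency |cor|^beta is raised to a
soft-threshold power chosen for approximate scale-free topology, converted to
topological overlap, and clustered by average linkage; clusters are read off
the dendrogram by a static cut at a quantile of merge heights, small clusters
are left unassigned, and modules that contain no seed are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DegenerateInputError
from .study import ExpressionStudy

__all__ = [
    "SeededNetwork",
    "SoftPowerScan",
    "ModulePartition",
    "seed_neighborhoods",
    "select_soft_power",
    "tom_from_adjacency",
    "topological_overlap",
    "detect_modules",
    "filter_seeded_modules",
]


@dataclass
class SeededNetwork:
    """Union of per-seed co-expression neighborhoods."""

    node_ids: list[str]
    seed_ids: list[str]
    expression_submatrix: pd.DataFrame  # nodes x samples

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ConfigurationError("duplicate network nodes")
        if not set(self.seed_ids) <= set(self.node_ids):
            raise ConfigurationError("seeds must be network nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def correlation(self) -> np.ndarray:
        X = self.expression_submatrix.to_numpy()
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise DegenerateInputError("degenerate correlations: constant node profile")
        C = np.corrcoef(X)
        return np.clip(C, -1.0, 1.0)


@dataclass
class SoftPowerScan:
    candidate_powers: list[int]
    scale_free_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    reached_target: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.candidate_powers,
                "scale_free_r2": self.scale_free_r2,
                "mean_connectivity": self.mean_connectivity,
                "chosen": [p == self.chosen_power for p in self.candidate_powers],
            }
        )


@dataclass
class ModulePartition:
    """Node -> module-number assignment; module 0 is the unassigned pool."""

    assignment: dict[str, int]
    seeded_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    @property
    def module_numbers(self) -> list[int]:
        return sorted(m for m in set(self.assignment.values()) if m != 0)

    def members(self, module: int) -> list[str]:
        return sorted(t for t, m in self.assignment.items() if m == module)

    def to_frame(self, seeds: list[str] | None = None) -> pd.DataFrame:
        seed_set = set(seeds or [])
        return pd.DataFrame(
            {
                "transcript_id": list(self.assignment),
                "module_number": list(self.assignment.values()),
                "is_seed": [t in seed_set for t in self.assignment],
            }
        )


def seed_neighborhoods(study: ExpressionStudy, seeds: list[str], fraction: float = 0.01) -> SeededNetwork:
    """Per-seed top-``fraction`` Pearson co-expression neighborhoods, unioned.

    Ranking is by signed correlation, descending (co-expression, not
    anti-correlation); the neighborhood size is ceil(fraction * (N - 1)).
    Ties are broken by transcript identifier order.
    """
    if not seeds:
        raise ConfigurationError("no seeds supplied")
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    missing = [s for s in seeds if s not in study.matrix.index]
    if missing:
        raise ConfigurationError(f"seeds not in study: {missing[:10]}")
    ids = np.array(study.transcript_ids)
    X = study.matrix.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    N = len(ids)
    k = math.ceil(fraction * (N - 1))
    order_idx = np.argsort(ids)  # identifier order for deterministic ties
    nodes: set[str] = set(seeds)
    pos = {t: i for i, t in enumerate(ids)}
    for s in seeds:
        i = pos[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = (Xc @ Xc[i]) / (sd * sd[i])
        cor[i] = -np.inf  # seed excluded from its own ranking
        cor = np.where(np.isfinite(cor), cor, -np.inf)
        # stable sort on identifier-ordered array => ties broken by identifier
        ranked = order_idx[np.argsort(-cor[order_idx], kind="stable")]
        nodes.update(ids[ranked[:k]])
    node_ids = sorted(nodes)
    return SeededNetwork(node_ids, sorted(set(seeds)), study.matrix.loc[node_ids])


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) vs log10(mean k) over occupied connectivity bins."""
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    logf, logk = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            logf.append(math.log10(sel.mean()))
            logk.append(math.log10(k[sel].mean()))
    if len(logf) < 3:
        return 0.0
    r = np.corrcoef(logk, logf)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def select_soft_power(
    net: SeededNetwork, powers: list[int] | None = None, r2_target: float = 0.8
) -> SoftPowerScan:
    """Scan candidate soft-threshold powers for approximate scale-free topology.

    The chosen power is the smallest with fit R^2 >= ``r2_target``; if none
    reaches the target the argmax R^2 is chosen with a warning (smallest power
    on ties).
    """
    if net.n_nodes < 30:
        raise ConfigurationError("need >= 30 nodes for a soft-power scan")
    powers = list(powers) if powers is not None else list(range(1, 21))
    A0 = np.abs(net.correlation())
    np.fill_diagonal(A0, 0.0)
    r2s, mean_k = [], []
    for beta in powers:
        k = (A0**beta).sum(axis=0)
        r2s.append(_scale_free_r2(k))
        mean_k.append(float(k.mean()))
    reached = [p for p, r2 in zip(powers, r2s) if r2 >= r2_target]
    if reached:
        chosen, ok = min(reached), True
    else:
        best = max(r2s)
        chosen = min(p for p, r2 in zip(powers, r2s) if r2 == best)
        ok = False
        warnings.warn(
            f"no candidate power reached scale-free R^2 {r2_target}; "
            f"using power {chosen} (R^2 = {best:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return SoftPowerScan(powers, r2s, mean_k, chosen, ok)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a weighted adjacency with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with unit
    diagonal; entries lie in [0, 1] and the matrix is symmetric.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def topological_overlap(net: SeededNetwork, beta: int) -> np.ndarray:
    """Topological overlap matrix of the unsigned adjacency |cor|^beta."""
    if beta < 1:
        raise ConfigurationError("beta must be >= 1")
    return tom_from_adjacency(np.abs(net.correlation()) ** beta)


def detect_modules(
    tom: np.ndarray,
    node_ids: list[str],
    min_module_size: int = 30,
    cut_height_quantile: float = 0.9,
    rescue_percentile: float = 25.0,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static quantile cut.

    The dendrogram is cut at the configured quantile of merge heights;
    clusters smaller than ``min_module_size`` go to the unassigned pool
    (module 0). A rescue pass (in the spirit of the PAM stage of dynamic
    tree cutting) then reassigns each unassigned node to its most similar
    surviving cluster, provided its mean TOM to that cluster reaches the
    cluster's ``rescue_percentile``-th percentile of internal member
    similarity; set ``rescue_percentile=0`` to disable. Surviving clusters
    are numbered 1..M by decreasing size (ties by smallest member
    identifier).
    """
    tom = np.asarray(tom, dtype=float)
    if tom.shape[0] != tom.shape[1] or not np.allclose(tom, tom.T, atol=1e-8):
        raise ConfigurationError("TOM must be square and symmetric")
    n = tom.shape[0]
    if len(node_ids) != n:
        raise ConfigurationError("node_ids length must match TOM")
    if n < min_module_size:
        warnings.warn(
            f"{n} nodes is below min_module_size={min_module_size}; all unassigned",
            RuntimeWarning,
            stacklevel=2,
        )
        return ModulePartition({t: 0 for t in node_ids})
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    cut = float(np.quantile(Z[:, 2], cut_height_quantile))
    labels = np.asarray(fcluster(Z, t=cut, criterion="distance"))
    sizes = np.bincount(labels)
    keep = sorted(c for c in np.unique(labels) if sizes[c] >= min_module_size)
    pred = np.where(np.isin(labels, keep), labels, 0)

    if rescue_percentile > 0 and keep:
        unassigned = np.flatnonzero(pred == 0)
        if unassigned.size:
            best_sim = np.full(unassigned.size, -1.0)
            best_cluster = np.zeros(unassigned.size, dtype=int)
            thresholds: dict[int, float] = {}
            for c in keep:
                idx = np.flatnonzero(pred == c)
                internal = (tom[np.ix_(idx, idx)].sum(axis=1) - 1.0) / (len(idx) - 1)
                thresholds[c] = float(np.percentile(internal, rescue_percentile))
                sim = tom[np.ix_(unassigned, idx)].mean(axis=1)
                better = sim > best_sim
                best_sim[better] = sim[better]
                best_cluster[better] = c
            for j, u in enumerate(unassigned):
                if best_cluster[j] and best_sim[j] >= thresholds[best_cluster[j]]:
                    pred[u] = best_cluster[j]

    clusters: dict[int, list[str]] = {}
    for t, lab in zip(node_ids, pred):
        if lab:
            clusters.setdefault(int(lab), []).append(t)
    surviving = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    assignment = {t: 0 for t in node_ids}
    for number, members in enumerate(surviving, start=1):
        for t in members:
            assignment[t] = number
    return ModulePartition(assignment)


def filter_seeded_modules(partition: ModulePartition, seeds: list[str]) -> ModulePartition:
    """Keep modules containing >= 1 seed; move seedless modules' nodes to unassigned."""
    seed_set = set(seeds)
    seeded = {
        m for m in partition.module_numbers if any(t in seed_set for t in partition.members(m))
    }
    if not seeded:
        warnings.warn("no module contains a seed; all nodes unassigned", RuntimeWarning, stacklevel=2)
    assignment = {
        t: (m if m in seeded else 0) for t, m in partition.assignment.items()
    }
    return ModulePartition(assignment, seeded_flags={m: True for m in seeded})
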